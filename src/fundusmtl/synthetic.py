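"""Seeded generator of fundus-like images with exact ground truth.

Each image carries the structures the screening pipeline relies on: a
bright elliptical optic disc enclosing a brighter elliptical cup whose
vertical extents realize a known cup-to-disc ratio, a darker fovea spot
a couple of disc diameters to the side, a smooth reddish background
texture and additive Gaussian noise.  The glaucoma label is 1 exactly
when the recorded vCDR exceeds a threshold (0.6 by default), and the
positive class is held at ~10% prevalence - the imbalance the focal
loss is there to handle - by stratifying the vCDR draws rather than
rejecting whole images.

Rasterization is exact-by-construction: a pixel belongs to an ellipse
iff its center satisfies the ellipse inequality, centers sit on integer
pixels and vertical semi-axes are half-integers, so a semi-axis of
m + 0.5 spans exactly 2m + 1 rows.  The recorded "true" vCDR is the
rasterized row-span ratio (2m+1)/(2M+1) nearest the drawn value (nudged
by one row where needed to keep the label side), which a mask-based
vCDR computation recovers exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .data import FundusDataset
from .postprocess import compute_vcdr

# rendered colors (R, G, B) and fovea dip depth, on the [0, 1] scale
_BG = np.array([0.55, 0.35, 0.22])
_OD = np.array([0.88, 0.72, 0.50])
_OC = np.array([0.97, 0.88, 0.62])
_FOVEA_DEPTH = 0.35


@dataclass(frozen=True)
class SynthParams:
    """Generative knobs for the synthetic fundus dataset."""

    n_images: int = 100
    image_size: int = 64
    od_radius: tuple = (0.12, 0.20)   # base radius as fraction of image side
    radius_jitter: float = 0.2        # vertical/horizontal radii jittered +-20%
    vcdr_range: tuple = (0.3, 0.9)
    fovea_offset_diameters: tuple = (2.0, 3.0)  # distance from OD center, in OD diameters
    noise_sd: float = 0.05
    label_rule_threshold: float = 0.6
    label_noise: float = 0.0
    positive_prevalence: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        rmax = self.od_radius[1] * (1 + self.radius_jitter)
        if rmax >= 0.5:
            raise ValueError("OD radius can reach half the frame; geometry unsatisfiable")
        if not (0 < self.od_radius[0] <= self.od_radius[1]):
            raise ValueError("od_radius range invalid")
        lo, hi = self.vcdr_range
        if not (0 < lo < self.label_rule_threshold < hi < 1):
            raise ValueError("need vcdr_range[0] < label_rule_threshold < vcdr_range[1]")
        if not (0 <= self.positive_prevalence <= 1 and 0 <= self.label_noise <= 1):
            raise ValueError("probabilities must lie in [0, 1]")


def _ellipse_mask(size: int, cy: int, cx: int, ry: float, rx: float) -> np.ndarray:
    r = np.arange(size)[:, None]
    c = np.arange(size)[None, :]
    return ((c - cx) / rx) ** 2 + ((r - cy) / ry) ** 2 <= 1.0


def generate_dataset(params: SynthParams) -> FundusDataset:
    """Generate a dataset; bitwise-deterministic given ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    n, size = params.n_images, params.image_size
    vlo, vhi = params.vcdr_range
    thr = params.label_rule_threshold

    # exact stratification of the positive class
    n_pos = int(round(n * params.positive_prevalence))
    positive = np.zeros(n, dtype=bool)
    positive[rng.permutation(n)[:n_pos]] = True

    images = np.empty((n, 3, size, size), dtype=np.float32)
    od_masks = np.empty((n, size, size), dtype=np.uint8)
    oc_masks = np.empty((n, size, size), dtype=np.uint8)
    fovea = np.empty((n, 2), dtype=np.float64)
    labels = np.empty(n, dtype=np.int8)
    vcdrs = np.empty(n, dtype=np.float64)

    margin = 4  # keep the fovea spot and ellipse off the border
    for i in range(n):
        v_drawn = rng.uniform(thr, vhi) if positive[i] else rng.uniform(vlo, thr)
        base = rng.uniform(*params.od_radius) * size
        j = params.radius_jitter
        ry = base * (1 + rng.uniform(-j, j))
        rx = base * (1 + rng.uniform(-j, j))
        M = max(3, int(np.floor(ry)))
        od_ry = M + 0.5
        od_h = 2 * M + 1

        # nearest rasterizable cup span, nudged one row to respect the label side
        m = int(round((v_drawn * od_h - 1) / 2.0))
        m = min(max(m, 0), M - 1)
        if positive[i]:
            while (2 * m + 1) / od_h <= thr and m < M - 1:
                m += 1
        else:
            while (2 * m + 1) / od_h > thr and m > 0:
                m -= 1
        oc_ry = m + 0.5
        oc_rx = rx * oc_ry / od_ry
        v_true = (2 * m + 1) / od_h

        rxi = int(np.ceil(rx))
        direction = 1 if rng.random() < 0.5 else -1
        cy = int(rng.integers(M + 2, size - M - 2))
        cx_lo, cx_hi = rxi + 2, size - 3 - rxi
        diam = 2.0 * rx
        offset = rng.uniform(*params.fovea_offset_diameters) * diam
        if direction == 1:
            offset = min(offset, (size - 1 - margin) - cx_lo)
            cx = int(rng.integers(cx_lo, min(cx_hi, int(size - 1 - margin - offset)) + 1))
        else:
            offset = min(offset, cx_hi - margin)
            cx = int(rng.integers(max(cx_lo, int(margin + offset)), cx_hi + 1))
        fx = int(round(cx + direction * offset))
        fy = int(np.clip(cy + rng.integers(-3, 4), margin, size - 1 - margin))

        od = _ellipse_mask(size, cy, cx, od_ry, rx)
        oc = _ellipse_mask(size, cy, cx, oc_ry, oc_rx)

        # smooth background texture + flat-colored structures
        texture = ndimage.gaussian_filter(rng.standard_normal((size, size)), sigma=size / 8.0)
        img = np.empty((3, size, size), dtype=np.float64)
        for ch in range(3):
            plane = np.full((size, size), _BG[ch]) + 0.08 * texture
            plane[od] = _OD[ch]
            plane[oc] = _OC[ch]
            img[ch] = plane
        rr = np.arange(size)[:, None]
        cc = np.arange(size)[None, :]
        dip = np.exp(-((cc - fx) ** 2 + (rr - fy) ** 2) / (2.0 * (size / 32.0) ** 2))
        img -= _FOVEA_DEPTH * dip[None]
        img += rng.normal(0.0, params.noise_sd, size=img.shape)
        np.clip(img, 0.0, 1.0, out=img)

        label = int(v_true > thr)
        if params.label_noise > 0 and rng.random() < params.label_noise:
            label = 1 - label

        images[i] = img
        od_masks[i] = od
        oc_masks[i] = oc
        fovea[i] = (fx, fy)
        labels[i] = label
        vcdrs[i] = v_true

    return FundusDataset(
        images=images, od_masks=od_masks, oc_masks=oc_masks,
        fovea=fovea, labels=labels, vcdr_true=vcdrs,
    )


@dataclass
class GroundTruthReport:
    """Outcome of the self-consistency audit of a generated dataset."""

    n_checked: int
    violations: list
    max_vcdr_deviation: float

    @property
    def ok(self) -> bool:
        return not self.violations


def verify_ground_truth(dataset: FundusDataset, tol: float = 0.05) -> GroundTruthReport:
    """Audit a generated dataset against its own recorded ground truth.

    Checks, per image: the mask-derived vCDR agrees with the recorded
    one within ``tol``; the cup lies inside the disc; and the recorded
    fovea coordinate sits at the local intensity minimum (after 3x3 mean
    smoothing to suppress pixel noise) to within one pixel.
    """
    violations = []
    max_dev = 0.0
    for i in range(len(dataset)):
        rec = compute_vcdr(dataset.od_masks[i], dataset.oc_masks[i])
        if rec.od_empty:
            violations.append((i, "vcdr", "empty disc mask"))
        else:
            dev = abs(rec.vcdr - dataset.vcdr_true[i])
            max_dev = max(max_dev, dev)
            if dev > tol:
                violations.append((i, "vcdr", f"deviation {dev:.4f} > {tol}"))
        if np.any(dataset.oc_masks[i] & ~dataset.od_masks[i].astype(bool)):
            violations.append((i, "containment", "cup pixels outside disc"))
        fx, fy = dataset.fovea[i]
        smooth = ndimage.uniform_filter(dataset.images[i].mean(axis=0), size=3)
        r0, r1 = int(fy) - 4, int(fy) + 5
        c0, c1 = int(fx) - 4, int(fx) + 5
        win = smooth[max(r0, 0) : r1, max(c0, 0) : c1]
        rmin, cmin = np.unravel_index(np.argmin(win), win.shape)
        rmin += max(r0, 0)
        cmin += max(c0, 0)
        if max(abs(rmin - fy), abs(cmin - fx)) > 1:
            violations.append((i, "fovea", f"intensity minimum at ({cmin}, {rmin}), recorded ({fx}, {fy})"))
    return GroundTruthReport(n_checked=len(dataset), violations=violations, max_vcdr_deviation=max_dev)
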