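"""Prediction post-processing, the vCDR classifier and evaluation metrics.

The segmentation maps are thresholded at 0.5 and reduced to their main
8-connected component, removing stray prediction noise around the disc
and cup.  The vertical cup-to-disc ratio vCDR = OC_height / OD_height is
read off the cleaned masks and fed to a one-feature logistic-regression
classifier; its probability is averaged with the network's own dense
classifier head, and glaucoma is called when the average reaches 0.5.
Fovea coordinates come from the center of mass of the predicted saliency
map, deliberately without any refinement that could shift the mass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

MAP_THRESHOLD = 0.5
_CONN8 = np.ones((3, 3), dtype=int)


def largest_connected_component(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 8-connected component of a binary mask.

    An all-zero mask is returned unchanged with a warning.  The result
    is always a subset of the input and the operation is idempotent.
    """
    mask = np.asarray(mask).astype(bool)
    labels, n = ndimage.label(mask, structure=_CONN8)
    if n == 0:
        warnings.warn("empty mask: no connected component to keep", stacklevel=2)
        return mask
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


def center_of_mass(map_: np.ndarray) -> tuple[float, float]:
    """Intensity-weighted mean coordinate ``(x, y)`` of a non-negative map.

    Negative values are clipped to zero first; an all-zero result raises
    because there is no localizable mass.
    """
    m = np.clip(np.asarray(map_, dtype=np.float64), 0, None)
    total = m.sum()
    if total <= 0:
        raise ValueError("map has no positive mass; center of mass undefined")
    r = np.arange(m.shape[0], dtype=np.float64)
    c = np.arange(m.shape[1], dtype=np.float64)
    y = float((m.sum(axis=1) * r).sum() / total)
    x = float((m.sum(axis=0) * c).sum() / total)
    return x, y


@dataclass(frozen=True)
class VCDRRecord:
    """Vertical extents of cup and disc and their ratio.

    ``vcdr`` is NaN (and ``od_empty`` True) when the disc mask is empty,
    in which case the ratio is undefined.
    """

    oc_height: int
    od_height: int
    vcdr: float
    od_empty: bool = False


def _row_extent(mask: np.ndarray) -> int:
    rows = np.flatnonzero(np.asarray(mask).astype(bool).any(axis=1))
    return 0 if rows.size == 0 else int(rows[-1] - rows[0] + 1)


def compute_vcdr(od_mask: np.ndarray, oc_mask: np.ndarray) -> VCDRRecord:
    """vCDR = OC_height / OD_height from post-processed binary masks.

    Height is the occupied-row span (max - min + 1).  An empty cup gives
    vCDR 0; an empty disc leaves the ratio undefined.
    """
    od_h = _row_extent(od_mask)
    oc_h = _row_extent(oc_mask)
    if od_h == 0:
        return VCDRRecord(oc_height=oc_h, od_height=0, vcdr=float("nan"), od_empty=True)
    return VCDRRecord(oc_height=oc_h, od_height=od_h, vcdr=oc_h / od_h)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class LogisticClassifier:
    """Two-parameter logistic model on the vCDR: sigmoid(w * vcdr + b)."""

    weight: float
    bias: float
    l2_lambda: float

    def predict_proba(self, vcdr) -> np.ndarray:
        return _sigmoid(self.weight * np.asarray(vcdr, dtype=np.float64) + self.bias)


def fit_logistic(vcdrs, labels, l2_lambda: float = 1e-3) -> LogisticClassifier:
    """Fit the vCDR logistic classifier by Newton's method.

    Maximizes the log-likelihood penalized by (l2_lambda / 2) * weight^2
    (the intercept is left unpenalized, as usual); the penalty
    guarantees a finite optimum even when the vCDRs separate the
    classes perfectly.  Iterates until the gradient norm drops below
    1e-8 (at most 100 steps).
    """
    v = np.asarray(vcdrs, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    if v.shape != y.shape or v.ndim != 1 or v.size < 2:
        raise ValueError("need >= 2 paired (vcdr, label) samples")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to fit the classifier")
    if l2_lambda <= 0:
        raise ValueError("l2_lambda must be > 0")
    X = np.column_stack([v, np.ones_like(v)])
    beta = np.zeros(2)
    pen = np.diag([l2_lambda, 0.0])  # intercept unpenalized
    for _ in range(100):
        p = _sigmoid(X @ beta)
        grad = X.T @ (p - y) + pen @ beta
        if np.linalg.norm(grad) < 1e-8:
            break
        W = p * (1 - p)
        H = (X * W[:, None]).T @ X + pen
        beta = beta - np.linalg.solve(H, grad)
    return LogisticClassifier(weight=float(beta[0]), bias=float(beta[1]), l2_lambda=l2_lambda)


def ensemble_classify(fc_prob: float, lin_prob: float) -> tuple[float, int]:
    """Average the two classifier probabilities; call positive at >= 0.5.

    The tie at exactly 0.5 goes positive (screening favors sensitivity).
    """
    if not (0 <= fc_prob <= 1 and 0 <= lin_prob <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    prob = (fc_prob + lin_prob) / 2.0
    return prob, int(prob >= 0.5)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|); two empty masks agree (1.0)."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom


def roc_curve(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    """ROC points (fpr, tpr) sweeping the threshold over the scores."""
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels)
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    n_pos = int((y == 1).sum())
    n_neg = int(y.size - n_pos)
    tps = np.cumsum(y == 1)
    fps = np.cumsum(y == 0)
    # collapse tied scores to a single operating point
    distinct = np.r_[np.flatnonzero(np.diff(s)), s.size - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    return fpr, tpr


def auc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney pair statistic.

    Equals the fraction of (positive, negative) pairs ranked correctly,
    counting ties as 1/2.  Requires both classes.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0 or n_pos + n_neg != y.size:
        raise ValueError("labels must contain both classes (0/1 only)")
    from scipy.stats import rankdata

    ranks = rankdata(s)  # average ranks handle ties as 1/2
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def fovea_error(pred: tuple, truth: tuple, scale: float = 1.0) -> float:
    """Euclidean distance between predicted and true (x, y), times ``scale``."""
    dx = pred[0] - truth[0]
    dy = pred[1] - truth[1]
    return float(scale * np.hypot(dx, dy))


@dataclass
class MetricsReport:
    """Aggregate metrics plus per-image records and ROC points."""

    auc: float
    dice_od: float
    dice_od_std: float
    dice_oc: float
    dice_oc_std: float
    fovea_error: float
    fovea_error_std: float
    per_image: list = field(default_factory=list)
    roc_points: tuple | None = None

    def to_dict(self) -> dict:
        d = {
            "auc": self.auc,
            "dice_od": self.dice_od,
            "dice_od_std": self.dice_od_std,
            "dice_oc": self.dice_oc,
            "dice_oc_std": self.dice_oc_std,
            "fovea_error": self.fovea_error,
            "fovea_error_std": self.fovea_error_std,
            "per_image": self.per_image,
        }
        if self.roc_points is not None:
            d["roc_points"] = [list(map(float, p)) for p in zip(*self.roc_points)]
        return d


def predict_images(model, images: np.ndarray, batch_size: int = 8):
    """Forward a stack of images in mini-batches; returns ForwardOutputs-like dict."""
    outs = {"od_map": [], "oc_map": [], "fovea_map": [], "glaucoma_prob": []}
    for i in range(0, len(images), batch_size):
        out = model.forward(images[i : i + batch_size])
        for k in outs:
            v = getattr(out, k)
            if v is not None:
                outs[k].append(v)
    return {k: (np.concatenate(v) if v else None) for k, v in outs.items()}


def evaluate(model, dataset, logistic: LogisticClassifier | None = None, batch_size: int = 8) -> MetricsReport:
    """Full evaluation pipeline on a dataset with ground truth.

    Per image: maps are thresholded at 0.5 and reduced to their main
    connected component before Dice and vCDR; the fovea is read as the
    saliency map's center of mass; the glaucoma score is the ensemble
    average (or the dense head alone when no vCDR classifier is given or
    the disc mask comes out empty).  Degenerate per-image failures are
    recorded as diagnostics instead of aborting the report.
    """
    preds = predict_images(model, dataset.images, batch_size=batch_size)
    n = len(dataset.images)
    dices_od, dices_oc, ferrs, scores, recs = [], [], [], [], []
    for i in range(n):
        rec = {"image_id": dataset.ids[i]}
        vcdr = float("nan")
        if preds["od_map"] is not None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                od = largest_connected_component(preds["od_map"][i] >= MAP_THRESHOLD)
                oc = largest_connected_component(preds["oc_map"][i] >= MAP_THRESHOLD)
            rec["dice_od"] = dice(od, dataset.od_masks[i])
            rec["dice_oc"] = dice(oc, dataset.oc_masks[i])
            dices_od.append(rec["dice_od"])
            dices_oc.append(rec["dice_oc"])
            r = compute_vcdr(od, oc)
            vcdr = r.vcdr
            rec["vcdr"] = None if r.od_empty else r.vcdr
            if r.od_empty:
                rec["diagnostic"] = "empty disc prediction; vCDR undefined"
        if preds["fovea_map"] is not None:
            try:
                xy = center_of_mass(preds["fovea_map"][i])
                rec["fovea_x"], rec["fovea_y"] = xy
                rec["fovea_error"] = fovea_error(xy, tuple(dataset.fovea[i]))
                ferrs.append(rec["fovea_error"])
            except ValueError as e:
                rec["diagnostic"] = f"fovea: {e}"
        if preds["glaucoma_prob"] is not None:
            fc = float(preds["glaucoma_prob"][i])
            rec["prob_fc"] = fc
            if logistic is not None and np.isfinite(vcdr):
                lin = float(logistic.predict_proba(vcdr))
                rec["prob_lin"] = lin
                rec["prob_avg"], rec["label_pred"] = ensemble_classify(fc, lin)
            else:
                rec["prob_lin"] = None
                rec["prob_avg"], rec["label_pred"] = fc, int(fc >= 0.5)
            scores.append(rec["prob_avg"])
        recs.append(rec)

    def _ms(v):
        return (float(np.mean(v)), float(np.std(v))) if v else (float("nan"), float("nan"))

    auc_val, roc = float("nan"), None
    if scores and dataset.labels is not None and len(np.unique(dataset.labels)) == 2:
        auc_val = auc(np.asarray(scores), np.asarray(dataset.labels))
        roc = roc_curve(np.asarray(scores), np.asarray(dataset.labels))
    m_od, s_od = _ms(dices_od)
    m_oc, s_oc = _ms(dices_oc)
    m_f, s_f = _ms(ferrs)
    return MetricsReport(
        auc=auc_val,
        dice_od=m_od, dice_od_std=s_od,
        dice_oc=m_oc, dice_oc_std=s_oc,
        fovea_error=m_f, fovea_error_std=s_f,
        per_image=recs,
        roc_points=roc,
    )
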