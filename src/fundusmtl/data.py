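"""In-memory dataset container shared by the generator, loaders and training."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class FundusDataset:
    """A stack of fundus images with whatever ground truth is available.

    ``images``: (N, 3, S, S) float32 in [0, 1].  ``od_masks``/``oc_masks``:
    (N, S, S) uint8 binary, or None when segmentation truth is absent.
    ``fovea``: (N, 2) float (x=column, y=row, 0-based, fractional allowed;
    NaN rows mark missing annotations).  ``labels``: (N,) int8 glaucoma
    labels (-1 marks missing).  ``vcdr_true`` is carried by the synthetic
    generator for bookkeeping and absent for real data.
    """

    images: np.ndarray
    od_masks: np.ndarray | None = None
    oc_masks: np.ndarray | None = None
    fovea: np.ndarray | None = None
    labels: np.ndarray | None = None
    vcdr_true: np.ndarray | None = None
    ids: list = field(default_factory=list)

    def __post_init__(self):
        if not self.ids:
            self.ids = [f"img{i:05d}" for i in range(len(self.images))]
        if len(self.ids) != len(self.images):
            raise ValueError("ids and images length mismatch")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def image_size(self) -> int:
        return self.images.shape[-1]

    def subset(self, idx) -> "FundusDataset":
        idx = np.asarray(idx)
        if idx.dtype != bool:
            idx = idx.astype(np.intp)
        else:
            idx = np.flatnonzero(idx)
        pick = lambda a: None if a is None else a[idx]
        return FundusDataset(
            images=self.images[idx],
            od_masks=pick(self.od_masks),
            oc_masks=pick(self.oc_masks),
            fovea=pick(self.fovea),
            labels=pick(self.labels),
            vcdr_true=pick(self.vcdr_true),
            ids=[self.ids[i] for i in idx],
        )
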