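"""Multi-rater reference construction by per-voxel majority voting.

Several experts contour the resection cavity independently; the reference
segmentation keeps each voxel marked by a strict majority of them (2 of 3
for three raters).  Fusion is purely voxel-wise: no smoothing or
connected-component postprocessing is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ConformanceError, LabelMap
from .evaluation import dice

__all__ = ["RaterSet", "majority_vote", "pairwise_agreement"]


@dataclass
class RaterSet:
    """The label maps drawn by each rater for one case, on one grid."""

    case_id: str
    masks: list[LabelMap]
    rater_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.masks:
            raise ValueError("RaterSet needs at least one rater")
        if not self.rater_labels:
            self.rater_labels = [f"rater{i + 1}" for i in range(len(self.masks))]
        if len(self.rater_labels) != len(self.masks):
            raise ValueError("rater_labels must match masks one-to-one")
        ref = self.masks[0].geometry
        mismatched = [
            self.rater_labels[i]
            for i, m in enumerate(self.masks)
            if not m.geometry.matches(ref)
        ]
        if mismatched:
            raise ConformanceError(f"rater masks on mixed grids: {mismatched}")

    def __len__(self) -> int:
        return len(self.masks)


def majority_vote(
    raters: RaterSet, threshold: int | None = None, include_ties: bool = False
) -> LabelMap:
    """Fuse rater masks: foreground iff the vote count reaches the threshold.

    The default threshold is a strict majority, ``floor(N/2) + 1`` (2 of 3
    raters).  For even rater counts a tie (exactly N/2 votes) is background
    unless ``include_ties`` is set.
    """
    n = len(raters)
    if threshold is None:
        threshold = n // 2 + 1
        if include_ties and n % 2 == 0:
            threshold = n // 2
    if not 1 <= threshold <= n:
        raise ValueError(f"threshold must be in [1, {n}], got {threshold}")
    votes = np.zeros(raters.masks[0].values.shape, dtype=np.int32)
    for m in raters.masks:
        votes += m.values
    fused = (votes >= threshold).astype(np.uint8)
    return LabelMap(values=fused, geometry=raters.masks[0].geometry)


def pairwise_agreement(raters: RaterSet) -> np.ndarray:
    """Symmetric matrix of pairwise Dice coefficients between raters."""
    if len(raters) < 2:
        raise ValueError("pairwise agreement needs at least 2 raters")
    k = len(raters)
    out = np.empty((k, k), dtype=float)
    for i in range(k):
        for j in range(i, k):
            d = dice(raters.masks[i], raters.masks[j])
            out[i, j] = out[j, i] = d
    return out
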