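"""Tri-planar (2.5D) inference: slice-wise prediction along the three
orthogonal planes, probability averaging, and binarization.

The 2D network is applied to every axial, coronal and sagittal slice of a
study in evaluation mode; each orientation yields a full 3D foreground
probability volume, and the final volume is the voxel-wise average of the
three.  The decision rule thresholds the averaged foreground probability at
0.5 (equivalent to argmax of the averaged two-class output); a binary
majority vote over the three per-orientation masks is available as an
alternative fusion mode.  No morphological postprocessing is applied.
"""

from __future__ import annotations

import numpy as np

from .core import ConfigurationError, ConformanceError, LabelMap, MultimodalStudy, ProbabilityMap
from .nn import FCDenseNet
from .preprocess import zscore_normalize
from .trainer import ORIENTATIONS

__all__ = [
    "predict_planewise",
    "fuse_triplanar",
    "binarize",
    "segment_study",
]


def predict_planewise(
    network: FCDenseNet,
    study: MultimodalStudy,
    orientation: str,
    batch_size: int = 16,
) -> ProbabilityMap:
    """Foreground probabilities from slice-wise evaluation along one plane.

    Every slice along the orientation axis is forwarded in evaluation mode
    (deterministic: dropout off, running normalization statistics) and the
    per-slice foreground probabilities are reassembled on the study grid.
    """
    if orientation not in ORIENTATIONS:
        raise ConfigurationError(f"unknown orientation {orientation!r}")
    axis = ORIENTATIONS[orientation]
    channels = study.channels().astype(network.dtype)
    n_slices = channels.shape[axis + 1]
    # move the slicing axis to the batch position: (n_slices, C, a, b)
    stack = np.moveaxis(channels, axis + 1, 0)
    out = np.empty(stack.shape[0:1] + stack.shape[2:], dtype=np.float64)
    for start in range(0, n_slices, batch_size):
        batch = np.ascontiguousarray(stack[start:start + batch_size])
        probs = network.forward(batch, training=False)
        out[start:start + batch_size] = probs[:, 1]
    volume = np.moveaxis(out, 0, axis)
    return ProbabilityMap(values=volume, geometry=study.geometry)


def fuse_triplanar(
    p_axial: ProbabilityMap, p_coronal: ProbabilityMap, p_sagittal: ProbabilityMap
) -> ProbabilityMap:
    """Voxel-wise arithmetic mean of the three plane-wise predictions."""
    maps = (p_axial, p_coronal, p_sagittal)
    ref = maps[0].geometry
    if not all(m.geometry.matches(ref) for m in maps[1:]):
        raise ConformanceError("tri-planar fusion requires maps on one grid")
    mean = (maps[0].values + maps[1].values + maps[2].values) / 3.0
    return ProbabilityMap(values=mean, geometry=ref)


def binarize(prob: ProbabilityMap, threshold: float = 0.5) -> LabelMap:
    """Foreground iff probability ≥ threshold (default 0.5 = argmax)."""
    if not 0.0 < threshold < 1.0:
        raise ConfigurationError(f"threshold must be in (0, 1), got {threshold}")
    return LabelMap(values=(prob.values >= threshold).astype(np.uint8),
                    geometry=prob.geometry)


def segment_study(
    network: FCDenseNet,
    study: MultimodalStudy,
    threshold: float = 0.5,
    normalize: bool = False,
    vote_fusion: bool = False,
    batch_size: int = 16,
) -> tuple[LabelMap, ProbabilityMap]:
    """Full 2.5D segmentation of one study: three plane-wise predictions,
    fusion, binarization.  Returns the mask and the fused probability map.

    With ``vote_fusion`` the three plane-wise predictions are binarized
    first and fused by 2-of-3 majority instead of probability averaging.
    """
    if normalize:
        study, _ = zscore_normalize(study)
    per_plane = {
        name: predict_planewise(network, study, name, batch_size=batch_size)
        for name in ("axial", "coronal", "sagittal")
    }
    fused = fuse_triplanar(per_plane["axial"], per_plane["coronal"], per_plane["sagittal"])
    if vote_fusion:
        votes = sum(
            (p.values >= threshold).astype(np.int32) for p in per_plane.values()
        )
        mask = LabelMap(values=(votes >= 2).astype(np.uint8), geometry=study.geometry)
    else:
        mask = binarize(fused, threshold)
    return mask, fused
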