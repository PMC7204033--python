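"""Intensity normalization applied before training and inference.

Skull-stripped input is zero-filled outside the brain, so the brain support
is recovered as the union of nonzero voxels across channels, and z-score
statistics are computed over that support only (per channel, per case) to
keep the zeroed background from dominating the mean and standard deviation.
The population (n) standard deviation is used, which makes normalization
exactly idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DegenerateInputError, LabelMap, MultimodalStudy, SEQUENCES

__all__ = ["NormalizationParams", "foreground_mask", "zscore_normalize"]


@dataclass(frozen=True)
class NormalizationParams:
    """Per-channel mean and standard deviation removed by normalization."""

    mu: dict[str, float]
    sigma: dict[str, float]

    def __post_init__(self) -> None:
        bad = [k for k, s in self.sigma.items() if not s > 0]
        if bad:
            raise ValueError(f"sigma must be > 0 for every channel, offending: {bad}")


def foreground_mask(study: MultimodalStudy) -> LabelMap:
    """Brain support mask: a voxel is foreground iff any channel is nonzero."""
    fg = np.any(study.channels() != 0, axis=0)
    if not fg.any():
        raise DegenerateInputError(f"study {study.case_id!r} is all-zero: no brain present")
    return LabelMap(values=fg.astype(np.uint8), geometry=study.geometry)


def zscore_normalize(
    study: MultimodalStudy, mask: LabelMap | None = None
) -> tuple[MultimodalStudy, NormalizationParams]:
    """Normalize each channel to mean 0, sd 1 within the brain mask.

    Voxels outside the mask are forced to exactly 0 so that background-only
    slices stay constant.  Raises :class:`DegenerateInputError` when a channel
    is constant inside the mask (σ undefined).
    """
    if mask is None:
        mask = foreground_mask(study)
    fg = mask.values.astype(bool)
    if fg.sum() < 2:
        raise DegenerateInputError("normalization needs at least 2 foreground voxels")

    channels = study.channels()
    mu: dict[str, float] = {}
    sigma: dict[str, float] = {}
    out = np.zeros_like(channels)
    for i, name in enumerate(SEQUENCES):
        inside = channels[i][fg]
        m = float(inside.mean())
        s = float(inside.std())  # population sd
        if s == 0.0:
            raise DegenerateInputError(f"channel {name!r} is constant inside the brain mask")
        mu[name] = m
        sigma[name] = s
        out[i][fg] = (channels[i][fg] - m) / s
    normalized = MultimodalStudy.from_channels(study.case_id, out, study.geometry)
    return normalized, NormalizationParams(mu=mu, sigma=sigma)
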