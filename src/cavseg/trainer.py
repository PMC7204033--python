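"""Slice sampling, the optimization loop, and cross-validation partitioning.

Training follows the slice-wise 2.5D protocol: batches of 16 two-dimensional
slices of random orientation (axial, coronal or sagittal) are drawn from the
normalized training cases, and the pixel-wise cross-entropy loss is
minimized with Adam at learning rate 1e-4.  Only slices that intersect the
brain foreground are eligible — background-only slices carry no gradient
signal under plain cross-entropy.  No class weighting, augmentation or
learning-rate schedule is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ConfigurationError, LabelMap, MultimodalStudy
from .nn import Adam, FCDenseNet, softmax_cross_entropy
from .preprocess import foreground_mask

__all__ = [
    "ORIENTATIONS",
    "TrainingConfig",
    "FoldSplit",
    "SliceBatch",
    "TrainingDivergenceError",
    "make_cv_splits",
    "SliceSampler",
    "sample_slice_batch",
    "train",
]

#: orientation name → volume axis sliced over (x=sagittal, y=coronal, z=axial)
ORIENTATIONS = {"sagittal": 0, "coronal": 1, "axial": 2}


class TrainingDivergenceError(RuntimeError):
    """Loss became non-finite during optimization."""

    def __init__(self, step: int):
        super().__init__(f"training loss became non-finite at step {step}")
        self.step = step


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization protocol parameters."""

    batch_size: int = 16
    learning_rate: float = 1e-4
    optimizer: str = "adam"
    loss: str = "cross_entropy"
    epochs: int = 1
    steps_per_epoch: int = 100
    seed: int = 0
    orientations: tuple[str, ...] = ("axial", "coronal", "sagittal")

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if self.learning_rate < 0:
            raise ConfigurationError("learning_rate must be >= 0")
        if self.epochs < 1 or self.steps_per_epoch < 1:
            raise ConfigurationError("epochs and steps_per_epoch must be >= 1")
        if self.optimizer != "adam":
            raise ConfigurationError(f"unknown optimizer {self.optimizer!r}")
        if self.loss != "cross_entropy":
            raise ConfigurationError(f"unknown loss {self.loss!r}")
        bad = [o for o in self.orientations if o not in ORIENTATIONS]
        if bad or not self.orientations:
            raise ConfigurationError(f"invalid orientations: {bad or 'empty'}")

    @property
    def total_steps(self) -> int:
        return self.epochs * self.steps_per_epoch


@dataclass(frozen=True)
class FoldSplit:
    """One cross-validation fold: disjoint train/test case-id lists."""

    fold_index: int
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    is_tuning_fold: bool = False

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test ids overlap")


@dataclass
class SliceBatch:
    """A stack of same-size 2D multi-channel slices with optional targets."""

    slices: np.ndarray  # (B, C, H, W)
    orientations: list[str]
    targets: np.ndarray | None = None  # (B, H, W) in {0, 1}

    def __post_init__(self) -> None:
        if self.slices.ndim != 4:
            raise ValueError("slices must be (B, C, H, W)")
        if len(self.orientations) != self.slices.shape[0]:
            raise ValueError("one orientation tag per slice required")
        if self.targets is not None and self.targets.shape != (
            self.slices.shape[0], *self.slices.shape[2:]
        ):
            raise ValueError("targets must match slices in batch and spatial shape")


def make_cv_splits(case_ids: list[str], k: int, seed: int) -> list[FoldSplit]:
    """Random k-fold partition: test sets cover every case exactly once,
    sizes differ by at most one, and exactly one fold (the first) is flagged
    for hyperparameter tuning.  Deterministic for a fixed seed.
    """
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    if k > len(case_ids):
        raise ConfigurationError(f"k={k} exceeds number of cases ({len(case_ids)})")
    ids = list(case_ids)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    shuffled = [ids[i] for i in order]
    chunks = np.array_split(np.arange(len(ids)), k)
    folds = []
    for f, chunk in enumerate(chunks):
        test = tuple(shuffled[i] for i in chunk)
        train = tuple(c for c in shuffled if c not in test)
        folds.append(FoldSplit(fold_index=f, train_ids=train, test_ids=test,
                               is_tuning_fold=(f == 0)))
    return folds


class SliceSampler:
    """Uniform sampler over (case, orientation, foreground-intersecting slice)."""

    def __init__(
        self,
        studies: list[tuple[MultimodalStudy, LabelMap]],
        orientations: tuple[str, ...] = ("axial", "coronal", "sagittal"),
    ):
        if not studies:
            raise ValueError("need at least one study")
        self.orientations = tuple(orientations)
        self._channels = []
        self._targets = []
        self._eligible: list[dict[str, np.ndarray]] = []
        any_eligible = False
        for study, ref in studies:
            if not ref.geometry.matches(study.geometry):
                raise ValueError(f"reference grid mismatch for case {study.case_id!r}")
            chans = study.channels().astype(np.float32)
            fg = foreground_mask(study).values.astype(bool)
            per_orient: dict[str, np.ndarray] = {}
            for name in self.orientations:
                axis = ORIENTATIONS[name]
                reduce_axes = tuple(a for a in range(3) if a != axis)
                idx = np.flatnonzero(fg.any(axis=reduce_axes))
                per_orient[name] = idx
                if idx.size:
                    any_eligible = True
            self._channels.append(chans)
            self._targets.append(ref.values)
            self._eligible.append(per_orient)
        if not any_eligible:
            raise ValueError("no foreground-intersecting slices in any study")

    def _draw_one(self, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, str]:
        while True:
            s = rng.integers(len(self._channels))
            orient = self.orientations[rng.integers(len(self.orientations))]
            idx = self._eligible[s][orient]
            if idx.size == 0:
                continue
            i = int(idx[rng.integers(idx.size)])
            axis = ORIENTATIONS[orient]
            sl = np.take(self._channels[s], i, axis=axis + 1)  # (C, a, b)
            tgt = np.take(self._targets[s], i, axis=axis)
            return sl, tgt, orient

    def sample(self, batch_size: int, rng: np.random.Generator) -> SliceBatch:
        slices, targets, orients = [], [], []
        for _ in range(batch_size):
            sl, tgt, o = self._draw_one(rng)
            slices.append(sl)
            targets.append(tgt)
            orients.append(o)
        shapes = {s.shape for s in slices}
        if len(shapes) > 1:  # mixed grids: zero-pad to the batch maximum
            hmax = max(s.shape[1] for s in slices)
            wmax = max(s.shape[2] for s in slices)
            slices = [
                np.pad(s, ((0, 0), (0, hmax - s.shape[1]), (0, wmax - s.shape[2])))
                for s in slices
            ]
            targets = [
                np.pad(t, ((0, hmax - t.shape[0]), (0, wmax - t.shape[1])))
                for t in targets
            ]
        return SliceBatch(
            slices=np.stack(slices),
            orientations=orients,
            targets=np.stack(targets),
        )


def sample_slice_batch(
    studies: list[tuple[MultimodalStudy, LabelMap]],
    config: TrainingConfig,
    rng: np.random.Generator,
) -> SliceBatch:
    """Draw one training batch per the slice-sampling protocol."""
    sampler = SliceSampler(studies, config.orientations)
    return sampler.sample(config.batch_size, rng)


def train(
    network: FCDenseNet,
    training_cases: list[tuple[MultimodalStudy, LabelMap]],
    config: TrainingConfig,
) -> tuple[FCDenseNet, list[float]]:
    """Optimize the network in place; returns it with the per-step loss history.

    Cases must already be normalized and fused.  Reproducible for a fixed
    seed: the sampling and dropout streams are derived from ``config.seed``.
    """
    sampler = SliceSampler(training_cases, config.orientations)
    rng_sample = np.random.default_rng([config.seed, 1])
    rng_dropout = np.random.default_rng([config.seed, 2])
    params = [p for _, p in network.named_params()]
    opt = Adam(params, lr=config.learning_rate)
    history: list[float] = []
    for step in range(config.total_steps):
        batch = sampler.sample(config.batch_size, rng_sample)
        logits = network.forward_logits(batch.slices, training=True, rng=rng_dropout)
        loss, dlogits = softmax_cross_entropy(logits, batch.targets)
        if not np.isfinite(loss):
            raise TrainingDivergenceError(step)
        opt.zero_grad()
        network.backward(dlogits.astype(network.dtype))
        opt.step()
        history.append(loss)
    return network, history
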