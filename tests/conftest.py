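"""Shared fixtures: geometry helpers, phantom cohorts, and the expensive
session-scoped training runs reused by the trainer and acceptance tests."""

from __future__ import annotations

import time
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cavseg.core import (
    Geometry,
    LabelMap,
    load_labelmap,
    load_study,
    read_case_manifest,
    read_cohort_manifest,
)
from cavseg.evaluation import dice
from cavseg.fusion import RaterSet, majority_vote
from cavseg.inference import segment_study
from cavseg.nn import ArchitectureConfig, build_network
from cavseg.phantom import PhantomSpec, RaterPerturbation, generate_cohort, generate_phantom
from cavseg.preprocess import zscore_normalize
from cavseg.trainer import TrainingConfig, make_cv_splits, train

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: the reduced architecture used for all scaled-down phantom experiments
REDUCED_ARCH = dict(stem_channels=16, growth_rate=4, units_per_block=2, levels=2)

#: training protocol for the scaled-down phantom experiments (the library
#: default learning rate 1e-4 suits long clinical training runs; the small
#: phantom runs use 1e-3)
PHANTOM_LR = 1e-3


def make_geometry(shape=(8, 8, 8), spacing=(1.0, 1.0, 1.0)) -> Geometry:
    return Geometry(shape=tuple(shape), spacing=tuple(spacing),
                    affine=np.diag([*spacing, 1.0]))


def mask_from(values: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> LabelMap:
    values = np.asarray(values, dtype=np.uint8)
    return LabelMap(values=values, geometry=make_geometry(values.shape, spacing))


def load_cohort(manifest_path: Path) -> dict[str, dict]:
    """Load every case of a cohort manifest into memory."""
    cohort = {}
    for cid, case_manifest in read_cohort_manifest(manifest_path).items():
        entries = read_case_manifest(case_manifest)
        study = load_study(entries, case_id=cid)
        rater_keys = sorted(k for k in entries if k.startswith("rater"))
        raters = RaterSet(
            case_id=cid,
            masks=[load_labelmap(entries[k], study) for k in rater_keys],
            rater_labels=rater_keys,
        )
        cohort[cid] = {
            "study": study,
            "raters": raters,
            "reference": majority_vote(raters),
            "truth": load_labelmap(entries["truth"], study) if "truth" in entries else None,
        }
    return cohort


@pytest.fixture(scope="session")
def reduced_arch() -> ArchitectureConfig:
    return ArchitectureConfig(in_channels=4, dropout_p=0.2, **REDUCED_ARCH)


@pytest.fixture(scope="session")
def small_phantom():
    """One quick 32³ phantom with simulated raters, for unit tests."""
    spec = PhantomSpec(shape=(32, 32, 32), cavity_radii_mm=(8.0, 14.0))
    study, reference, components = generate_phantom(spec, seed=42)
    return {"spec": spec, "study": study, "reference": reference,
            "components": components}


@pytest.fixture(scope="session")
def phantom_cohort64(tmp_path_factory) -> Path:
    """The 6-case 64³ study cohort used by the learnability experiments."""
    out = tmp_path_factory.mktemp("cohort64")
    return generate_cohort(6, PhantomSpec(), RaterPerturbation(), seed=11,
                           out_dir=out)


@pytest.fixture(scope="session")
def overfit_results(reduced_arch):
    """Overfit fixture: 2 clean-reference 48³ phantom cases, 200 steps,
    3 seeds.  Returns loss history endpoints and training-set Dice per seed.
    """
    spec = PhantomSpec(shape=(48, 48, 48))
    results = []
    for seed in (0, 1, 2):
        cases = []
        for i in range(2):
            study, ref, _ = generate_phantom(spec, seed=400 + 10 * seed + i)
            norm, _ = zscore_normalize(study)
            cases.append((norm, ref))
        net = build_network(reduced_arch, seed=seed)
        tc = TrainingConfig(learning_rate=PHANTOM_LR, epochs=2,
                            steps_per_epoch=100, seed=seed)
        net, hist = train(net, cases, tc)
        train_dice = [dice(segment_study(net, s)[0], r) for s, r in cases]
        results.append({
            "seed": seed,
            "initial_loss": hist[0],
            "final_loss": hist[-1],
            "history": hist,
            "train_dice": train_dice,
        })
    return results


@pytest.fixture(scope="session")
def crossval_config_yaml(tmp_path_factory) -> Path:
    """Run config for the scaled-down crossval experiments."""
    path = tmp_path_factory.mktemp("config") / "reduced.yaml"
    path.write_text(
        "architecture:\n"
        f"  stem_channels: {REDUCED_ARCH['stem_channels']}\n"
        f"  growth_rate: {REDUCED_ARCH['growth_rate']}\n"
        f"  units_per_block: {REDUCED_ARCH['units_per_block']}\n"
        f"  levels: {REDUCED_ARCH['levels']}\n"
        "training:\n"
        f"  learning_rate: {PHANTOM_LR}\n"
        "  epochs: 1\n"
        "  steps_per_epoch: 120\n"
    )
    return path


@pytest.fixture(scope="session")
def learnability_results(phantom_cohort64, crossval_config_yaml, reduced_arch,
                         tmp_path_factory):
    """Scaled-down learnability protocol on the 6-case 64³ cohort.

    Seed 0: a full 3-fold cross-validation through the CLI (every case
    predicted once by a network that never saw it).  Seeds 1 and 2: one
    train/test fold each through the library API.  Returns the held-out
    median Dice (prediction vs fused reference) per seed and the crossval
    wall time.
    """
    import pandas as pd
    from click.testing import CliRunner

    from cavseg.cli import main

    out = tmp_path_factory.mktemp("crossval")
    t0 = time.time()
    result = CliRunner().invoke(main, [
        "crossval", "--manifest", str(phantom_cohort64),
        "--config", str(crossval_config_yaml),
        "--k", "3", "--seed", "0", "--out", str(out),
    ])
    elapsed = time.time() - t0
    assert result.exit_code == 0, result.output
    records = pd.read_csv(out / "metrics.csv")
    heldout = {0: float(records.loc[records["pairing"] == "auto-reference",
                                    "dice"].median())}

    cohort = load_cohort(phantom_cohort64)
    ids = sorted(cohort)
    for seed in (1, 2):
        fold = make_cv_splits(ids, 3, seed=seed)[0]
        cases = []
        for cid in fold.train_ids:
            norm, _ = zscore_normalize(cohort[cid]["study"])
            cases.append((norm, cohort[cid]["reference"]))
        net = build_network(reduced_arch, seed=seed)
        tc = TrainingConfig(learning_rate=PHANTOM_LR, epochs=1,
                            steps_per_epoch=120, seed=seed)
        net, _ = train(net, cases, tc)
        ds = []
        for cid in fold.test_ids:
            mask, _ = segment_study(net, cohort[cid]["study"], normalize=True)
            ds.append(dice(mask, cohort[cid]["reference"]))
        heldout[seed] = float(np.median(ds))
    return {"heldout_median_dice": heldout, "crossval_seconds": elapsed,
            "crossval_dir": out, "metrics": records}
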