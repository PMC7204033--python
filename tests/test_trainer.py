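"""Cross-validation partitioning, slice sampling, and the training loop."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cavseg.core import ConfigurationError, LabelMap, MultimodalStudy
from cavseg.nn import ArchitectureConfig, build_network
from cavseg.phantom import PhantomSpec, generate_phantom
from cavseg.preprocess import zscore_normalize
from cavseg.trainer import (
    SliceSampler,
    TrainingConfig,
    TrainingDivergenceError,
    make_cv_splits,
    sample_slice_batch,
    train,
)

from conftest import make_geometry

MICRO_ARCH = ArchitectureConfig(in_channels=4, stem_channels=4, growth_rate=2,
                                units_per_block=1, levels=2, dropout_p=0.2)


class TestTrainingConfig:
    def test_protocol_defaults(self):
        config = TrainingConfig()
        assert config.batch_size == 16
        assert config.learning_rate == pytest.approx(1e-4)
        assert config.optimizer == "adam"
        assert config.loss == "cross_entropy"
        assert set(config.orientations) == {"axial", "coronal", "sagittal"}

    @pytest.mark.parametrize("bad", [{"batch_size": 0}, {"epochs": 0},
                                     {"orientations": ("oblique",)},
                                     {"optimizer": "sgd"}])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            TrainingConfig(**bad)


class TestMakeCvSplits:
    def test_thirty_cases_six_folds(self):
        ids = [f"case{i:02d}" for i in range(30)]
        folds = make_cv_splits(ids, 6, seed=0)
        assert len(folds) == 6
        assert all(len(f.test_ids) == 5 for f in folds)
        assert all(len(f.train_ids) == 25 for f in folds)
        assert sum(f.is_tuning_fold for f in folds) == 1

    def test_twelve_cases_six_folds(self):
        folds = make_cv_splits([str(i) for i in range(12)], 6, seed=1)
        assert all(len(f.test_ids) == 2 for f in folds)

    def test_deterministic_per_seed(self):
        ids = [str(i) for i in range(10)]
        assert make_cv_splits(ids, 3, seed=5) == make_cv_splits(ids, 3, seed=5)
        assert make_cv_splits(ids, 3, seed=5) != make_cv_splits(ids, 3, seed=6)

    def test_k_larger_than_cohort_rejected(self):
        with pytest.raises(ConfigurationError):
            make_cv_splits(["a", "b"], 3, seed=0)

    @given(st.integers(5, 40), st.integers(2, 8), st.integers(0, 2**31 - 1))
    def test_partition_invariants(self, n, k, seed):
        if k > n:
            return
        ids = [f"c{i}" for i in range(n)]
        folds = make_cv_splits(ids, k, seed)
        all_test = [cid for f in folds for cid in f.test_ids]
        assert sorted(all_test) == sorted(ids)  # coverage, each exactly once
        sizes = [len(f.test_ids) for f in folds]
        assert max(sizes) - min(sizes) <= 1
        for f in folds:
            assert not set(f.train_ids) & set(f.test_ids)
            assert sorted(f.train_ids + f.test_ids) == sorted(ids)


def _phantom_case(seed=0, shape=(24, 24, 24)):
    spec = PhantomSpec(shape=shape, cavity_radii_mm=(6.0, 10.0))
    study, ref, _ = generate_phantom(spec, seed=seed)
    norm, _ = zscore_normalize(study)
    return norm, ref


class TestSliceSampling:
    def test_batch_shape_and_binary_targets(self):
        case = _phantom_case()
        config = TrainingConfig()
        batch = sample_slice_batch([case], config, np.random.default_rng(0))
        assert batch.slices.shape == (16, 4, 24, 24)
        assert set(np.unique(batch.targets)) <= {0, 1}
        assert len(batch.orientations) == 16

    def test_restricted_orientation_tags(self):
        case = _phantom_case()
        config = TrainingConfig(orientations=("axial",))
        batch = sample_slice_batch([case], config, np.random.default_rng(0))
        assert set(batch.orientations) == {"axial"}

    def test_reproducible_for_fixed_rng_state(self):
        case = _phantom_case()
        config = TrainingConfig()
        a = sample_slice_batch([case], config, np.random.default_rng(3))
        b = sample_slice_batch([case], config, np.random.default_rng(3))
        np.testing.assert_array_equal(a.slices, b.slices)
        assert a.orientations == b.orientations

    def test_only_foreground_intersecting_slices(self):
        # brain occupies a thin axial slab; every sampled axial slice must
        # intersect it
        channels = np.zeros((4, 16, 16, 16))
        channels[:, :, :, 7:9] = 1.0 + np.random.default_rng(0).random((4, 16, 16, 2))
        geom = make_geometry((16, 16, 16))
        study = MultimodalStudy.from_channels("c", channels, geom)
        ref = LabelMap(values=np.zeros((16, 16, 16), dtype=np.uint8), geometry=geom)
        sampler = SliceSampler([(study, ref)], orientations=("axial",))
        batch = sampler.sample(32, np.random.default_rng(1))
        assert batch.slices.shape[0] == 32
        # axial slices come from indices 7 or 8 only, so they carry signal
        assert (np.abs(batch.slices).sum(axis=(1, 2, 3)) > 0).all()

    def test_empty_foreground_rejected(self):
        channels = np.zeros((4, 16, 16, 16))
        geom = make_geometry((16, 16, 16))
        study = MultimodalStudy.from_channels("c", channels, geom)
        ref = LabelMap(values=np.zeros((16, 16, 16), dtype=np.uint8), geometry=geom)
        with pytest.raises(ValueError):
            SliceSampler([(study, ref)])


class TestTrain:
    def test_zero_learning_rate_leaves_parameters_unchanged(self):
        case = _phantom_case()
        net = build_network(MICRO_ARCH, seed=0)
        before = {name: p.data.copy() for name, p in net.named_params()}
        config = TrainingConfig(learning_rate=0.0, epochs=1, steps_per_epoch=5,
                                seed=0)
        net, history = train(net, [case], config)
        assert len(history) == 5
        assert all(np.isfinite(history))
        for name, p in net.named_params():
            np.testing.assert_array_equal(p.data, before[name])

    def test_loss_history_reproducible_per_seed(self):
        case = _phantom_case()
        config = TrainingConfig(learning_rate=1e-3, epochs=1, steps_per_epoch=8,
                                seed=4)
        _, h1 = train(build_network(MICRO_ARCH, seed=1), [case], config)
        _, h2 = train(build_network(MICRO_ARCH, seed=1), [case], config)
        assert h1 == h2

    def test_divergence_reports_step_index(self):
        case = _phantom_case()
        net = build_network(MICRO_ARCH, seed=0)
        for _, p in net.named_params():
            p.data[...] = 1e30  # overflow the logits
        config = TrainingConfig(learning_rate=1e-3, epochs=1, steps_per_epoch=3,
                                seed=0)
        with pytest.raises(TrainingDivergenceError) as err:
            train(net, [case], config)
        assert err.value.step == 0

    def test_loss_decreases_on_overfit_fixture(self, overfit_results):
        # 2 phantom cases, reduced levels=2 network, 200 steps
        for result in overfit_results:
            assert result["final_loss"] < result["initial_loss"]

    def test_overfit_training_dice_above_095_majority_of_seeds(self, overfit_results):
        passed = sum(float(np.median(r["train_dice"])) > 0.95
                     for r in overfit_results)
        assert passed >= 2
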