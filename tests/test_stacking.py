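import numpy as np
import pandas as pd
import pytest

from peptidestack.evaluation import auc_score
from peptidestack.stacking import (
    ENCODERS,
    PFVMatrix,
    StackingArchitecture,
    build_external_pfv,
    build_training_pfv,
    fit_full_baselines,
    fit_meta,
)
from peptidestack.learners import ALGORITHMS
from peptidestack.peptide_io import LabeledDataset
from peptidestack.synthetic import SynthConfig, generate

SMALL_ARCH = StackingArchitecture(("AAC", "PCP"), ("LR", "NB"))


@pytest.fixture(scope="module")
def small_ds():
    return generate(SynthConfig(n_pos=20, n_neg=20, seed=13))


@pytest.fixture(scope="module")
def small_pfv(small_ds):
    return build_training_pfv(SMALL_ARCH, small_ds, k=4, seed=13, tune_folds=3)


class TestArchitecture:
    def test_default_cross_product_has_130_baselines(self):
        arch = StackingArchitecture()
        assert arch.n_baselines == 130
        assert len(ENCODERS) == 10 and len(ALGORITHMS) == 13

    def test_column_naming_convention(self):
        assert "MLP-PAAC" in StackingArchitecture().baseline_names
        assert SMALL_ARCH.baseline_names == [
            "LR-AAC", "NB-AAC", "LR-PCP", "NB-PCP",
        ]

    def test_unknown_names_rejected(self):
        with pytest.raises(KeyError):
            StackingArchitecture(("AAC", "BAD"), ("LR",))


class TestTrainingPfv:
    def test_shape_and_range(self, small_pfv, small_ds):
        assert small_pfv.frame.shape == (len(small_ds), SMALL_ARCH.n_baselines)
        assert small_pfv.values.min() >= 0.0 and small_pfv.values.max() <= 1.0
        assert small_pfv.provenance == "out-of-fold"

    def test_identical_seed_identical_matrix(self, small_ds, small_pfv):
        again = build_training_pfv(SMALL_ARCH, small_ds, k=4, seed=13, tune_folds=3)
        pd.testing.assert_frame_equal(small_pfv.frame, again.frame)

    def test_every_sample_covered_by_exactly_one_fold(self, small_pfv, small_ds):
        assert small_pfv.fold_of_sample.shape == (len(small_ds),)
        assert set(small_pfv.fold_of_sample) == set(range(4))


@pytest.fixture(scope="module")
def fitted(small_ds):
    return fit_full_baselines(SMALL_ARCH, small_ds, seed=13, tune_folds=3)


class TestExternalPfv:
    def test_single_peptide_gives_one_row(self, fitted, small_ds):
        one = small_ds.subset([0])
        pfv = build_external_pfv(fitted, one)
        assert pfv.frame.shape == (1, SMALL_ARCH.n_baselines)

    def test_columns_align_with_training_pfv(self, fitted, small_ds, small_pfv):
        ext = build_external_pfv(fitted, small_ds)
        assert ext.columns == small_pfv.columns
        assert ext.provenance == "full-model"

    def test_full_model_scores_differ_from_oof(self, fitted, small_ds, small_pfv):
        ext = build_external_pfv(fitted, small_ds)
        # full-data models saw every sample, OOF models did not
        assert not np.allclose(ext.values, small_pfv.values)


def test_meta_cv_mcc_is_null_under_label_permutation():
    """With shuffled labels the whole stack (OOF PFV + PLS meta) must not
    find signal: median |CV MCC| stays near zero across seeds."""
    from peptidestack.stacking import _pooled_mcc_of_pls

    mccs = []
    for seed in range(5):
        ds = generate(SynthConfig(n_pos=100, n_neg=100, signal=1.0, seed=50 + seed))
        rng = np.random.default_rng(seed)
        ds_perm = LabeledDataset(
            ds.peptides, list(rng.permutation(ds.labels)), "perm"
        )
        pfv = build_training_pfv(SMALL_ARCH, ds_perm, k=5, seed=seed, tune_folds=3)
        mccs.append(_pooled_mcc_of_pls(pfv.values, ds_perm.y, 2, 5, seed))
    assert abs(np.median(mccs)) <= 0.2, mccs


def _pfv_from_array(X, ids=None, columns=None):
    n, m = X.shape
    frame = pd.DataFrame(
        X,
        index=pd.Index(ids or [f"s{i}" for i in range(n)], name="id"),
        columns=columns or [f"PF{j}" for j in range(m)],
    )
    return PFVMatrix(frame, provenance="out-of-fold")


class TestMetaModel:
    def test_perfectly_informative_column_gives_training_mcc_one(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1], 20)
        X = rng.uniform(size=(40, 6))
        X[:, 2] = y.astype(float)
        pfv = _pfv_from_array(X)
        mask = np.zeros(6, dtype=bool)
        mask[2] = True
        meta = fit_meta(pfv, y, mask=mask, k=4, seed=0)
        conf, cls = meta.predict(pfv)
        assert (cls == y).all()

    def test_full_mask_uses_every_column(self):
        rng = np.random.default_rng(1)
        y = np.repeat([0, 1], 15)
        pfv = _pfv_from_array(rng.uniform(size=(30, 130)))
        meta = fit_meta(pfv, y, mask=None, components=2, k=3, seed=0)
        assert len(meta.columns) == 130

    def test_boundary_confidence_is_positive(self):
        y = np.repeat([0, 1], 10)
        rng = np.random.default_rng(3)
        pfv = _pfv_from_array(rng.uniform(size=(20, 4)))
        meta = fit_meta(pfv, y, components=1, k=3, seed=0)
        conf, cls = meta.predict(pfv)
        np.testing.assert_array_equal(cls, (conf >= 0.5).astype(int))

    def test_all_zero_row_is_scored_in_range(self):
        y = np.repeat([0, 1], 10)
        rng = np.random.default_rng(4)
        pfv = _pfv_from_array(rng.uniform(size=(20, 4)))
        meta = fit_meta(pfv, y, components=1, k=3, seed=0)
        zero = _pfv_from_array(np.zeros((1, 4)))
        conf, _ = meta.predict(zero)
        assert 0.0 <= conf[0] <= 1.0

    def test_prediction_invariant_to_sample_order(self):
        y = np.repeat([0, 1], 10)
        rng = np.random.default_rng(5)
        X = rng.uniform(size=(20, 4))
        pfv = _pfv_from_array(X)
        meta = fit_meta(pfv, y, components=2, k=3, seed=0)
        conf, _ = meta.predict(pfv)
        rev = _pfv_from_array(X[::-1], ids=[f"s{i}" for i in range(19, -1, -1)])
        conf_rev, _ = meta.predict(rev)
        np.testing.assert_allclose(conf, conf_rev[::-1])

    def test_missing_columns_rejected(self):
        y = np.repeat([0, 1], 10)
        rng = np.random.default_rng(6)
        pfv = _pfv_from_array(rng.uniform(size=(20, 4)))
        meta = fit_meta(pfv, y, components=1, k=3, seed=0)
        narrow = _pfv_from_array(rng.uniform(size=(20, 2)),
                                 columns=["PF0", "PF1"])
        with pytest.raises(ValueError):
            meta.predict(narrow)

    def test_single_class_labels_rejected(self):
        pfv = _pfv_from_array(np.random.default_rng(7).uniform(size=(10, 3)))
        with pytest.raises(ValueError):
            fit_meta(pfv, np.ones(10, dtype=int))
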