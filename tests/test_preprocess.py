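"""Zero imputation, log transform, QC drift correction, IS normalization."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_table
from toxmetab.preprocess import (
    PreprocessError,
    PreprocessReport,
    impute_zeros,
    is_normalize,
    log_transform,
    preprocess_pipeline,
    qc_drift_correct,
)
from toxmetab.synthetic_data import SyntheticConfig, generate_experiment


class TestImputeZeros:
    def test_zeros_get_global_min_nonzero(self):
        t = make_table([[0, 5], [2, 3]], ["Blank", "Low"])
        out = impute_zeros(t)
        assert out.abundances.to_numpy().tolist() == [[2, 5], [2, 3]]

    def test_no_zeros_identity(self):
        t = make_table([[1, 5], [2, 3]], ["Blank", "Low"])
        out = impute_zeros(t)
        pd.testing.assert_frame_equal(out.abundances, t.abundances)

    def test_single_nonzero_fills_everything(self):
        t = make_table([[0, 0], [0, 7]], ["Blank", "Low"])
        assert (impute_zeros(t).abundances.to_numpy() == 7).all()

    def test_all_zero_rejected(self):
        with pytest.raises(PreprocessError):
            impute_zeros(make_table([[0, 0], [0, 0]], ["Blank", "Low"]))

    def test_detection_mask_preserved(self):
        t = make_table([[0, 5], [2, 3]], ["Blank", "Low"])
        out = impute_zeros(t)
        assert out.detected.to_numpy().tolist() == [[False, True], [True, True]]


class TestLogTransform:
    def test_log10_values(self):
        t = make_table([[100, 1], [10**3, 10**6]], ["Blank", "Low"])
        out = log_transform(t)
        assert out.abundances.to_numpy().tolist() == [[2.0, 0.0], [3.0, 6.0]]
        assert out.log_scale

    def test_nonpositive_rejected_with_hint(self):
        with pytest.raises(PreprocessError, match="impute"):
            log_transform(make_table([[0, 5], [2, 3]], ["Blank", "Low"]))


def _drifting_table(qc_values, study_values, n_leading=0):
    """One feature; QCs at odd injections, study samples between them."""
    groups = []
    values = []
    inj = []
    i = 1
    for k, q in enumerate(qc_values):
        groups.append("QC")
        values.append([q])
        inj.append(i)
        i += 1
        if k < len(study_values):
            groups.append(["Blank", "Low", "High"][k % 3])
            values.append([study_values[k]])
            inj.append(i)
            i += 1
    return make_table(values, groups, inj)


class TestDriftCorrect:
    def test_proportional_drift_fully_removed(self):
        # QC abundance proportional to injection index -> equal after correction
        t = _drifting_table([10, 30, 50], [20, 40])
        out, report = qc_drift_correct(t, n_leading_qc=0)
        qc = out.abundances.loc[out.qc_mask(), "F0"]
        assert qc.std() == pytest.approx(0.0, abs=1e-12)
        assert report.n_drift_corrected == 1

    def test_feature_absent_in_one_qc_untouched(self):
        t = make_table(
            [[10, 10], [5, 5], [0, 20], [7, 7], [30, 30]],
            ["QC", "Blank", "QC", "Low", "QC"],
        )
        out, report = qc_drift_correct(t, n_leading_qc=0)
        # F0 has a zero in the middle QC: passes through unchanged
        pd.testing.assert_series_equal(out.abundances["F0"], t.abundances["F0"])
        assert report.n_drift_corrected == 1

    def test_constant_qc_identity(self):
        t = make_table(
            [[10, 4], [5, 5], [10, 4], [7, 7], [10, 4]],
            ["QC", "Blank", "QC", "Low", "QC"],
        )
        out, _ = qc_drift_correct(t, n_leading_qc=0)
        assert np.allclose(out.abundances.to_numpy(), t.abundances.to_numpy(), atol=1e-12)

    def test_idempotence(self):
        cfg = SyntheticConfig(seed=3, drift_slope=0.01)
        table, truth = generate_experiment(cfg)
        t = log_transform(impute_zeros(table))
        once, _ = qc_drift_correct(t)
        twice, _ = qc_drift_correct(once)
        assert np.allclose(
            once.abundances.to_numpy(), twice.abundances.to_numpy(), atol=1e-9
        )

    def test_requires_two_qcs(self):
        with pytest.raises(PreprocessError):
            qc_drift_correct(make_table([[1], [2], [3]], ["Blank", "Low", "QC"]))

    def test_anchor_qcs_flat_after_correction_noise_free(self):
        cfg = SyntheticConfig(seed=1, noise_cv=0.0, drift_slope=0.01)
        table, _ = generate_experiment(cfg)
        t = log_transform(impute_zeros(table))
        out, report = qc_drift_correct(t, n_leading_qc=cfg.n_leading_qc)
        qc = out.samples[out.qc_mask()].sort_values("injection_index")
        anchors = qc.index[cfg.n_leading_qc:]
        detected = t.detected.loc[out.qc_mask()[out.qc_mask()].index].all(axis=0)
        spread = out.abundances.loc[anchors, detected].std()
        assert spread.max() == pytest.approx(0.0, abs=1e-9)

    def test_noise_qc_dispersion_shrinks_for_most_features(self):
        # with every QC serving as an anchor, correction pins all QC values
        # of a fully-detected feature to the mean QC level, so their spread
        # strictly shrinks wherever it was nonzero
        cfg = SyntheticConfig(seed=9, noise_cv=0.2, drift_slope=0.01)
        table, _ = generate_experiment(cfg)
        t = log_transform(impute_zeros(table))
        out, _ = qc_drift_correct(t, n_leading_qc=0)
        qc_ids = t.samples.index[t.qc_mask()]
        detected = t.detected.loc[qc_ids].all(axis=0)
        before = t.abundances.loc[qc_ids, detected].std()
        after = out.abundances.loc[qc_ids, detected].std()
        assert (after < before).mean() >= 0.95

    def test_noise_qc_cv_median_shrinks_with_conditioning_qcs_excluded(self):
        # conditioning QCs are corrected by flat extrapolation and keep their
        # noise, so the guarantee over all QC injections is a median one
        cfg = SyntheticConfig(seed=9, noise_cv=0.2, drift_slope=0.01)
        table, _ = generate_experiment(cfg)
        t = log_transform(impute_zeros(table))
        out, _ = qc_drift_correct(t)
        qc_ids = t.samples.index[t.qc_mask()]
        detected = t.detected.loc[qc_ids].all(axis=0)
        before = t.abundances.loc[qc_ids, detected].std()
        after = out.abundances.loc[qc_ids, detected].std()
        assert after.median() < before.median()


class TestISNormalize:
    def test_log_scale_subtracts_is_column(self):
        t = make_table([[3.0, 5.0], [1.0, 4.0]], ["Blank", "Low"])
        t.log_scale = True
        out = is_normalize(t, "F0")
        assert out.abundances["F1"].tolist() == [2.0, 3.0]
        assert out.abundances["F0"].tolist() == [0.0, 0.0]

    def test_raw_scale_divides(self):
        t = make_table([[2.0, 8.0], [4.0, 8.0]], ["Blank", "Low"])
        out = is_normalize(t, "F0")
        # sample with 2x IS has its features halved relative to the other
        assert out.abundances["F1"].tolist() == [4.0, 2.0]

    def test_constant_is_leaves_relative_values(self):
        t = make_table([[10.0, 8.0, 6.0], [10.0, 4.0, 2.0]], ["Blank", "Low"])
        out = is_normalize(t, "F0")
        ratio = out.abundances[["F1", "F2"]] / t.abundances[["F1", "F2"]]
        assert np.allclose(ratio.to_numpy(), 0.1)

    def test_missing_or_nonpositive_is_rejected(self):
        t = make_table([[1.0, 2.0], [0.0, 3.0]], ["Blank", "Low"])
        with pytest.raises(PreprocessError):
            is_normalize(t, "nope")
        with pytest.raises(PreprocessError):
            is_normalize(t, "F0")


class TestPipelineComposition:
    def test_default_order_recorded(self, default_experiment):
        table, truth = default_experiment
        out, report = preprocess_pipeline(table, is_feature_id=truth.is_feature_id)
        assert report.steps_applied == ("impute", "log10", "drift", "is_normalize")
        assert report.surrogate_lod > 0
        assert report.is_feature_id == truth.is_feature_id
        assert out.log_scale
        # IS column exactly constant after normalization
        assert out.abundances[truth.is_feature_id].std() == 0.0

    def test_alternative_order_supported(self, default_experiment):
        table, truth = default_experiment
        out, report = preprocess_pipeline(
            table,
            is_feature_id=truth.is_feature_id,
            order=("impute", "is_normalize", "log10", "drift"),
        )
        assert report.steps_applied == ("impute", "is_normalize", "log10", "drift")

    def test_unknown_step_rejected(self, default_experiment):
        table, truth = default_experiment
        with pytest.raises(PreprocessError):
            preprocess_pipeline(table, truth.is_feature_id, order=("impute", "scale"))

    def test_null_settings_compose_to_identity_plus_constant(self):
        # no zeros, no drift, constant IS: pipeline = log10 then constant shift
        rng = np.random.default_rng(0)
        vals = 10 ** rng.uniform(3, 6, size=(6, 4))
        vals[3] = vals[0]
        vals[5] = vals[0]  # constant QC level per feature -> zero drift
        vals[:, 0] = 1e4  # IS channel constant
        t = make_table(vals, ["QC", "Blank", "Low", "QC", "High", "QC"],
                       injection_indices=[1, 2, 3, 4, 5, 6])
        out, _ = preprocess_pipeline(t, is_feature_id="F0", n_leading_qc=0)
        expect = np.log10(vals) - 4.0
        assert np.allclose(out.abundances.to_numpy(), expect, atol=1e-9)
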