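"""ROC/AUC, Youden cut-point, calibration binning and model Rs."""

import numpy as np
import pytest

from ntcpkit.cohort import CohortSpec, generate_cohort
from ntcpkit.evaluation import calibration_bins, model_rs, roc_auc, youden_cutoff
from ntcpkit.logistic import LogisticNTCPModel
from ntcpkit import reference


def brute_force_auc(pred, y):
    """Concordance probability over all case-control pairs, ties = 1/2."""
    pred, y = np.asarray(pred), np.asarray(y)
    cases, controls = pred[y == 1], pred[y == 0]
    wins = (cases[:, None] > controls[None, :]).sum()
    ties = (cases[:, None] == controls[None, :]).sum()
    return (wins + 0.5 * ties) / (len(cases) * len(controls))


class TestROC:
    def test_perfect_separation(self):
        roc = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert roc.auc == pytest.approx(1.0)

    def test_constant_predictions_uninformative(self):
        roc = roc_auc([0.3] * 6, [0, 1, 0, 1, 0, 1])
        assert roc.auc == pytest.approx(0.5)

    def test_four_point_example(self):
        roc = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert roc.auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            roc_auc([0.2, 0.4, 0.6], [1, 1, 1])

    def test_equals_brute_force_concordance(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = int(rng.integers(6, 50))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            pred = np.round(rng.random(n), 1)  # induce ties
            roc = roc_auc(pred, y)
            assert roc.auc == pytest.approx(brute_force_auc(pred, y), abs=1e-12)

    def test_matches_sklearn(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        pred = rng.random(40)
        assert roc_auc(pred, y).auc == pytest.approx(
            sk.roc_auc_score(y, pred), abs=1e-12
        )

    def test_complement_identity(self):
        rng = np.random.default_rng(10)
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        pred = rng.random(30)
        assert roc_auc(pred, y).auc + roc_auc(1 - pred, y).auc == pytest.approx(1.0)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(11)
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        pred = rng.random(30)
        assert roc_auc(np.exp(3 * pred), y).auc == pytest.approx(
            roc_auc(pred, y).auc, abs=1e-12
        )


class TestYouden:
    def test_perfect_predictor_j_is_one(self):
        roc = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert roc.youden_j == pytest.approx(1.0)
        assert roc.youden_threshold == pytest.approx(0.8)

    def test_four_point_tie_broken_to_specificity(self):
        roc = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        # J = 0.5 at thresholds 0.8 (sens .5, spec 1) and 0.35 (sens 1, spec .5)
        assert roc.youden_j == pytest.approx(0.5)
        assert roc.youden_threshold == pytest.approx(0.8)

    def test_covariate_backmap_inverts_monotone_model(self):
        """For a V65-only model the probability cut-off maps back to the
        dose-volume scale through the logistic inverse."""
        cohort = generate_cohort(CohortSpec(seed=3))
        model = reference.MODEL_V65_ONLY
        pred = np.asarray(model.ntcp(cohort))
        y = cohort["late_gi"].to_numpy(float)
        roc = roc_auc(pred, y)
        v65_cut = youden_cutoff(roc, cohort["v65"].to_numpy(), pred)
        assert model.ntcp({"v65": v65_cut}) == pytest.approx(roc.youden_threshold, abs=1e-12)

    def test_backmap_requires_monotone(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 20)
        y[:2] = [0, 1]
        pred = rng.random(20)
        cov = rng.random(20)  # unrelated to predictions
        roc = roc_auc(pred, y)
        with pytest.raises(ValueError, match="monotone"):
            youden_cutoff(roc, cov, pred)


class TestCalibration:
    def test_simulated_cohort_calibrated(self):
        """Outcomes drawn from the model's own NTCP are calibrated in every
        equal-count bin to within 3 binomial SEs."""
        rng = np.random.default_rng(12)
        n = 5000
        pred = rng.beta(2, 4, n)
        y = (rng.random(n) < pred).astype(float)
        bins = calibration_bins(pred, y, 5)
        assert np.array_equal(bins.counts, [1000] * 5)
        for mp, obs, cnt in zip(bins.mean_predicted, bins.observed_rate, bins.counts):
            se = np.sqrt(mp * (1 - mp) / cnt)
            assert abs(obs - mp) < 3 * se

    def test_equal_predictions_degenerate(self):
        rng = np.random.default_rng(13)
        y = rng.integers(0, 2, 400).astype(float)
        bins = calibration_bins(np.full(400, 0.4), y, 4)
        for obs in bins.observed_rate:
            se = np.sqrt(y.mean() * (1 - y.mean()) / 100)
            assert abs(obs - y.mean()) < 3 * se

    def test_hand_enumerated_three_bins(self):
        pred = np.array([0.1, 0.2, 0.3, 0.6, 0.7, 0.8])
        y = np.array([0, 0, 0, 1, 1, 1])
        bins = calibration_bins(pred, y, 3)
        np.testing.assert_array_equal(bins.counts, [2, 2, 2])
        np.testing.assert_allclose(bins.observed_rate, [0.0, 0.5, 1.0])

    def test_bin_counts_differ_by_at_most_one(self):
        rng = np.random.default_rng(14)
        pred = rng.random(57)
        y = rng.integers(0, 2, 57)
        bins = calibration_bins(pred, y, 5)
        assert bins.counts.max() - bins.counts.min() <= 1
        assert bins.counts.sum() == 57

    def test_too_many_bins_rejected(self):
        with pytest.raises(ValueError, match="n_bins"):
            calibration_bins(np.arange(6) / 6, [0, 1, 0, 1, 0, 1], 4)


class TestModelRs:
    def test_perfect_and_anti_ranking(self):
        y = np.array([0, 0, 1, 1], dtype=float)
        assert model_rs(y, y) == pytest.approx(1.0)
        assert model_rs(1 - y, y) == pytest.approx(-1.0)

    def test_constant_predictions_flagged_zero(self, caplog):
        assert model_rs([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1]) == 0.0

    def test_reference_model_neighbourhood(self):
        """Replica cohorts at the study size: the three-variable model's mean
        Rs lands in the neighbourhood of the reported 0.47."""
        model = reference.MODEL_THREE_VARIABLE
        rs = []
        for seed in range(200):
            cohort = generate_cohort(CohortSpec(seed=50_000 + seed))
            pred = np.asarray(model.ntcp(cohort))
            rs.append(model_rs(pred, cohort["late_gi"].to_numpy(float)))
        assert np.mean(rs) == pytest.approx(0.47, abs=0.15)
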