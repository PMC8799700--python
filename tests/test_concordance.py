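"""Beta-series GLM, concordance coefficients, group and behavior statistics."""

import numpy as np
import pandas as pd
import pytest

from dyadscope.concordance import (
    ROISpec,
    beta_series,
    behavior_correlation,
    dyad_concordance,
    group_regression,
    partner_roi_vector,
    roi_pair_concordance,
)
from dyadscope.datatypes import EventTable
from dyadscope.exceptions import (
    DataError,
    DegenerateInputError,
    DesignError,
    InsufficientDataError,
    ROIError,
)
from dyadscope.simulate import BetaSeries, BrainSimParams, generate_dyad_brain


def _bs(betas, conds=None):
    betas = np.asarray(betas, dtype=float)
    n = betas.shape[1]
    return BetaSeries("s", betas, conds or ["anticipation_treat"] * n,
                      [t // (n // 2 or 1) for t in range(n)])


class TestBetaSeries:
    def test_noiseless_bold_recovers_true_betas(self):
        p = BrainSimParams(emit_bold=True, bold_noise_sd=0.0, seed=5, n_parcels=18)
        pat, _, _, truth = generate_dyad_brain(p, 1.0, seed=5)
        bs = beta_series(truth.extras["bold_patient"], truth.extras["bold_events"],
                         truth.extras["tr_s"])
        assert bs.n_trials == 12  # two runs x six trials
        np.testing.assert_allclose(bs.betas, pat.betas, atol=1e-9)

    def test_pure_noise_bold_gives_zero_mean_betas(self):
        p = BrainSimParams(emit_bold=True, seed=6)
        _, _, _, truth = generate_dyad_brain(p, 0.0, seed=6)
        rng = np.random.default_rng(0)
        noise = rng.standard_normal(truth.extras["bold_patient"].shape)
        bs = beta_series(noise, truth.extras["bold_events"], truth.extras["tr_s"])
        assert abs(bs.betas.mean()) < 0.1

    def test_rank_deficient_design_named(self):
        # identical anticipation events in different runs -> collinear columns
        rows = [(0.0, 6.0, "anticipation_treat", 0, 0),
                (0.0, 6.0, "anticipation_treat", 0, 1)]
        ev = EventTable(pd.DataFrame(
            rows, columns=["onset", "duration", "condition", "trial_index", "run_index"]))
        bold = np.random.default_rng(0).standard_normal((3, 40))
        with pytest.raises(DesignError, match="collinear"):
            beta_series(bold, ev, 1.25)


class TestPartnerVector:
    def test_single_parcel_roi_is_zscored_trial_vector(self):
        betas = np.random.default_rng(1).standard_normal((5, 12))
        v = partner_roi_vector(_bs(betas), ROISpec("seed", (2,)))
        expected = (betas[2] - betas[2].mean()) / betas[2].std()
        np.testing.assert_allclose(v.values, expected)
        assert not v.degenerate

    def test_constant_betas_flagged_degenerate(self):
        v = partner_roi_vector(_bs(np.ones((3, 12))), ROISpec("seed", (0,)))
        assert v.degenerate

    def test_cancelling_parcels_flagged_degenerate(self):
        row = np.random.default_rng(2).standard_normal(12)
        v = partner_roi_vector(_bs(np.vstack([row, -row])), ROISpec("seed", (0, 1)))
        assert v.degenerate

    def test_empty_roi_rejected(self):
        with pytest.raises(ROIError):
            ROISpec("empty", ())


class TestDyadConcordance:
    def test_identical_vectors_give_one(self):
        base = np.random.default_rng(3).standard_normal(12)
        own = _bs(np.tile(base, (4, 1)))
        v = partner_roi_vector(_bs(base[None, :]), ROISpec("seed", (0,)))
        np.testing.assert_allclose(dyad_concordance(own, v), 1.0, atol=1e-12)

    def test_negated_vectors_give_minus_one(self):
        base = np.random.default_rng(4).standard_normal(12)
        own = _bs(np.tile(-base, (2, 1)))
        v = partner_roi_vector(_bs(base[None, :]), ROISpec("seed", (0,)))
        np.testing.assert_allclose(dyad_concordance(own, v), -1.0, atol=1e-12)

    def test_equals_pearson_closed_form(self):
        rng = np.random.default_rng(5)
        own = _bs(rng.standard_normal((30, 12)))
        v = partner_roi_vector(_bs(rng.standard_normal((4, 12))), ROISpec("seed", (0, 1, 2, 3)))
        coeffs = dyad_concordance(own, v)
        pearson = np.array([np.corrcoef(own.betas[k], v.values)[0, 1] for k in range(30)])
        np.testing.assert_allclose(coeffs, pearson, atol=1e-12)

    def test_degenerate_partner_rejected(self):
        own = _bs(np.random.default_rng(6).standard_normal((3, 12)))
        from dyadscope.concordance import PartnerVector

        with pytest.raises(DegenerateInputError):
            dyad_concordance(own, PartnerVector(np.zeros(12), "seed", degenerate=True))


class TestGroupRegression:
    def test_noiseless_slope_recovered(self):
        rng = np.random.default_rng(7)
        score = rng.standard_normal(20)
        score = (score - score.mean()) / score.std()  # unit variance
        coeffs = 0.5 * score[:, None] + np.zeros((20, 6))
        stats = group_regression(coeffs, score)
        np.testing.assert_allclose(stats.slope, 0.5, atol=1e-12)
        assert stats.significant.all()

    def test_null_calibration_fraction_below_alpha(self):
        rng = np.random.default_rng(8)
        fracs = []
        for _ in range(40):
            coeffs = rng.standard_normal((20, 30))
            score = rng.standard_normal(20)
            stats = group_regression(coeffs, score, alpha=0.05)
            fracs.append(stats.significant.mean())
        assert np.mean(fracs) <= 0.05 + 0.02

    def test_planted_parcels_recovered_at_high_snr(self):
        rng = np.random.default_rng(9)
        score = rng.standard_normal(30)
        coeffs = 0.02 * rng.standard_normal((30, 12))
        planted = [3, 4, 5]
        coeffs[:, planted] += 0.5 * score[:, None]
        stats = group_regression(coeffs, score)
        assert set(np.where(stats.significant)[0]) == set(planted)

    def test_constant_regressor_rejected(self):
        with pytest.raises(DegenerateInputError):
            group_regression(np.random.default_rng(0).standard_normal((5, 3)), np.ones(5))


class TestBehaviorCorrelation:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        assert behavior_correlation(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert behavior_correlation(x, -x)[0] == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            behavior_correlation(np.ones(5), np.arange(5.0))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InsufficientDataError):
            behavior_correlation([1.0, 2.0], [1.0, 2.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError):
            behavior_correlation([1.0, 2.0, 3.0], [1.0, 2.0])

    def test_permuting_dyad_assignment_destroys_correlation(self):
        rng = np.random.default_rng(10)
        coupling = rng.uniform(0.2, 0.8, size=30)
        scores = 30 + 10 * coupling + rng.normal(0, 1, size=30)
        r_true, _ = behavior_correlation(coupling, scores)
        assert r_true > 0.5
        perm_rs = []
        for _ in range(50):
            perm_rs.append(behavior_correlation(coupling, rng.permutation(scores))[0])
        assert abs(np.mean(perm_rs)) < 0.1


class TestRoiPairConcordance:
    def test_tracks_planted_cross_brain_coupling(self):
        rs, rhos = [], []
        for s in range(25):
            p = BrainSimParams(seed=s)
            pat, cli, _, truth = generate_dyad_brain(p, 1.2, seed=s)
            rs.append(roi_pair_concordance(cli, pat, ROISpec("aIns", (0, 1, 2, 3, 4)),
                                           ROISpec("m_pIns", (5, 6, 7, 8, 9))))
            rhos.append(truth.cross_brain_rho)
        assert np.mean(rs) == pytest.approx(np.mean(rhos), abs=0.15)
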