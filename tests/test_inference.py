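"""Pseudo-dyad enumeration, rank-sum cell tests, and BH-FDR against oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from dyadscope.datatypes import DyadRoster, GCMatrix
from dyadscope.exceptions import DataError, EmptyInputError, InsufficientDataError
from dyadscope.inference import (
    SigMatrix,
    cell_test,
    enumerate_pseudo_dyads,
    fdr_correct,
    grid_inference,
    summarize_links,
)


def _roster(pairs):
    rows = [(f"d{i}", p, c, True) for i, (p, c) in enumerate(pairs)]
    return DyadRoster(pd.DataFrame(rows, columns=["dyad_id", "patient_id", "clinician_id", "is_real"]))


class TestPseudoDyads:
    @pytest.mark.parametrize("n,expected", [(2, 2), (5, 20), (40, 1560)])
    def test_counts_are_n_times_n_minus_1(self, n, expected):
        roster = _roster([(f"p{i}", f"c{i}") for i in range(n)])
        assert len(enumerate_pseudo_dyads(roster)) == expected

    def test_real_pairings_excluded(self):
        # clinician c1 serves two dyads, so the mismatched pair (p3, c1)
        # would duplicate a real pairing and must be dropped
        roster = _roster([("p1", "c1"), ("p2", "c2"), ("p3", "c1")])
        pseudo = enumerate_pseudo_dyads(roster)
        real = {("p1", "c1"), ("p2", "c2"), ("p3", "c1")}
        got = set(zip(pseudo.table["patient_id"], pseudo.table["clinician_id"]))
        assert got.isdisjoint(real)
        assert not pseudo.table["is_real"].any()

    def test_cap_is_deterministic(self):
        roster = _roster([(f"p{i}", f"c{i}") for i in range(8)])
        a = enumerate_pseudo_dyads(roster, cap=10, seed=3)
        b = enumerate_pseudo_dyads(roster, cap=10, seed=3)
        assert len(a) == 10
        assert a.table.equals(b.table)

    def test_single_dyad_rejected(self):
        with pytest.raises(InsufficientDataError):
            enumerate_pseudo_dyads(_roster([("p1", "c1")]))


def mannwhitney_exact_oracle(real, null):
    """Brute-force one-sided p: enumerate all rank arrangements."""
    pooled = np.concatenate([real, null])
    n = len(real)
    obs = sum(1 for r in real for s in null if r > s)
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        a = pooled[list(idx)]
        b = np.delete(pooled, list(idx))
        u = sum(1 for r in a for s in b if r > s)
        count += u >= obs
        total += 1
    return count / total


class TestCellTest:
    def test_perfect_separation_exact_p(self):
        res = cell_test([3, 4, 5], [0, 1, 2])
        assert res.p_value == pytest.approx(1 / 20)  # C(6,3) = 20 arrangements

    def test_reversed_extreme(self):
        # inclusive enumeration P(U >= u_obs): every arrangement has U >= 0
        res = cell_test([0, 1, 2], [3, 4, 5], alternative="greater")
        assert res.p_value == pytest.approx(
            mannwhitney_exact_oracle(np.array([0.0, 1, 2]), np.array([3.0, 4, 5])))
        assert res.p_value == 1.0

    def test_identical_arrays_not_significant(self):
        res = cell_test([0.3, 1.2, 2.1], [0.3, 1.2, 2.1])
        assert res.p_value >= 0.5

    def test_all_identical_degenerate(self):
        res = cell_test([1.0, 1.0], [1.0, 1.0, 1.0])
        assert res.p_value == 1.0 and res.degenerate

    def test_empty_rejected(self):
        with pytest.raises(EmptyInputError):
            cell_test([], [1.0])

    @pytest.mark.parametrize("n,m", [(3, 3), (2, 8), (4, 5), (6, 6), (8, 7)])
    def test_matches_exact_enumeration_oracle(self, n, m):
        rng = np.random.default_rng(n * 100 + m)
        for _ in range(3):
            real = rng.standard_normal(n)
            null = rng.standard_normal(m)
            expected = mannwhitney_exact_oracle(real, null)
            assert cell_test(real, null).p_value == pytest.approx(expected, abs=1e-12)


def bh_oracle(p, alpha):
    """Independent brute-force Benjamini-Hochberg step-up."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    thresh = alpha * (np.arange(1, m + 1)) / m
    below = p[order] <= thresh
    k = np.max(np.nonzero(below)[0]) + 1 if below.any() else 0
    sig = np.zeros(m, dtype=bool)
    sig[order[:k]] = True
    q = np.empty(m)
    prev = 1.0
    for i in range(m - 1, -1, -1):
        prev = min(prev, p[order[i]] * m / (i + 1))
        q[order[i]] = prev
    return sig, q


class TestFDR:
    def test_hand_applied_thresholds(self):
        sig = fdr_correct(np.array([[0.01, 0.02], [0.03, 0.5]]), alpha=0.05)
        assert sig.n_significant == 3
        assert not sig.significant[1, 1]

    def test_all_ones_none_significant(self):
        assert fdr_correct(np.ones((4, 4))).n_significant == 0

    def test_boundary_p_exactly_alpha_over_m_significant(self):
        p = np.ones((2, 2))
        p[0, 0] = 0.05 / 4
        assert fdr_correct(p, alpha=0.05).significant[0, 0]

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            fdr_correct(np.array([[1.5]]))

    def test_q_dominates_p_and_missing_cells_excluded(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=(5, 5))
        p[0, 0] = np.nan
        sig = fdr_correct(p)
        assert sig.m_tested == 24
        valid = ~np.isnan(p)
        assert (sig.q[valid] >= p[valid] - 1e-12).all()
        assert np.isnan(sig.q[0, 0])

    def test_matches_brute_force_oracle_on_random_grids(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            p = rng.uniform(size=20) ** rng.uniform(0.5, 3)
            sig = fdr_correct(p.reshape(4, 5), alpha=0.05)
            exp_sig, exp_q = bh_oracle(p, 0.05)
            np.testing.assert_array_equal(sig.significant.ravel(), exp_sig)
            np.testing.assert_allclose(sig.q.ravel(), exp_q, atol=1e-12)


class TestGridInferenceAndSummary:
    def test_grid_shapes_and_counts(self):
        rng = np.random.default_rng(2)
        real = rng.standard_normal((6, 4, 4))
        null = rng.standard_normal((12, 4, 4))
        real[:, 1, 2] += 5.0  # one strongly separated cell
        sig = grid_inference(real, null, direction="patient_to_clinician")
        assert sig.p.shape == (4, 4)
        assert sig.significant[1, 2]

    def test_summary_counts_and_degrees(self):
        sig = np.zeros((3, 3), dtype=bool)
        sig[0, 1] = sig[0, 2] = sig[2, 0] = True
        s = SigMatrix(p=np.ones((3, 3)), q=np.ones((3, 3)), significant=sig,
                      alpha=0.05, n_real=5, n_null=10, direction="patient_to_clinician")
        summary = summarize_links({"patient_to_clinician": s})
        assert summary.n_significant["patient_to_clinician"] == 3
        assert list(summary.out_degree["patient_to_clinician"]) == [2, 0, 1]
        assert list(summary.in_degree["patient_to_clinician"]) == [1, 1, 1]
        assert summary.out_degree["patient_to_clinician"].sum() == 3

    def test_au28_score_is_row_mean(self):
        values = np.zeros((20, 20))
        values[17, :] = 0.2  # AU28_lip_suck row
        gcm = GCMatrix("dyadA", "patient_to_clinician", "anticipation", values)
        s = SigMatrix(p=np.ones((20, 20)), q=np.ones((20, 20)),
                      significant=np.zeros((20, 20), dtype=bool), alpha=0.05,
                      n_real=1, n_null=1, direction="patient_to_clinician")
        summary = summarize_links({"patient_to_clinician": s}, {"dyadA": gcm})
        assert summary.au28_scores["dyadA"] == pytest.approx(0.2)

    def test_empty_grid_all_degrees_zero(self):
        s = SigMatrix(p=np.ones((4, 4)), q=np.ones((4, 4)),
                      significant=np.zeros((4, 4), dtype=bool), alpha=0.05,
                      n_real=2, n_null=2, direction="clinician_to_patient")
        summary = summarize_links({"clinician_to_patient": s})
        assert summary.n_significant["clinician_to_patient"] == 0
        assert summary.out_degree["clinician_to_patient"].sum() == 0
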