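"""Group-level inference on directed AU->AU causal links.

Real-dyad GC strengths are contrasted, cell by cell, against an empirical
null built from pseudo-dyads: patient-clinician pairings who never
interacted but experienced the same protocol, so protocol-driven
"pseudo-concordance" is present in the null and cancels.  Each of the 400
cells gets a one-sided Mann-Whitney U test (real > null), and the p-value
grid is corrected with Benjamini-Hochberg FDR across all cells of a
direction's matrix (alpha = 0.05 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .datatypes import DyadRoster, GCMatrix
from .exceptions import DataError, EmptyInputError, InsufficientDataError, SchemaError


@dataclass
class CellTestResult:
    p_value: float
    degenerate: bool = False


@dataclass
class SigMatrix:
    """Per-cell p, BH q, and significance grids for one direction/paradigm."""

    p: np.ndarray
    q: np.ndarray
    significant: np.ndarray
    alpha: float
    n_real: int
    n_null: int
    direction: str = ""
    paradigm: str = ""
    m_tested: int = 0

    @property
    def n_significant(self) -> int:
        return int(np.nansum(self.significant))


@dataclass
class LinkSummary:
    """Counts and degrees of significant links, plus the per-dyad facial score.

    ``au28_scores`` is the per-patient mean causal strength of the source AU
    row (lip suck AU28 by default) across all clinician target AUs — the
    scalar used as the between-dyad regressor in the concordance stage.
    """

    n_significant: dict[str, int]
    out_degree: dict[str, np.ndarray]
    in_degree: dict[str, np.ndarray]
    au28_scores: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    source_au: str = "AU28_lip_suck"


def enumerate_pseudo_dyads(roster: DyadRoster, cap: int | None = None, seed: int = 0) -> DyadRoster:
    """All ordered mismatched (patient_i, clinician_j) pairings, i != j.

    Never contains a real pairing.  With ``cap`` set, a seeded uniform
    subsample of that size is returned.
    """
    real = roster.real
    if len(real) < 2:
        raise InsufficientDataError("need at least 2 real dyads to form pseudo-dyads")
    real_pairs = set(zip(real["patient_id"], real["clinician_id"]))
    seen: dict[tuple, tuple] = {}
    for _, a in real.iterrows():
        for _, b in real.iterrows():
            if a["dyad_id"] == b["dyad_id"]:
                continue
            pair = (a["patient_id"], b["clinician_id"])
            if pair in real_pairs or pair in seen:
                continue
            seen[pair] = (f"pseudo_{pair[0]}_{pair[1]}", *pair, False)
    df = pd.DataFrame(list(seen.values()),
                      columns=["dyad_id", "patient_id", "clinician_id", "is_real"])
    if cap is not None and cap < len(df):
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(len(df), size=cap, replace=False))
        df = df.iloc[keep].reset_index(drop=True)
    return DyadRoster(df)


def cell_test(real_values, null_values, alternative: str = "greater") -> CellTestResult:
    """One-sided Mann-Whitney (rank-sum) test of real vs pseudo-dyad GC values.

    Exact enumeration when ``min(n, m) <= 8`` and the pooled sample is
    tie-free; midrank normal approximation with tie correction otherwise.
    All-identical pooled values yield p = 1 with a degenerate flag.
    """
    real = np.asarray(real_values, dtype=float)
    null = np.asarray(null_values, dtype=float)
    if real.size == 0 or null.size == 0:
        raise EmptyInputError("cell_test requires non-empty samples")
    if not (np.isfinite(real).all() and np.isfinite(null).all()):
        raise DataError("cell_test requires finite samples")
    pooled = np.concatenate([real, null])
    if np.all(pooled == pooled[0]):
        return CellTestResult(p_value=1.0, degenerate=True)
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(real.size, null.size) <= 8 and not has_ties) else "asymptotic"
    res = mannwhitneyu(real, null, alternative=alternative, method=method)
    return CellTestResult(p_value=float(res.pvalue))


def fdr_correct(p_grid: np.ndarray, alpha: float = 0.05) -> SigMatrix:
    """Benjamini-Hochberg step-up across all cells of the grid.

    NaN cells (flagged-missing channels) are excluded and the effective
    family size recorded.  A cell with p exactly at its step-up threshold is
    significant (<= convention).
    """
    p = np.asarray(p_grid, dtype=float)
    valid = ~np.isnan(p)
    if ((p[valid] < 0) | (p[valid] > 1)).any():
        raise DataError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    sig = np.zeros_like(p, dtype=bool)
    m = int(valid.sum())
    if m:
        rej, qvals, *_ = multipletests(p[valid].ravel(), alpha=alpha, method="fdr_bh")
        q[valid] = qvals
        sig[valid] = qvals <= alpha
    return SigMatrix(p=p, q=q, significant=sig, alpha=alpha,
                     n_real=0, n_null=0, m_tested=m)


def grid_inference(
    real_matrices: np.ndarray,
    null_matrices: np.ndarray,
    alpha: float = 0.05,
    direction: str = "",
    paradigm: str = "anticipation",
) -> SigMatrix:
    """Cell-wise Mann-Whitney tests over stacked GC matrices, then BH-FDR.

    ``real_matrices``/``null_matrices`` are ``(n_dyads, R, C)`` stacks; a
    cell that is missing (NaN) in any dyad is excluded from the family.
    """
    real = np.asarray(real_matrices, dtype=float)
    null = np.asarray(null_matrices, dtype=float)
    if real.ndim != 3 or null.ndim != 3 or real.shape[1:] != null.shape[1:]:
        raise SchemaError("matrix stacks must be (n_dyads, R, C) with matching grids")
    R, C = real.shape[1:]
    p = np.full((R, C), np.nan)
    for i in range(R):
        for j in range(C):
            rv, nv = real[:, i, j], null[:, i, j]
            if np.isnan(rv).any() or np.isnan(nv).any():
                continue
            p[i, j] = cell_test(rv, nv).p_value
    sig = fdr_correct(p, alpha=alpha)
    sig.n_real, sig.n_null = real.shape[0], null.shape[0]
    sig.direction, sig.paradigm = direction, paradigm
    return sig


def summarize_links(
    sig_by_direction: dict[str, SigMatrix],
    gc_by_dyad: dict[str, GCMatrix] | None = None,
    source_au: str = "AU28_lip_suck",
) -> LinkSummary:
    """Significant-link counts/degrees per direction plus per-dyad AU28 scores.

    The AU28 score of a dyad is the arithmetic mean of the patient's
    ``source_au`` row of the patient-to-clinician matrix, i.e. the overall
    causal strength of that patient AU on all clinician AUs.
    """
    counts: dict[str, int] = {}
    out_deg: dict[str, np.ndarray] = {}
    in_deg: dict[str, np.ndarray] = {}
    for direction, sig in sig_by_direction.items():
        counts[direction] = sig.n_significant
        out_deg[direction] = sig.significant.sum(axis=1)
        in_deg[direction] = sig.significant.sum(axis=0)
    scores = pd.Series(dtype=float)
    if gc_by_dyad:
        vals = {}
        for dyad_id, gcm in gc_by_dyad.items():
            if gcm.direction != "patient_to_clinician":
                raise SchemaError("AU28 scores are defined on patient_to_clinician matrices")
            row = gcm.values[gcm.source_labels.index(source_au)]
            vals[dyad_id] = float(np.nanmean(row))
        scores = pd.Series(vals).sort_index()
    return LinkSummary(
        n_significant=counts, out_degree=out_deg, in_degree=in_deg,
        au28_scores=scores, source_au=source_au,
    )
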