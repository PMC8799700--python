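"""Trial-wise beta series and dyadic brain-to-brain concordance.

For each subject, a first-level GLM estimates one anticipation-phase beta per
trial and parcel (pain and rating periods enter as nuisance regressors).  A
partner's ROI trial vector is then regressed against the subject's own trial
betas parcel by parcel; with both sides z-scored across the 12 trials the
standardized slope equals the Pearson correlation.  Dyad-level concordance
coefficients are regressed on a between-dyad facial-causality score
(BH-FDR across parcels stands in for voxelwise cluster correction), and
dyad-level ROI-pair concordance is correlated with behavioral measures
(dyad-mean CARE, Berkeley negative expressivity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import EventTable
from .exceptions import (
    DataError,
    DegenerateInputError,
    DesignError,
    InsufficientDataError,
    ROIError,
)
from .simulate import BetaSeries, _trial_design


@dataclass(frozen=True)
class ROISpec:
    """Named parcel index set (e.g. clinician_aIns, patient_m_pIns)."""

    name: str
    parcels: tuple[int, ...]

    def __post_init__(self):
        if len(self.parcels) == 0:
            raise ROIError(f"ROI {self.name} is empty")


@dataclass
class PartnerVector:
    """Per-trial ROI mean, z-scored across trials; degenerate if zero variance."""

    values: np.ndarray
    roi: str
    degenerate: bool = False


@dataclass
class GroupStats:
    """Per-parcel group regression of concordance on the between-dyad score."""

    slope: np.ndarray
    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    significant: np.ndarray
    n_dyads: int
    alpha: float


def beta_series(bold: np.ndarray, events: EventTable, tr_s: float) -> BetaSeries:
    """First-level trial-wise GLM on parcel BOLD.

    ``bold`` is (n_parcels, n_timepoints).  The design holds one
    HRF-convolved boxcar per anticipation trial, pain and rating nuisance
    regressors, and an intercept; the returned betas are the anticipation
    trial estimates only.
    """
    bold = np.asarray(bold, dtype=float)
    if bold.ndim != 2:
        raise DataError("bold must be (n_parcels, n_timepoints)")
    n_tp = bold.shape[1]
    if events.end_s() > n_tp * tr_s + 1e-9:
        raise DesignError("events extend beyond the scan length")
    X, names = _trial_design(events, tr_s, n_tp)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns via tiny R diagonal entries
        _, R = np.linalg.qr(X)
        bad = [names[i] for i in np.where(np.abs(np.diag(R)) < 1e-8)[0]]
        raise DesignError(f"rank-deficient design (rank {rank} < {X.shape[1]}); collinear: {bad}")
    coefs, *_ = np.linalg.lstsq(X, bold.T, rcond=None)
    trial_cols = [i for i, n in enumerate(names) if n.startswith("anticipation_trial")]
    ant = events.select(
        {"anticipation_pain", "anticipation_nopain", "anticipation_treat", "anticipation_notreat"}
    )
    return BetaSeries(
        subject_id="",
        betas=coefs[trial_cols].T,
        conditions=list(ant["condition"]),
        runs=list(ant["run_index"]),
    )


def partner_roi_vector(bs: BetaSeries, roi: ROISpec) -> PartnerVector:
    """Per-trial mean over the ROI's parcels, z-scored across trials."""
    parcels = np.asarray(roi.parcels, dtype=int)
    if parcels.max() >= bs.betas.shape[0] or parcels.min() < 0:
        raise ROIError(f"ROI {roi.name} indexes parcels outside 0..{bs.betas.shape[0] - 1}")
    vec = bs.betas[parcels].mean(axis=0)
    sd = vec.std()
    if sd == 0:
        return PartnerVector(values=np.zeros_like(vec), roi=roi.name, degenerate=True)
    return PartnerVector(values=(vec - vec.mean()) / sd, roi=roi.name)


def dyad_concordance(own: BetaSeries, partner_vec: PartnerVector) -> np.ndarray:
    """Per-parcel standardized slope of own trial betas on the partner vector.

    With both sides z-scored across trials this equals the Pearson
    correlation between the two trial vectors.  Zero-variance parcels yield
    NaN (flagged missing).
    """
    if partner_vec.degenerate:
        raise DegenerateInputError("partner ROI vector is degenerate (zero trial variance)")
    B = own.betas
    if B.shape[1] != partner_vec.values.shape[0]:
        raise DataError("trial counts differ between subject and partner vector")
    mu = B.mean(axis=1, keepdims=True)
    sd = B.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (B - mu) / np.where(sd == 0, 1.0, sd), np.nan)
    return (z * partner_vec.values).mean(axis=1)


def roi_pair_concordance(a: BetaSeries, b: BetaSeries, roi_a: ROISpec, roi_b: ROISpec) -> float:
    """Dyad-level scalar concordance: Pearson r of the two ROI trial vectors."""
    va = partner_roi_vector(a, roi_a)
    vb = partner_roi_vector(b, roi_b)
    if va.degenerate or vb.degenerate:
        raise DegenerateInputError("ROI trial vector has zero variance")
    return float(np.mean(va.values * vb.values))


def group_regression(
    coeffs: np.ndarray,
    regressor: np.ndarray,
    alpha: float = 0.05,
) -> GroupStats:
    """Per-parcel OLS of concordance coefficients on a between-dyad score.

    The regressor is z-scored; two-sided t-based p-values per parcel are
    BH-FDR corrected across parcels.
    """
    from .inference import fdr_correct

    coeffs = np.asarray(coeffs, dtype=float)
    regressor = np.asarray(regressor, dtype=float).ravel()
    n = coeffs.shape[0]
    if n < 3:
        raise InsufficientDataError("group regression needs at least 3 dyads")
    if coeffs.shape[0] != regressor.shape[0]:
        raise DataError("coeffs rows must match regressor length")
    if regressor.std() == 0:
        raise DegenerateInputError("constant between-dyad regressor")
    x = (regressor - regressor.mean()) / regressor.std()

    xc = x - x.mean()
    denom = float(xc @ xc)
    yc = coeffs - coeffs.mean(axis=0, keepdims=True)
    slope = (xc @ yc) / denom
    resid = yc - np.outer(xc, slope)
    dof = n - 2
    s2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(s2 / denom)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, slope / se, np.inf * np.sign(slope))
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    nan_cols = np.isnan(coeffs).any(axis=0)
    p = np.where(nan_cols, np.nan, p)
    sig = fdr_correct(p.reshape(1, -1), alpha=alpha)
    return GroupStats(
        slope=slope, t=t, p=p, q=sig.q.ravel(), significant=sig.significant.ravel(),
        n_dyads=n, alpha=alpha,
    )


def behavior_correlation(dyad_concordance_values, scores) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) of dyad concordance with a behavior.

    The CARE dyad score is the mean of patient- and clinician-rated totals,
    computed upstream.
    """
    x = np.asarray(dyad_concordance_values, dtype=float).ravel()
    y = np.asarray(scores, dtype=float).ravel()
    if x.shape != y.shape:
        raise DataError("paired vectors must have equal length")
    if len(x) < 3:
        raise InsufficientDataError("need at least 3 dyads")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DataError("non-finite values in behavior correlation inputs")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateInputError("zero variance in a correlation input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
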