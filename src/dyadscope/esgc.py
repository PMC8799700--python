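"""Echo-state network Granger causality (ESGC) over block-structured series.

Granger causality from a source series *x* to a target series *y* asks whether
the past of *x* improves prediction of *y* beyond *y*'s own past.  Here both
the restricted model (target past only) and the full model (target and source
past) are echo-state networks: a fixed random recurrent reservoir with a
leaky-tanh update and a ridge-regressed linear readout, so the only trained
parameters are the readout weights.  The causality statistic is

    gc_strength = ln( MSE_restricted / MSE_full )

with both mean squared errors pooled over held-out blocks under
leave-one-block-out cross-validation, which guards the nonlinear readout
against in-sample overfitting.  Estimates may be negative and are not
clipped, so the pseudo-dyad null distribution stays unbiased for rank-based
inference.

The per-dyad product is a nonsymmetric (source AU x target AU) matrix per
direction (patient-to-clinician and clinician-to-patient), 20 x 20 = 400
bivariate estimates by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import BlockSeries, DEFAULT_AU_LABELS, DIRECTIONS, GCMatrix
from .exceptions import BoundsError, DataError, EmptyInputError, ParameterError


@dataclass(frozen=True)
class ReservoirParams:
    """Echo-state reservoir configuration.

    The recurrent weight matrix is rescaled to ``spectral_radius`` (< 1 keeps
    the echo-state property: the input-driven state has fading memory).
    ``n_reservoirs`` independent reservoir realizations are averaged to
    reduce the variance contributed by the random weights; recurrent weights
    are shared between the restricted and full models of a realization while
    input weights are drawn independently (the input dimensionality differs).
    """

    n_units: int = 100
    spectral_radius: float = 0.9
    input_scale: float = 1.0
    leak_rate: float = 0.3
    ridge_lambda: float = 1e-2
    washout_frames: int = 10
    n_reservoirs: int = 5
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.spectral_radius < 1:
            raise ParameterError("spectral_radius must be in (0, 1) for the echo-state property")
        if not 0 <= self.leak_rate <= 1:
            raise ParameterError("leak_rate must be in [0, 1]")
        if self.ridge_lambda < 0:
            raise ParameterError("ridge_lambda must be >= 0")
        if self.n_units < 1 or self.n_reservoirs < 1:
            raise ParameterError("n_units and n_reservoirs must be positive")


@dataclass
class GCEstimate:
    """Single-pair ESGC result; ``gc_strength = ln(mse_restricted / mse_full)``."""

    gc_strength: float
    mse_restricted: float
    mse_full: float
    n_frames_used: int
    missing: bool = False


def _reservoir_weights(p: ReservoirParams, reservoir_index: int):
    """Deterministic (W, w_in_restricted, W_in_full) for one realization."""
    ss = np.random.SeedSequence(entropy=p.seed, spawn_key=(reservoir_index,))
    rng = np.random.default_rng(ss)
    W = rng.standard_normal((p.n_units, p.n_units)) / np.sqrt(p.n_units)
    radius = np.max(np.abs(np.linalg.eigvals(W)))
    if radius > 0:
        W *= p.spectral_radius / radius
    w_in_r = rng.uniform(-1.0, 1.0, size=(1, p.n_units)) * p.input_scale
    W_in_f = rng.uniform(-1.0, 1.0, size=(2, p.n_units)) * p.input_scale
    return W, w_in_r, W_in_f


def _run_states(drive: np.ndarray, W: np.ndarray, leak: float) -> np.ndarray:
    """Leaky-tanh reservoir run from a zero state.

    ``drive`` is the precomputed input projection, shape ``(B, T, n_units)``
    for B independent series; returns the state trajectories, same shape.
    The state is reset to zero at the start of every block (callers run this
    per block), so no information leaks across block boundaries.
    """
    B, T, n = drive.shape
    out = np.empty_like(drive)
    s = np.zeros((B, n))
    keep = 1.0 - leak
    for t in range(T):
        s = keep * s + leak * np.tanh(s @ W.T + drive[:, t])
        out[:, t] = s
    return out


def esn_states(u: np.ndarray, p: ReservoirParams, reservoir_index: int = 0) -> np.ndarray:
    """States of reservoir ``reservoir_index`` driven by input ``u`` (frames x d).

    Deterministic given ``p.seed`` and ``reservoir_index``; the state starts
    at zero (block start).
    """
    u = np.atleast_2d(np.asarray(u, dtype=float))
    if u.ndim != 2 or u.shape[1] not in (1, 2):
        raise ParameterError("input must be (frames, d) with d in {1, 2}")
    if not np.isfinite(u).all():
        raise DataError("non-finite values in ESN input")
    W, w_in_r, W_in_f = _reservoir_weights(p, reservoir_index)
    W_in = w_in_r if u.shape[1] == 1 else W_in_f
    drive = (u @ W_in)[None]
    return _run_states(drive, W, p.leak_rate)[0]


def _ridge_solve(G: np.ndarray, c: np.ndarray, lam: float) -> np.ndarray:
    """Batched ridge solve: (B, k, k) Grams, (B, k) cross-products -> (B, k)."""
    k = G.shape[-1]
    A = G + lam * np.eye(k)
    return np.linalg.solve(A, c[..., None])[..., 0]


def _esgc_grid(src_blocks, tgt_blocks, p: ReservoirParams):
    """Batched ESGC over every (source channel, target channel) pair.

    ``src_blocks``/``tgt_blocks`` are aligned per-block arrays of shape
    ``(T_b, n_src)`` / ``(T_b, n_tgt)``.  Returns ``(gc, mse_r, mse_f,
    missing, n_used)`` where ``gc`` is ``(n_src, n_tgt)``, ``mse_r`` is the
    per-target restricted MSE and ``mse_f`` the per-pair full-model MSE, both
    geometric means over reservoir realizations so the log-ratio identity
    holds exactly.
    """
    n_blocks = len(src_blocks)
    if n_blocks == 0:
        raise EmptyInputError("no blocks supplied")
    if n_blocks < 2:
        raise BoundsError("leave-one-block-out needs at least 2 blocks")
    src_blocks = [np.asarray(b, dtype=float) for b in src_blocks]
    tgt_blocks = [np.asarray(b, dtype=float) for b in tgt_blocks]
    n_src = src_blocks[0].shape[1]
    n_tgt = tgt_blocks[0].shape[1]
    for bs, bt in zip(src_blocks, tgt_blocks):
        if bs.shape[0] != bt.shape[0]:
            raise DataError("source and target blocks must be time-aligned")
        if bs.shape[0] <= p.washout_frames + 2:
            raise BoundsError(
                f"block of {bs.shape[0]} frames too short for washout {p.washout_frames}"
            )
        if not (np.isfinite(bs).all() and np.isfinite(bt).all()):
            raise DataError("non-finite values in input blocks")

    n_pairs = n_src * n_tgt
    k = p.n_units + 1  # readout features: states + bias
    missing_src = np.zeros(n_src, dtype=bool)
    missing_tgt = np.zeros(n_tgt, dtype=bool)
    log_ratios = np.zeros((p.n_reservoirs, n_src, n_tgt))
    log_mse_r = np.zeros((p.n_reservoirs, n_tgt))
    log_mse_f = np.zeros((p.n_reservoirs, n_src, n_tgt))
    n_used_total = 0

    for r in range(p.n_reservoirs):
        W, w_in_r, W_in_f = _reservoir_weights(p, r)
        w0, w1 = W_in_f[0], W_in_f[1]  # full-model projections: target, source
        wr = w_in_r[0]
        sse_r = np.zeros(n_tgt)
        sse_f = np.zeros((n_src, n_tgt))
        n_pred = 0

        for held in range(n_blocks):
            train = [b for b in range(n_blocks) if b != held]
            s_cat = np.concatenate([src_blocks[b] for b in train])
            t_cat = np.concatenate([tgt_blocks[b] for b in train])
            s_mu, s_sd = s_cat.mean(0), s_cat.std(0)
            t_mu, t_sd = t_cat.mean(0), t_cat.std(0)
            missing_src |= s_sd == 0
            missing_tgt |= t_sd == 0
            s_sd = np.where(s_sd == 0, 1.0, s_sd)
            t_sd = np.where(t_sd == 0, 1.0, t_sd)

            def zs(b):
                return (src_blocks[b] - s_mu) / s_sd

            def zt(b):
                return (tgt_blocks[b] - t_mu) / t_sd

            G_r = np.zeros((n_tgt, k, k))
            c_r = np.zeros((n_tgt, k))
            G_f = np.zeros((n_pairs, k, k))
            c_f = np.zeros((n_pairs, k))

            def block_states(b):
                Zs, Zt = zs(b), zt(b)
                T = Zs.shape[0]
                # restricted drive: each target channel alone
                Dr = Zt.T[:, :, None] * wr
                Sr = _run_states(Dr, W, p.leak_rate)
                # full drive: pair (i, j) -> source i and target j jointly
                Df = (Zt.T[None, :, :, None] * w0) + (Zs.T[:, None, :, None] * w1)
                Sf = _run_states(Df.reshape(n_pairs, T, p.n_units), W, p.leak_rate)
                sl = slice(p.washout_frames, T - 1)
                y = Zt[p.washout_frames + 1 : T]  # (Tu, n_tgt)
                ones = np.ones((*Sr[:, sl].shape[:2], 1))
                Xr = np.concatenate([Sr[:, sl], ones], axis=2)  # (n_tgt, Tu, k)
                ones_f = np.ones((*Sf[:, sl].shape[:2], 1))
                Xf = np.concatenate([Sf[:, sl], ones_f], axis=2)  # (n_pairs, Tu, k)
                return Xr, Xf, y

            for b in train:
                Xr, Xf, y = block_states(b)
                G_r += Xr.transpose(0, 2, 1) @ Xr
                c_r += np.einsum("jtk,tj->jk", Xr, y)
                G_f += Xf.transpose(0, 2, 1) @ Xf
                y_f = np.tile(y.T, (n_src, 1))  # pair (i, j) predicts target j
                c_f += np.einsum("ptk,pt->pk", Xf, y_f)

            w_hat_r = _ridge_solve(G_r, c_r, p.ridge_lambda)
            w_hat_f = _ridge_solve(G_f, c_f, p.ridge_lambda)

            Xr, Xf, y = block_states(held)
            pred_r = np.einsum("jtk,jk->tj", Xr, w_hat_r)
            sse_r += ((y - pred_r) ** 2).sum(0)
            pred_f = np.einsum("ptk,pk->pt", Xf, w_hat_f)
            y_f = np.tile(y.T, (n_src, 1))
            sse_f += ((y_f - pred_f) ** 2).sum(1).reshape(n_src, n_tgt)
            n_pred += y.shape[0]

        mse_r = sse_r / n_pred
        mse_f = sse_f / n_pred
        log_mse_r[r] = np.log(mse_r)
        log_mse_f[r] = np.log(mse_f)
        log_ratios[r] = np.log(mse_r)[None, :] - np.log(mse_f)
        n_used_total = n_pred

    gc = log_ratios.mean(0)
    mse_r_geo = np.exp(log_mse_r.mean(0))
    mse_f_geo = np.exp(log_mse_f.mean(0))
    missing = missing_src[:, None] | missing_tgt[None, :]
    gc = np.where(missing, np.nan, gc)
    return gc, mse_r_geo, mse_f_geo, missing, n_used_total


def esgc_pair(source_blocks, target_blocks, p: ReservoirParams) -> GCEstimate:
    """ESGC for a single source/target channel pair.

    ``source_blocks`` and ``target_blocks`` are lists of 1-D per-block arrays
    (time-aligned, equal lengths per block).  Channels with zero variance
    across training blocks yield a flagged-missing estimate rather than an
    error.
    """
    src = [np.asarray(b, dtype=float).reshape(-1, 1) for b in source_blocks]
    tgt = [np.asarray(b, dtype=float).reshape(-1, 1) for b in target_blocks]
    gc, mse_r, mse_f, missing, n_used = _esgc_grid(src, tgt, p)
    if missing[0, 0]:
        return GCEstimate(np.nan, np.nan, np.nan, n_used, missing=True)
    return GCEstimate(
        gc_strength=float(gc[0, 0]),
        mse_restricted=float(mse_r[0]),
        mse_full=float(mse_f[0, 0]),
        n_frames_used=int(n_used),
    )


def esgc_matrix(
    blocks: list[BlockSeries],
    direction: str,
    p: ReservoirParams,
    paradigm: str = "anticipation",
    source_channels=None,
    target_channels=None,
    au_labels=DEFAULT_AU_LABELS,
) -> GCMatrix:
    """Directed ESGC matrix over all (source AU, target AU) pairs of a dyad.

    ``direction`` selects which member's channels act as sources.  Channel
    subsets may be given as label lists to estimate a sub-grid (the default
    estimates the full 20 x 20 grid, 400 bivariate estimates).
    """
    if direction not in DIRECTIONS:
        raise ParameterError(f"direction must be one of {DIRECTIONS}")
    if not blocks:
        raise EmptyInputError("empty block list")
    labels = tuple(au_labels)
    src_labels = tuple(source_channels) if source_channels is not None else labels
    tgt_labels = tuple(target_channels) if target_channels is not None else labels
    src_idx = [labels.index(l) for l in src_labels]
    tgt_idx = [labels.index(l) for l in tgt_labels]

    if direction == "patient_to_clinician":
        src_blocks = [b.patient_segment[:, src_idx] for b in blocks]
        tgt_blocks = [b.clinician_segment[:, tgt_idx] for b in blocks]
    else:
        src_blocks = [b.clinician_segment[:, src_idx] for b in blocks]
        tgt_blocks = [b.patient_segment[:, tgt_idx] for b in blocks]

    gc, _, _, missing, _ = _esgc_grid(src_blocks, tgt_blocks, p)
    return GCMatrix(
        dyad_id=blocks[0].dyad_id,
        direction=direction,
        paradigm=paradigm,
        values=gc,
        source_labels=src_labels,
        target_labels=tgt_labels,
        missing=missing,
    )


def linear_gc_reference(source: np.ndarray, target: np.ndarray, order: int = 1) -> float:
    """Classical linear Granger causality (log residual-variance ratio).

    Fits AR(``order``) models of the target by ordinary least squares, with
    and without lagged source terms, on a single stationary series.  Serves
    as an independent closed-form check on the echo-state estimator for
    linear dynamics; for target_t = a * source_{t-1} + e with unit variances
    the population value is ln(1 + a^2).
    """
    source = np.asarray(source, dtype=float).ravel()
    target = np.asarray(target, dtype=float).ravel()
    if source.shape != target.shape:
        raise DataError("source and target must have equal length")
    T = len(target)
    if T <= 10 * order:
        raise BoundsError("series too short for the requested model order")
    y = target[order:]
    lags_t = np.column_stack([target[order - l : T - l] for l in range(1, order + 1)])
    lags_s = np.column_stack([source[order - l : T - l] for l in range(1, order + 1)])
    ones = np.ones((len(y), 1))
    X_r = np.hstack([ones, lags_t])
    X_f = np.hstack([ones, lags_t, lags_s])
    if np.linalg.matrix_rank(X_f) < X_f.shape[1]:
        raise DataError("singular design in linear GC reference")

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        return float(resid @ resid)

    return float(np.log(rss(X_r) / rss(X_f)))
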