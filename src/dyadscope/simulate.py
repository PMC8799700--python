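"""Synthetic dyadic data with known ground truth.

Every downstream stage (classification, echo-state Granger causality,
pseudo-dyad inference, brain concordance) is exercised on data from this
module, so each generator plants a controllable, recoverable effect:

* :func:`generate_dyad_au` — patient and clinician AU streams evolving as
  per-channel AR(1) noise, with optional directed lagged nonlinear coupling
  between named AU channels (the signal the causality stage must detect).
* :func:`generate_pain_session` — a cuff-pressure pain paradigm in which a
  small set of pain-expressive AUs (lip suck AU28, eye closure AU43, lid
  tighten AU7, brow furrow AU4 by default) shift upward during painful blocks.
* :func:`generate_dyad_brain` — trial-wise parcel beta series for both dyad
  members whose cross-brain correlation in seeded regions is a squashed
  linear function of the dyad's facial-coupling score, plus behavioral
  scores (CARE, Berkeley subscales) generated from the true coupling.
* :func:`build_cohort` — a complete on-disk dataset plus ``truth.json``.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .datatypes import (
    ANTICIPATION_CONDITIONS,
    DEFAULT_AU_LABELS,
    AURecording,
    DyadRoster,
    EventTable,
)
from .exceptions import ParameterError, ProtocolError
from .utils import derive_seed

AU28 = DEFAULT_AU_LABELS.index("AU28_lip_suck")  # 17
AU43 = DEFAULT_AU_LABELS.index("AU43_eye_closure")  # 18
AU07 = DEFAULT_AU_LABELS.index("AU07_lid_tighten")  # 5
AU04 = DEFAULT_AU_LABELS.index("AU04_brow_furrow")  # 2


@dataclass(frozen=True)
class CouplingEdge:
    """Directed lagged coupling: target AU driven by nonlinearity(source AU)."""

    source_role: str
    source_au: int
    target_role: str
    target_au: int
    gain: float
    lag_frames: int = 4

    def __post_init__(self):
        if self.lag_frames < 1:
            raise ParameterError("lag_frames must be >= 1")


# Cohort-default planted edges: patient lip suck (AU28) drives several
# clinician AUs, mirroring a leader-follower pattern in which the patient's
# pain-expressive face leads and the clinician's face follows.
DEFAULT_EDGES: tuple[CouplingEdge, ...] = (
    CouplingEdge("patient", AU28, "clinician", AU43, gain=1.5, lag_frames=4),
    CouplingEdge("patient", AU28, "clinician", AU07, gain=1.0, lag_frames=6),
    CouplingEdge("patient", AU04, "clinician", AU43, gain=0.8, lag_frames=8),
)


@dataclass(frozen=True)
class DyadSimParams:
    """Dyadic AU-stream generator (pain/treatment session layout).

    The session alternates rest, cued anticipation (the causality window,
    duration uniform on ``block_duration_range_s``), painful stimulation, and
    rating, for ``n_blocks`` trials split over ``n_runs`` runs.
    """

    n_aus: int = 20
    sampling_rate_hz: float = 20.0
    n_blocks: int = 12
    n_runs: int = 2
    block_duration_range_s: tuple[float, float] = (6.0, 12.0)
    rest_s: float = 6.0
    stim_s: float = 10.0
    rating_s: float = 5.0
    coupling_edges: tuple[CouplingEdge, ...] = DEFAULT_EDGES
    ar_coef: float = 0.8
    noise_sd: float = 1.0
    nonlinearity: str = "tanh"
    couple_in_pain: bool = False
    seed: int = 0

    def __post_init__(self):
        if not abs(self.ar_coef) < 1:
            raise ParameterError(f"|ar_coef| must be < 1 for stationarity; got {self.ar_coef}")
        if self.noise_sd <= 0:
            raise ParameterError("noise_sd must be positive")
        if self.nonlinearity not in ("tanh", "logistic", "linear"):
            raise ParameterError(f"unknown nonlinearity {self.nonlinearity!r}")
        if self.n_aus != len(DEFAULT_AU_LABELS):
            raise ParameterError("recordings carry exactly 20 AU channels")
        lo, hi = self.block_duration_range_s
        if not (0 < lo <= hi):
            raise ParameterError("invalid block duration range")


@dataclass(frozen=True)
class PainSimParams:
    """Pain-MRI generator: pain vs innocuous cuff-pressure blocks.

    ``discriminative_aus`` lists (channel index, mean shift during painful
    blocks); all other channels are identically distributed across
    conditions.  Defaults plant the pain-expression set AU28 > AU43 > AU7 >
    AU4 with decreasing shifts.
    """

    sampling_rate_hz: float = 20.0
    discriminative_aus: tuple[tuple[int, float], ...] = (
        (AU28, 2.5),
        (AU43, 2.0),
        (AU07, 1.6),
        (AU04, 1.2),
    )
    n_trials_per_condition: int = 3
    n_runs: int = 2
    rest_s: float = 6.0
    cue_s: float = 6.0
    stim_s: float = 10.0
    rating_s: float = 5.0
    ar_coef: float = 0.8
    noise_sd: float = 1.0
    trial_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if len(self.discriminative_aus) < 1:
            raise ParameterError("at least one discriminative AU required")
        for idx, shift in self.discriminative_aus:
            if not np.isfinite(shift):
                raise ParameterError("pain shifts must be finite")
            if not 0 <= idx < len(DEFAULT_AU_LABELS):
                raise ParameterError(f"AU index {idx} out of range")
        if not abs(self.ar_coef) < 1:
            raise ParameterError("|ar_coef| must be < 1")


@dataclass(frozen=True)
class BrainSimParams:
    """Dyadic trial-beta generator with planted cross-brain coupling.

    The trial-wise correlation between the clinician's anterior-insula betas
    and the patient's coupled-ROI betas equals ``tanh(concordance_gain x
    facial_score)``; CARE and Berkeley negative-expressivity scores are
    linear in that true coupling plus noise, clamped to instrument ranges
    (CARE total 9-45; Berkeley subscales 6-42).
    """

    n_parcels: int = 50
    roi_definitions: tuple[tuple[str, tuple[int, ...]], ...] = (
        ("clinician_aIns", (0, 1, 2, 3, 4)),
        ("patient_m_pIns", (5, 6, 7, 8, 9)),
        ("patient_vlPFC", (10, 11, 12, 13)),
        ("patient_TPJ", (14, 15, 16, 17)),
    )
    coupled_patient_rois: tuple[str, ...] = ("patient_m_pIns",)
    n_trials: int = 12
    concordance_gain: float = 0.8
    parcel_noise_sd: float = 0.3
    care_patient_intercept: float = 36.0
    care_clinician_intercept: float = 30.0
    care_slope: float = 10.0
    care_sd: float = 1.5
    negexp_intercept: float = 15.0
    negexp_slope: float = 20.0
    negexp_sd: float = 3.0
    tr_s: float = 1.25
    emit_bold: bool = False
    bold_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        rois = dict(self.roi_definitions)
        by_subject: dict[str, set[int]] = {}
        for name, parcels in rois.items():
            subj = name.split("_")[0]
            if max(parcels) >= self.n_parcels:
                raise ParameterError(f"ROI {name} exceeds parcel range")
            seen = by_subject.setdefault(subj, set())
            if seen & set(parcels):
                raise ParameterError(f"ROI {name} overlaps another ROI of the same subject")
            seen |= set(parcels)


@dataclass
class GroundTruth:
    """Everything needed to score downstream estimates against the generator."""

    coupling_edges: tuple[CouplingEdge, ...] = ()
    coupling_strength: float = 0.0
    block_conditions: list[str] = field(default_factory=list)
    pain_shifts: dict[int, float] = field(default_factory=dict)
    block_labels: list[int] = field(default_factory=list)
    cross_brain_rho: float | None = None
    behavior_coefficients: dict[str, float] = field(default_factory=dict)
    coupled_parcels: tuple[int, ...] = ()
    extras: dict = field(default_factory=dict)


@dataclass
class BetaSeries:
    """Trial-wise parcel parameter estimates (anticipation phase)."""

    subject_id: str
    betas: np.ndarray  # (n_parcels, n_trials)
    conditions: list[str]
    runs: list[int]

    def __post_init__(self):
        self.betas = np.asarray(self.betas, dtype=float)
        if self.betas.ndim != 2:
            raise ParameterError("betas must be (n_parcels, n_trials)")

    @property
    def n_trials(self) -> int:
        return self.betas.shape[1]


@dataclass
class BehavioralScores:
    dyad_id: str
    care_patient: float
    care_clinician: float
    negative_expressivity: float
    positive_expressivity: float
    impulse_strength: float

    @property
    def care_dyad(self) -> float:
        return 0.5 * (self.care_patient + self.care_clinician)


# ---------------------------------------------------------------------------
# Event-table construction
# ---------------------------------------------------------------------------

def _session_events(rng, n_blocks, n_runs, dur_range, rest_s, stim_s, rating_s,
                    anticipation_labels, stim_labels=None) -> EventTable:
    """Trial layout: rest -> cued anticipation -> stimulus -> rating."""
    if n_blocks % n_runs:
        raise ProtocolError("n_blocks must divide evenly across runs")
    rows = []
    t = 0.0
    per_run = n_blocks // n_runs
    for k in range(n_blocks):
        run = k // per_run
        trial = k % per_run
        dur = float(rng.uniform(*dur_range))
        cond_ant = anticipation_labels[k]
        cond_stim = stim_labels[k] if stim_labels is not None else "pain_moderate"
        rows.append((t, rest_s, "rest", trial, run))
        t += rest_s
        rows.append((t, dur, cond_ant, trial, run))
        t += dur
        rows.append((t, stim_s, cond_stim, trial, run))
        t += stim_s
        rows.append((t, rating_s, "rating", trial, run))
        t += rating_s
    df = pd.DataFrame(rows, columns=["onset", "duration", "condition", "trial_index", "run_index"])
    return EventTable(df)


def _frame_mask(events: EventTable, conditions, rate: float, n_frames: int) -> np.ndarray:
    mask = np.zeros(n_frames, dtype=bool)
    for row in events.select(conditions).itertuples(index=False):
        a, b = dio._event_frames(row.onset, row.duration, rate)
        mask[a : min(b, n_frames)] = True
    return mask


_NONLINEARITIES = {
    "tanh": np.tanh,
    "logistic": lambda x: 1.0 / (1.0 + np.exp(-x)) - 0.5,  # centered at 0
    "linear": lambda x: x,
}


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def generate_dyad_au(p: DyadSimParams):
    """Simulate a dyad's AU streams for one pain/treatment session.

    Each channel evolves as AR(1) with Gaussian innovations; for every
    coupling edge, the target channel additionally receives ``gain *
    f(source value lagged by lag_frames)`` while the dyad is inside an
    anticipation block (optionally also pain blocks).

    Returns ``(patient AURecording, clinician AURecording, EventTable,
    GroundTruth)``.
    """
    rng = np.random.default_rng(p.seed)
    n_treat = int(round(p.n_blocks * 2 / 3))
    labels = ["anticipation_treat"] * n_treat + ["anticipation_notreat"] * (p.n_blocks - n_treat)
    labels = list(rng.permutation(labels))
    events = _session_events(
        rng, p.n_blocks, p.n_runs, p.block_duration_range_s,
        p.rest_s, p.stim_s, p.rating_s, labels,
    )
    rate = p.sampling_rate_hz
    n_frames = int(np.ceil(events.end_s() * rate))
    active = _frame_mask(events, ANTICIPATION_CONDITIONS, rate, n_frames)
    if p.couple_in_pain:
        active |= _frame_mask(events, {"pain_moderate", "pain_innocuous"}, rate, n_frames)

    f = _NONLINEARITIES[p.nonlinearity]
    streams = {
        "patient": np.zeros((n_frames, p.n_aus)),
        "clinician": np.zeros((n_frames, p.n_aus)),
    }
    noise = {
        role: rng.normal(0.0, p.noise_sd, size=(n_frames, p.n_aus)) for role in streams
    }
    edges = tuple(p.coupling_edges)
    for t in range(n_frames):
        for role in ("patient", "clinician"):
            prev = streams[role][t - 1] if t > 0 else 0.0
            streams[role][t] = p.ar_coef * prev + noise[role][t]
        if active[t]:
            for e in edges:
                if t - e.lag_frames >= 0:
                    src = streams[e.source_role][t - e.lag_frames, e.source_au]
                    streams[e.target_role][t, e.target_au] += e.gain * f(src)

    pat = AURecording("patient", "patient", rate, streams["patient"])
    cli = AURecording("clinician", "clinician", rate, streams["clinician"])
    truth = GroundTruth(
        coupling_edges=edges,
        coupling_strength=float(np.mean([e.gain for e in edges])) if edges else 0.0,
        block_conditions=labels,
    )
    return pat, cli, events, truth


def generate_pain_session(p: PainSimParams):
    """Simulate a patient's pain-MRI session (pain vs innocuous blocks).

    Returns ``(AURecording, EventTable, GroundTruth)``; ``GroundTruth.block_labels``
    holds the binary pain label (1 = moderate pain) per stimulus block in
    chronological order.
    """
    rng = np.random.default_rng(p.seed)
    n_blocks = 2 * p.n_trials_per_condition * p.n_runs
    per_run = 2 * p.n_trials_per_condition
    stim_labels: list[str] = []
    for _ in range(p.n_runs):
        run_labels = ["pain_moderate"] * p.n_trials_per_condition + \
                     ["pain_innocuous"] * p.n_trials_per_condition
        stim_labels.extend(rng.permutation(run_labels))
    ant_labels = ["anticipation_pain" if s == "pain_moderate" else "anticipation_nopain"
                  for s in stim_labels]
    events = _session_events(
        rng, n_blocks, p.n_runs, (p.cue_s, p.cue_s),
        p.rest_s, p.stim_s, p.rating_s, ant_labels, stim_labels,
    )
    rate = p.sampling_rate_hz
    n_frames = int(np.ceil(events.end_s() * rate))
    n_aus = len(DEFAULT_AU_LABELS)

    values = np.zeros((n_frames, n_aus))
    innov = rng.normal(0.0, p.noise_sd, size=(n_frames, n_aus))
    for t in range(1, n_frames):
        values[t] = p.ar_coef * values[t - 1] + innov[t]
    values[0] = innov[0]

    # additive pain-expression shift during moderate-pain blocks
    pain_rows = events.select({"pain_moderate"})
    for row in pain_rows.itertuples(index=False):
        a, b = dio._event_frames(row.onset, row.duration, rate)
        for au, shift in p.discriminative_aus:
            values[a:b, au] += shift + rng.normal(0.0, p.trial_sd)

    rec = AURecording("patient", "patient", rate, values)
    block_labels = [1 if s == "pain_moderate" else 0 for s in stim_labels]
    truth = GroundTruth(
        pain_shifts={au: s for au, s in p.discriminative_aus},
        block_labels=block_labels,
        block_conditions=stim_labels,
    )
    return rec, events, truth


def _double_gamma_hrf(dt: float, duration_s: float = 32.0,
                      peak=6.0, undershoot=16.0, ratio=1.0 / 6.0) -> np.ndarray:
    from scipy.stats import gamma

    t = np.arange(0, duration_s, dt)
    h = gamma.pdf(t, peak) - ratio * gamma.pdf(t, undershoot)
    return h / h.max()


def _trial_design(events: EventTable, tr_s: float, n_tp: int) -> tuple[np.ndarray, list[str]]:
    """Design matrix: one HRF-convolved regressor per anticipation trial plus
    pain and rating nuisance regressors and an intercept."""
    oversample = 10
    dt = tr_s / oversample
    n_fine = n_tp * oversample
    hrf = _double_gamma_hrf(dt)

    def conv(onsets_durs):
        box = np.zeros(n_fine)
        for onset, dur in onsets_durs:
            a = int(round(onset / dt))
            b = int(round((onset + dur) / dt))
            box[a : min(b, n_fine)] = 1.0
        reg = np.convolve(box, hrf)[:n_fine]
        return reg[::oversample]

    cols, names = [], []
    ant = events.select(ANTICIPATION_CONDITIONS)
    for k, row in enumerate(ant.itertuples(index=False)):
        cols.append(conv([(row.onset, row.duration)]))
        names.append(f"anticipation_trial{k:02d}")
    for cond in ("pain", "rating"):
        sel = events.events[events.events["condition"].str.startswith(cond)]
        if len(sel):
            cols.append(conv(list(zip(sel["onset"], sel["duration"]))))
            names.append(cond)
    cols.append(np.ones(n_tp))
    names.append("intercept")
    return np.column_stack(cols), names


def generate_dyad_brain(p: BrainSimParams, facial_score: float, seed: int | None = None):
    """Simulate dyadic trial betas, behavioral scores, and (optionally) raw BOLD.

    The trial-wise correlation between clinician anterior-insula betas and
    patient coupled-ROI betas is ``rho = tanh(concordance_gain * facial_score)``.
    Returns ``(patient BetaSeries, clinician BetaSeries, BehavioralScores,
    GroundTruth)``.
    """
    if not np.isfinite(facial_score):
        raise ParameterError("facial_score must be finite")
    rng = np.random.default_rng(p.seed if seed is None else seed)
    rho = float(np.tanh(p.concordance_gain * facial_score))
    if not -1.0 < rho < 1.0:
        raise ParameterError(f"requested cross-brain correlation {rho} outside (-1, 1)")

    latent = rng.multivariate_normal([0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=p.n_trials)
    a, b = latent[:, 0], latent[:, 1]  # clinician aIns signal, patient coupled signal

    rois = dict(p.roi_definitions)
    coupled_parcels: list[int] = []
    for name in p.coupled_patient_rois:
        coupled_parcels.extend(rois[name])

    def subject_betas(signal, seeded_parcels):
        betas = rng.standard_normal((p.n_parcels, p.n_trials))
        for parcel in seeded_parcels:
            betas[parcel] = signal + rng.normal(0.0, p.parcel_noise_sd, size=p.n_trials)
        return betas

    cli_betas = subject_betas(a, rois["clinician_aIns"])
    pat_betas = subject_betas(b, coupled_parcels)

    n_treat = int(round(p.n_trials * 2 / 3))
    conds = ["anticipation_treat"] * n_treat + ["anticipation_notreat"] * (p.n_trials - n_treat)
    conds = list(rng.permutation(conds))
    runs = [k // (p.n_trials // 2) for k in range(p.n_trials)]

    pat_bs = BetaSeries("patient", pat_betas, conds, runs)
    cli_bs = BetaSeries("clinician", cli_betas, conds, runs)

    def clamp(x, lo, hi):
        return float(np.clip(x, lo, hi))

    scores = BehavioralScores(
        dyad_id="",
        care_patient=clamp(p.care_patient_intercept + p.care_slope * rho + rng.normal(0, p.care_sd), 9, 45),
        care_clinician=clamp(p.care_clinician_intercept + p.care_slope * rho + rng.normal(0, p.care_sd), 9, 45),
        negative_expressivity=clamp(p.negexp_intercept + p.negexp_slope * rho + rng.normal(0, p.negexp_sd), 6, 42),
        positive_expressivity=clamp(rng.normal(28, 4), 6, 42),
        impulse_strength=clamp(rng.normal(24, 4), 6, 42),
    )
    truth = GroundTruth(
        cross_brain_rho=rho,
        behavior_coefficients={
            "care_slope": p.care_slope,
            "care_sd": p.care_sd,
            "negexp_slope": p.negexp_slope,
            "negexp_sd": p.negexp_sd,
        },
        coupled_parcels=tuple(coupled_parcels),
    )

    if p.emit_bold:
        # Emit parcel BOLD consistent with the betas so the first-level
        # beta-series GLM can be exercised end to end.
        bold_rng = np.random.default_rng(derive_seed(p.seed if seed is None else seed, "bold"))
        n_blocks = p.n_trials
        labels = conds
        ev = _session_events(bold_rng, n_blocks, 2, (6.0, 12.0), 6.0, 10.0, 5.0, labels)
        n_tp = int(np.ceil(ev.end_s() / p.tr_s)) + 8
        X, names = _trial_design(ev, p.tr_s, n_tp)
        bolds = {}
        for who, betas in (("patient", pat_betas), ("clinician", cli_betas)):
            coefs = np.zeros((X.shape[1], p.n_parcels))
            coefs[: p.n_trials] = betas.T
            coefs[p.n_trials :] = bold_rng.standard_normal((X.shape[1] - p.n_trials, p.n_parcels))
            bold = (X @ coefs).T + bold_rng.normal(0, p.bold_noise_sd, size=(p.n_parcels, n_tp))
            bolds[who] = bold
        truth.extras = {"bold_patient": bolds["patient"], "bold_clinician": bolds["clinician"],
                        "bold_events": ev, "tr_s": p.tr_s}
    return pat_bs, cli_bs, scores, truth


# ---------------------------------------------------------------------------
# Cohort builder
# ---------------------------------------------------------------------------

def build_cohort(
    out_dir,
    n_dyads: int,
    dyad_params: DyadSimParams | None = None,
    pain_params: PainSimParams | None = None,
    brain_params: BrainSimParams | None = None,
    gain_jitter_range: tuple[float, float] = (0.25, 1.75),
    seed: int = 0,
    overwrite: bool = False,
) -> DyadRoster:
    """Write a complete loadable cohort dataset and its ground truth.

    Per-dyad coupling gains are jittered by a uniform factor so the facial
    coupling score varies across dyads; the dyad's brain/behavior data are
    generated from that same score, closing the loop the concordance stage
    must recover.
    """
    if n_dyads < 2:
        raise ParameterError("a cohort needs at least 2 dyads")
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise ParameterError(f"output dir {out} is not empty (pass overwrite=True)")
    out.mkdir(parents=True, exist_ok=True)

    dyad_params = dyad_params or DyadSimParams()
    pain_params = pain_params or PainSimParams()
    brain_params = brain_params or BrainSimParams()

    roster_rows, score_rows, truth = [], [], {"dyads": {}}
    for d in range(n_dyads):
        dyad_id = f"dyad{d:03d}"
        pat_id, cli_id = f"pat{d:03d}", f"cli{d:03d}"
        ddir = out / "dyads" / dyad_id

        jit_rng = np.random.default_rng(derive_seed(seed, "jitter", d))
        factor = float(jit_rng.uniform(*gain_jitter_range))
        edges = tuple(
            dataclasses.replace(e, gain=e.gain * factor) for e in dyad_params.coupling_edges
        )
        dp = dataclasses.replace(dyad_params, coupling_edges=edges, seed=derive_seed(seed, "au", d))
        pat, cli, events, au_truth = generate_dyad_au(dp)
        pat.subject_id, cli.subject_id = pat_id, cli_id
        dio.write_au_recording(pat, ddir / "patient_au.csv")
        dio.write_au_recording(cli, ddir / "clinician_au.csv")
        dio.write_events(events, ddir / "events.tsv")

        pp = dataclasses.replace(pain_params, seed=derive_seed(seed, "pain", d))
        pain_rec, pain_events, pain_truth = generate_pain_session(pp)
        pain_rec.subject_id = pat_id
        dio.write_au_recording(pain_rec, ddir / "pain_patient_au.csv")
        dio.write_events(pain_events, ddir / "pain_events.tsv")

        facial_score = au_truth.coupling_strength
        pat_bs, cli_bs, scores, brain_truth = generate_dyad_brain(
            brain_params, facial_score, seed=derive_seed(seed, "brain", d)
        )
        for bs, name in ((pat_bs, "patient_betas.csv"), (cli_bs, "clinician_betas.csv")):
            df = pd.DataFrame(bs.betas, columns=[f"trial{t:02d}" for t in range(bs.n_trials)])
            df.insert(0, "parcel", np.arange(brain_params.n_parcels))
            df.to_csv(ddir / name, index=False, float_format="%.17g")

        roster_rows.append((dyad_id, pat_id, cli_id, True))
        score_rows.append(
            (dyad_id, scores.care_patient, scores.care_clinician, scores.care_dyad,
             scores.negative_expressivity, scores.positive_expressivity, scores.impulse_strength)
        )
        truth["dyads"][dyad_id] = {
            "facial_score": facial_score,
            "gain_factor": factor,
            "edges": [dataclasses.asdict(e) for e in edges],
            "cross_brain_rho": brain_truth.cross_brain_rho,
            "coupled_parcels": list(brain_truth.coupled_parcels),
            "pain_block_labels": pain_truth.block_labels,
            "pain_shifts": {str(k): v for k, v in pain_truth.pain_shifts.items()},
        }

    roster = DyadRoster(pd.DataFrame(roster_rows, columns=["dyad_id", "patient_id", "clinician_id", "is_real"]))
    dio.write_roster(roster, out / "roster.csv")
    pd.DataFrame(
        score_rows,
        columns=["dyad_id", "care_patient", "care_clinician", "care_dyad",
                 "negative_expressivity", "positive_expressivity", "impulse_strength"],
    ).to_csv(out / "scores.csv", index=False, float_format="%.17g")
    truth["behavior_coefficients"] = {
        "care_slope": brain_params.care_slope,
        "negexp_slope": brain_params.negexp_slope,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    params_echo = {
        "seed": seed,
        "n_dyads": n_dyads,
        "gain_jitter_range": list(gain_jitter_range),
        "dyad_params": _params_dict(dyad_params),
        "pain_params": _params_dict(pain_params),
        "brain_params": _params_dict(brain_params),
    }
    (out / "params.json").write_text(json.dumps(params_echo, indent=1, sort_keys=True, default=str))
    return roster


def _params_dict(p) -> dict:
    d = dataclasses.asdict(p)
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
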