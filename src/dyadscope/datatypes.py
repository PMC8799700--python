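"""Core domain types shared by every analysis stage.

The pipeline works on framewise facial action-unit (AU) recordings from both
members of a patient-clinician dyad, block/trial annotations, and trial-wise
parcel beta series.  Types validate their invariants at construction time;
readers reject malformed inputs instead of coercing them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError, ProtocolError, SchemaError

N_AU_CHANNELS = 20

#: Affectiva-style channel manifest: 20 facial action units, FACS codes where
#: they exist.  Matrices are only comparable across dyads if every recording
#: in a cohort uses this order, so the manifest is cohort-level configuration.
DEFAULT_AU_LABELS: tuple[str, ...] = (
    "AU01_inner_brow_raise",
    "AU02_outer_brow_raise",
    "AU04_brow_furrow",
    "AU05_eye_widen",
    "AU06_cheek_raise",
    "AU07_lid_tighten",
    "AU09_nose_wrinkle",
    "AU10_upper_lip_raise",
    "AU12_lip_corner_pull",
    "AU14_dimpler",
    "AU15_lip_corner_depress",
    "AU17_chin_raise",
    "AU18_lip_pucker",
    "AU20_lip_stretch",
    "AU24_lip_press",
    "AU25_lips_part",
    "AU26_jaw_drop",
    "AU28_lip_suck",
    "AU43_eye_closure",
    "smirk",
)

ROLES = ("patient", "clinician")

CONDITIONS = (
    "anticipation_pain",
    "anticipation_nopain",
    "anticipation_treat",
    "anticipation_notreat",
    "pain_moderate",
    "pain_innocuous",
    "rating",
    "rest",
)

#: Conditions over which directed facial causality is estimated (the cued
#: pre-stimulus windows) and over which pain states are classified.
ANTICIPATION_CONDITIONS = frozenset(
    {"anticipation_pain", "anticipation_nopain", "anticipation_treat", "anticipation_notreat"}
)
PAIN_CONDITIONS = frozenset({"pain_moderate", "pain_innocuous"})

EVENT_COLUMNS = ("onset", "duration", "condition", "trial_index", "run_index")
ROSTER_COLUMNS = ("dyad_id", "patient_id", "clinician_id", "is_real")


@dataclass
class AURecording:
    """Framewise 20-channel AU activations for one subject.

    ``values`` has shape ``(n_frames, 20)`` with one column per entry of
    ``au_labels``; frame indices run gap-free from ``frame_start``.
    """

    subject_id: str
    role: str
    sampling_rate_hz: float
    values: np.ndarray
    au_labels: tuple[str, ...] = DEFAULT_AU_LABELS
    frame_start: int = 0

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise SchemaError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if not np.isfinite(self.sampling_rate_hz) or self.sampling_rate_hz <= 0:
            raise DataError("sampling_rate_hz must be a positive real")
        self.values = np.asarray(self.values, dtype=float)
        self.au_labels = tuple(self.au_labels)
        if self.values.ndim != 2 or self.values.shape[1] != N_AU_CHANNELS:
            raise SchemaError(
                f"AU value array must be (n_frames, {N_AU_CHANNELS}); got {self.values.shape}"
            )
        if len(self.au_labels) != N_AU_CHANNELS:
            raise SchemaError(f"expected {N_AU_CHANNELS} AU labels, got {len(self.au_labels)}")
        if len(set(self.au_labels)) != N_AU_CHANNELS:
            raise SchemaError("AU labels must be unique")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))
            frame = int(bad[0, 0]) + self.frame_start
            raise DataError(f"non-finite AU value at frame {frame}, channel {self.au_labels[bad[0, 1]]}")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.sampling_rate_hz

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.values[:, self.au_labels.index(label)]
        except ValueError:
            raise SchemaError(f"unknown AU label {label!r}") from None


@dataclass
class EventTable:
    """Block/trial annotations (BIDS-events style, onsets in seconds).

    Onsets are on the recording's own clock, cumulative across runs, so an
    event maps directly to frames of the continuous recording.
    """

    events: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.events
        missing = set(EVENT_COLUMNS) - set(df.columns)
        if missing:
            raise SchemaError(f"event table missing columns: {sorted(missing)}")
        df = df.loc[:, list(EVENT_COLUMNS)].reset_index(drop=True)
        if not np.isfinite(df["onset"]).all() or (df["onset"] < 0).any():
            raise DataError("event onsets must be finite and >= 0")
        if not np.isfinite(df["duration"]).all() or (df["duration"] <= 0).any():
            raise DataError("event durations must be finite and > 0")
        unknown = set(df["condition"]) - set(CONDITIONS)
        if unknown:
            raise SchemaError(f"unknown conditions: {sorted(unknown)}")
        for run, grp in df.groupby("run_index"):
            grp = grp.sort_values("onset")
            ends = (grp["onset"] + grp["duration"]).to_numpy()
            if (grp["onset"].to_numpy()[1:] < ends[:-1] - 1e-9).any():
                raise ProtocolError(f"overlapping events in run {run}")
            if grp["trial_index"].duplicated().any():
                # trial_index groups the phases of one trial; duplicates are
                # only allowed across distinct conditions
                dup = grp[grp.duplicated(["trial_index", "condition"], keep=False)]
                if len(dup):
                    raise ProtocolError(f"duplicate (trial, condition) rows in run {run}")
        self.events = df

    def __len__(self) -> int:
        return len(self.events)

    def select(self, conditions) -> pd.DataFrame:
        conditions = set(conditions)
        out = self.events[self.events["condition"].isin(conditions)]
        return out.sort_values(["run_index", "onset"]).reset_index(drop=True)

    def end_s(self) -> float:
        return float((self.events["onset"] + self.events["duration"]).max())


@dataclass
class DyadRoster:
    """Patient-clinician pairings; pseudo-dyads carry ``is_real == False``."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = set(ROSTER_COLUMNS) - set(df.columns)
        if missing:
            raise SchemaError(f"roster missing columns: {sorted(missing)}")
        df = df.loc[:, list(ROSTER_COLUMNS)].reset_index(drop=True)
        df["is_real"] = df["is_real"].astype(bool)
        if df["dyad_id"].duplicated().any():
            raise SchemaError("duplicate dyad_id in roster")
        self.table = df

    def __len__(self) -> int:
        return len(self.table)

    @property
    def real(self) -> pd.DataFrame:
        return self.table[self.table["is_real"]].reset_index(drop=True)

    @property
    def pseudo(self) -> pd.DataFrame:
        return self.table[~self.table["is_real"]].reset_index(drop=True)


@dataclass
class BlockSeries:
    """One time-aligned dyadic block: patient and clinician AU segments."""

    dyad_id: str
    condition: str
    block_index: int
    patient_segment: np.ndarray
    clinician_segment: np.ndarray

    def __post_init__(self) -> None:
        self.patient_segment = np.asarray(self.patient_segment, dtype=float)
        self.clinician_segment = np.asarray(self.clinician_segment, dtype=float)
        if self.patient_segment.shape != self.clinician_segment.shape:
            raise DataError(
                "patient and clinician segments must be time-aligned with equal shape; "
                f"got {self.patient_segment.shape} vs {self.clinician_segment.shape}"
            )

    @property
    def n_frames(self) -> int:
        return self.patient_segment.shape[0]


@dataclass
class GCMatrix:
    """Directed Granger-causality strengths, (source AU, target AU) indexed."""

    dyad_id: str
    direction: str  # "patient_to_clinician" | "clinician_to_patient"
    paradigm: str  # "anticipation" | "pain"
    values: np.ndarray
    source_labels: tuple[str, ...] = DEFAULT_AU_LABELS
    target_labels: tuple[str, ...] = DEFAULT_AU_LABELS
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.source_labels = tuple(self.source_labels)
        self.target_labels = tuple(self.target_labels)
        if self.values.shape != (len(self.source_labels), len(self.target_labels)):
            raise SchemaError(
                f"GC matrix shape {self.values.shape} does not match labels "
                f"({len(self.source_labels)}, {len(self.target_labels)})"
            )
        if self.missing is None:
            self.missing = ~np.isfinite(self.values)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)


DIRECTIONS = ("patient_to_clinician", "clinician_to_patient")
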