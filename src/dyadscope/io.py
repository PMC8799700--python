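"""Readers, writers, and block segmentation.

File formats (all plain text):

* AU CSV — columns ``frame,time_s,<AU label x20>``, one row per video frame.
* Events TSV — BIDS-events style: ``onset,duration,condition,trial_index,run_index``.
* Roster CSV — ``dyad_id,patient_id,clinician_id,is_real``.
* Matrix CSV — header row/column of AU labels, row = source AU, column = target AU.

Floats are written with 17 significant digits so write/read round trips are
bit-identical.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    AURecording,
    BlockSeries,
    DyadRoster,
    EventTable,
    N_AU_CHANNELS,
)
from .exceptions import AlignmentError, BoundsError, DataError, SchemaError

_FLOAT_FMT = "%.17g"


# ---------------------------------------------------------------------------
# AU recordings
# ---------------------------------------------------------------------------

def load_au_recording(
    path,
    subject_id: str,
    role: str,
    sampling_rate_hz: float = 20.0,
    au_labels=None,
) -> AURecording:
    """Load a framewise AU CSV and validate it against the cohort manifest.

    Channel order in the file may differ from ``au_labels``; columns are
    normalized to the manifest order.  Missing/extra AU columns, non-monotone
    frame indices, and NaNs are rejected.
    """
    from .datatypes import DEFAULT_AU_LABELS

    labels = tuple(au_labels) if au_labels is not None else DEFAULT_AU_LABELS
    df = pd.read_csv(path, float_precision="round_trip")
    if "frame" not in df.columns:
        raise SchemaError(f"{path}: missing 'frame' column")
    au_cols = [c for c in df.columns if c not in ("frame", "time_s")]
    if set(au_cols) != set(labels):
        missing = sorted(set(labels) - set(au_cols))
        extra = sorted(set(au_cols) - set(labels))
        raise SchemaError(
            f"{path}: AU columns do not match the cohort manifest "
            f"(missing={missing}, extra={extra}, expected {N_AU_CHANNELS})"
        )
    frames = df["frame"].to_numpy()
    if len(frames) == 0:
        raise DataError(f"{path}: empty recording")
    diffs = np.diff(frames)
    if (diffs != 1).any():
        bad = int(frames[np.argmax(diffs != 1)])
        raise DataError(f"{path}: frame indices must be strictly increasing and gap-free (after frame {bad})")
    values = df.loc[:, list(labels)].to_numpy(dtype=float)
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise DataError(f"{path}: NaN AU value at frame {int(frames[r])}, channel {labels[c]}")
    return AURecording(
        subject_id=subject_id,
        role=role,
        sampling_rate_hz=sampling_rate_hz,
        values=values,
        au_labels=labels,
        frame_start=int(frames[0]),
    )


def write_au_recording(rec: AURecording, path) -> None:
    frames = np.arange(rec.frame_start, rec.frame_start + rec.n_frames)
    df = pd.DataFrame({"frame": frames, "time_s": frames / rec.sampling_rate_hz})
    for j, label in enumerate(rec.au_labels):
        df[label] = rec.values[:, j]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# Events and rosters
# ---------------------------------------------------------------------------

def load_events(path) -> EventTable:
    df = pd.read_csv(path, sep="\t")
    return EventTable(df)


def write_events(events: EventTable, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    events.events.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def load_roster(path) -> DyadRoster:
    return DyadRoster(pd.read_csv(path))


def write_roster(roster: DyadRoster, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    roster.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------

def write_matrix(values: np.ndarray, labels, path, target_labels=None) -> None:
    """Write a directed (source x target) matrix as labelled CSV."""
    values = np.asarray(values, dtype=float)
    row_labels = list(labels)
    col_labels = list(target_labels) if target_labels is not None else row_labels
    if values.shape != (len(row_labels), len(col_labels)):
        raise SchemaError(f"matrix shape {values.shape} does not match labels "
                          f"({len(row_labels)}, {len(col_labels)})")
    df = pd.DataFrame(values, index=row_labels, columns=col_labels)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index_label="source_au", float_format=_FLOAT_FMT)


def read_matrix(path):
    """Read a labelled matrix CSV; returns ``(values, row_labels, col_labels)``."""
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    return df.to_numpy(dtype=float), tuple(df.index), tuple(df.columns)


# ---------------------------------------------------------------------------
# Block segmentation
# ---------------------------------------------------------------------------

def _event_frames(onset: float, duration: float, rate: float) -> tuple[int, int]:
    # Half-open [onset, onset+duration) window; n_frames = round(duration*rate)
    # by construction, so boundary frames are never double counted.
    start = int(round(onset * rate))
    n = int(round(duration * rate))
    return start, start + n


def segment_blocks(
    patient: AURecording,
    clinician: AURecording,
    events: EventTable,
    conditions,
    dyad_id: str = "",
) -> list[BlockSeries]:
    """Cut time-aligned dyadic blocks for every event matching ``conditions``.

    Both recordings must share a sampling rate and clock; the event window is
    the half-open frame interval ``[round(onset*rate), round(onset*rate) +
    round(duration*rate))``.
    """
    if patient.sampling_rate_hz != clinician.sampling_rate_hz:
        raise AlignmentError(
            f"sampling rates differ: {patient.sampling_rate_hz} vs {clinician.sampling_rate_hz}"
        )
    rate = patient.sampling_rate_hz
    rows = events.select(conditions)
    blocks: list[BlockSeries] = []
    for k, row in enumerate(rows.itertuples(index=False)):
        start, stop = _event_frames(row.onset, row.duration, rate)
        for rec in (patient, clinician):
            if start < rec.frame_start or stop > rec.frame_start + rec.n_frames:
                raise BoundsError(
                    f"event (onset={row.onset}, duration={row.duration}) exceeds "
                    f"recording {rec.subject_id} ({rec.n_frames} frames)"
                )
        i0, i1 = start - patient.frame_start, stop - patient.frame_start
        j0, j1 = start - clinician.frame_start, stop - clinician.frame_start
        blocks.append(
            BlockSeries(
                dyad_id=dyad_id,
                condition=row.condition,
                block_index=k,
                patient_segment=patient.values[i0:i1],
                clinician_segment=clinician.values[j0:j1],
            )
        )
    return blocks


def segment_pseudo_blocks(
    patient: AURecording,
    patient_events: EventTable,
    clinician: AURecording,
    clinician_events: EventTable,
    conditions,
    dyad_id: str = "",
) -> list[BlockSeries]:
    """Blocks for a pseudo-dyad whose members followed their own protocols.

    Each member's blocks are cut with their own event table and paired by
    block index; each pair is truncated to the shorter member so segments
    stay time-aligned in length.  This preserves the shared protocol
    structure while pairing subjects who never interacted.
    """
    if patient.sampling_rate_hz != clinician.sampling_rate_hz:
        raise AlignmentError("pseudo-dyad members must share a sampling rate")
    rate = patient.sampling_rate_hz
    prows = patient_events.select(conditions)
    crows = clinician_events.select(conditions)
    n = min(len(prows), len(crows))
    blocks: list[BlockSeries] = []
    for k in range(n):
        p = prows.iloc[k]
        c = crows.iloc[k]
        p0, p1 = _event_frames(p["onset"], p["duration"], rate)
        c0, c1 = _event_frames(c["onset"], c["duration"], rate)
        m = min(p1 - p0, c1 - c0)
        blocks.append(
            BlockSeries(
                dyad_id=dyad_id,
                condition=str(p["condition"]),
                block_index=k,
                patient_segment=patient.values[p0 - patient.frame_start : p0 - patient.frame_start + m],
                clinician_segment=clinician.values[c0 - clinician.frame_start : c0 - clinician.frame_start + m],
            )
        )
    return blocks
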