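"""Shared fixtures and cohort-building helpers for the test suite."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

from dyadscope.datatypes import DEFAULT_AU_LABELS, DyadRoster
from dyadscope.simulate import CouplingEdge, DyadSimParams, generate_dyad_au
from dyadscope.utils import derive_seed

# AU channel subset used for desk-scale causality grids: the planted
# pain-expression channels plus one neutral channel layout (4 x 4 grid).
GRID_CHANNELS = (
    "AU28_lip_suck",
    "AU43_eye_closure",
    "AU07_lid_tighten",
    "AU04_brow_furrow",
)

#: Two strong planted patient->clinician edges inside the 4-channel sub-grid.
PLANTED_EDGES = (
    CouplingEdge("patient", DEFAULT_AU_LABELS.index("AU28_lip_suck"),
                 "clinician", DEFAULT_AU_LABELS.index("AU43_eye_closure"),
                 gain=3.0, lag_frames=3),
    CouplingEdge("patient", DEFAULT_AU_LABELS.index("AU07_lid_tighten"),
                 "clinician", DEFAULT_AU_LABELS.index("AU04_brow_furrow"),
                 gain=3.0, lag_frames=3),
)

PLANTED_CELLS = (("AU28_lip_suck", "AU43_eye_closure"),
                 ("AU07_lid_tighten", "AU04_brow_furrow"))


def fast_dyad_params(**overrides) -> DyadSimParams:
    """Session layout with short rest/stimulus periods for desk-scale runs."""
    defaults = dict(rest_s=2.0, stim_s=3.0, rating_s=2.0,
                    n_blocks=6, block_duration_range_s=(2.5, 3.5))
    defaults.update(overrides)
    return DyadSimParams(**defaults)


def make_cohort(n_dyads: int, params: DyadSimParams, seed: int):
    """In-memory cohort: per-dyad recordings/events plus a roster."""
    dyads = {}
    rows = []
    for d in range(n_dyads):
        dp = dataclasses.replace(params, seed=derive_seed(seed, "au", d))
        pat, cli, events, _ = generate_dyad_au(dp)
        dyad_id = f"dyad{d:03d}"
        pat.subject_id, cli.subject_id = f"pat{d:03d}", f"cli{d:03d}"
        dyads[dyad_id] = (pat, cli, events)
        rows.append((dyad_id, pat.subject_id, cli.subject_id, True))
    roster = DyadRoster(pd.DataFrame(
        rows, columns=["dyad_id", "patient_id", "clinician_id", "is_real"]))
    return dyads, roster


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
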