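"""Ground-truth fidelity of the synthetic generators."""

import dataclasses
import hashlib
from pathlib import Path

import numpy as np
import pytest

from dyadscope import io as dio
from dyadscope.datatypes import ANTICIPATION_CONDITIONS, DEFAULT_AU_LABELS
from dyadscope.exceptions import ParameterError
from dyadscope.inference import enumerate_pseudo_dyads
from dyadscope.simulate import (
    AU28,
    AU43,
    BrainSimParams,
    CouplingEdge,
    DyadSimParams,
    PainSimParams,
    build_cohort,
    generate_dyad_au,
    generate_dyad_brain,
    generate_pain_session,
)

from conftest import fast_dyad_params


class TestDyadAU:
    def test_same_seed_identical(self):
        a = generate_dyad_au(DyadSimParams(seed=7))
        b = generate_dyad_au(DyadSimParams(seed=7))
        np.testing.assert_array_equal(a[0].values, b[0].values)
        np.testing.assert_array_equal(a[1].values, b[1].values)
        assert a[2].events.equals(b[2].events)

    def test_uncoupled_streams_uncorrelated(self):
        p = DyadSimParams(coupling_edges=(), n_blocks=4,
                          block_duration_range_s=(30.0, 30.0), seed=5)
        pat, cli, *_ = generate_dyad_au(p)
        r = np.corrcoef(pat.values[:, AU28], cli.values[:, AU43])[0, 1]
        assert abs(r) < 0.1

    def test_planted_edge_peaks_at_its_lag(self):
        edge = CouplingEdge("patient", AU28, "clinician", AU43, gain=1.0, lag_frames=5)
        p = DyadSimParams(coupling_edges=(edge,), n_blocks=4,
                          block_duration_range_s=(30.0, 30.0), seed=9)
        pat, cli, events, _ = generate_dyad_au(p)
        blocks = dio.segment_blocks(pat, cli, events, ANTICIPATION_CONDITIONS)
        # brute-force cross-correlogram oracle on the target's innovations
        # (removing the target's own AR memory isolates the coupling lag)
        corr = []
        for lag in range(12):
            vals = []
            for b in blocks:
                innov = b.clinician_segment[1:, AU43] - p.ar_coef * b.clinician_segment[:-1, AU43]
                x = b.patient_segment[1 : b.n_frames - lag, AU28]
                y = innov[lag:]
                vals.append(np.corrcoef(x, y)[0, 1])
            corr.append(np.mean(vals))
        assert int(np.argmax(corr)) == 5

    def test_unstable_ar_rejected(self):
        with pytest.raises(ParameterError, match="stationarity"):
            DyadSimParams(ar_coef=1.0)

    def test_coupling_restricted_to_anticipation_by_default(self):
        edge = CouplingEdge("patient", AU28, "clinician", AU43, gain=5.0, lag_frames=2)
        p = fast_dyad_params(coupling_edges=(edge,), seed=3)
        pat, cli, events, _ = generate_dyad_au(p)
        rate = p.sampling_rate_hz
        rest = events.select({"rest"})
        vals = []
        for row in rest.itertuples(index=False):
            a, b = dio._event_frames(row.onset, row.duration, rate)
            # skip edge frames where anticipation coupling can bleed via AR memory
            x = pat.values[a + 5 : b - 2, AU28]
            y = cli.values[a + 7 : b, AU43]
            if len(x) > 4:
                vals.append(np.corrcoef(x, y)[0, 1])
        assert abs(np.mean(vals)) < 0.25


class TestPainSession:
    def test_default_protocol_yields_12_labeled_blocks(self):
        rec, events, truth = generate_pain_session(PainSimParams(seed=1))
        stim = events.select({"pain_moderate", "pain_innocuous"})
        assert len(stim) == 12
        assert len(truth.block_labels) == 12
        assert sum(truth.block_labels) == 6  # balanced pain/innocuous

    def test_planted_shift_recovered_by_sample_means(self):
        p = PainSimParams(discriminative_aus=((AU28, 2.0),), trial_sd=0.0,
                          n_trials_per_condition=12, n_runs=2, seed=2)
        rec, events, _ = generate_pain_session(p)
        means = {}
        for cond in ("pain_moderate", "pain_innocuous"):
            sel = events.select({cond})
            segs = []
            for row in sel.itertuples(index=False):
                a, b = dio._event_frames(row.onset, row.duration, p.sampling_rate_hz)
                segs.append(rec.values[a:b, AU28])
            means[cond] = np.concatenate(segs).mean()
        diff = means["pain_moderate"] - means["pain_innocuous"]
        assert diff == pytest.approx(2.0, abs=0.25)

    def test_zero_shift_requires_discriminative_entry(self):
        with pytest.raises(ParameterError):
            PainSimParams(discriminative_aus=())


class TestDyadBrain:
    def test_zero_gain_gives_zero_mean_coupling(self):
        rs = []
        for s in range(100):
            p = BrainSimParams(concordance_gain=0.0, seed=s)
            pat, cli, *_ = generate_dyad_brain(p, 1.0, seed=s)
            a = cli.betas[:5].mean(0)
            b = pat.betas[5:10].mean(0)
            rs.append(np.corrcoef(a, b)[0, 1])
        assert abs(np.mean(rs)) < 0.1

    def test_noiseless_behavior_tracks_true_coupling(self):
        rng = np.random.default_rng(0)
        rhos, negs = [], []
        for s in range(20):
            p = BrainSimParams(negexp_sd=0.0, seed=s)
            score = float(rng.uniform(0.2, 1.8))
            *_, scores, truth = generate_dyad_brain(p, score, seed=s)
            rhos.append(truth.cross_brain_rho)
            negs.append(scores.negative_expressivity)
        assert np.corrcoef(rhos, negs)[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_nonfinite_score_rejected(self):
        with pytest.raises(ParameterError):
            generate_dyad_brain(BrainSimParams(), np.nan)


class TestBuildCohort:
    def _params(self):
        return dict(
            dyad_params=fast_dyad_params(),
            pain_params=PainSimParams(n_trials_per_condition=1, n_runs=2,
                                      rest_s=2.0, cue_s=3.0, stim_s=3.0, rating_s=2.0),
        )

    def test_roster_and_pseudo_enumeration(self, tmp_path):
        roster = build_cohort(tmp_path / "c", 2, seed=1, **self._params())
        assert len(roster.real) == 2
        assert len(enumerate_pseudo_dyads(roster)) == 2  # n(n-1), n=2

    def test_refuses_nonempty_dir(self, tmp_path):
        out = tmp_path / "c"
        out.mkdir()
        (out / "junk.txt").write_text("x")
        with pytest.raises(ParameterError, match="not empty"):
            build_cohort(out, 2, seed=1, **self._params())

    def test_same_seed_byte_identical(self, tmp_path):
        def digest(root):
            h = hashlib.sha256()
            for f in sorted(Path(root).rglob("*")):
                if f.is_file():
                    h.update(f.name.encode())
                    h.update(f.read_bytes())
            return h.hexdigest()

        build_cohort(tmp_path / "a", 2, seed=9, **self._params())
        build_cohort(tmp_path / "b", 2, seed=9, **self._params())
        assert digest(tmp_path / "a") == digest(tmp_path / "b")

    def test_dataset_loads_through_readers(self, tmp_path):
        build_cohort(tmp_path / "c", 2, seed=3, **self._params())
        roster = dio.load_roster(tmp_path / "c" / "roster.csv")
        row = roster.real.iloc[0]
        ddir = tmp_path / "c" / "dyads" / row["dyad_id"]
        pat = dio.load_au_recording(ddir / "patient_au.csv", row["patient_id"], "patient")
        cli = dio.load_au_recording(ddir / "clinician_au.csv", row["clinician_id"], "clinician")
        events = dio.load_events(ddir / "events.tsv")
        blocks = dio.segment_blocks(pat, cli, events, ANTICIPATION_CONDITIONS)
        assert len(blocks) == 6
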