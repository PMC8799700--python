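"""End-to-end orchestration: simulate -> classify -> esgc -> infer -> concord.

The pipeline operates on an on-disk cohort (see :func:`dyadscope.simulate.
build_cohort` for the layout) and writes one artifact directory per stage
plus a consolidated ``report.json``.  A single global seed deterministically
derives per-stage/per-dyad sub-seeds, so outputs are a pure function of
config + seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .classify import assemble_frames, rank_shap, train_classify
from .concordance import (
    ROISpec,
    behavior_correlation,
    dyad_concordance,
    group_regression,
    partner_roi_vector,
    roi_pair_concordance,
)
from .datatypes import ANTICIPATION_CONDITIONS, DIRECTIONS, GCMatrix
from .esgc import ReservoirParams, esgc_matrix
from .exceptions import DependencyError, ParameterError
from .inference import enumerate_pseudo_dyads, grid_inference, summarize_links
from .simulate import BetaSeries, BrainSimParams, DyadSimParams, PainSimParams, build_cohort
from .utils import derive_seed

log = logging.getLogger("dyadscope")

STAGES = ("simulate", "classify", "esgc", "infer", "concord")


@dataclass
class RunConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    out_dir: str
    seed: int = 0
    cohort_dir: str | None = None
    n_dyads: int = 10
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    dyad: dict = field(default_factory=dict)
    pain: dict = field(default_factory=dict)
    brain: dict = field(default_factory=dict)
    reservoir: dict = field(default_factory=dict)
    channels: list | None = None  # AU label subset for the GC grid
    inference: dict = field(default_factory=lambda: {"alpha": 0.05, "cap": None})
    classifier: dict = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        unknown_stages = set(cfg.stages) - set(STAGES)
        if unknown_stages:
            raise ParameterError(f"unknown stages: {sorted(unknown_stages)}")
        for block, params_cls in (("dyad", DyadSimParams), ("pain", PainSimParams),
                                  ("brain", BrainSimParams), ("reservoir", ReservoirParams)):
            fields = {f.name for f in dataclasses.fields(params_cls)}
            bad = set(getattr(cfg, block)) - fields
            if bad:
                raise ParameterError(f"unknown keys in {block!r} block: {sorted(bad)}")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Cohort-level helpers (also used by the CLI and the acceptance script)
# ---------------------------------------------------------------------------

def load_dyad_recordings(cohort_dir, dyad_row):
    ddir = Path(cohort_dir) / "dyads" / dyad_row["dyad_id"]
    pat = dio.load_au_recording(ddir / "patient_au.csv", dyad_row["patient_id"], "patient")
    cli = dio.load_au_recording(ddir / "clinician_au.csv", dyad_row["clinician_id"], "clinician")
    events = dio.load_events(ddir / "events.tsv")
    return pat, cli, events


def esgc_ensemble(
    dyads: dict,
    roster,
    params: ReservoirParams,
    directions=DIRECTIONS,
    channels=None,
    conditions=ANTICIPATION_CONDITIONS,
    cap: int | None = None,
    seed: int = 0,
) -> dict[str, dict[str, list]]:
    """ESGC matrices for all real dyads and a pseudo-dyad null ensemble.

    ``dyads`` maps ``dyad_id -> (patient AURecording, clinician AURecording,
    EventTable)`` for every real dyad in ``roster``.  Pseudo-dyad members
    keep their own block timings, paired by block index.  Returns
    ``{"real"|"null": {direction: [GCMatrix, ...]}}``; matrices use
    per-dyad reservoir seeds derived from ``seed`` so results do not depend
    on iteration order.
    """
    out: dict[str, dict[str, list]] = {"real": {d: [] for d in directions},
                                       "null": {d: [] for d in directions}}
    for _, row in roster.real.iterrows():
        dyad_id = row["dyad_id"]
        pat, cli, events = dyads[dyad_id]
        blocks = dio.segment_blocks(pat, cli, events, conditions, dyad_id=dyad_id)
        for direction in directions:
            p = dataclasses.replace(params, seed=derive_seed(seed, "esgc", dyad_id, direction))
            out["real"][direction].append(
                esgc_matrix(blocks, direction, p, source_channels=channels, target_channels=channels)
            )

    pseudo = enumerate_pseudo_dyads(roster, cap=cap, seed=derive_seed(seed, "pseudo-cap"))
    by_patient = {row["patient_id"]: row["dyad_id"] for _, row in roster.real.iterrows()}
    by_clinician = {row["clinician_id"]: row["dyad_id"] for _, row in roster.real.iterrows()}
    for _, prow in pseudo.table.iterrows():
        pat, _, pat_ev = dyads[by_patient[prow["patient_id"]]]
        _, cli, cli_ev = dyads[by_clinician[prow["clinician_id"]]]
        blocks = dio.segment_pseudo_blocks(pat, pat_ev, cli, cli_ev, conditions,
                                           dyad_id=prow["dyad_id"])
        for direction in directions:
            p = dataclasses.replace(params, seed=derive_seed(seed, "esgc", prow["dyad_id"], direction))
            out["null"][direction].append(
                esgc_matrix(blocks, direction, p, source_channels=channels, target_channels=channels)
            )
    return out


def esgc_cohort(
    cohort_dir,
    roster,
    params: ReservoirParams,
    directions=DIRECTIONS,
    channels=None,
    conditions=ANTICIPATION_CONDITIONS,
    cap: int | None = None,
    seed: int = 0,
) -> dict[str, dict[str, list]]:
    """Disk-backed variant of :func:`esgc_ensemble` over a cohort directory."""
    cohort_dir = Path(cohort_dir)
    dyads = {}
    for _, row in roster.real.iterrows():
        dyads[row["dyad_id"]] = load_dyad_recordings(cohort_dir, row)
    return esgc_ensemble(dyads, roster, params, directions=directions, channels=channels,
                         conditions=conditions, cap=cap, seed=seed)


def infer_cohort(gc: dict, alpha: float = 0.05) -> dict:
    """Pseudo-dyad null inference per direction + link summary."""
    sig_by_direction = {}
    for direction, mats in gc["real"].items():
        real = np.stack([m.values for m in mats])
        null = np.stack([m.values for m in gc["null"][direction]])
        sig_by_direction[direction] = grid_inference(real, null, alpha=alpha, direction=direction)
    p2c = gc["real"].get("patient_to_clinician", [])
    gc_by_dyad = {m.dyad_id: m for m in p2c}
    source_au = p2c[0].source_labels[0] if p2c else "AU28_lip_suck"
    source_au = "AU28_lip_suck" if "AU28_lip_suck" in (p2c[0].source_labels if p2c else ()) else source_au
    summary = summarize_links(sig_by_direction, gc_by_dyad or None, source_au=source_au)
    return {"sig": sig_by_direction, "summary": summary}


def load_beta_series(cohort_dir, dyad_id, who) -> BetaSeries:
    path = Path(cohort_dir) / "dyads" / dyad_id / f"{who}_betas.csv"
    df = pd.read_csv(path)
    betas = df.drop(columns=["parcel"]).to_numpy(dtype=float)
    n_trials = betas.shape[1]
    return BetaSeries(subject_id=f"{who}_{dyad_id}", betas=betas,
                      conditions=["anticipation_treat"] * n_trials,
                      runs=[t // (n_trials // 2) for t in range(n_trials)])


def concord_cohort(
    cohort_dir,
    roster,
    au28_scores: pd.Series,
    brain_params: BrainSimParams | None = None,
    alpha: float = 0.05,
) -> dict:
    """Concordance maps, group regression on the AU28 score, behavior correlations."""
    bp = brain_params or BrainSimParams()
    rois = {name: ROISpec(name, tuple(parcels)) for name, parcels in bp.roi_definitions}
    cli_seed_roi = rois["clinician_aIns"]
    pat_roi = rois["patient_m_pIns"]

    dyad_ids = [d for d in roster.real["dyad_id"] if d in au28_scores.index]
    coeffs, pair_scalars = [], []
    for dyad_id in dyad_ids:
        pat_bs = load_beta_series(cohort_dir, dyad_id, "patient")
        cli_bs = load_beta_series(cohort_dir, dyad_id, "clinician")
        partner = partner_roi_vector(cli_bs, cli_seed_roi)
        coeffs.append(dyad_concordance(pat_bs, partner))
        pair_scalars.append(roi_pair_concordance(cli_bs, pat_bs, cli_seed_roi, pat_roi))
    coeffs = np.stack(coeffs)
    scores = au28_scores.loc[dyad_ids].to_numpy()
    group = group_regression(coeffs, scores, alpha=alpha)

    scores_df = pd.read_csv(Path(cohort_dir) / "scores.csv").set_index("dyad_id").loc[dyad_ids]
    care_r, care_p = behavior_correlation(pair_scalars, scores_df["care_dyad"])
    neg_r, neg_p = behavior_correlation(pair_scalars, scores_df["negative_expressivity"])
    return {
        "dyad_ids": dyad_ids,
        "concordance": coeffs,
        "pair_scalars": np.asarray(pair_scalars),
        "group": group,
        "care": {"r": care_r, "p": care_p},
        "negative_expressivity": {"r": neg_r, "p": neg_p},
    }


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the report."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(config.to_dict(), indent=1, default=str))
    stages = {s: bool(config.stages.get(s, False)) for s in STAGES}
    report: dict = {"config_hash": config.digest(), "seed": config.seed, "stages": {}}

    def stage_done(name, t0, **extra):
        report["stages"][name] = {"wall_time_s": round(time.perf_counter() - t0, 3), **extra}
        log.info("stage %s done in %.2fs", name, report["stages"][name]["wall_time_s"])

    cohort_dir = Path(config.cohort_dir) if config.cohort_dir else out / "cohort"
    if stages["simulate"]:
        t0 = time.perf_counter()
        build_cohort(
            cohort_dir, config.n_dyads,
            dyad_params=DyadSimParams(**config.dyad),
            pain_params=PainSimParams(**config.pain),
            brain_params=BrainSimParams(**config.brain),
            seed=derive_seed(config.seed, "simulate"),
            overwrite=True,
        )
        stage_done("simulate", t0, cohort_dir=str(cohort_dir), n_dyads=config.n_dyads)
    elif any(stages.values()) and not (cohort_dir / "roster.csv").exists():
        raise DependencyError("stage 'simulate' disabled and no cohort found at "
                              f"{cohort_dir} (required by downstream stages)")

    roster = dio.load_roster(cohort_dir / "roster.csv")

    if stages["classify"]:
        t0 = time.perf_counter()
        frames = []
        for _, row in roster.real.iterrows():
            ddir = cohort_dir / "dyads" / row["dyad_id"]
            rec = dio.load_au_recording(ddir / "pain_patient_au.csv", row["patient_id"], "patient")
            events = dio.load_events(ddir / "pain_events.tsv")
            frames.append(assemble_frames(rec, events))
        table = pd.concat(frames, ignore_index=True)
        rep = train_classify(table, seed=derive_seed(config.seed, "classify"),
                             hyperparams=config.classifier or None)
        ranking = rank_shap(rep.model, table)
        ranking.to_csv(out / "shap_ranking.csv", index=False)
        report["classifier"] = {
            "auc": rep.auc, "precision": rep.precision, "recall": rep.recall,
            "cv_scheme": rep.cv_scheme, "threshold": rep.threshold,
            "top4_aus": list(ranking["au_label"][:4]),
        }
        stage_done("classify", t0, n_frames=int(len(table)))

    gc = None
    if stages["esgc"]:
        t0 = time.perf_counter()
        params = ReservoirParams(**config.reservoir)
        gc = esgc_cohort(
            cohort_dir, roster, params,
            channels=config.channels,
            cap=config.inference.get("cap"),
            seed=derive_seed(config.seed, "esgc"),
        )
        gc_dir = out / "gc"
        for kind in ("real", "null"):
            for direction, mats in gc[kind].items():
                for m in mats:
                    dio.write_matrix(m.values, m.source_labels,
                                     gc_dir / kind / direction / f"{m.dyad_id}.csv",
                                     target_labels=m.target_labels)
        stage_done("esgc", t0, n_real=len(gc["real"][DIRECTIONS[0]]),
                   n_null=len(gc["null"][DIRECTIONS[0]]))

    summary = None
    if stages["infer"]:
        if gc is None:
            raise DependencyError("stage 'infer' requires stage 'esgc' output")
        t0 = time.perf_counter()
        inf = infer_cohort(gc, alpha=float(config.inference.get("alpha", 0.05)))
        summary = inf["summary"]
        for direction, sig in inf["sig"].items():
            dio.write_matrix(sig.p, gc["real"][direction][0].source_labels,
                             out / "infer" / f"p_{direction}.csv",
                             target_labels=gc["real"][direction][0].target_labels)
            dio.write_matrix(sig.q, gc["real"][direction][0].source_labels,
                             out / "infer" / f"q_{direction}.csv",
                             target_labels=gc["real"][direction][0].target_labels)
        link_summary = {
            "n_significant": summary.n_significant,
            "source_au": summary.source_au,
            "au28_scores": summary.au28_scores.to_dict(),
        }
        (out / "infer" / "link_summary.json").write_text(json.dumps(link_summary, indent=1))
        report["links"] = {"n_significant": summary.n_significant}
        stage_done("infer", t0)

    if stages["concord"]:
        if summary is None:
            raise DependencyError("stage 'concord' requires stage 'infer' output")
        t0 = time.perf_counter()
        res = concord_cohort(cohort_dir, roster, summary.au28_scores,
                             brain_params=BrainSimParams(**config.brain),
                             alpha=float(config.inference.get("alpha", 0.05)))
        pd.DataFrame({
            "parcel": np.arange(res["group"].slope.shape[0]),
            "slope": res["group"].slope, "t": res["group"].t,
            "p": res["group"].p, "q": res["group"].q,
            "significant": res["group"].significant,
        }).to_csv(out / "concordance_group_stats.csv", index=False)
        report["concordance"] = {
            "n_significant_parcels": int(res["group"].significant.sum()),
            "care": res["care"],
            "negative_expressivity": res["negative_expressivity"],
        }
        stage_done("concord", t0, n_dyads=len(res["dyad_ids"]))

    (out / "report.json").write_text(json.dumps(report, indent=1, default=str))
    return report
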