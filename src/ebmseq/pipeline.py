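"""End-to-end orchestration: cohort -> weights -> ordering -> staging -> states.

All randomness flows from one configured seed, fanned out to per-stage
generators with :class:`numpy.random.SeedSequence` spawning (stage i uses
``SeedSequence(seed).spawn(n)[i]``), so stages can be rerun independently yet
reproducibly. Every output file is recorded in a JSON manifest together with
the seed, a hash of the configuration, and stage timings.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import alteration, atlas as atlas_mod, pairwise, progression, staging, states

VALID_GROUPS = {"patient", "control"}
VALID_COG = {"NC", "MCI", "D"}

#: stage names in fan-out order; each gets its own spawned seed
STAGES = ("weights", "pairwise", "order", "stage_hys", "stage_cognition", "predict")


@dataclass
class PipelineConfig:
    cohort_path: str
    atlas_path: str
    out_dir: str
    cutoff_sd: float = 2.5
    n_trajectories: int = 10_000
    seed: int = 0
    binarize_at: float = pairwise.DEFAULT_BINARIZE_AT
    fdr_level: float = 0.05
    #: clinical staging schemes to run
    schemes: tuple[str, ...] = ("HYS", "COGNITION")
    epsilon: float = 1e-9

    def validate(self) -> None:
        for name, p in (("cohort_path", self.cohort_path), ("atlas_path", self.atlas_path)):
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} does not exist: {p}")
        if not (0 < self.fdr_level <= 1):
            raise ValueError("fdr_level must lie in (0, 1]")
        if not (0 < self.binarize_at <= 1):
            raise ValueError("binarize_at must lie in (0, 1]")
        unknown = set(self.schemes) - set(staging.SCHEMES)
        if unknown:
            raise ValueError(f"unknown clinical schemes: {sorted(unknown)}")

    def config_hash(self) -> str:
        payload = yaml.safe_dump(
            {k: list(v) if isinstance(v, tuple) else v for k, v in vars(self).items()},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> np.random.SeedSequence:
        children = np.random.SeedSequence(self.seed).spawn(len(STAGES))
        return children[STAGES.index(stage)]


def validate_inputs(cohort_path: str | Path, atlas_path: str | Path) -> list[dict]:
    """Machine-readable validation findings; an empty list means clean."""
    findings: list[dict] = []
    cohort = pd.read_csv(cohort_path)
    try:
        atlas = atlas_mod.read_atlas(atlas_path)
    except ValueError as exc:
        return [{"check": "atlas", "detail": str(exc)}]

    atlas_regions = set(atlas["region_id"])
    cohort_regions = set(cohort.columns) - set(
        ["subject_id", "group", "age", "sex", "hys", "cognitive_status", "updrs"]
    )
    for r in sorted(cohort_regions - atlas_regions):
        findings.append({"check": "region_agreement", "detail": f"cohort column {r!r} absent from atlas"})
    for r in sorted(atlas_regions - cohort_regions):
        findings.append({"check": "region_agreement", "detail": f"atlas region {r!r} absent from cohort"})
    if "subject_id" in cohort.columns and cohort["subject_id"].duplicated().any():
        dup = cohort.loc[cohort["subject_id"].duplicated(), "subject_id"].iloc[0]
        findings.append({"check": "subject_ids", "detail": f"duplicate subject id {dup!r}"})
    if "group" in cohort.columns:
        bad = set(cohort["group"].unique()) - VALID_GROUPS
        if bad:
            findings.append({"check": "group_labels", "detail": f"unknown group labels {sorted(bad)}"})
    else:
        findings.append({"check": "group_labels", "detail": "missing 'group' column"})
    if "hys" in cohort.columns:
        hys = pd.to_numeric(cohort["hys"], errors="coerce")
        if (hys.dropna() < 0).any():
            findings.append({"check": "clinical_domain", "detail": "hys values below 0"})
    if "cognitive_status" in cohort.columns:
        bad = set(cohort["cognitive_status"].dropna().unique()) - VALID_COG
        if bad:
            findings.append(
                {"check": "clinical_domain", "detail": f"cognitive_status outside {sorted(VALID_COG)}: {sorted(bad)}"}
            )
    return findings


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage in dependency order; return (and write) the manifest."""
    cfg.validate()
    findings = validate_inputs(cfg.cohort_path, cfg.atlas_path)
    if findings:
        raise ValueError(f"input validation failed: {findings[0]['detail']} "
                         f"({len(findings)} finding(s) in total)")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "outputs": {},
        "timings_s": {},
        "summary": {},
    }

    def record(stage: str, name: str, path: Path, t0: float) -> None:
        manifest["outputs"][name] = str(path)
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 3)

    cohort = pd.read_csv(cfg.cohort_path)
    atlas = atlas_mod.read_atlas(cfg.atlas_path)
    controls = cohort[cohort["group"] == "control"]
    patients = cohort[cohort["group"] == "patient"]

    t0 = time.perf_counter()
    model = alteration.fit_normative(controls)
    w = alteration.compute_weights(patients, model, alteration.WeightConfig(cutoff_sd=cfg.cutoff_sd))
    alteration.write_model(model, out / "normative_model.csv")
    alteration.write_weights(w, out / "weights.csv")
    record("weights", "normative_model", out / "normative_model.csv", t0)
    manifest["outputs"]["weights"] = str(out / "weights.csv")

    t0 = time.perf_counter()
    cpt_cross = pairwise.build_cpt(
        w, atlas, pairs="cross_tissue", binarize_at=cfg.binarize_at, fdr_level=cfg.fdr_level
    )
    cpt_all = pairwise.build_cpt(
        w, atlas, pairs="all", binarize_at=cfg.binarize_at, fdr_level=cfg.fdr_level
    )
    census = pairwise.pairwise_significance_census(cpt_cross, atlas)
    sig_all, total_all = pairwise.all_regions_census(cpt_all)
    summary = pairwise.cross_tissue_summary(cpt_cross, atlas)
    cpt_cross.cond.to_csv(out / "conditional_probabilities.csv", index_label="X")
    cpt_cross.tests.to_csv(out / "mcnemar_cross_tissue.csv", index=False)
    cpt_all.tests.to_csv(out / "mcnemar_all_pairs.csv", index=False)
    summary.summary.to_csv(out / "cross_tissue_precedence.csv", index=False)
    record("pairwise", "conditional_probabilities", out / "conditional_probabilities.csv", t0)
    manifest["outputs"]["cross_tissue_precedence"] = str(out / "cross_tissue_precedence.csv")
    manifest["summary"]["cross_tissue"] = {
        "wm_precedes_gm": census.wm_precedes_gm,
        "gm_precedes_wm": census.gm_precedes_wm,
        "total_pairs": census.total_pairs,
    }
    manifest["summary"]["all_regions"] = {"significant_ordered_pairs": sig_all,
                                          "total_ordered_pairs": total_all}

    t0 = time.perf_counter()
    sim_cfg = progression.SimulationConfig(
        n_trajectories=cfg.n_trajectories,
        seed=int(cfg.stage_seed("order").generate_state(1)[0]),
        epsilon=cfg.epsilon,
    )
    tc = progression.simulate(w, sim_cfg)
    seq = progression.modal_sequence(tc)
    progression.write_counts(tc, out / "trajectory_counts.csv")
    progression.write_sequence(seq, out / "event_sequence.csv", atlas)
    record("order", "event_sequence", out / "event_sequence.csv", t0)
    manifest["outputs"]["trajectory_counts"] = str(out / "trajectory_counts.csv")

    for scheme_id in cfg.schemes:
        t0 = time.perf_counter()
        scheme = staging.build_clinical_events(cohort, scheme_id)
        stage_cfg = progression.SimulationConfig(
            n_trajectories=cfg.n_trajectories,
            seed=int(cfg.stage_seed(f"stage_{scheme_id.lower()}").generate_state(1)[0]),
            epsilon=cfg.epsilon,
        )
        staged = staging.stage_events(w, scheme, stage_cfg)
        path = out / f"staged_sequence_{scheme_id.lower()}.csv"
        staging.write_staged(staged, path)
        record(f"stage_{scheme_id.lower()}", f"staged_{scheme_id.lower()}", path, t0)
        manifest["summary"][f"stages_{scheme_id.lower()}"] = staged.stage_counts.to_dict()

    t0 = time.perf_counter()
    assignment = states.predict_states(w, seq)
    updrs = patients.set_index("subject_id")["updrs"]
    assoc = states.associate_with_updrs(assignment, updrs)
    states.write_states(assignment, out / "disease_states.csv")
    states.write_association(assoc, out / "state_updrs_association.csv")
    record("predict", "disease_states", out / "disease_states.csv", t0)
    manifest["outputs"]["state_updrs_association"] = str(out / "state_updrs_association.csv")
    manifest["summary"]["state_updrs"] = {
        "kendall_tau": assoc.tau, "p_value": assoc.p_value, "n": assoc.n
    }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
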