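"""End-to-end orchestration: simulate -> extract -> effects -> single-case
-> exposure.

A single YAML (or dict) configuration defines the task constants, one or
more cohorts (each a control group plus lesion agents), the dissociation
contrast, and the exposure-model settings.  A single master seed
deterministically spawns every per-subject and per-stage random stream, so
re-running with the same configuration and seed reproduces every artifact
byte for byte.

The default configuration mirrors the design shape of the motivating
study: three MTL-like agents with 10 matched controls, one HC-like agent
with 9 controls, and one amygdala-like agent with 24 controls.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import CohortSpec, PatientSpec, TaskConfig, derive_seed
from .effects import LMESpec, ConditionEffectsModel, subject_summary
from .events import read_cohort_jsonl, write_cohort_jsonl
from .exposure import (ExposureMixtureModel, build_null_distribution,
                       compare_models, exposure_latencies, merge_latency_sets)
from .extract import (cohort_catch_rates, condition_means, extract_latencies,
                      performance_qc, reconstruct_decisions,
                      uncaught_approach_counts)
from .simulate import simulate_cohort
from .singlecase import ordinal_dissociation_test, percentile_rank

logger = logging.getLogger(__name__)

STAGES = ("simulate", "extract", "effects", "dissociate", "exposure")

DEFAULT_PIPELINE_CONFIG: dict = {
    "task": {},
    "cohorts": {
        "mtl": {
            "n_controls": 10,
            "patients": [
                {"label": f"MTL{i}", "group": "mtl",
                 "approach_overrides": {"approach_coef_loss": -0.2},
                 "exposure_overrides": {"lam": 1.0 / 900.0}}
                for i in (1, 2, 3)],
        },
        "hc": {
            "n_controls": 9,
            "patients": [
                {"label": "HC1", "group": "hc",
                 "approach_overrides": {"approach_coef_loss": -0.35},
                 "exposure_overrides": {"lam": 1.0 / 700.0}}],
        },
        "amy": {
            "n_controls": 24,
            "patients": [
                {"label": "AMY1", "group": "amy",
                 "approach_overrides": {"rl_base": 300.0,
                                        "rl_coef_threat": 0.0}}],
        },
    },
    "dissociation": {
        "statistic": "loss_linear_coefficient",
        # attenuated (less negative) loss slopes mark impairment
        "direction": "higher_is_impaired",
        "group_a": ["MTL1", "MTL2", "MTL3"],
        "group_b": ["HC1", "AMY1"],
        "n_sim": 10_000,
        "sidedness": "one",
    },
    "exposure": {
        "cohort": "mtl",
        "null_method": "uniform_time",
        "n_sim": 5000,
        "n_starts": 8,
    },
}


class StageDependencyError(RuntimeError):
    """A stage was requested before its upstream artifacts exist."""


@dataclass
class RunManifest:
    """Record of one pipeline run: inputs, seed, and every artifact."""

    config_hash: str
    master_seed: int
    version: str
    stages: list[str] = field(default_factory=list)
    artifacts: dict[str, str] = field(default_factory=dict)  # path -> sha256
    timestamps: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_pipeline_config(source=None) -> dict:
    """Load a pipeline config from YAML path / dict, merged over defaults."""
    if source is None:
        return json.loads(json.dumps(DEFAULT_PIPELINE_CONFIG))
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(source)
    cfg = _merge(DEFAULT_PIPELINE_CONFIG, user)
    if "cohorts" in user:        # user cohorts replace, not merge
        cfg["cohorts"] = user["cohorts"]
    return cfg


def _cohort_spec(name: str, ccfg: Mapping, master_seed: int) -> CohortSpec:
    patients = tuple(
        PatientSpec(label=p["label"], group=p.get("group", "patient"),
                    approach_overrides=p.get("approach_overrides", {}),
                    exposure_overrides=p.get("exposure_overrides", {}),
                    control_group_id=name)
        for p in ccfg.get("patients", []))
    return CohortSpec(
        n_controls=ccfg.get("n_controls", 10), patients=patients,
        control_policy_mean=ccfg.get("control_policy_mean", {}),
        control_policy_sd=ccfg.get("control_policy_sd", {}),
        control_exposure_mean=ccfg.get("control_exposure_mean", {}),
        control_exposure_sd=ccfg.get("control_exposure_sd", {}),
        master_seed=derive_seed(master_seed, "cohort", name))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _register(manifest: RunManifest, path: Path) -> None:
    manifest.artifacts[path.name] = _sha256(path)
    manifest.timestamps[path.name] = time.time()


def _require(out: Path, name: str, stage: str) -> Path:
    p = out / name
    if not p.exists():
        raise StageDependencyError(
            f"stage {stage!r} requires missing artifact {name}; "
            "run the upstream stage first")
    return p


def run_pipeline(config=None, out_dir="aacsim_run", seed: int = 0,
                 stages: Sequence[str] = STAGES) -> RunManifest:
    """Execute the requested pipeline stages in order.

    Every artifact is written under ``out_dir`` and recorded (with a
    content hash) in the returned :class:`RunManifest`, which is also
    saved as ``manifest.json``.
    """
    cfg = load_pipeline_config(config)
    task = TaskConfig.from_dict(cfg.get("task", {}))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")

    manifest = RunManifest(config_hash=task.config_hash(), master_seed=seed,
                           version=__version__)
    cohort_names = list(cfg["cohorts"])

    if "simulate" in stages:
        logger.info("simulate: %d cohorts", len(cohort_names))
        for name in cohort_names:
            spec = _cohort_spec(name, cfg["cohorts"][name], seed)
            logs, mani = simulate_cohort(spec, task)
            path = out / f"events_{name}.jsonl"
            write_cohort_jsonl(logs, path)
            _register(manifest, path)
            mpath = out / f"subjects_{name}.csv"
            mani.to_csv(mpath, index=False)
            _register(manifest, mpath)
        manifest.stages.append("simulate")

    if "extract" in stages:
        for name in cohort_names:
            logs = read_cohort_jsonl(_require(out, f"events_{name}.jsonl",
                                              "extract"))
            t1 = [lg for lg in logs if lg.task == "task1"]
            decisions = pd.concat([reconstruct_decisions(lg) for lg in t1],
                                  ignore_index=True)
            latencies = pd.concat([extract_latencies(lg, task) for lg in t1],
                                  ignore_index=True)
            means = condition_means(decisions)
            rates = cohort_catch_rates(t1)
            subjects = pd.read_csv(out / f"subjects_{name}.csv")
            controls = set(subjects.loc[subjects.group == "control",
                                        "subject_id"])
            perf = uncaught_approach_counts(decisions)
            qc = performance_qc({s: perf.get(s, 0) for s in controls})
            for frame, stem in ((decisions, "decisions"),
                                (latencies, "latencies"),
                                (means, "condition_means"),
                                (rates, "catch_rates")):
                p = out / f"{stem}_{name}.csv"
                frame.to_csv(p, index=False)
                _register(manifest, p)
            qpath = out / f"qc_{name}.json"
            qpath.write_text(json.dumps(dataclasses.asdict(qc), indent=2))
            _register(manifest, qpath)
        manifest.stages.append("extract")

    if "effects" in stages:
        all_summaries = []
        for name in cohort_names:
            means = pd.read_csv(_require(out, f"condition_means_{name}.csv",
                                         "effects"))
            subjects = pd.read_csv(out / f"subjects_{name}.csv")
            grp = subjects.set_index("subject_id")["group"]
            means["group"] = means["subject_id"].map(
                lambda s: "control" if grp.get(s) == "control" else "patient")
            has_patients = (means["group"] == "patient").any()
            model = ConditionEffectsModel(
                means, LMESpec(outcome="approach_proportion",
                               include_group=has_patients))
            res = model.fit()
            p = out / f"effects_{name}.csv"
            res.table.to_csv(p, index=False)
            _register(manifest, p)
            summ = subject_summary(means, "loss_linear_coefficient")
            summ["cohort"] = name
            summ["group"] = summ["subject_id"].map(grp)
            all_summaries.append(summ)
        spath = out / "subject_summaries.csv"
        pd.concat(all_summaries, ignore_index=True).to_csv(spath, index=False)
        _register(manifest, spath)
        manifest.stages.append("effects")

    if "dissociate" in stages:
        summ = pd.read_csv(_require(out, "subject_summaries.csv", "dissociate"))
        dcfg = cfg["dissociation"]
        ranks, sizes = {}, {}
        for cohort, g in summ.groupby("cohort"):
            controls = g[g.group == "control"]
            for _, row in g[g.group != "control"].iterrows():
                rs = percentile_rank(row["value"], controls["value"].to_numpy(),
                                     direction=dcfg["direction"],
                                     patient_id=row["subject_id"],
                                     control_group_id=cohort)
                ranks[row["subject_id"]] = rs.rank_pct
                sizes[row["subject_id"]] = rs.n_controls
        group_a = [p for p in dcfg["group_a"] if p in ranks]
        group_b = [p for p in dcfg["group_b"] if p in ranks]
        if not group_a or not group_b:
            raise StageDependencyError("dissociation groups not found in "
                                       "subject summaries")
        result = ordinal_dissociation_test(
            [ranks[p] for p in group_a], [sizes[p] for p in group_a],
            [ranks[p] for p in group_b], [sizes[p] for p in group_b],
            n_sim=dcfg.get("n_sim", 10_000),
            sidedness=dcfg.get("sidedness", "one"),
            seed=derive_seed(seed, "dissociation"))
        payload = json.loads(result.to_json())
        payload["patient_ranks"] = ranks
        dpath = out / "dissociation.json"
        dpath.write_text(json.dumps(payload, indent=2))
        _register(manifest, dpath)
        manifest.stages.append("dissociate")

    if "exposure" in stages:
        ecfg = cfg["exposure"]
        name = ecfg.get("cohort", cohort_names[0])
        logs = read_cohort_jsonl(_require(out, f"events_{name}.jsonl",
                                          "exposure"))
        subjects = pd.read_csv(out / f"subjects_{name}.csv")
        grp = subjects.set_index("subject_id")["group"]
        sets_by_group: dict[str, list] = {"control": [], "patient": []}
        for lg in logs:
            if lg.task != "task2":
                continue
            key = "control" if grp.get(lg.subject_id) == "control" else "patient"
            sets_by_group[key].append(exposure_latencies(lg))
        null = build_null_distribution(
            task, method=ecfg.get("null_method", "uniform_time"),
            n_sim=ecfg.get("n_sim", 5000),
            seed=derive_seed(seed, "exposure-null"))
        pooled = {g: merge_latency_sets(s, subject_id=g).latencies
                  for g, s in sets_by_group.items() if s}
        model = ExposureMixtureModel(pooled, null)
        fits = model.fit_all(n_starts=ecfg.get("n_starts", 8),
                             seed=derive_seed(seed, "exposure-fit"))
        table = compare_models(fits)
        cpath = out / "exposure_model_comparison.csv"
        table.to_csv(cpath, index=False)
        _register(manifest, cpath)
        fpath = out / "exposure_fits.json"
        fpath.write_text(json.dumps(
            {k: json.loads(v.to_json()) for k, v in fits.items()}, indent=2))
        _register(manifest, fpath)
        manifest.stages.append("exposure")

    mpath = out / "manifest.json"
    mpath.write_text(manifest.to_json())
    return manifest
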