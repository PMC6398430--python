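"""End-to-end orchestration of the fission-fusion analysis.

Stages run in dependency order: simulate (or load sightings) -> estimate
-> classify -> subgroups -> seasontests -> avgmodel -> summarize.  Every
stage writes CSV outputs into the run directory together with a
provenance record (config hash, seed, package version), and a rerun with
the same configuration reproduces the outputs exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, flock, presence, seasons, subgroups, synthetic
from .modelavg import all_subsets_average, prepare_model_data

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "summarize_population", "stage_seed"]

ALL_STAGES = ("simulate", "estimate", "classify", "subgroups", "seasontests", "avgmodel", "summarize")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``sightings``/``sessions`` paths may point at existing CSVs; when
    absent the generator produces them.  The default model stage uses a
    reduced subgroup candidate set sized for a single-CPU run; listing all
    ten terms in ``subgroup_terms`` restores the full 1024-model set.
    """

    out_dir: str = "run"
    seed: int = 1
    stages: tuple = ALL_STAGES
    sightings: str | None = None
    sessions: str | None = None
    min_days: int = 5
    k: int = 3
    radius: float = 5.0
    n_boot: int = 10_000
    sample_size: int = 38
    alpha_friedman: float = 0.05
    alpha_wilcoxon: float = 0.017
    alpha_mwu: float = 0.008
    flock_family: str = "poisson"
    subgroup_family: str = "nb"
    random_intercept: bool = True
    subgroup_terms: tuple = ("weather", "season", "transect_time", "forested_area", "food")
    subgroup_per_record: bool = True
    world: dict = field(default_factory=dict)
    agents: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        for key in ("stages", "subgroup_terms"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def stage_seed(seed: int, stage: str) -> int:
    """Per-stage seed derived from the global seed and the stage name."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _provenance(config: RunConfig, stage: str) -> dict:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return {
        "stage": stage,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": config.seed,
        "stage_seed": stage_seed(config.seed, stage),
        "crowflock_version": __version__,
    }


def _read_sightings(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["date"])
    required = {"date", "session", "bird_id", "marked"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sightings CSV {path} lacks columns {sorted(missing)}")
    return df


def summarize_population(records: pd.DataFrame, assignments: pd.DataFrame | None = None,
                         marked_total: int | None = None) -> dict:
    """Descriptive study summary.

    Percentages are rounded to the nearest integer and rates to one
    decimal.  ``marked_total`` is the number of ringed birds in the wider
    population (resighted or not); it defaults to the number of distinct
    identified marked birds in the records (a lower bound).
    """
    marked_mask = records["marked"].astype(int) == 1
    identified = marked_mask & records["bird_id"].notna() & ~records["bird_id"].isin(["unmarked", ""])
    resighted = int(records.loc[identified, "bird_id"].nunique())
    if marked_total is None:
        marked_total = resighted
    marked_sightings = int(marked_mask.sum())
    ident_rate = round(100.0 * identified.sum() / marked_sightings, 1) if marked_sightings else 0.0
    per_day = records.groupby("date")["session"].nunique()
    summary = {
        "n_observations": int(len(records)),
        "marked_total": int(marked_total),
        "resighted": resighted,
        "resighted_pct": int(round(100.0 * resighted / marked_total)) if marked_total else 0,
        "identified_marked_sightings": int(identified.sum()),
        "marked_sightings": marked_sightings,
        "identification_rate_pct": ident_rate,
        "n_days": int(per_day.size),
        "transects_per_day_mean": round(float(per_day.mean()), 2) if per_day.size else 0.0,
        "transects_per_day_sd": round(float(per_day.std(ddof=1)), 2) if per_day.size > 1 else 0.0,
    }
    if assignments is not None and len(assignments):
        counts = assignments["category"].value_counts().to_dict()
        summary["category_counts"] = {c: int(counts.get(c, 0)) for c in presence.CATEGORY_ORDER}
    else:
        summary["category_counts"] = {}
    if "age_class" in records.columns and identified.any():
        birds = records.loc[identified].drop_duplicates("bird_id")
        juv = int((birds["age_class"] == "juvenile").sum())
        summary["juvenile_pct"] = int(round(100.0 * juv / len(birds)))
    return summary


def _results_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "test": r.test,
                "label": r.label,
                "statistic_mean": r.statistic_mean,
                "statistic_se": r.statistic_se,
                "p_mean": r.p_mean,
                "p_se": r.p_se,
                "p_calibrated": r.p_calibrated,
                "n_iterations": r.n_iterations,
                "sample_size": r.sample_size,
                "alpha": r.alpha,
                "significant": r.significant,
            }
            for r in results
        ]
    )


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory.

    A stage failure raises with a structured message naming the stage;
    downstream stages are not attempted.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    state: dict = {}
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        try:
            _run_stage(stage, config, out, state)
        except Exception as exc:
            report = {"failed_stage": stage, "error": str(exc)}
            (out / "error.json").write_text(json.dumps(report, indent=2))
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        (out / f"provenance_{stage}.json").write_text(json.dumps(_provenance(config, stage), indent=2))
    return out


def _require(state: dict, key: str, config: RunConfig):
    """Fetch an upstream artifact, loading it from disk or regenerating it
    when its stage was toggled off."""
    if key in state:
        return state[key]
    if key == "records":
        if config.sightings:
            state["records"] = _read_sightings(config.sightings)
        else:
            _run_stage("simulate", config, Path(config.out_dir), state, write=False)
        return state["records"]
    if key == "covariates":
        if config.sessions:
            state["covariates"] = pd.read_csv(config.sessions, parse_dates=["date"])
        else:
            _require(state, "records", config)
        return state["covariates"]
    raise KeyError(key)


def _run_stage(stage: str, config: RunConfig, out: Path, state: dict, write: bool = True) -> None:
    seed = stage_seed(config.seed, "simulate")
    if stage == "simulate":
        world_cfg = synthetic.WorldConfig(**config.world) if config.world else synthetic.WorldConfig()
        agent_cfg = synthetic.AgentConfig(**config.agents) if config.agents else synthetic.AgentConfig()
        sim = synthetic.simulate_study(world_cfg, agent_cfg, seed=seed)
        state.update(sim)
        if write:
            sim["records"].to_csv(out / "sightings.csv", index=False)
            sim["covariates"].to_csv(out / "sessions.csv", index=False)
            sim["truth"].to_csv(out / "truth.csv", index=False)
            world = sim["world"]
            world_doc = {
                "zones": world.zones.to_dict(orient="records"),
                "barriers": world.barriers.tolist(),
                "monitoring_days": [str(d.date()) for d in world.monitoring_days],
            }
            (out / "world.yaml").write_text(yaml.safe_dump(world_doc))
    elif stage == "estimate":
        records = _require(state, "records", config)
        daily = flock.daily_series(records)
        transect = flock.transect_series(records)
        state["daily"], state["transect"] = daily, transect
        if write:
            daily.to_csv(out / "daily_estimates.csv", index=False)
            transect.to_csv(out / "transect_estimates.csv", index=False)
    elif stage == "classify":
        records = _require(state, "records", config)
        features = presence.feature_table(records)
        assignments = presence.assign_categories(features, min_days=config.min_days, k=config.k)
        state["features"], state["assignments"] = features, assignments
        if write:
            features.to_csv(out / "features.csv", index=False)
            assignments.to_csv(out / "assignments.csv", index=False)
            eligible = features[features["days_seen"] >= config.min_days]
            if len(eligible) >= 2:
                std = presence.standardize_features(eligible[["days_seen", "max_gap", "gap_sd"]])
                presence.dendrogram_table(std).to_csv(out / "dendrogram.csv", index=False)
    elif stage == "subgroups":
        records = _require(state, "records", config)
        barriers = state["world"].barriers if "world" in state else None
        sg = subgroups.subgroup_table(records, barriers=barriers, radius=config.radius)
        state["subgroup_records"] = sg
        if write:
            sg.to_csv(out / "subgroup_records.csv", index=False)
            per_group = sg.drop_duplicates("subgroup_id")[["date", "session", "subgroup_id", "subgroup_size"]]
            per_group.to_csv(out / "subgroup_sizes.csv", index=False)
    elif stage == "seasontests":
        records = _require(state, "records", config)
        if "assignments" not in state:
            _run_stage("classify", config, out, state, write=False)
        assignments = state["assignments"]
        if "subgroup_records" not in state:
            _run_stage("subgroups", config, out, state, write=False)
        sg = state["subgroup_records"]
        stest_seed = stage_seed(config.seed, "seasontests")
        table = seasons.season_table(records, assignments)
        results = []
        for i, cat in enumerate(presence.CATEGORY_ORDER):
            results.append(
                seasons.bootstrap_friedman(
                    table, cat, n_boot=config.n_boot, sample_size=config.sample_size,
                    alpha=config.alpha_friedman, seed=stest_seed + i,
                )
            )
            results.extend(
                seasons.bootstrap_wilcoxon_pairs(
                    table, cat, alpha=config.alpha_wilcoxon, n_boot=config.n_boot,
                    sample_size=config.sample_size, seed=stest_seed + 100 + i,
                )
            )
        rel = seasons.relative_days_seen(records, assignments)
        for j, cat in enumerate(presence.CATEGORY_ORDER):
            vals = rel[rel["category"] == cat][list(seasons.SEASONS)]
            if len(vals) >= 3:
                results.append(
                    seasons.monte_carlo_friedman(
                        vals.to_numpy(), n_resamples=config.n_boot, seed=stest_seed + 200 + j, label=cat
                    )
                )
                results.extend(seasons.exact_wilcoxon_pairs(vals, alpha=config.alpha_wilcoxon))
        ident = sg[(sg["marked"].astype(int) == 1) & ~sg["bird_id"].isin(["unmarked", ""])]
        merged = ident.merge(assignments[["bird_id", "category"]], on="bird_id", how="inner")
        if merged["category"].nunique() >= 2:
            results.extend(seasons.subgroup_size_by_category(merged, alpha=config.alpha_mwu))
        state["season_results"] = results
        if write:
            _results_frame(results).to_csv(out / "season_tests.csv", index=False)
    elif stage == "avgmodel":
        covariates = _require(state, "covariates", config)
        if "transect" not in state:
            _run_stage("estimate", config, out, state, write=False)
        if "subgroup_records" not in state:
            _run_stage("subgroups", config, out, state, write=False)
        flock_table = state["transect"].merge(covariates, on=["date", "session"], how="left")
        fdata = prepare_model_data(flock_table, response="flock")
        fres = all_subsets_average(fdata, family=config.flock_family, random_intercept=config.random_intercept)
        state["flock_average"] = fres

        sg = state["subgroup_records"]
        if not config.subgroup_per_record:
            sg = sg.drop_duplicates("subgroup_id")
        n_present = (
            state["subgroup_records"].groupby(["date", "session"]).size().rename("n_crows_present").reset_index()
        )
        sg_table = sg.merge(covariates, on=["date", "session"], how="left").merge(
            n_present, on=["date", "session"], how="left"
        )
        sdata = prepare_model_data(sg_table, response="subgroup", candidate_terms=config.subgroup_terms)
        sres = all_subsets_average(sdata, family=config.subgroup_family, random_intercept=config.random_intercept)
        state["subgroup_average"] = sres
        if write:
            fres["average"].to_csv(out / "flock_model_average.csv")
            fres["aic_table"].to_csv(out / "flock_model_aics.csv", index=False)
            sres["average"].to_csv(out / "subgroup_model_average.csv")
            sres["aic_table"].to_csv(out / "subgroup_model_aics.csv", index=False)
    elif stage == "summarize":
        records = _require(state, "records", config)
        assignments = state.get("assignments")
        marked_total = None
        if "birds" in state:
            marked_total = int(state["birds"]["marked"].sum())
        summary = summarize_population(records, assignments, marked_total=marked_total)
        state["summary"] = summary
        if write:
            (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    else:
        raise ValueError(f"unknown stage {stage!r}")
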