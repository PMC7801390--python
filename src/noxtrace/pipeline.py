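"""End-to-end pipeline: observations -> offset -> mixing -> budgets.

The pipeline is configured by a single YAML mapping (see ``PipelineConfig``)
and driven by one master seed, from which every stage seed is spawned
deterministically.  Each stage writes its table to the output directory and
a manifest records the configuration, seeds, and outputs so that any run can
be reproduced from the manifest alone.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from . import budget as bd
from . import descriptive, io, mixing, synthetic
from .reconstruction import FractionationEstimate, pooled_offset, scenario_offset

__all__ = ["PipelineConfig", "run_pipeline", "fit_contributions"]

SOURCE_ORDER = ("coal_combustion", "vehicle_exhaust", "biomass_burning",
                "microbial_N")
#: sources eligible at each site class; vehicle exhaust is not a dominant
#: source away from traffic and is excluded at non-urban sites
CLASS_SOURCES = {
    "urban": SOURCE_ORDER,
    "non-urban": ("coal_combustion", "biomass_burning", "microbial_N"),
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    ``sources`` must name all four end-members (mean/sd in permil); there
    are no built-in defaults for vehicle exhaust and biomass burning, whose
    signatures vary between compilations and must be supplied.
    """

    seed: int
    outdir: Path
    sources: dict[str, mixing.SourceSignature]
    observations_path: Path | None = None
    synthetic_strata: list[synthetic.StratumSpec] = field(default_factory=list)
    offset: FractionationEstimate | None = None
    scenario_paths: dict[str, Path] = field(default_factory=dict)
    mcmc: dict[str, Any] = field(default_factory=dict)
    n_mc_draws: int = 10_000
    fit_mode: str = "site_year"  # or "stratum"
    contributions_path: Path | None = None
    regions: dict[str, dict[str, Any]] = field(default_factory=dict)
    raw: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, cfg: dict[str, Any], base: Path | None = None) -> "PipelineConfig":
        base = Path(base) if base is not None else Path.cwd()

        def _path(p: str | None) -> Path | None:
            if p is None:
                return None
            q = Path(p)
            return q if q.is_absolute() else base / q

        src_cfg = cfg.get("sources") or {}
        missing = [s for s in SOURCE_ORDER if s not in src_cfg]
        if missing:
            raise io.SchemaError(f"config must define source signatures {missing}")
        sources = {
            name: mixing.SourceSignature(name, float(v["mean"]), float(v["sd"]))
            for name, v in src_cfg.items()
        }

        obs_cfg = cfg.get("observations") or {}
        obs_path = _path(obs_cfg.get("path"))
        strata = [
            synthetic.StratumSpec(
                region=s["region"],
                site_class=s["site_class"],
                mean_delta=float(s["mean_delta"]),
                sd_delta=float(s["sd_delta"]),
                n_sites=int(s["n_sites"]),
                replicates_per_site=int(s.get("replicates_per_site", 5)),
                year_range=tuple(s.get("year_range", (2010, 2010))),
            )
            for s in (obs_cfg.get("synthetic") or {}).get("strata", [])
        ]
        if (obs_path is None) == (not strata):
            raise io.SchemaError(
                "exactly one of observations.path and observations.synthetic "
                "must be configured"
            )
        if obs_path is not None and not obs_path.exists():
            raise io.SchemaError(f"observation table not found: {obs_path}")

        off_cfg = cfg.get("offset") or {}
        offset = None
        scenario_paths: dict[str, Path] = {}
        if "mean" in off_cfg:
            offset = FractionationEstimate(
                float(off_cfg["mean"]), float(off_cfg.get("sd", 0.0)), "pooled"
            )
        else:
            for key in ("scenario1", "scenario2"):
                if key not in off_cfg:
                    raise io.SchemaError(
                        "offset requires either mean/sd or scenario1/scenario2 paths"
                    )
                p = _path(off_cfg[key]["path"])
                if p is None or not p.exists():
                    raise io.SchemaError(f"ambient table not found: {p}")
                scenario_paths[key] = p

        return cls(
            seed=int(cfg.get("seed", 0)),
            outdir=_path(cfg.get("outdir", "noxtrace_out")),
            sources=sources,
            observations_path=obs_path,
            synthetic_strata=strata,
            offset=offset,
            scenario_paths=scenario_paths,
            mcmc=dict(cfg.get("mcmc") or {}),
            n_mc_draws=int((cfg.get("monte_carlo") or {}).get("n_draws", 10_000)),
            fit_mode=str(cfg.get("fit_mode", "site_year")),
            contributions_path=_path(cfg.get("contributions_path")),
            regions={str(k): dict(v) for k, v in (cfg.get("regions") or {}).items()},
            raw=cfg,
        )


def _stage_seeds(master: int) -> dict[str, int]:
    children = np.random.SeedSequence(master).spawn(3)
    names = ("synthetic", "mixing", "monte_carlo")
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def fit_contributions(
    observations: pd.DataFrame,
    sources: dict[str, mixing.SourceSignature],
    offset: FractionationEstimate,
    settings_kwargs: dict[str, Any],
    seed: int,
    fit_mode: str = "site_year",
) -> pd.DataFrame:
    """Fit the mixing model per group and average into stratum contributions.

    ``fit_mode='site_year'`` fits one posterior per site and sampling year
    and then averages posterior means within each region x site-class
    stratum (total SD by the law of total variance: mean within-fit variance
    plus between-fit variance of the means).  ``fit_mode='stratum'`` pools
    all replicates of a stratum into a single fit.
    """
    if fit_mode not in ("site_year", "stratum"):
        raise ValueError("fit_mode must be 'site_year' or 'stratum'")
    group_cols = (
        ["region", "site_class", "site_id", "year"]
        if fit_mode == "site_year"
        else ["region", "site_class"]
    )
    groups = sorted(observations.groupby(group_cols).groups.items())
    seeds = np.random.SeedSequence(seed).spawn(len(groups))
    per_fit: list[dict[str, Any]] = []
    for (key, idx), seq in zip(groups, seeds):
        key = key if isinstance(key, tuple) else (key,)
        region, site_class = key[0], key[1]
        names = CLASS_SOURCES[site_class]
        settings = mixing.McmcSettings(
            seed=int(seq.generate_state(1)[0] % (2**31)), **settings_kwargs
        )
        post = mixing.fit_mixing_model(
            observations.loc[idx, "delta15n_permil"].to_numpy(),
            [sources[n] for n in names],
            offset,
            settings,
        )
        summ = mixing.summarize(post)
        for name in SOURCE_ORDER:
            if name in names:
                mean, sd = summ.loc[name, "mean"], summ.loc[name, "sd"]
            else:
                mean, sd = 0.0, 0.0
            per_fit.append({
                "region": region, "site_class": site_class, "source": name,
                "f_mean": float(mean), "f_sd": float(sd),
            })
    fits = pd.DataFrame(per_fit)
    rows = []
    for (region, site_class, name), g in fits.groupby(
        ["region", "site_class", "source"], sort=False
    ):
        within = float(np.mean(g["f_sd"] ** 2))
        between = float(np.var(g["f_mean"], ddof=0))
        rows.append({
            "region": region, "site_class": site_class, "source": name,
            "f_mean": float(g["f_mean"].mean()),
            "f_sd": float(np.sqrt(within + between)),
            "n_fits": int(len(g)),
        })
    out = pd.DataFrame(rows)
    order = {n: i for i, n in enumerate(SOURCE_ORDER)}
    return out.sort_values(
        ["region", "site_class", "source"],
        key=lambda s: s.map(order) if s.name == "source" else s,
        ignore_index=True,
    )


def _resolve_offset(config: PipelineConfig) -> FractionationEstimate:
    if config.offset is not None:
        return config.offset
    s1 = scenario_offset(
        io.read_ambient_records(config.scenario_paths["scenario1"]), "scenario1"
    )
    s2 = scenario_offset(
        io.read_ambient_records(config.scenario_paths["scenario2"]), "scenario2"
    )
    return pooled_offset(s1, s2)


def _aggregate_region(
    contributions: pd.DataFrame, region: str, region_cfg: dict[str, Any]
) -> pd.DataFrame:
    weights = bd.PopulationWeights.from_urban(float(region_cfg["p_urban"]))
    sub = contributions[contributions["region"] == region]
    rows = []
    for name in SOURCE_ORDER:
        pair_rows = {
            sc: sub[(sub["site_class"] == sc) & (sub["source"] == name)]
            for sc in ("urban", "non-urban")
        }
        if any(r.empty for r in pair_rows.values()):
            raise ValueError(
                f"region {region!r} lacks urban or non-urban contributions "
                f"for source {name!r}"
            )
        u, n = pair_rows["urban"].iloc[0], pair_rows["non-urban"].iloc[0]
        pair = bd.ContributionPair(
            name, u["f_mean"], n["f_mean"], u["f_sd"], n["f_sd"]
        )
        f_region = bd.regionwide_contribution(pair, weights)
        f_sd = float(np.hypot(weights.p_urban * pair.f_urban_sd,
                              weights.p_non_urban * pair.f_non_urban_sd))
        rows.append({"region": region, "source": name,
                     "F_mean": f_region, "F_sd": f_sd})
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the full inference chain and write all outputs.

    Returns a result bundle with the observation table, offset estimate,
    contribution tables, per-region budgets, headline aggregates, and the
    manifest.  Fully deterministic given the configured seed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    outputs: list[str] = []

    def _stage(name: str):
        def fail(exc: Exception) -> RuntimeError:
            return RuntimeError(f"pipeline stage {name!r} failed: {exc}")
        return fail

    # 1. observations
    try:
        if config.observations_path is not None:
            observations = io.read_observations(config.observations_path)
        else:
            observations = synthetic.generate_observation_table(
                config.synthetic_strata, seeds["synthetic"]
            )
    except Exception as exc:
        raise _stage("observations")(exc) from exc
    io.write_observations(observations, outdir / "observations.tsv")
    outputs.append("observations.tsv")

    # 2. fractionation offset
    try:
        offset = _resolve_offset(config)
    except Exception as exc:
        raise _stage("offset")(exc) from exc
    (outdir / "offset.json").write_text(json.dumps({
        "mean_permil": offset.mean, "sd_permil": offset.sd,
        "scenario": offset.scenario, "n_records": offset.n_records,
    }, indent=2))
    outputs.append("offset.json")

    # 3. mixing-model contributions (skipped when precomputed)
    try:
        if config.contributions_path is not None:
            contributions = pd.read_csv(config.contributions_path, sep=io.SEP)
        else:
            # restrict each region to its configured year window, if any
            obs = observations
            frames = []
            for region, g in obs.groupby("region"):
                window = (config.regions.get(region, {}) or {}).get("year_window")
                if window:
                    lo, hi = int(window[0]), int(window[1])
                    g = g[(g["year"] >= lo) & (g["year"] <= hi)]
                frames.append(g)
            obs = pd.concat(frames, ignore_index=True)
            contributions = fit_contributions(
                obs, config.sources, offset, config.mcmc,
                seeds["mixing"], config.fit_mode,
            )
    except Exception as exc:
        raise _stage("mixing")(exc) from exc
    contributions.to_csv(outdir / "contributions.tsv", sep=io.SEP, index=False)
    outputs.append("contributions.tsv")

    # 4. regional aggregation and 5. emission budgets
    regional_frames, budget_rows = [], []
    mc_seeds = np.random.SeedSequence(seeds["monte_carlo"]).spawn(
        max(len(config.regions), 1)
    )
    try:
        for (region, region_cfg), seq in zip(sorted(config.regions.items()), mc_seeds):
            regional = _aggregate_region(contributions, region, region_cfg)
            regional_frames.append(regional)
            f = {r["source"]: r["F_mean"] for _, r in regional.iterrows()}
            f_sd = {r["source"]: r["F_sd"] for _, r in regional.iterrows()}
            f_fossil, f_non_fossil = bd.fossil_nonfossil_split(
                f["coal_combustion"], f["vehicle_exhaust"],
                f["biomass_burning"], f["microbial_N"],
            )
            f_fossil_sd = float(np.hypot(f_sd["coal_combustion"],
                                         f_sd["vehicle_exhaust"]))
            result = bd.propagate_uncertainty(
                a_fossil=float(region_cfg["a_fossil"]),
                a_fossil_sd=float(region_cfg.get("a_fossil_sd", 0.0)),
                f_fossil=f_fossil,
                f_fossil_sd=f_fossil_sd,
                n_draws=config.n_mc_draws,
                seed=int(seq.generate_state(1)[0] % (2**31)),
            )
            budget_rows.append({
                "region": region,
                "a_fossil": result.a_fossil, "a_fossil_sd": result.a_fossil_sd,
                "f_fossil": result.f_fossil, "f_fossil_sd": result.f_fossil_sd,
                "f_non_fossil": result.f_non_fossil,
                "f_non_fossil_sd": result.f_non_fossil_sd,
                "a_total": result.a_total, "a_total_sd": result.a_total_sd,
                "a_non_fossil": result.a_non_fossil,
                "a_non_fossil_sd": result.a_non_fossil_sd,
            })
    except Exception as exc:
        raise _stage("budget")(exc) from exc

    regional_table = (
        pd.concat(regional_frames, ignore_index=True)
        if regional_frames
        else pd.DataFrame(columns=["region", "source", "F_mean", "F_sd"])
    )
    regional_table.to_csv(outdir / "regional_contributions.tsv", sep=io.SEP,
                          index=False)
    outputs.append("regional_contributions.tsv")
    budgets = pd.DataFrame(budget_rows)
    budgets.to_csv(outdir / "budgets.tsv", sep=io.SEP, index=False)
    outputs.append("budgets.tsv")

    summary: dict[str, Any] = {}
    if len(budgets):
        shares = budgets["f_non_fossil"].to_numpy()
        summary["non_fossil_share_unweighted_mean"] = bd.aggregate_regions(shares)
        summary["non_fossil_share_emission_weighted_mean"] = bd.aggregate_regions(
            shares, budgets["a_total"].to_numpy()
        )
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    outputs.append("summary.json")

    # 6. descriptive statistics (site-mean comparisons); best effort on
    # sparse synthetic tables
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        comparisons = descriptive.compare_groups(observations)
    comp_table = pd.DataFrame([
        {
            "test": c.test, "groups": "|".join(c.groups),
            "statistic": c.statistic, "p_value": c.p_value,
            "significant": c.significant, "alpha": c.alpha,
        }
        for c in comparisons
    ])
    comp_table.to_csv(outdir / "comparisons.tsv", sep=io.SEP, index=False)
    outputs.append("comparisons.tsv")

    manifest = {
        "package": "noxtrace",
        "version": __version__,
        "master_seed": config.seed,
        "stage_seeds": seeds,
        "config": config.raw,
        "outputs": outputs,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    return {
        "observations": observations,
        "offset": offset,
        "contributions": contributions,
        "regional": regional_table,
        "budgets": budgets,
        "summary": summary,
        "comparisons": comparisons,
        "manifest": manifest,
    }
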