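"""End-to-end orchestration: simulate -> filter -> fit -> derive -> regress.

Each stage reads and writes plain CSV under a common output directory,
so a run can resume from any completed stage.  A JSON manifest records
per-stage seeds, input checksums, timings and the package version; the
manifest plus the configuration suffice to re-run any stage
identically.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import CesDataset, drop_unsexed, filter_sites, read_dataset, write_dataset
from .derived import sex_ratio_draws, survival_sex_ratio_correlations
from .regress import (fit_abundance_sexratio, fit_abundance_surface,
                      fit_productivity, fit_sexratio_trend, report)
from .simulate import SimulationConfig, simulate_census_counts, simulate_dataset
from .survival import McmcConfig, SurvivalPosterior, fit

STAGES = ("simulate", "filter", "fit", "derive", "regress")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    stages: tuple[str, ...] = STAGES
    simulation: dict = field(default_factory=dict)
    filter_params: dict = field(default_factory=dict)
    mcmc: dict = field(default_factory=dict)
    n_census_squares: int = 300
    seeds: dict = field(default_factory=dict)   # per-stage named seeds

    def __post_init__(self):
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stages {bad}; valid: {STAGES}")
        self.stages = tuple(s for s in STAGES if s in self.stages)
        defaults = {"simulate": 1, "fit": 2}
        self.seeds = {**defaults, **self.seeds}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["stages"] = list(self.stages)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _checksums(directory: Path) -> dict[str, str]:
    return {p.name: _sha256(p) for p in sorted(directory.glob("*.csv"))}


def validate_config(config: PipelineConfig) -> None:
    """Fail before execution if a stage's inputs cannot be produced."""
    out = Path(config.out_dir)
    have = set(config.stages)
    if "filter" in have and "simulate" not in have and not (out / "data").exists():
        raise PipelineError("filter", "no 'simulate' stage and no existing data/ inputs")
    if "fit" in have and not ({"simulate", "filter"} & have) \
            and not (out / "filtered").exists():
        raise PipelineError("fit", "no upstream stage and no existing filtered/ inputs")
    if "derive" in have and "fit" not in have and not (out / "posterior").exists():
        raise PipelineError("derive", "fit disabled and no posterior present")
    if "regress" in have and "derive" not in have and not (out / "derived").exists():
        raise PipelineError("regress", "derive disabled and no derived outputs present")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and return the run manifest."""
    validate_config(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seeds": dict(config.seeds),
                      "stages": {}, "config": {
                          "simulation": config.simulation,
                          "filter_params": config.filter_params,
                          "mcmc": config.mcmc,
                          "n_census_squares": config.n_census_squares}}

    def record(stage: str, t0: float, indirs: list[Path]) -> None:
        manifest["stages"][stage] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "inputs": {str(d.name): _checksums(d) for d in indirs if d.exists()},
        }

    try:
        if "simulate" in config.stages:
            t0 = time.perf_counter()
            sim_cfg = SimulationConfig(**{"seed": config.seeds["simulate"],
                                          **config.simulation})
            result = simulate_dataset(sim_cfg)
            (out / "data").mkdir(exist_ok=True)
            result.write(out / "data")
            census = simulate_census_counts(sim_cfg, config.n_census_squares)
            census.to_csv(out / "data" / "census.csv", index=False)
            record("simulate", t0, [])

        if "filter" in config.stages:
            t0 = time.perf_counter()
            ds = read_dataset(out / "data")
            ds = filter_sites(ds, **config.filter_params)
            ds, frac = drop_unsexed(ds)
            write_dataset(ds, out / "filtered")
            (out / "filtered" / "retained_sexed_fraction.txt").write_text(f"{frac:.6f}\n")
            record("filter", t0, [out / "data"])

        if "fit" in config.stages:
            t0 = time.perf_counter()
            ds = read_dataset(out / "filtered")
            mcmc = McmcConfig(**{"seed": config.seeds["fit"], **config.mcmc})
            posterior = fit(ds, mcmc=mcmc)
            posterior.write(out / "posterior")
            record("fit", t0, [out / "filtered"])

        if "derive" in config.stages:
            t0 = time.perf_counter()
            ds = read_dataset(out / "filtered")
            posterior = SurvivalPosterior.read(out / "posterior")
            sr = sex_ratio_draws(ds, posterior)
            (out / "derived").mkdir(exist_ok=True)
            sr.site_year.to_csv(out / "derived" / "sexratio_site_year.csv", index=False)
            sr.site_mean.to_csv(out / "derived" / "sexratio_site_mean.csv", index=False)
            corr = survival_sex_ratio_correlations(posterior, sr)
            pd.DataFrame([
                {"quantity": k, "mean_r": v.mean_r, "cri_low": v.cri_low,
                 "cri_high": v.cri_high, "prob_positive": v.prob_positive,
                 "n_dropped": v.n_dropped}
                for k, v in corr.items()
            ]).to_csv(out / "derived" / "correlations.csv", index=False)
            record("derive", t0, [out / "filtered", out / "posterior"])

        if "regress" in config.stages:
            t0 = time.perf_counter()
            ds = read_dataset(out / "filtered")
            site_year = pd.read_csv(out / "derived" / "sexratio_site_year.csv",
                                    dtype={"site_id": str})
            site_mean = pd.read_csv(out / "derived" / "sexratio_site_mean.csv",
                                    dtype={"site_id": str})
            sites_df = pd.DataFrame(
                [(s.site_id, s.longitude, s.latitude) for s in ds.sites.values()],
                columns=["site_id", "longitude", "latitude"]).sort_values("site_id")
            census = pd.read_csv(out / "data" / "census.csv")

            results = []
            results.append(fit_sexratio_trend(site_year, sites_df))
            surface = fit_abundance_surface(census)
            log_ab = surface.predict_log(sites_df["longitude"].to_numpy(),
                                         sites_df["latitude"].to_numpy(),
                                         warn_extrapolation=False)
            log_ab = log_ab - log_ab.mean()   # relative scale
            ab_df = sites_df.assign(log_abundance=log_ab)
            sm_df = site_mean.merge(ab_df[["site_id", "log_abundance"]], on="site_id")
            results.append(fit_abundance_sexratio(sm_df))
            juv = pd.read_csv(out / "filtered" / "juvenile_counts.csv",
                              dtype={"site_id": str})
            prod = (juv.rename(columns={"count": "juveniles"})
                    .merge(site_year[["site_id", "year", "posterior_mean"]]
                           .rename(columns={"posterior_mean": "sex_ratio"}),
                           on=["site_id", "year"])
                    .merge(ab_df[["site_id", "log_abundance"]], on="site_id"))
            results.append(fit_productivity(prod))

            (out / "regress").mkdir(exist_ok=True)
            report(results).to_csv(out / "regress" / "coefficients.csv", index=False)
            ab_df.to_csv(out / "regress" / "site_log_abundance.csv", index=False)
            record("regress", t0, [out / "derived", out / "data"])
    except PipelineError:
        raise
    except Exception as exc:  # halt with the failing stage named
        done = set(manifest["stages"])
        current = next(s for s in config.stages if s not in done)
        raise PipelineError(current, str(exc)) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
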