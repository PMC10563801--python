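"""End-to-end orchestration: simulate a fixture estuary, then run
chronology → era binning → isoscapes → change-point decomposition → NLM.

Everything stochastic is seeded from one global seed, so a rerun with the
same configuration produces byte-identical reports.  Stage timings go to
the log only (never into the report) to keep reports reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import changepoint as cp
from . import chronology as chron
from . import core
from . import isoscape as iso
from . import nitrogen as nlm
from . import synthetic as syn

log = logging.getLogger("paleoscape")

VARIABLES = ("d15N", "d13C", "cn_molar")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Run configuration; loadable from YAML with CLI overrides."""

    input_dir: str = "fixture"
    output_dir: str = "out"
    seed: int = 0
    scenario_overrides: dict = field(default_factory=dict)
    force_family: str | None = "spherical"
    families: Sequence[str] = iso.FAMILIES
    harbor_year: float = 1946.0
    harbor_tolerance: float = 10.0
    alpha: float = 0.05
    mcmc_iterations: int = 2000
    nlm_params_path: str | None = None
    grid_cell: float = 100.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        obj = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(obj) - known
        if bad:
            raise PipelineError(f"unknown config keys: {sorted(bad)}")
        return cls(**obj)

    def scenario(self) -> syn.ScenarioConfig:
        base = syn.mini_estuary_config(seed=self.seed)
        if self.scenario_overrides:
            base = dataclasses.replace(base, **self.scenario_overrides)
        return base


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=1), encoding="utf-8")


def _round(x: float, nd: int = 6) -> float:
    return float(np.round(float(x), nd))


# ---------------------------------------------------------------------------
# simulate


def run_simulate(config: PipelineConfig) -> dict:
    """Generate the synthetic estuary fixture on disk.

    Writes sites (GeoJSON), the core-sample table, per-focal-core
    radionuclide profiles and annual series, water-quality records, the
    watershed history and a ground-truth JSON recording every injected
    parameter.  Returns the output manifest.
    """
    scen = config.scenario()
    outdir = Path(config.input_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    sites = syn.gen_sites(scen)
    fields = {
        var: {
            era.label: syn.gen_true_field(
                scen, var, era.label, seed=seed * 1000 + 17 * vi + ei, points=np.array(
                    [[s.x, s.y] for s in sites]
                )
            )
            for ei, era in enumerate(scen.eras)
        }
        for vi, var in enumerate(VARIABLES)
    }
    samples = syn.gen_core_samples(scen, sites, fields, seed=seed + 7)
    core.write_core_table(samples, sites, outdir / "cores.csv")
    core.write_sites_geojson(sites, outdir / "sites.geojson")

    focal = [s for s in sites if s.role == "focal"]
    series_rows = []
    for i, site in enumerate(focal):
        # profiles span the full cored depth so the composite chronology
        # can date the coarse sections; below the 210Pb horizon the model
        # leans on its autoregressive accretion prior
        profile, truth = syn.gen_radionuclide_profile(
            scen, seed=seed * 100 + i, depth_max_cm=100.0, slab_cm=2.5
        )
        profile.to_csv(outdir / f"profile_{site.site_id}.csv")
        for var in VARIABLES:
            s, params = syn.gen_core_timeseries(site, scen, seed * 100 + 31 * i + 3, var)
            for year, value in s.items():
                series_rows.append(
                    {"site_id": site.site_id, "variable": var,
                     "year": int(year), "value": _round(value)}
                )
    pd.DataFrame(series_rows).to_csv(outdir / "series.csv", index=False)

    wq = syn.gen_water_quality(scen, sites, seed=seed + 13)
    core.write_water_quality_table(wq, outdir / "water_quality.csv")

    history = syn.gen_watershed_history(scen, seed=seed)
    history.to_csv(outdir / "watershed.csv", float_format="%.4f")

    truth_obj = {
        "n_sites": scen.n_sites,
        "n_focal": scen.n_focal,
        "accretion_cm_yr": scen.accretion_rate,
        "pb210_influx": scen.pb210_influx,
        "supported_pb210": scen.supported_pb210,
        "step_year": scen.step_year,
        "step_magnitude": scen.step_magnitude,
        "trend_start": scen.trend_start,
        "trend_end": scen.trend_end,
        "trend_slope": scen.trend_slope,
        "noise_sd": scen.noise_sd,
        "ar1_coeff": scen.ar1_coeff,
        "eras": [e.label for e in scen.eras],
        "field_endmembers": {
            var: {era: [fp.mouth, fp.head] for era, fp in scen.field_params[var].items()}
            for var in VARIABLES
        },
    }
    _dump_json(truth_obj, outdir / "truth.json")

    manifest = {
        "files": sorted(p.name for p in outdir.iterdir() if p.is_file()),
        "n_sites": len(sites),
        "n_focal": len(focal),
        "n_samples": len(samples),
    }
    log.info("simulate: wrote %d files to %s", len(manifest["files"]), outdir)
    return manifest


# ---------------------------------------------------------------------------
# full pipeline


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage on the fixture in ``input_dir``; returns the report.

    Writes ``report.json`` plus stage CSV outputs into ``output_dir``.
    A missing water-quality table downgrades to a warning and omits the
    pairing section.
    """
    t_start = time.time()
    indir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not (indir / "cores.csv").exists():
        raise PipelineError(f"no cores.csv in {indir}; run simulate first")

    report: dict = {"seed": config.seed, "stages": {}}

    # --- chronology ----------------------------------------------------
    t0 = time.time()
    samples, sites = core.read_core_table(indir / "cores.csv")
    focal = [s for s in sites if s.role == "focal"]
    posteriors = []
    chron_summaries = {}
    mcmc = chron.MCMCConfig(iterations=config.mcmc_iterations)
    for i, site in enumerate(sorted(focal, key=lambda s: s.site_id)):
        ppath = indir / f"profile_{site.site_id}.csv"
        if not ppath.exists():
            continue
        profile = chron.RadionuclideProfile.from_csv(
            ppath, collection_year=site.collection_year
        )
        markers = chron.detect_markers(profile)
        post = chron.fit_age_depth(
            profile, markers, mcmc=mcmc, seed=config.seed * 100 + i
        )
        post.save(outdir / f"posterior_{site.site_id}")
        posteriors.append(post)
        chron_summaries[site.site_id] = {
            "accretion_cm_yr": _round(post.accretion_draws.mean(), 4),
            "acceptance_rate": _round(post.acceptance_rate, 4),
            "flags": sorted(post.flags),
        }
    if not posteriors:
        raise PipelineError("no focal profiles found; cannot build a chronology")
    composite = chron.composite_chronology(posteriors)
    composite.to_csv(outdir / "composite_chronology.csv")
    report["stages"]["chronology"] = {
        "cores": chron_summaries,
        "n_cores": len(posteriors),
        "composite_flags": sorted(composite.flags),
    }
    log.info("chronology: %d cores in %.1fs", len(posteriors), time.time() - t0)

    # --- era binning + isoscapes ---------------------------------------
    # mapping eras are the calendar spans of the coarse depth sections as
    # dated by the composite chronology (the labels are model outputs)
    t0 = time.time()
    grid_ids = {s.site_id for s in sites if s.role == "grid"}
    grid_bounds = sorted(
        {s.interval.top for s in samples if s.site_id in grid_ids}
        | {s.interval.bottom for s in samples if s.site_id in grid_ids}
    )
    eras = chron.derive_era_bins(
        composite, grid_bounds, max_bins=6,
        collection_year=sites[0].collection_year,
    )
    report["stages"]["eras"] = [
        {"label": e.label, "start": e.start_year, "end": e.end_year} for e in eras
    ]
    unique_intervals = sorted(
        {(s.interval.top, s.interval.bottom) for s in samples}
    )
    dated_list = chron.apply_chronology(
        composite,
        [core.DepthInterval(t, b) for t, b in unique_intervals],
        eras,
    )
    dated = {}
    for s in samples:
        key = (s.site_id, s.interval.top, s.interval.bottom)
        di = dated_list[unique_intervals.index((s.interval.top, s.interval.bottom))]
        if di.in_range:
            dated[key] = (di.mean_year, di.era)
    iso_summary: dict = {}
    for var in VARIABLES:
        maps = iso.build_isoscapes(
            samples, dated, sites, eras, var,
            force_family=config.force_family,
            families=config.families,
            seed=config.seed,
            cell=config.grid_cell,
        )
        iso_summary[var] = {}
        for m in maps:
            iso.write_ascii_grid(m, outdir / f"isoscape_{var}_{m.era.label}.asc")
            iso_summary[var][m.era.label] = {
                "mean": _round(m.mean, 4),
                "family": m.model.family,
                "n_sites": len(m.site_values),
            }
    report["stages"]["isoscape"] = iso_summary
    log.info("isoscape: %d maps in %.1fs",
             sum(len(v) for v in iso_summary.values()), time.time() - t0)

    # --- change-point decomposition ------------------------------------
    t0 = time.time()
    series_df = pd.read_csv(indir / "series.csv")
    wq_path = indir / "water_quality.csv"
    wq_records = None
    if wq_path.exists():
        wq_records = core.read_water_quality_table(wq_path)
    else:
        log.warning("no water_quality.csv; pairing section omitted")
    cp_rows = []
    pair_summary = {}
    for (site_id, var), grp in series_df.groupby(["site_id", "variable"]):
        s = pd.Series(grp["value"].to_numpy(), index=grp["year"].to_numpy())
        s45 = syn.subsample_series(s, 45)
        d = cp.decompose(
            s45, harbor_year=config.harbor_year,
            harbor_tolerance=config.harbor_tolerance, alpha=config.alpha,
        )
        cp_rows.append(
            {
                "site_id": site_id,
                "variable": var,
                "change_year": d.change_year,
                "step_offset": None if d.step_offset is None else _round(d.step_offset, 4),
                "slope_after": None if d.slope_after is None else _round(d.slope_after, 5),
                "step_component": _round(d.flags.get("step_component", float("nan")), 4),
                "trend_component": _round(d.flags.get("trend_component", float("nan")), 4),
                "dif": _round(d.dif, 4),
                "abs": _round(d.abs_value, 4),
                "attributed_to_inlet": bool(d.flags.get("step_attributed_to_inlet", False)),
                "significant": bool(d.flags.get("change_significant", False)),
            }
        )
        if wq_records is not None and var == "d15N":
            pairing = cp.pair_with_water_quality(s, wq_records, station=site_id)
            if pairing.n >= 3:
                pair_summary[site_id] = {
                    "r_no3": _round(pairing.r_no3, 4),
                    "n_years": pairing.n,
                }
    cp_table = pd.DataFrame(cp_rows).sort_values(["site_id", "variable"])
    cp_table.to_csv(outdir / "decomposition.csv", index=False)
    report["stages"]["changepoint"] = {
        "table": cp_table.to_dict(orient="records"),
    }
    if pair_summary:
        report["stages"]["water_quality_pairing"] = pair_summary
    log.info("changepoint: %d series in %.1fs", len(cp_rows), time.time() - t0)

    # --- nitrogen budget ------------------------------------------------
    t0 = time.time()
    history = pd.read_csv(indir / "watershed.csv", index_col="decade")
    params = (
        nlm.NLMParams.from_yaml(config.nlm_params_path)
        if config.nlm_params_path
        else nlm.default_nlm_params()
    )
    budget = nlm.nlm_budget(history, params)
    budget.to_csv(outdir / "nlm_budget.csv")
    budget.stacked_series().to_csv(outdir / "nlm_stacked.csv", index=False)
    report["stages"]["nitrogen_loading"] = {
        str(dec): {
            "total": _round(row["total"], 2),
            "dominant": budget.dominant_source(dec),
        }
        for dec, row in budget.table.iterrows()
    }
    log.info("nlm: %d decades in %.1fs", len(budget.table), time.time() - t0)

    report["manifest"] = sorted(
        {p.name for p in outdir.iterdir() if p.is_file()} | {"report.json"}
    )
    _dump_json(report, outdir / "report.json")
    log.info("run_all finished in %.1fs", time.time() - t_start)
    return report
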