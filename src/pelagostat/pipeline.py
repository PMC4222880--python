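"""End-to-end orchestration: data -> transforms -> aggregation -> variography
-> kriging -> distribution indicators -> collocation, with a reproducible
manifest.

Every stage writes a plain-text product (CSV/JSON) into the output directory
and shares the same projected coordinates, log-transform offset and seed
stream, so re-running an identical config reproduces every number
bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aggregation import annual_summaries, metric_vs_logbiomass
from .collocation import collocation_table
from .distribution import eof, identify_patches, inertia, pointwise_cv
from .kriging import (
    NeighbourhoodSpec,
    average_variability_maps,
    classify_areas,
    krige,
    make_grid,
)
from .simulate import default_simulation_spec, simulate_survey
from .survey import LogTransformSpec, SurveyDataset, log_transform, read_survey, write_survey
from .variogram import (
    empirical_variogram,
    mean_variogram,
    standardize_by_year,
    test_annual_stability,
    variogram_envelope,
)

log = logging.getLogger("pelagostat")


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; YAML-serialisable."""

    input_path: str | None = None  # None -> default synthetic scenario
    out_dir: str = "pelagostat_out"
    seed: int = 0
    n_years: int = 10
    log_c: float = 0.05
    # variography
    lag_width: float = 2.0
    n_lags: int = 25
    angular_tol: float = 15.0
    n_structures: int = 2
    envelope_n_sim: int = 1000
    stability_tolerance: float = 0.05
    n_bands: int = 180
    # patches
    patch_d_along: float = 6.0
    patch_d_across: float = 24.0
    patch_min_share: float = 0.10
    # kriging neighbourhood
    radius_along: float = 12.0
    radius_across: float = 30.0
    min_neighbours: int = 4
    max_neighbours: int = 32
    grid_resolution: float = 1.0
    # collocation
    n_resamples: int = 1000
    species: list[str] | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class PipelineResult:
    out_dir: Path
    outputs: dict[str, Path]
    summary: dict

    def checksum(self) -> dict[str, str]:
        return {
            name: hashlib.sha256(path.read_bytes()).hexdigest()
            for name, path in sorted(self.outputs.items())
        }


def _load_or_simulate(config: PipelineConfig) -> SurveyDataset:
    if config.input_path is not None:
        ds = read_survey(config.input_path)
    else:
        ds = simulate_survey(
            default_simulation_spec(config.seed, n_years=config.n_years,
                                    n_bands=config.n_bands)
        )
    if config.species:
        missing = set(config.species) - set(ds.species)
        if missing:
            raise ValueError(f"requested species not in data: {sorted(missing)}")
        keep = [sp for sp in ds.species if sp in config.species]
        drop = [sp for sp in ds.species if sp not in keep]
        ds = SurveyDataset(
            data=ds.data.drop(columns=drop), species=keep, design=ds.design,
            ref_lon=ds.ref_lon, ref_lat=ds.ref_lat,
        )
    return ds


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis; returns the output paths and headline numbers.

    Stage order: survey data (read or simulated), annual aggregation
    summaries and indicator-vs-log-biomass regressions, per-species
    variography with the mean-variogram envelope and the interannual
    stability test, ordinary kriging of annual log-biomass plus
    mean/variability maps and area classification, spatial indicators
    (CG/inertia/patches/EOF/pointwise CV), and pairwise collocation.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    summary: dict = {"seed": config.seed}
    stage = "input"
    try:
        ds = _load_or_simulate(config)
        azimuth = ds.design.transect_azimuth if ds.design else 0.0
        spec = LogTransformSpec(config.log_c)
        p = out / "survey.csv"
        write_survey(ds, p)
        outputs["survey"] = p

        stage = "aggregation"
        log.info("stage: aggregation")
        summaries = annual_summaries(ds, spec)
        p = out / "summaries.csv"
        summaries.to_csv(p, index=False)
        outputs["summaries"] = p
        reg_rows = []
        for sp_name in ds.species:
            sub = summaries[summaries.species == sp_name]
            ok = np.isfinite(sub.log_biomass)
            for metric in ("presence_area_pct", "mean_density_presence", "selectivity"):
                vals = sub[metric].to_numpy()[ok]
                lb = sub.log_biomass.to_numpy()[ok]
                good = np.isfinite(vals)
                if good.sum() >= 3:
                    r = metric_vs_logbiomass(vals[good], lb[good])
                    reg_rows.append({"species": sp_name, "metric": metric,
                                     "slope": r.slope, "r2_adj": r.r2_adj,
                                     "p_value": r.p_value, "n": r.n})
        regs = pd.DataFrame(reg_rows)
        p = out / "regressions.csv"
        regs.to_csv(p, index=False)
        outputs["regressions"] = p

        stage = "variography"
        log.info("stage: variography")
        vario_rows, stab_rows = [], []
        chosen_models = {}
        for k, sp_name in enumerate(ds.species):
            yrs = ds.years
            pts_by_year, logv_by_year = [], []
            years_arr = ds.data["year"].to_numpy()
            logv_all = log_transform(ds.data[sp_name].to_numpy(), spec)
            std_all = standardize_by_year(years_arr, logv_all)
            for y in yrs:
                m = years_arr == y
                pts_by_year.append(ds.data.loc[m, ["x", "y"]].to_numpy(float))
                logv_by_year.append(std_all[m])
            mv = mean_variogram(pts_by_year, logv_by_year, config.lag_width,
                                config.n_lags, config.angular_tol, azimuth,
                                config.n_structures)
            chosen_models[sp_name] = mv.model
            for emp in (mv.along, mv.across):
                for c, g, npair in zip(emp.lag_centres, emp.gamma, emp.n_pairs):
                    vario_rows.append({"species": sp_name, "direction": emp.direction,
                                       "lag": c, "gamma": g, "n_pairs": int(npair)})
            env = variogram_envelope(
                mv.model, pts_by_year[0], n_sim=config.envelope_n_sim,
                seed=config.seed + 1000 + k, lag_width=config.lag_width,
                n_lags=config.n_lags, angular_tol=config.angular_tol,
                azimuth=azimuth, n_bands=config.n_bands,
            )
            annual = {
                y: {
                    d: empirical_variogram(pts, vals, d, config.lag_width,
                                           config.n_lags, config.angular_tol, azimuth)
                    for d in ("along", "across")
                }
                for y, pts, vals in zip(yrs, pts_by_year, logv_by_year)
            }
            stability = test_annual_stability(annual, env, config.stability_tolerance)
            for y, res in stability.items():
                stab_rows.append({"species": sp_name, "year": y, "stable": res.stable,
                                  "frac_outside": res.frac_outside,
                                  "n_lags_checked": res.n_lags_checked})
            summary[f"stable_years_{sp_name}"] = int(sum(r.stable for r in stability.values()))
        pd.DataFrame(vario_rows).to_csv(out / "mean_variograms.csv", index=False)
        outputs["mean_variograms"] = out / "mean_variograms.csv"
        stab = pd.DataFrame(stab_rows)
        stab.to_csv(out / "stability.csv", index=False)
        outputs["stability"] = out / "stability.csv"
        model_json = {
            sp_name: {
                "nugget": m.nugget,
                "structures": [
                    {"type": "spherical", "sill": s.sill,
                     "range_along": s.range_along, "range_across": s.range_across}
                    for s in m.structures
                ],
            }
            for sp_name, m in chosen_models.items()
        }
        (out / "variogram_models.json").write_text(json.dumps(model_json, indent=2))
        outputs["variogram_models"] = out / "variogram_models.json"

        stage = "kriging"
        log.info("stage: kriging")
        nbhd = NeighbourhoodSpec(config.radius_along, config.radius_across,
                                 config.min_neighbours, config.max_neighbours)
        domain = ds.design.domain_polygon if ds.design else None
        grid = make_grid(ds.points(), config.grid_resolution, domain)
        class_rows = []
        for sp_name in ds.species:
            maps = []
            for y in ds.years:
                pts = ds.points(y)
                vals = log_transform(ds.values(sp_name, y), spec)
                maps.append(krige(pts, vals, chosen_models[sp_name], grid, nbhd, azimuth))
            mean_map, sd_map = average_variability_maps(maps)
            classification = classify_areas(mean_map, sd_map, grid)
            cdf = classification.to_dataframe()
            cdf.insert(0, "species", sp_name)
            class_rows.append(cdf)
            counts = classification.counts()
            total = sum(counts.values())
            summary[f"recurrent_fraction_{sp_name}"] = counts["recurrent"] / total
            summary[f"occasional_fraction_{sp_name}"] = counts["occasional"] / total
        pd.concat(class_rows).to_csv(out / "area_classification.csv", index=False)
        outputs["area_classification"] = out / "area_classification.csv"

        stage = "distribution"
        log.info("stage: distribution")
        ind_rows, patch_rows, eof_rows = [], [], []
        for sp_name in ds.species:
            for y in ds.years:
                pts = ds.points(y)
                vals = ds.values(sp_name, y)
                if vals.sum() <= 0:
                    continue
                g = inertia(pts, vals)
                ind_rows.append({"species": sp_name, "year": y,
                                 "cg_x": g.cg[0], "cg_y": g.cg[1],
                                 "inertia": g.inertia,
                                 "semi_major": g.ellipse.semi_major,
                                 "semi_minor": g.ellipse.semi_minor,
                                 "angle_deg": g.ellipse.angle_deg})
                for pid, patch in enumerate(identify_patches(
                        pts, vals, config.patch_d_along, config.patch_d_across,
                        config.patch_min_share, azimuth)):
                    patch_rows.append({"species": sp_name, "year": y, "patch_id": pid,
                                       "cg_x": patch.cg[0], "cg_y": patch.cg[1],
                                       "inertia": patch.inertia,
                                       "biomass_share": patch.biomass_share,
                                       "retained": patch.retained})
            yrs_m, M = ds.year_matrix(sp_name)
            if (M.sum(axis=1) > 0).all() and M.shape[0] >= 2:
                res = eof(M, standardization="relative")
                for ax in range(min(3, len(res.pct_variance))):
                    eof_rows.append({"species": sp_name, "axis": ax + 1,
                                     "pct_variance": res.pct_variance[ax]})
                summary[f"eof_axis1_pct_{sp_name}"] = float(res.pct_variance[0])
                rel = M / M.sum(axis=1, keepdims=True)
                cv = pointwise_cv(rel)
                summary[f"cv_gt1_fraction_{sp_name}"] = float(
                    np.mean(cv[np.isfinite(cv)] > 1.0))
        pd.DataFrame(ind_rows).to_csv(out / "gravity_indices.csv", index=False)
        outputs["gravity_indices"] = out / "gravity_indices.csv"
        pd.DataFrame(patch_rows).to_csv(out / "patches.csv", index=False)
        outputs["patches"] = out / "patches.csv"
        pd.DataFrame(eof_rows).to_csv(out / "eof.csv", index=False)
        outputs["eof"] = out / "eof.csv"

        stage = "collocation"
        log.info("stage: collocation")
        if len(ds.species) >= 2:
            colloc = collocation_table(
                ds, d_along=config.patch_d_along, d_across=config.patch_d_across,
                min_share=config.patch_min_share, n_resamples=config.n_resamples,
                seed=config.seed + 7, azimuth=azimuth,
            )
            colloc.to_csv(out / "collocation.csv", index=False)
            outputs["collocation"] = out / "collocation.csv"
            pooled = colloc[colloc.year == "pooled"]
            summary["mean_global_overlap"] = float(pooled.global_overlap.mean())
            summary["mean_patch_overlap"] = float(pooled.patch_overlap.mean())
            summary["mean_lic"] = float(pooled.lic.mean())

        stage = "manifest"
        result = PipelineResult(out, outputs, summary)
        manifest = {
            "package_version": __version__,
            "config": asdict(config),
            "summary": summary,
            "checksums": result.checksum(),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        outputs["manifest"] = out / "manifest.json"
        return result
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {stage!r} failed: {exc}; partial outputs kept in {out}"
        ) from exc
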