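"""End-to-end pipeline: simulate -> classify -> sample -> metrics -> stats ->
ordination -> heat maps, writing every intermediate artifact plus a run
manifest (config hash, stage seeds, package versions)."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as bio
from .config import PipelineConfig, save_config, stage_seed
from .heatmap import kernel_density, render_png
from .metrics import metric_table
from .multivariate import anosim, bray_curtis, centroid_overlay, nmds, pairwise_anosim
from .raster import classify, distance_to_tracks, level_areas, rasterize
from .sampling import allocate_units, assign_specimens
from .synthetic import generate_specimens, make_scene
from .univariate import eta_squared, fit_glm, global_test, pairwise_compare

log = logging.getLogger("benthograd")

__all__ = ["run_pipeline", "build_scenes", "build_rasters"]


class StageError(RuntimeError):
    def __init__(self, stage, cause, completed):
        super().__init__(f"stage {stage!r} failed: {cause}; completed: {completed}")
        self.stage = stage
        self.completed = completed


def build_scenes(cfg: PipelineConfig):
    dea = make_scene(
        cfg.dea.extent_ha, cfg.dea.n_tracks, cfg.dea.track_width,
        cfg.dea.track_spacing, seed=cfg.seed, height=cfg.dea.height,
        name=cfg.dea.name,
    )
    ref = make_scene(
        cfg.ref.extent_ha, cfg.ref.n_tracks, cfg.ref.track_width,
        cfg.ref.track_spacing, seed=cfg.seed, height=cfg.ref.height,
        name=cfg.ref.name,
    )
    return dea, ref


def build_rasters(cfg: PipelineConfig, scenes):
    out = []
    for scene in scenes:
        r = rasterize(scene, cfg.cell_size)
        r = distance_to_tracks(r, scene.tracks)
        r = classify(r, cfg.band_bounds)
        out.append(r)
    return out


def _count_metric_columns(metrics: pd.DataFrame):
    """Metric name -> integer per-unit counts, recovered from densities."""
    ha = metrics["area_m2"] / 1e4
    cols = {}
    cols["total"] = metrics["N"].to_numpy()
    for c in metrics.columns:
        if c.startswith("density_") and c != "density_total":
            name = c.replace("density_", "")
            cols[name] = np.rint(metrics[c].to_numpy() * ha.to_numpy()).astype(int)
    return cols


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Run the full analysis; returns the result bundle as a dict.

    Scenes with a single disturbance level skip the comparative statistics
    stages with an explanatory log message.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    completed = []
    bundle = {}
    manifest = {
        "config_hash": cfg.config_hash(),
        "master_seed": cfg.seed,
        "stage_seeds": {},
        "versions": _versions(),
    }
    save_config(cfg, outdir / "config.yaml")

    def stage(name):
        def wrap(fn):
            try:
                fn()
                completed.append(name)
            except Exception as exc:  # noqa: BLE001 - abort with stage context
                raise StageError(name, exc, completed) from exc
        return wrap

    state = {}

    @stage("simulate")
    def _simulate():
        seed = stage_seed(cfg.seed, "simulate")
        manifest["stage_seeds"]["simulate"] = seed
        scenes = build_scenes(cfg)
        rasters = build_rasters(cfg, scenes)
        tables = []
        for i, (scene, raster) in enumerate(zip(scenes, rasters)):
            t = generate_specimens(scene, raster, cfg.community, seed + i)
            bio.write_specimens(t, outdir / f"specimens_{scene.name}.csv")
            bio.write_json(bio.scene_to_geojson(scene), outdir / f"scene_{scene.name}.geojson")
            tables.append(t)
        state.update(scenes=scenes, rasters=rasters, tables=tables)

    @stage("classify")
    def _classify():
        for scene, raster in zip(state["scenes"], state["rasters"]):
            bio.write_ascii_grid(
                outdir / f"distance_{scene.name}.asc",
                raster.origin, raster.cell_size, raster.distance,
            )
            bio.write_ascii_grid(
                outdir / f"levels_{scene.name}.asc",
                raster.origin, raster.cell_size, raster.level.astype(float),
            )
        bundle["level_areas_ha"] = {
            scene.name: level_areas(raster)
            for scene, raster in zip(state["scenes"], state["rasters"])
        }
        bio.write_json(bundle["level_areas_ha"], outdir / "level_areas.json")

    @stage("sample")
    def _sample():
        seed = stage_seed(cfg.seed, "sample")
        manifest["stage_seeds"]["sample"] = seed
        scenes, rasters, tables = state["scenes"], state["rasters"], state["tables"]
        all_units, mats = [], []
        for scene, raster, table in zip(scenes, rasters, tables):
            areas = level_areas(raster)
            reps = {
                lv: n for lv, n in cfg.replicates.items()
                if areas.get(lv, 0.0) > 0
            }
            if not reps:
                continue
            units = allocate_units(raster, cfg.cells_per_unit, reps, seed,
                                   prefix=f"{scene.name}-")
            mat = assign_specimens(table, raster, units)
            bio.write_units(units, outdir / f"units_{scene.name}.csv")
            all_units.append((scene, units))
            mats.append(mat)
        counts = pd.concat([m.counts for m in mats]).fillna(0).astype(int)
        meta = pd.concat([m.meta for m in mats])
        from .sampling import AbundanceMatrix

        abund = AbundanceMatrix(
            counts=counts, meta=meta,
            n_dropped=sum(m.n_dropped for m in mats),
        )
        bio.write_abundance(abund, outdir / "abundance.csv")
        state["abund"] = abund

    @stage("metrics")
    def _metrics():
        msp_info = cfg.community.morphospecies_table().set_index("morphospecies")
        metrics = metric_table(state["abund"], msp_info)
        metrics.to_csv(outdir / "metrics.csv", float_format="%.6f")
        state["metrics"] = metrics

    @stage("stats")
    def _stats():
        metrics = state["metrics"]
        levels = metrics["level"].to_numpy()
        if len(pd.unique(levels)) < 2:
            log.info("single disturbance level: comparative statistics skipped")
            bundle["univariate"] = None
            return
        seed = stage_seed(cfg.seed, "stats")
        manifest["stage_seeds"]["stats"] = seed
        results = {}
        count_cols = _count_metric_columns(metrics)
        diversity_cols = {c: metrics[c].to_numpy() for c in ("S", "expH", "invD")}
        for name, y in {**count_cols, **diversity_cols}.items():
            family = (
                cfg.diversity_metrics_family
                if name in diversity_cols
                else cfg.count_metrics_family
            )
            fit = fit_glm(y, levels, family=family, metric=name)
            F, df1, df2, p = global_test(fit)
            pw = pairwise_compare(fit, alpha=cfg.alpha, seed=seed)
            results[name] = {
                "family": family,
                "F": F, "df1": df1, "df2": df2, "p": p,
                "phi": fit.phi,
                "eta_squared": eta_squared(y, levels),
                "levels": fit.levels,
                "means": fit.means,
                "ci_low": fit.ci_low,
                "ci_high": fit.ci_high,
                "pairwise": {
                    f"{a}-{b}": {"estimate": e, "p_raw": pr, "p_adj": pa}
                    for (a, b), e, pr, pa in zip(
                        pw.pairs, pw.estimates, pw.p_raw, pw.p_adj
                    )
                },
                "mvt_error": pw.mc_error,
                "letters": pw.letters,
            }
        bio.write_json(results, outdir / "univariate.json")
        bundle["univariate"] = results

    @stage("ordinate")
    def _ordinate():
        metrics = state["metrics"]
        if len(pd.unique(metrics["level"])) < 2:
            log.info("single disturbance level: multivariate stage skipped")
            bundle["multivariate"] = None
            return
        seed = stage_seed(cfg.seed, "ordinate")
        manifest["stage_seeds"]["ordinate"] = seed
        d = bray_curtis(state["abund"], transform="sqrt")
        pd.DataFrame(d.values, index=d.labels, columns=d.labels).to_csv(
            outdir / "braycurtis.csv", float_format="%.6f"
        )
        glob = anosim(d, cfg.anosim_max_exact, cfg.anosim_n_perm, seed)
        pairs = pairwise_anosim(d, cfg.anosim_max_exact, cfg.anosim_n_perm, seed)
        ordin = nmds(
            d, cfg.nmds_dims, cfg.nmds_starts, cfg.nmds_max_iter,
            cfg.nmds_tol, seed,
        )
        coords = ordin.coords.copy()
        coords["stress"] = ordin.stress
        coords.to_csv(outdir / "nmds_coords.csv", float_format="%.6f")
        report = {
            "global": _anosim_dict(glob),
            "pairwise": [_anosim_dict(r) for r in pairs],
            "nmds_stress": ordin.stress,
            "nmds_converged": ordin.converged,
            "centroids": centroid_overlay(ordin).to_dict(orient="index"),
        }
        bio.write_json(report, outdir / "multivariate.json")
        bundle["multivariate"] = report

    @stage("heatmap")
    def _heatmap():
        dea_scene = state["scenes"][0]
        table = state["tables"][0]
        for group in cfg.heatmap_groups:
            surf = kernel_density(
                table, group, dea_scene,
                cfg.heatmap_resolution, cfg.heatmap_radius,
            )
            bio.write_ascii_grid(
                outdir / f"heatmap_{group}.asc",
                surf.origin, surf.cell_size, surf.density,
            )
            render_png(surf, outdir / f"heatmap_{group}.png", dea_scene.tracks)

    bundle["n_dropped_specimens"] = state["abund"].n_dropped
    bundle["manifest"] = manifest
    bio.write_json(manifest, outdir / "manifest.json")
    return bundle


def _anosim_dict(r):
    return {
        "R": r.R, "p": r.p, "scheme": r.scheme,
        "n_arrangements": r.n_arrangements, "seed": r.seed,
        "groups": list(r.groups), "group_sizes": list(r.group_sizes),
    }


def _versions():
    import numpy
    import pandas
    import scipy
    import sklearn
    import statsmodels

    from . import __version__

    return {
        "benthograd": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "statsmodels": statsmodels.__version__,
        "scikit-learn": sklearn.__version__,
    }
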