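"""End-to-end orchestration: configuration, staged runs, robustness check.

A run executes ingest -> coverage screening -> environmental pairing ->
multivariate GLM niche test -> per-genus random forests -> percentile
envelopes -> legacy evaluation, writing every intermediate artifact plus
a machine-readable manifest.  All randomness flows from named seeds in
the configuration, and rerunning the same configuration reproduces
byte-identical tabular outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy.spatial import procrustes

from . import coverage as cov
from . import envelope as envl
from . import envpair, evaluate, ingest, niche_glm, rfm, synth
from .fields import EnvFieldSet, PREDICTORS

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name and context."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclasses.dataclass
class RunConfig:
    """Everything a run needs; round-trips through YAML unchanged."""

    # input paths; None means "simulate with the synthetic generator"
    reports_csv: Optional[str] = None
    legacy_csv: Optional[str] = None
    env_dir: Optional[str] = None

    # seeds (every stochastic stage has its own)
    synth_seed: int = 1
    split_seed: int = 11
    rf_seed: int = 21
    perm_seed: int = 31

    # synthetic study conditions
    lat_step: float = 4.0
    months: int = 12
    land_fraction: float = 0.3
    smooth_deg: float = 12.0
    n_target: Optional[dict[str, int]] = None   # default: synth.DEFAULT_N_TARGET
    legacy_n: int = synth.DEFAULT_LEGACY_N
    clustering: str = "sites"
    site_frac: float = 0.97

    # curation / pairing
    genera: tuple[str, ...] = ingest.DEFAULT_GENERA
    round_digits: int = 1
    sc_threshold: float = 0.95
    window: float = 2.0
    map_step: float = 2.0
    collapse_months: bool = False

    # models
    n_resamples: int = 199
    n_trees: int = 500
    test_fraction: float = 0.2
    class_weight: Optional[str] = None
    central_fraction: float = 0.90
    month_mode: str = "any_month"
    tolerance_cells: int = 0
    flag_threshold: float = 0.5
    make_maps: bool = False

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        d = dataclasses.asdict(self)
        d["genera"] = list(self.genera)
        path.write_text(yaml.safe_dump(d, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "genera" in d:
            d["genera"] = tuple(d["genera"])
        return cls(**d)


def _simulate_inputs(config: RunConfig, outdir: Path):
    env = synth.make_environment(
        seed=config.synth_seed,
        lat_step=config.lat_step,
        months=config.months,
        land_fraction=config.land_fraction,
        smooth_deg=config.smooth_deg,
    )
    niches = synth.default_niches()
    effort = synth.ParticipationSurface.western_bias(env)
    targets = config.n_target or synth.DEFAULT_N_TARGET
    reports = synth.sample_reports(
        niches, env, effort, targets, seed=config.synth_seed,
        clustering=config.clustering, site_frac=config.site_frac,
    )
    legacy = synth.sample_legacy(niches, env, config.legacy_n, seed=config.synth_seed)
    synth.write_reports_csv(reports, outdir / "reports.csv", style="inaturalist")
    synth.write_reports_csv(legacy, outdir / "legacy.csv", style="legacy")
    env.to_netcdf(outdir / "env")
    return env


def run_all(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the full pipeline; returns the manifest dictionary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": json.loads(json.dumps(dataclasses.asdict(config))),
                      "stages": {}}

    # -- inputs ----------------------------------------------------------
    try:
        if config.reports_csv is None:
            env = _simulate_inputs(config, outdir)
            reports_csv = outdir / "reports.csv"
            legacy_csv = outdir / "legacy.csv"
        else:
            reports_csv = Path(config.reports_csv)
            legacy_csv = Path(config.legacy_csv) if config.legacy_csv else None
            if not reports_csv.exists():
                raise FileNotFoundError(f"missing input: {reports_csv}")
            if legacy_csv is not None and not legacy_csv.exists():
                raise FileNotFoundError(f"missing input: {legacy_csv}")
            if config.env_dir is None:
                raise ValueError("env_dir is required when reports_csv is given")
            if not Path(config.env_dir).exists():
                raise FileNotFoundError(f"missing input: {config.env_dir}")
            env = EnvFieldSet.from_netcdf(config.env_dir)
    except (OSError, ValueError) as e:
        raise PipelineError("inputs", str(e)) from e

    # -- ingest ----------------------------------------------------------
    try:
        wl = ingest.GenusWhitelist(tuple(config.genera))
        accepted, rejlog = ingest.read_reports(reports_csv, "inaturalist")
        accepted = ingest.filter_taxonomy(accepted, wl)
        accepted = ingest.round_reports(accepted, config.round_digits)
        rejlog.to_csv(outdir / "rejections.csv", index=False)
        legacy_reports: list[ingest.Report] = []
        if legacy_csv is not None:
            legacy_reports, leg_log = ingest.read_reports(legacy_csv, "legacy")
            legacy_reports = ingest.filter_taxonomy(legacy_reports, wl)
            leg_log.to_csv(outdir / "legacy_rejections.csv", index=False)
        manifest["stages"]["ingest"] = {
            "accepted": len(accepted), "rejected": int(len(rejlog)),
            "legacy": len(legacy_reports),
        }
    except (OSError, ValueError) as e:
        raise PipelineError("ingest", str(e)) from e

    # -- coverage --------------------------------------------------------
    try:
        results = cov.retain_genera(accepted, config.sc_threshold,
                                    genera=list(config.genera))
        cov_df = pd.DataFrame(
            [dataclasses.asdict(r) for r in results],
            columns=["genus", "n", "n_coords", "sc", "retained"],
        )
        cov_df.to_csv(outdir / "coverage.csv", index=False)
        retained = [r.genus for r in results if r.retained]
        if not retained:
            raise ValueError("no genus passed the coverage screen")
        kept_reports = [r for r in accepted if r.genus in retained]
        manifest["stages"]["coverage"] = {
            "retained": retained,
            "dropped": [r.genus for r in results if not r.retained],
        }
    except ValueError as e:
        raise PipelineError("coverage", str(e)) from e

    # -- envpair ---------------------------------------------------------
    try:
        frame = envpair.build_frame(
            kept_reports, env, map_step=config.map_step, window=config.window,
            collapse_months=config.collapse_months, genera=retained,
        )
        if len(frame.df) == 0:
            raise ValueError("curated frame is empty (0 pairable reports)")
        frame.df.to_csv(outdir / "curated_frame.csv", index=False)
        manifest["stages"]["envpair"] = {
            "rows": len(frame.df), "unpairable": frame.n_unpairable,
        }
    except ValueError as e:
        raise PipelineError("envpair", str(e)) from e

    # -- niche_glm -------------------------------------------------------
    try:
        mv = niche_glm.manyglm_test(frame, n_resamples=config.n_resamples,
                                    seed=config.perm_seed)
        mv.coefficients.to_csv(outdir / "glm_coefficients.csv")
        glm_summary = {
            "statistic": mv.statistic, "p_value": mv.p_value,
            "n_resamples": mv.n_resamples, "seed": mv.seed,
            "deviances": mv.deviances, "warnings": mv.warnings,
        }
        if len(retained) >= 3:
            scores, explained, _ = niche_glm.niche_biplot(mv.coefficients)
            scores.to_csv(outdir / "biplot.csv")
            glm_summary["biplot_explained"] = [float(v) for v in explained]
        lat_groups = {g: [r.latitude for r in kept_reports if r.genus == g]
                      for g in retained}
        lon_groups = {g: [r.longitude for r in kept_reports if r.genus == g]
                      for g in retained}
        letters = {}
        for name, groups in (("latitude", lat_groups), ("longitude", lon_groups)):
            gl = niche_glm.kruskal_dunn_letters(groups)
            letters[name] = {"statistic": gl.statistic, "p_value": gl.p_value,
                             "letters": gl.letters}
        (outdir / "glm_summary.json").write_text(
            json.dumps(glm_summary, indent=2, sort_keys=True))
        (outdir / "distribution_letters.json").write_text(
            json.dumps(letters, indent=2, sort_keys=True))
        manifest["stages"]["niche_glm"] = {
            "statistic": mv.statistic, "p_value": mv.p_value,
        }
    except ValueError as e:
        raise PipelineError("niche_glm", str(e)) from e

    # -- rfm -------------------------------------------------------------
    try:
        table = rfm.build_labels(frame)
        rf_results = rfm.fit_genus_forests(
            table, retained, split_seed=config.split_seed,
            rf_seed=config.rf_seed, n_trees=config.n_trees,
            test_fraction=config.test_fraction, class_weight=config.class_weight,
        )
        if not rf_results:
            raise ValueError("no genus could be modelled (degenerate labels)")
        imp_rows = []
        for r in rf_results:
            for pid, val in r.importance.items():
                var, depth = pid.rsplit("_", 1)
                imp_rows.append({"genus": r.genus, "variable": var,
                                 "depth": depth, "relative_importance": val})
        pd.DataFrame(imp_rows).to_csv(outdir / "importance.csv", index=False)
        rf_json = [
            {
                "genus": r.genus,
                "test_accuracy": r.test_accuracy,
                "test_specificity": r.test_specificity,
                "selected": list(r.selected),
                "confusion": r.confusion,
                "split_seed": r.split_seed,
                "n_trees": r.n_trees,
            }
            for r in rf_results
        ]
        (outdir / "rf_results.json").write_text(
            json.dumps(rf_json, indent=2, sort_keys=True))
        manifest["stages"]["rfm"] = {
            "genera": [r.genus for r in rf_results],
            "accuracy_min": min(r.test_accuracy for r in rf_results),
            "accuracy_max": max(r.test_accuracy for r in rf_results),
        }
    except ValueError as e:
        raise PipelineError("rfm", str(e)) from e

    # -- envelope + evaluate ---------------------------------------------
    try:
        accs, area_fracs, envelopes = [], {}, {}
        for r in rf_results:
            positives = frame.df[frame.df[r.genus] > 0]
            env_b = envl.build_envelope(positives[list(PREDICTORS)], r.selected,
                                        config.central_fraction, genus=r.genus)
            envelopes[r.genus] = env_b.bounds
            smap = envl.predict_suitable(env, env_b, month_mode=config.month_mode)
            area_fracs[r.genus] = smap.area_fraction()
            cells = sorted(smap.suitable_cells)
            dens = (envl.density_surface(np.array(cells), env.lats, env.lons)
                    if cells else np.zeros_like(smap.mask, dtype=float))
            grid = pd.DataFrame({
                "lat": np.repeat(env.lats, len(env.lons)),
                "lon": np.tile(env.lons, len(env.lats)),
                "suitable": smap.mask.astype(int).ravel(),
                "density": dens.ravel(),
            })
            grid.to_csv(outdir / f"suitability_{r.genus}.csv", index=False)
            genus_legacy = [x for x in legacy_reports if x.genus == r.genus]
            if genus_legacy:
                accs.append(evaluate.legacy_accuracy(
                    smap, genus_legacy, config.tolerance_cells))
            if config.make_maps:
                from .plots import plot_distribution_map
                (outdir / "maps").mkdir(exist_ok=True)
                plot_distribution_map(
                    smap,
                    [x for x in kept_reports if x.genus == r.genus],
                    genus_legacy, density=dens,
                    path=outdir / "maps" / f"{r.genus}.png",
                )
        (outdir / "envelopes.json").write_text(
            json.dumps(envelopes, indent=2, sort_keys=True))
        if accs:
            acc_df = evaluate.accuracy_report(accs, area_fracs,
                                              config.flag_threshold)
            acc_df.to_csv(outdir / "accuracy.csv", index=False)
            manifest["stages"]["evaluate"] = {
                "accuracy_min": acc_df.attrs["accuracy_min"],
                "accuracy_max": acc_df.attrs["accuracy_max"],
            }
    except ValueError as e:
        raise PipelineError("envelope/evaluate", str(e)) from e

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def robustness_check(config: RunConfig, outdir: str | Path) -> dict:
    """Compare the niche model at 1-degree vs 2-degree mapping.

    Runs the GLM stage at both resolutions on identical inputs and
    reports both permutation p-values plus a Procrustes correlation
    between the two biplot configurations (1.0 = identical shapes).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    base = dataclasses.replace(config, make_maps=False)
    results = {}
    coords = {}
    for step in (1.0, 2.0):
        cfg = dataclasses.replace(base, map_step=step)
        rundir = outdir / f"map_{int(step)}deg"
        try:
            manifest = run_all(cfg, rundir)
        except PipelineError as e:
            raise PipelineError("robustness", f"map_step={step}: {e}") from e
        results[f"p_value_{int(step)}deg"] = manifest["stages"]["niche_glm"]["p_value"]
        bip = rundir / "biplot.csv"
        if not bip.exists():
            raise PipelineError("robustness",
                                f"map_step={step}: biplot unavailable (<3 genera)")
        coords[step] = pd.read_csv(bip, index_col=0)

    common = coords[1.0].index.intersection(coords[2.0].index)
    if len(common) < 3:
        raise PipelineError("robustness", "fewer than 3 genera shared across scales")
    _, _, disparity = procrustes(coords[1.0].loc[common].to_numpy(),
                                 coords[2.0].loc[common].to_numpy())
    results["biplot_procrustes_correlation"] = float(np.sqrt(max(0.0, 1.0 - disparity)))
    results["n_genera_compared"] = int(len(common))
    (outdir / "robustness.json").write_text(
        json.dumps(results, indent=2, sort_keys=True))
    return results
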