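"""End-to-end orchestration: survey files in, tidy model outputs out.

Each run writes its intermediate tables, a tidy odds-ratio CSV and a JSON
manifest recording config hash, input checksums, per-stage row counts and
timings — the survey's own exclusions (tuxedo and unknown coats, short
cat-free deployments, moon-excluded nights) are the main silent-failure
risk, so every stage that drops rows logs the count and reason into the
manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import pandas as pd

from . import __version__
from .activity import bootstrap_pde, site_night_table
from .events import (
    RetentionConfig,
    black_estimate_from_detections,
    daily_records,
    filter_sites,
    group_events,
    read_deployments,
    read_detections,
    site_summaries,
)
from .moon import LunarConfig, classify_range
from .multinom import ModelConfig, build_spatial_model, build_temporal_model, fit_multinomial, wald_intervals

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record for one pipeline run."""

    command: str
    version: str = __version__
    config_hash: str = ""
    inputs: dict = dc_field(default_factory=dict)
    stages: list = dc_field(default_factory=list)
    seeds: dict = dc_field(default_factory=dict)
    outputs: dict = dc_field(default_factory=dict)

    def stage(self, name: str, rows_in: int, rows_out: int, t0: float, note: str = "") -> None:
        dropped = rows_in - rows_out
        if dropped:
            logger.info("stage %s dropped %d rows (%s)", name, dropped, note or "see note")
        self.stages.append(
            {
                "name": name,
                "rows_in": int(rows_in),
                "rows_out": int(rows_out),
                "rows_dropped": int(dropped),
                "note": note,
                "seconds": round(time.perf_counter() - t0, 4),
            }
        )

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)


def _hash_config(*objs) -> str:
    return hashlib.sha256(repr(objs).encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, manifest: RunManifest) -> None:
    df.to_csv(path, index=False)
    manifest.outputs[path.name] = _sha256(path)


def camera_nights(deployments: pd.DataFrame, lunar: LunarConfig = LunarConfig()) -> pd.DataFrame:
    """Expand deployments into one row per camera operating night with its
    moon class (site_id, date, moon_class)."""
    lo = deployments["start_date"].min()
    hi = deployments["end_date"].max()
    calendar = classify_range(lo, hi, lunar).set_index("date")["moon_class"]
    frames = []
    for row in deployments.itertuples(index=False):
        dates = pd.date_range(row.start_date, row.end_date, freq="D")
        frames.append(
            pd.DataFrame(
                {"site_id": row.site_id, "date": dates, "moon_class": calendar.loc[dates].to_numpy()}
            )
        )
    return pd.concat(frames, ignore_index=True)


def _load_and_prepare(paths: dict, manifest: RunManifest, retention: RetentionConfig):
    """Shared front half: read, group events, retain sites."""
    for key in ("detections", "deployments"):
        if key not in paths:
            raise ValueError(f"missing input path: {key}")
        manifest.inputs[key] = _sha256(Path(paths[key]))

    t0 = time.perf_counter()
    detections = read_detections(paths["detections"])
    manifest.stage("read_detections", len(detections), len(detections), t0)
    if detections.empty:
        raise ValueError("empty detection table: nothing to analyse")
    deployments = read_deployments(paths["deployments"])

    t0 = time.perf_counter()
    events = group_events(detections)
    manifest.stage("group_events", len(detections), len(events), t0, "images aggregated to events")

    t0 = time.perf_counter()
    retained = filter_sites(deployments, events, retention)
    kept_dep = deployments[deployments["site_id"].isin(retained)]
    manifest.stage(
        "filter_sites",
        len(deployments),
        len(kept_dep),
        t0,
        f"cat-free deployments < {retention.threshold_days} days discarded",
    )
    n_ev = len(events)
    events = events[events["site_id"].isin(retained)]
    detections = detections[detections["site_id"].isin(retained)]
    manifest.stage("restrict_events_to_retained", n_ev, len(events), t0)
    return detections, deployments, kept_dep, events


def run_spatial(
    paths: dict,
    outdir: str | Path,
    model_config: ModelConfig = ModelConfig(),
    retention: RetentionConfig = RetentionConfig(),
) -> RunManifest:
    """Spatial analysis: modal coat type per site vs. site environment.

    ``paths`` needs detections, deployments and site covariates; writes
    events, site summaries, the odds-ratio table and a manifest to
    ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(command="run-spatial", config_hash=_hash_config(model_config, retention))
    if "sites" not in paths:
        raise ValueError("missing input path: sites")
    manifest.inputs["sites"] = _sha256(Path(paths["sites"]))
    detections, _, kept_dep, events = _load_and_prepare(paths, manifest, retention)
    covariates = pd.read_csv(paths["sites"], dtype={"site_id": str})

    t0 = time.perf_counter()
    black = black_estimate_from_detections(detections)
    summaries = site_summaries(events, detections, black.images_per_cat)
    manifest.stage("site_summaries", len(events), len(summaries), t0, "events tallied per site")

    t0 = time.perf_counter()
    X, y = build_spatial_model(summaries, covariates, model_config)
    manifest.stage(
        "build_spatial_model", len(summaries), len(y), t0, "sites with excluded modal coat dropped"
    )
    fit = fit_multinomial(X, y, model_config.spatial_reference, ridge=model_config.ridge)
    table = wald_intervals(fit, model_config.ci_level)
    table.insert(0, "model", "spatial")

    _write_csv(events, outdir / "events.csv", manifest)
    _write_csv(summaries, outdir / "site_summaries.csv", manifest)
    _write_csv(table, outdir / "spatial_odds_ratios.csv", manifest)
    black_report = pd.DataFrame(
        [
            {
                "images_identifiable": black.images_identifiable,
                "individuals_identified": black.individuals_identified,
                "black_images": black.black_images,
                "images_per_cat": black.images_per_cat,
                "estimated_black": black.estimated_black,
                "estimated_black_rounded": black.estimated_black_rounded,
            }
        ]
    )
    _write_csv(black_report, outdir / "black_estimate.csv", manifest)
    manifest.seeds = {}
    if not fit.converged:
        manifest.outputs["convergence"] = "FAILED"
    manifest.write(outdir / "manifest.json")
    if not fit.converged:
        raise ConvergenceFailure("spatial multinomial fit did not converge")
    return manifest


def run_temporal(
    paths: dict,
    outdir: str | Path,
    model_config: ModelConfig = ModelConfig(),
    retention: RetentionConfig = RetentionConfig(),
    lunar: LunarConfig = LunarConfig(),
    bootstrap_reps: int = 1000,
    seed: int = 1,
) -> RunManifest:
    """Temporal analysis: nightly coat-type activity vs. moon and weather.

    ``paths`` needs detections, deployments and weather; writes the night
    table, odds ratios, the stratified PDE report and a manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        command="run-temporal", config_hash=_hash_config(model_config, retention, lunar)
    )
    if "weather" not in paths:
        raise ValueError("missing input path: weather")
    manifest.inputs["weather"] = _sha256(Path(paths["weather"]))
    detections, _, kept_dep, events = _load_and_prepare(paths, manifest, retention)
    weather = pd.read_csv(paths["weather"])

    t0 = time.perf_counter()
    daily = daily_records(events, kept_dep)
    manifest.stage("daily_records", len(events), len(daily), t0, "events flagged per camera-date")

    t0 = time.perf_counter()
    nights = camera_nights(kept_dep, lunar)
    modelled = nights[nights["moon_class"] != "excluded"]
    manifest.stage(
        "moon_subset", len(nights), len(modelled), t0, "mid-luminosity nights excluded"
    )
    if modelled.empty:
        raise ValueError("no modelling nights: every night has intermediate moon luminosity")

    t0 = time.perf_counter()
    X, y = build_temporal_model(daily, modelled, weather, model_config)
    manifest.stage("build_temporal_model", len(modelled), len(y), t0)
    fit = fit_multinomial(X, y, "absence", ridge=model_config.ridge)
    table = wald_intervals(fit, model_config.ci_level)
    table.insert(0, "model", "temporal")

    night_counts = site_night_table(modelled, daily)
    pde_rows = []
    for stratum in ("full", "new", "all"):
        res = bootstrap_pde(night_counts, stratum, B=bootstrap_reps, seed=seed)
        pde_rows.append(res.__dict__)
    pde_report = pd.DataFrame(pde_rows)

    _write_csv(modelled, outdir / "camera_nights.csv", manifest)
    _write_csv(table, outdir / "temporal_odds_ratios.csv", manifest)
    _write_csv(pde_report, outdir / "pde_report.csv", manifest)
    manifest.seeds = {"bootstrap": seed}
    if not fit.converged:
        manifest.outputs["convergence"] = "FAILED"
    manifest.write(outdir / "manifest.json")
    if not fit.converged:
        raise ConvergenceFailure("temporal multinomial fit did not converge")
    return manifest


class ConvergenceFailure(RuntimeError):
    """A model fit failed to converge; outputs are written but flagged."""
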