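"""Synthetic camera-trap surveys with known ground truth.

Generates everything the analysis pipeline consumes — site covariates, coat
assignments, nightly detections with image bursts and individual identities,
deployments and weather — from a seeded configuration, so every pipeline
stage can be verified against a known truth without the original survey.

The generative model mirrors the analysis models read forwards:

* site coat-category probabilities are softmax(B* . x) over z-scored site
  covariates, with solid black the reference category and intercepts
  calibrated to the surveyed category prevalences (solid black ~40%,
  mackerel brown ~31%, blotched brown ~15%, orange ~4.4%, tortoiseshell
  ~2.9%);
* each resident individual triggers a capture on a given night with a small
  Bernoulli rate whose new-moon value is ``moon_multiplier`` times its
  full-moon value (intermediate nights interpolate geometrically);
* captures expand into image bursts spaced well under the one-minute event
  gap; individual IDs are dropped at a configured rate, and solid black cats
  are never individually identifiable;
* a small fraction of images is unclassifiable (unknown coat) and rare
  mostly-white (tuxedo) cats occur, exercising the exclusion paths.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .moon import LunarConfig, classify_range
from .taxonomy import MODEL_CATEGORIES, ModelCategory

CATEGORY_ORDER = tuple(c.value for c in MODEL_CATEGORIES)
NONREF_CATEGORIES = CATEGORY_ORDER[1:]  # solid_black is the softmax reference
SITE_COVARIATES = ("elevation", "roughness", "isothermality", "fpar", "dtnt")
VEG_CLASSES = ("grassland", "woodland", "forest")

#: design columns of the site coat-assignment softmax
COAT_FIELD_COLUMNS = (
    ("intercept",) + SITE_COVARIATES + tuple(f"vegetation[{v}]" for v in VEG_CLASSES[1:])
)

#: raw pattern choices per modelling category, weighted by surveyed frequency
_PATTERNS = {
    "solid_black": ((("solid", "black"),), (1.0,)),
    "blotched_brown": ((("blotched", "brown"),), (1.0,)),
    "mackerel_brown": (
        (("broken", "brown"), ("spotted", "brown"), ("striped", "brown"), ("ticked", "brown")),
        (0.576, 0.388, 0.030, 0.006),
    ),
    "orange": (
        (("blotched", "orange"), ("broken", "orange"), ("spotted", "orange"),
         ("striped", "orange"), ("ticked", "orange")),
        (0.281, 0.432, 0.272, 0.007, 0.008),
    ),
    "tortoiseshell": ((("tortoiseshell", "mixed"),), (1.0,)),
}


def default_coat_coefficients() -> pd.DataFrame:
    """Ground-truth softmax coefficients B* (non-reference rows).

    Intercepts are calibrated so the *marginal* category mix over the default
    covariate distribution matches the surveyed image shares (solid black
    43%, mackerel brown 33%, blotched brown 16%, orange 4.7%, tortoiseshell
    3.1% after normalising over the five categories) — the raw log prevalence
    ratios would undershoot the minority categories because the non-zero
    slopes lift them on average. A handful of environmental slopes (on
    z-scored covariates) give the recovery tests signal.
    """
    B = pd.DataFrame(0.0, index=list(NONREF_CATEGORIES), columns=list(COAT_FIELD_COLUMNS))
    B.loc["mackerel_brown", "intercept"] = -0.5386
    B.loc["blotched_brown", "intercept"] = -1.0244
    B.loc["orange", "intercept"] = -2.3406
    B.loc["tortoiseshell", "intercept"] = -2.8769
    B.loc["orange", "elevation"] = 0.5
    B.loc["tortoiseshell", "elevation"] = 0.7
    B.loc["blotched_brown", "elevation"] = -0.3
    B.loc["mackerel_brown", "fpar"] = 0.3
    B.loc["mackerel_brown", "vegetation[forest]"] = 0.6
    return B


@dataclass(frozen=True)
class SimConfig:
    """Study-scale defaults: 651 sites, one full year of nights."""

    n_sites: int = 651
    start_date: str = "2019-01-01"
    n_nights: int = 365
    seed: int = 0

    # site covariate ranges (Tasmanian scales)
    elevation_range: tuple[float, float] = (0.0, 1500.0)  # m
    roughness_range: tuple[float, float] = (0.0, 100.0)  # index
    isothermality_mean_sd: tuple[float, float] = (50.0, 5.0)  # %
    fpar_range: tuple[float, float] = (0.1, 0.95)
    dtnt_scale_km: float = 15.0
    veg_probs: tuple[float, float, float] = (0.25, 0.35, 0.40)

    #: ground-truth coat-field coefficients; None -> default_coat_coefficients()
    coat_coefficients: pd.DataFrame | None = field(default=None, compare=False)
    #: draw the site's dominant category from the softmax (else arg-max)
    draw_dominant: bool = True

    # detection process
    base_rate: float = 0.015  # per-individual nightly capture prob, full moon
    moon_multipliers: dict = field(
        default_factory=lambda: {
            "solid_black": 1.4,
            "mackerel_brown": 1.5,
            "blotched_brown": 1.3,
            "orange": 1.0,
            "tortoiseshell": 2.0,
        }
    )
    mean_dominant_individuals: float = 2.0
    mean_minority_individuals: float = 1.0
    minority_presence_prob: float = 0.3
    intruder_rate_frac: float = 0.08  # minority categories capture at this fraction of base
    images_per_event_mean: float = 3.0
    image_spacing_seconds: float = 10.0
    unknown_id_prob: float = 0.3
    black_always_unmarked: bool = True
    white_prob: float = 0.02  # per-individual white-patch trait
    unknown_coat_prob: float = 0.055  # per-image quality failure
    tuxedo_night_rate: float = 0.0002

    # weather (independent of moon class by default; the correlation knob
    # exists for stress tests only)
    rain_prob: float = 0.45
    rain_scale_mm: float = 4.0
    solar_mean_sd: tuple[float, float] = (15.0, 5.0)  # MJ/m^2
    tmin_mean_sd: tuple[float, float] = (8.0, 4.0)  # degC
    weather_moon_corr: float = 0.0

    # deployments: fraction of cameras failing early, and how long they last
    short_fraction: float = 0.0
    short_days_range: tuple[int, int] = (20, 82)

    lunar: LunarConfig = field(default_factory=LunarConfig)

    def __post_init__(self) -> None:
        for name in ("base_rate", "unknown_id_prob", "minority_presence_prob",
                     "unknown_coat_prob", "white_prob", "rain_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if any(m <= 0 for m in self.moon_multipliers.values()):
            raise ValueError("moon multipliers must be positive")

    def coefficients(self) -> pd.DataFrame:
        return (
            self.coat_coefficients
            if self.coat_coefficients is not None
            else default_coat_coefficients()
        )


def gen_sites(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Site covariate table; reproducible from the seed."""
    rng = rng or np.random.default_rng(config.seed)
    n = config.n_sites
    lo, hi = config.elevation_range
    rlo, rhi = config.roughness_range
    im, isd = config.isothermality_mean_sd
    flo, fhi = config.fpar_range
    df = pd.DataFrame(
        {
            "site_id": [f"S{i:04d}" for i in range(n)],
            "elevation": rng.uniform(lo, hi, n),
            "roughness": rng.uniform(rlo, rhi, n),
            "isothermality": rng.normal(im, isd, n),
            "fpar": rng.uniform(flo, fhi, n),
            "dtnt": np.clip(rng.exponential(config.dtnt_scale_km, n), 0.5, 120.0),
            "vegetation": rng.choice(VEG_CLASSES, size=n, p=config.veg_probs),
        }
    )
    return df


def _coat_design(sites: pd.DataFrame) -> np.ndarray:
    """Internal z-scored design for the coat-assignment softmax."""
    cols = [np.ones(len(sites))]
    for name in SITE_COVARIATES:
        v = sites[name].to_numpy(dtype=float)
        sd = v.std() or 1.0
        cols.append((v - v.mean()) / sd)
    for veg in VEG_CLASSES[1:]:
        cols.append((sites["vegetation"] == veg).to_numpy(dtype=float))
    return np.column_stack(cols)


def gen_coat_field(
    sites: pd.DataFrame,
    coefficients: pd.DataFrame | None = None,
    seed: int | np.random.Generator = 0,
    draw: bool = True,
) -> pd.DataFrame:
    """Per-site category probabilities and the dominant category.

    Probabilities are softmax(B* . x) with solid black the (zero-row)
    reference; the dominant category is drawn from them (or arg-maxed when
    ``draw`` is False).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    B = coefficients if coefficients is not None else default_coat_coefficients()
    X = _coat_design(sites)
    if B.shape != (len(NONREF_CATEGORIES), X.shape[1]):
        raise ValueError(
            f"coefficient matrix must be {(len(NONREF_CATEGORIES), X.shape[1])}, got {B.shape}"
        )
    eta = X @ B.to_numpy().T
    full = np.concatenate([np.zeros((len(eta), 1)), eta], axis=1)
    full -= full.max(axis=1, keepdims=True)
    probs = np.exp(full)
    probs /= probs.sum(axis=1, keepdims=True)

    if draw:
        cum = probs.cumsum(axis=1)
        u = rng.random(len(sites))
        idx = (u[:, None] > cum).sum(axis=1)
    else:
        idx = probs.argmax(axis=1)
    out = pd.DataFrame(probs, columns=[f"p_{c}" for c in CATEGORY_ORDER])
    out.insert(0, "site_id", sites["site_id"].to_numpy())
    out["dominant_category"] = [CATEGORY_ORDER[i] for i in idx]
    return out


def gen_deployments(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    start = pd.Timestamp(config.start_date)
    end = start + pd.Timedelta(days=config.n_nights - 1)
    ends = np.full(config.n_sites, end)
    if config.short_fraction > 0:
        short = rng.random(config.n_sites) < config.short_fraction
        days = rng.integers(*config.short_days_range, size=config.n_sites)
        ends = np.where(short, start + pd.to_timedelta(days - 1, unit="D"), ends)
    return pd.DataFrame(
        {
            "site_id": [f"S{i:04d}" for i in range(config.n_sites)],
            "start_date": start,
            "end_date": pd.to_datetime(ends),
        }
    )


def gen_weather(config: SimConfig, nights: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """One weather record per date (a single regional station)."""
    n = len(nights)
    sm, ss = config.solar_mean_sd
    tm, ts = config.tmin_mean_sd
    solar = np.clip(rng.normal(sm, ss, n), 0.5, None)
    if config.weather_moon_corr:
        # optional stress-test coupling: brighter-moon nights get clearer skies
        solar = solar + config.weather_moon_corr * ss * (nights["fraction"].to_numpy() - 0.5) * 2
    rain = np.where(rng.random(n) < config.rain_prob, rng.exponential(config.rain_scale_mm, n), 0.0)
    return pd.DataFrame(
        {
            "date": nights["date"].to_numpy(),
            "rainfall": rain,
            "solar_exposure": solar,
            "min_temp": rng.normal(tm, ts, n),
        }
    )


def _moon_factor(moon_class: np.ndarray, multiplier: float) -> np.ndarray:
    factor = np.ones(len(moon_class))
    factor[moon_class == "new"] = multiplier
    factor[moon_class == "excluded"] = np.sqrt(multiplier)
    return factor


@dataclass
class Survey:
    """A complete synthetic survey plus its generating truth."""

    sites: pd.DataFrame
    assignments: pd.DataFrame
    detections: pd.DataFrame
    deployments: pd.DataFrame
    weather: pd.DataFrame
    truth: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.sites.to_csv(outdir / "sites.csv", index=False)
        self.detections.to_csv(outdir / "detections.csv", index=False)
        self.deployments.to_csv(outdir / "deployments.csv", index=False)
        self.weather.to_csv(outdir / "weather.csv", index=False)
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, default=str)


def gen_detections(
    sites: pd.DataFrame,
    assignments: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
    deployments: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Nightly detection and weather tables for assigned sites.

    Returns (detections, weather, truth-extras). Captures only occur inside
    each site's deployment window; image timestamps stay within the evening
    (19:00-23:59) of the capture date so a night and its calendar date
    coincide.
    """
    start = pd.Timestamp(config.start_date)
    end = start + pd.Timedelta(days=config.n_nights - 1)
    night_frame = classify_range(start, end, config.lunar)
    moon_class = night_frame["moon_class"].to_numpy()
    dates = night_frame["date"]
    if deployments is None:
        deployments = gen_deployments(config, rng)
    op_days = dict(zip(deployments["site_id"], (deployments["end_date"] - deployments["start_date"]).dt.days + 1))

    weather = gen_weather(config, night_frame, rng)

    dominant = dict(zip(assignments["site_id"], assignments["dominant_category"]))
    records: list[dict] = []
    individual_counts: dict[str, int] = {c: 0 for c in CATEGORY_ORDER}
    spacing = config.image_spacing_seconds

    def _emit_event(site_id, date_ts, cat, ind_id, white, minute_slot):
        n_images = 1 + rng.poisson(max(config.images_per_event_mean - 1.0, 0.0))
        t0 = date_ts + pd.Timedelta(hours=19) + pd.Timedelta(minutes=int(minute_slot))
        pats, wts = _PATTERNS[cat]
        pat, col = pats[rng.choice(len(pats), p=wts)]
        for j in range(n_images):
            ts = t0 + pd.Timedelta(seconds=j * spacing)
            pattern, colour, wht = pat, col, int(white)
            img_id = ind_id
            if rng.random() < config.unknown_coat_prob:
                pattern, colour, wht, img_id = "unknown", "unknown", 0, ""
            records.append(
                {
                    "site_id": site_id,
                    "timestamp": ts,
                    "pattern": pattern,
                    "colour": colour,
                    "white": wht,
                    "individual_id": img_id,
                }
            )

    for site_id in sites["site_id"]:
        dom = dominant[site_id]
        n_nights_site = min(op_days.get(site_id, config.n_nights), config.n_nights)
        site_moon = moon_class[:n_nights_site]
        site_dates = dates.iloc[:n_nights_site]
        # resident individuals per category
        residents: dict[str, list[tuple[str, bool]]] = {}
        for cat in CATEGORY_ORDER:
            if cat == dom:
                n_ind = 1 + rng.poisson(max(config.mean_dominant_individuals - 1.0, 0.0))
            elif rng.random() < config.minority_presence_prob:
                n_ind = max(1, rng.poisson(config.mean_minority_individuals))
            else:
                n_ind = 0
            residents[cat] = [
                (f"{site_id}_{cat}_{i}", bool(rng.random() < config.white_prob))
                for i in range(n_ind)
            ]
            individual_counts[cat] += n_ind

        for cat, inds in residents.items():
            if not inds:
                continue
            rate = config.base_rate * (1.0 if cat == dom else config.intruder_rate_frac)
            nightly = np.clip(rate * _moon_factor(site_moon, config.moon_multipliers[cat]), 0, 1)
            for ind_id, white in inds:
                hits = np.nonzero(rng.random(n_nights_site) < nightly)[0]
                for night_idx in hits:
                    unmarked = (cat == "solid_black" and config.black_always_unmarked) or (
                        rng.random() < config.unknown_id_prob
                    )
                    _emit_event(
                        site_id,
                        site_dates.iloc[night_idx],
                        cat,
                        "" if unmarked else ind_id,
                        white,
                        rng.integers(0, 295),
                    )
        # rare mostly-white (tuxedo) cats
        tux_hits = np.nonzero(rng.random(n_nights_site) < config.tuxedo_night_rate)[0]
        for night_idx in tux_hits:
            t0 = site_dates.iloc[night_idx] + pd.Timedelta(hours=19, minutes=int(rng.integers(0, 295)))
            records.append(
                {
                    "site_id": site_id,
                    "timestamp": t0,
                    "pattern": "tuxedo",
                    "colour": "black",
                    "white": 1,
                    "individual_id": f"{site_id}_tuxedo_0",
                }
            )

    detections = pd.DataFrame(
        records,
        columns=["site_id", "timestamp", "pattern", "colour", "white", "individual_id"],
    )
    if not detections.empty:
        detections = detections.sort_values(["site_id", "timestamp"]).reset_index(drop=True)
    extras = {"individual_counts": individual_counts}
    return detections, weather, extras


def simulate_survey(config: SimConfig) -> Survey:
    """Generate a full survey (sites, coats, detections, weather, truth)."""
    rng = np.random.default_rng(config.seed)
    sites = gen_sites(config, rng)
    B = config.coefficients()
    assignments = gen_coat_field(sites, B, rng, draw=config.draw_dominant)
    deployments = gen_deployments(config, rng)
    detections, weather, extras = gen_detections(sites, assignments, config, rng, deployments)
    truth = {
        "seed": config.seed,
        "coat_coefficients": {c: B.loc[c].to_dict() for c in B.index},
        "moon_multipliers": dict(config.moon_multipliers),
        "base_rate": config.base_rate,
        "dominant_categories": dict(
            zip(assignments["site_id"], assignments["dominant_category"])
        ),
        "individual_counts": extras["individual_counts"],
        "n_black_individuals": extras["individual_counts"]["solid_black"],
    }
    return Survey(sites, assignments, detections, deployments, weather, truth)


def config_from_yaml(path: str | Path) -> SimConfig:
    """Build a SimConfig from a YAML mapping of field names to values."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    fields = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(raw) - fields
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    for key in ("elevation_range", "roughness_range", "isothermality_mean_sd", "fpar_range",
                "veg_probs", "solar_mean_sd", "tmin_mean_sd", "short_days_range"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return SimConfig(**raw)
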