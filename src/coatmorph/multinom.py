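"""Maximum-likelihood multinomial logistic regression, built from first
principles, with Wald odds-ratio intervals and builders for the two survey
models (spatial: modal coat type vs. site environment; temporal: nightly
coat-type capture vs. moon luminosity and weather).

Model: for observation i with covariate row x_i and outcome category y_i in
{1..K}, the non-reference categories k carry coefficient rows b_k and

    P(y_i = k) = exp(b_k . x_i) / (1 + sum_l exp(b_l . x_i)),

with the reference category's row fixed at zero. The log-likelihood is
maximised by Newton-Raphson with step halving; the coefficient covariance is
the inverse observed information at the optimum. An optional ridge penalty
(-ridge/2 * ||B||^2 added to the log-likelihood) stabilises separated or
degenerate fits — never silently: its use is recorded on the fit and a
warning is emitted when divergence is detected.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.stats import norm

from .taxonomy import ModelCategory

logger = logging.getLogger(__name__)

#: coefficient magnitude (log-odds) beyond which a fit is treated as diverging
_DIVERGENCE_NORM = 40.0


class ConvergenceError(RuntimeError):
    """Raised only for unusable inputs; non-convergence itself is flagged."""


class RankError(ValueError):
    """Design matrix is rank deficient; names the offending columns."""


@dataclass(frozen=True)
class DesignMatrix:
    """A dense model matrix with column metadata.

    ``kinds`` labels each column as intercept / continuous / dummy /
    interaction; ``standardization`` records (mean, sd) per z-scored
    continuous column so odds ratios can be mapped back to raw units.
    """

    X: np.ndarray
    names: tuple[str, ...]
    kinds: tuple[str, ...]
    encoding: dict = field(default_factory=dict)
    standardization: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.X.ndim != 2 or self.X.shape[1] != len(self.names):
            raise ValueError("X shape inconsistent with column names")
        if self.names and self.kinds[0] != "intercept":
            raise ValueError("intercept must be the first column")
        check_rank(self.X, self.names)


def check_rank(X: np.ndarray, names) -> None:
    """Verify full column rank; report near-collinear columns by name.

    With fewer rows than columns full column rank is impossible whatever the
    data, so that case warns rather than raises (the eventual fit is what
    cannot proceed, not the matrix construction).
    """
    if X.shape[0] == 0:
        raise ValueError("empty design matrix")
    if X.shape[0] < X.shape[1]:
        warnings.warn(
            f"design matrix has fewer rows ({X.shape[0]}) than columns ({X.shape[1]}); "
            "coefficients will not be identifiable",
            stacklevel=2,
        )
        return
    _, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        bad = [names[j] for j in piv[rank:]]
        raise RankError(f"design matrix is rank deficient; collinear or constant columns: {bad}")


@dataclass
class MultinomFit:
    """Fitted multinomial logit.

    ``coef`` holds one row per non-reference category (in ``categories``
    order, reference omitted), on the log-odds scale; ``cov`` is the
    covariance of ``coef.ravel()`` from the inverse observed information.
    """

    reference: str
    categories: tuple[str, ...]  # reference first, then modelled categories
    names: tuple[str, ...]
    coef: np.ndarray  # (K-1, P)
    cov: np.ndarray  # ((K-1)P, (K-1)P)
    loglik: float
    iterations: int
    converged: bool
    ridge: float = 0.0
    n_obs: int = 0

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None)).reshape(self.coef.shape)

    def coef_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.coef, index=list(self.categories[1:]), columns=list(self.names))


def _probabilities(B: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Category probabilities (n, K) with the reference in column 0."""
    eta = X @ B.T  # (n, K-1)
    full = np.concatenate([np.zeros((eta.shape[0], 1)), eta], axis=1)
    full -= full.max(axis=1, keepdims=True)
    np.exp(full, out=full)
    full /= full.sum(axis=1, keepdims=True)
    return full


def _loglik(B: np.ndarray, X: np.ndarray, Y: np.ndarray, ridge: float) -> float:
    p = _probabilities(B, X)
    obs = p[np.arange(len(Y)), Y]
    return float(np.log(np.clip(obs, 1e-300, None)).sum() - 0.5 * ridge * (B**2).sum())


def _score_hessian(B, X, Y_onehot, ridge):
    """Penalised score vector and negative Hessian (observed information)."""
    n, P = X.shape
    Km1 = B.shape[0]
    p = _probabilities(B, X)[:, 1:]  # (n, K-1)
    score = ((Y_onehot - p).T @ X).ravel() - ridge * B.ravel()
    info = np.empty((Km1 * P, Km1 * P))
    for k in range(Km1):
        for l in range(k, Km1):
            w = p[:, k] * ((1.0 if k == l else 0.0) - p[:, l])
            block = -(X * w[:, None]).T @ X  # Hessian block, negative definite
            info[k * P:(k + 1) * P, l * P:(l + 1) * P] = -block
            if l != k:
                info[l * P:(l + 1) * P, k * P:(k + 1) * P] = -block.T
    info[np.diag_indices_from(info)] += ridge
    return score, info


def fit_multinomial(
    X,
    y,
    reference: str,
    tol: float = 1e-8,
    max_iter: int = 200,
    ridge: float = 0.0,
    categories: tuple[str, ...] | None = None,
) -> MultinomFit:
    """Fit the multinomial logit by Newton-Raphson.

    Parameters
    ----------
    X
        A :class:`DesignMatrix` or a plain (n, P) array (columns then named
        x0..x{P-1}); the first column should be the intercept.
    y
        Outcome labels, length n.
    reference
        Category whose coefficient row is fixed at zero.
    tol
        Convergence when the maximum absolute score component falls below
        ``tol * max(1, n)``.
    ridge
        Optional L2 penalty; 0 gives the plain MLE.
    categories
        Explicit category set (reference may then be unobserved-robust);
        defaults to the sorted levels observed in y.
    """
    if isinstance(X, DesignMatrix):
        names = X.names
        Xmat = np.asarray(X.X, dtype=float)
    else:
        Xmat = np.asarray(X, dtype=float)
        names = tuple(f"x{j}" for j in range(Xmat.shape[1]))
        check_rank(Xmat, names)
    y = np.asarray([str(v) for v in np.asarray(y)])
    n, P = Xmat.shape
    if len(y) != n:
        raise ValueError("X and y length mismatch")

    if categories is None:
        categories = tuple(sorted(set(y)))
    if reference not in categories:
        raise ValueError(f"reference {reference!r} not among categories {categories}")
    if len(categories) < 2:
        raise ValueError("y must take at least two levels")
    ordered = (reference,) + tuple(c for c in categories if c != reference)
    unseen = sorted(set(ordered[1:]) - set(y))
    mle_exists = True
    if unseen and ridge == 0.0:
        # zero-count categories push their intercepts to -inf; the gradient
        # flattens out numerically but no finite maximiser exists
        warnings.warn(
            f"categories never observed in y: {unseen}; coefficients diverge and "
            "the MLE does not exist — consider a small ridge penalty",
            stacklevel=2,
        )
        mle_exists = False
    Km1 = len(ordered) - 1
    if n <= P * Km1:
        warnings.warn(
            f"n={n} observations for {P * Km1} parameters; estimates may be unstable",
            stacklevel=2,
        )

    index = {c: i for i, c in enumerate(ordered)}
    Y = np.array([index[v] for v in y])
    Y_onehot = np.zeros((n, Km1))
    seen = Y > 0
    Y_onehot[np.nonzero(seen)[0], Y[seen] - 1] = 1.0

    B = np.zeros((Km1, P))
    ll = _loglik(B, Xmat, Y, ridge)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        score, info = _score_hessian(B, Xmat, Y_onehot, ridge)
        if np.max(np.abs(score)) < tol * max(1.0, n):
            converged = mle_exists
            break
        try:
            step = scipy.linalg.solve(info, score, assume_a="sym")
        except scipy.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        # step halving keeps the penalised log-likelihood monotone
        scale = 1.0
        for _ in range(40):
            cand = B + scale * step.reshape(Km1, P)
            ll_cand = _loglik(cand, Xmat, Y, ridge)
            if ll_cand >= ll - 1e-12:
                break
            scale *= 0.5
        B = B + scale * step.reshape(Km1, P)
        ll = _loglik(B, Xmat, Y, ridge)
        if np.max(np.abs(B)) > _DIVERGENCE_NORM:
            warnings.warn(
                "coefficient norm diverging (separation or unobserved category); "
                "fit flagged non-converged — consider a small ridge penalty",
                stacklevel=2,
            )
            break

    if it == max_iter and not converged:
        warnings.warn("multinomial fit did not converge within max_iter", stacklevel=2)

    _, info = _score_hessian(B, Xmat, Y_onehot, ridge)
    try:
        cov = scipy.linalg.inv(info)
    except scipy.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    cov = (cov + cov.T) / 2.0
    return MultinomFit(
        reference=reference,
        categories=ordered,
        names=names,
        coef=B,
        cov=cov,
        loglik=_loglik(B, Xmat, Y, 0.0),
        iterations=it,
        converged=converged,
        ridge=ridge,
        n_obs=n,
    )


def predict_proba(fit: MultinomFit, X) -> np.ndarray:
    """Fitted category probabilities (n, K), columns in ``fit.categories``
    order (reference first); rows sum to one."""
    Xmat = X.X if isinstance(X, DesignMatrix) else np.asarray(X, dtype=float)
    return _probabilities(fit.coef, Xmat)


def score_vector(fit: MultinomFit, X, y) -> np.ndarray:
    """Score (gradient of the unpenalised log-likelihood) at the fit."""
    Xmat = X.X if isinstance(X, DesignMatrix) else np.asarray(X, dtype=float)
    y = np.asarray([str(v) for v in np.asarray(y)])
    index = {c: i for i, c in enumerate(fit.categories)}
    Y = np.array([index[v] for v in y])
    Y_onehot = np.zeros((len(y), len(fit.categories) - 1))
    seen = Y > 0
    Y_onehot[np.nonzero(seen)[0], Y[seen] - 1] = 1.0
    score, _ = _score_hessian(fit.coef, Xmat, Y_onehot, 0.0)
    return score


def wald_intervals(fit: MultinomFit, level: float = 0.975) -> pd.DataFrame:
    """Odds ratios with two-sided Wald confidence intervals.

    For coefficient b with standard error s the interval is
    exp(b +/- z * s) with z the two-sided ``level`` quantile (level 0.975
    gives z ~ 2.2414). ``significant`` flags intervals excluding 1.
    """
    if not 0.5 < level < 1.0:
        raise ValueError("confidence level must lie in (0.5, 1)")
    z = norm.ppf(0.5 + level / 2.0)
    se = fit.se
    rows = []
    for i, cat in enumerate(fit.categories[1:]):
        for j, name in enumerate(fit.names):
            b, s = fit.coef[i, j], se[i, j]
            with np.errstate(over="ignore"):  # huge SE -> infinite upper bound
                lower, upper = np.exp(b - z * s), np.exp(b + z * s)
            rows.append(
                {
                    "category": cat,
                    "predictor": name,
                    "estimate": b,
                    "se": s,
                    "odds_ratio": np.exp(b),
                    "lower": lower,
                    "upper": upper,
                    "significant": bool(lower > 1.0 or upper < 1.0),
                    "level": level,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Model builders


SPATIAL_COVARIATES = ("elevation", "roughness", "isothermality", "fpar", "dtnt")
WEATHER_COVARIATES = ("rainfall", "solar_exposure", "min_temp")
ABSENCE = "absence"


@dataclass(frozen=True)
class ModelConfig:
    """Shared modelling options for the spatial and temporal models."""

    standardize: bool = True
    ci_level: float = 0.975
    spatial_reference: str = ModelCategory.SOLID_BLACK.value
    veg_classes: tuple[str, ...] = ("grassland", "woodland", "forest")
    veg_reference: str = "grassland"
    moon_new_is_one: bool = True  # positive moon coefficient = more active on new moons
    ridge: float = 0.0

    @classmethod
    def from_mapping(cls, mapping: dict) -> "ModelConfig":
        known = {k: v for k, v in mapping.items() if k in cls.__dataclass_fields__}
        if "veg_classes" in known:
            known["veg_classes"] = tuple(known["veg_classes"])
        return cls(**known)


def _standardize(col: np.ndarray, name: str, record: dict, enabled: bool) -> np.ndarray:
    if not enabled:
        return col
    mean, sd = float(np.mean(col)), float(np.std(col, ddof=0))
    if sd == 0:
        raise RankError(f"design matrix is rank deficient; collinear or constant columns: ['{name}']")
    record[name] = (mean, sd)
    return (col - mean) / sd


def build_spatial_model(
    summaries: pd.DataFrame,
    covariates: pd.DataFrame,
    config: ModelConfig = ModelConfig(),
) -> tuple[DesignMatrix, np.ndarray]:
    """Design matrix and response for the spatial model.

    Response: the site's modal coat category (reference solid black).
    Predictors: intercept, five continuous site covariates (z-scored by
    default) and dummy-coded vegetation class.
    """
    needed = list(SPATIAL_COVARIATES) + ["vegetation"]
    missing_cols = [c for c in needed if c not in covariates.columns]
    if missing_cols:
        raise ValueError(f"site covariate table missing columns: {missing_cols}")

    df = summaries.merge(covariates, on="site_id", how="left", validate="one_to_one")
    dropped = int((df["modal_category"] == ModelCategory.EXCLUDED.value).sum())
    if dropped:
        logger.info("dropping %d sites with excluded modal category", dropped)
        df = df[df["modal_category"] != ModelCategory.EXCLUDED.value]
    incomplete = df[df[needed].isna().any(axis=1)]
    if len(incomplete):
        raise ValueError(
            f"sites with missing covariates: {sorted(incomplete['site_id'])[:10]}"
            + ("..." if len(incomplete) > 10 else "")
        )

    std: dict = {}
    cols = [np.ones(len(df))]
    names, kinds = ["intercept"], ["intercept"]
    for name in SPATIAL_COVARIATES:
        cols.append(_standardize(df[name].to_numpy(dtype=float), name, std, config.standardize))
        names.append(name)
        kinds.append("continuous")
    veg = df["vegetation"].astype(str)
    unknown_veg = sorted(set(veg) - set(config.veg_classes))
    if unknown_veg:
        raise ValueError(f"unrecognised vegetation classes: {unknown_veg}")
    encoding = {"vegetation": {"reference": config.veg_reference, "classes": config.veg_classes}}
    for cls_ in config.veg_classes:
        if cls_ == config.veg_reference:
            continue
        cols.append((veg == cls_).to_numpy(dtype=float))
        names.append(f"vegetation[{cls_}]")
        kinds.append("dummy")
    X = DesignMatrix(
        np.column_stack(cols), tuple(names), tuple(kinds), encoding=encoding, standardization=std
    )
    y = df["modal_category"].to_numpy(dtype=object)
    return X, y


def build_temporal_model(
    daily: pd.DataFrame,
    nights: pd.DataFrame,
    weather: pd.DataFrame,
    config: ModelConfig = ModelConfig(),
) -> tuple[DesignMatrix, np.ndarray]:
    """Design matrix and response for the temporal (nightly activity) model.

    ``nights`` lists the modelling camera-nights (site_id, date, moon_class),
    already restricted to full/new moon; a leftover 'excluded' class is an
    error. Each observed (site, night, category) contributes one row; each
    cat-free camera-night contributes one 'absence' row, the reference level.
    Predictors: intercept, rainfall, solar exposure, minimum temperature,
    moon dummy (new = 1 by default) and the moon x solar interaction.
    """
    if (nights["moon_class"] == "excluded").any():
        raise ValueError("nights classified 'excluded' must be filtered out before modelling")
    if nights.empty:
        raise ValueError("no modelling nights")

    nights = nights.copy()
    nights["date"] = pd.to_datetime(nights["date"]).dt.normalize()
    obs = daily.copy()
    obs["date"] = pd.to_datetime(obs["date"]).dt.normalize()
    n_excl = int((obs["category"] == ModelCategory.EXCLUDED.value).sum())
    if n_excl:
        logger.info("dropping %d daily records with excluded coat category", n_excl)
        obs = obs[obs["category"] != ModelCategory.EXCLUDED.value]
    obs = obs.merge(nights, on=["site_id", "date"], how="inner")

    taken = set(map(tuple, obs[["site_id", "date"]].itertuples(index=False)))
    mask = [
        (s, d) not in taken for s, d in nights[["site_id", "date"]].itertuples(index=False)
    ]
    absences = nights[mask].copy()
    absences["category"] = ABSENCE
    rows = pd.concat([obs, absences], ignore_index=True)

    weather = weather.copy()
    weather["date"] = pd.to_datetime(weather["date"]).dt.normalize()
    on = ["site_id", "date"] if "site_id" in weather.columns else ["date"]
    rows = rows.merge(weather, on=on, how="left", validate="many_to_one")
    nmiss = int(rows[list(WEATHER_COVARIATES)].isna().any(axis=1).sum())
    if nmiss:
        raise ValueError(f"{nmiss} modelling rows lack weather covariates")

    std: dict = {}
    cols = [np.ones(len(rows))]
    names, kinds = ["intercept"], ["intercept"]
    for name in WEATHER_COVARIATES:
        cols.append(_standardize(rows[name].to_numpy(dtype=float), name, std, config.standardize))
        names.append(name)
        kinds.append("continuous")
    new_is_one = config.moon_new_is_one
    moon = (rows["moon_class"] == ("new" if new_is_one else "full")).to_numpy(dtype=float)
    cols.append(moon)
    names.append("moon[new]" if new_is_one else "moon[full]")
    kinds.append("dummy")
    solar = cols[names.index("solar_exposure")]
    cols.append(moon * solar)
    names.append(f"{names[-1]}:solar_exposure")
    kinds.append("interaction")
    X = DesignMatrix(
        np.column_stack(cols),
        tuple(names),
        tuple(kinds),
        encoding={"moon": {"new_is_one": new_is_one}},
        standardization=std,
    )
    y = rows["category"].to_numpy(dtype=object)
    return X, y
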