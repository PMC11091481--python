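"""Approximate Bayesian computation over reference tables of simulations.

The workflow is the classical rejection + regression-adjustment scheme:
draw parameters from their priors, simulate summary statistics, keep the
fraction ``tolerance`` of simulations closest to the observation (Euclidean
distance on MAD-scaled statistics, Epanechnikov kernel weights), then sharpen
the accepted sample by local ridge regression of each parameter on the
statistics with a multiplicative heteroscedasticity correction.  Model choice
uses weighted multinomial logistic regression of the model label on the
statistics of the pooled accepted set.  Cross-validation, confusion matrices
and a distance-based goodness-of-fit test provide the standard diagnostics.

Priors: the selection coefficient uses a shifted Gamma, ``Gamma(shape 3,
rate 3) - 1`` (support (-1, inf), mean 0); dominance ``h`` and the mating
penalty ``lam`` are Uniform(0, 1); the fitness-noise SD ``g`` is
Uniform(0, 0.5).
"""
from __future__ import annotations

import dataclasses
import math
import warnings
from pathlib import Path
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit
from sklearn.linear_model import LogisticRegression

from ._util import spawn_rng, weighted_quantile
from .demography import DemographySchedule
from .errors import ExtinctionError
from .simulate import FitnessModel, InitSpec, simulate_experiment

# ---------------------------------------------------------------------------
# Priors and model variants

#: Gamma shape/rate of the shifted selection-coefficient prior
S_PRIOR_SHAPE = 3.0
S_PRIOR_RATE = 3.0
G_PRIOR_HIGH = 0.5


@dataclasses.dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the parameter priors (defaults are the study's)."""

    s_shape: float = S_PRIOR_SHAPE
    s_rate: float = S_PRIOR_RATE
    s_shift: float = -1.0
    h_low: float = 0.0
    h_high: float = 1.0
    g_low: float = 0.0
    g_high: float = G_PRIOR_HIGH
    lam_low: float = 0.0
    lam_high: float = 1.0

    def draw_s(self, rng: np.random.Generator, size=None):
        return rng.gamma(self.s_shape, 1.0 / self.s_rate, size) + self.s_shift

    def draw_h(self, rng: np.random.Generator, size=None):
        return rng.uniform(self.h_low, self.h_high, size)

    def draw_g(self, rng: np.random.Generator, size=None):
        return rng.uniform(self.g_low, self.g_high, size)

    def draw_lam(self, rng: np.random.Generator, size=None):
        return rng.uniform(self.lam_low, self.lam_high, size)


@dataclasses.dataclass(frozen=True)
class ModelVariant:
    """Which fitness parameters are free, fixed, or integrated over.

    ``estimated`` lists the parameter names reported and regression-adjusted;
    ``integrated`` lists nuisance parameters sampled from their prior but not
    reported (e.g. ``g`` during model comparison, or ``lam`` in the
    two-parameter non-random-mating model).  ``fixed`` pins parameters to
    constants (the neutral model fixes ``s = h = 0``; the point-estimate
    selection model used for confusion matrices fixes ``s``).
    """

    name: str
    kind: str  # FitnessModel variant: neutral | males_only | sex_averaged | sex_specific
    estimated: tuple[str, ...]
    integrated: tuple[str, ...] = ()
    fixed: Mapping[str, float] = dataclasses.field(default_factory=dict)

    @property
    def sampled(self) -> tuple[str, ...]:
        return self.estimated + self.integrated


def variant(name: str, **fixed: float) -> ModelVariant:
    """Construct one of the named model variants of the experiment grid."""
    table: dict[str, tuple[str, tuple[str, ...], tuple[str, ...]]] = {
        "neutral": ("neutral", (), ()),
        "males_only": ("males_only", ("s", "h"), ()),
        "sex_averaged": ("sex_averaged", ("s", "h"), ()),
        "sex_specific": (
            "sex_specific",
            ("s_female", "s_male", "h_female", "h_male"),
            (),
        ),
        "males_only_g": ("males_only", ("s", "h"), ("g",)),
        "males_only_lambda": ("males_only", ("s", "h"), ("lam",)),
        "males_only_lambda3": ("males_only", ("s", "h", "lam"), ()),
        "males_only_lambda_g": ("males_only", ("s", "h"), ("lam", "g")),
    }
    if name not in table:
        raise ValueError(f"unknown model variant {name!r}")
    kind, est, integ = table[name]
    est = tuple(p for p in est if p not in fixed)
    return ModelVariant(name, kind, est, integ, dict(fixed))


def sample_prior(
    spec: PriorSpec, model_variant: ModelVariant, rng: np.random.Generator
) -> dict[str, float]:
    """One joint prior draw of the variant's sampled parameters."""
    draw: dict[str, float] = {}
    for p in model_variant.sampled:
        if p.startswith("s"):
            draw[p] = float(spec.draw_s(rng))
        elif p.startswith("h"):
            draw[p] = float(spec.draw_h(rng))
        elif p == "g":
            draw[p] = float(spec.draw_g(rng))
        elif p == "lam":
            draw[p] = float(spec.draw_lam(rng))
        else:
            raise ValueError(f"no prior for parameter {p!r}")
    return draw


def draw_to_model(model_variant: ModelVariant, draw: Mapping[str, float]) -> FitnessModel:
    """Materialise a FitnessModel from a prior draw plus the variant's fixings."""
    v = {**draw, **model_variant.fixed}
    g = float(v.get("g", 0.0))
    lam = float(v.get("lam", 0.0))
    kind = model_variant.kind
    if kind == "neutral":
        return FitnessModel(g=g, lam=lam, variant="neutral")
    if kind == "males_only":
        return FitnessModel.males_only(v["s"], v["h"], g=g, lam=lam)
    if kind == "sex_averaged":
        return FitnessModel.sex_averaged(v["s"], v["h"], g=g, lam=lam)
    if kind == "sex_specific":
        return FitnessModel.sex_specific(
            v["s_male"], v["h_male"], v["s_female"], v["h_female"], g=g, lam=lam
        )
    raise ValueError(kind)


# ---------------------------------------------------------------------------
# Reference tables


@dataclasses.dataclass
class ReferenceTable:
    """Prior parameter draws paired with their simulated summary statistics."""

    parameters: pd.DataFrame  # N x p, columns named after the parameters
    statistics: np.ndarray  # N x d
    model_label: str | None = None
    n_valid: int = 0
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.parameters) != len(self.statistics):
            raise ValueError("parameters and statistics row counts differ")
        if self.n_valid == 0:
            self.n_valid = len(self.parameters)

    @property
    def n(self) -> int:
        return len(self.parameters)

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        stat_cols = [f"S{i}" for i in range(self.statistics.shape[1])]
        df = pd.concat(
            [
                self.parameters.reset_index(drop=True),
                pd.DataFrame(self.statistics, columns=stat_cols),
            ],
            axis=1,
        )
        df.to_csv(path, index=False)
        sidecar = dict(
            self.meta,
            model_label=self.model_label,
            parameter_columns=list(self.parameters.columns),
            n=self.n,
        )
        path.with_suffix(path.suffix + ".meta.yaml").write_text(
            yaml.safe_dump(sidecar, sort_keys=False)
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "ReferenceTable":
        path = Path(path)
        meta = yaml.safe_load(path.with_suffix(path.suffix + ".meta.yaml").read_text())
        df = pd.read_csv(path)
        p_cols = meta["parameter_columns"]
        s_cols = [c for c in df.columns if c not in p_cols]
        return cls(
            parameters=df[p_cols],
            statistics=df[s_cols].to_numpy(dtype=float),
            model_label=meta.get("model_label"),
            meta={k: v for k, v in meta.items() if k not in {"parameter_columns", "n"}},
        )


def build_reference_table(
    n: int,
    spec: PriorSpec,
    model_variant: ModelVariant,
    schedules: Sequence[DemographySchedule],
    inits: Mapping[str, InitSpec],
    mode: Literal["A", "G"],
    seed: int,
    start_time: int = 0,
    max_retries: int = 20,
) -> ReferenceTable:
    """Simulate ``n`` prior draws of the full experiment.

    Replicates whose simulation goes extinct are re-drawn from a fresh
    sub-stream (bounded retries); the run aborts if more than 1% of
    replicates fail persistently.  Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rows: list[dict[str, float]] = []
    stats: list[np.ndarray] = []
    failures = 0
    for i in range(n):
        ok = False
        for attempt in range(max_retries):
            rng = spawn_rng(seed, i, attempt)
            draw = sample_prior(spec, model_variant, rng)
            model = draw_to_model(model_variant, draw)
            try:
                vec = simulate_experiment(schedules, model, inits, mode, rng, start_time)
            except ExtinctionError:
                continue
            rows.append(draw)
            stats.append(vec)
            ok = True
            break
        if not ok:
            failures += 1
            if failures > max(1, math.ceil(0.01 * n)):
                raise RuntimeError(
                    f"reference table aborted: {failures} replicates failed "
                    f"all {max_retries} extinction retries"
                )
    params = pd.DataFrame(rows, columns=list(model_variant.sampled))
    return ReferenceTable(
        parameters=params,
        statistics=np.asarray(stats),
        model_label=model_variant.name,
        n_valid=len(rows),
        meta=dict(seed=seed, mode=mode, variant=model_variant.name, n_requested=n),
    )


# ---------------------------------------------------------------------------
# Rejection and regression adjustment


@dataclasses.dataclass
class AbcResult:
    """Accepted (and optionally regression-adjusted) posterior sample."""

    accepted_idx: np.ndarray
    weights: np.ndarray  # normalised, same length as accepted_idx
    adjusted_sample: pd.DataFrame
    posterior_mean: pd.Series
    interval95: pd.DataFrame  # index = parameter, columns = lo, hi
    tolerance: float
    adjusted: bool = False
    distances: np.ndarray | None = None
    scale: np.ndarray | None = None
    kept_columns: np.ndarray | None = None


def _mad_scale(statistics: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column median absolute deviation; zero-MAD columns are flagged."""
    med = np.median(statistics, axis=0)
    mad = np.median(np.abs(statistics - med), axis=0)
    keep = mad > 0.0
    return mad, keep


def _epanechnikov(distances: np.ndarray) -> np.ndarray:
    dmax = distances.max()
    if dmax == 0.0:
        return np.full(len(distances), 1.0 / len(distances))
    w = 1.0 - (distances / dmax) ** 2
    total = w.sum()
    if total <= 0.0:
        return np.full(len(distances), 1.0 / len(distances))
    return w / total


def _summaries(sample: pd.DataFrame, weights: np.ndarray) -> tuple[pd.Series, pd.DataFrame]:
    mean = pd.Series(
        {c: float(np.average(sample[c], weights=weights)) for c in sample.columns}
    )
    iv = pd.DataFrame(
        {
            c: weighted_quantile(sample[c].to_numpy(), [0.025, 0.975], weights)
            for c in sample.columns
        },
        index=["lo", "hi"],
    ).T
    return mean, iv


def abc_reject(
    obs: np.ndarray,
    table: ReferenceTable,
    tolerance: float,
    exclude: int | None = None,
) -> AbcResult:
    """Rejection step: keep the ceil(tolerance*N) rows closest to ``obs``.

    Statistics are scaled by their full-table median absolute deviation;
    distance is Euclidean; accepted rows get Epanechnikov kernel weights in
    the distance.  ``exclude`` removes one row from consideration (used by
    the leave-one-out diagnostics).  Distance ties break by row index.
    """
    obs = np.asarray(obs, dtype=float)
    if obs.shape != (table.statistics.shape[1],):
        raise ValueError(
            f"observation has length {obs.shape}, table statistics are "
            f"{table.statistics.shape[1]}-dimensional"
        )
    if not 0.0 < tolerance <= 1.0:
        raise ValueError("tolerance must lie in (0, 1]")
    mad, keep = _mad_scale(table.statistics)
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-MAD statistic column(s)",
            stacklevel=2,
        )
    scaled = table.statistics[:, keep] / mad[keep]
    d = np.sqrt(((scaled - obs[keep] / mad[keep]) ** 2).sum(axis=1))
    n_avail = table.n if exclude is None else table.n - 1
    if exclude is not None:
        d[exclude] = np.inf
    k = math.ceil(tolerance * n_avail)
    order = np.argsort(d, kind="stable")[:k]
    dist = d[order]
    w = _epanechnikov(dist)
    sample = table.parameters.iloc[order].reset_index(drop=True)
    if sample.shape[1]:
        mean, iv = _summaries(sample, w)
    else:
        mean, iv = pd.Series(dtype=float), pd.DataFrame(columns=["lo", "hi"])
    return AbcResult(
        accepted_idx=order,
        weights=w,
        adjusted_sample=sample,
        posterior_mean=mean,
        interval95=iv,
        tolerance=tolerance,
        adjusted=False,
        distances=dist,
        scale=mad,
        kept_columns=keep,
    )


# parameter transforms keeping adjusted draws inside their supports
_EPS = 1e-8


def _transform_pair(name: str) -> tuple[Callable, Callable]:
    if name.startswith("s"):
        return (lambda x: np.log1p(np.maximum(x, -1 + _EPS)),
                lambda t: np.expm1(t))
    if name.startswith("h") or name == "lam":
        return (lambda x: logit(np.clip(x, _EPS, 1 - _EPS)),
                lambda t: expit(t))
    if name == "g":
        return (lambda x: logit(np.clip(x / G_PRIOR_HIGH, _EPS, 1 - _EPS)),
                lambda t: G_PRIOR_HIGH * expit(t))
    return (lambda x: np.asarray(x, dtype=float), lambda t: t)


_RIDGE_GRID = np.logspace(-4, 0, 9)


def _weighted_ridge(Z: np.ndarray, y: np.ndarray, w: np.ndarray,
                    alpha: float | None = None):
    """Weighted ridge of y on Z (columns weighted-centred by caller).

    The penalty is chosen by generalised cross-validation over a fixed log
    grid unless ``alpha`` pins it.  Returns (slopes, fitted values,
    intercept) where the intercept is the weighted mean of y.
    """
    sw = np.sqrt(w)
    ybar = float(np.average(y, weights=w))
    B = sw[:, None] * Z
    yt = sw * (y - ybar)
    U, S, Vt = np.linalg.svd(B, full_matrices=False)
    Uty = U.T @ yt
    n = len(y)
    grid = _RIDGE_GRID if alpha is None else (alpha,)
    best = (np.inf, None)
    for a in grid:
        shrink = S / (S**2 + a)
        b = Vt.T @ (shrink * Uty)
        resid = yt - B @ b
        df = float((S**2 / (S**2 + a)).sum()) + 1.0
        denom = max(1.0 - df / n, 1e-3)
        gcv = float((resid**2).sum() / n) / denom**2
        if gcv < best[0]:
            best = (gcv, b)
    b = best[1]
    fitted = ybar + Z @ b
    return b, fitted, ybar


def ridge_adjust(
    result: AbcResult,
    obs: np.ndarray,
    table: ReferenceTable,
    transform: bool = True,
    alpha: float | None = None,
    heteroscedastic: bool = True,
) -> AbcResult:
    """Local-linear ridge regression adjustment with heteroscedasticity correction.

    Per parameter (on its transformed scale when ``transform``): a weighted
    ridge regression of the parameter on the obs-centred scaled statistics
    gives the conditional mean at the observation; residuals are rescaled by
    the ratio of conditional standard deviations (from a second weighted
    regression of the log squared residuals on the statistics) and re-attached
    to the conditional mean.  Falls back to the rejection-only result when the
    accepted set is too small.
    """
    params = table.parameters
    p = params.shape[1]
    k = len(result.accepted_idx)
    if p == 0:
        return result
    if k < p + 2:
        warnings.warn("too few accepted rows for regression; keeping rejection result",
                      stacklevel=2)
        return result
    keep = result.kept_columns
    mad = result.scale
    obs = np.asarray(obs, dtype=float)
    Xc = (table.statistics[result.accepted_idx][:, keep] - obs[keep]) / mad[keep]
    w = result.weights
    xbar = np.average(Xc, axis=0, weights=w)
    Z = Xc - xbar
    adjusted = {}
    for name in params.columns:
        fwd, inv = _transform_pair(name) if transform else _transform_pair("")
        y = np.asarray(fwd(params[name].to_numpy()[result.accepted_idx]), dtype=float)
        try:
            b, fitted, ybar = _weighted_ridge(Z, y, w, alpha)
            m_obs = ybar - xbar @ b  # conditional mean at x = obs (Xc = 0)
            resid = y - fitted
            if heteroscedastic:
                # regress log e^2 on the same design
                y2 = np.log(resid**2 + 1e-12)
                b2, fitted2, ybar2 = _weighted_ridge(Z, y2, w, alpha)
                sigma_obs = np.exp((ybar2 - xbar @ b2) / 2.0)
                sigma_i = np.maximum(np.exp(fitted2 / 2.0), 1e-8)
                resid = resid * (sigma_obs / sigma_i)
            adjusted[name] = inv(m_obs + resid)
        except np.linalg.LinAlgError:
            warnings.warn(f"singular regression for {name}; keeping rejection draws",
                          stacklevel=2)
            adjusted[name] = params[name].to_numpy()[result.accepted_idx]
    sample = pd.DataFrame(adjusted, columns=params.columns)
    mean, iv = _summaries(sample, w)
    return dataclasses.replace(
        result,
        adjusted_sample=sample,
        posterior_mean=mean,
        interval95=iv,
        adjusted=True,
    )


def abc_fit(
    obs: np.ndarray,
    table: ReferenceTable,
    tolerance: float,
    adjust: bool = True,
    transform: bool = True,
    exclude: int | None = None,
) -> AbcResult:
    """Convenience wrapper: rejection followed by regression adjustment."""
    res = abc_reject(obs, table, tolerance, exclude=exclude)
    if adjust:
        res = ridge_adjust(res, obs, table, transform=transform)
    return res


# ---------------------------------------------------------------------------
# Model choice, cross-validation, confusion, goodness of fit


@dataclasses.dataclass
class ModelChoiceResult:
    posterior_probs: dict[str, float]
    confusion: pd.DataFrame | None = None
    n_pseudo: int = 0


@dataclasses.dataclass
class CvResult:
    prediction_error: dict[str, float]
    n_folds: int
    estimates: pd.DataFrame | None = None
    truths: pd.DataFrame | None = None


def _pool_tables(tables: Mapping[str, ReferenceTable]):
    labels = list(tables)
    stats = np.vstack([tables[m].statistics for m in labels])
    lab = np.concatenate(
        [np.full(tables[m].n, i) for i, m in enumerate(labels)]
    )
    return labels, stats, lab


def model_posterior(
    obs: np.ndarray,
    tables: Mapping[str, ReferenceTable],
    tolerance: float,
    exclude: tuple[str, int] | None = None,
) -> ModelChoiceResult:
    """Posterior model probabilities by weighted multinomial logistic regression.

    Tables are pooled, the rejection step keeps the closest fraction
    ``tolerance`` of the pooled rows, and a logistic regression of the model
    label on the scaled statistics is evaluated at the observation.
    """
    if len(tables) < 2:
        raise ValueError("model choice needs at least two models")
    dims = {t.statistics.shape[1] for t in tables.values()}
    if len(dims) != 1:
        raise ValueError("tables have unequal statistic dimensions")
    labels, stats, lab = _pool_tables(tables)
    obs = np.asarray(obs, dtype=float)
    mad, keep = _mad_scale(stats)
    scaled = stats[:, keep] / mad[keep]
    obs_s = obs[keep] / mad[keep]
    d = np.sqrt(((scaled - obs_s) ** 2).sum(axis=1))
    n_avail = len(d)
    if exclude is not None:
        m_name, row = exclude
        offset = sum(tables[m].n for m in labels[: labels.index(m_name)])
        d[offset + row] = np.inf
        n_avail -= 1
    k = math.ceil(tolerance * n_avail)
    order = np.argsort(d, kind="stable")[:k]
    w = _epanechnikov(d[order])
    y = lab[order]
    present = np.unique(y)
    probs = dict.fromkeys(labels, 0.0)
    if len(present) == 1:
        warnings.warn("only one model in the accepted set", stacklevel=2)
        probs[labels[int(present[0])]] = 1.0
        return ModelChoiceResult(posterior_probs=probs)
    X = scaled[order]
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0.0] = 1.0
    clf = LogisticRegression(C=1e6, max_iter=2000)
    clf.fit((X - mu) / sd, y, sample_weight=w * len(w))
    p = clf.predict_proba(((obs_s - mu) / sd).reshape(1, -1))[0]
    for cls, pi in zip(clf.classes_, p):
        probs[labels[int(cls)]] = float(pi)
    return ModelChoiceResult(posterior_probs=probs)


def cross_validate(
    table: ReferenceTable,
    n_folds: int,
    tolerance: float,
    rng: np.random.Generator,
    adjust: bool = True,
    transform: bool = True,
) -> CvResult:
    """Leave-one-out cross-validation of the parameter estimator.

    Each fold treats one table row's statistics as the pseudo-observation and
    estimates the parameters from the remaining rows.  The prediction error
    per parameter is sum((est - truth)^2) / (n_folds * Var(truth)), which is
    ~1 for a parameter the statistics carry no information about.
    """
    if n_folds > table.n:
        raise ValueError("n_folds cannot exceed the table size")
    folds = rng.choice(table.n, size=n_folds, replace=False)
    ests, trues = [], []
    for i in folds:
        res = abc_fit(
            table.statistics[i], table, tolerance,
            adjust=adjust, transform=transform, exclude=int(i),
        )
        ests.append(res.posterior_mean)
        trues.append(table.parameters.iloc[int(i)])
    est_df = pd.DataFrame(ests).reset_index(drop=True)
    true_df = pd.DataFrame(trues).reset_index(drop=True)
    err = {}
    for c in table.parameters.columns:
        var = float(np.var(true_df[c]))
        err[c] = float(((est_df[c] - true_df[c]) ** 2).sum() / (n_folds * var))
    return CvResult(prediction_error=err, n_folds=n_folds,
                    estimates=est_df, truths=true_df)


def confusion_matrix(
    tables: Mapping[str, ReferenceTable],
    n_pseudo: int,
    tolerance: float,
    rng: np.random.Generator,
) -> ModelChoiceResult:
    """Leave-one-out model-choice cross-validation.

    For each model, ``n_pseudo`` of its rows serve in turn as pseudo-observed
    data; the fraction of pseudo-observations assigned (highest posterior
    probability) to each candidate model forms that model's confusion row.
    Rows sum to 1 exactly.
    """
    if n_pseudo < 1:
        raise ValueError("n_pseudo must be >= 1")
    labels = list(tables)
    counts = pd.DataFrame(0.0, index=labels, columns=labels)
    for true_m in labels:
        nrows = tables[true_m].n
        picks = rng.choice(nrows, size=n_pseudo, replace=n_pseudo > nrows)
        for row in picks:
            obs = tables[true_m].statistics[int(row)]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mc = model_posterior(obs, tables, tolerance, exclude=(true_m, int(row)))
            best = max(mc.posterior_probs, key=mc.posterior_probs.get)
            counts.loc[true_m, best] += 1.0
    return ModelChoiceResult(
        posterior_probs={}, confusion=counts / n_pseudo, n_pseudo=n_pseudo
    )


def goodness_of_fit(
    obs: np.ndarray,
    table: ReferenceTable,
    n_null: int,
    tolerance: float,
    rng: np.random.Generator,
) -> float:
    """Distance-based posterior-predictive goodness-of-fit p-value.

    The test statistic is the mean scaled distance between a (pseudo-)
    observation and its accepted set; the null distribution is formed by
    treating ``n_null`` table rows as pseudo-observations (each excluded from
    its own reference set).  Returns the fraction of null statistics at least
    as large as the observed one.
    """
    if n_null < 100:
        raise ValueError("n_null must be >= 100")
    res = abc_reject(obs, table, tolerance)
    d_obs = float(res.distances.mean())
    picks = rng.choice(table.n, size=n_null, replace=n_null > table.n)
    null = np.empty(n_null)
    for j, row in enumerate(picks):
        r = abc_reject(table.statistics[int(row)], table, tolerance, exclude=int(row))
        null[j] = r.distances.mean()
    return float((null >= d_obs).mean())
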