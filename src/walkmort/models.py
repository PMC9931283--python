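"""Penalized Cox modelling and evaluation machinery.

The core model is the Cox proportional hazards model with an elastic-net
penalty: coefficients maximize

    (1/n) * sum_{i: event} [ x_i'b - log sum_{j: T_j >= T_i} exp(x_j'b) ]
        - lambda * ( alpha * ||b||_1 + (1 - alpha)/2 * ||b||_2^2 )

with Breslow handling of tied event times and predictors standardized
internally (coefficients are reported on both scales).  Elastic-net fits are
delegated to scikit-survival's coxnet (alpha > 0) and ridge Cox (alpha = 0);
lambda is on the per-observation (glmnet) scale throughout.

Discrimination is Harrell's concordance index; model selection uses
outcome-stratified 10-fold cross-validation, greedy forward stepwise
selection scored by CV concordance, and per-feature marginal ranking.
Diagnostics: Schoenfeld residual proportional-hazards tests (via lifelines),
feature dendrograms on 1 - |Pearson correlation|, percentile survival curves
stratified by sex and feature tertile, and per-group concordance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "PenaltySpec",
    "FitResult",
    "CVResult",
    "StepwiseConfig",
    "concordance_index",
    "stratified_folds",
    "lambda_max",
    "fit_penalized_cox",
    "cross_validate",
    "stepwise_select",
    "marginal_feature_ranking",
    "feature_hierarchy",
    "schoenfeld_test",
    "percentile_survival_curves",
    "grouped_cindex",
]

DEFAULT_SEED = 45178


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------


def concordance_index(times, events, scores) -> float:
    """Harrell's C-index: concordant share of comparable pairs.

    Comparable pairs are (i, j) with T_i < T_j and event_i = 1, plus
    tied-time pairs where exactly one subject has an event.  A pair is
    concordant when the shorter-lived subject has the strictly higher risk
    score; tied scores count 1/2.  Raises on zero comparable pairs.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(int)
    s = np.asarray(scores, dtype=float)
    if not (t.shape == e.shape == s.shape):
        raise ValueError("times, events and scores must have equal length")
    concordant = 0.0
    comparable = 0
    for i in np.flatnonzero(e == 1):
        later = t > t[i]
        tied = (t == t[i]) & (e == 0)
        others = later | tied
        others[i] = False
        m = int(np.count_nonzero(others))
        if m == 0:
            continue
        comparable += m
        s_others = s[others]
        concordant += float(np.count_nonzero(s[i] > s_others))
        concordant += 0.5 * float(np.count_nonzero(s[i] == s_others))
    if comparable == 0:
        raise ValueError("no comparable pairs: concordance is undefined")
    return concordant / comparable


# ---------------------------------------------------------------------------
# stratified folds
# ---------------------------------------------------------------------------


def stratified_folds(events, k: int = 10, seed: int = DEFAULT_SEED) -> np.ndarray:
    """Outcome-stratified fold assignment (0..k-1 per subject).

    Within each outcome class, fold sizes differ by at most one, so every
    fold carries ~1/k of the events and ~1/k of the non-events.
    """
    e = np.asarray(events).astype(int)
    n_events = int(e.sum())
    n_censored = int((1 - e).sum())
    if n_events < k:
        raise ValueError(f"need >= {k} events for {k}-fold stratification, have {n_events}")
    if n_censored < k:
        raise ValueError(f"need >= {k} non-events for {k}-fold stratification, have {n_censored}")
    rng = np.random.default_rng(seed)
    folds = np.empty(len(e), dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(e == cls)
        perm = rng.permutation(idx)
        folds[perm] = np.arange(len(perm)) % k
    return folds


# ---------------------------------------------------------------------------
# penalized Cox
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PenaltySpec:
    """Elastic-net tuning space: mixing parameters and a lambda grid.

    ``lambdas=None`` means an automatic grid of ``n_lambda`` log-spaced
    values from lambda_max (the smallest lambda with an all-zero penalized
    fit; a fixed ceiling for alpha = 0, whose lambda_max is infinite) down to
    ``lambda_min_ratio * lambda_max``.
    """

    alphas: tuple[float, ...] = (0.0, 0.5, 1.0)
    lambdas: tuple[float, ...] | None = None
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-3

    def __post_init__(self) -> None:
        if self.lambdas is not None and list(self.lambdas) != sorted(self.lambdas, reverse=True):
            raise ValueError("lambdas must be sorted descending")


@dataclass
class FitResult:
    predictors: list[str]
    coef: np.ndarray  # original predictor scale
    coef_std: np.ndarray  # standardized-predictor scale
    alpha: float
    lam: float
    center: np.ndarray
    scale: np.ndarray
    converged: bool = True

    def risk_scores(self, table: pd.DataFrame) -> np.ndarray:
        x = table[self.predictors].to_numpy(dtype=float)
        return x @ self.coef


@dataclass
class CVResult:
    fold_cindex: np.ndarray
    mean_cindex: float
    folds: np.ndarray
    horizon: float | None
    label: str
    alpha: float | None = None
    lam: float | None = None
    grid: pd.DataFrame | None = None  # mean CV C-index per (alpha, lambda)


@dataclass(frozen=True)
class StepwiseConfig:
    candidates: tuple[str, ...]
    threshold: float = 0.01  # minimum CV C-index increment to accept a step
    base: tuple[str, ...] = ()
    k: int = 10

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")


def _standardize(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    center = x.mean(axis=0)
    scale = x.std(axis=0, ddof=0)
    scale = np.where(scale > 0, scale, 1.0)
    return (x - center) / scale, center, scale


def _score_at_zero(x_std: np.ndarray, time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Breslow partial-likelihood score at beta = 0 (standardized predictors)."""
    order = np.argsort(-time, kind="stable")  # descending time
    xs = x_std[order]
    ts = time[order]
    es = event[order]
    csum = np.cumsum(xs, axis=0)
    u = np.zeros(x_std.shape[1])
    i = 0
    n = len(ts)
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            j += 1
        risk_mean = csum[j - 1] / j  # all subjects with T >= ts[i]
        for kk in range(i, j):
            if es[kk]:
                u += xs[kk] - risk_mean
        i = j
    return u


def lambda_max(table: pd.DataFrame, predictors, alpha: float,
               duration_col: str = "time", event_col: str = "event") -> float:
    """Smallest lambda with an all-zero penalized solution (per-observation
    scale).  For alpha = 0 this is infinite; a fixed ceiling (the alpha=0.01
    value) is returned instead."""
    x = table[list(predictors)].to_numpy(dtype=float)
    t = table[duration_col].to_numpy(dtype=float)
    e = table[event_col].to_numpy().astype(int)
    x_std, _, _ = _standardize(x)
    u = _score_at_zero(x_std, t, e)
    a = alpha if alpha > 0 else 0.01
    return float(np.max(np.abs(u)) / (len(t) * a))


def _lambda_grid(table, predictors, alpha, spec: PenaltySpec,
                 duration_col="time", event_col="event") -> np.ndarray:
    if spec.lambdas is not None:
        return np.asarray(spec.lambdas, dtype=float)
    lmax = lambda_max(table, predictors, alpha, duration_col, event_col)
    return np.geomspace(lmax, spec.lambda_min_ratio * lmax, spec.n_lambda)


def _surv_y(time: np.ndarray, event: np.ndarray):
    from sksurv.util import Surv

    return Surv.from_arrays(event=event.astype(bool), time=time)


def fit_penalized_cox(
    table: pd.DataFrame,
    predictors,
    alpha: float = 1.0,
    lam: float = 0.0,
    duration_col: str = "time",
    event_col: str = "event",
) -> FitResult:
    """Fit one penalized Cox model at a single (alpha, lambda).

    Predictors are standardized internally; lambda is on the per-observation
    scale (see module docstring).  ``lam = 0`` gives the unpenalized fit.
    Ties use the Breslow approximation.  Non-convergence is flagged on the
    result, never silent.
    """
    predictors = list(predictors)
    x = table[predictors].to_numpy(dtype=float)
    t = table[duration_col].to_numpy(dtype=float)
    e = table[event_col].to_numpy().astype(int)
    if e.sum() < 2:
        raise ValueError("need at least 2 events to fit a Cox model")
    x_std, center, scale = _standardize(x)
    n = len(t)
    converged = True

    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if lam > 0 and alpha > 0 and lam >= lambda_max(table, predictors, alpha, duration_col, event_col):
        beta_std = np.zeros(len(predictors))
    elif lam > 0 and alpha > 0:
        from sksurv.linear_model import CoxnetSurvivalAnalysis

        model = CoxnetSurvivalAnalysis(
            l1_ratio=alpha, alphas=[lam], normalize=False, fit_baseline_model=False
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(x_std, _surv_y(t, e))
        beta_std = model.coef_[:, 0]
    else:
        from sksurv.linear_model import CoxPHSurvivalAnalysis

        ridge = n * lam * (1.0 - alpha) if lam > 0 else 0.0
        model = CoxPHSurvivalAnalysis(alpha=ridge, ties="breslow", n_iter=200)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(x_std, _surv_y(t, e))
            beta_std = model.coef_
        except Exception as exc:  # pragma: no cover - pathological inputs
            logger.warning("Cox fit failed to converge: %s", exc)
            beta_std = np.zeros(len(predictors))
            converged = False

    coef = beta_std / scale
    return FitResult(
        predictors=predictors,
        coef=coef,
        coef_std=np.asarray(beta_std, dtype=float),
        alpha=alpha,
        lam=lam,
        center=center,
        scale=scale,
        converged=converged,
    )


def _coxnet_path_scores(
    x_train: np.ndarray,
    t_train: np.ndarray,
    e_train: np.ndarray,
    x_test: np.ndarray,
    alpha: float,
    grid: np.ndarray,
) -> np.ndarray:
    """Risk scores for the held-out block at every lambda of one alpha's path.

    Returns (n_test, n_lambda); lambdas at/above the training lambda_max give
    all-zero scores.
    """
    from sksurv.linear_model import CoxnetSurvivalAnalysis

    scores = np.zeros((x_test.shape[0], len(grid)))
    u = _score_at_zero(*_standardize(x_train)[:1], t_train, e_train)
    lmax_train = float(np.max(np.abs(u))) / (len(t_train) * alpha)
    active = grid < lmax_train
    if not active.any():
        return scores
    sub = np.asarray(sorted(grid[active], reverse=True))
    model = CoxnetSurvivalAnalysis(
        l1_ratio=alpha, alphas=list(sub), normalize=False, fit_baseline_model=False
    )
    xs, center, scale = _standardize(x_train)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(xs, _surv_y(t_train, e_train))
    fitted = {round(a, 12): model.coef_[:, j] for j, a in enumerate(model.alphas_)}
    x_test_std = (x_test - center) / scale
    for j, lam in enumerate(grid):
        beta = fitted.get(round(lam, 12))
        if beta is None:
            # coxnet may truncate the path; reuse the last fitted lambda
            beta = model.coef_[:, -1] if lam < model.alphas_[-1] else np.zeros(x_train.shape[1])
        scores[:, j] = x_test_std @ beta
    return scores


def cross_validate(
    table: pd.DataFrame,
    predictors,
    penalty: PenaltySpec | None = None,
    horizon: float | None = None,
    k: int = 10,
    seed: int = DEFAULT_SEED,
    duration_col: str = "time",
    event_col: str = "event",
    label: str = "",
) -> CVResult:
    """Stratified k-fold cross-validated concordance.

    Follow-up truncation (``horizon``) is applied before splitting.  With a
    PenaltySpec, each fold is fit along the full (alpha, lambda) grid and the
    pair with the best mean CV C-index is selected; with ``penalty=None`` the
    model is the unpenalized Cox fit of the given predictors.
    """
    from .cohort import truncate_followup

    predictors = list(predictors)
    work = truncate_followup(table, horizon) if horizon is not None else table
    t = work[duration_col].to_numpy(dtype=float)
    e = work[event_col].to_numpy().astype(int)
    x = work[predictors].to_numpy(dtype=float)
    folds = stratified_folds(e, k=k, seed=seed)

    if penalty is None:
        fold_ci = np.empty(k)
        for f in range(k):
            train = folds != f
            fit = fit_penalized_cox(
                work[train], predictors, alpha=0.0, lam=0.0,
                duration_col=duration_col, event_col=event_col,
            )
            scores = x[~train] @ fit.coef
            fold_ci[f] = concordance_index(t[~train], e[~train], scores)
        return CVResult(
            fold_cindex=fold_ci,
            mean_cindex=float(fold_ci.mean()),
            folds=folds,
            horizon=horizon,
            label=label,
        )

    rows = []
    best = None
    for alpha in penalty.alphas:
        grid = _lambda_grid(work, predictors, alpha, penalty, duration_col, event_col)
        ci = np.empty((k, len(grid)))
        for f in range(k):
            train = folds != f
            if alpha > 0:
                scores = _coxnet_path_scores(
                    x[train], t[train], e[train], x[~train], alpha, grid
                )
            else:
                scores = np.empty((int((~train).sum()), len(grid)))
                for j, lam in enumerate(grid):
                    fit = fit_penalized_cox(
                        work[train], predictors, alpha=0.0, lam=lam,
                        duration_col=duration_col, event_col=event_col,
                    )
                    scores[:, j] = x[~train] @ fit.coef
            for j in range(len(grid)):
                col = scores[:, j]
                if np.all(col == col[0]):
                    ci[f, j] = 0.5  # null model: no discrimination
                else:
                    ci[f, j] = concordance_index(t[~train], e[~train], col)
        means = ci.mean(axis=0)
        for lam, m in zip(grid, means):
            rows.append({"alpha": alpha, "lambda": lam, "mean_cindex": m})
        j_best = int(np.argmax(means))
        if best is None or means[j_best] > best[0]:
            best = (means[j_best], alpha, float(grid[j_best]), ci[:, j_best].copy())

    assert best is not None
    mean_ci, alpha_best, lam_best, fold_ci = best
    return CVResult(
        fold_cindex=fold_ci,
        mean_cindex=float(mean_ci),
        folds=folds,
        horizon=horizon,
        label=label,
        alpha=alpha_best,
        lam=lam_best,
        grid=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# stepwise and marginal selection
# ---------------------------------------------------------------------------


def stepwise_select(
    table: pd.DataFrame,
    config: StepwiseConfig,
    horizon: float | None = None,
    seed: int = DEFAULT_SEED,
    duration_col: str = "time",
    event_col: str = "event",
) -> pd.DataFrame:
    """Greedy forward selection scored by mean CV C-index.

    At each step the candidate that raises the CV C-index most is added; the
    search stops when the best increment falls below the threshold.  Returns
    the cumulative trace (step, name, cumulative C-index, increment).
    """
    selected = list(config.base)
    remaining = [c for c in config.candidates if c not in selected]
    if not remaining:
        raise ValueError("no candidate predictors")

    def score(preds) -> float:
        if not preds:
            return 0.5
        return cross_validate(
            table, preds, penalty=None, horizon=horizon, k=config.k, seed=seed,
            duration_col=duration_col, event_col=event_col,
        ).mean_cindex

    current = score(selected)
    trace = [
        {"step": i + 1, "name": name, "cumulative_cindex": np.nan, "increment": np.nan}
        for i, name in enumerate(selected)
    ]
    if selected:
        trace[-1]["cumulative_cindex"] = current

    while remaining:
        scores = {c: score(selected + [c]) for c in remaining}
        best = max(scores, key=lambda c: scores[c])
        inc = scores[best] - current
        if inc < config.threshold:
            break
        selected.append(best)
        remaining.remove(best)
        current = scores[best]
        trace.append(
            {
                "step": len(selected),
                "name": best,
                "cumulative_cindex": current,
                "increment": inc,
            }
        )
    return pd.DataFrame(trace)


def marginal_feature_ranking(
    table: pd.DataFrame,
    candidates,
    horizon: float | None = None,
    k: int = 10,
    seed: int = DEFAULT_SEED,
    duration_col: str = "time",
    event_col: str = "event",
) -> pd.DataFrame:
    """Single-predictor CV C-index for every candidate, ranked descending."""
    rows = []
    for cand in candidates:
        if table[cand].nunique() <= 1:
            ci = 0.5  # constant feature carries no ordering information
        else:
            ci = cross_validate(
                table, [cand], penalty=None, horizon=horizon, k=k, seed=seed,
                duration_col=duration_col, event_col=event_col,
            ).mean_cindex
        rows.append({"feature": cand, "cindex": ci})
    out = pd.DataFrame(rows).sort_values("cindex", ascending=False, kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# feature hierarchy
# ---------------------------------------------------------------------------


def feature_hierarchy(
    table: pd.DataFrame,
    feature_cols,
    duration_col: str | None = None,
    event_col: str | None = None,
    penalty: PenaltySpec | None = None,
    k: int = 10,
    seed: int = DEFAULT_SEED,
):
    """Agglomerative clustering of features on 1 - |Pearson correlation|.

    Returns a dict with the scipy ``linkage`` matrix (average linkage), the
    leaf names, and — when survival columns are given — boolean ``selected``
    flags marking the nonzero coefficients of the CV-selected lasso fit.
    """
    feature_cols = list(feature_cols)
    if len(feature_cols) < 2:
        raise ValueError("need at least 2 features to build a hierarchy")
    x = table[feature_cols].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    dist = np.clip(1.0 - np.abs(corr), 0.0, None)
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")

    selected = None
    if duration_col is not None and event_col is not None:
        spec = penalty or PenaltySpec(alphas=(1.0,))
        cv = cross_validate(
            table, feature_cols, penalty=spec, k=k, seed=seed,
            duration_col=duration_col, event_col=event_col,
        )
        fit = fit_penalized_cox(
            table, feature_cols, alpha=cv.alpha, lam=cv.lam,
            duration_col=duration_col, event_col=event_col,
        )
        selected = fit.coef_std != 0.0
    return {"linkage": z, "names": feature_cols, "selected": selected}


# ---------------------------------------------------------------------------
# proportional hazards diagnostics
# ---------------------------------------------------------------------------


def schoenfeld_test(
    table: pd.DataFrame,
    predictors,
    duration_col: str = "time",
    event_col: str = "event",
    threshold: float = 0.001,
):
    """Schoenfeld-residual proportional-hazards test per predictor.

    Refits an unpenalized Cox model on the given predictors, computes scaled
    Schoenfeld residuals at event times, and tests each predictor's residual
    association with (rank-transformed) time.  Returns (summary DataFrame
    with p-values and pass flags at ``threshold``, residual DataFrame indexed
    by event subjects).
    """
    from lifelines import CoxPHFitter
    from lifelines.statistics import proportional_hazard_test

    predictors = list(predictors)
    df = table[predictors + [duration_col, event_col]].copy()
    if int(df[event_col].sum()) < 3:
        raise ValueError("need at least 3 events for a Schoenfeld test")
    cph = CoxPHFitter()
    cph.fit(df, duration_col=duration_col, event_col=event_col)
    test = proportional_hazard_test(cph, df, time_transform="rank")
    pvals = test.summary["p"]
    # lifelines indexes by (variable, transform) or variable depending on version
    if isinstance(pvals.index, pd.MultiIndex):
        pvals = pvals.droplevel(-1)
    summary = pd.DataFrame(
        {
            "predictor": predictors,
            "p": [float(pvals.loc[p]) for p in predictors],
        }
    )
    summary["pass_ph"] = summary["p"] > threshold
    residuals = cph.compute_residuals(df, "scaled_schoenfeld")
    return summary, residuals


# ---------------------------------------------------------------------------
# percentile survival curves
# ---------------------------------------------------------------------------


def _km_crossing_time(time, event, percentile: float) -> tuple[float, bool]:
    """Interpolated time where the KM curve crosses ``percentile``.

    Ties (S == percentile on a flat stretch) resolve to the next event time;
    a curve that never reaches the percentile reports the largest observed
    time, flagged as censored.
    """
    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter().fit(time, event)
    sf = km.survival_function_.iloc[:, 0]
    times = sf.index.to_numpy(dtype=float)
    surv = sf.to_numpy(dtype=float)
    below = np.flatnonzero(surv < percentile)
    if below.size == 0:
        return float(np.max(np.asarray(time, dtype=float))), True
    j = int(below[0])
    if j == 0:
        return float(times[0]), False
    s_prev, s_next = surv[j - 1], surv[j]
    t_prev, t_next = times[j - 1], times[j]
    if s_prev <= percentile:  # curve sat exactly on the percentile
        return float(t_next), False
    frac = (s_prev - percentile) / (s_prev - s_next)
    return float(t_prev + frac * (t_next - t_prev)), False


def percentile_survival_curves(
    table: pd.DataFrame,
    feature: str,
    percentile: float = 0.98,
    age_col: str = "age",
    sex_col: str = "sex",
    duration_col: str = "time",
    event_col: str = "event",
    age_bin_years: float = 5.0,
    n_tertiles: int = 3,
) -> pd.DataFrame:
    """Survival-time-at-percentile vs age, stratified by sex x feature tertile.

    Within each (sex, tertile, age-bin) stratum the Kaplan-Meier estimate is
    computed and the time at which it crosses the percentile reported
    (censored at the stratum's horizon when it never does).  Empty strata are
    flagged as gaps, not failures.
    """
    if not 0 < percentile <= 1:
        raise ValueError("percentile must be in (0, 1]")
    work = table.dropna(subset=[feature]).copy()
    work["_tertile"] = pd.qcut(work[feature], n_tertiles, labels=False, duplicates="drop") + 1
    lo = np.floor(work[age_col].min() / age_bin_years) * age_bin_years
    hi = np.ceil(work[age_col].max() / age_bin_years) * age_bin_years
    edges = np.arange(lo, hi + age_bin_years, age_bin_years)
    work["_agebin"] = pd.cut(work[age_col], edges, right=False, include_lowest=True)

    rows = []
    for (sex, tert, agebin), grp in work.groupby(
        [sex_col, "_tertile", "_agebin"], observed=True
    ):
        row = {
            "sex": sex,
            "tertile": int(tert),
            "age_lo": float(agebin.left),
            "age_hi": float(agebin.right),
            "n": len(grp),
            "events": int(grp[event_col].sum()),
        }
        if len(grp) == 0:
            row.update({"crossing_time": np.nan, "censored": True, "empty": True})
        else:
            ct, censored = _km_crossing_time(
                grp[duration_col].to_numpy(), grp[event_col].to_numpy(), percentile
            )
            row.update({"crossing_time": ct, "censored": censored, "empty": False})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# grouped evaluation
# ---------------------------------------------------------------------------


def grouped_cindex(
    table: pd.DataFrame,
    fit: FitResult,
    group_col: str,
    duration_col: str = "time",
    event_col: str = "event",
    refit_per_group: bool = False,
    min_pairs: int = 1,
) -> pd.DataFrame:
    """Concordance evaluated within each group separately.

    Default protocol scores the single full-cohort fit per group;
    ``refit_per_group=True`` refits an unpenalized model within each group
    instead.  Groups without comparable pairs are flagged and carry no
    C-index.
    """
    rows = []
    for group, grp in table.groupby(group_col):
        row = {"group": group, "n": len(grp), "events": int(grp[event_col].sum())}
        try:
            if refit_per_group:
                gfit = fit_penalized_cox(
                    grp, fit.predictors, alpha=fit.alpha, lam=fit.lam,
                    duration_col=duration_col, event_col=event_col,
                )
                scores = gfit.risk_scores(grp)
            else:
                scores = fit.risk_scores(grp)
            ci = concordance_index(
                grp[duration_col].to_numpy(), grp[event_col].to_numpy(), scores
            )
            row.update({"cindex": ci, "flagged": False})
        except ValueError:
            row.update({"cindex": np.nan, "flagged": True})
        rows.append(row)
    out = pd.DataFrame(rows)
    return out
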