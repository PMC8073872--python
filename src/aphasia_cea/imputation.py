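"""Multiple imputation by predictive mean matching (PMM).

Missing utility and outcome scores are imputed m times.  For each target
variable a linear model is fitted on complete cases; under proper
imputation the residual variance and coefficients are drawn from their
sampling distributions, predictions are computed for every record, and
each missing value is filled with the observed value of a donor chosen at
random among the k complete cases whose predictions are nearest the target
record's prediction.  Imputed values are therefore always members of the
observed support of the variable.  Targets are imputed in time order, so
later variables may use earlier (already-imputed) ones as predictors.

Downstream estimates from the m completed datasets are pooled with the
standard combination rules: the pooled estimate is the mean of the
per-imputation estimates; total variance is the mean within-imputation
variance plus ``(1 + 1/m)`` times the between-imputation variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ImputationSpec:
    """Settings for one PMM run."""

    m: int = 20                    # number of imputed datasets
    k: int = 5                     # donor-pool size
    predictors: tuple[str, ...] = ("arm", "age0", "cat_naming0")
    #: variables with missingness, imputed in this (time) order; earlier
    #: targets become available as predictors for later ones
    targets: tuple[str, ...] = (
        "u_0", "naming_6", "tom_6", "u_6", "naming_9", "tom_9", "u_9",
        "naming_12", "tom_12", "u_12")
    #: draw model parameters from their sampling distribution (proper
    #: imputation); disable for deterministic tests
    proper: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not self.targets:
            raise ValueError("targets must be nonempty")


def _design_matrix(df: pd.DataFrame, predictors) -> np.ndarray:
    cols = [np.ones(len(df))]
    for p in predictors:
        s = df[p]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            # one-hot minus reference level
            levels = sorted(s.dropna().unique())
            for lev in levels[1:]:
                cols.append((s == lev).to_numpy(dtype=float))
        else:
            cols.append(s.to_numpy(dtype=float))
    return np.column_stack(cols)


def _pmm_one_variable(work: pd.DataFrame, target: str, predictors,
                      k: int, proper: bool, rng: np.random.Generator) -> None:
    """Impute one variable in place on the working copy."""
    y = work[target].to_numpy(dtype=float)
    miss = np.isnan(y)
    if not miss.any():
        return
    obs = ~miss
    n_obs = int(obs.sum())
    if n_obs == 0:
        raise ValueError(f"no complete cases for {target!r}")
    if k > n_obs:
        raise ValueError(f"donor pool k={k} exceeds the {n_obs} complete "
                         f"cases for {target!r}")
    X = _design_matrix(work, predictors)
    if np.isnan(X).any():
        raise ValueError("predictors must be observed or previously "
                         "imputed (chain targets in time order)")
    Xo, yo = X[obs], y[obs]
    beta_hat, *_ = np.linalg.lstsq(Xo, yo, rcond=None)
    if proper:
        p = Xo.shape[1]
        resid = yo - Xo @ beta_hat
        dof = max(n_obs - p, 1)
        rss = float(resid @ resid)
        sigma2 = rss / rng.chisquare(dof)
        xtx_inv = np.linalg.pinv(Xo.T @ Xo)
        cov = sigma2 * xtx_inv
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(p))
        beta = beta_hat + L @ rng.standard_normal(p)
    else:
        beta = beta_hat
    pred = X @ beta
    pred_obs = pred[obs]
    order = np.argsort(pred_obs, kind="stable")
    sorted_pred = pred_obs[order]
    donors_sorted = yo[order]
    for i in np.flatnonzero(miss):
        pos = np.searchsorted(sorted_pred, pred[i])
        lo = max(0, min(pos - k, n_obs - 2 * k))
        hi = min(n_obs, lo + 2 * k)
        window = np.arange(lo, hi)
        dist = np.abs(sorted_pred[window] - pred[i])
        nearest = window[np.argsort(dist, kind="stable")[:k]]
        donor = nearest[rng.integers(k)] if k > 1 else nearest[0]
        y[i] = donors_sorted[donor]
    work[target] = y


def pmm_impute(df: pd.DataFrame, spec: ImputationSpec,
               seed: int | None = None) -> list[pd.DataFrame]:
    """Produce ``spec.m`` completed copies of ``df``.

    Datasets differ only in the imputed cells; with no missing values the
    result is m identical copies of the input.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    completed = []
    for _ in range(spec.m):
        work = df.copy()
        available = list(spec.predictors)
        for target in spec.targets:
            if target not in work.columns:
                continue
            _pmm_one_variable(work, target, available, spec.k,
                              spec.proper, rng)
            available.append(target)
        completed.append(work)
    return completed


def impute_long(df: pd.DataFrame, spec: ImputationSpec,
                seed: int | None = None) -> pd.DataFrame:
    """All m completed datasets stacked, with an ``imputation`` column."""
    parts = []
    for i, comp in enumerate(pmm_impute(df, spec, seed)):
        comp = comp.copy()
        comp.insert(0, "imputation", i)
        parts.append(comp)
    return pd.concat(parts, ignore_index=True)


@dataclass(frozen=True)
class PooledEstimate:
    """A multiply-imputed estimate combined across datasets."""

    estimate: float
    total_variance: float
    within_variance: float
    between_variance: float
    m: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_variance))


def pool_estimates(estimates, variances) -> PooledEstimate:
    """Combine per-imputation estimates with the standard rules.

    pooled = mean(estimates); total variance = mean(variances)
    + (1 + 1/m) * var(estimates).
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.shape != u.shape:
        raise ValueError("estimates and variances differ in length")
    m = len(q)
    if m < 2:
        raise ValueError("pooling requires m >= 2")
    within = float(u.mean())
    between = float(q.var(ddof=1))
    total = within + (1.0 + 1.0 / m) * between
    return PooledEstimate(estimate=float(q.mean()), total_variance=total,
                          within_variance=within, between_variance=between,
                          m=m)
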