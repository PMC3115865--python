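"""All-subsets additive linear modelling with AIC conventions and Akaike weights.

Every non-empty subset of the candidate predictors is fitted by ordinary
least squares (binary factors as 0/1 dummies, continuous predictors
untransformed, intercept always included).  Each model is scored by an
information criterion and the candidate set is compared through Akaike
weights w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2).

Two AIC conventions are exposed:

* ``"gaussian-full"``: AIC = N[ln(2*pi*SS_res/N) + 1] + 2(k + 1) with k the
  number of predictor terms — the full Gaussian log-likelihood form whose
  parameter count excludes the variance term.
* ``"aicc"``: the same plus the small-sample correction 2K(K+1)/(N-K-1) with
  K = k + 2 (slopes + intercept + variance), the Burnham & Anderson form.

``"aicc"`` is the default for new analyses; ``"gaussian-full"`` is the
convention that matches published Gaussian-GLM model-selection tables built
from (N, SS_res, d.f.) alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "ModelFit",
    "fit_additive_model",
    "compute_aic",
    "akaike_weights",
    "all_subsets_selection",
]

NEG_INF = float("-inf")


@dataclass
class ModelFit:
    response: str
    predictors: tuple[str, ...]
    n: int
    df: int  # number of predictor terms
    ss_res: float
    pct_var: float
    aic: float
    weight: float = np.nan
    coefficients: pd.Series | None = None


def _design(X: pd.DataFrame, predictors: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
    cols: list[np.ndarray] = [np.ones(len(X))]
    names = ["intercept"]
    for p in predictors:
        v = X[p]
        if v.dtype == object or isinstance(v.dtype, pd.CategoricalDtype):
            levels = sorted(set(v))
            for lvl in levels[1:]:  # first level is the reference
                cols.append((v == lvl).to_numpy(float))
                names.append(f"{p}[{lvl}]")
        elif v.dtype == bool:
            cols.append(v.to_numpy(float))
            names.append(p)
        else:
            cols.append(v.to_numpy(float))
            names.append(p)
    return np.column_stack(cols), names


def fit_additive_model(
    y: pd.Series, X: pd.DataFrame, predictors: tuple[str, ...]
) -> ModelFit:
    """OLS fit of an additive predictor subset (complete cases only).

    d.f. is the number of predictor terms.  A rank-deficient design warns and
    proceeds on the minimum-norm solution (the aliased term carries no extra
    explanatory freedom).
    """
    mask = y.notna() & X[list(predictors)].notna().all(axis=1)
    yv = y[mask].to_numpy(float)
    A, names = _design(X[mask], predictors)
    n, p = A.shape
    if n <= p + 1:
        raise ValueError(f"N={n} too small for {p - 1} terms (need N > d.f. + 2)")
    beta, _, rank, _ = np.linalg.lstsq(A, yv, rcond=None)
    if rank < p:
        warnings.warn(
            f"rank-deficient design for {predictors}: aliased term(s) present"
        )
    resid = yv - A @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((yv - yv.mean()) ** 2))
    pct = 100.0 * (1.0 - ss_res / ss_tot) if ss_tot > 0 else np.nan
    return ModelFit(
        response=str(y.name),
        predictors=predictors,
        n=n,
        df=p - 1,
        ss_res=ss_res,
        pct_var=pct,
        aic=np.nan,
        coefficients=pd.Series(beta, index=names),
    )


def compute_aic(
    n: int, ss_res: float, k_terms: int, convention: str = "gaussian-full"
) -> float:
    """Information criterion from sample size, residual SS and term count.

    See the module docstring for the two conventions.  SS_res = 0 returns
    -inf with a warning (a saturated/interpolating model).
    """
    if ss_res < 0:
        raise ValueError("SS_res must be >= 0")
    if n <= k_terms + 1:
        raise ValueError("need N > k_terms + 1")
    if ss_res == 0:
        warnings.warn("SS_res = 0: AIC is -inf (saturated model)")
        return NEG_INF
    aic = n * (np.log(2 * np.pi * ss_res / n) + 1.0) + 2 * (k_terms + 1)
    if convention == "gaussian-full":
        return float(aic)
    if convention == "aicc":
        K = k_terms + 2
        if n - K - 1 <= 0:
            raise ValueError("N too small for the AICc correction")
        return float(aic + 2 * K * (K + 1) / (n - K - 1))
    raise ValueError(f"unknown AIC convention {convention!r}")


def akaike_weights(aics) -> np.ndarray:
    """Normalized relative likelihoods exp(-Delta/2) over the candidate set.

    Invariant to adding a constant to every AIC; -inf entries absorb all
    weight (split evenly if several).
    """
    a = np.asarray(aics, dtype=float)
    if len(a) == 0 or not (a < np.inf).any():
        raise ValueError("need at least one finite AIC")
    if np.isneginf(a).any():
        w = np.where(np.isneginf(a), 1.0, 0.0)
        return w / w.sum()
    d = a - a.min()
    w = np.exp(-d / 2.0)
    return w / w.sum()


def all_subsets_selection(
    y: pd.Series,
    X: pd.DataFrame,
    predictors: list[str] | None = None,
    convention: str = "aicc",
    display_threshold: float = 0.05,
    max_predictors: int = 12,
    force: bool = False,
) -> pd.DataFrame:
    """Fit all 2^p - 1 non-empty additive subsets and rank them by AIC.

    Returns a table sorted by ascending AIC with columns predictors, df,
    SS_res, pct_var, AIC, weight and a ``displayed`` flag for models with
    more than ``display_threshold`` Akaike weight.  Weights are computed over
    the full candidate set, not just the displayed rows.
    """
    preds = predictors if predictors is not None else list(X.columns)
    if len(preds) > max_predictors and not force:
        raise ValueError(
            f"{len(preds)} predictors would mean {2 ** len(preds) - 1} models; "
            "pass force=True to proceed"
        )
    if y.notna().sum() < 10:
        raise ValueError("response needs >= 10 complete cases")
    fits: list[ModelFit] = []
    for r in range(1, len(preds) + 1):
        for subset in combinations(preds, r):
            fit = fit_additive_model(y, X, subset)
            fit.aic = compute_aic(fit.n, fit.ss_res, fit.df, convention)
            fits.append(fit)
    w = akaike_weights([f.aic for f in fits])
    rows = []
    for fit, wi in zip(fits, w):
        rows.append(
            {
                "predictors": "+".join(fit.predictors),
                "df": fit.df,
                "SS_res": fit.ss_res,
                "pct_var": fit.pct_var,
                "AIC": fit.aic,
                "weight": float(wi),
                "N": fit.n,
            }
        )
    table = pd.DataFrame(rows).sort_values("AIC", ignore_index=True)
    table["displayed"] = table["weight"] > display_threshold
    table.attrs["response"] = str(y.name)
    table.attrs["convention"] = convention
    return table
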