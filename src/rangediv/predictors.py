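"""Construction of the explanatory variables for the diversity models.

* ``lim`` — geographic marginality: distance (km) from each site to the
  boundary of the convex hull spanned by all sites, the hull standing in for
  the range margin.  Computed on a local equirectangular projection about the
  mean latitude; at the spatial extents this pipeline targets (tens of
  degrees) the planar approximation is far below the predictor's noise.
* ``marg`` — environmental marginality: Euclidean distance of a site from
  the origin of the space spanned by the retained axes of a correlation-matrix
  PCA of the climate columns (axes retained by the Kaiser eigenvalue > 1 rule
  by default, broken-stick optionally).
* quantile groupings — the top (1 - q) fraction of a continuous predictor
  (default q = 0.85, i.e. top 15% = marginal group, strictly-greater rule).
* expansion factor — ``ref``/``hol`` are merged into one level when
  permutation tests detect no ref-vs-hol difference in any diversity measure,
  leaving the two-level contrast exp vs ref+hol.

``bar``, ``bio`` and ``size`` arrive as curated input columns (assigned by
map inspection and habitat class) and are treated as data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import Point, Polygon

from .differentiation import EARTH_RADIUS_KM
from .popdata import SiteTable

__all__ = [
    "distance_to_range_margin",
    "environmental_marginality",
    "PCAReport",
    "quantile_grouping",
    "merge_expansion_levels",
    "predictor_table",
]


def _project_km(sites: SiteTable) -> np.ndarray:
    """Equirectangular projection about the mean latitude, in km."""
    coords = sites.coords()
    lat0 = np.radians(coords[:, 0].mean())
    x = EARTH_RADIUS_KM * np.cos(lat0) * np.radians(coords[:, 1])
    y = EARTH_RADIUS_KM * np.radians(coords[:, 0])
    return np.column_stack([x, y])


def distance_to_range_margin(sites: SiteTable) -> pd.Series:
    """km from each site to the convex hull of all sites (hull vertices: 0)."""
    pts = _project_km(sites)
    if len(pts) < 3:
        raise ValueError("range margin needs at least 3 sites")
    try:
        hull = ConvexHull(pts)
    except QhullError as e:
        raise ValueError(f"degenerate site configuration (collinear?): {e}") from e
    boundary = Polygon(pts[hull.vertices]).exterior
    lim = [boundary.distance(Point(p)) for p in pts]
    return pd.Series(lim, index=sites.codes, name="lim_km")


@dataclass
class PCAReport:
    eigenvalues: np.ndarray
    n_retained: int
    loadings: np.ndarray  # columns x retained axes
    columns: list[str]
    dropped_constant: list[str]


def environmental_marginality(
    sites: SiteTable,
    columns: list[str] | None = None,
    retention: str = "kaiser",
) -> tuple[pd.Series, PCAReport]:
    """Climate-space distance from the multivariate climate mean.

    Correlation-matrix PCA of the (z-scored) climate columns; ``marg`` is the
    Euclidean norm of each site's scores on the retained axes.  Constant
    columns are dropped with a warning.
    """
    cols = columns if columns is not None else sites.climate_columns()
    if len(cols) < 2:
        raise ValueError("environmental marginality needs >= 2 climate columns")
    X = sites.frame[cols].to_numpy(float)
    sd = X.std(axis=0, ddof=1)
    dropped = [c for c, s in zip(cols, sd) if s == 0]
    if dropped:
        warnings.warn(f"constant climate columns dropped: {dropped}")
        keep = sd > 0
        X, cols = X[:, keep], [c for c in cols if c not in dropped]
        sd = sd[keep]
    Z = (X - X.mean(axis=0)) / sd
    R = np.corrcoef(Z, rowvar=False)
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if retention == "kaiser":
        n_ret = int(np.sum(evals > 1.0))
    elif retention == "broken-stick":
        p = len(evals)
        bstick = np.array([np.sum(1.0 / np.arange(i + 1, p + 1)) for i in range(p)])
        n_ret = int(np.sum(evals > bstick * evals.sum() / p))
    else:
        raise ValueError(f"unknown retention rule {retention!r}")
    n_ret = max(n_ret, 1)
    scores = Z @ evecs[:, :n_ret]
    marg = pd.Series(
        np.linalg.norm(scores, axis=1), index=sites.codes, name="marg"
    )
    return marg, PCAReport(
        eigenvalues=evals,
        n_retained=n_ret,
        loadings=evecs[:, :n_ret],
        columns=cols,
        dropped_constant=dropped,
    )


def quantile_grouping(values: pd.Series, q: float = 0.85) -> pd.Series:
    """Boolean marginal-group flag: values strictly above the q-quantile.

    Empirical quantile with linear (type-7) interpolation; ties at the
    threshold fall in the non-marginal group (strictly-greater rule).
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    v = values.astype(float)
    thr = float(np.quantile(v.dropna(), q))
    flag = v > thr
    if not flag.any():
        warnings.warn("all values tie at the quantile threshold: empty marginal group")
    return flag.rename(f"{values.name or 'value'}_group")


def merge_expansion_levels(
    div: pd.DataFrame,
    expansion: pd.Series,
    measures: tuple[str, ...] = ("H_E", "A", "s", "H_mt"),
    n_perm: int = 10_000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Merge ref and hol when no diversity measure separates them.

    For each measure, a two-sided permutation test of the ref-vs-hol
    group-mean difference (labels shuffled among ref+hol sites).  If none
    rejects at ``alpha`` the returned factor has the two levels
    {"exp", "ref+hol"}; otherwise the original three levels are kept.
    """
    rng = rng if rng is not None else np.random.default_rng()
    levels = set(expansion)
    if not {"ref", "hol", "exp"} <= levels:
        raise ValueError(f"all three expansion classes required, got {sorted(levels)}")
    codes = [c for c in expansion.index if c in div.index]
    expansion = expansion.loc[codes]
    for lvl in ("ref", "hol"):
        if (expansion == lvl).sum() < 2:
            raise ValueError(f"class {lvl!r} has < 2 sites with diversity data")
    rows = []
    merge = True
    for m in measures:
        if m not in div.columns:
            continue
        sub = div.loc[codes, m]
        mask = expansion.isin(["ref", "hol"]) & sub.notna()
        vals = sub[mask].to_numpy(float)
        is_ref = (expansion[mask] == "ref").to_numpy()
        if is_ref.sum() < 2 or (~is_ref).sum() < 2:
            continue
        obs = abs(vals[is_ref].mean() - vals[~is_ref].mean())
        hits = 0
        k = int(is_ref.sum())
        n = len(vals)
        for _ in range(n_perm):
            pm = np.zeros(n, dtype=bool)
            pm[rng.choice(n, size=k, replace=False)] = True
            hits += abs(vals[pm].mean() - vals[~pm].mean()) >= obs
        p = (hits + 1) / (n_perm + 1)
        rows.append({"measure": m, "abs_diff": obs, "p": p})
        if p < alpha:
            merge = False
    report = pd.DataFrame(rows)
    if merge:
        factor = expansion.map(lambda v: "exp" if v == "exp" else "ref+hol")
    else:
        factor = expansion.copy()
    return factor.rename("expansion_merged"), report


def predictor_table(
    sites: SiteTable,
    div: pd.DataFrame | None = None,
    q: float = 0.85,
    retention: str = "kaiser",
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Assemble the full predictor table (lim, marg, bar, bio, size,
    expansion with the ref+hol merge rule applied when ``div`` is given,
    and the quantile-group flags for lim and marg)."""
    out = pd.DataFrame(index=pd.Index(sites.codes, name="code"))
    out["lim_km"] = distance_to_range_margin(sites)
    marg, _ = environmental_marginality(sites, retention=retention)
    out["marg"] = marg
    for f in SiteTable.FACTORS:
        if f in sites.frame.columns:
            out[f] = sites.frame[f].astype(int)
    expansion = sites.frame["expansion"]
    if div is not None:
        try:
            merged, _ = merge_expansion_levels(
                div, expansion, n_perm=n_perm, rng=rng
            )
        except ValueError as e:
            warnings.warn(f"ref+hol merge not applicable: {e}")
            merged = expansion.copy()
        out["expansion"] = merged.reindex(out.index)
        # sites without diversity data keep their raw class, merged consistently
        raw = expansion.reindex(out.index)
        fill = raw.map(
            lambda v: "exp" if v == "exp" else "ref+hol"
        ) if set(merged.dropna()) == {"exp", "ref+hol"} else raw
        out["expansion"] = out["expansion"].fillna(fill)
    else:
        out["expansion"] = expansion
    out["lim_group"] = quantile_grouping(out["lim_km"], q)
    out["marg_group"] = quantile_grouping(out["marg"], q)
    return out
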