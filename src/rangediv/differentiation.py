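"""Population differentiation: Weir-Cockerham theta, haplotype F_ST,
isolation-by-distance (Mantel), minimum spanning tree, and permutation
contrasts of differentiation among population classes.

Theta follows Weir & Cockerham (1984): per locus and allele the variance
components

    a  (among populations), b (among individuals within populations),
    c  (within individuals)

are summed over alleles and loci and theta = sum(a) / sum(a + b + c).
Negative estimates are legitimate (finite-sample noise around zero) and are
preserved in reports; they are clamped to zero only when linearizing.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .popdata import GenotypeTable, HaplotypeTable, SiteTable

__all__ = [
    "DistanceMatrix",
    "ContrastResult",
    "wc_fst",
    "pairwise_fst",
    "haplotype_fst",
    "linearize_fst",
    "geo_distance_matrix",
    "mantel_test",
    "minimum_spanning_tree",
    "category_fst_contrast",
    "EARTH_RADIUS_KM",
]

EARTH_RADIUS_KM = 6371.0


@dataclass
class DistanceMatrix:
    """Symmetric site-by-site matrix with a kind tag.

    kind is one of {"geographic_km", "fst", "linearized_fst"}.
    """

    codes: list[str]
    values: np.ndarray
    kind: str = "fst"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.codes)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("matrix not symmetric")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.codes, columns=self.codes)

    def condensed(self) -> np.ndarray:
        """Upper-triangle (i<j) values in row-major order."""
        iu = np.triu_indices(len(self.codes), k=1)
        return self.values[iu]


@dataclass
class ContrastResult:
    """Permutation contrast of mean pairwise F_ST within a category vs rest."""

    label: str
    mean_within: float
    mean_rest: float
    observed_diff: float
    p_one_sided: float
    p_two_sided: float
    n_perm: int


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------


def _calls_by_site_locus(
    geno: GenotypeTable, codes: list[str]
) -> dict[str, list[np.ndarray]]:
    """code -> per-locus arrays of typed (n_i, 2) calls (missing rows dropped)."""
    out: dict[str, list[np.ndarray]] = {}
    for code in codes:
        calls = geno.calls[geno.site_mask(code)]
        per_locus = []
        for l in range(geno.n_loci):
            c = calls[:, l, :]
            per_locus.append(c[c[:, 0] != 0])
        out[code] = per_locus
    return out


def _locus_components(pops: list[np.ndarray]) -> tuple[float, float, float]:
    """Weir-Cockerham (a, b, c) summed over alleles for one locus.

    pops: per-population typed (n_i, 2) call arrays; returns zeros when the
    locus is unusable (fewer than 2 populations with data, or monomorphic).
    """
    pops = [c for c in pops if len(c) > 1]
    r = len(pops)
    if r < 2:
        return 0.0, 0.0, 0.0
    ns = np.array([len(c) for c in pops], dtype=float)
    alleles = np.unique(np.concatenate([c.ravel() for c in pops]))
    if len(alleles) < 2:
        return 0.0, 0.0, 0.0
    n_tot = ns.sum()
    nbar = n_tot / r
    nc = (n_tot - np.sum(ns**2) / n_tot) / (r - 1)
    # p[i, allele] frequencies, h[i, allele] het-carrier proportions
    p = np.zeros((r, len(alleles)))
    h = np.zeros((r, len(alleles)))
    for i, calls in enumerate(pops):
        idx = np.searchsorted(alleles, calls.ravel())
        p[i] = np.bincount(idx, minlength=len(alleles)) / (2 * len(calls))
        het = calls[:, 0] != calls[:, 1]
        if het.any():
            idx_h = np.searchsorted(alleles, calls[het].ravel())
            h[i] = np.bincount(idx_h, minlength=len(alleles)) / len(calls)
    pbar = ns @ p / n_tot
    s2 = (ns[:, None] * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = ns @ h / n_tot
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar)
        - (r - 1) / r * s2
        - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return float(a.sum()), float(b.sum()), float(c.sum())


def _theta_from_cache(cache: dict[str, list[np.ndarray]], codes: list[str], n_loci: int) -> float:
    A = B = C = 0.0
    for l in range(n_loci):
        a, b, c = _locus_components([cache[code][l] for code in codes])
        A, B, C = A + a, B + b, C + c
    denom = A + B + C
    if denom == 0:
        return float("nan")
    return A / denom


def wc_fst(geno: GenotypeTable, codes: list[str] | None = None) -> float:
    """Multi-locus Weir-Cockerham theta over the given (default: all) sites.

    May be negative; returns NaN with no usable locus (then no shared
    polymorphic locus exists among the requested sites).
    """
    codes = codes if codes is not None else geno.site_codes()
    if len(codes) < 2:
        raise ValueError("theta requires at least two sites")
    cache = _calls_by_site_locus(geno, codes)
    return _theta_from_cache(cache, codes, geno.n_loci)


def pairwise_fst(geno: GenotypeTable) -> DistanceMatrix:
    """Pairwise theta for all site pairs (raw, possibly negative)."""
    codes = geno.site_codes()
    cache = _calls_by_site_locus(geno, codes)
    n = len(codes)
    out = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        out[i, j] = out[j, i] = _theta_from_cache(
            cache, [codes[i], codes[j]], geno.n_loci
        )
    return DistanceMatrix(codes=codes, values=out, kind="fst")


# ---------------------------------------------------------------------------
# haplotype (AMOVA) F_ST
# ---------------------------------------------------------------------------


def _amova_fst(count_matrix: np.ndarray) -> float:
    """Haplotype-frequency AMOVA F_ST with identity/non-identity distance.

    count_matrix: populations x haplotypes.
    """
    ns = count_matrix.sum(axis=1).astype(float)
    keep = ns > 0
    count_matrix = count_matrix[keep]
    ns = ns[keep]
    r = len(ns)
    if r < 2:
        raise ValueError("haplotype F_ST requires >= 2 sites with sequences")
    N = ns.sum()
    tot = count_matrix.sum(axis=0)
    ssd_total = (N - np.sum(tot**2) / N) / 2
    ssd_within = np.sum((ns - (count_matrix**2).sum(axis=1) / ns) / 2)
    ssd_among = ssd_total - ssd_within
    df_among, df_within = r - 1, N - r
    ms_among = ssd_among / df_among
    ms_within = ssd_within / df_within if df_within > 0 else 0.0
    nc = (N - np.sum(ns**2) / N) / (r - 1)
    sigma_a = (ms_among - ms_within) / nc
    denom = sigma_a + ms_within
    if denom == 0:
        return float("nan")
    return float(sigma_a / denom)


def haplotype_fst(haps: HaplotypeTable) -> tuple[float, DistanceMatrix]:
    """Overall and pairwise haplotype-frequency F_ST (AMOVA, identity distance).

    Sites with zero sequences are excluded.
    """
    freq = haps.frequency_frame()
    freq = freq[freq.sum(axis=1) > 0]
    codes = list(freq.index)
    overall = _amova_fst(freq.to_numpy(float))
    n = len(codes)
    out = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        out[i, j] = out[j, i] = _amova_fst(freq.iloc[[i, j]].to_numpy(float))
    return overall, DistanceMatrix(codes=codes, values=out, kind="fst")


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------


def linearize_fst(m: DistanceMatrix) -> DistanceMatrix:
    """Elementwise F/(1-F) after clamping F into [0, 0.999]."""
    f = np.clip(m.values, 0.0, 0.999)
    return DistanceMatrix(codes=list(m.codes), values=f / (1 - f), kind="linearized_fst")


def geo_distance_matrix(sites: SiteTable) -> DistanceMatrix:
    """Great-circle (haversine) distances in km, Earth radius 6371 km.

    Sites with missing coordinates are excluded with a warning.
    """
    import warnings

    df = sites.frame
    ok = df[["lat", "lon"]].notna().all(axis=1)
    if not ok.all():
        warnings.warn(
            f"sites without coordinates excluded: {df.index[~ok].tolist()}"
        )
    codes = df.index[ok].tolist()
    lat = np.radians(df.loc[ok, "lat"].to_numpy(float))
    lon = np.radians(df.loc[ok, "lon"].to_numpy(float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = (
        np.sin(dlat / 2) ** 2
        + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    )
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    return DistanceMatrix(codes=codes, values=d, kind="geographic_km")


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------


def mantel_test(
    x: DistanceMatrix,
    y: DistanceMatrix,
    n_perm: int = 10_000,
    alternative: str = "greater",
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices with a permutation p.

    Pearson r over the off-diagonal upper triangle; the null is built by
    jointly permuting rows and columns of one matrix.  One-sided "greater"
    (the isolation-by-distance alternative) by default, with the +1
    correction in numerator and denominator.
    """
    if x.codes != y.codes:
        raise ValueError("matrices must share the same site order")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = rng if rng is not None else np.random.default_rng()
    xv = x.condensed()
    n = len(x.codes)
    iu = np.triu_indices(n, k=1)
    yv = y.values[iu]
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise ValueError("constant matrix: Mantel r undefined")
    r_obs = float(np.corrcoef(xv, yv)[0, 1])
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = y.values[np.ix_(perm, perm)][iu]
        r_p = np.corrcoef(xv, yp)[0, 1]
        if alternative == "greater":
            hits += r_p >= r_obs
        elif alternative == "less":
            hits += r_p <= r_obs
        else:
            hits += abs(r_p) >= abs(r_obs)
    return r_obs, (hits + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# minimum spanning tree
# ---------------------------------------------------------------------------


def minimum_spanning_tree(m: DistanceMatrix) -> list[tuple[str, str, float]]:
    """Kruskal MST with deterministic lexicographic tie-break on site pairs.

    Returns n-1 edges as (site_a, site_b, weight) with site_a < site_b,
    sorted by (weight, site_a, site_b).
    """
    n = len(m.codes)
    if n < 2:
        raise ValueError("MST requires at least two sites")
    if not np.isfinite(m.condensed()).all():
        raise ValueError("MST requires finite distances")
    edges = []
    for i, j in combinations(range(n), 2):
        a, b = sorted((m.codes[i], m.codes[j]))
        edges.append((m.values[i, j], a, b))
    edges.sort()
    parent = {c: c for c in m.codes}

    def find(c: str) -> str:
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    out: list[tuple[str, str, float]] = []
    for w, a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            out.append((a, b, float(w)))
            if len(out) == n - 1:
                break
    return out


# ---------------------------------------------------------------------------
# category contrast
# ---------------------------------------------------------------------------


def _mean_within(values: np.ndarray, mask: np.ndarray) -> float:
    sub = values[np.ix_(mask, mask)]
    iu = np.triu_indices(mask.sum(), k=1)
    return float(sub[iu].mean())


def category_fst_contrast(
    m: DistanceMatrix,
    membership: dict[str, bool] | list[str],
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    label: str = "category",
) -> ContrastResult:
    """Mean pairwise F_ST among category members minus among the rest.

    Cross pairs are excluded.  The null is built by shuffling the membership
    labels across sites; one- and two-sided p-values carry the +1 correction.
    Both the category and the rest need at least two members.
    """
    rng = rng if rng is not None else np.random.default_rng()
    if isinstance(membership, dict):
        mask = np.array([bool(membership[c]) for c in m.codes])
    else:
        member = set(membership)
        mask = np.array([c in member for c in m.codes])
    k = int(mask.sum())
    n = len(m.codes)
    if k < 2 or n - k < 2:
        raise ValueError(
            f"contrast needs >= 2 sites on each side (got {k} vs {n - k})"
        )
    obs = _mean_within(m.values, mask) - _mean_within(m.values, ~mask)
    ge = ab = 0
    for _ in range(n_perm):
        pm = np.zeros(n, dtype=bool)
        pm[rng.choice(n, size=k, replace=False)] = True
        d = _mean_within(m.values, pm) - _mean_within(m.values, ~pm)
        ge += d >= obs
        ab += abs(d) >= abs(obs)
    p_one = (ge + 1) / (n_perm + 1)
    p_two = (ab + 1) / (n_perm + 1)
    return ContrastResult(
        label=label,
        mean_within=_mean_within(m.values, mask),
        mean_rest=_mean_within(m.values, ~mask),
        observed_diff=float(obs),
        p_one_sided=float(p_one),
        p_two_sided=float(min(1.0, p_two)),
        n_perm=n_perm,
    )
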