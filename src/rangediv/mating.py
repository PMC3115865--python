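"""Selfing-rate estimation from multilocus identity disequilibrium (g2).

Under partial self-fertilization, heterozygosity is correlated across loci
within individuals: recently outcrossed individuals are heterozygous at many
loci, individuals from long selfing lineages at few.  g2 quantifies this
identity disequilibrium as the standardized excess of joint heterozygosity
over locus pairs,

    g2 = P(het at k and l) / (P(het at k) * P(het at l)) - 1,

estimated, following the multilocus approach of David et al. (2007) behind
the RMES program, as a ratio of sums over locus pairs k < l:

    g2_hat = sum_kl N_kl / sum_kl D_kl - 1,

with N_kl the within-individual double-heterozygosity rate (normalized by
the number of individuals typed at both loci) and D_kl the unbiased
cross-individual product rate sum_{i != j} h_ik h_jl / sum_{i != j} m_ik
m_jl (m the typed-indicator).  The estimator depends only on het/hom states,
so null alleles and partial dominance that depress apparent heterozygosity
symmetrically leave it far less biased than F_IS-based selfing estimates.

At inbreeding equilibrium under mixed mating with selfing rate s and unlinked
loci, the selfing-lineage age t is geometric (P(t) = (1-s) s^t) and
1 - F_t = 2^{-t}, giving

    g2(s) = E[(1-F)^2] / E[1-F]^2 - 1 = s / ((4 - s)(1 - s)),

which is inverted (monotone on [0, 1)) to map g2_hat to s_hat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .popdata import GenotypeTable

__all__ = [
    "SelfingEstimate",
    "estimate_g2",
    "g2_from_selfing",
    "selfing_from_g2",
    "test_selfing",
    "selfing_table",
]


@dataclass
class SelfingEstimate:
    code: str
    g2: float
    s_hat: float
    p_value: float
    n_individuals: int
    n_loci: int
    degenerate: bool = False


def _g2_from_het(h_raw: np.ndarray) -> tuple[float, bool]:
    """g2 from an individuals x loci het matrix (1 het, 0 hom, NaN missing).

    Returns (g2, degenerate); degenerate when no locus pair has the
    heterozygosity variance needed (then g2 is reported as 0).
    """
    m = (~np.isnan(h_raw)).astype(float)
    h = np.nan_to_num(h_raw, nan=0.0)
    A = h.T @ h  # sum_i h_ik h_il
    M = m.T @ m  # sum_i m_ik m_il
    u = h.sum(axis=0)
    v = m.sum(axis=0)
    cross_h = np.outer(u, u) - A  # sum_{i != j} h_ik h_jl
    cross_m = np.outer(v, v) - M
    L = h.shape[1]
    iu = np.triu_indices(L, k=1)
    ok = (M[iu] > 0) & (cross_m[iu] > 0) & (cross_h[iu] > 0)
    if not ok.any():
        return 0.0, True
    num = (A[iu][ok] / M[iu][ok]).sum()
    den = (cross_h[iu][ok] / cross_m[iu][ok]).sum()
    if den == 0:
        return 0.0, True
    return float(num / den - 1.0), False


def _site_het(site_geno: GenotypeTable) -> tuple[np.ndarray, bool]:
    """(het matrix, degenerate flag): degenerate when fewer than 2 loci carry
    both heterozygous and homozygous calls (no identity disequilibrium can be
    measured; g2 is then reported as 0)."""
    h = site_geno.het_matrix()
    if len(site_geno.ids) < 5:
        raise ValueError("g2 estimation requires at least 5 individuals")
    usable = 0
    for l in range(h.shape[1]):
        col = h[:, l]
        col = col[~np.isnan(col)]
        if len(col) and 0 < col.mean() < 1:
            usable += 1
    return h, usable < 2


def estimate_g2(site_geno: GenotypeTable) -> tuple[float, bool]:
    """Multilocus identity disequilibrium g2 for one site.

    Returns (g2, degenerate_flag); depends only on het/hom states so it is
    invariant under allele relabeling.  Sites without heterozygosity variance
    (every individual heterozygous, or homozygous, at each locus) are
    degenerate and report g2 = 0.
    """
    h, degenerate = _site_het(site_geno)
    if degenerate:
        return 0.0, True
    return _g2_from_het(h)


def g2_from_selfing(s: float) -> float:
    """Equilibrium identity disequilibrium for selfing rate s in [0, 1)."""
    if not 0 <= s < 1:
        raise ValueError("s must be in [0, 1)")
    return s / ((4 - s) * (1 - s))


def selfing_from_g2(g2: float) -> float:
    """Invert the equilibrium g2(s) relation; clamps into [0, 1].

    g2 <= 0 maps to 0 (no identity disequilibrium, no inferred selfing).
    Monotone non-decreasing in g2; g2 -> inf gives s -> 1.
    """
    if not np.isfinite(g2):
        raise ValueError("g2 must be finite")
    if g2 <= 0:
        return 0.0
    # g2 * s^2 - (5 g2 + 1) s + 4 g2 = 0; the root below 1
    b = 5 * g2 + 1
    disc = b * b - 16 * g2 * g2
    s = (b - np.sqrt(disc)) / (2 * g2)
    return float(min(max(s, 0.0), 1.0))


def test_selfing(
    site_geno: GenotypeTable,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, float]:
    """Permutation test of H0: g2 = 0 for one site.

    Each locus's heterozygosity column is permuted independently among
    individuals, destroying across-locus correlation while preserving
    per-locus heterozygosity.  Returns (g2, s_hat, one-sided p for g2 > 0);
    a degenerate g2 yields p = 1.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = rng if rng is not None else np.random.default_rng()
    h, degenerate = _site_het(site_geno)
    if not degenerate:
        g2, degenerate = _g2_from_het(h)
    else:
        g2 = 0.0
    if degenerate:
        return g2, 0.0, 1.0
    n, L = h.shape
    hits = 0
    for _ in range(n_perm):
        hp = np.empty_like(h)
        for l in range(L):
            hp[:, l] = h[rng.permutation(n), l]
        g2p, _ = _g2_from_het(hp)
        hits += g2p >= g2
    p = (hits + 1) / (n_perm + 1)
    return g2, selfing_from_g2(g2), float(p)


def selfing_table(
    geno: GenotypeTable,
    n_perm: int = 1000,
    min_individuals: int = 7,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-site g2, s_hat and permutation p (sites below the floor skipped).

    "Selfing inferred" downstream means p < 0.05; sites with s_hat = 0 are the
    ones eligible for the bottleneck test.
    """
    rng = rng if rng is not None else np.random.default_rng()
    sizes = geno.site_sample_sizes()
    rows = {}
    for code in geno.site_codes():
        if sizes[code] < min_individuals:
            continue
        sub = geno.subset(code)
        try:
            g2, s_hat, p = test_selfing(sub, n_perm=n_perm, rng=rng)
        except ValueError:
            continue
        rows[code] = {
            "g2": g2,
            "s_hat": s_hat,
            "p": p,
            "n_ind": sizes[code],
            "n_loci": sub.n_loci,
            "selfing_inferred": p < 0.05,
        }
    df = pd.DataFrame(rows).T
    df.index.name = "code"
    return df
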