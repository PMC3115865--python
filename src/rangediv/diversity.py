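"""Per-site nuclear and mitochondrial diversity statistics with rarefaction.

Expected heterozygosity uses the unbiased gene-diversity form
``n/(n-1) * (1 - sum p_i^2)`` with n the number of non-missing gene copies at
the locus; the site value is the unweighted mean over loci with data.

Allelic and haplotype richness are standardized to a common sample size g by
hypergeometric rarefaction,

    E[A_g] = sum_i [ 1 - C(N - N_i, g) / C(N, g) ],

the expected number of distinct alleles (haplotypes) in a random subsample of
g gene copies (sequences) without replacement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .popdata import MIN_DIVERSITY_INDIVIDUALS, GenotypeTable, HaplotypeTable

__all__ = [
    "expected_heterozygosity",
    "rarefied_allelic_richness",
    "rarefied_haplotype_richness",
    "diversity_table",
    "group_deviation_summary",
    "supplementary_summary",
    "DEFAULT_RAREFACTION_COPIES",
]

#: Default rarefaction depth in gene copies: twice the seven-individual
#: inclusion floor for per-site diversity statistics.
DEFAULT_RAREFACTION_COPIES = 2 * MIN_DIVERSITY_INDIVIDUALS


def _unbiased_gene_diversity(counts: np.ndarray) -> float:
    n = counts.sum()
    p = counts / n
    return float(n / (n - 1) * (1.0 - np.sum(p**2)))


def expected_heterozygosity(site_geno: GenotypeTable) -> tuple[pd.Series, float]:
    """Unbiased expected heterozygosity per locus and its unweighted mean.

    Loci with fewer than 2 non-missing gene copies are excluded from the mean.
    Returns ``(per_locus, site_mean)``; the mean is NaN if no locus qualifies.
    """
    per_locus = {}
    code = site_geno.site_codes()
    if len(code) != 1:
        raise ValueError("expected genotypes of a single site")
    for locus in site_geno.loci:
        counts = np.asarray(list(site_geno.allele_counts(code[0], locus).values()))
        if counts.sum() < 2:
            per_locus[locus] = np.nan
            continue
        per_locus[locus] = _unbiased_gene_diversity(counts)
    s = pd.Series(per_locus, name="H_E")
    return s, float(s.mean())


def _log_comb(n: np.ndarray, k: int) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefied_richness(counts: np.ndarray, g: int) -> float:
    """Expected number of distinct classes in a subsample of g copies.

    Hypergeometric rarefaction of class counts (alleles or haplotypes);
    requires ``1 <= g <= counts.sum()``.
    """
    counts = np.asarray(counts, dtype=np.int64)
    N = int(counts.sum())
    if g < 1 or g > N:
        raise ValueError(f"rarefaction depth g={g} outside [1, N={N}]")
    # P(class i absent) = C(N - N_i, g) / C(N, g); zero when N - N_i < g
    absent = np.zeros(len(counts))
    ok = (N - counts) >= g
    if ok.any():
        absent[ok] = np.exp(_log_comb(N - counts[ok], g) - _log_comb(np.array(N), g))
    return float(np.sum(1.0 - absent))


def rarefied_allelic_richness(
    site_geno: GenotypeTable, g: int = DEFAULT_RAREFACTION_COPIES
) -> tuple[pd.Series, float]:
    """Mean rarefied alleles per locus at depth ``g`` gene copies.

    Loci with fewer than g non-missing gene copies are excluded with a
    warning.  Returns ``(per_locus, site_mean)``.
    """
    if g < 2:
        raise ValueError("rarefaction depth must be >= 2 gene copies")
    code = site_geno.site_codes()
    if len(code) != 1:
        raise ValueError("expected genotypes of a single site")
    per_locus = {}
    for locus in site_geno.loci:
        counts = np.asarray(list(site_geno.allele_counts(code[0], locus).values()))
        if counts.sum() < g:
            warnings.warn(
                f"locus {locus!r} at site {code[0]!r}: "
                f"{counts.sum()} gene copies < g={g}; excluded"
            )
            per_locus[locus] = np.nan
            continue
        per_locus[locus] = rarefied_richness(counts, g)
    s = pd.Series(per_locus, name="A")
    return s, float(s.mean())


def rarefied_haplotype_richness(counts, g: int) -> float:
    """Rarefied haplotype number from per-site haplotype counts."""
    if g < 1:
        raise ValueError("g must be >= 1")
    return rarefied_richness(np.asarray(list(counts), dtype=np.int64), g)


def diversity_table(
    geno: GenotypeTable,
    haps: HaplotypeTable | None = None,
    g_nuc: int = DEFAULT_RAREFACTION_COPIES,
    g_mt: int | None = None,
    min_individuals: int = MIN_DIVERSITY_INDIVIDUALS,
) -> pd.DataFrame:
    """Per-site diversity summary (H_E, rarefied A, rarefied H_mt).

    Sites with fewer than ``min_individuals`` genotyped individuals are
    omitted (they remain available to the differentiation stage).  ``g_mt``
    defaults to the smallest per-site sequence total.
    """
    rows = {}
    sizes = geno.site_sample_sizes()
    for code in geno.site_codes():
        if sizes[code] < min_individuals:
            continue
        sub = geno.subset(code)
        he_loc, he = expected_heterozygosity(sub)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a_loc, a = rarefied_allelic_richness(sub, g_nuc)
        rows[code] = {
            "n_nuc": sizes[code],
            "H_E": he,
            "H_E_sd": float(he_loc.std(ddof=1)),
            "A": a,
            "A_sd": float(a_loc.std(ddof=1)),
        }
    df = pd.DataFrame(rows).T
    df.index.name = "code"
    if haps is not None:
        totals = {c: haps.site_total(c) for c in haps.site_codes()}
        if g_mt is None:
            g_mt = min(totals.values())
        for code in haps.site_codes():
            if code not in df.index:
                continue
            if totals[code] < g_mt:
                continue
            df.loc[code, "n_mt"] = totals[code]
            df.loc[code, "H_mt"] = rarefied_haplotype_richness(
                haps.counts[code].values(), g_mt
            )
    return df


def group_deviation_summary(
    div: pd.DataFrame,
    grouping: dict[str, list[str]],
    measures: tuple[str, ...] = ("H_E", "A", "s", "H_mt"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group mean +/- sd of each diversity measure against the overall mean.

    ``grouping`` maps a group label to the member site codes; groups may
    overlap (a site can carry several predictor flags).  Also returns the
    Pearson correlation matrix among the measures across sites.
    """
    measures = tuple(m for m in measures if m in div.columns)
    rows = []
    for m in measures:
        overall = div[m].mean()
        for label, codes in grouping.items():
            vals = div.loc[[c for c in codes if c in div.index], m].dropna()
            rows.append(
                {
                    "measure": m,
                    "group": label,
                    "n": len(vals),
                    "mean": vals.mean() if len(vals) else np.nan,
                    "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
                    "overall_mean": overall,
                }
            )
    summary = pd.DataFrame(rows)
    corr = div[list(measures)].corr(method="pearson")
    return summary, corr


def supplementary_summary(div: pd.DataFrame) -> dict[str, float]:
    """Unweighted across-site means of the diversity measures and r(H_E, A).

    The layout mirrors the study's supplementary per-site table (code, lat,
    lon, N_nuc, H_E, A, N_mt, H_mt), so a published table in that shape can be
    summarized directly.
    """
    out = {
        "mean_H_E": float(div["H_E"].mean()),
        "mean_A": float(div["A"].mean()),
        "r_HE_A": float(div["H_E"].corr(div["A"])),
    }
    if "H_mt" in div.columns:
        out["mean_H_mt"] = float(div["H_mt"].mean())
    return out
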