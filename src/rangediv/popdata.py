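"""Domain containers and I/O for genotype, sequence and site-metadata inputs.

The pipeline consumes three kinds of input:

* co-dominant diploid genotype tables (microsatellite allele lengths), read
  from GENEPOP files or from a long-form CSV dialect;
* aligned mitochondrial sequences (FASTA) with an individual-to-site
  assignment table, collapsed to per-site haplotype counts;
* a per-site metadata table (coordinates, climate columns, categorical
  factors) that is the join key for everything downstream.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "GenotypeTable",
    "SiteTable",
    "HaplotypeTable",
    "GenepopParseError",
    "read_genepop",
    "write_genepop",
    "read_genotypes_csv",
    "write_genotypes_csv",
    "read_sites",
    "collapse_haplotypes",
    "validate_dataset",
    "MIN_DIVERSITY_INDIVIDUALS",
]

#: Sites with fewer genotyped individuals than this are excluded from the
#: per-site diversity and selfing statistics (they are kept for F_ST).
MIN_DIVERSITY_INDIVIDUALS = 7

MISSING = 0  # allele value encoding a missing call


@dataclass
class GenotypeTable:
    """Diploid multi-locus genotype calls grouped by sampling site.

    ``calls`` has shape ``(n_individuals, n_loci, 2)`` with positive integer
    allele lengths; a missing call is ``(0, 0)`` — a call is either fully
    present or fully missing, never half-typed.
    """

    ids: list[str]
    sites: list[str]
    loci: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n, L = len(self.ids), len(self.loci)
        if self.calls.shape != (n, L, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} != ({n}, {L}, 2)"
            )
        if len(self.sites) != n:
            raise ValueError("one site code per individual required")
        half = (self.calls == MISSING).sum(axis=2) == 1
        if half.any():
            i, l = np.argwhere(half)[0]
            raise ValueError(
                f"half-missing call for individual {self.ids[i]!r} at locus "
                f"{self.loci[l]!r}: calls are either fully present or missing"
            )
        if (self.calls < 0).any():
            raise ValueError("allele values must be positive integers")

    # -- basic accessors ---------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def site_codes(self) -> list[str]:
        """Unique site codes in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.sites:
            seen.setdefault(s)
        return list(seen)

    def site_mask(self, code: str) -> np.ndarray:
        return np.asarray([s == code for s in self.sites])

    def subset(self, code: str) -> "GenotypeTable":
        """Genotypes of a single site."""
        m = self.site_mask(code)
        idx = np.flatnonzero(m)
        return GenotypeTable(
            ids=[self.ids[i] for i in idx],
            sites=[code] * len(idx),
            loci=list(self.loci),
            calls=self.calls[idx],
        )

    def site_sample_sizes(self) -> dict[str, int]:
        """Individuals with at least one typed locus, per site."""
        typed = (self.calls[:, :, 0] != MISSING).any(axis=1)
        out: dict[str, int] = {c: 0 for c in self.site_codes()}
        for s, t in zip(self.sites, typed):
            out[s] += int(t)
        return out

    def allele_counts(self, code: str, locus: str) -> dict[int, int]:
        """Allele length -> count of gene copies at a site and locus."""
        l = self.loci.index(locus)
        a = self.calls[self.site_mask(code), l, :].ravel()
        a = a[a != MISSING]
        vals, cnt = np.unique(a, return_counts=True)
        return dict(zip(vals.tolist(), cnt.tolist()))

    def het_matrix(self) -> np.ndarray:
        """Per individual x locus heterozygosity state (1 het, 0 hom, NaN missing)."""
        a, b = self.calls[:, :, 0], self.calls[:, :, 1]
        het = (a != b).astype(float)
        het[a == MISSING] = np.nan
        return het


@dataclass
class SiteTable:
    """Per-site metadata: coordinates, climate columns, categorical factors.

    ``frame`` is indexed by site code and carries at least ``lat`` and ``lon``
    (decimal degrees).  Binary factor columns (``bar``, ``bio``, ``size``) and
    the ``expansion`` class (``ref``/``hol``/``exp``) are optional on read but
    required by the predictor stage.  Any other numeric column is treated as a
    climate-variable candidate.
    """

    frame: pd.DataFrame
    FACTORS = ("bar", "bio", "size")
    EXPANSION_LEVELS = ("ref", "hol", "exp")

    def __post_init__(self) -> None:
        df = self.frame
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].tolist()
            raise ValueError(f"duplicate site codes: {dup}")
        for c in ("lat", "lon"):
            if c not in df.columns:
                raise ValueError(f"required column {c!r} missing")
            if not np.issubdtype(df[c].dtype, np.number):
                raise ValueError(f"column {c!r} must be numeric")
        if ((df["lat"] < -90) | (df["lat"] > 90)).any():
            raise ValueError("latitude outside [-90, 90]")
        if ((df["lon"] < -180) | (df["lon"] > 180)).any():
            raise ValueError("longitude outside [-180, 180]")
        if "expansion" in df.columns:
            bad = set(df["expansion"]) - set(self.EXPANSION_LEVELS)
            if bad:
                raise ValueError(f"unknown expansion classes: {sorted(bad)}")

    @property
    def codes(self) -> list[str]:
        return list(self.frame.index)

    def coords(self) -> np.ndarray:
        return self.frame[["lat", "lon"]].to_numpy(float)

    def climate_columns(self) -> list[str]:
        reserved = {"lat", "lon", "n_nuc", "n_mt", "expansion", *self.FACTORS}
        return [
            c
            for c in self.frame.columns
            if c not in reserved and np.issubdtype(self.frame[c].dtype, np.number)
        ]


@dataclass
class HaplotypeTable:
    """Per-site counts of collapsed mtDNA haplotypes.

    ``counts``: site code -> {haplotype id -> positive count}.  Haplotype ids
    are canonical keys (identical retained sequence strings share one id).
    """

    counts: dict[str, dict[str, int]]
    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for site, hc in self.counts.items():
            for h, c in hc.items():
                if c <= 0:
                    raise ValueError(f"non-positive count for {h} at {site}")

    def site_codes(self) -> list[str]:
        return list(self.counts)

    def site_total(self, code: str) -> int:
        return sum(self.counts[code].values())

    def count_vector(self, code: str) -> np.ndarray:
        return np.asarray(sorted(self.counts[code].values(), reverse=True))

    def frequency_frame(self) -> pd.DataFrame:
        """Sites x haplotypes count matrix (0 for absent)."""
        return (
            pd.DataFrame(self.counts).T.fillna(0).astype(int).sort_index(axis=1)
        )


# ---------------------------------------------------------------------------
# GENEPOP
# ---------------------------------------------------------------------------


class GenepopParseError(ValueError):
    """Malformed GENEPOP input; message names the offending line."""


_POP_RE = re.compile(r"^\s*pop\s*$", re.IGNORECASE)


def read_genepop(path) -> GenotypeTable:
    """Read a GENEPOP file (2- or 3-digit allele encoding, one POP per site).

    The site code for each POP block is taken from the identifier of its first
    individual (the conventional "CODE_xx , ..." usage); all-zero entries
    ("0000"/"000000") decode to missing.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise GenepopParseError(f"{path}: empty file (line 1)")
    # line 1 is a free-text title; locus names follow until the first POP
    loci: list[str] = []
    i = 1
    while i < len(lines) and not _POP_RE.match(lines[i]):
        # loci may be one-per-line or comma-separated on one line
        loci.extend(x.strip() for x in lines[i].split(",") if x.strip())
        i += 1
    if not loci:
        raise GenepopParseError(f"{path}: no locus names before first POP (line {i + 1})")
    if i == len(lines):
        raise GenepopParseError(f"{path}: no POP block found (line {i})")

    ids: list[str] = []
    sites: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    width: int | None = None
    site_code = ""
    first_in_pop = True
    for ln, raw in enumerate(lines[i:], start=i + 1):
        if _POP_RE.match(raw):
            first_in_pop = True
            continue
        if not raw.strip():
            continue
        if "," not in raw:
            raise GenepopParseError(f"{path}: line {ln}: expected 'id , genotypes'")
        ind_id, geno = raw.split(",", 1)
        ind_id = ind_id.strip()
        if first_in_pop:
            site_code = ind_id.split("_")[0] if "_" in ind_id else ind_id
            first_in_pop = False
        entries = geno.split()
        if len(entries) != len(loci):
            raise GenepopParseError(
                f"{path}: line {ln}: {len(entries)} genotype entries for "
                f"{len(loci)} loci"
            )
        row: list[tuple[int, int]] = []
        for e in entries:
            if len(e) % 2 != 0 or len(e) // 2 not in (2, 3):
                raise GenepopParseError(
                    f"{path}: line {ln}: entry {e!r} is not 2x2- or 2x3-digit"
                )
            w = len(e) // 2
            if width is None:
                width = w
            elif w != width:
                raise GenepopParseError(
                    f"{path}: line {ln}: mixed allele digit widths"
                )
            a, b = int(e[:w]), int(e[w:])
            if (a == 0) != (b == 0):
                raise GenepopParseError(
                    f"{path}: line {ln}: half-missing entry {e!r}"
                )
            row.append((a, b))
        ids.append(ind_id)
        sites.append(site_code)
        rows.append(row)
    calls = np.asarray(rows, dtype=np.int64).reshape(len(ids), len(loci), 2)
    return GenotypeTable(ids=ids, sites=sites, loci=loci, calls=calls)


def write_genepop(table: GenotypeTable, path, title: str = "rangediv export") -> None:
    """Write GENEPOP with 3-digit alleles; inverse of :func:`read_genepop`."""
    if (table.calls > 999).any():
        raise ValueError("allele length > 999 cannot be written as 3-digit GENEPOP")
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in table.loci:
            fh.write(locus + "\n")
        for code in table.site_codes():
            fh.write("POP\n")
            sub = table.subset(code)
            for ind, row in zip(sub.ids, sub.calls):
                geno = " ".join(f"{a:03d}{b:03d}" for a, b in row)
                fh.write(f"{ind} , {geno}\n")


# ---------------------------------------------------------------------------
# long-form CSV dialect
# ---------------------------------------------------------------------------


def read_genotypes_csv(path) -> GenotypeTable:
    """Read the long-form dialect: individual, site, locus, allele1, allele2."""
    df = pd.read_csv(path, dtype={"individual": str, "site": str, "locus": str})
    need = {"individual", "site", "locus", "allele1", "allele2"}
    if not need <= set(df.columns):
        raise ValueError(f"long-form CSV requires columns {sorted(need)}")
    df = df.fillna({"allele1": 0, "allele2": 0})
    loci = list(dict.fromkeys(df["locus"]))
    inds = list(dict.fromkeys(zip(df["individual"], df["site"])))
    idx = {p: i for i, p in enumerate(inds)}
    lidx = {l: j for j, l in enumerate(loci)}
    calls = np.zeros((len(inds), len(loci), 2), dtype=np.int64)
    for ind, site, locus, a1, a2 in df[
        ["individual", "site", "locus", "allele1", "allele2"]
    ].itertuples(index=False):
        calls[idx[(ind, site)], lidx[locus]] = (int(a1), int(a2))
    return GenotypeTable(
        ids=[i for i, _ in inds],
        sites=[s for _, s in inds],
        loci=loci,
        calls=calls,
    )


def write_genotypes_csv(table: GenotypeTable, path) -> None:
    recs = []
    for i, (ind, site) in enumerate(zip(table.ids, table.sites)):
        for j, locus in enumerate(table.loci):
            a, b = table.calls[i, j]
            recs.append((ind, site, locus, a, b))
    pd.DataFrame(
        recs, columns=["individual", "site", "locus", "allele1", "allele2"]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# sites
# ---------------------------------------------------------------------------


def read_sites(path) -> SiteTable:
    """Read the per-site metadata CSV (code, lat, lon, optional columns).

    Unknown numeric columns are preserved as climate candidates.  A missing
    ``expansion`` column defaults every site to the Holocene class ``hol``
    with a warning.
    """
    df = pd.read_csv(path, dtype={"code": str})
    if "code" not in df.columns:
        raise ValueError("sites CSV requires a 'code' column")
    if df["code"].duplicated().any():
        raise ValueError(
            f"duplicate site codes: {df['code'][df['code'].duplicated()].tolist()}"
        )
    df = df.set_index("code")
    for c in ("lat", "lon"):
        if c in df.columns:
            df[c] = pd.to_numeric(df[c], errors="raise")
    if "expansion" not in df.columns:
        warnings.warn("no 'expansion' column: defaulting all sites to 'hol'")
        df["expansion"] = "hol"
    return SiteTable(df)


# ---------------------------------------------------------------------------
# haplotypes
# ---------------------------------------------------------------------------


def collapse_haplotypes(
    fasta, assignments: Mapping[str, str], min_length: int = 400
) -> HaplotypeTable:
    """Collapse aligned sequences to per-site haplotype counts.

    Sequences with fewer than ``min_length`` non-gap positions are dropped;
    identical retained strings (exact match over the full aligned window, 'N'
    counts as a mismatch) share one haplotype id.

    Parameters
    ----------
    fasta : path or handle of the pre-aligned FASTA (equal lengths required)
    assignments : sequence id -> site code
    min_length : minimum number of non-gap positions to retain a sequence
    """
    records = list(SeqIO.parse(fasta, "fasta"))
    lengths = {len(r.seq) for r in records}
    if len(lengths) > 1:
        raise ValueError(f"unequal alignment lengths: {sorted(lengths)}")
    counts: dict[str, dict[str, int]] = {}
    hap_ids: dict[str, str] = {}
    seqs: dict[str, str] = {}
    for rec in records:
        if rec.id not in assignments:
            raise KeyError(f"sequence {rec.id!r} has no site assignment")
        s = str(rec.seq).upper()
        if sum(c != "-" for c in s) < min_length:
            continue
        if s not in hap_ids:
            hap_ids[s] = f"H{len(hap_ids) + 1:03d}"
            seqs[hap_ids[s]] = s
        site = assignments[rec.id]
        counts.setdefault(site, {})
        counts[site][hap_ids[s]] = counts[site].get(hap_ids[s], 0) + 1
    return HaplotypeTable(counts=counts, sequences=seqs)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationIssue:
    level: str  # "fatal" | "warning" | "info"
    message: str


def validate_dataset(
    geno: GenotypeTable | None,
    sites: SiteTable | None,
    haps: HaplotypeTable | None,
) -> list[ValidationIssue]:
    """Cross-reference the three inputs; report-only (never raises).

    Flags genotype/haplotype site codes absent from the site table as fatal,
    and sites below the seven-individual diversity threshold as excluded from
    the per-site diversity statistics.
    """
    issues: list[ValidationIssue] = []
    known = set(sites.codes) if sites is not None else None
    if geno is not None:
        sizes = geno.site_sample_sizes()
        for code, n in sizes.items():
            if known is not None and code not in known:
                issues.append(
                    ValidationIssue("fatal", f"genotype site {code!r} not in site table")
                )
            if n < MIN_DIVERSITY_INDIVIDUALS:
                issues.append(
                    ValidationIssue(
                        "warning",
                        f"site {code!r}: {n} genotyped individuals "
                        f"(< {MIN_DIVERSITY_INDIVIDUALS}); excluded from diversity",
                    )
                )
    if haps is not None:
        for code in haps.site_codes():
            if known is not None and code not in known:
                issues.append(
                    ValidationIssue("fatal", f"haplotype site {code!r} not in site table")
                )
    return issues
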