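"""Forward-time metapopulation simulator with known ground truth.

The generator emulates the population structure the analysis pipeline
assumes: patchily distributed demes along a Southwest-Northeast axis with
strong local drift, per-deme mixed mating (selfing rate 0..1),
distance-independent jump dispersal, recently founded demes at the NE end of
the axis (serial founder effects from <= 2 colonists followed by rapid
growth), microsatellites mutating under a two-phase stepwise model and
maternally inherited mtDNA under infinite-alleles mutation, plus site
covariates correlated with geography.

Demes are initialized at mutation-drift equilibrium by drawing each locus
from a coalescent TPM sample (``init="equilibrium"``: demes independent,
i.e. long-isolated; ``init="shared"``: all demes split from one panmictic
pool, for drift-from-zero experiments).  Forward generations are
non-overlapping: each offspring is selfed with probability s, otherwise
outcrossed to a uniformly drawn other parent within the deme; migrants
replace residents at rate m from a uniformly random other deme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bottleneck import TPMParams, simulate_coalescent_tpm
from .popdata import GenotypeTable, HaplotypeTable, SiteTable

__all__ = [
    "SimScenario",
    "SimTruth",
    "simulate_metapopulation",
    "simulate_mixed_mating_population",
    "scenario_null",
    "scenario_range_expansion",
    "haplotype_fasta_records",
]

_ALLELE_BASE = 300  # repeat scores are offsets around this GENEPOP-safe value


@dataclass
class SimScenario:
    """Fully concrete simulation scenario; the seed alone fixes the outcome."""

    name: str
    coords: np.ndarray  # (n_demes, 2) lat, lon
    deme_sizes: np.ndarray  # census size per deme
    selfing_rates: np.ndarray  # per-deme s in [0, 1]
    founding_gens: np.ndarray  # 0 for demes present from the start
    source_demes: np.ndarray  # founding source index (-1 for core demes)
    expansion_class: list[str]  # "ref" | "hol" | "exp" per deme
    bar: np.ndarray
    bio: np.ndarray
    size: np.ndarray
    generations: int = 40
    migration: float = 0.01
    n_loci: int = 8
    mu: float = 5e-4
    tpm: TPMParams = field(default_factory=TPMParams)
    mu_mt: float = 1e-3
    theta_init: float = 2.0
    theta_mt: float = 3.0
    init: str = "equilibrium"  # or "shared"
    founder_size: int = 2
    sample_size: int = 25
    mt_sample_size: int = 12

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.deme_sizes = np.asarray(self.deme_sizes, dtype=int)
        self.selfing_rates = np.asarray(self.selfing_rates, dtype=float)
        self.founding_gens = np.asarray(self.founding_gens, dtype=int)
        self.source_demes = np.asarray(self.source_demes, dtype=int)
        n = len(self.coords)
        for arr, nm in [
            (self.deme_sizes, "deme_sizes"),
            (self.selfing_rates, "selfing_rates"),
            (self.founding_gens, "founding_gens"),
            (self.source_demes, "source_demes"),
        ]:
            if len(arr) != n:
                raise ValueError(f"{nm} length {len(arr)} != {n} demes")
        if ((self.selfing_rates < 0) | (self.selfing_rates > 1)).any():
            raise ValueError("selfing rates must be in [0, 1]")
        if (self.deme_sizes < 2).any():
            raise ValueError("deme sizes must be >= 2")
        for d in np.flatnonzero(self.founding_gens > 0):
            src = self.source_demes[d]
            if src < 0 or self.founding_gens[src] >= self.founding_gens[d]:
                raise ValueError(
                    f"deme {d} founded at gen {self.founding_gens[d]} from a "
                    "source that does not exist yet"
                )

    @property
    def n_demes(self) -> int:
        return len(self.coords)

    def site_codes(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_demes)]


@dataclass
class SimTruth:
    """Ground truth of a simulation run (fully determines it given the seed)."""

    scenario: str
    seed: int
    selfing_rates: dict[str, float]
    founding_gens: dict[str, int]
    expansion_class: dict[str, str]
    migration: float
    mu: float
    mu_mt: float


# ---------------------------------------------------------------------------
# core engine
# ---------------------------------------------------------------------------


def _tpm_steps(k: int, tpm: TPMParams, rng: np.random.Generator) -> np.ndarray:
    mag = np.ones(k, dtype=np.int64)
    multi = rng.random(k) >= tpm.p_single
    if multi.any():
        mag[multi] = rng.geometric(tpm.geometric_q(), multi.sum())
    return (rng.integers(0, 2, k) * 2 - 1) * mag


def _reproduce(
    alleles: np.ndarray,
    mt: np.ndarray,
    target: int,
    s: float,
    mu: float,
    mu_mt: float,
    tpm: TPMParams,
    rng: np.random.Generator,
    mt_counter: list[int],
) -> tuple[np.ndarray, np.ndarray]:
    n_cur, L, _ = alleles.shape
    mothers = rng.integers(n_cur, size=target)
    if n_cur > 1:
        fathers = (mothers + 1 + rng.integers(n_cur - 1, size=target)) % n_cur
    else:
        fathers = mothers.copy()
    selfed = rng.random(target) < s
    fathers[selfed] = mothers[selfed]
    li = np.arange(L)[None, :]
    mat = alleles[mothers[:, None], li, rng.integers(0, 2, (target, L))]
    pat = alleles[fathers[:, None], li, rng.integers(0, 2, (target, L))]
    child = np.stack([mat, pat], axis=2)
    hit = rng.random(child.shape) < mu
    k = int(hit.sum())
    if k:
        child[hit] = np.clip(child[hit] + _tpm_steps(k, tpm, rng), 10, 990)
    child_mt = mt[mothers].copy()
    mmut = rng.random(target) < mu_mt
    for i in np.flatnonzero(mmut):
        mt_counter[0] += 1
        child_mt[i] = mt_counter[0]
    return child, child_mt


def _init_states(
    sc: SimScenario, rng: np.random.Generator
) -> tuple[list, list, list[int]]:
    """Initial allele/mt state for the demes present at generation 0."""
    core = np.flatnonzero(sc.founding_gens == 0)
    alleles: list = [None] * sc.n_demes
    mts: list = [None] * sc.n_demes
    mt_counter = [0]

    def urn(n: int, theta: float) -> np.ndarray:
        # Hoppe urn: new haplotype with prob theta/(theta + i)
        out = np.empty(n, dtype=np.int64)
        for i in range(n):
            if rng.random() < theta / (theta + i) or i == 0:
                mt_counter[0] += 1
                out[i] = mt_counter[0]
            else:
                out[i] = out[rng.integers(i)]
        return out

    if sc.init == "shared":
        total = int(sc.deme_sizes[core].sum())
        pool = np.empty((total, sc.n_loci, 2), dtype=np.int64)
        for l in range(sc.n_loci):
            leaves = simulate_coalescent_tpm(2 * total, sc.theta_init, sc.tpm, rng)
            pool[:, l, :] = _ALLELE_BASE + leaves.astype(np.int64).reshape(total, 2)
        pool_mt = urn(total, sc.theta_mt)
        off = 0
        for d in core:
            n = int(sc.deme_sizes[d])
            alleles[d] = pool[off : off + n].copy()
            mts[d] = pool_mt[off : off + n].copy()
            off += n
    elif sc.init == "equilibrium":
        for d in core:
            n = int(sc.deme_sizes[d])
            a = np.empty((n, sc.n_loci, 2), dtype=np.int64)
            for l in range(sc.n_loci):
                leaves = simulate_coalescent_tpm(2 * n, sc.theta_init, sc.tpm, rng)
                a[:, l, :] = _ALLELE_BASE + leaves.astype(np.int64).reshape(n, 2)
            alleles[d] = a
            mts[d] = urn(n, sc.theta_mt)
    else:
        raise ValueError(f"unknown init mode {sc.init!r}")
    return alleles, mts, mt_counter


def simulate_metapopulation(
    scenario: SimScenario, seed: int
) -> tuple[GenotypeTable, HaplotypeTable, SiteTable, SimTruth]:
    """Run the scenario and sample genotype/haplotype/site tables at the end.

    Deterministic given (scenario, seed): the same seed yields byte-identical
    outputs.
    """
    rng = np.random.default_rng(seed)
    sc = scenario
    alleles, mts, mt_counter = _init_states(sc, rng)

    for gen in range(1, sc.generations + 1):
        new_alleles: list = [None] * sc.n_demes
        new_mts: list = [None] * sc.n_demes
        for d in range(sc.n_demes):
            fg = sc.founding_gens[d]
            if fg > gen:
                continue
            if fg == gen:  # colonization by founder_size individuals
                src = sc.source_demes[d]
                pick = rng.choice(len(alleles[src]), size=sc.founder_size, replace=False)
                new_alleles[d] = alleles[src][pick].copy()
                new_mts[d] = mts[src][pick].copy()
                continue
            n_cur = len(alleles[d])
            target = int(min(sc.deme_sizes[d], max(2 * n_cur, sc.founder_size)))
            new_alleles[d], new_mts[d] = _reproduce(
                alleles[d], mts[d], target, float(sc.selfing_rates[d]),
                sc.mu, sc.mu_mt, sc.tpm, rng, mt_counter,
            )
        # distance-independent jump dispersal among demes already present
        active = [d for d in range(sc.n_demes) if new_alleles[d] is not None]
        if sc.migration > 0 and len(active) > 1:
            snapshots = {d: (new_alleles[d].copy(), new_mts[d].copy()) for d in active}
            for d in active:
                n = len(new_alleles[d])
                mig = np.flatnonzero(rng.random(n) < sc.migration)
                for i in mig:
                    src = active[rng.integers(len(active) - 1)]
                    if src == d:
                        src = active[-1]
                    sa, sm = snapshots[src]
                    j = rng.integers(len(sa))
                    new_alleles[d][i] = sa[j]
                    new_mts[d][i] = sm[j]
        for d in range(sc.n_demes):
            if new_alleles[d] is not None:
                alleles[d], mts[d] = new_alleles[d], new_mts[d]

    # --- sampling ---------------------------------------------------------
    codes = sc.site_codes()
    ids: list[str] = []
    site_col: list[str] = []
    rows: list[np.ndarray] = []
    hap_counts: dict[str, dict[str, int]] = {}
    n_nuc: dict[str, int] = {}
    n_mt: dict[str, int] = {}
    for d, code in enumerate(codes):
        n = len(alleles[d])
        k = min(sc.sample_size, n)
        pick = rng.choice(n, size=k, replace=False)
        for r, i in enumerate(pick):
            ids.append(f"{code}_{r + 1:03d}")
            site_col.append(code)
            rows.append(alleles[d][i])
        n_nuc[code] = k
        km = min(sc.mt_sample_size, n)
        mpick = rng.choice(n, size=km, replace=False)
        counts: dict[str, int] = {}
        for i in mpick:
            h = f"H{mts[d][i]:05d}"
            counts[h] = counts.get(h, 0) + 1
        hap_counts[code] = counts
        n_mt[code] = km
    geno = GenotypeTable(
        ids=ids,
        sites=site_col,
        loci=[f"L{j + 1}" for j in range(sc.n_loci)],
        calls=np.stack(rows),
    )
    haps = HaplotypeTable(counts=hap_counts)

    lat, lon = sc.coords[:, 0], sc.coords[:, 1]
    lat_z = (lat - lat.mean()) / (lat.std() or 1.0)
    climate = {}
    for j in range(5):  # climate gradients tied to latitude plus local noise
        w = 1.0 - 0.15 * j
        climate[f"clim{j + 1}"] = w * lat_z + 0.4 * rng.standard_normal(sc.n_demes)
    frame = pd.DataFrame(
        {
            "lat": lat,
            "lon": lon,
            **climate,
            "bar": sc.bar.astype(int),
            "bio": sc.bio.astype(int),
            "size": sc.size.astype(int),
            "expansion": sc.expansion_class,
            "n_nuc": [n_nuc[c] for c in codes],
            "n_mt": [n_mt[c] for c in codes],
        },
        index=pd.Index(codes, name="code"),
    )
    truth = SimTruth(
        scenario=sc.name,
        seed=seed,
        selfing_rates=dict(zip(codes, sc.selfing_rates.tolist())),
        founding_gens=dict(zip(codes, sc.founding_gens.tolist())),
        expansion_class=dict(zip(codes, sc.expansion_class)),
        migration=sc.migration,
        mu=sc.mu,
        mu_mt=sc.mu_mt,
    )
    return geno, haps, SiteTable(frame), truth


def simulate_mixed_mating_population(
    n_individuals: int,
    s: float,
    n_loci: int = 8,
    generations: int = 60,
    theta_init: float = 4.0,
    mu: float = 1e-3,
    seed: int = 0,
    sizes: list[int] | None = None,
    sample_size: int | None = None,
) -> GenotypeTable:
    """One deme under mixed mating, for estimator calibration.

    Initialized from a coalescent equilibrium draw, then run forward long
    enough for the selfing-lineage age distribution (hence g2) to
    equilibrate.  ``sizes`` optionally prescribes the census size of each
    forward generation (overriding ``generations``), which is how demographic
    crashes for bottleneck power experiments are expressed; ``sample_size``
    limits the individuals returned (default: the whole final generation).
    """
    rng = np.random.default_rng(seed)
    tpm = TPMParams()
    a = np.empty((n_individuals, n_loci, 2), dtype=np.int64)
    for l in range(n_loci):
        leaves = simulate_coalescent_tpm(2 * n_individuals, theta_init, tpm, rng)
        a[:, l, :] = _ALLELE_BASE + leaves.astype(np.int64).reshape(n_individuals, 2)
    mt = np.zeros(n_individuals, dtype=np.int64)
    counter = [0]
    trajectory = sizes if sizes is not None else [n_individuals] * generations
    for target in trajectory:
        a, mt = _reproduce(a, mt, int(target), s, mu, 0.0, tpm, rng, counter)
    if sample_size is not None and sample_size < len(a):
        pick = rng.choice(len(a), size=sample_size, replace=False)
        a = a[pick]
    code = "POP"
    return GenotypeTable(
        ids=[f"{code}_{i + 1:03d}" for i in range(len(a))],
        sites=[code] * len(a),
        loci=[f"L{j + 1}" for j in range(n_loci)],
        calls=a,
    )


# ---------------------------------------------------------------------------
# packaged scenarios
# ---------------------------------------------------------------------------


def _axis_coords(n: int, lat0: float, lat1: float, lon0: float, lon1: float) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)
    jit = np.sin(np.arange(n) * 2.399) * 0.8  # deterministic scatter off-axis
    lat = lat0 + (lat1 - lat0) * t + jit * 0.4
    lon = lon0 + (lon1 - lon0) * t + jit
    return np.column_stack([lat, lon])


def scenario_null(
    n_demes: int = 20,
    deme_size: int = 50,
    selfing: float = 0.0,
    generations: int = 30,
    migration: float = 0.02,
    sample_size: int = 25,
) -> SimScenario:
    """Homogeneous island model: uniform selfing, no expansion, all predictor
    effects null.  The calibration baseline for every type-I suite."""
    n = n_demes
    third = n // 3
    classes = ["ref"] * third + ["hol"] * (n - 2 * third) + ["exp"] * third
    idx = np.arange(n)
    return SimScenario(
        name="null",
        coords=_axis_coords(n, 44.0, 56.0, -2.0, 14.0),
        deme_sizes=np.full(n, deme_size),
        selfing_rates=np.full(n, float(selfing)),
        founding_gens=np.zeros(n, dtype=int),
        source_demes=np.full(n, -1),
        expansion_class=classes,
        bar=(idx % 6 == 0),
        bio=(idx % 6 == 3),
        size=(idx % 2 == 0),
        generations=generations,
        migration=migration,
        sample_size=sample_size,
    )


def scenario_range_expansion(
    n_core: int = 40,
    n_expansion: int = 15,
    deme_size: int = 60,
    generations: int = 40,
    founding_gen: int = 10,
    migration: float = 0.005,
    sample_size: int = 25,
) -> SimScenario:
    """Core range plus recently founded demes along the NE end of the axis.

    Expansion demes are colonized at ``founding_gen`` by two individuals from
    scattered core sources and then grow rapidly, producing the qualitative
    target pattern: reduced H_E/A/H_mt and elevated pairwise F_ST in the
    expansion class, with slightly higher selfing there.
    """
    n = n_core + n_expansion
    coords = np.vstack(
        [
            _axis_coords(n_core, 44.0, 56.0, -2.0, 14.0),
            _axis_coords(n_expansion, 56.5, 60.5, 14.5, 20.0),
        ]
    )
    idx = np.arange(n)
    n_ref = max(4, n_core // 3)
    classes = (
        ["ref"] * n_ref + ["hol"] * (n_core - n_ref) + ["exp"] * n_expansion
    )
    # mixed mating: alternating outcrossers and partial selfers (core mean ~0.2)
    s = np.where(idx % 2 == 0, 0.0, 0.1 + 0.3 * ((idx * 37) % 100) / 100.0)
    s[n_core:] = np.minimum(s[n_core:] + 0.1, 0.9)  # selfing aids colonization
    founding = np.zeros(n, dtype=int)
    founding[n_core:] = founding_gen
    sources = np.full(n, -1)
    sources[n_core:] = (np.arange(n_expansion) * 7) % n_core
    return SimScenario(
        name="range_expansion",
        coords=coords,
        deme_sizes=np.full(n, deme_size),
        selfing_rates=s,
        founding_gens=founding,
        source_demes=sources,
        expansion_class=classes,
        bar=(idx < 4) | ((idx >= n_ref) & (idx < n_ref + 2)),
        bio=(idx % 9 == 4) & (idx < n_core),
        size=(idx % 2 == 0),
        generations=generations,
        migration=migration,
        sample_size=sample_size,
        theta_init=2.5,
    )


# ---------------------------------------------------------------------------
# FASTA realism for exports
# ---------------------------------------------------------------------------


def haplotype_fasta_records(
    haps: HaplotypeTable, length: int = 450, seed: int = 0
) -> list[tuple[str, str]]:
    """Synthesize one aligned sequence per haplotype id (id -> sequence).

    Identity structure is what matters downstream; sequences are a random
    reference with id-specific substitutions so identical ids collapse back
    to identical strings.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    ref = rng.integers(0, 4, length)
    out = []
    all_ids = sorted({h for c in haps.counts.values() for h in c})
    for hap in all_ids:
        tag = sum(ord(c) * 31**k for k, c in enumerate(hap)) % (2**31)
        sub_rng = np.random.default_rng(tag + seed)
        seq = ref.copy()
        for pos in sub_rng.choice(length, size=8, replace=False):
            seq[pos] = (seq[pos] + 1 + sub_rng.integers(3)) % 4
        out.append((hap, "".join(bases[seq])))
    return out
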