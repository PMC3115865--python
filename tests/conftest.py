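import numpy as np
import pytest

from rangediv.popdata import GenotypeTable


def make_genotypes(site_allele_pairs, loci=None):
    """Build a GenotypeTable from {site: [[(a, b), ...] per individual]}."""
    ids, sites, rows = [], [], []
    n_loci = None
    for site, inds in site_allele_pairs.items():
        for k, calls in enumerate(inds):
            ids.append(f"{site}_{k + 1}")
            sites.append(site)
            rows.append(calls)
            n_loci = len(calls)
    loci = loci or [f"L{j + 1}" for j in range(n_loci)]
    return GenotypeTable(
        ids=ids, sites=sites, loci=loci, calls=np.asarray(rows)
    )


@pytest.fixture
def two_site_geno():
    """Two sites x three individuals x two loci, fully typed."""
    return make_genotypes(
        {
            "AAA": [
                [(100, 102), (200, 200)],
                [(100, 100), (200, 202)],
                [(102, 104), (202, 202)],
            ],
            "BBB": [
                [(104, 104), (204, 204)],
                [(104, 106), (204, 206)],
                [(106, 106), (206, 206)],
            ],
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
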