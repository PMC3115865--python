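import textwrap

import numpy as np
import pandas as pd
import pytest

from rangediv import popdata
from rangediv.popdata import (
    GenepopParseError,
    GenotypeTable,
    collapse_haplotypes,
    read_genepop,
    read_genotypes_csv,
    read_sites,
    validate_dataset,
    write_genepop,
    write_genotypes_csv,
)

GENEPOP = textwrap.dedent(
    """\
    two ponds, three loci
    locA
    locB
    locC
    POP
    AAA_1 , 100102 200200 300300
    AAA_2 , 100100 000000 300302
    POP
    BBB_1 , 104104 204204 302302
    BBB_2 , 104106 204206 000000
    """
)


@pytest.fixture
def genepop_file(tmp_path):
    p = tmp_path / "two_pops.gen"
    p.write_text(GENEPOP)
    return p


class TestGenepop:
    def test_structure_preserving_parse(self, genepop_file):
        t = read_genepop(genepop_file)
        assert t.n_individuals == 4
        assert t.loci == ["locA", "locB", "locC"]
        assert t.site_codes() == ["AAA", "BBB"]
        assert tuple(t.calls[0, 0]) == (100, 102)

    def test_all_zero_entry_decodes_missing(self, genepop_file):
        t = read_genepop(genepop_file)
        assert tuple(t.calls[1, 1]) == (0, 0)  # AAA_2 locB
        assert tuple(t.calls[3, 2]) == (0, 0)  # BBB_2 locC

    def test_round_trip_is_lossless(self, genepop_file, tmp_path):
        t = read_genepop(genepop_file)
        out = tmp_path / "rt.gen"
        write_genepop(t, out)
        t2 = read_genepop(out)
        assert t.ids == t2.ids
        assert t.sites == t2.sites
        assert t.loci == t2.loci
        assert np.array_equal(t.calls, t2.calls)

    @pytest.mark.parametrize(
        "bad,match",
        [
            ("title\nlocA\nPOP\nA_1 , 100100 200200\n", "2 genotype entries"),
            ("title\nlocA\nPOP\nA_1 , 10010\n", "not 2x2- or 2x3-digit"),
            ("title\nlocA\nPOP\nA_1 , 100000\n", "half-missing"),
            ("title\nPOP\nA_1 , 100100\n", "no locus names"),
        ],
    )
    def test_malformed_inputs_name_the_line(self, tmp_path, bad, match):
        p = tmp_path / "bad.gen"
        p.write_text(bad)
        with pytest.raises(GenepopParseError, match=match):
            read_genepop(p)


class TestLongFormCsv:
    def test_round_trip(self, two_site_geno, tmp_path):
        p = tmp_path / "long.csv"
        write_genotypes_csv(two_site_geno, p)
        t = read_genotypes_csv(p)
        assert t.ids == two_site_geno.ids
        assert np.array_equal(t.calls, two_site_geno.calls)


class TestGenotypeTable:
    def test_half_missing_call_rejected(self):
        with pytest.raises(ValueError, match="fully present or missing"):
            GenotypeTable(
                ids=["a"], sites=["A"], loci=["L1"], calls=[[(100, 0)]]
            )

    def test_site_subset_and_allele_counts(self, two_site_geno):
        sub = two_site_geno.subset("AAA")
        assert sub.n_individuals == 3
        assert two_site_geno.allele_counts("AAA", "L1") == {100: 3, 102: 2, 104: 1}


class TestSites:
    def test_reads_three_sites(self, tmp_path):
        p = tmp_path / "sites.csv"
        p.write_text("code,lat,lon,tmin\nA,50,8,1.0\nB,51,9,2.0\nC,52,10,3.0\n")
        with pytest.warns(UserWarning, match="expansion"):
            s = read_sites(p)
        assert s.codes == ["A", "B", "C"]
        assert s.climate_columns() == ["tmin"]
        assert set(s.frame["expansion"]) == {"hol"}

    def test_duplicate_codes_rejected(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text("code,lat,lon\nA,50,8\nA,51,9\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_sites(p)


class TestCollapseHaplotypes:
    def _write(self, tmp_path, seqs):
        p = tmp_path / "aln.fasta"
        p.write_text("".join(f">{k}\n{v}\n" for k, v in seqs.items()))
        return p

    def test_identical_sequences_share_one_haplotype(self, tmp_path):
        seq = "ACGT" * 110
        p = self._write(tmp_path, {f"s{i}": seq for i in range(3)})
        h = collapse_haplotypes(p, {f"s{i}": "A" for i in range(3)})
        assert h.counts == {"A": {"H001": 3}}

    def test_short_sequence_dropped_at_threshold(self, tmp_path):
        seq = "ACGT" * 110  # 440 positions
        short = "A" * 399 + "-" * 41
        p = self._write(tmp_path, {"long": seq, "short": short})
        h = collapse_haplotypes(p, {"long": "A", "short": "A"})
        assert h.site_total("A") == 1

    def test_single_difference_splits_haplotypes(self, tmp_path):
        seq = "ACGT" * 110
        seq2 = "T" + seq[1:]
        p = self._write(tmp_path, {"a": seq, "b": seq2})
        h = collapse_haplotypes(p, {"a": "A", "b": "A"})
        assert len(h.counts["A"]) == 2

    def test_input_order_invariance(self, tmp_path):
        seqs = {"a": "ACGT" * 110, "b": "TCGT" * 110, "c": "ACGT" * 110}
        assign = {k: "A" for k in seqs}
        p1 = self._write(tmp_path, seqs)
        h1 = collapse_haplotypes(p1, assign)
        p2 = self._write(tmp_path, dict(reversed(list(seqs.items()))))
        h2 = collapse_haplotypes(p2, assign)
        assert sorted(h1.counts["A"].values()) == sorted(h2.counts["A"].values())

    def test_unassigned_sequence_errors(self, tmp_path):
        p = self._write(tmp_path, {"a": "ACGT" * 110})
        with pytest.raises(KeyError, match="no site assignment"):
            collapse_haplotypes(p, {})


class TestValidation:
    def test_small_site_flagged_for_diversity_exclusion(self):
        from conftest import make_genotypes

        geno = make_genotypes(
            {"SML": [[(100, 102)] for _ in range(6)]}
        )
        issues = validate_dataset(geno, None, None)
        assert any("excluded from diversity" in i.message for i in issues)

    def test_unknown_site_code_is_fatal(self, two_site_geno, tmp_path):
        p = tmp_path / "sites.csv"
        p.write_text("code,lat,lon,expansion\nAAA,50,8,ref\n")
        sites = read_sites(p)
        issues = validate_dataset(two_site_geno, sites, None)
        assert any(i.level == "fatal" and "BBB" in i.message for i in issues)

    def test_consistent_inputs_have_no_fatal_issues(self, tmp_path):
        from conftest import make_genotypes

        geno = make_genotypes(
            {"AAA": [[(100, 102)] for _ in range(8)]}
        )
        p = tmp_path / "sites.csv"
        p.write_text("code,lat,lon,expansion\nAAA,50,8,ref\n")
        issues = validate_dataset(geno, read_sites(p), None)
        assert not [i for i in issues if i.level == "fatal"]
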