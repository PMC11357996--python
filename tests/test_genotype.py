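"""Molecule allele calls, the three-way cell rule, and the mutation matrix."""

import itertools

import pytest

import _oracles
from mutlink.align import AlignmentRecord, parse_cigar
from mutlink.genotype import (
    MutationMatrix,
    VariantSite,
    build_mutation_matrix,
    call_molecule,
    classify_cell,
    observed_mutation_frequency,
    read_sites,
)


def _aln(ref_start, cigar, contig="g"):
    return AlignmentRecord("m", contig, ref_start, parse_cigar(cigar))


class TestCallMoleculeSNV:
    SITE = VariantSite("g", 105, "C", "T")

    def test_alt_base(self):
        seq = "AAAA" + "T" + "AAAA"
        assert call_molecule(seq, _aln(101, "9M"), self.SITE).call == "alt"

    def test_ref_base(self):
        seq = "AAAA" + "C" + "AAAA"
        assert call_molecule(seq, _aln(101, "9M"), self.SITE).call == "ref"

    def test_other_base(self):
        seq = "AAAA" + "G" + "AAAA"
        assert call_molecule(seq, _aln(101, "9M"), self.SITE).call == "other"

    def test_site_deleted_or_uncovered_is_none(self):
        assert call_molecule("AAAAAAAA", _aln(101, "4M1D4M"), self.SITE).call == "none"
        assert call_molecule("AAA", _aln(101, "3M"), self.SITE).call == "none"
        assert call_molecule("AAA", _aln(101, "3M", contig="x"), self.SITE).call == "none"


class TestCallMoleculeIndel:
    DEL = VariantSite("g", 105, "CTG", "C", "del")  # deletes ref 106-107
    INS = VariantSite("g", 105, "C", "CAG", "ins")  # inserts AG after 105

    def test_deletion_allele(self):
        # read skips ref 106-107
        assert call_molecule("AAAACAAAA", _aln(101, "5M2D4M"), self.DEL).call == "alt"

    def test_deletion_ref_allele(self):
        seq = "AAAA" + "CTG" + "AAAA"
        assert call_molecule(seq, _aln(101, "11M"), self.DEL).call == "ref"

    def test_deletion_span_uncovered_is_none(self):
        assert call_molecule("AAAAC", _aln(101, "5M"), self.DEL).call == "none"

    def test_insertion_allele(self):
        seq = "AAAAC" + "AG" + "AAAA"
        assert call_molecule(seq, _aln(101, "5M2I4M"), self.INS).call == "alt"

    def test_insertion_ref_allele(self):
        assert call_molecule("AAAACAAAA", _aln(101, "9M"), self.INS).call == "ref"

    def test_wrong_insertion_is_other(self):
        seq = "AAAAC" + "GG" + "AAAA"
        assert call_molecule(seq, _aln(101, "5M2I4M"), self.INS).call == "other"


class TestClassifyCell:
    @pytest.mark.parametrize(
        "calls,expected",
        [
            (["alt"], "mutated"),
            (["ref", "alt"], "mutated"),
            (["alt", "alt", "ref"], "mutated"),
            ([], "no_coverage"),
            (["none", "none"], "no_coverage"),
            (["ref", "ref"], "non_mutated"),
            (["other"], "non_mutated"),  # coverage without mutant evidence
            (["ref", "none"], "non_mutated"),
        ],
    )
    def test_rule_table(self, calls, expected):
        assert classify_cell("bc", "s", calls).status == expected

    def test_exhaustive_multisets_vs_oracle(self):
        """All call multisets up to size 5 agree with the brute-force rule."""
        values = ("ref", "alt", "other", "none")
        for size in range(6):
            for combo in itertools.combinations_with_replacement(values, size):
                for min_alt in (1, 2):
                    got = classify_cell("bc", "s", list(combo), min_alt)
                    assert got.status == _oracles.classify_oracle(list(combo), min_alt)
                    assert got.n_alt_molecules == combo.count("alt")

    def test_min_alt_threshold(self):
        assert classify_cell("bc", "s", ["alt"], min_alt_molecules=2).status == "non_mutated"
        assert classify_cell("bc", "s", ["alt", "alt"], min_alt_molecules=2).status == "mutated"


class TestMutationMatrix:
    G = lambda self, bc, status: classify_cell(
        bc, "s", {"mutated": ["alt"], "non_mutated": ["ref"], "no_coverage": []}[status]
    )

    def test_missing_cells_become_no_coverage(self):
        genos = [self.G("b1", "mutated"), self.G("b2", "non_mutated")]
        mat = build_mutation_matrix(genos, ["b1", "b2", "b3"])
        assert mat.statuses("s")["b3"] == "no_coverage"
        assert mat.status_counts("s") == {
            "mutated": 1, "non_mutated": 1, "no_coverage": 1,
        }

    def test_row_order_follows_expression_barcodes(self):
        genos = [self.G("b2", "mutated"), self.G("b1", "non_mutated")]
        mat = build_mutation_matrix(genos, ["b1", "b2"])
        assert list(mat.table["cell_barcode"]) == ["b1", "b2"]

    def test_unknown_barcode_dropped_with_warning(self):
        genos = [self.G("b1", "mutated"), self.G("zz", "mutated")]
        with pytest.warns(UserWarning, match="dropped"):
            mat = build_mutation_matrix(genos, ["b1"])
        assert list(mat.table["cell_barcode"]) == ["b1"]

    def test_conflicting_duplicates_rejected(self):
        genos = [self.G("b1", "mutated"), self.G("b1", "non_mutated")]
        with pytest.raises(ValueError, match="conflict"):
            build_mutation_matrix(genos, ["b1"])

    def test_status_conservation(self):
        """Statuses over any site partition the expression barcode list."""
        genos = [self.G(f"b{i}", "mutated" if i % 3 == 0 else "non_mutated")
                 for i in range(7)]
        barcodes = [f"b{i}" for i in range(10)]
        mat = build_mutation_matrix(genos, barcodes)
        assert sum(mat.status_counts("s").values()) == len(barcodes)

    def test_tsv_round_trip(self, tmp_path):
        genos = [self.G("b1", "mutated"), self.G("b2", "non_mutated")]
        mat = build_mutation_matrix(genos, ["b1", "b2", "b3"])
        mat.to_tsv(tmp_path / "m.tsv")
        back = MutationMatrix.from_tsv(tmp_path / "m.tsv")
        assert back.table.equals(mat.table)


class TestObservedFrequency:
    def _matrix(self, n_mut, n_non, n_nc):
        genos = (
            [classify_cell(f"m{i}", "s", ["alt"]) for i in range(n_mut)]
            + [classify_cell(f"w{i}", "s", ["ref"]) for i in range(n_non)]
        )
        barcodes = [g.cell_barcode for g in genos] + [f"n{i}" for i in range(n_nc)]
        return build_mutation_matrix(genos, barcodes)

    def test_no_coverage_excluded_from_denominator(self):
        freq = observed_mutation_frequency(self._matrix(20, 60, 20), "s")
        assert freq.frequency == pytest.approx(0.25)
        assert freq.allele_frequency_estimate == pytest.approx(0.125)

    def test_zero_mutated(self):
        assert observed_mutation_frequency(self._matrix(0, 5, 0), "s").frequency == 0.0

    def test_no_covered_cells_flagged(self):
        with pytest.raises(ValueError, match="undefined"):
            observed_mutation_frequency(self._matrix(0, 0, 3), "s")


def test_read_sites_tsv_and_vcf(tmp_path):
    tsv = tmp_path / "sites.tsv"
    tsv.write_text("contig\tpos\tref\talt\tlabel\ng\t105\tC\tT\tR882H\n")
    (site,) = read_sites(tsv)
    assert (site.contig, site.pos, site.ref_allele, site.alt_allele) == ("g", 105, "C", "T")
    assert site.label == "R882H"

    vcf = tmp_path / "sites.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "g\t105\trs1\tC\tT\t.\t.\t.\n"
    )
    (site,) = read_sites(vcf)
    assert (site.contig, site.pos, site.label) == ("g", 105, "rs1")


def test_variant_site_kinds():
    assert VariantSite("g", 5, "C", "T").kind == "SNV"
    assert VariantSite("g", 5, "CTG", "C").kind == "deletion"
    assert VariantSite("g", 5, "C", "CAG").kind == "insertion"
    with pytest.raises(ValueError):
        VariantSite("g", 0, "C", "T")
    with pytest.raises(ValueError):
        VariantSite("g", 5, "C", "C")
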