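"""Genetic-code tables, codon algebra and codon-usage extraction."""

import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import framechannel as fc
from framechannel.genetic_code import (
    CODONS64,
    SENSE_CODONS,
    STOP_CODONS,
    InvalidCodonError,
    codon_usage_from_cds,
    count_cds_codons,
)


class TestGeneticCode:
    @pytest.mark.parametrize(
        "codon,expected", [("ATG", "M"), ("TAA", "*"), ("AAA", "K"),
                           ("TGG", "W"), ("TGA", "*")]
    )
    def test_translate_standard_codons(self, code, codon, expected):
        assert code.translate(codon) == expected

    def test_table_partitions_all_64_codons(self, code):
        assert len(CODONS64) == 64
        assert len(SENSE_CODONS) == 61
        assert set(STOP_CODONS) == {"TAA", "TAG", "TGA"}
        labels = [code.translate(c) for c in CODONS64]
        assert labels.count("*") == 3
        assert len(set(labels) - {"*"}) == 20
        # every amino acid has at least one codon
        for aa in code.amino_acids:
            assert labels.count(aa) >= 1

    def test_invalid_symbol_raises(self, code):
        with pytest.raises(InvalidCodonError):
            code.translate("AXG")
        with pytest.raises(InvalidCodonError):
            fc.reverse_complement("A-G")

    @pytest.mark.parametrize("codon,rc", [("ATG", "CAT"), ("TAA", "TTA")])
    def test_reverse_complement_examples(self, codon, rc):
        assert fc.reverse_complement(codon) == rc

    def test_reverse_complement_is_involution(self):
        for c in CODONS64:
            assert fc.reverse_complement(fc.reverse_complement(c)) == c


class TestCodonUsageFromCds:
    def test_single_cds_counts(self):
        u = codon_usage_from_cds(["ATGAAATAA"])
        assert u["ATG"] == pytest.approx(0.5)
        assert u["AAA"] == pytest.approx(0.5)
        assert u.freqs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_stops_excluded(self):
        u = codon_usage_from_cds(["ATGTGA", "ATGTAA"])
        assert u["ATG"] == pytest.approx(1.0)

    def test_partial_codon_truncated_with_warning(self):
        with pytest.warns(UserWarning, match="truncat"):
            u = codon_usage_from_cds(["ATGAAAC"])
        assert u["ATG"] == pytest.approx(0.5)

    def test_ambiguous_codons_skipped(self):
        counts = count_cds_codons(["ATGNNNAAA"])
        assert counts == {"ATG": 1, "AAA": 1}

    def test_empty_input_raises(self):
        with pytest.raises(ValueError, match="empty"):
            codon_usage_from_cds([])

    @given(st.lists(
        st.lists(st.sampled_from(SENSE_CODONS), min_size=1, max_size=30),
        min_size=1, max_size=5,
    ))
    @settings(max_examples=30, deadline=None)
    def test_usage_is_probability_vector_without_stop_mass(self, cds_codons):
        u = codon_usage_from_cds(["".join(c) for c in cds_codons])
        assert u.freqs.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(u.freqs >= 0)
        v = u.vector64
        for s in STOP_CODONS:
            assert v[fc.CODONS64.index(s)] == 0.0


class TestCodonUsageContainer:
    def test_tsv_round_trip(self, usage, tmp_path):
        p = tmp_path / "usage.tsv"
        usage.to_tsv(p)
        again = fc.CodonUsage.from_tsv(p)
        np.testing.assert_allclose(again.freqs, usage.freqs, atol=1e-9)

    def test_rejects_bad_vectors(self):
        with pytest.raises(ValueError):
            fc.CodonUsage(np.full(61, 0.5))
        with pytest.raises(ValueError):
            fc.CodonUsage(np.full(60, 1 / 60))

    def test_floor_removes_zeros(self):
        v = np.zeros(61)
        v[0] = 1.0
        u = fc.CodonUsage(v).with_floor(1e-6)
        assert u.freqs.min() > 0
        assert u.freqs.sum() == pytest.approx(1.0)


def _write_genbank(path):
    """Two-CDS synthetic GenBank record, one CDS on the minus strand."""
    from Bio.Seq import Seq
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    # plus-strand CDS: ATG AAA TAA at 0..9
    # minus-strand CDS: reverse complement of ATG CCC TAA at 12..21
    insert = str(Seq("ATGCCCTAA").reverse_complement())
    seq = Seq("ATGAAATAA" + "GGG" + insert + "AT")
    rec = SeqRecord(seq, id="SYN1", name="SYN1", description="synthetic",
                    annotations={"molecule_type": "DNA"})
    rec.features = [
        SeqFeature(FeatureLocation(0, 9, strand=1), type="CDS"),
        SeqFeature(FeatureLocation(12, 21, strand=-1), type="CDS"),
    ]
    SeqIO.write([rec], str(path), "genbank")
    return str(seq)


class TestGenomeReaders:
    def test_genbank_cds_extraction_is_strand_aware(self, tmp_path):
        gb = tmp_path / "syn.gb"
        _write_genbank(gb)
        u = fc.codon_usage_from_genbank(gb)
        # codons: ATG,AAA (plus) + ATG,CCC (minus); stops excluded
        assert u["ATG"] == pytest.approx(0.5)
        assert u["AAA"] == pytest.approx(0.25)
        assert u["CCC"] == pytest.approx(0.25)

    def test_fasta_reader_matches_direct_counts(self, tmp_path):
        fa = tmp_path / "cds.fa"
        fa.write_text(">a\nATGAAATAA\n>b\nATGTGA\n")
        u = fc.codon_usage_from_fasta(fa)
        assert u["ATG"] == pytest.approx(2 / 3)
        assert u["AAA"] == pytest.approx(1 / 3)

    def test_genome_summary_length_and_gc(self, tmp_path):
        gb = tmp_path / "syn.gb"
        seq = _write_genbank(gb)
        s = fc.genome_summary(gb)
        assert s["length_bp"] == len(seq)
        expected_gc = 100 * (seq.count("G") + seq.count("C")) / len(seq)
        assert s["gc_percent"] == pytest.approx(expected_gc)
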