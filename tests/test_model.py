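from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from domestiscan.model import (
    ClassifiedVariant,
    Genome,
    VariantCall,
    VariantStatus,
    VcfParseError,
    VType,
    allele_string,
    read_fasta,
    read_gff3,
    read_vcf,
    write_fasta,
    write_variant_table,
    write_vcf,
)
from helpers import naive_small_del_recall, small_del, small_ins, snp

MINUS = "−"


def write_lines(path, *lines):
    path.write_text("\n".join(lines) + "\n")


VCF_HEADER = ("##fileformat=VCFv4.2", "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")


class TestReadVcf:
    def test_insertion_record(self, tmp_path):
        # insertion serialized with its anchor; internally it sits after the anchor
        path = tmp_path / "a.vcf"
        write_lines(path, *VCF_HEADER, "V\t3556386\t.\tT\tTC\t80\t.\t.")
        (call,) = read_vcf(path, "LSJ1")
        assert call.vtype is VType.small_ins
        assert call.pos == 3556386
        assert call.length == 1
        assert call.alt_allele == "C"
        assert call.quality == 80
        assert call.source_strain == "LSJ1"

    def test_ref_equals_alt_is_parse_error(self, tmp_path):
        path = tmp_path / "a.vcf"
        write_lines(path, *VCF_HEADER, "I\t100\t.\tA\tA\t50\t.\t.")
        with pytest.raises(VcfParseError, match="3"):  # line number is named
            read_vcf(path)

    def test_deletion_coordinate_convention(self, tmp_path):
        # deleted base sits at the position after the VCF anchor
        path = tmp_path / "a.vcf"
        write_lines(path, *VCF_HEADER, "X\t3293917\t.\tAC\tA\t60\t.\t.")
        (call,) = read_vcf(path)
        assert call.vtype is VType.small_del
        assert call.pos == 3293918
        assert call.length == 1
        assert call.ref_allele == "C"

    def test_deletion_convention_against_string_edit(self, tmp_path):
        # oracle: apply the anchored VCF edit and the internal-convention edit
        # to a toy sequence and confirm they agree
        toy = "GGTACGTTG"  # anchor A at pos 4, deleted C at pos 5
        path = tmp_path / "a.vcf"
        write_lines(path, *VCF_HEADER, "chr\t4\t.\tAC\tA\t60\t.\t.")
        (call,) = read_vcf(path)
        vcf_edit = toy[:3] + "A" + toy[5:]  # REF "AC" -> ALT "A" at anchor 4
        i = call.pos - 1
        internal_edit = toy[:i] + toy[i + call.length :]
        assert vcf_edit == internal_edit
        assert call.pos == 5

    def test_missing_qual_rejected(self, tmp_path):
        path = tmp_path / "a.vcf"
        write_lines(path, *VCF_HEADER, "I\t100\t.\tA\tG\t.\t.\t.")
        with pytest.raises(VcfParseError, match="QUAL"):
            read_vcf(path)

    def test_ambig_flag(self, tmp_path):
        path = tmp_path / "a.vcf"
        write_lines(
            path,
            *VCF_HEADER,
            "I\t100\t.\tA\tG\t50\t.\tAMBIG",
            "I\t200\t.\tA\tG\t50\t.\tAMBIG=1",
            "I\t300\t.\tA\tG\t50\t.\t.",
        )
        calls = read_vcf(path)
        assert [c.ambiguous for c in calls] == [True, True, False]


class TestVariantCallInvariants:
    def test_snp_needs_distinct_alleles(self):
        with pytest.raises(ValueError):
            VariantCall("I", 5, "A", "A", VType.snp, 1)

    def test_position_must_be_positive(self):
        with pytest.raises(ValueError):
            snp("I", 0, "A", "G")

    def test_small_indel_length_bound(self):
        with pytest.raises(ValueError):
            VariantCall("I", 5, "", "ACGT", VType.small_ins, 4)

    def test_large_indel_accepts_gap_length(self):
        call = VariantCall("I", 5, "", "ACGT", VType.large_ins, 4, 40.0)
        assert call.length == 4


class TestVcfRoundTrip:
    @given(
        data=st.lists(
            st.tuples(
                st.sampled_from(["chr1", "chr2"]),
                st.integers(min_value=10, max_value=2900),
                st.sampled_from(["snp", "ins", "del"]),
                st.text(alphabet="ACGT", min_size=1, max_size=3),
                st.integers(min_value=0, max_value=500),
                st.booleans(),
            ),
            max_size=12,
            unique_by=lambda t: (t[0], t[1]),
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, tmp_path_factory, toy_genome, data):
        calls = []
        for chrom, pos, kind, seq, quality, ambig in data:
            if kind == "snp":
                ref = toy_genome.base(chrom, pos)
                alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
                calls.append(snp(chrom, pos, ref, alt, float(quality), ambig))
            elif kind == "ins":
                calls.append(small_ins(chrom, pos, seq, float(quality), ambig))
            else:
                ref = toy_genome.slice(chrom, pos, pos + len(seq) - 1)
                calls.append(small_del(chrom, pos, ref, float(quality), ambig))
        path = tmp_path_factory.mktemp("rt") / "rt.vcf"
        write_vcf(calls, path, toy_genome)
        back = read_vcf(path)
        assert sorted(back) == sorted(calls)

    def test_large_indel_round_trip(self, tmp_path, toy_genome):
        calls = [
            VariantCall("chr1", 100, "", "ACGTACGTA", VType.large_ins, 9, 50.0),
            VariantCall(
                "chr1", 500, toy_genome.slice("chr1", 500, 507), "", VType.large_del, 8, 1.0
            ),
        ]
        path = tmp_path / "rt.vcf"
        write_vcf(calls, path, toy_genome)
        assert sorted(read_vcf(path)) == sorted(calls)


class TestSmallDelOracle:
    def test_apply_then_recall(self, toy_genome):
        # applying a small_del then naively re-diffing recovers pos/length
        seq = toy_genome.sequences["chr1"]
        for pos, length in [(11, 1), (250, 2), (1000, 3)]:
            # placement is only unambiguous when the first deleted base differs
            # from the base that takes its place
            while seq[pos - 1] == seq[pos - 1 + length]:
                pos += 1
            ref = seq[pos - 1 : pos - 1 + length]
            edited = seq[: pos - 1] + seq[pos - 1 + length :]
            got_pos, got_len = naive_small_del_recall(seq, edited)
            assert (got_pos, got_len) == (pos, length)


class TestFasta:
    def test_two_records_sum_length(self, tmp_path):
        path = tmp_path / "a.fa"
        write_lines(path, ">a", "ACGTACGTAC", ">b", "TTTTTTTTTT")
        genome = read_fasta(path)
        assert genome.L == 20

    def test_lowercase_uppercased(self, tmp_path):
        path = tmp_path / "a.fa"
        write_lines(path, ">a", "acgt")
        assert read_fasta(path).sequences["a"] == "ACGT"

    def test_empty_file_errors(self, tmp_path):
        path = tmp_path / "a.fa"
        path.write_text("")
        with pytest.raises(ValueError):
            read_fasta(path)

    def test_duplicate_name_errors(self, tmp_path):
        path = tmp_path / "a.fa"
        write_lines(path, ">a", "ACGT", ">a", "ACGT")
        with pytest.raises(ValueError, match="duplicate"):
            read_fasta(path)

    def test_write_read_round_trip(self, tmp_path, toy_genome):
        path = tmp_path / "g.fa"
        write_fasta(toy_genome, path)
        assert read_fasta(path).sequences == toy_genome.sequences


GFF_HEADER = "##gff-version 3"


class TestGff3:
    def test_two_exon_plus_strand(self, tmp_path):
        path = tmp_path / "a.gff3"
        write_lines(
            path,
            GFF_HEADER,
            "I\t.\tgene\t100\t400\t.\t+\t.\tID=g1;biotype=protein_coding",
            "I\t.\tmRNA\t100\t400\t.\t+\t.\tID=t1;Parent=g1",
            "I\t.\tCDS\t300\t400\t.\t+\t0\tParent=t1",
            "I\t.\tCDS\t100\t200\t.\t+\t0\tParent=t1",
        )
        (model,) = read_gff3(path)
        assert model.cds_exons == ((100, 200), (300, 400))
        assert model.strand == "+"
        assert model.biotype.value == "protein_coding"

    def test_pseudogene_feature_type(self, tmp_path):
        path = tmp_path / "a.gff3"
        write_lines(
            path,
            GFF_HEADER,
            "X\t.\tpseudogene\t100\t200\t.\t+\t.\tID=g1",
            "X\t.\tpseudogenic_transcript\t100\t200\t.\t+\t.\tID=t1;Parent=g1",
            "X\t.\texon\t100\t200\t.\t+\t.\tParent=t1",
        )
        (model,) = read_gff3(path)
        assert model.biotype.value == "pseudogene"

    def test_minus_strand_keeps_genomic_order(self, tmp_path):
        path = tmp_path / "a.gff3"
        write_lines(
            path,
            GFF_HEADER,
            "I\t.\tgene\t100\t400\t.\t-\t.\tID=g1",
            "I\t.\tmRNA\t100\t400\t.\t-\t.\tID=t1;Parent=g1",
            "I\t.\tCDS\t100\t201\t.\t-\t0\tParent=t1",
            "I\t.\tCDS\t300\t400\t.\t-\t0\tParent=t1",
        )
        (model,) = read_gff3(path)
        assert model.strand == "-"
        assert model.cds_exons == ((100, 201), (300, 400))

    def test_orphan_cds_errors(self, tmp_path):
        path = tmp_path / "a.gff3"
        write_lines(
            path,
            GFF_HEADER,
            "I\t.\tCDS\t100\t200\t.\t+\t0\tParent=nosuch",
        )
        with pytest.raises(ValueError, match="parent"):
            read_gff3(path)


class TestVariantTable:
    def test_insertion_row(self, tmp_path):
        row = ClassifiedVariant(
            call=small_ins("V", 3556386, "C"),
            status=VariantStatus.reference_error,
            ancestral="LSJ1",
            gene_name="grd-30",
            gene_function="ground-like related",
        )
        path = tmp_path / "t.tsv"
        write_variant_table([row], path)
        lines = path.read_text().splitlines()
        assert lines[0].startswith("Chr\tVariation")
        assert lines[1] == "V\t3556386\tgrd-30\tground-like related\t+C/+C\tLSJ1"

    def test_deletion_allele_string(self):
        call = small_del("X", 3293917, "C")
        assert allele_string(call) == f"{MINUS}c/{MINUS}c"

    def test_snp_allele_string(self):
        assert allele_string(snp("I", 10, "A", "T")) == "T/T"

    def test_empty_list_header_only(self, tmp_path):
        path = tmp_path / "t.tsv"
        write_variant_table([], path)
        assert path.read_text().splitlines() == [
            "Chr\tVariation\tGene Name\tGene Function\tLSJ1_allele\tAncestral Status"
        ]

    def test_unannotated_variant_blank_columns(self, tmp_path):
        row = ClassifiedVariant(call=snp("I", 5, "A", "G"), status=VariantStatus.polymorphism)
        path = tmp_path / "t.tsv"
        write_variant_table([row], path)
        assert path.read_text().splitlines()[1] == "I\t5\t\t\tG/G\t"
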