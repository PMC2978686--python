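from __future__ import annotations

import numpy as np
import pytest

from domestiscan.effects import (
    EffectCategory,
    build_cds,
    classify_indel_effect,
    classify_snp_effect,
    reverse_complement,
    summarize_effects,
    translate,
)
from domestiscan.model import Biotype, GeneModel, Genome
from domestiscan.synth import SynthConfig, _place_genes
from helpers import (
    bio_translate,
    naive_cds_walk,
    oracle_snp_category,
    small_del,
    small_ins,
    snp,
)


def make_genome(seq: str, chrom: str = "chr") -> Genome:
    return Genome({chrom: seq})


def gene(cds, utr=(), strand="+", biotype=Biotype.protein_coding, chrom="chr"):
    return GeneModel(
        gene_id="g1",
        transcript_id="t1",
        chrom=chrom,
        strand=strand,
        cds_exons=tuple(cds),
        utr_exons=tuple(utr),
        biotype=biotype,
    )


class TestBuildCds:
    def test_plus_strand_concatenation(self):
        #        123456789012
        genome = make_genome("ATGAAATTTTAA")
        model = gene([(1, 6), (10, 12)])
        cds, mapping = build_cds(model, genome)
        assert cds == "ATGAAATAA"
        assert mapping[1] == 0 and mapping[6] == 5 and mapping[10] == 6

    def test_minus_strand_is_reverse_complement(self):
        genome = make_genome("ATGAAATTTTAA")
        plus = gene([(1, 6), (10, 12)])
        minus = gene([(1, 6), (10, 12)], strand="-")
        cds_plus, _ = build_cds(plus, genome)
        cds_minus, mapping = build_cds(minus, genome)
        assert cds_minus == reverse_complement(cds_plus)
        assert mapping[12] == 0  # genomically last base is first in CDS

    def test_out_of_bounds_errors(self):
        genome = make_genome("ATGAAA")
        with pytest.raises(ValueError, match="outside"):
            build_cds(gene([(1, 9)]), genome)

    def test_mapping_bijective_random_genes(self):
        rng = np.random.default_rng(3)
        bases = np.array(list("ACGT"))
        seq = "".join(bases[rng.integers(0, 4, size=5000)])
        genome = make_genome(seq)
        for start in (10, 500, 1200):
            exons = [(start, start + 89), (start + 150, start + 239), (start + 300, start + 320)]
            for strand in "+-":
                model = gene(exons, strand=strand)
                cds, mapping = build_cds(model, genome)
                assert len(mapping) == len(cds)
                assert sorted(mapping.values()) == list(range(len(cds)))
                # brute-force per-base walk oracle
                assert cds == naive_cds_walk(model, genome.sequences)
                for pos, idx in mapping.items():
                    expected = genome.base("chr", pos)
                    got = cds[idx]
                    if strand == "-":
                        got = reverse_complement(got)
                    assert got == expected


class TestSnpEffects:
    # layout: CDS 11..22 in "NNNNNNNNNN ATGTACTTTTGA ..." (1-based 11..22)
    SEQ = "GGGGGGGGGG" + "ATGTACTTTTGA" + "GGGGGGGGGG"

    def test_stop_gained(self):
        genome = make_genome(self.SEQ)
        model = gene([(11, 22)])
        # codon 2 is TAC (Tyr); C->A at pos 16 makes TAA
        effect = classify_snp_effect(snp("chr", 16, "C", "A"), [model], genome)
        assert effect.category is EffectCategory.stop_gained
        assert effect.codon_change == ("TAC", "TAA", 2)

    def test_synonymous_third_position(self):
        genome = make_genome(self.SEQ)
        model = gene([(11, 22)])
        # codon 3 TTT -> TTC, both Phe
        effect = classify_snp_effect(snp("chr", 19, "T", "C"), [model], genome)
        assert effect.category is EffectCategory.synonymous

    def test_stop_lost(self):
        genome = make_genome(self.SEQ)
        model = gene([(11, 22)])
        # codon 4 TGA -> TGG (Trp)
        effect = classify_snp_effect(snp("chr", 22, "A", "G"), [model], genome)
        assert effect.category is EffectCategory.stop_lost

    def test_intergenic_intronic_utr(self):
        genome = make_genome(self.SEQ + "G" * 40)
        model = gene([(11, 16), (21, 26)], utr=[(5, 10), (27, 32)])
        cases = {
            2: EffectCategory.intergenic,
            7: EffectCategory.utr,
            18: EffectCategory.intronic,
            30: EffectCategory.utr,
            50: EffectCategory.intergenic,
        }
        for pos, expected in cases.items():
            ref = genome.base("chr", pos)
            alt = "A" if ref != "A" else "C"
            effect = classify_snp_effect(snp("chr", pos, ref, alt), [model], genome)
            assert effect.category is expected, pos

    def test_ref_mismatch_raises(self):
        genome = make_genome(self.SEQ)
        model = gene([(11, 22)])
        with pytest.raises(ValueError, match="does not match"):
            classify_snp_effect(snp("chr", 16, "G", "A"), [model], genome)

    def test_pseudogene_hit(self):
        genome = make_genome(self.SEQ)
        model = gene([(11, 22)], biotype=Biotype.pseudogene)
        effect = classify_snp_effect(snp("chr", 16, "C", "A"), [model], genome)
        assert effect.category is EffectCategory.pseudogene_hit


class TestIndelEffects:
    SEQ = "G" * 10 + "ATGTACTTTTGA" + "G" * 10

    def test_one_bp_insertion_frameshift(self):
        genome = make_genome(self.SEQ)
        model = gene([(11, 22)])
        effect = classify_indel_effect(small_ins("chr", 15, "C"), [model], genome)
        assert effect.category is EffectCategory.frameshift

    def test_three_bp_insertion_inframe(self):
        genome = make_genome(self.SEQ)
        model = gene([(11, 22)])
        effect = classify_indel_effect(small_ins("chr", 15, "CCC"), [model], genome)
        assert effect.category is EffectCategory.inframe_single_aa

    def test_three_bp_deletion_inframe(self):
        genome = make_genome(self.SEQ)
        model = gene([(11, 22)])
        effect = classify_indel_effect(small_del("chr", 14, "TAC"), [model], genome)
        assert effect.category is EffectCategory.inframe_single_aa

    def test_pseudogene_indel(self):
        genome = make_genome(self.SEQ)
        model = gene([(11, 22)], biotype=Biotype.pseudogene)
        effect = classify_indel_effect(small_ins("chr", 15, "C"), [model], genome)
        assert effect.category is EffectCategory.pseudogene_hit

    def test_boundary_deletion_flagged_frameshift(self):
        genome = make_genome(self.SEQ)
        model = gene([(11, 16), (20, 25)])
        # deletion straddling the exon 1 / intron boundary
        effect = classify_indel_effect(small_del("chr", 15, "CTT"), [model], genome)
        assert effect.category is EffectCategory.frameshift
        assert effect.exon_boundary

    def test_intronic_insertion(self):
        genome = make_genome(self.SEQ)
        model = gene([(11, 14), (20, 25)])
        effect = classify_indel_effect(small_ins("chr", 16, "A"), [model], genome)
        assert effect.category is EffectCategory.intronic


class TestStrandEquivalence:
    def test_mirrored_construct_same_category(self):
        rng = np.random.default_rng(11)
        bases = np.array(list("ACGT"))
        seq = "".join(bases[rng.integers(0, 4, size=400)])
        genome = make_genome(seq)
        n = len(seq)
        exons = [(101, 190), (231, 320)]
        plus = gene(exons, strand="+")
        # mirror: reverse-complemented genome, intervals flipped, minus strand
        mirrored_genome = make_genome(reverse_complement(seq))
        flipped = tuple(
            sorted((n - e + 1, n - s + 1) for s, e in exons)
        )
        minus = gene(flipped, strand="-")
        for pos in range(101, 321, 7):
            ref = genome.base("chr", pos)
            alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
            eff_plus = classify_snp_effect(snp("chr", pos, ref, alt), [plus], genome)
            mpos = n - pos + 1
            mref = reverse_complement(ref)
            malt = reverse_complement(alt)
            eff_minus = classify_snp_effect(
                snp("chr", mpos, mref, malt), [minus], mirrored_genome
            )
            assert eff_plus.category is eff_minus.category, pos


class TestTranslationOracle:
    def test_translate_agrees_with_biopython(self):
        rng = np.random.default_rng(5)
        bases = np.array(list("ACGT"))
        for _ in range(50):
            cds = "".join(bases[rng.integers(0, 4, size=30)])
            assert translate(cds) == bio_translate(cds)

    def test_random_snps_match_brute_force_oracle(self):
        """Random SNPs over a synthetic annotation, checked against whole-protein
        re-translation."""
        rng = np.random.default_rng(99)
        config = SynthConfig(
            chrom_lengths=(("I", 30_000), ("II", 30_000)), n_genes=10, seed=99
        )
        genes = _place_genes(config, rng)
        bases = np.array(list("ACGT"))
        sequences = {
            name: "".join(bases[rng.integers(0, 4, size=length)])
            for name, length in config.chrom_lengths
        }
        genome = Genome(sequences)
        spans = [(g.chrom, *g.span) for g in genes]
        n_checked = 0
        for i in range(300):
            if i % 2 == 0:
                chrom, lo, hi = spans[rng.integers(0, len(spans))]
                pos = int(rng.integers(lo, hi + 1))
            else:
                chrom = ["I", "II"][rng.integers(0, 2)]
                pos = int(rng.integers(1, 30_001))
            ref = genome.base(chrom, pos)
            alt = "ACGT"[("ACGT".index(ref) + 1 + rng.integers(0, 3)) % 4]
            if alt == ref:
                continue
            call = snp(chrom, pos, ref, alt)
            got = classify_snp_effect(call, genes, genome).category
            want = oracle_snp_category(call, genes, genome)
            assert got is want, (chrom, pos, ref, alt)
            n_checked += 1
        assert n_checked > 250


class TestSummarize:
    def test_counts(self):
        from domestiscan.effects import CodingEffect

        errors = [
            CodingEffect(EffectCategory.nonsynonymous),
            CodingEffect(EffectCategory.nonsynonymous),
            CodingEffect(EffectCategory.frameshift),
            CodingEffect(EffectCategory.pseudogene_hit),
        ]
        polys = [CodingEffect(EffectCategory.synonymous)]
        table = summarize_effects(errors, polys)
        assert table.loc["nonsynonymous", "reference_errors"] == 2
        assert table.loc["frameshift", "reference_errors"] == 1
        assert table.loc["pseudogene_hit", "reference_errors"] == 1
        assert table.loc["synonymous", "polymorphisms"] == 1
        assert table.loc["exonic", "reference_errors"] == 4

    def test_empty_inputs_all_zero(self):
        table = summarize_effects([], [])
        assert (table == 0).all().all()

    def test_categories_mutually_exclusive(self, noiseless_dataset):
        # each truth record got exactly one category
        effects = [r.coding_effect for r in noiseless_dataset.truth.records]
        assert all(e in {c.value for c in EffectCategory} for e in effects)
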