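"""Coding-consequence classification of SNPs and indels against gene models.

Effects are computed per transcript and summarized per variant by picking the
most severe category.  Categories form a fixed severity order; indels whose
length is not a multiple of 3 inside a coding sequence are frameshifts, 3-bp
indels change a single amino acid, and any exonic hit to a transcript
annotated as a pseudogene is reported as ``pseudogene_hit`` (such sites are
candidates for restoring a functional reading frame when the reference is
corrected).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .model import Biotype, GeneModel, Genome, VariantCall, VType

__all__ = [
    "EffectCategory",
    "CodingEffect",
    "SEVERITY_ORDER",
    "build_cds",
    "classify_snp_effect",
    "classify_indel_effect",
    "classify_effect",
    "summarize_effects",
    "translate",
    "reverse_complement",
]


class EffectCategory(str, enum.Enum):
    intergenic = "intergenic"
    intronic = "intronic"
    utr = "utr"
    synonymous = "synonymous"
    nonsynonymous = "nonsynonymous"
    stop_gained = "stop_gained"
    stop_lost = "stop_lost"
    inframe_single_aa = "inframe_single_aa"
    frameshift = "frameshift"
    pseudogene_hit = "pseudogene_hit"


#: most severe first
SEVERITY_ORDER: tuple[EffectCategory, ...] = (
    EffectCategory.stop_gained,
    EffectCategory.stop_lost,
    EffectCategory.frameshift,
    EffectCategory.inframe_single_aa,
    EffectCategory.nonsynonymous,
    EffectCategory.pseudogene_hit,
    EffectCategory.utr,
    EffectCategory.synonymous,
    EffectCategory.intronic,
    EffectCategory.intergenic,
)

_SEVERITY_RANK = {cat: i for i, cat in enumerate(SEVERITY_ORDER)}

STOP_CODONS = {"TAA", "TAG", "TGA"}

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    """Translate a nucleotide sequence codon by codon (standard nuclear table).

    Trailing bases that do not fill a codon are ignored; stop codons appear
    as ``*`` and do not terminate translation (we compare whole proteins).
    """
    return "".join(
        _CODON_TABLE.get(cds[i : i + 3], "X") for i in range(0, len(cds) - 2, 3)
    )


@dataclass(frozen=True)
class CodingEffect:
    category: EffectCategory
    gene_id: str = ""
    transcript_id: str = ""
    codon_change: Optional[tuple[str, str, int]] = None  # (ref_codon, alt_codon, aa_pos)
    exon_boundary: bool = False

    @property
    def severity(self) -> int:
        return _SEVERITY_RANK[self.category]


def build_cds(gene: GeneModel, genome: Genome) -> tuple[str, dict[int, int]]:
    """Concatenate a transcript's coding exons 5'->3'.

    Returns the CDS string and a bijective map from genomic position (1-based)
    to 0-based CDS index.  Minus-strand transcripts are reverse-complemented,
    so index 0 is the genomically last coding base.
    """
    chrom_len = len(genome.sequences[gene.chrom])
    for start, end in gene.cds_exons:
        if start < 1 or end > chrom_len:
            raise ValueError(
                f"CDS interval {(start, end)} outside chromosome {gene.chrom} "
                f"of length {chrom_len}"
            )
    forward = "".join(genome.slice(gene.chrom, s, e) for s, e in gene.cds_exons)
    positions = [p for s, e in gene.cds_exons for p in range(s, e + 1)]
    if gene.strand == "+":
        cds = forward
        mapping = {pos: i for i, pos in enumerate(positions)}
    else:
        cds = reverse_complement(forward)
        n = len(positions)
        mapping = {pos: n - 1 - i for i, pos in enumerate(positions)}
    return cds, mapping


def _in_intervals(pos: int, intervals: Iterable[tuple[int, int]]) -> bool:
    return any(s <= pos <= e for s, e in intervals)


def _overlaps(lo: int, hi: int, intervals: Iterable[tuple[int, int]]) -> bool:
    return any(s <= hi and lo <= e for s, e in intervals)


def classify_snp_effect(
    call: VariantCall, genes: Sequence[GeneModel], genome: Genome
) -> CodingEffect:
    """Classify a SNP against all overlapping transcripts; most severe wins."""
    if call.vtype is not VType.snp:
        raise ValueError("classify_snp_effect expects a SNP")
    effects = []
    for gene in genes:
        if gene.chrom != call.chrom:
            continue
        span = gene.span
        if not span[0] <= call.pos <= span[1]:
            continue
        effects.append(_snp_effect_on_transcript(call, gene, genome))
    if not effects:
        return CodingEffect(EffectCategory.intergenic)
    return min(effects, key=lambda e: e.severity)


def _snp_effect_on_transcript(
    call: VariantCall, gene: GeneModel, genome: Genome
) -> CodingEffect:
    in_cds = _in_intervals(call.pos, gene.cds_exons)
    in_utr = _in_intervals(call.pos, gene.utr_exons)
    if gene.biotype is Biotype.pseudogene:
        if in_cds or in_utr:
            return CodingEffect(
                EffectCategory.pseudogene_hit, gene.gene_id, gene.transcript_id
            )
        return CodingEffect(EffectCategory.intronic, gene.gene_id, gene.transcript_id)
    if in_cds:
        ref_base = genome.base(call.chrom, call.pos)
        if ref_base != call.ref_allele:
            raise ValueError(
                f"reference allele {call.ref_allele} at {call.chrom}:{call.pos} "
                f"does not match genome base {ref_base}"
            )
        cds, mapping = build_cds(gene, genome)
        idx = mapping[call.pos]
        alt = call.alt_allele
        if gene.strand == "-":
            alt = reverse_complement(alt)
        codon_start = (idx // 3) * 3
        ref_codon = cds[codon_start : codon_start + 3]
        offset = idx - codon_start
        alt_codon = ref_codon[:offset] + alt + ref_codon[offset + 1 :]
        aa_pos = idx // 3 + 1
        change = (ref_codon, alt_codon, aa_pos)
        ref_stop = ref_codon in STOP_CODONS
        alt_stop = alt_codon in STOP_CODONS
        if alt_stop and not ref_stop:
            cat = EffectCategory.stop_gained
        elif ref_stop and not alt_stop:
            cat = EffectCategory.stop_lost
        elif _CODON_TABLE[ref_codon] == _CODON_TABLE[alt_codon]:
            cat = EffectCategory.synonymous
        else:
            cat = EffectCategory.nonsynonymous
        return CodingEffect(cat, gene.gene_id, gene.transcript_id, change)
    if in_utr:
        return CodingEffect(EffectCategory.utr, gene.gene_id, gene.transcript_id)
    return CodingEffect(EffectCategory.intronic, gene.gene_id, gene.transcript_id)


def classify_indel_effect(
    call: VariantCall, genes: Sequence[GeneModel], genome: Genome
) -> CodingEffect:
    """Classify an indel against all overlapping transcripts; most severe wins.

    Deletions occupy ``[pos, pos + length - 1]``; insertions sit between
    ``pos`` and ``pos + 1`` and are exonic only when both flanking bases are.
    A deletion partially overlapping a coding exon is reported as a frameshift
    with ``exon_boundary=True`` (splice consequences are not modelled).
    """
    if call.vtype is VType.snp:
        raise ValueError("classify_indel_effect expects an indel")
    if call.vtype.is_deletion:
        lo, hi = call.pos, call.pos + call.length - 1
    else:
        lo, hi = call.pos, call.pos + 1
    effects = []
    for gene in genes:
        if gene.chrom != call.chrom:
            continue
        span = gene.span
        if hi < span[0] or lo > span[1]:
            continue
        effects.append(_indel_effect_on_transcript(call, lo, hi, gene))
    if not effects:
        return CodingEffect(EffectCategory.intergenic)
    return min(effects, key=lambda e: e.severity)


def _indel_effect_on_transcript(
    call: VariantCall, lo: int, hi: int, gene: GeneModel
) -> CodingEffect:
    if call.vtype.is_insertion:
        touches_cds = _in_intervals(lo, gene.cds_exons) and _in_intervals(hi, gene.cds_exons)
        fully_inside = touches_cds
        touches_utr = _in_intervals(lo, gene.utr_exons) and _in_intervals(hi, gene.utr_exons)
    else:
        touches_cds = _overlaps(lo, hi, gene.cds_exons)
        fully_inside = any(s <= lo and hi <= e for s, e in gene.cds_exons)
        touches_utr = _overlaps(lo, hi, gene.utr_exons)
    if gene.biotype is Biotype.pseudogene:
        if touches_cds or touches_utr:
            return CodingEffect(
                EffectCategory.pseudogene_hit, gene.gene_id, gene.transcript_id
            )
        return CodingEffect(EffectCategory.intronic, gene.gene_id, gene.transcript_id)
    if touches_cds:
        boundary = not fully_inside
        if boundary or call.length % 3 != 0:
            return CodingEffect(
                EffectCategory.frameshift,
                gene.gene_id,
                gene.transcript_id,
                exon_boundary=boundary,
            )
        return CodingEffect(
            EffectCategory.inframe_single_aa, gene.gene_id, gene.transcript_id
        )
    if touches_utr:
        return CodingEffect(EffectCategory.utr, gene.gene_id, gene.transcript_id)
    return CodingEffect(EffectCategory.intronic, gene.gene_id, gene.transcript_id)


def classify_effect(
    call: VariantCall, genes: Sequence[GeneModel], genome: Genome
) -> CodingEffect:
    if call.vtype is VType.snp:
        return classify_snp_effect(call, genes, genome)
    return classify_indel_effect(call, genes, genome)


def summarize_effects(
    classified_errors: Sequence[CodingEffect],
    classified_polymorphisms: Sequence[CodingEffect],
) -> pd.DataFrame:
    """Per-category counts for the error and polymorphism sets.

    ``exonic`` counts CDS-consequence categories plus UTR hits; the two
    components are also reported separately.
    """
    rows = {}
    for name, effects in (
        ("reference_errors", classified_errors),
        ("polymorphisms", classified_polymorphisms),
    ):
        counts = {cat.value: 0 for cat in EffectCategory}
        for e in effects:
            counts[e.category.value] += 1
        cds_cats = (
            EffectCategory.synonymous,
            EffectCategory.nonsynonymous,
            EffectCategory.stop_gained,
            EffectCategory.stop_lost,
            EffectCategory.inframe_single_aa,
            EffectCategory.frameshift,
            EffectCategory.pseudogene_hit,
        )
        counts["exonic_cds"] = sum(counts[c.value] for c in cds_cats)
        counts["exonic_utr"] = counts[EffectCategory.utr.value]
        counts["exonic"] = counts["exonic_cds"] + counts["exonic_utr"]
        rows[name] = counts
    return pd.DataFrame(rows)
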