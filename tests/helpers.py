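"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own classification paths: CDS
extraction walks intervals base by base, translation goes through Biopython,
and categories are derived by diffing whole mutant proteins.
"""

from __future__ import annotations

from Bio.Seq import Seq

from domestiscan.effects import SEVERITY_ORDER, EffectCategory
from domestiscan.model import Biotype, GeneModel, Genome, VariantCall, VType
from domestiscan.polarize import AncestralCall, AncestralState
from domestiscan.model import Allele, GenotypeObservation

_RANK = {cat: i for i, cat in enumerate(SEVERITY_ORDER)}

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def naive_cds_walk(gene: GeneModel, sequences: dict[str, str]) -> str:
    """Per-base walk over CDS intervals; reverse-complement for minus strand."""
    bases = []
    for start, end in gene.cds_exons:
        for p in range(start, end + 1):
            bases.append(sequences[gene.chrom][p - 1])
    seq = "".join(bases)
    return revcomp(seq) if gene.strand == "-" else seq


def bio_translate(cds: str) -> str:
    usable = cds[: len(cds) - len(cds) % 3]
    return str(Seq(usable).translate())


def _stop_positions(protein: str) -> set[int]:
    return {i for i, aa in enumerate(protein) if aa == "*"}


def oracle_snp_category(
    call: VariantCall, genes: list[GeneModel], genome: Genome
) -> EffectCategory:
    """Classify a SNP by brute-force mutant-CDS translation."""
    cats = []
    for gene in genes:
        if gene.chrom != call.chrom:
            continue
        exons = gene.cds_exons + gene.utr_exons
        lo = min(s for s, _ in exons)
        hi = max(e for _, e in exons)
        if not lo <= call.pos <= hi:
            continue
        in_cds = any(s <= call.pos <= e for s, e in gene.cds_exons)
        in_utr = any(s <= call.pos <= e for s, e in gene.utr_exons)
        if gene.biotype is Biotype.pseudogene:
            cats.append(
                EffectCategory.pseudogene_hit if (in_cds or in_utr) else EffectCategory.intronic
            )
            continue
        if in_cds:
            mutated = dict(genome.sequences)
            seq = mutated[call.chrom]
            i = call.pos - 1
            assert seq[i] == call.ref_allele
            mutated[call.chrom] = seq[:i] + call.alt_allele + seq[i + 1 :]
            ref_prot = bio_translate(naive_cds_walk(gene, genome.sequences))
            alt_prot = bio_translate(naive_cds_walk(gene, mutated))
            ref_stops = _stop_positions(ref_prot)
            alt_stops = _stop_positions(alt_prot)
            if alt_stops - ref_stops:
                cats.append(EffectCategory.stop_gained)
            elif ref_stops - alt_stops:
                cats.append(EffectCategory.stop_lost)
            elif ref_prot != alt_prot:
                cats.append(EffectCategory.nonsynonymous)
            else:
                cats.append(EffectCategory.synonymous)
        elif in_utr:
            cats.append(EffectCategory.utr)
        else:
            cats.append(EffectCategory.intronic)
    if not cats:
        return EffectCategory.intergenic
    return min(cats, key=lambda c: _RANK[c])


def naive_small_del_recall(original: str, edited: str) -> tuple[int, int]:
    """Locate a single small deletion by naive string diff; returns (pos, length)."""
    n = len(original) - len(edited)
    assert n > 0
    i = 0
    while i < len(edited) and original[i] == edited[i]:
        i += 1
    return i + 1, n


def naive_genome_diff(ref: str, other: str, context: int = 6) -> list[tuple]:
    """Recover well-separated snp/ins/del events between two sequences.

    Events are reported in the internal coordinate convention: deletions at
    the first deleted reference base, insertions after the last matching
    reference base.  Requires events separated by more than ``context`` bases.
    """
    events = []
    i = j = 0
    while i < len(ref) or j < len(other):
        if i < len(ref) and j < len(other) and ref[i] == other[j]:
            i += 1
            j += 1
            continue
        if (
            i < len(ref)
            and j < len(other)
            and ref[i + 1 : i + 1 + context] == other[j + 1 : j + 1 + context]
        ):
            events.append(("snp", i + 1, ref[i], other[j]))
            i += 1
            j += 1
            continue
        for length in (1, 2, 3):
            if ref[i + length : i + length + context] == other[j : j + context]:
                events.append(("del", i + 1, ref[i : i + length], ""))
                i += length
                break
            if ref[i : i + context] == other[j + length : j + length + context]:
                events.append(("ins", i, "", other[j : j + length]))
                j += length
                break
        else:
            raise AssertionError(f"could not resolve difference at ref index {i}")
    return events


def make_ancestral(state: AncestralState) -> AncestralCall:
    """Construct a polarization call with dummy outgroup support."""
    allele = {
        AncestralState.ancestral_N2: Allele.reference_like,
        AncestralState.ancestral_LSJ1: Allele.focal_like,
        AncestralState.unknown: Allele.missing,
    }[state]
    obs = (GenotypeObservation("og1", allele), GenotypeObservation("og2", allele))
    return AncestralCall(state, obs)


def snp(chrom: str, pos: int, ref: str, alt: str, quality: float = 99.0,
        ambiguous: bool = False) -> VariantCall:
    return VariantCall(chrom, pos, ref, alt, VType.snp, 1, quality, ambiguous)


def small_ins(chrom: str, pos: int, seq: str, quality: float = 99.0,
              ambiguous: bool = False) -> VariantCall:
    return VariantCall(chrom, pos, "", seq, VType.small_ins, len(seq), quality, ambiguous)


def small_del(chrom: str, pos: int, seq: str, quality: float = 99.0,
              ambiguous: bool = False) -> VariantCall:
    return VariantCall(chrom, pos, seq, "", VType.small_del, len(seq), quality, ambiguous)
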