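"""Domain types and readers/writers for the standard formats the pipeline touches.

Coordinate conventions
----------------------
Internally, indels are stored *unanchored*:

* an insertion at ``pos`` places ``alt_allele`` **after** reference base ``pos``;
* a deletion at ``pos`` removes ``ref_allele`` starting **at** ``pos``.

VCF uses left-anchored ref/alt pairs; :func:`read_vcf` converts anchored
records into this convention and :func:`write_vcf` converts back (it needs the
reference genome to recover the anchor base).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "VType",
    "Allele",
    "VariantStatus",
    "VariantCall",
    "GenotypeObservation",
    "GeneModel",
    "Genome",
    "ClassifiedVariant",
    "VcfParseError",
    "read_vcf",
    "write_vcf",
    "read_fasta",
    "read_gff3",
    "write_variant_table",
    "allele_string",
]

SMALL_INDEL_MAX = 3  # bp; anything longer is "large"
LARGE_DEL_MAX = 10_000
LARGE_INS_MAX = 33

#: character used for deletion alleles in output tables (true minus sign)
MINUS = "−"


class VType(str, enum.Enum):
    snp = "snp"
    small_ins = "small_ins"
    small_del = "small_del"
    large_ins = "large_ins"
    large_del = "large_del"

    @property
    def is_insertion(self) -> bool:
        return self in (VType.small_ins, VType.large_ins)

    @property
    def is_deletion(self) -> bool:
        return self in (VType.small_del, VType.large_del)

    @property
    def is_indel(self) -> bool:
        return self is not VType.snp


class Allele(str, enum.Enum):
    """What a strain shows at a candidate site."""

    reference_like = "reference_like"
    focal_like = "focal_like"
    missing = "missing"


class VariantStatus(str, enum.Enum):
    reference_error = "reference_error"
    polymorphism = "polymorphism"


class VcfParseError(ValueError):
    """Raised for malformed or degenerate VCF records; names the line number."""


_BASES = set("ACGT")


@dataclass(frozen=True, order=True)
class VariantCall:
    """One candidate difference between the focal strain and the reference."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    vtype: VType
    length: int
    quality: float = 0.0
    ambiguous: bool = False
    source_strain: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.quality < 0:
            raise ValueError(f"quality must be >= 0, got {self.quality}")
        if self.length < 1:
            raise ValueError(f"length must be positive, got {self.length}")
        vt = self.vtype
        if vt is VType.snp:
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise ValueError("snp alleles must be single bases")
            if self.ref_allele == self.alt_allele:
                raise ValueError("snp ref and alt alleles must differ")
            if self.length != 1:
                raise ValueError("snp length must be 1")
        elif vt.is_insertion:
            if self.ref_allele:
                raise ValueError("insertion stores inserted bases in alt_allele only")
            if len(self.alt_allele) != self.length:
                raise ValueError("insertion length must match alt_allele")
        elif vt.is_deletion:
            if self.alt_allele:
                raise ValueError("deletion stores deleted bases in ref_allele only")
            if len(self.ref_allele) != self.length:
                raise ValueError("deletion length must match ref_allele")
        if vt in (VType.small_ins, VType.small_del) and not 1 <= self.length <= SMALL_INDEL_MAX:
            raise ValueError(f"small indel length must be 1-{SMALL_INDEL_MAX}")
        if vt in (VType.large_ins, VType.large_del) and self.length <= SMALL_INDEL_MAX:
            raise ValueError(f"large indel length must exceed {SMALL_INDEL_MAX}")
        if vt is VType.large_del and self.length > LARGE_DEL_MAX:
            warnings.warn(f"large deletion of {self.length} bp exceeds detection bound")
        if vt is VType.large_ins and self.length > LARGE_INS_MAX:
            warnings.warn(f"large insertion of {self.length} bp exceeds detection bound")

    @property
    def site_key(self) -> tuple[str, int, str, str]:
        """Exact-allele identity used to match sites across strains."""
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)

    @property
    def is_small(self) -> bool:
        return self.vtype in (VType.snp, VType.small_ins, VType.small_del)


@dataclass(frozen=True)
class GenotypeObservation:
    """Per-strain observation at one site.

    ``missing`` means no informative coverage and is never treated as
    ``reference_like``.
    """

    strain: str
    allele: Allele


class Biotype(str, enum.Enum):
    protein_coding = "protein_coding"
    pseudogene = "pseudogene"


@dataclass(frozen=True)
class GeneModel:
    """One transcript's worth of gene structure, in genomic coordinates.

    ``cds_exons`` and ``utr_exons`` are 1-based closed intervals sorted by
    genomic coordinate regardless of strand.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    cds_exons: tuple[tuple[int, int], ...]
    utr_exons: tuple[tuple[int, int], ...] = ()
    biotype: Biotype = Biotype.protein_coding
    gene_name: str = ""
    gene_function: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        prev_end = 0
        for start, end in self.cds_exons:
            if start > end:
                raise ValueError(f"bad interval {(start, end)}")
            if start <= prev_end:
                raise ValueError("cds_exons must be sorted and non-overlapping")
            prev_end = end
        cds_len = sum(end - start + 1 for start, end in self.cds_exons)
        if self.biotype is Biotype.protein_coding and cds_len % 3 != 0:
            warnings.warn(
                f"CDS length {cds_len} of {self.transcript_id} not divisible by 3"
            )

    @property
    def span(self) -> tuple[int, int]:
        """Genomic extent covered by any exon of this transcript."""
        exons = self.cds_exons + self.utr_exons
        return (min(s for s, _ in exons), max(e for _, e in exons))


@dataclass
class Genome:
    """Reference sequences keyed by chromosome name."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError("genome must contain sequence")
        for name, seq in self.sequences.items():
            bad = set(seq) - set("ACGTN")
            if bad:
                raise ValueError(f"unexpected characters {sorted(bad)} in {name}")

    @property
    def L(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def base(self, chrom: str, pos: int) -> str:
        """1-based single-base lookup."""
        return self.sequences[chrom][pos - 1]

    def slice(self, chrom: str, start: int, end: int) -> str:
        """1-based closed-interval substring."""
        return self.sequences[chrom][start - 1 : end]


@dataclass
class ClassifiedVariant:
    """A call plus everything the pipeline has learned about it."""

    call: VariantCall
    status: VariantStatus
    support_count: int = 0
    ancestral: str = ""  # "N2" | "LSJ1" | "unknown" | ""
    gene_name: str = ""
    gene_function: str = ""
    effect: str = ""


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _classify_lengths(ref: str, alt: str) -> tuple[VType, int]:
    if len(ref) == len(alt) == 1:
        return VType.snp, 1
    diff = abs(len(ref) - len(alt))
    if len(ref) > len(alt):
        return (VType.small_del if diff <= SMALL_INDEL_MAX else VType.large_del), diff
    return (VType.small_ins if diff <= SMALL_INDEL_MAX else VType.large_ins), diff


def read_vcf(path: str | Path, strain_id: str = "") -> list[VariantCall]:
    """Read a single-sample VCF into a list of :class:`VariantCall`.

    Anchored indel records are converted to the unanchored internal
    convention (insertions after ``pos``, deletions starting at ``pos``).
    QUAL is required; the optional INFO key ``AMBIG=1`` marks ambiguous
    placement.
    """
    calls: list[VariantCall] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise VcfParseError(f"{path}:{lineno}: expected >= 8 columns")
            chrom, pos_s, _id, ref, alt, qual_s, _filt, info = fields[:8]
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise VcfParseError(f"{path}:{lineno}: bad POS {pos_s!r}") from exc
            ref = ref.upper()
            alt = alt.upper()
            if "," in alt:
                raise VcfParseError(f"{path}:{lineno}: multi-allelic records unsupported")
            if ref == alt:
                raise VcfParseError(f"{path}:{lineno}: REF equals ALT")
            if not (set(ref) <= _BASES and set(alt) <= _BASES):
                raise VcfParseError(f"{path}:{lineno}: non-ACGT allele")
            if qual_s in (".", ""):
                raise VcfParseError(
                    f"{path}:{lineno}: QUAL is required by downstream filters"
                )
            quality = float(qual_s)
            ambiguous = _info_flag(info, "AMBIG")
            vtype, length = _classify_lengths(ref, alt)
            if vtype is VType.snp:
                call = VariantCall(chrom, pos, ref, alt, vtype, 1, quality, ambiguous, strain_id)
            else:
                if ref[0] != alt[0] or min(len(ref), len(alt)) != 1:
                    raise VcfParseError(
                        f"{path}:{lineno}: complex allele pair {ref}/{alt}; "
                        "expected a single shared anchor base"
                    )
                if vtype.is_insertion:
                    # inserted bases go after the anchor coordinate
                    call = VariantCall(
                        chrom, pos, "", alt[1:], vtype, length, quality, ambiguous, strain_id
                    )
                else:
                    # first deleted base is the position after the anchor
                    call = VariantCall(
                        chrom, pos + 1, ref[1:], "", vtype, length, quality, ambiguous, strain_id
                    )
            calls.append(call)
    return calls


def _info_flag(info: str, key: str) -> bool:
    for item in info.split(";"):
        if item == key:
            return True
        if "=" in item:
            k, v = item.split("=", 1)
            if k == key:
                return v not in ("0", "", "false")
    return False


def write_vcf(
    calls: Iterable[VariantCall], path: str | Path, genome: Genome, source: str = "domestiscan"
) -> None:
    """Write calls as VCF 4.2, re-anchoring indels against ``genome``."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##source={source}",
        '##INFO=<ID=AMBIG,Number=0,Type=Flag,Description="Ambiguous placement">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    ordered = sorted(calls, key=lambda c: (c.chrom, c.pos, c.ref_allele, c.alt_allele))
    for call in ordered:
        if call.vtype is VType.snp:
            pos, ref, alt = call.pos, call.ref_allele, call.alt_allele
        elif call.vtype.is_insertion:
            anchor = genome.base(call.chrom, call.pos)
            pos, ref, alt = call.pos, anchor, anchor + call.alt_allele
        else:
            if call.pos < 2:
                raise ValueError("cannot anchor a deletion starting at position 1")
            anchor = genome.base(call.chrom, call.pos - 1)
            pos, ref, alt = call.pos - 1, anchor + call.ref_allele, anchor
        info = "AMBIG" if call.ambiguous else "."
        qual = f"{call.quality:g}"
        lines.append(f"{call.chrom}\t{pos}\t.\t{ref}\t{alt}\t{qual}\t.\t{info}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> Genome:
    """Read a FASTA file into a :class:`Genome`; sequences are uppercased."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate sequence name {record.id!r} in {path}")
        sequences[record.id] = str(record.seq).upper()
    if not sequences:
        raise ValueError(f"no sequences found in {path}")
    return Genome(sequences)


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as out:
        for name, seq in genome.sequences.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3, one :class:`GeneModel` per transcript.

    Biotype comes from a ``biotype``/``gene_biotype`` attribute or from the
    parent feature type being ``pseudogene``.  Pseudogene transcripts that
    carry only ``exon`` children use those exons as their coding intervals
    (the annotation of a former coding structure).
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    known_ids = {f.id for f in db.all_features()}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent", [])
        if not parents or any(p not in known_ids for p in parents):
            raise ValueError(f"CDS at {cds.seqid}:{cds.start} has no parent transcript")

    models: list[GeneModel] = []
    for ttype in ("mRNA", "transcript", "pseudogenic_transcript"):
        for tx in db.features_of_type(ttype):
            gene_id, biotype, gene_name, gene_function = tx.id, None, "", ""
            for parent in db.parents(tx, level=1):
                gene_id = parent.id
                gene_name = _first_attr(parent, "Name", "gene_name") or gene_name
                gene_function = _first_attr(parent, "description", "function") or ""
                if parent.featuretype == "pseudogene":
                    biotype = Biotype.pseudogene
                attr = _first_attr(parent, "biotype", "gene_biotype")
                if attr:
                    biotype = Biotype(attr)
            attr = _first_attr(tx, "biotype", "transcript_biotype")
            if attr:
                biotype = Biotype(attr)
            if ttype == "pseudogenic_transcript" and biotype is None:
                biotype = Biotype.pseudogene
            if biotype is None:
                biotype = Biotype.protein_coding

            cds = sorted(
                (f.start, f.end) for f in db.children(tx, featuretype="CDS", level=1)
            )
            utr = sorted(
                (f.start, f.end)
                for f in db.children(tx, level=1)
                if f.featuretype in ("five_prime_UTR", "three_prime_UTR", "UTR")
            )
            if not cds:
                # pseudogenes are often annotated with bare exons
                cds = sorted(
                    (f.start, f.end)
                    for f in db.children(tx, featuretype="exon", level=1)
                )
            if not cds:
                continue
            models.append(
                GeneModel(
                    gene_id=gene_id,
                    transcript_id=tx.id,
                    chrom=tx.seqid,
                    strand=tx.strand,
                    cds_exons=tuple(cds),
                    utr_exons=tuple(utr),
                    biotype=biotype,
                    gene_name=gene_name or gene_id,
                    gene_function=gene_function,
                )
            )
    return models


def _first_attr(feature, *keys: str) -> str | None:
    for key in keys:
        values = feature.attributes.get(key)
        if values:
            return values[0]
    return None


# ---------------------------------------------------------------------------
# Output tables
# ---------------------------------------------------------------------------

def allele_string(call: VariantCall) -> str:
    """Serialize the focal allele in the homozygous table dialect.

    Insertions read ``+G/+G``, deletions ``−g/−g`` (lowercase, true minus),
    SNPs ``T/T``.
    """
    if call.vtype is VType.snp:
        a = call.alt_allele.upper()
        return f"{a}/{a}"
    if call.vtype.is_insertion:
        a = "+" + call.alt_allele.upper()
        return f"{a}/{a}"
    a = MINUS + call.ref_allele.lower()
    return f"{a}/{a}"


TABLE_COLUMNS = ("Chr", "Variation", "Gene Name", "Gene Function", "LSJ1_allele", "Ancestral Status")


def write_variant_table(variants: Sequence[ClassifiedVariant], path: str | Path) -> None:
    """Write classified variants as a TSV in the published table shape."""
    lines = ["\t".join(TABLE_COLUMNS)]
    for v in variants:
        lines.append(
            "\t".join(
                (
                    v.call.chrom,
                    str(v.call.pos),
                    v.gene_name,
                    v.gene_function,
                    allele_string(v.call),
                    v.ancestral,
                )
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
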