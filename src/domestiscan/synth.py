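"""Synthetic dataset generator with a planted-event truth ledger.

All planted events are defined directly in the coordinate system of the
emitted reference sequence, so no coordinate lifting is ever needed:

* ``reference_error`` — the emitted reference is wrong at the site; the focal
  strain, every panel strain and both outgroups carry the ALT (true) allele.
* ``mutation_in_N2_lineage`` — the reference lineage acquired the derived
  allele, which is what the reference shows; the focal strain and the
  outgroups carry the ALT (ancestral) allele.
* ``mutation_in_LSJ1_lineage`` — the focal strain acquired the derived ALT
  allele; panel strains and outgroups match the reference.

The focal VCF therefore contains every event; panel VCFs contain the error
events (minus dropout/miscall noise); outgroup VCFs contain error plus
reference-lineage-mutation events.  Identical seeds produce byte-identical
files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import effects as fx
from .model import (
    GeneModel,
    Genome,
    VariantCall,
    VType,
    write_fasta,
    write_vcf,
)

__all__ = [
    "SynthConfig",
    "TruthRecord",
    "SyntheticTruth",
    "SyntheticDataset",
    "generate_dataset",
    "apply_variants",
    "score_recovery",
]

_BASES = np.array(list("ACGT"))

EVENT_CLASSES = (
    "reference_error",
    "mutation_in_N2_lineage",
    "mutation_in_LSJ1_lineage",
)

#: minimum spacing between planted events so exact-allele site matching is safe
MIN_SPACING = 10


@dataclass(frozen=True)
class SynthConfig:
    """Generator knobs.

    ``mu`` is the real-scale substitution rate; ``mu_scale`` inflates it so
    event counts on the small synthetic genome match published magnitudes
    (the default 33.4 is the ratio of a 1.0028e8 bp genome to the default
    3e6 bp synthetic one, giving ~438 substitutions per lineage at t=1620).
    """

    chrom_lengths: tuple[tuple[str, int], ...] = (
        ("I", 500_000),
        ("II", 500_000),
        ("III", 500_000),
        ("IV", 500_000),
        ("V", 500_000),
        ("X", 500_000),
    )
    t: int = 1620
    mu: float = 2.7e-9
    mu_scale: float = 33.4
    indel_fraction: float = 331 / 1208  # share of lineage events that are 1-3 bp indels
    spectrum_weights: tuple[float, ...] = (1.0,) * 6  # over stats.SPECTRUM_CLASSES
    e: float = 6.8e-4  # reference errors per bp (paper magnitude x mu_scale)
    error_indel_fraction: float = 1490 / 2038
    d: float = 0.0  # panel per-site dropout probability
    m: float = 0.0  # per-site miscall probability (panel and outgroups)
    n_panel: int = 6
    n_genes: int = 80
    mean_exons: float = 3.0
    pseudogene_fraction: float = 0.1
    outgroup_private_rate: float = 0.0  # private outgroup variants per bp
    noise_rate: float = 0.0  # junk focal records per bp (low quality / ambiguous)
    quality: float = 99.0
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("indel_fraction", "error_indel_fraction", "d", "m", "pseudogene_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if any(w < 0 for w in self.spectrum_weights) or len(self.spectrum_weights) != 6:
            raise ValueError("spectrum_weights must be 6 non-negative numbers")

    @property
    def L(self) -> int:
        return sum(length for _, length in self.chrom_lengths)

    @property
    def mu_effective(self) -> float:
        return self.mu * self.mu_scale


@dataclass(frozen=True)
class TruthRecord:
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    vtype: str
    length: int
    event_class: str  # one of EVENT_CLASSES, or "noise"
    ancestral: str  # "N2" | "LSJ1" | "" (errors and noise)
    coding_effect: str = ""

    @property
    def site_key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


@dataclass
class SyntheticTruth:
    records: list[TruthRecord]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.by_key = {r.site_key: r for r in self.records}

    def of_class(self, event_class: str) -> list[TruthRecord]:
        return [r for r in self.records if r.event_class == event_class]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.records])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SyntheticTruth":
        frame = pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"chrom": str})
        records = [
            TruthRecord(
                chrom=row.chrom,
                pos=int(row.pos),
                ref_allele=row.ref_allele,
                alt_allele=row.alt_allele,
                vtype=row.vtype,
                length=int(row.length),
                event_class=row.event_class,
                ancestral=row.ancestral,
                coding_effect=row.coding_effect,
            )
            for row in frame.itertuples()
        ]
        return cls(records)


@dataclass
class SyntheticDataset:
    reference: Genome
    genes: list[GeneModel]
    truth: SyntheticTruth
    paths: dict[str, Path]


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _spectrum_choice_derived(anc: str, weights: Sequence[float], rng) -> str:
    """Sample a derived base given the ancestral base, per 6-class weights."""
    from .stats import SPECTRUM_CLASSES, spectrum_class

    options = [b for b in "ACGT" if b != anc]
    w = np.array(
        [weights[SPECTRUM_CLASSES.index(spectrum_class(anc, der))] for der in options]
    )
    return options[rng.choice(3, p=w / w.sum())]


def _spectrum_choice_ancestral(der: str, weights: Sequence[float], rng) -> str:
    """Sample an ancestral base given the derived base (uniform founder prior)."""
    from .stats import SPECTRUM_CLASSES, spectrum_class

    options = [b for b in "ACGT" if b != der]
    w = np.array(
        [weights[SPECTRUM_CLASSES.index(spectrum_class(anc, der))] for anc in options]
    )
    return options[rng.choice(3, p=w / w.sum())]


def _has_long_run(seq: str, max_run: int = 5) -> bool:
    run, prev = 1, ""
    for ch in seq:
        run = run + 1 if ch == prev else 1
        prev = ch
        if run > max_run:
            return True
    return False


def apply_variants(genome: Genome, calls: Sequence[VariantCall]) -> Genome:
    """Return a new genome with the calls applied (internal coordinates).

    Calls are applied per chromosome in descending position order so earlier
    edits never shift later coordinates; callers must not pass overlapping
    calls.
    """
    sequences = dict(genome.sequences)
    by_chrom: dict[str, list[VariantCall]] = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, []).append(c)
    for chrom, chrom_calls in by_chrom.items():
        seq = sequences[chrom]
        for c in sorted(chrom_calls, key=lambda c: c.pos, reverse=True):
            i = c.pos - 1
            if c.vtype is VType.snp:
                if seq[i] != c.ref_allele:
                    raise ValueError(f"ref mismatch at {chrom}:{c.pos}")
                seq = seq[:i] + c.alt_allele + seq[i + 1 :]
            elif c.vtype.is_deletion:
                if seq[i : i + c.length] != c.ref_allele:
                    raise ValueError(f"ref mismatch at {chrom}:{c.pos}")
                seq = seq[:i] + seq[i + c.length :]
            else:  # insertion after pos
                seq = seq[: i + 1] + c.alt_allele + seq[i + 1 :]
        sequences[chrom] = seq
    return Genome(sequences)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _draw_positions(config: SynthConfig, count: int, rng) -> list[tuple[str, int]]:
    """Draw ``count`` event positions, globally spaced by ``MIN_SPACING``."""
    names = [n for n, _ in config.chrom_lengths]
    lengths = np.array([l for _, l in config.chrom_lengths])
    offsets = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    total = int(lengths.sum())
    chosen: np.ndarray = np.empty(0, dtype=np.int64)
    attempts = 0
    while len(chosen) < count:
        attempts += 1
        if attempts > 50:
            raise RuntimeError("could not place events with required spacing")
        extra = rng.integers(MIN_SPACING, total - MIN_SPACING, size=max(count * 2, 64))
        merged = np.unique(np.concatenate([chosen, extra]))
        keep = np.concatenate([[True], np.diff(merged) >= MIN_SPACING])
        chosen = merged[keep]
    idx = rng.choice(len(chosen), size=count, replace=False)
    chosen = chosen[np.sort(idx)]
    out = []
    for g in chosen:
        c = int(np.searchsorted(np.cumsum(lengths), g, side="right"))
        out.append((names[c], int(g - offsets[c]) + 1))
    return out


def _make_event(
    chrom: str,
    pos: int,
    event_class: str,
    is_indel: bool,
    reference: dict[str, str],
    config: SynthConfig,
    rng,
) -> Optional[TruthRecord]:
    """Build one planted event at a reference position; None to resample."""
    seq = reference[chrom]
    if is_indel:
        length = int(rng.integers(1, 4))
        is_del = bool(rng.integers(0, 2))
        window = seq[max(0, pos - 7) : pos + 7 + length]
        if pos < 2 or _has_long_run(window):
            return None
        if is_del:
            if pos + length > len(seq):
                return None
            ref_allele, alt_allele = seq[pos - 1 : pos - 1 + length], ""
            vtype = VType.small_del
            # placement must be unambiguous: a one-step shift left or right
            # would represent the same edit
            if seq[pos - 2] == seq[pos - 2 + length] or seq[pos - 1] == seq[pos - 1 + length]:
                return None
        else:
            ref_allele = ""
            alt_allele = "".join(_BASES[rng.integers(0, 4, size=length)])
            vtype = VType.small_ins
            # same uniqueness requirement for insertions
            if alt_allele[-1] == seq[pos - 1] or (
                pos < len(seq) and alt_allele[0] == seq[pos]
            ):
                return None
    else:
        length = 1
        ref_base = seq[pos - 1]
        if event_class == "mutation_in_LSJ1_lineage":
            alt = _spectrum_choice_derived(ref_base, config.spectrum_weights, rng)
        elif event_class == "mutation_in_N2_lineage":
            alt = _spectrum_choice_ancestral(ref_base, config.spectrum_weights, rng)
        else:  # sequencing errors have no mutational spectrum
            alt = [b for b in "ACGT" if b != ref_base][int(rng.integers(0, 3))]
        ref_allele, alt_allele, vtype = ref_base, alt, VType.snp
    ancestral = {
        "reference_error": "",
        "mutation_in_N2_lineage": "LSJ1",  # focal (ALT) allele is ancestral
        "mutation_in_LSJ1_lineage": "N2",  # reference allele is ancestral
    }[event_class]
    return TruthRecord(
        chrom=chrom,
        pos=pos,
        ref_allele=ref_allele,
        alt_allele=alt_allele,
        vtype=vtype.value,
        length=length,
        event_class=event_class,
        ancestral=ancestral,
    )


def _place_genes(config: SynthConfig, rng) -> list[GeneModel]:
    from .model import Biotype

    names = [n for n, _ in config.chrom_lengths]
    lengths = np.array([l for _, l in config.chrom_lengths], dtype=float)
    occupied: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
    genes: list[GeneModel] = []
    gi = 0
    attempts = 0
    while gi < config.n_genes and attempts < config.n_genes * 60:
        attempts += 1
        chrom = names[rng.choice(len(names), p=lengths / lengths.sum())]
        n_exons = 1 + int(rng.poisson(max(config.mean_exons - 1.0, 0.0)))
        exon_lens = rng.integers(60, 181, size=n_exons)
        total = int(exon_lens.sum())
        exon_lens[-1] -= total % 3
        intron_lens = rng.integers(40, 91, size=max(n_exons - 1, 0))
        utr5, utr3 = int(rng.integers(20, 41)), int(rng.integers(20, 41))
        body = int(exon_lens.sum() + intron_lens.sum())
        span = utr5 + body + utr3
        chrom_len = dict(config.chrom_lengths)[chrom]
        if span + 20 >= chrom_len:
            continue
        start = int(rng.integers(10, chrom_len - span - 10))
        end = start + span - 1
        if any(s <= end + 50 and start - 50 <= e for s, e in occupied[chrom]):
            continue
        occupied[chrom].append((start, end))
        cds = []
        cursor = start + utr5
        for i, el in enumerate(exon_lens):
            cds.append((cursor, cursor + int(el) - 1))
            cursor += int(el)
            if i < len(intron_lens):
                cursor += int(intron_lens[i])
        strand = "+" if rng.integers(0, 2) else "-"
        pseudo = rng.random() < config.pseudogene_fraction
        # pseudogenes are annotated as bare exon structures without UTRs
        utr = () if pseudo else ((start, start + utr5 - 1), (end - utr3 + 1, end))
        gi += 1
        genes.append(
            GeneModel(
                gene_id=f"gene{gi:04d}",
                transcript_id=f"tx{gi:04d}",
                chrom=chrom,
                strand=strand,
                cds_exons=tuple(cds),
                utr_exons=utr,
                biotype=Biotype.pseudogene if pseudo else Biotype.protein_coding,
                gene_name=f"gene{gi:04d}",
            )
        )
    if gi < config.n_genes:
        raise RuntimeError("could not place requested number of genes")
    return sorted(genes, key=lambda g: (g.chrom, g.span[0]))


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    from .model import Biotype

    lines = ["##gff-version 3"]
    for g in genes:
        span = g.span
        pseudo = g.biotype is Biotype.pseudogene
        gene_type = "pseudogene" if pseudo else "gene"
        tx_type = "pseudogenic_transcript" if pseudo else "mRNA"
        attrs = f"ID={g.gene_id};Name={g.gene_name};biotype={g.biotype.value}"
        lines.append(
            f"{g.chrom}\tsynth\t{gene_type}\t{span[0]}\t{span[1]}\t.\t{g.strand}\t.\t{attrs}"
        )
        lines.append(
            f"{g.chrom}\tsynth\t{tx_type}\t{span[0]}\t{span[1]}\t.\t{g.strand}\t.\t"
            f"ID={g.transcript_id};Parent={g.gene_id}"
        )
        cds_type = "exon" if pseudo else "CDS"
        for start, end in g.cds_exons:
            lines.append(
                f"{g.chrom}\tsynth\t{cds_type}\t{start}\t{end}\t.\t{g.strand}\t0\t"
                f"Parent={g.transcript_id}"
            )
        for i, (start, end) in enumerate(g.utr_exons):
            utr_type = "five_prime_UTR" if i == 0 else "three_prime_UTR"
            if g.strand == "-":
                utr_type = "three_prime_UTR" if i == 0 else "five_prime_UTR"
            if pseudo:
                continue
            lines.append(
                f"{g.chrom}\tsynth\t{utr_type}\t{start}\t{end}\t.\t{g.strand}\t.\t"
                f"Parent={g.transcript_id}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def _truth_to_call(rec: TruthRecord, quality: float, ambiguous: bool = False,
                   strain: str = "") -> VariantCall:
    return VariantCall(
        chrom=rec.chrom,
        pos=rec.pos,
        ref_allele=rec.ref_allele,
        alt_allele=rec.alt_allele,
        vtype=VType(rec.vtype),
        length=rec.length,
        quality=quality,
        ambiguous=ambiguous,
        source_strain=strain,
    )


def generate_dataset(
    config: SynthConfig, outdir: str | Path, rng: Optional[np.random.Generator] = None
) -> SyntheticDataset:
    """Generate the full synthetic input set and its truth ledger.

    Writes ``ref.fa``, ``genes.gff3``, ``lsj1.vcf``, ``n2_panel_<i>.vcf`` for
    each panel strain, two outgroup VCFs, ``truth.tsv`` and
    ``metadata.json`` into ``outdir``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # reference sequence (the published, possibly erroneous assembly)
    sequences = {
        name: "".join(_BASES[rng.integers(0, 4, size=length)])
        for name, length in config.chrom_lengths
    }
    reference = Genome(sequences)

    genes = _place_genes(config, rng)

    # event counts
    lam_sub = config.mu_effective * config.L * config.t
    n_lsj1 = int(rng.poisson(lam_sub))
    n_n2 = int(rng.poisson(lam_sub))
    n_err = int(rng.poisson(config.e * config.L))
    n_noise = int(rng.poisson(config.noise_rate * config.L))
    n_priv = int(rng.poisson(config.outgroup_private_rate * config.L)) * 2

    # lineage events get extra indel events on top of the substitution counts
    def with_indels(n_sub: int, frac: float) -> list[bool]:
        if frac >= 1.0:
            raise ValueError("indel fraction must be < 1")
        n_indel = int(rng.poisson(n_sub * frac / (1.0 - frac)))
        return [False] * n_sub + [True] * n_indel

    plan: list[tuple[str, bool]] = []
    for flag in with_indels(n_lsj1, config.indel_fraction):
        plan.append(("mutation_in_LSJ1_lineage", flag))
    for flag in with_indels(n_n2, config.indel_fraction):
        plan.append(("mutation_in_N2_lineage", flag))
    n_err_indel = int(round(n_err * config.error_indel_fraction))
    for i in range(n_err):
        plan.append(("reference_error", i < n_err_indel))

    n_events = len(plan)
    positions = _draw_positions(config, 2 * n_events + n_noise + n_priv + 64, rng)
    spare = positions[n_events:]

    records: list[TruthRecord] = []
    resampled = 0
    cursor = 0
    for event_class, is_indel in plan:
        rec = None
        while rec is None:
            if cursor < n_events:
                chrom, pos = positions[cursor]
                cursor += 1
            else:
                if not spare:
                    raise RuntimeError("ran out of spare positions")
                chrom, pos = spare.pop()
                resampled += 1
            rec = _make_event(chrom, pos, event_class, is_indel, sequences, config, rng)
        records.append(rec)

    # annotate true coding effects on the truth ledger
    records = [
        TruthRecord(
            **{
                **asdict(r),
                "coding_effect": fx.classify_effect(
                    _truth_to_call(r, config.quality), genes, reference
                ).category.value,
            }
        )
        for r in records
    ]
    records.sort(key=lambda r: (r.chrom, r.pos))

    # focal strain: every event, plus optional junk records
    focal_calls = [_truth_to_call(r, config.quality, strain="LSJ1") for r in records]
    noise_records: list[TruthRecord] = []
    for _ in range(n_noise):
        if not spare:
            break
        chrom, pos = spare.pop()
        ref_base = sequences[chrom][pos - 1]
        alt = [b for b in "ACGT" if b != ref_base][int(rng.integers(0, 3))]
        ambiguous = bool(rng.integers(0, 2))
        quality = config.quality if ambiguous else float(rng.integers(0, 25))
        rec = TruthRecord(chrom, pos, ref_base, alt, "snp", 1, "noise", "")
        noise_records.append(rec)
        focal_calls.append(_truth_to_call(rec, quality, ambiguous=ambiguous, strain="LSJ1"))

    # panel strains: error events minus dropout/miscall, spurious at mutation sites
    panel_calls: dict[str, list[VariantCall]] = {}
    for i in range(1, config.n_panel + 1):
        strain = f"N2_panel_{i}"
        calls = []
        for r in records:
            if r.event_class == "reference_error":
                if rng.random() < config.d or rng.random() < config.m:
                    continue
                calls.append(_truth_to_call(r, config.quality, strain=strain))
            else:
                if rng.random() < config.m:
                    calls.append(_truth_to_call(r, config.quality, strain=strain))
        panel_calls[strain] = calls

    # outgroups: founder allele (error + reference-lineage-mutation events)
    outgroup_calls: dict[str, list[VariantCall]] = {}
    for name in ("outgroup_1", "outgroup_2"):
        calls = []
        for r in records:
            due = r.event_class in ("reference_error", "mutation_in_N2_lineage")
            if rng.random() < config.m:
                due = not due  # miscall flips presence
            if due:
                calls.append(_truth_to_call(r, config.quality, strain=name))
        for _ in range(n_priv // 2):
            if not spare:
                break
            chrom, pos = spare.pop()
            ref_base = sequences[chrom][pos - 1]
            alt = [b for b in "ACGT" if b != ref_base][int(rng.integers(0, 3))]
            calls.append(
                VariantCall(chrom, pos, ref_base, alt, VType.snp, 1, config.quality,
                            source_strain=name)
            )
        outgroup_calls[name] = calls

    truth = SyntheticTruth(
        records + noise_records,
        metadata={
            "seed": config.seed,
            "mu_scale": config.mu_scale,
            "mu_effective": config.mu_effective,
            "L": config.L,
            "t": config.t,
            "lambda_substitutions_per_lineage": lam_sub,
            "n_events": n_events,
            "n_noise": len(noise_records),
            "resampled": resampled,
        },
    )

    paths: dict[str, Path] = {}
    paths["ref"] = outdir / "ref.fa"
    write_fasta(reference, paths["ref"])
    paths["gff3"] = outdir / "genes.gff3"
    write_gff3(genes, paths["gff3"])
    paths["focal"] = outdir / "lsj1.vcf"
    write_vcf(focal_calls, paths["focal"], reference)
    for strain, calls in panel_calls.items():
        key = strain.lower()
        paths[key] = outdir / f"{key}.vcf"
        write_vcf(calls, paths[key], reference)
    for name, calls in outgroup_calls.items():
        paths[name] = outdir / f"{name}.vcf"
        write_vcf(calls, paths[name], reference)
    paths["truth"] = outdir / "truth.tsv"
    truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    paths["metadata"] = outdir / "metadata.json"
    paths["metadata"].write_text(json.dumps(truth.metadata, indent=2, sort_keys=True) + "\n")

    return SyntheticDataset(reference=reference, genes=genes, truth=truth, paths=paths)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def score_recovery(
    predicted_errors: Sequence[VariantCall],
    predicted_polymorphisms: Sequence[VariantCall],
    truth: SyntheticTruth,
    predicted_ancestral: Optional[Sequence[tuple[VariantCall, str]]] = None,
) -> dict:
    """Precision/recall/F1 for error-vs-polymorphism recovery, plus ancestral
    accuracy when polarization output is supplied.

    ``predicted_ancestral`` pairs each polymorphism call with an ancestral
    label in the table vocabulary ("N2"/"LSJ1"/"unknown").
    """
    true_errors = {r.site_key for r in truth.of_class("reference_error")}
    true_polys = {
        r.site_key
        for r in truth.records
        if r.event_class in ("mutation_in_N2_lineage", "mutation_in_LSJ1_lineage")
    }
    pred_err = {c.site_key for c in predicted_errors}
    pred_poly = {c.site_key for c in predicted_polymorphisms}

    def prf(pred: set, true: set) -> dict:
        tp = len(pred & true)
        precision = tp / len(pred) if pred else 1.0
        recall = tp / len(true) if true else 1.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision + recall > 0
            else 0.0
        )
        return {"precision": precision, "recall": recall, "f1": f1, "tp": tp}

    result = {
        "reference_error": prf(pred_err, true_errors),
        "polymorphism": prf(pred_poly, true_polys),
    }

    if predicted_ancestral is not None:
        correct = total = 0
        confusion: dict[tuple[str, str], int] = {}
        for call, label in predicted_ancestral:
            rec = truth.by_key.get(call.site_key)
            if rec is None or not rec.ancestral:
                continue
            total += 1
            confusion[(rec.ancestral, label)] = confusion.get((rec.ancestral, label), 0) + 1
            if label == rec.ancestral:
                correct += 1
        result["ancestral"] = {
            "accuracy": correct / total if total else 1.0,
            "n": total,
            "confusion": confusion,
        }
    return result
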