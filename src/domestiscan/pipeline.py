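"""End-to-end driver: filter calls, vote out reference errors, polarize the
survivors, and annotate coding consequences."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import effects as fx
from .filters import DiscardReason, FilterConfig, apply_all_filters
from .model import (
    ClassifiedVariant,
    GeneModel,
    Genome,
    VariantCall,
    VariantStatus,
    read_fasta,
    read_gff3,
    read_vcf,
)
from .panel import PanelConfig, SiteClassification, partition_variants
from .polarize import AncestralCall, polarize_variants

__all__ = ["PipelineResult", "run_pipeline", "run_pipeline_files"]


@dataclass
class PipelineResult:
    kept: list[VariantCall]
    discarded: list[tuple[VariantCall, DiscardReason]]
    errors: list[tuple[VariantCall, SiteClassification]]
    polymorphisms: list[tuple[VariantCall, SiteClassification]]
    ancestral: list[AncestralCall]
    error_effects: list[fx.CodingEffect] = field(default_factory=list)
    polymorphism_effects: list[fx.CodingEffect] = field(default_factory=list)

    @property
    def error_calls(self) -> list[VariantCall]:
        return [c for c, _ in self.errors]

    @property
    def polymorphism_calls(self) -> list[VariantCall]:
        return [c for c, _ in self.polymorphisms]

    def classified_variants(self, genes: Sequence[GeneModel] = ()) -> list[ClassifiedVariant]:
        """Flatten into table-ready rows (polymorphisms then errors)."""
        by_id = {g.gene_id: g for g in genes}
        rows = []
        for (call, cls), anc, eff in zip(
            self.polymorphisms, self.ancestral, self.polymorphism_effects or
            [None] * len(self.polymorphisms)
        ):
            gene = by_id.get(eff.gene_id) if eff else None
            rows.append(
                ClassifiedVariant(
                    call=call,
                    status=VariantStatus.polymorphism,
                    support_count=cls.support_count,
                    ancestral=anc.label,
                    gene_name=gene.gene_name if gene else "",
                    gene_function=gene.gene_function if gene else "",
                    effect=eff.category.value if eff else "",
                )
            )
        for (call, cls), eff in zip(
            self.errors, self.error_effects or [None] * len(self.errors)
        ):
            gene = by_id.get(eff.gene_id) if eff else None
            rows.append(
                ClassifiedVariant(
                    call=call,
                    status=VariantStatus.reference_error,
                    support_count=cls.support_count,
                    gene_name=gene.gene_name if gene else "",
                    gene_function=gene.gene_function if gene else "",
                    effect=eff.category.value if eff else "",
                )
            )
        return rows


def run_pipeline(
    focal_calls: Sequence[VariantCall],
    panel_calls: dict[str, Sequence[VariantCall]],
    outgroup_a: tuple[str, Sequence[VariantCall]],
    outgroup_b: tuple[str, Sequence[VariantCall]],
    genome: Optional[Genome] = None,
    genes: Sequence[GeneModel] = (),
    filter_config: FilterConfig = FilterConfig(),
    panel_config: PanelConfig = PanelConfig(),
    require_both_outgroups: bool = True,
) -> PipelineResult:
    kept, discarded = apply_all_filters(focal_calls, filter_config)
    errors, polymorphisms = partition_variants(kept, panel_calls, panel_config)
    poly_calls = [c for c, _ in polymorphisms]
    ancestral = polarize_variants(
        poly_calls, outgroup_a, outgroup_b, require_both=require_both_outgroups
    )
    error_effects: list[fx.CodingEffect] = []
    poly_effects: list[fx.CodingEffect] = []
    if genome is not None and genes:
        error_effects = [fx.classify_effect(c, genes, genome) for c, _ in errors]
        poly_effects = [fx.classify_effect(c, genes, genome) for c in poly_calls]
    return PipelineResult(
        kept=kept,
        discarded=discarded,
        errors=errors,
        polymorphisms=polymorphisms,
        ancestral=ancestral,
        error_effects=error_effects,
        polymorphism_effects=poly_effects,
    )


def run_pipeline_files(
    focal_vcf: str | Path,
    panel_vcfs: dict[str, str | Path],
    outgroup_vcfs: dict[str, str | Path],
    fasta: Optional[str | Path] = None,
    gff3: Optional[str | Path] = None,
    filter_config: FilterConfig = FilterConfig(),
    panel_config: PanelConfig = PanelConfig(),
    require_both_outgroups: bool = True,
) -> PipelineResult:
    """File-path front end for :func:`run_pipeline`."""
    if len(outgroup_vcfs) != 2:
        raise ValueError("exactly two outgroups are required")
    focal = read_vcf(focal_vcf, "focal")
    panel = {name: read_vcf(path, name) for name, path in panel_vcfs.items()}
    (name_a, path_a), (name_b, path_b) = outgroup_vcfs.items()
    genome = read_fasta(fasta) if fasta else None
    genes = read_gff3(gff3) if gff3 else ()
    return run_pipeline(
        focal,
        panel,
        (name_a, read_vcf(path_a, name_a)),
        (name_b, read_vcf(path_b, name_b)),
        genome=genome,
        genes=genes,
        filter_config=filter_config,
        panel_config=panel_config,
        require_both_outgroups=require_both_outgroups,
    )
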