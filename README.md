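# domestiscan

Tools for comparing two sibling selfing lineages of the same founder strain
(a "focal" strain vs the lineage behind the published reference genome) after
decades of separate laboratory cultivation:

- **Quality filtering** of candidate differences (SNP/indel quality
  thresholds, ambiguous-placement discard, large-indel retention rules).
- **Reference-error detection** by panel vote: a site where ≥ k of n
  independently resequenced reference-lineage strains show the focal allele is
  an error in the published reference, not a real polymorphism.
- **Ancestral-allele polarization** by two-outgroup concordance, assigning
  each retained polymorphism to the lineage in which it arose.
- **Coding-consequence annotation** (synonymous/nonsynonymous, stop gain/loss,
  frameshift, single-amino-acid indels, pseudogene hits) against GFF3 gene
  models.
- **Summary statistics**: Ts/Tv ratios, strand-collapsed substitution
  spectrum, mutation-rate divergence dating (t = S / 2μL), reference error
  rate, and a per-chromosome K-S uniformity scan with Benjamini–Hochberg
  correction.
- **Forward-time intercross simulation** of advanced-intercross-line
  construction (random inter-plate matings, line founding, single-hermaphrodite
  selfing descent, X-linked or autosomal focal locus, linked marker, and a
  phenomenological picking bias) to build neutral nulls and fit the bias
  needed to explain observed allele fixation.
- **Synthetic-data generation** with a planted-event truth ledger covering
  every pipeline stage (reference errors, lineage mutations, panel
  dropout/miscall noise, outgroup miscalls, junk calls), byte-deterministic
  per seed.

## CLI

```bash
# generate a synthetic dataset with ground truth
domestiscan synth --preset paper-scale --seed 42 --outdir data/synth

# quality/ambiguity filtering
domestiscan filter --vcf data/synth/lsj1.vcf --fasta data/synth/ref.fa \
    --out kept.vcf --discarded-out discarded.tsv

# reference-error vs polymorphism split (panel vote, k of n)
domestiscan classify --focal kept.vcf --panel data/synth/n2_panel_*.vcf \
    --k 4 --fasta data/synth/ref.fa \
    --errors-out errors.vcf --polymorphisms-out polys.vcf

# ancestral-state polarization against two outgroups
domestiscan polarize --polymorphisms polys.vcf \
    --outgroup data/synth/outgroup_1.vcf --outgroup data/synth/outgroup_2.vcf \
    --out polarized.tsv

# summary statistics report
domestiscan stats --polymorphisms polys.vcf --errors errors.vcf \
    --fasta data/synth/ref.fa

# the whole chain in one step
domestiscan run --focal data/synth/lsj1.vcf --panel data/synth/n2_panel_*.vcf \
    --outgroup data/synth/outgroup_1.vcf --outgroup data/synth/outgroup_2.vcf \
    --fasta data/synth/ref.fa --gff3 data/synth/genes.gff3 --outdir results/

# neutral null for the breeding experiment
domestiscan simulate-intercross --replicates 200 --seed 1 --bias 1.0
```

## Layout

| path | role |
| --- | --- |
| `src/domestiscan/model.py` | domain types; VCF/FASTA/GFF3/TSV readers and writers |
| `src/domestiscan/filters.py` | call-level quality and ambiguity rules |
| `src/domestiscan/panel.py` | panel-vote reference-error classification |
| `src/domestiscan/polarize.py` | two-outgroup ancestral-state inference |
| `src/domestiscan/effects.py` | coding-consequence classification |
| `src/domestiscan/stats.py` | spectrum, Ts/Tv, divergence dating, K-S/FDR scan |
| `src/domestiscan/intercross.py` | forward-time breeding simulator and bias fit |
| `src/domestiscan/synth.py` | synthetic data generator and recovery scoring |
| `src/domestiscan/pipeline.py` | end-to-end driver |
| `src/domestiscan/cli.py` | `domestiscan` command group |
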