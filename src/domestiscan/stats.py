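"""Mutational spectrum, Ts/Tv, divergence dating, error rate, and the
per-chromosome uniformity scan.

The divergence model treats the two lineages as accumulating substitutions
independently at per-bp per-generation rate ``mu``, so ``S`` observed
differences imply ``t = S / (2 mu L)`` generations since separation, while
the expected accumulation in a single lineage over ``t`` generations is
``mu L t``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .model import VariantCall, VType
from .polarize import AncestralCall, AncestralState

__all__ = [
    "DivergenceModel",
    "SpectrumTable",
    "SPECTRUM_CLASSES",
    "ts_tv",
    "substitution_spectrum",
    "divergence_generations",
    "expected_snps",
    "separation_years",
    "reference_error_rate",
    "ks_uniformity_scan",
    "bh_fdr",
]

DEFAULT_MU = 2.7e-9  # substitutions per bp per generation (mutation-accumulation estimate)
DEFAULT_GENERATION_DAYS = 4.0
DAYS_PER_YEAR = 365.25

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

#: strand-collapsed substitution classes, ancestral pair first
SPECTRUM_CLASSES = (
    "G:C>A:T",
    "G:C>T:A",
    "G:C>C:G",
    "A:T>G:C",
    "A:T>T:A",
    "A:T>C:G",
)

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def spectrum_class(ancestral: str, derived: str) -> str:
    """Collapse an oriented single-base substitution onto the 6 classes."""
    anc, der = ancestral.upper(), derived.upper()
    if anc in "CT":
        anc, der = _COMP[anc], _COMP[der]
    return f"{anc}:{_COMP[anc]}>{der}:{_COMP[der]}"


# ---------------------------------------------------------------------------
# Ts/Tv and spectrum
# ---------------------------------------------------------------------------

def ts_tv(snps: Iterable[VariantCall]) -> float:
    """Transitions / transversions; infinity if there are no transversions."""
    ts = tv = 0
    for c in snps:
        if c.vtype is not VType.snp:
            continue
        if (c.ref_allele, c.alt_allele) in _TRANSITIONS:
            ts += 1
        else:
            tv += 1
    if tv == 0:
        return math.inf if ts else math.nan
    return ts / tv


@dataclass
class SpectrumTable:
    """Counts per collapsed substitution class, overall and per derived lineage.

    The per-lineage columns cover polarized SNPs only; the ``overall`` column
    additionally counts unknown-polarity SNPs using the reference->focal
    orientation (flagged in ``unpolarized_in_overall``).
    """

    overall: dict[str, int]
    derived_in_LSJ1: dict[str, int]
    derived_in_N2: dict[str, int]
    unpolarized_in_overall: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "overall": self.overall,
                "derived_in_LSJ1": self.derived_in_LSJ1,
                "derived_in_N2": self.derived_in_N2,
            }
        ).loc[list(SPECTRUM_CLASSES)]


def substitution_spectrum(
    snps: Sequence[VariantCall], polarization: Sequence[AncestralCall]
) -> SpectrumTable:
    """Assign each SNP its ancestral->derived class, strand-collapsed.

    ``polarization`` runs parallel to ``snps``.  For a SNP with N2 ancestral
    the derived (LSJ1) allele is the alt allele; with LSJ1 ancestral the
    mutation happened in the N2 lineage and ancestral/derived are swapped.
    """
    if len(snps) != len(polarization):
        raise ValueError("snps and polarization must run parallel")
    overall = {k: 0 for k in SPECTRUM_CLASSES}
    in_lsj1 = {k: 0 for k in SPECTRUM_CLASSES}
    in_n2 = {k: 0 for k in SPECTRUM_CLASSES}
    unpolarized = 0
    for call, anc in zip(snps, polarization):
        if call.vtype is not VType.snp:
            continue
        if anc.state is AncestralState.ancestral_N2:
            klass = spectrum_class(call.ref_allele, call.alt_allele)
            in_lsj1[klass] += 1
        elif anc.state is AncestralState.ancestral_LSJ1:
            klass = spectrum_class(call.alt_allele, call.ref_allele)
            in_n2[klass] += 1
        else:
            klass = spectrum_class(call.ref_allele, call.alt_allele)
            unpolarized += 1
        overall[klass] += 1
    return SpectrumTable(overall, in_lsj1, in_n2, unpolarized)


# ---------------------------------------------------------------------------
# Divergence dating
# ---------------------------------------------------------------------------

@dataclass
class DivergenceModel:
    """Mutation-rate divergence model; ``t`` is always derived from ``S``."""

    S: int
    L: int
    mu: float = DEFAULT_MU
    g: float = DEFAULT_GENERATION_DAYS

    def __post_init__(self) -> None:
        if self.S < 0 or self.L <= 0 or self.mu <= 0 or self.g <= 0:
            raise ValueError("S must be >= 0 and L, mu, g positive")

    @property
    def t(self) -> float:
        return divergence_generations(self.S, self.mu, self.L)

    @property
    def years(self) -> float:
        return separation_years(self.t, self.g)


def divergence_generations(S: float, mu: float, L: float) -> float:
    """Generations since separation: S substitutions over two lineages."""
    if S < 0:
        raise ValueError("S must be >= 0")
    return S / (2.0 * mu * L)


def expected_snps(mu: float, L: float, t: float) -> float:
    """Expected substitutions accumulated by a *single* lineage over t generations."""
    return mu * L * t


def separation_years(t: float, g: float = DEFAULT_GENERATION_DAYS) -> float:
    return t * g / DAYS_PER_YEAR


def reference_error_rate(L: float, n_errors: int) -> float:
    """Error rate as one error per X bp (returns X; infinity for 0 errors)."""
    if n_errors == 0:
        return math.inf
    return L / n_errors


# ---------------------------------------------------------------------------
# Uniformity scan
# ---------------------------------------------------------------------------

def bh_fdr(pvalues: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted q-values, rejection mask)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    reject, qvals, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return qvals, reject


def ks_uniformity_scan(
    variants: Sequence[VariantCall],
    chrom_lengths: Mapping[str, int],
    q: float = 0.05,
    exact_below: int = 30,
) -> pd.DataFrame:
    """One-sample two-sided K-S test of position uniformity per chromosome.

    Positions are scaled by chromosome length and compared with Uniform(0,1);
    p-values are Benjamini-Hochberg adjusted across chromosomes.  The exact
    null distribution is used below ``exact_below`` variants, the asymptotic
    one otherwise.  Chromosomes with zero variants are skipped with a warning.
    ``deviation_sign`` is +1 when the empirical CDF exceeds the uniform CDF at
    the point of largest deviation (variants shifted toward the chromosome
    start), -1 otherwise — a descriptive arm-vs-center indicator only.
    """
    import warnings

    by_chrom: dict[str, list[int]] = {name: [] for name in chrom_lengths}
    for v in variants:
        if v.chrom in by_chrom:
            by_chrom[v.chrom].append(v.pos)
    rows = []
    for name, length in chrom_lengths.items():
        positions = np.sort(np.asarray(by_chrom[name], dtype=float))
        n = positions.size
        if n == 0:
            warnings.warn(f"chromosome {name} has no variants; skipped")
            continue
        u = positions / float(length)
        method = "exact" if n < exact_below else "asymp"
        result = sps.kstest(u, "uniform", method=method)
        # signed deviation: D+ (ECDF above) vs D- at the maximizing point
        ecdf_hi = np.arange(1, n + 1) / n - u
        ecdf_lo = u - np.arange(0, n) / n
        sign = 1 if ecdf_hi.max() >= ecdf_lo.max() else -1
        rows.append(
            {
                "chrom": name,
                "n": n,
                "length": length,
                "density_per_bp": n / length,
                "D": result.statistic,
                "deviation_sign": sign,
                "p": result.pvalue,
            }
        )
    frame = pd.DataFrame(rows)
    if not frame.empty:
        qvals, reject = bh_fdr(frame["p"].to_numpy(), q=q)
        frame["q"] = qvals
        frame["reject"] = reject
    return frame
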