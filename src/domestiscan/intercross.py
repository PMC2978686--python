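"""Forward-time simulator of advanced-intercross-line construction.

The breeding design: founder crosses between two homozygous strains, a fixed
number of generations of random inter-plate matings, founding of selfing
lines by picking hermaphrodites from each mating plate, then propagation of
each line by single-hermaphrodite descent.  A phenomenological picking bias
``b`` (relative probability that a hermaphrodite carrying at least one focal
allele is picked at a transfer) converts the neutral null into a selection
model; ``b = 1`` is neutral.

The focal locus is X-linked by default (hermaphrodites XX, males X0; males
transmit their single X to hermaphrodite offspring only).  An optional linked
marker at recombination fraction ``r`` rides along on each X haplotype.
Founder cross directions alternate so the initial X-allele frequency is 1/2
and the neutral case is symmetric under allele relabelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "SimResult",
    "BiasFit",
    "simulate_intercross",
    "heterozygosity_trajectory",
    "expected_selfing_heterozygosity",
    "fit_pick_bias",
]

FOCAL, MARKER = 0, 1  # locus indices on a haplotype


@dataclass(frozen=True)
class SimConfig:
    n_founder_crosses: int = 100
    intermating_generations: int = 10
    lines_per_cross: int = 10
    selfing_generations: int = 9
    linkage: str = "x_linked"  # or "autosomal"
    r: float = 0.2  # recombination fraction to the linked marker
    pick_bias: float = 1.0  # b; relative pick probability of focal carriers
    brood_size: int = 100  # progeny per brood from which picks are drawn
    extinction_prob: float = 0.022  # per-line loss, genotype-independent
    bias_scope: str = "both"  # "both" | "intermating" | "selfing"

    def __post_init__(self) -> None:
        if not 0.0 <= self.r <= 0.5:
            raise ValueError("r must be in [0, 0.5]")
        if not self.pick_bias >= 0:
            raise ValueError("pick_bias must be >= 0")
        if self.linkage not in ("x_linked", "autosomal"):
            raise ValueError("linkage must be 'x_linked' or 'autosomal'")
        if self.bias_scope not in ("both", "intermating", "selfing"):
            raise ValueError("bias_scope must be 'both', 'intermating' or 'selfing'")
        if self.brood_size < self.lines_per_cross:
            raise ValueError("brood_size must be >= lines_per_cross")

    @property
    def n_lines(self) -> int:
        return self.n_founder_crosses * self.lines_per_cross


@dataclass
class SimResult:
    """Final per-line genotypes and summaries for one replicate."""

    focal_genotypes: np.ndarray  # (n_lines, 2) alleles, 1 = focal
    marker_genotypes: np.ndarray  # (n_lines, 2)
    surviving: np.ndarray  # (n_lines,) bool
    het_trajectory: np.ndarray  # het fraction at focal locus per selfing generation
    config: SimConfig

    @property
    def n_surviving(self) -> int:
        return int(self.surviving.sum())

    def _fraction(self, genotypes: np.ndarray) -> float:
        g = genotypes[self.surviving]
        per_line = g.mean(axis=1)  # 0, 0.5 or 1 focal dose
        # heterozygous survivors carry both alleles; count half toward each
        return float(np.where(per_line == 0.5, 0.5, per_line).mean())

    @property
    def focal_fraction(self) -> float:
        """Fraction of surviving lines carrying the focal allele (hets count 1/2)."""
        return self._fraction(self.focal_genotypes)

    @property
    def marker_fraction(self) -> float:
        return self._fraction(self.marker_genotypes)

    @property
    def allele_fractions(self) -> dict[str, float]:
        f = self.focal_fraction
        return {"focal": f, "other": 1.0 - f}


def _gametes(parents: np.ndarray, shape: tuple[int, ...], r: float, rng) -> np.ndarray:
    """Draw gametes from diploid parents.

    ``parents`` has shape ``rows x 2 x 2`` (individual, chromatid, locus);
    ``shape`` is ``(rows, k)`` — k gametes per row.  Returns ``rows x k x 2``
    haplotypes with recombination fraction ``r`` between the two loci.
    """
    rows, k = shape
    chromatid = rng.integers(0, 2, size=(rows, k))
    rec = rng.random(size=(rows, k)) < r
    other = chromatid ^ rec
    idx = np.arange(rows)[:, None]
    focal = parents[idx, chromatid, FOCAL]
    marker = parents[idx, other, MARKER]
    return np.stack([focal, marker], axis=-1)


def _weighted_pick_one(brood: np.ndarray, bias: float, rng) -> np.ndarray:
    """Pick one individual per row, weighting focal-allele carriers by ``bias``.

    ``brood`` is ``rows x B x 2 x 2`` (diploid) or ``rows x B x 2`` (haploid X).
    """
    carrier = (brood[..., FOCAL] == 1).any(axis=-1) if brood.ndim == 4 else (
        brood[..., FOCAL] == 1
    )
    weights = np.where(carrier, bias, 1.0)
    totals = weights.sum(axis=1)
    # all-zero weights (b=0, all carriers): fall back to uniform pick
    uniform = totals <= 0
    if uniform.any():
        weights[uniform] = 1.0
        totals = weights.sum(axis=1)
    cum = np.cumsum(weights, axis=1)
    u = rng.random(len(brood)) * totals
    idx = (cum < u[:, None]).sum(axis=1)
    return brood[np.arange(len(brood)), idx]


def _weighted_pick_k(brood: np.ndarray, k: int, bias: float, rng) -> np.ndarray:
    """Weighted sample of k individuals per row without replacement
    (Efraimidis-Spirakis keys)."""
    carrier = (brood[..., FOCAL] == 1).any(axis=-1)
    weights = np.where(carrier, bias, 1.0)
    weights = np.maximum(weights, 1e-12)
    keys = rng.random(weights.shape) ** (1.0 / weights)
    idx = np.argpartition(-keys, k - 1, axis=1)[:, :k]
    return brood[np.arange(len(brood))[:, None], idx]


def simulate_intercross(config: SimConfig, rng: Optional[np.random.Generator] = None) -> SimResult:
    """Run one replicate of the breeding design."""
    if rng is None:
        rng = np.random.default_rng()
    P = config.n_founder_crosses
    B = config.brood_size
    r = config.r
    bias_inter = config.pick_bias if config.bias_scope in ("both", "intermating") else 1.0
    bias_self = config.pick_bias if config.bias_scope in ("both", "selfing") else 1.0
    x_linked = config.linkage == "x_linked"

    # founder plates; directions alternate so initial allele frequency is 1/2
    herm = np.empty((P, 2, 2), dtype=np.int8)
    herm[0::2] = 1  # focal-strain hermaphrodite
    herm[1::2] = 0
    if x_linked:
        male = np.empty((P, 2), dtype=np.int8)  # single X haplotype
        male[0::2] = 0
        male[1::2] = 1
    else:
        male = np.empty((P, 2, 2), dtype=np.int8)
        male[0::2] = 0
        male[1::2] = 1

    for _ in range(config.intermating_generations):
        herm_src = rng.integers(0, P, size=P)
        male_src = (herm_src + rng.integers(1, P, size=P)) % P
        # hermaphrodite offspring of each source plate's parents
        oocytes = _gametes(herm[herm_src], (P, B), r, rng)
        if x_linked:
            paternal_h = np.broadcast_to(male[herm_src][:, None, :], (P, B, 2))
            herm_brood = np.stack([oocytes, paternal_h], axis=2)
            # male offspring carry only the maternal X
            male_brood = _gametes(herm[male_src], (P, B), r, rng)
        else:
            paternal_h = _gametes(male[herm_src], (P, B), r, rng)
            herm_brood = np.stack([oocytes, paternal_h], axis=2)
            male_brood = np.stack(
                [
                    _gametes(herm[male_src], (P, B), r, rng),
                    _gametes(male[male_src], (P, B), r, rng),
                ],
                axis=2,
            )
        herm = _weighted_pick_one(herm_brood, bias_inter, rng)
        male = _weighted_pick_one(male_brood, 1.0, rng)  # bias acts on hermaphrodites

    # found the selfing lines: k hermaphrodites per final mating plate
    oocytes = _gametes(herm, (P, B), r, rng)
    if x_linked:
        paternal_h = np.broadcast_to(male[:, None, :], (P, B, 2))
    else:
        paternal_h = _gametes(male, (P, B), r, rng)
    herm_brood = np.stack([oocytes, paternal_h], axis=2)
    founders = _weighted_pick_k(herm_brood, config.lines_per_cross, bias_inter, rng)
    lines = founders.reshape(-1, 2, 2)
    n_lines = len(lines)

    het = [float((lines[:, 0, FOCAL] != lines[:, 1, FOCAL]).mean())]
    for _ in range(config.selfing_generations):
        # selfing: two independent gametes from the same hermaphrodite
        g1 = _gametes(lines, (n_lines, B), r, rng)
        g2 = _gametes(lines, (n_lines, B), r, rng)
        brood = np.stack([g1, g2], axis=2)
        lines = _weighted_pick_one(brood, bias_self, rng)
        het.append(float((lines[:, 0, FOCAL] != lines[:, 1, FOCAL]).mean()))

    surviving = rng.random(n_lines) >= config.extinction_prob
    return SimResult(
        focal_genotypes=lines[:, :, FOCAL].copy(),
        marker_genotypes=lines[:, :, MARKER].copy(),
        surviving=surviving,
        het_trajectory=np.asarray(het),
        config=config,
    )


def heterozygosity_trajectory(result: SimResult) -> np.ndarray:
    """Observed heterozygous-line fraction at the focal locus, one entry per
    selfing generation (index 0 = line founders)."""
    return result.het_trajectory


def expected_selfing_heterozygosity(h0: float, generations: int) -> float:
    """Closed form: selfing halves expected heterozygosity each generation."""
    return h0 * 0.5**generations


@dataclass
class BiasFit:
    b_hat: float
    interval: tuple[float, float]
    table: pd.DataFrame  # per grid point: mean fraction, SE


def fit_pick_bias(
    observed_fraction: float,
    config: SimConfig,
    grid: Sequence[float],
    replicates: int = 20,
    seed: int = 0,
) -> BiasFit:
    """Grid-search the picking bias that reproduces an observed line fraction.

    Each grid point is simulated with common random numbers (the same
    replicate seeds), the point minimizing ``|mean fraction - observed|``
    wins, and the interval collects grid values whose mean lies within two
    Monte-Carlo standard errors of the observation.
    """
    if not 0.0 <= observed_fraction <= 1.0:
        raise ValueError("observed_fraction must be in [0, 1]")
    seeds = np.random.SeedSequence(seed).spawn(replicates)
    rows = []
    for b in grid:
        cfg = SimConfig(
            n_founder_crosses=config.n_founder_crosses,
            intermating_generations=config.intermating_generations,
            lines_per_cross=config.lines_per_cross,
            selfing_generations=config.selfing_generations,
            linkage=config.linkage,
            r=config.r,
            pick_bias=b,
            brood_size=config.brood_size,
            extinction_prob=config.extinction_prob,
            bias_scope=config.bias_scope,
        )
        fractions = [
            simulate_intercross(cfg, np.random.default_rng(s)).focal_fraction
            for s in seeds
        ]
        fractions = np.asarray(fractions)
        rows.append(
            {
                "b": b,
                "mean_fraction": fractions.mean(),
                "se": fractions.std(ddof=1) / np.sqrt(replicates),
            }
        )
    table = pd.DataFrame(rows)
    gap = (table["mean_fraction"] - observed_fraction).abs()
    best = int(gap.idxmin())
    b_hat = float(table.loc[best, "b"])
    se = float(table.loc[best, "se"])
    within = table[gap <= 2.0 * max(se, 1e-12)]
    if within.empty:
        interval = (b_hat, b_hat)
    else:
        interval = (float(within["b"].min()), float(within["b"].max()))
    return BiasFit(b_hat=b_hat, interval=interval, table=table)
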