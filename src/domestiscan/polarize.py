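"""Ancestral-allele assignment by two-outgroup concordance.

At each polymorphic site the two outgroup wild strains are read out as
carrying either the reference-lineage (N2) allele or the focal-lineage (LSJ1)
allele.  When both agree, that allele is called ancestral and the mutation is
assigned to the opposite lineage; discordant or insufficient observations
yield an unknown ancestral state.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .model import Allele, GenotypeObservation, VariantCall

__all__ = [
    "AncestralState",
    "AncestralCall",
    "infer_ancestral",
    "observe_outgroup",
    "polarize_variants",
    "summarize_polarization",
]


class AncestralState(str, enum.Enum):
    ancestral_N2 = "ancestral_N2"
    ancestral_LSJ1 = "ancestral_LSJ1"
    unknown = "unknown"


_DERIVED = {
    AncestralState.ancestral_N2: "LSJ1",
    AncestralState.ancestral_LSJ1: "N2",
    AncestralState.unknown: "unknown",
}

_TABLE_LABEL = {
    AncestralState.ancestral_N2: "N2",
    AncestralState.ancestral_LSJ1: "LSJ1",
    AncestralState.unknown: "unknown",
}


@dataclass(frozen=True)
class AncestralCall:
    state: AncestralState
    outgroup_support: tuple[GenotypeObservation, GenotypeObservation]
    third_allele: bool = False

    @property
    def derived_lineage(self) -> str:
        return _DERIVED[self.state]

    @property
    def label(self) -> str:
        """Ancestral-state vocabulary used in output tables (N2/LSJ1/unknown)."""
        return _TABLE_LABEL[self.state]


def infer_ancestral(
    outgroup_obs: tuple[GenotypeObservation, GenotypeObservation],
    *,
    third_allele: bool = False,
    require_both: bool = True,
) -> AncestralCall:
    """Apply the two-witness concordance rule to a pair of outgroup observations.

    ``reference_like`` means the outgroup carries the N2 allele and
    ``focal_like`` the LSJ1 allele.  Under the default strict rule both
    outgroups must show the same allele; a single informative witness (the
    other missing) yields ``unknown`` unless ``require_both=False``.  An
    outgroup allele matching neither strain allele is signalled via
    ``third_allele`` and always yields ``unknown``.
    """
    a, b = outgroup_obs
    if third_allele:
        return AncestralCall(AncestralState.unknown, (a, b), third_allele=True)
    alleles = (a.allele, b.allele)
    informative = [x for x in alleles if x is not Allele.missing]
    if len(set(informative)) == 1 and (len(informative) == 2 or not require_both):
        state = (
            AncestralState.ancestral_N2
            if informative[0] is Allele.reference_like
            else AncestralState.ancestral_LSJ1
        )
        return AncestralCall(state, (a, b))
    return AncestralCall(AncestralState.unknown, (a, b))


def observe_outgroup(
    call: VariantCall,
    outgroup_calls_by_pos: Mapping[tuple[str, int], Sequence[VariantCall]],
    strain: str,
) -> tuple[GenotypeObservation, bool]:
    """Read one outgroup strain out at a focal site.

    An outgroup record exactly matching the focal allele means the outgroup
    carries the LSJ1 allele; no record at the position means it matches the
    reference (N2 allele); a different record at the same position is a third
    allele.  Returns (observation, third_allele_flag).
    """
    here = outgroup_calls_by_pos.get((call.chrom, call.pos), ())
    if any(c.site_key == call.site_key for c in here):
        return GenotypeObservation(strain, Allele.focal_like), False
    if here:
        return GenotypeObservation(strain, Allele.reference_like), True
    return GenotypeObservation(strain, Allele.reference_like), False


def _index_by_pos(calls: Iterable[VariantCall]) -> dict[tuple[str, int], list[VariantCall]]:
    index: dict[tuple[str, int], list[VariantCall]] = {}
    for c in calls:
        index.setdefault((c.chrom, c.pos), []).append(c)
    return index


def polarize_variants(
    polymorphisms: Sequence[VariantCall],
    outgroup_a: tuple[str, Sequence[VariantCall]],
    outgroup_b: tuple[str, Sequence[VariantCall]],
    *,
    require_both: bool = True,
) -> list[AncestralCall]:
    """Polarize every polymorphism against two named outgroup call sets."""
    name_a, calls_a = outgroup_a
    name_b, calls_b = outgroup_b
    index_a = _index_by_pos(calls_a)
    index_b = _index_by_pos(calls_b)
    result = []
    for call in polymorphisms:
        obs_a, third_a = observe_outgroup(call, index_a, name_a)
        obs_b, third_b = observe_outgroup(call, index_b, name_b)
        result.append(
            infer_ancestral(
                (obs_a, obs_b),
                third_allele=third_a or third_b,
                require_both=require_both,
            )
        )
    return result


def summarize_polarization(calls: Sequence[AncestralCall]) -> dict:
    """Counts and percentages per ancestral state, with explicit denominators."""
    counts = {state: 0 for state in AncestralState}
    for c in calls:
        counts[c.state] += 1
    total = len(calls)
    polarized = counts[AncestralState.ancestral_N2] + counts[AncestralState.ancestral_LSJ1]
    discordant = sum(
        1
        for c in calls
        if not c.third_allele
        and Allele.missing not in (c.outgroup_support[0].allele, c.outgroup_support[1].allele)
        and c.outgroup_support[0].allele is not c.outgroup_support[1].allele
    )
    pct = {
        state: (100.0 * n / total if total else 0.0) for state, n in counts.items()
    }
    return {
        "counts": {state.value: n for state, n in counts.items()},
        "percent_of_total": {state.value: pct[state] for state in AncestralState},
        "total": total,
        "polarized": polarized,
        "discordant": discordant,
    }
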