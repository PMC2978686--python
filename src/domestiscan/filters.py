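"""Call-level quality, ambiguity, and large-indel retention rules.

Boundary semantics are deliberate: SNPs below 50 and small indels below 25
are discarded (strict less-than), large insertions are kept only with scores
strictly above 35, and every large deletion is kept regardless of score.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

from .model import VariantCall, VType

__all__ = [
    "FilterConfig",
    "DiscardReason",
    "apply_quality_filter",
    "apply_large_indel_filter",
    "apply_all_filters",
]


class DiscardReason(str, enum.Enum):
    low_quality = "low_quality"
    ambiguous = "ambiguous"


@dataclass(frozen=True)
class FilterConfig:
    q_snp_min: float = 50.0
    q_small_indel_min: float = 25.0
    q_large_ins_min: float = 35.0
    drop_ambiguous: bool = True

    def __post_init__(self) -> None:
        for name in ("q_snp_min", "q_small_indel_min", "q_large_ins_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


Partition = tuple[list[VariantCall], list[tuple[VariantCall, DiscardReason]]]


def apply_quality_filter(
    calls: Iterable[VariantCall], config: FilterConfig = FilterConfig()
) -> Partition:
    """Partition SNPs and small indels into kept vs discarded-with-reason.

    Large indels pass through untouched (see :func:`apply_large_indel_filter`).
    Ambiguity is checked first: an ambiguous call is discarded as ambiguous
    even if it also fails the quality threshold.
    """
    kept: list[VariantCall] = []
    discarded: list[tuple[VariantCall, DiscardReason]] = []
    for call in calls:
        if not call.is_small:
            kept.append(call)
            continue
        if config.drop_ambiguous and call.ambiguous:
            discarded.append((call, DiscardReason.ambiguous))
            continue
        threshold = config.q_snp_min if call.vtype is VType.snp else config.q_small_indel_min
        if call.quality < threshold:
            discarded.append((call, DiscardReason.low_quality))
        else:
            kept.append(call)
    return kept, discarded


def apply_large_indel_filter(
    calls: Iterable[VariantCall], config: FilterConfig = FilterConfig()
) -> Partition:
    """Keep all large deletions; keep large insertions only above the score bound.

    Small calls pass through untouched.
    """
    kept: list[VariantCall] = []
    discarded: list[tuple[VariantCall, DiscardReason]] = []
    for call in calls:
        if call.vtype is VType.large_ins and not call.quality > config.q_large_ins_min:
            discarded.append((call, DiscardReason.low_quality))
        else:
            kept.append(call)
    return kept, discarded


def apply_all_filters(
    calls: Sequence[VariantCall], config: FilterConfig = FilterConfig()
) -> Partition:
    """Route each call through the filter appropriate to its type."""
    small = [c for c in calls if c.is_small]
    large = [c for c in calls if not c.is_small]
    kept_s, disc_s = apply_quality_filter(small, config)
    kept_l, disc_l = apply_large_indel_filter(large, config)
    return kept_s + kept_l, disc_s + disc_l
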