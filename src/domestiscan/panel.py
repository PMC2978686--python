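"""Reference-error classification by panel vote.

Each candidate focal-vs-reference difference is checked against a panel of
independently resequenced reference-lineage strains.  If at least ``k`` of the
``n`` panel strains show the focal allele, the published reference sequence —
not the focal strain — is taken to be wrong at that site and the call is
classified as a reference error; otherwise it is a true polymorphism.

A panel strain whose VCF lacks the site cannot be distinguished from one with
no coverage there, so absence is conservatively recorded as ``missing`` and
never votes for an error.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .model import Allele, GenotypeObservation, VariantCall, VariantStatus

__all__ = [
    "PanelConfig",
    "SiteClassification",
    "classify_site",
    "partition_variants",
]


@dataclass(frozen=True)
class PanelConfig:
    #: minimum number of panel strains showing the focal allele to call an error
    k: int = 4
    #: panel size
    n: int = 6
    #: "panel" counts k against the full panel; "observed" rescales k by the
    #: number of strains with an informative observation
    vote_denominator: str = "panel"

    def __post_init__(self) -> None:
        if not 1 <= self.k <= self.n:
            raise ValueError(f"need 1 <= k <= n, got k={self.k}, n={self.n}")
        if self.vote_denominator not in ("panel", "observed"):
            raise ValueError("vote_denominator must be 'panel' or 'observed'")


@dataclass(frozen=True)
class SiteClassification:
    status: VariantStatus
    support_count: int
    missing_count: int


def classify_site(
    observations: Sequence[GenotypeObservation], config: PanelConfig = PanelConfig()
) -> SiteClassification:
    """Vote across panel observations at one site.

    ``missing`` observations never count toward ``k``.  In the default
    ("panel") mode the threshold is ``k`` regardless of how many strains were
    observed; in "observed" mode it is ``ceil(k * observed / n)`` with at
    least one supporting strain required.
    """
    strains = [o.strain for o in observations]
    if len(strains) != len(set(strains)):
        raise ValueError("duplicate strain in observations")
    if len(observations) > config.n:
        raise ValueError(f"more observations ({len(observations)}) than panel size {config.n}")
    support = sum(o.allele is Allele.focal_like for o in observations)
    missing = sum(o.allele is Allele.missing for o in observations)
    if config.vote_denominator == "observed":
        observed = len(observations) - missing
        threshold = max(1, math.ceil(config.k * observed / config.n))
    else:
        threshold = config.k
    status = (
        VariantStatus.reference_error if support >= threshold else VariantStatus.polymorphism
    )
    return SiteClassification(status, support, missing)


def partition_variants(
    calls: Iterable[VariantCall],
    panel_calls: Mapping[str, Sequence[VariantCall]],
    config: PanelConfig = PanelConfig(),
) -> tuple[
    list[tuple[VariantCall, SiteClassification]],
    list[tuple[VariantCall, SiteClassification]],
]:
    """Split quality-filtered calls into (reference errors, polymorphisms).

    ``panel_calls`` maps each panel strain to its own focal-vs-reference call
    set; sites are matched on exact ``(chrom, pos, ref, alt)`` identity.  A
    panel strain sharing no site with the focal calls triggers a warning
    (suspicious input) but not a failure.
    """
    if len(panel_calls) != config.n:
        warnings.warn(
            f"panel has {len(panel_calls)} strains but config.n={config.n}; "
            "votes are counted against config.n"
        )
    call_list = list(calls)
    focal_keys = {c.site_key for c in call_list}
    strain_sites: dict[str, set] = {}
    for strain, sc in panel_calls.items():
        keys = {c.site_key for c in sc}
        if call_list and not keys & focal_keys:
            warnings.warn(f"panel strain {strain!r} shares no site with the focal calls")
        strain_sites[strain] = keys

    errors: list[tuple[VariantCall, SiteClassification]] = []
    polymorphisms: list[tuple[VariantCall, SiteClassification]] = []
    for call in call_list:
        obs = [
            GenotypeObservation(
                strain,
                Allele.focal_like if call.site_key in keys else Allele.missing,
            )
            for strain, keys in strain_sites.items()
        ]
        cls = classify_site(obs, config)
        if cls.status is VariantStatus.reference_error:
            errors.append((call, cls))
        else:
            polymorphisms.append((call, cls))
    return errors, polymorphisms
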