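"""Degrader verdicts and pathway assignment from per-genome hits.

A genome is called a steroid degrader when its proteome hits at least six of
the eight key enzyme groups, and those present include both mandatory groups:
the KshA-like oxygenase subunit of the 3-ketosteroid 9alpha-hydroxylase and
the HsaC-like extradiol dioxygenase (both required for opening the steroid
A/B rings; the mandatory set is read inclusively, i.e. the two mandatory
groups count toward the six).

Pathway labels are assigned from reciprocal-best-hit coverage of reference
gene-cluster panels: a pathway applies when at least ``coverage_threshold``
(default 0.7, "a large majority") of the panel's query proteins have
reciprocal hits.  Side-chain degradation genes get a present/partial/absent
profile with 80%/20% bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set

from .errors import ConfigurationError
from .orthology import OrthologMap
from .phmm import HmmHit
from .simulate import CORE_GROUPS, MANDATORY_GROUPS

__all__ = [
    "EnzymePanel",
    "DegraderCall",
    "classify_degrader",
    "assign_pathway",
    "side_chain_profile",
]


@dataclass
class EnzymePanel:
    """The eight enzyme groups, their mandatory subset, and the HMM-to-group map."""

    groups: List[str] = field(default_factory=lambda: list(CORE_GROUPS))
    mandatory: Set[str] = field(default_factory=lambda: set(MANDATORY_GROUPS))
    hmm_to_group: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.mandatory <= set(self.groups):
            raise ConfigurationError("mandatory groups must be a subset of groups")
        unknown = set(self.hmm_to_group.values()) - set(self.groups)
        if unknown:
            raise ConfigurationError(f"hmm_to_group maps to unknown groups: {sorted(unknown)}")

    def group_of(self, hmm_id: str) -> str:
        try:
            return self.hmm_to_group[hmm_id]
        except KeyError:
            raise ConfigurationError(f"hit references unknown HMM id {hmm_id!r}") from None


@dataclass
class DegraderCall:
    genome_id: str
    groups_present: Set[str]
    mandatory_satisfied: bool
    verdict: str  # "degrader" | "non-degrader"
    pathways: Dict[str, float] = field(default_factory=dict)  # label -> coverage

    @property
    def is_degrader(self) -> bool:
        return self.verdict == "degrader"


def classify_degrader(
    hits: Iterable[HmmHit],
    panel: EnzymePanel,
    min_groups: int = 6,
    genome_id: Optional[str] = None,
) -> DegraderCall:
    """Apply the presence/absence decision rule to one genome's HMM hits.

    verdict = degrader iff |groups with a passing hit| >= ``min_groups`` and
    every mandatory group is among them.
    """
    hits = list(hits)
    gids = {h.genome_id for h in hits if h.genome_id}
    if genome_id is None:
        if len(gids) > 1:
            raise ConfigurationError(f"hits span multiple genomes: {sorted(gids)}")
        genome_id = next(iter(gids), "")
    elif gids - {genome_id}:
        raise ConfigurationError("hits do not all belong to the stated genome")
    present = {panel.group_of(h.hmm_id) for h in hits}
    mandatory_ok = panel.mandatory <= present
    verdict = "degrader" if len(present) >= min_groups and mandatory_ok else "non-degrader"
    return DegraderCall(
        genome_id=genome_id,
        groups_present=present,
        mandatory_satisfied=mandatory_ok,
        verdict=verdict,
    )


def assign_pathway(
    ortholog_maps: Mapping[str, OrthologMap],
    panels: Mapping[str, Sequence[str]],
    coverage_threshold: float = 0.7,
) -> Dict[str, float]:
    """Pathway labels whose reference-panel reciprocal-hit coverage reaches
    the threshold (inclusive comparison).

    ``ortholog_maps`` maps pathway label to the genome's RBH map against that
    pathway's reference panel; ``panels`` maps label to panel protein ids.
    Returns every qualifying label with its coverage fraction.
    """
    if not panels:
        raise ConfigurationError("no reference panels configured")
    out: Dict[str, float] = {}
    for label, ref_ids in panels.items():
        if not ref_ids:
            raise ConfigurationError(f"empty reference panel {label!r}")
        omap = ortholog_maps.get(label)
        if omap is None:
            continue
        cov = omap.coverage(list(ref_ids))
        if cov >= coverage_threshold:
            out[label] = cov
    return out


def side_chain_profile(
    ortholog_map: OrthologMap,
    side_chain_gene_ids: Sequence[str],
    present_threshold: float = 0.8,
    absent_threshold: float = 0.2,
) -> str:
    """'present' if >= 80% of the side-chain genes have reciprocal hits,
    'absent' if <= 20%, else 'partial'."""
    if not side_chain_gene_ids:
        return "absent"
    frac = sum(g in ortholog_map.entries for g in side_chain_gene_ids) / len(
        side_chain_gene_ids
    )
    if frac >= present_threshold:
        return "present"
    if frac <= absent_threshold:
        return "absent"
    return "partial"
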