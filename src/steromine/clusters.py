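"""Genomic localization of pathway hits: cluster detection on replicons and
chromosome-vs-plasmid classification.

Hits are mapped onto gene coordinates and chained per replicon by
single-linkage: two hit genes belong to one cluster when at most
``max_gap_genes`` non-hit genes lie between them (a gene-count criterion,
robust to intergenic-length choices; the threshold is configurable and
reported in outputs).  Circular replicons are chained with wraparound, so the
partition is invariant under rotation of the origin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .errors import InputError

__all__ = [
    "LocatedGene",
    "GeneClusterCall",
    "locate_hits",
    "detect_clusters",
    "replicon_summary",
]


@dataclass(frozen=True)
class LocatedGene:
    gene_id: str
    genome_id: str
    replicon_id: str
    replicon_type: str  # chromosome | plasmid
    start: int  # 0-based half-open
    end: int
    strand: str
    gene_index: int  # ordinal position on the replicon
    group_label: str = ""


@dataclass
class GeneClusterCall:
    cluster_id: str
    genome_id: str
    replicon_id: str
    replicon_type: str
    members: List[LocatedGene]  # sorted by coordinate

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def span(self) -> Tuple[int, int]:
        return (min(g.start for g in self.members), max(g.end for g in self.members))

    @property
    def member_ids(self) -> List[str]:
        return [g.gene_id for g in self.members]


def locate_hits(
    hit_protein_ids: Iterable[str],
    annotation: pd.DataFrame,
    genome_id: str = "",
    labels: Optional[Mapping[str, str]] = None,
) -> Tuple[List[LocatedGene], List[str]]:
    """Resolve hit protein ids to located genes via an annotation table.

    ``annotation`` needs columns gene_id, replicon_id, replicon_type, start,
    end, strand, gene_index.  Returns (located genes, unresolved ids);
    unresolvable ids are reported, never silently dropped.
    """
    required = {"gene_id", "replicon_id", "replicon_type", "start", "end", "strand", "gene_index"}
    missing = required - set(annotation.columns)
    if missing:
        raise InputError(f"annotation lacks columns: {sorted(missing)}")
    by_id = annotation.set_index("gene_id")
    located: List[LocatedGene] = []
    unresolved: List[str] = []
    for pid in sorted(set(hit_protein_ids)):
        if pid not in by_id.index:
            unresolved.append(pid)
            continue
        row = by_id.loc[pid]
        located.append(
            LocatedGene(
                gene_id=pid,
                genome_id=genome_id,
                replicon_id=str(row["replicon_id"]),
                replicon_type=str(row["replicon_type"]),
                start=int(row["start"]),
                end=int(row["end"]),
                strand=str(row["strand"]),
                gene_index=int(row["gene_index"]),
                group_label=(labels or {}).get(pid, ""),
            )
        )
    return located, unresolved


def detect_clusters(
    located: Sequence[LocatedGene],
    max_gap_genes: int = 10,
    replicon_gene_counts: Optional[Mapping[str, int]] = None,
    circular: Optional[Mapping[str, bool]] = None,
) -> List[GeneClusterCall]:
    """Single-linkage chaining of located genes per replicon.

    Two genes join one cluster iff at most ``max_gap_genes`` non-hit genes
    lie between them (by gene index).  For circular replicons the gap across
    the origin also links, which requires the replicon's total gene count
    (``replicon_gene_counts``); replicons default to circular.
    """
    if max_gap_genes < 0:
        raise InputError("max_gap_genes must be non-negative")
    by_rep: Dict[str, List[LocatedGene]] = {}
    for g in located:
        by_rep.setdefault(g.replicon_id, []).append(g)
    calls: List[GeneClusterCall] = []
    for rep in sorted(by_rep):
        genes = sorted(by_rep[rep], key=lambda g: g.gene_index)
        # chain linearly
        groups: List[List[LocatedGene]] = [[genes[0]]]
        for g in genes[1:]:
            gap = g.gene_index - groups[-1][-1].gene_index - 1
            if gap <= max_gap_genes:
                groups[-1].append(g)
            else:
                groups.append([g])
        # wraparound: join last and first group if the origin gap links them
        is_circular = True if circular is None else circular.get(rep, True)
        n_total = (replicon_gene_counts or {}).get(rep)
        if is_circular and len(groups) > 1 and n_total is not None:
            wrap_gap = (n_total - 1 - groups[-1][-1].gene_index) + groups[0][0].gene_index
            if wrap_gap <= max_gap_genes:
                groups[0] = groups.pop() + groups[0]
        for ci, members in enumerate(groups):
            ordered = sorted(members, key=lambda g: g.gene_index)
            calls.append(
                GeneClusterCall(
                    cluster_id=f"{rep}_cluster{ci + 1}",
                    genome_id=ordered[0].genome_id,
                    replicon_id=rep,
                    replicon_type=ordered[0].replicon_type,
                    members=ordered,
                )
            )
    return calls


@dataclass
class GenomeClusterSummary:
    genome_id: str
    n_clusters: int
    n_plasmid_clusters: int
    plasmid_only: bool
    cluster_ids: List[str]
    group_composition: Dict[str, List[str]]  # cluster id -> group labels


def replicon_summary(clusters: Sequence[GeneClusterCall]) -> Dict[str, GenomeClusterSummary]:
    """Per-genome counts and plasmid flags.

    A genome whose pathway clusters sit exclusively on plasmids is flagged
    ``plasmid_only`` (the pattern of degraders whose chromosomes carry no
    steroid genes)."""
    by_genome: Dict[str, List[GeneClusterCall]] = {}
    for c in clusters:
        by_genome.setdefault(c.genome_id, []).append(c)
    out: Dict[str, GenomeClusterSummary] = {}
    for gid, cs in sorted(by_genome.items()):
        n_plasmid = sum(c.replicon_type == "plasmid" for c in cs)
        out[gid] = GenomeClusterSummary(
            genome_id=gid,
            n_clusters=len(cs),
            n_plasmid_clusters=n_plasmid,
            plasmid_only=n_plasmid == len(cs) and n_plasmid > 0,
            cluster_ids=[c.cluster_id for c in cs],
            group_composition={
                c.cluster_id: [g.group_label for g in c.members] for c in cs
            },
        )
    return out
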