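"""Reference-protein binning: thresholded similarity graphs and greedy
incremental (CD-HIT-style) subclustering.

Homologous groups are the connected components of a graph whose edges are
best local alignments passing both an identity and an E-value filter
(defaults 30% and 1e-30, the binning thresholds of the pipeline).  Groups are
then split into subclusters by greedy incremental clustering at 50% identity
with a word-size-3 prefilter: proteins are processed longest first and join
the earliest-created cluster whose representative they match, else found a
new cluster.

Identity convention for clustering: identical aligned residues divided by the
length of the shorter sequence (the convention of the reference clustering
tool); the graph stage uses alignment-length identity like every BLAST-style
step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Set, Tuple

import networkx as nx
import pandas as pd

from .align import ScoringScheme, default_scheme, estimate_evalue, local_align
from .errors import InputError

__all__ = [
    "HomologyGraph",
    "SubclusterSet",
    "build_graph",
    "connected_components",
    "greedy_cluster",
    "retain_seeded",
    "cluster_identity",
]


@dataclass
class HomologyGraph:
    """Undirected similarity graph over protein ids."""

    graph: nx.Graph
    min_identity: float
    max_evalue: float

    @property
    def nodes(self) -> List[str]:
        return sorted(self.graph.nodes)

    def edges(self) -> List[Tuple[str, str, float, float]]:
        return sorted(
            (min(a, b), max(a, b), d["identity"], d["evalue"])
            for a, b, d in self.graph.edges(data=True)
        )


def build_graph(
    proteins: Dict[str, str],
    min_identity: float = 0.30,
    max_evalue: float = 1e-30,
    scoring: Optional[ScoringScheme] = None,
) -> HomologyGraph:
    """All-vs-all similarity graph; an edge is present iff the best local
    alignment of the pair passes both thresholds.

    E-values are computed against the whole input set (database residues =
    total residue count), matching an all-vs-all search.
    """
    if len(proteins) < 2:
        raise InputError("need at least 2 proteins to build a graph")
    scoring = scoring or default_scheme()
    db_residues = sum(len(s) for s in proteins.values())
    g = nx.Graph()
    g.add_nodes_from(proteins)
    ids = sorted(proteins)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            hit = local_align(proteins[a], proteins[b], scoring, a, b)
            if hit is None:
                continue
            ev = estimate_evalue(hit, len(proteins[a]), db_residues, scoring)
            if hit.identity >= min_identity and ev <= max_evalue:
                g.add_edge(a, b, identity=hit.identity, evalue=ev)
    return HomologyGraph(graph=g, min_identity=min_identity, max_evalue=max_evalue)


def connected_components(graph: HomologyGraph) -> List[Set[str]]:
    """Homologous groups: connected components, largest first then by the
    lexicographically smallest member (singletons allowed)."""
    comps = [set(c) for c in nx.connected_components(graph.graph)]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


@dataclass
class SubclusterSet:
    """Partition of proteins into clusters with one representative each."""

    clusters: List[List[str]]  # creation order; representative is first member
    min_identity: float

    @property
    def representatives(self) -> List[str]:
        return [c[0] for c in self.clusters]

    def members(self) -> Set[str]:
        return {m for c in self.clusters for m in c}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ci, cluster in enumerate(self.clusters):
            for m in cluster:
                rows.append(
                    {
                        "cluster_id": ci,
                        "member_id": m,
                        "representative": m == cluster[0],
                    }
                )
        return pd.DataFrame(rows)

    def to_clstr(self, lengths: Dict[str, int]) -> str:
        out = []
        for ci, cluster in enumerate(self.clusters):
            out.append(f">Cluster {ci}")
            for mi, m in enumerate(cluster):
                mark = "*" if m == cluster[0] else f"at {self.min_identity:.0%}"
                out.append(f"{mi}\t{lengths[m]}aa, >{m}... {mark}")
        return "\n".join(out) + "\n"


def cluster_identity(a: str, b: str, scoring: Optional[ScoringScheme] = None) -> float:
    """Identity for clustering decisions: identical residues of the best local
    alignment over the shorter sequence length."""
    hit = local_align(a, b, scoring)
    if hit is None:
        return 0.0
    matches = round(hit.identity * hit.aligned_length)
    return matches / min(len(a), len(b))


def _kmers(seq: str, k: int) -> Dict[str, int]:
    out: Dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        out[w] = out.get(w, 0) + 1
    return out


def _shared_words(ka: Dict[str, int], kb: Dict[str, int]) -> int:
    if len(kb) < len(ka):
        ka, kb = kb, ka
    return sum(min(n, kb[w]) for w, n in ka.items() if w in kb)


def greedy_cluster(
    proteins: Dict[str, str],
    min_identity: float = 0.50,
    word_size: int = 3,
    scoring: Optional[ScoringScheme] = None,
) -> SubclusterSet:
    """Greedy incremental clustering, longest sequence first (length ties
    broken lexicographically by id).

    Each protein is compared against existing cluster representatives in
    cluster-creation order and joins the first one it matches at
    ``min_identity`` or better; otherwise it founds a new cluster.  A shared
    k-mer count prefilter skips representatives that cannot reach the
    threshold (each mismatching position destroys at most ``word_size``
    k-mers); correctness is defined by the identity test alone.
    """
    if not proteins:
        raise InputError("no proteins to cluster")
    if word_size < 1:
        raise InputError("word_size must be at least 1")
    scoring = scoring or default_scheme()
    order = sorted(proteins, key=lambda i: (-len(proteins[i]), i))
    clusters: List[List[str]] = []
    rep_kmers: List[Dict[str, int]] = []
    for pid in order:
        seq = proteins[pid]
        km = _kmers(seq, word_size) if len(seq) >= word_size else {}
        placed = False
        for ci, cluster in enumerate(clusters):
            rep = proteins[cluster[0]]
            short = min(len(seq), len(rep))
            if short >= word_size:
                allowed_mismatches = short - int(min_identity * short)
                needed = (short - word_size + 1) - word_size * allowed_mismatches
                if needed > 0 and _shared_words(km, rep_kmers[ci]) < needed:
                    continue
            if cluster_identity(seq, rep, scoring) >= min_identity:
                cluster.append(pid)
                placed = True
                break
        if not placed:
            clusters.append([pid])
            rep_kmers.append(km)
    return SubclusterSet(clusters=clusters, min_identity=min_identity)


def retain_seeded(subclusters: SubclusterSet, seed_ids: Iterable[str]) -> SubclusterSet:
    """Keep only clusters containing at least one seed protein (the filter
    that discards potentially non-orthologous subclusters)."""
    seeds = set(seed_ids)
    unknown = seeds - subclusters.members()
    if unknown:
        raise InputError(f"unknown seed ids: {sorted(unknown)}")
    kept = [c for c in subclusters.clusters if seeds.intersection(c)]
    return SubclusterSet(clusters=[list(c) for c in kept], min_identity=subclusters.min_identity)
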