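"""Concatenated-marker (MLSA) phylogenetics: supermatrix construction,
Poisson-corrected distances, neighbor joining, bootstrap support, and
Robinson-Foulds congruence testing.

The marker panel defaults to the four steroid-degradation proteins used for
the pathway phylogeny (the KshA-like oxygenase, HsaA-like monooxygenase,
HsaC-like extradiol dioxygenase and HsaD-like hydrolase); one taxon is
emitted per gene cluster, so a genome carrying two pathway clusters appears
twice.  Trees are built by neighbor joining on Poisson-corrected protein
distances d = -ln(1 - p) with pairwise gap deletion; congruence between the
marker tree and the species tree is measured as the Robinson-Foulds
bipartition distance on shared leaves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .errors import AnalysisError, InputError
from .msa import GAP, progressive_align, trim_columns

__all__ = [
    "DEFAULT_MARKERS",
    "Supermatrix",
    "extract_markers",
    "build_supermatrix",
    "protein_distance",
    "distance_matrix",
    "nj_tree",
    "bootstrap_support",
    "bipartitions",
    "rf_distance",
]

DEFAULT_MARKERS = ["KshA", "HsaA", "HsaC", "HsaD"]


@dataclass
class Supermatrix:
    """Concatenated per-marker trimmed alignments over a common taxon set."""

    taxa: List[str]
    rows: Dict[str, str]  # taxon -> concatenated aligned row
    block_coords: List[Tuple[str, int, int]]  # (marker, start, end) half-open

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def block(self, marker: str) -> Dict[str, str]:
        for m, s, e in self.block_coords:
            if m == marker:
                return {t: self.rows[t][s:e] for t in self.taxa}
        raise KeyError(marker)


def extract_markers(
    taxon_markers: Mapping[str, Mapping[str, Optional[str]]],
    marker_panel: Sequence[str] = tuple(DEFAULT_MARKERS),
) -> Tuple[Dict[str, Dict[str, str]], List[str]]:
    """Retain taxa (gene clusters) that carry all panel markers.

    ``taxon_markers`` maps taxon id (typically one per gene cluster) to the
    marker sequences found for it; taxa missing any marker go to the drop
    report.  Raises when no complete taxon remains.
    """
    kept: Dict[str, Dict[str, str]] = {}
    dropped: List[str] = []
    for taxon in sorted(taxon_markers):
        seqs = taxon_markers[taxon]
        if all(seqs.get(m) for m in marker_panel):
            kept[taxon] = {m: str(seqs[m]) for m in marker_panel}
        else:
            dropped.append(taxon)
    if not kept:
        raise AnalysisError("no taxon carries the complete marker panel")
    return kept, dropped


def build_supermatrix(
    marker_sets: Mapping[str, Mapping[str, str]],
    marker_panel: Optional[Sequence[str]] = None,
    max_gap_fraction: float = 0.5,
) -> Supermatrix:
    """Align each marker across taxa, trim gappy columns, and concatenate the
    blocks in fixed marker order."""
    taxa = sorted(marker_sets)
    if len(taxa) < 3:
        raise AnalysisError("a supermatrix needs at least 3 taxa")
    if marker_panel is None:
        marker_panel = sorted(next(iter(marker_sets.values())))
    rows = {t: "" for t in taxa}
    coords: List[Tuple[str, int, int]] = []
    pos = 0
    for marker in marker_panel:
        aln = progressive_align({t: marker_sets[t][marker] for t in taxa})
        aln = trim_columns(aln, max_gap_fraction)
        for t, row in zip(aln.ids, aln.rows):
            rows[t] += row
        coords.append((marker, pos, pos + aln.n_columns))
        pos += aln.n_columns
    return Supermatrix(taxa=taxa, rows=rows, block_coords=coords)


def _p_distance(row_a: str, row_b: str) -> Tuple[float, int]:
    diffs = 0
    shared = 0
    for a, b in zip(row_a, row_b):
        if a == GAP or b == GAP:
            continue
        shared += 1
        if a != b:
            diffs += 1
    return (diffs / shared if shared else 0.0), shared


def protein_distance(row_a: str, row_b: str) -> float:
    """Poisson-corrected distance d = -ln(1 - p) in substitutions per site,
    with pairwise deletion of gapped columns."""
    if len(row_a) != len(row_b):
        raise InputError("aligned rows must have equal length")
    p, shared = _p_distance(row_a, row_b)
    if shared == 0:
        raise InputError("no shared non-gap column")
    if p >= 1.0:
        raise AnalysisError("saturated pair (p >= 1): distance undefined")
    return -math.log(1.0 - p)


def distance_matrix(sm: Supermatrix, p_cap: Optional[float] = None) -> DistanceMatrix:
    """All-pairs Poisson-corrected distances; ``p_cap`` optionally truncates
    the observed proportion (used by bootstrap resampling, where a resampled
    pair can otherwise saturate)."""
    n = len(sm.taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p, shared = _p_distance(sm.rows[sm.taxa[i]], sm.rows[sm.taxa[j]])
            if shared == 0:
                raise AnalysisError(
                    f"taxa {sm.taxa[i]} and {sm.taxa[j]} share no non-gap column"
                )
            if p_cap is not None:
                p = min(p, p_cap)
            elif p >= 1.0:
                raise AnalysisError("saturated pair (p >= 1): distance undefined")
            d[i, j] = d[j, i] = -math.log(1.0 - p)
    return DistanceMatrix(d, ids=sm.taxa)


def nj_tree(dm) -> TreeNode:
    """Neighbor-joining tree; negative branch-length estimates are clamped to
    zero.  Accepts a skbio DistanceMatrix or a square array plus ids tuple."""
    if not isinstance(dm, DistanceMatrix):
        data, ids = dm
        data = np.asarray(data, dtype=float)
        if not np.allclose(data, data.T):
            raise InputError("distance matrix must be symmetric")
        dm = DistanceMatrix(data, ids=list(ids))
    if dm.shape[0] < 3:
        raise InputError("neighbor joining needs at least 3 taxa")
    tree = nj(dm)
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def bipartitions(tree: TreeNode, leaves: Optional[Set[str]] = None) -> Set[FrozenSet[str]]:
    """Non-trivial bipartitions as canonical frozensets: for each internal
    edge, the side not containing the lexicographically smallest leaf."""
    all_leaves = {t.name for t in tree.tips()}
    if leaves is not None:
        all_leaves = all_leaves & leaves
    if not all_leaves:
        return set()
    anchor = min(all_leaves)
    out: Set[FrozenSet[str]] = set()
    for node in tree.non_tips(include_self=False):
        clade = {t.name for t in node.tips()} & all_leaves
        side = all_leaves - clade if anchor in clade else clade
        if 2 <= len(side) <= len(all_leaves) - 2:
            out.add(frozenset(side))
    return out


def rf_distance(tree_a: TreeNode, tree_b: TreeNode) -> int:
    """Robinson-Foulds distance on the shared leaf set: the symmetric
    difference of non-trivial bipartitions after pruning both trees to the
    shared leaves.  0 means identical unrooted topologies."""
    leaves_a = {t.name for t in tree_a.tips()}
    leaves_b = {t.name for t in tree_b.tips()}
    shared = leaves_a & leaves_b
    if len(shared) < 3:
        raise InputError("need at least 3 shared leaves")
    pa = tree_a.shear(sorted(shared))
    pb = tree_b.shear(sorted(shared))
    ba = bipartitions(pa, shared)
    bb = bipartitions(pb, shared)
    return len(ba ^ bb)


def bootstrap_support(
    sm: Supermatrix,
    n_replicates: int = 2500,
    seed: int = 0,
    p_cap: float = 0.95,
) -> Tuple[TreeNode, Dict[FrozenSet[str], float]]:
    """NJ tree from the full supermatrix with bootstrap supports.

    Columns are resampled with replacement per replicate; support is the
    percentage of replicate trees containing each original bipartition, and
    is written onto internal node names.  Resampled pairs use a truncated
    observed proportion (``p_cap``) so a saturated draw cannot abort a
    replicate.
    """
    if n_replicates < 1:
        raise InputError("n_replicates must be positive")
    rng = np.random.default_rng(seed)
    tree = nj_tree(distance_matrix(sm))
    target = bipartitions(tree)
    counts = {bp: 0 for bp in target}
    n_cols = sm.n_columns
    mat = np.array([list(sm.rows[t]) for t in sm.taxa])
    for _ in range(n_replicates):
        idx = rng.integers(0, n_cols, size=n_cols)
        rep_rows = {t: "".join(mat[i, idx]) for i, t in enumerate(sm.taxa)}
        rep_sm = Supermatrix(taxa=sm.taxa, rows=rep_rows, block_coords=[("all", 0, n_cols)])
        rep_tree = nj_tree(distance_matrix(rep_sm, p_cap=p_cap))
        rep_bps = bipartitions(rep_tree)
        for bp in target:
            if bp in rep_bps:
                counts[bp] += 1
    support = {bp: 100.0 * c / n_replicates for bp, c in counts.items()}
    all_leaves = {t.name for t in tree.tips()}
    anchor = min(all_leaves)
    for node in tree.non_tips(include_self=False):
        clade = {t.name for t in node.tips()}
        side = all_leaves - clade if anchor in clade else clade
        key = frozenset(side)
        if key in support:
            node.name = f"{support[key]:.0f}"
    return tree, support
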