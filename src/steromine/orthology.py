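"""Reciprocal-best-hit orthology between a reference panel and target
proteomes, and the per-genome identity matrix behind the heat-map views.

Two threshold modes mirror the two stages of the screen:

* ``expansion`` — building the reference set (E <= 1e-30, identity >= 25%),
* ``confirmation`` — confirming candidate degraders (E <= 1e-25,
  identity >= 25%).

A reference protein maps to a target protein when the forward best hit passes
the mode's thresholds and the target's own best hit in the *complete*
reference proteome is the originating reference protein (the reciprocal
criterion that rejects out-paralogs).  Only the forward hit is thresholded;
the back hit must merely be best.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .align import (
    AlignmentHit,
    ScoringScheme,
    best_local_scores,
    default_scheme,
    local_align,
)
from .errors import ConfigurationError, InputError

__all__ = [
    "MODES",
    "OrthologEntry",
    "OrthologMap",
    "best_hit",
    "reciprocal_best_hits",
    "identity_matrix",
]

#: (max_evalue, min_identity) per threshold mode
MODES: Dict[str, Tuple[float, float]] = {
    "expansion": (1e-30, 0.25),
    "confirmation": (1e-25, 0.25),
}


@dataclass(frozen=True)
class OrthologEntry:
    reference_id: str
    target_id: str
    identity: float
    evalue: float
    reciprocal: bool


@dataclass
class OrthologMap:
    """Reference-to-target ortholog assignments for one genome."""

    mode: str
    entries: Dict[str, OrthologEntry]  # reference id -> entry (reciprocal only)
    collisions: Dict[str, List[str]] = field(default_factory=dict)

    def coverage(self, reference_ids: Sequence[str]) -> float:
        if not reference_ids:
            raise ConfigurationError("empty reference panel")
        return sum(r in self.entries for r in reference_ids) / len(reference_ids)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "reference_id": e.reference_id,
                "target_id": e.target_id,
                "identity": e.identity,
                "evalue": e.evalue,
                "reciprocal": e.reciprocal,
            }
            for e in sorted(self.entries.values(), key=lambda e: e.reference_id)
        ]
        return pd.DataFrame(
            rows, columns=["reference_id", "target_id", "identity", "evalue", "reciprocal"]
        )


def _ranked_targets(
    query: str, proteome: Dict[str, str], scoring: ScoringScheme
) -> List[Tuple[int, str]]:
    ids = sorted(proteome)
    scores = best_local_scores(query, [proteome[t] for t in ids], scoring)
    return sorted(zip((int(s) for s in scores), ids), key=lambda p: (-p[0], p[1]))


def best_hit(
    query_id: str,
    query: str,
    proteome: Dict[str, str],
    min_identity: float,
    max_evalue: float,
    scoring: Optional[ScoringScheme] = None,
) -> Optional[AlignmentHit]:
    """Best passing hit of one query in a proteome.

    Candidates are ranked by raw score (ties by target id); the highest-ranked
    one passing both the E-value and identity filters is returned.  E-values
    use the whole proteome's residue count as database size.
    """
    if not proteome:
        raise InputError("empty proteome")
    scoring = scoring or default_scheme()
    db_residues = sum(len(s) for s in proteome.values())
    for score, tid in _ranked_targets(query, proteome, scoring):
        if score <= 0:
            return None
        hit = local_align(
            query, proteome[tid], scoring, query_id, tid, database_residues=db_residues
        )
        if hit.evalue > max_evalue:
            return None  # ranked by score, so no later candidate can pass
        if hit.identity >= min_identity:
            return hit
    return None


def _best_scoring_id(
    query: str, proteome: Dict[str, str], scoring: ScoringScheme
) -> Optional[str]:
    ranked = _ranked_targets(query, proteome, scoring)
    if not ranked or ranked[0][0] <= 0:
        return None
    return ranked[0][1]


def reciprocal_best_hits(
    panel: Dict[str, str],
    target_proteome: Dict[str, str],
    reference_proteome: Dict[str, str],
    mode: str = "confirmation",
    scoring: Optional[ScoringScheme] = None,
) -> OrthologMap:
    """BackBLAST-style reciprocal best hits of a reference panel in a target
    proteome.

    The back search runs against the complete reference proteome, which must
    contain every panel protein.
    """
    if mode not in MODES:
        raise ConfigurationError(f"unknown mode {mode!r}")
    missing = [p for p in panel if p not in reference_proteome]
    if missing:
        raise ConfigurationError(f"panel proteins missing from reference proteome: {missing}")
    scoring = scoring or default_scheme()
    max_evalue, min_identity = MODES[mode]
    entries: Dict[str, OrthologEntry] = {}
    target_of: Dict[str, List[str]] = {}
    back_cache: Dict[str, Optional[str]] = {}
    for rid in sorted(panel):
        fwd = best_hit(rid, panel[rid], target_proteome, min_identity, max_evalue, scoring)
        if fwd is None:
            continue
        tid = fwd.target_id
        if tid not in back_cache:
            back_cache[tid] = _best_scoring_id(target_proteome[tid], reference_proteome, scoring)
        if back_cache[tid] == rid:
            entries[rid] = OrthologEntry(
                reference_id=rid,
                target_id=tid,
                identity=fwd.identity,
                evalue=fwd.evalue,
                reciprocal=True,
            )
            target_of.setdefault(tid, []).append(rid)
    collisions = {t: sorted(rs) for t, rs in target_of.items() if len(rs) > 1}
    return OrthologMap(mode=mode, entries=entries, collisions=collisions)


def identity_matrix(
    panel: Dict[str, str],
    genomes: Dict[str, Dict[str, str]],
    reference_proteome: Dict[str, str],
    mode: str = "confirmation",
    scoring: Optional[ScoringScheme] = None,
    panel_order: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Reference-by-genome matrix of reciprocal-best-hit identities (NaN where
    no reciprocal hit passes the mode's thresholds)."""
    if not genomes:
        raise InputError("need at least one genome")
    order = list(panel_order) if panel_order is not None else sorted(panel)
    data = {}
    for gid in sorted(genomes):
        omap = reciprocal_best_hits(panel, genomes[gid], reference_proteome, mode, scoring)
        data[gid] = [
            omap.entries[r].identity if r in omap.entries else np.nan for r in order
        ]
    return pd.DataFrame(data, index=order)
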