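"""Markov amino-acid substitution process with indels, for simulating protein
family divergence.

The rate matrix is built from a BLOSUM62-compatible exchangeability: inverting
the half-bit log-odds scores gives joint residue probabilities
``q_ab ~ p_a * p_b * 2^(s_ab/2)``, which define a time-reversible rate matrix
normalized to one expected substitution per site per unit time.  Divergence to
a target percent identity is obtained by solving for the branch length whose
expected diagonal transition probability matches the target, applying i.i.d.
per-site substitution, and superimposing geometric-length indels; the realized
identity is verified by global re-alignment with bounded redraws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.optimize import brentq

from .alphabet import AMINO_ACIDS, BACKGROUND, blosum62, decode, encode
from .errors import InputError, SimulationError

__all__ = ["EvolutionModel", "evolve_sequence", "evolve_along_tree", "expected_identity"]

_RETRY_LIMIT = 20


def _rate_matrix() -> np.ndarray:
    """Reversible 20x20 rate matrix from BLOSUM62 exchangeabilities."""
    s = blosum62()[:20, :20].astype(float)
    q_joint = np.outer(BACKGROUND, BACKGROUND) * np.power(2.0, s / 2.0)
    np.fill_diagonal(q_joint, 0.0)
    Q = q_joint / BACKGROUND[:, None]  # off-diagonal rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    # normalize: one expected substitution per site per unit time
    rate = -(BACKGROUND * np.diag(Q)).sum()
    return Q / rate


@dataclass
class EvolutionModel:
    """Substitution + indel process; same seed and inputs give identical output."""

    indel_rate: float = 0.02  # expected indels per site per unit time
    indel_length_mean: float = 3.0  # geometric mean indel length
    seed: int = 0
    substitution_matrix: np.ndarray = field(default_factory=_rate_matrix)

    def __post_init__(self) -> None:
        if self.indel_rate < 0:
            raise InputError("indel_rate must be non-negative")
        if self.indel_length_mean < 1:
            raise InputError("indel_length_mean must be at least 1")
        self._rng = np.random.default_rng(self.seed)
        Q = self.substitution_matrix
        # eigendecomposition via the symmetrized (reversible) form
        d = np.sqrt(BACKGROUND)
        S = (Q * d[:, None]) / d[None, :]
        w, V = np.linalg.eigh((S + S.T) / 2.0)
        self._eig_w = w
        self._eig_V = V
        self._d = d

    def rng(self) -> np.random.Generator:
        return self._rng

    def reseed(self, seed: int) -> None:
        self._rng = np.random.default_rng(seed)

    def transition(self, t: float) -> np.ndarray:
        """P(t) = expm(Q t), clipped and renormalized row-stochastic."""
        V, w, d = self._eig_V, self._eig_w, self._d
        P = (V * np.exp(w * t)) @ V.T
        P = P / d[:, None] * d[None, :]
        P = np.clip(P, 0.0, None)
        return P / P.sum(axis=1, keepdims=True)

    def expected_identity(self, t: float) -> float:
        """Expected fraction of unchanged sites after time t (no indels)."""
        return float(BACKGROUND @ np.diag(self.transition(t)))

    def time_for_identity(self, identity: float) -> float:
        """Branch length whose expected site identity equals ``identity``."""
        floor = float(BACKGROUND @ BACKGROUND) + 1e-4
        if identity >= 1.0:
            return 0.0
        target = max(identity, floor)
        return brentq(lambda t: self.expected_identity(t) - target, 0.0, 50.0)


def expected_identity(model: EvolutionModel, t: float) -> float:
    return model.expected_identity(t)


def _substitute(seq: np.ndarray, P: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    for i, a in enumerate(seq):
        if a >= 20:  # X passes through unchanged
            continue
        out[i] = rng.choice(20, p=P[a])
    return out


def _apply_indels(
    seq: np.ndarray, n_events: int, mean_len: float, rng: np.random.Generator
) -> np.ndarray:
    s = list(seq)
    p_geom = 1.0 / mean_len
    for _ in range(n_events):
        if len(s) < 2:
            break
        length = int(rng.geometric(p_geom))
        pos = int(rng.integers(0, len(s)))
        if rng.random() < 0.5 and len(s) - length >= 10:
            del s[pos : pos + length]
        else:
            insert = rng.choice(20, size=length, p=BACKGROUND)
            s[pos:pos] = list(insert)
    return np.array(s, dtype=np.int8)


def _evolve_once(
    seq: np.ndarray, t: float, model: EvolutionModel, rng: np.random.Generator
) -> np.ndarray:
    if t <= 0:
        return seq.copy()
    out = _substitute(seq, model.transition(t), rng)
    n_indels = rng.poisson(model.indel_rate * t * len(seq))
    if n_indels:
        out = _apply_indels(out, n_indels, model.indel_length_mean, rng)
    return out


def evolve_sequence(
    ancestor: str,
    target_identity: float,
    model: EvolutionModel,
    tolerance: float = 0.05,
) -> str:
    """Descendant whose global-alignment identity to ``ancestor`` lies within
    ``tolerance`` of ``target_identity`` (bounded redraws, then
    :class:`SimulationError` reporting the closest realized identity)."""
    from .align import global_identity

    if not 0.05 < target_identity <= 1.0:
        raise InputError("target_identity must be in (0.05, 1.0]")
    if len(ancestor) < 10:
        raise InputError("ancestor must have at least 10 residues")
    if target_identity == 1.0:
        return ancestor
    seq = encode(ancestor)
    rng = model.rng()
    # compensate the identity loss from gap columns when solving for t
    t = model.time_for_identity(target_identity)
    gap_frac = min(0.5, model.indel_rate * t * model.indel_length_mean)
    t = model.time_for_identity(min(1.0, target_identity * (1.0 + gap_frac)))
    best: Tuple[float, Optional[str]] = (np.inf, None)
    for _ in range(_RETRY_LIMIT):
        cand = decode(_evolve_once(seq, t, model, rng))
        realized = global_identity(ancestor, cand)
        err = abs(realized - target_identity)
        if err <= tolerance:
            return cand
        if err < best[0]:
            best = (err, cand)
        # multiplicative time adjustment toward the target
        if realized > target_identity:
            t *= 1.15
        else:
            t /= 1.15
    raise SimulationError(
        f"could not realize identity {target_identity:.2f} within ±{tolerance}; "
        f"closest attempt was off by {best[0]:.3f}"
    )


def evolve_along_tree(
    root_sequences: Dict[str, str],
    tree,
    model: EvolutionModel,
    rate_scale: float = 1.0,
) -> Dict[str, Dict[str, str]]:
    """Evolve every labeled root sequence down a branch-lengthed tree.

    ``tree`` is a ``skbio.TreeNode``; returns ``{leaf_name: {seq_id: seq}}``.
    Zero-length branches transmit sequences unchanged.  Branch lengths are in
    expected substitutions per site, multiplied by ``rate_scale``.
    """
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise InputError(f"tree node {node.name!r} lacks a branch length")
        if node.length < 0:
            raise InputError("branch lengths must be non-negative")
    rng = model.rng()
    out: Dict[str, Dict[str, str]] = {}

    def walk(node, seqs: Dict[str, np.ndarray]) -> None:
        for child in node.children:
            t = child.length * rate_scale
            child_seqs = {k: _evolve_once(v, t, model, rng) for k, v in seqs.items()}
            if child.is_tip():
                out[child.name] = {k: decode(v) for k, v in child_seqs.items()}
            else:
                walk(child, child_seqs)

    walk(tree, {k: encode(v) for k, v in root_sequences.items()})
    return out


def random_protein(length: int, rng: np.random.Generator) -> str:
    """Background-composition random protein."""
    return "".join(
        AMINO_ACIDS[i] for i in rng.choice(20, size=length, p=BACKGROUND)
    )
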