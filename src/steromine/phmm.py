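"""Plan7-lite profile hidden Markov models: construction from alignments,
all-path (forward) log-odds scoring, Gumbel E-value calibration, and proteome
screening.

Architecture.  Match/insert/delete chain with local alignment in both the
model and the sequence: entry B -> M_k with probability 2(M-k+1)/(M(M+1)) and
exit M_k -> E with probability 1/(M-k+1) (the remaining mass scales the
transitions learned from the training alignment), the convention that makes
every (entry, exit) match-state pair equiprobable a priori.  Sequence
residues outside the aligned span are emitted by the background null, so
their emission odds cancel and carry no transition cost.  Insert states emit
the background distribution.  The null model is i.i.d. background.

Scores are log2 odds over all paths (forward algorithm, numerically scaled).
E-values come from a per-model Gumbel tail fitted to forward scores of random
background-composition sequences: E(s, N) = N * P(S >= s) for a database of
N sequences.  The screening threshold (default 1e-25) is interpreted on this
calibrated scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
from numba import njit
from scipy import stats

from .alphabet import BACKGROUND, X_INDEX, encode
from .errors import CalibrationError, InputError
from .msa import GAP, MultipleAlignment

__all__ = [
    "ProfileHMM",
    "HmmHit",
    "build_profile",
    "forward_score",
    "viterbi_score",
    "calibrate_evalue",
    "screen_proteome",
]


@dataclass
class ProfileHMM:
    """Match-insert-delete profile with local-alignment entry/exit."""

    hmm_id: str
    match_emissions: np.ndarray  # (M, 20), rows sum to 1
    insert_emissions: np.ndarray  # (20,), background by construction
    # transitions out of position k (0-based, k = 0..M-2 used for k -> k+1)
    t_mm: np.ndarray
    t_mi: np.ndarray
    t_md: np.ndarray
    t_im: np.ndarray
    t_ii: np.ndarray
    t_dm: np.ndarray
    t_dd: np.ndarray
    background: np.ndarray = field(default_factory=lambda: BACKGROUND.copy())
    gumbel_mu: Optional[float] = None
    gumbel_lambda: Optional[float] = None
    source_subcluster: str = ""

    @property
    def n_match_states(self) -> int:
        return self.match_emissions.shape[0]

    @property
    def calibrated(self) -> bool:
        return self.gumbel_mu is not None and self.gumbel_lambda is not None

    def validate(self) -> None:
        M = self.n_match_states
        if M < 1:
            raise InputError("model needs at least one match state")
        if not np.allclose(self.match_emissions.sum(axis=1), 1.0, atol=1e-9):
            raise InputError("match emissions must sum to 1")
        for k in range(M - 1):
            if abs(self.t_mm[k] + self.t_mi[k] + self.t_md[k] - 1.0) > 1e-9:
                raise InputError(f"match transitions at {k} must sum to 1")
            if abs(self.t_im[k] + self.t_ii[k] - 1.0) > 1e-9:
                raise InputError(f"insert transitions at {k} must sum to 1")
            if abs(self.t_dm[k] + self.t_dd[k] - 1.0) > 1e-9:
                raise InputError(f"delete transitions at {k} must sum to 1")

    def entry_probabilities(self) -> np.ndarray:
        M = self.n_match_states
        k = np.arange(1, M + 1)
        return 2.0 * (M - k + 1) / (M * (M + 1.0))

    def exit_probabilities(self) -> np.ndarray:
        M = self.n_match_states
        k = np.arange(1, M + 1)
        return 1.0 / (M - k + 1.0)


@dataclass(frozen=True)
class HmmHit:
    hmm_id: str
    protein_id: str
    genome_id: str
    log_odds_score: float  # bits
    evalue: float


def build_profile(
    alignment: MultipleAlignment,
    pseudocount_weight: Optional[float] = None,
    hmm_id: str = "",
    source_subcluster: str = "",
) -> ProfileHMM:
    """Estimate a profile HMM from a multiple alignment.

    Match states are the columns with gap fraction < 0.5; emissions are
    background-proportional pseudocount mixtures with total weight
    ``pseudocount_weight`` (default 20/(rows+20)); transitions are counted
    from per-row state paths with Laplace (+1) smoothing.
    """
    n_rows = len(alignment.rows)
    if n_rows < 2:
        raise InputError("profile construction needs at least 2 rows")
    if pseudocount_weight is None:
        pseudocount_weight = 20.0 / (n_rows + 20.0)
    if pseudocount_weight < 0:
        raise InputError("pseudocount_weight must be non-negative")
    fracs = alignment.gap_fractions()
    match_cols = [j for j, f in enumerate(fracs) if f < 0.5]
    if not match_cols:
        raise InputError("alignment has no match columns (all gap fraction >= 0.5)")
    M = len(match_cols)
    em_counts = np.zeros((M, 20))
    # transition counts out of position k toward k+1
    c_mm = np.zeros(max(M - 1, 1))
    c_mi = np.zeros(max(M - 1, 1))
    c_md = np.zeros(max(M - 1, 1))
    c_im = np.zeros(max(M - 1, 1))
    c_ii = np.zeros(max(M - 1, 1))
    c_dm = np.zeros(max(M - 1, 1))
    c_dd = np.zeros(max(M - 1, 1))
    match_set = set(match_cols)
    for row in alignment.rows:
        # state path across match positions; inserts live between them
        states: List[str] = []  # per match position: 'M' or 'D'
        n_inserts: List[int] = [0] * (M + 1)  # inserts before position index
        pos = 0
        for j, c in enumerate(row):
            if j in match_set:
                if c == GAP:
                    states.append("D")
                else:
                    states.append("M")
                    idx = encode(c)[0]
                    if idx != X_INDEX:
                        em_counts[pos, idx] += 1.0
                pos += 1
            elif c != GAP:
                n_inserts[pos] += 1
        for k in range(M - 1):
            src, dst = states[k], states[k + 1]
            ins = n_inserts[k + 1]
            if ins > 0 and src == "M":
                c_mi[k] += 1.0
                c_ii[k] += ins - 1
                c_im[k] += 1.0  # insert run ends into the next position
                if dst == "D":
                    # deletions after inserts are folded into the I->M move
                    pass
            else:
                if src == "M" and dst == "M":
                    c_mm[k] += 1.0
                elif src == "M" and dst == "D":
                    c_md[k] += 1.0
                elif src == "D" and dst == "M":
                    c_dm[k] += 1.0
                else:
                    c_dd[k] += 1.0
    # emissions with background-proportional pseudocounts
    weights = em_counts.sum(axis=1, keepdims=True) + pseudocount_weight
    if pseudocount_weight == 0 and (em_counts.sum(axis=1) == 0).any():
        raise InputError("zero pseudocount weight with an all-delete match column")
    em = (em_counts + pseudocount_weight * BACKGROUND) / weights
    # transitions with Laplace smoothing
    t_mm = (c_mm + 1.0) / (c_mm + c_mi + c_md + 3.0)
    t_mi = (c_mi + 1.0) / (c_mm + c_mi + c_md + 3.0)
    t_md = (c_md + 1.0) / (c_mm + c_mi + c_md + 3.0)
    t_im = (c_im + 1.0) / (c_im + c_ii + 2.0)
    t_ii = (c_ii + 1.0) / (c_im + c_ii + 2.0)
    t_dm = (c_dm + 1.0) / (c_dm + c_dd + 2.0)
    t_dd = (c_dd + 1.0) / (c_dm + c_dd + 2.0)
    hmm = ProfileHMM(
        hmm_id=hmm_id or (source_subcluster or "hmm"),
        match_emissions=em,
        insert_emissions=BACKGROUND.copy(),
        t_mm=t_mm,
        t_mi=t_mi,
        t_md=t_md,
        t_im=t_im,
        t_ii=t_ii,
        t_dm=t_dm,
        t_dd=t_dd,
        source_subcluster=source_subcluster,
    )
    hmm.validate()
    return hmm


@njit(cache=True)
def _forward_odds(odds_em, t_mm, t_mi, t_md, t_im, t_ii, t_dm, t_dd, entry, exits, use_max):
    """Forward (or Viterbi when use_max) in odds space with per-row scaling.

    odds_em: (L, M) match emission odds for the sequence. Returns log2 of the
    summed (or maximal) path odds of the local alignment.
    """
    L, M = odds_em.shape
    fM = np.zeros(M)
    fI = np.zeros(M)
    fD = np.zeros(M)
    total = 0.0
    log_scale = 0.0
    for i in range(L):
        nM = np.zeros(M)
        nI = np.zeros(M)
        nD = np.zeros(M)
        for k in range(M):
            # entry at any position (null-emitted prefix has odds 1)
            val = entry[k]
            if k > 0:
                keep_m = 1.0 - exits[k - 1]
                if use_max:
                    best = fM[k - 1] * t_mm[k - 1] * keep_m
                    v2 = fI[k - 1] * t_im[k - 1]
                    if v2 > best:
                        best = v2
                    v3 = fD[k - 1] * t_dm[k - 1]
                    if v3 > best:
                        best = v3
                    if best > val:
                        val = best
                else:
                    val += (
                        fM[k - 1] * t_mm[k - 1] * keep_m
                        + fI[k - 1] * t_im[k - 1]
                        + fD[k - 1] * t_dm[k - 1]
                    )
            nM[k] = val * odds_em[i, k]
        for k in range(M - 1):
            keep_m = 1.0 - exits[k]
            if use_max:
                a = fM[k] * t_mi[k] * keep_m
                b = fI[k] * t_ii[k]
                nI[k] = a if a > b else b
            else:
                nI[k] = fM[k] * t_mi[k] * keep_m + fI[k] * t_ii[k]
        for k in range(1, M):
            keep_m = 1.0 - exits[k - 1]
            if use_max:
                a = nM[k - 1] * t_md[k - 1] * keep_m
                b = nD[k - 1] * t_dd[k - 1]
                nD[k] = a if a > b else b
            else:
                nD[k] = nM[k - 1] * t_md[k - 1] * keep_m + nD[k - 1] * t_dd[k - 1]
        # exits (null-emitted suffix has odds 1)
        for k in range(M):
            contrib = nM[k] * exits[k]
            if use_max:
                if contrib > total:
                    total = contrib
            else:
                total += contrib
        fM, fI, fD = nM, nI, nD
        # rescale to avoid overflow
        peak = total
        for k in range(M):
            if fM[k] > peak:
                peak = fM[k]
            if fI[k] > peak:
                peak = fI[k]
            if fD[k] > peak:
                peak = fD[k]
        if peak > 1e100:
            inv = 1.0 / peak
            for k in range(M):
                fM[k] *= inv
                fI[k] *= inv
                fD[k] *= inv
            total *= inv
            log_scale += math.log2(peak)
    if total <= 0.0:
        return -1e30
    return math.log2(total) + log_scale


def _emission_odds(hmm: ProfileHMM, seq: np.ndarray) -> np.ndarray:
    M = hmm.n_match_states
    em = hmm.match_emissions / hmm.background[None, :]
    out = np.empty((seq.shape[0], M))
    for i, a in enumerate(seq):
        if a == X_INDEX:
            out[i, :] = 1.0  # ambiguity scores as background
        else:
            out[i, :] = em[:, a]
    return out


def _score(hmm: ProfileHMM, sequence: str, use_max: bool) -> float:
    if not sequence:
        raise InputError("empty sequence")
    seq = encode(sequence)
    odds = _emission_odds(hmm, seq)
    return float(
        _forward_odds(
            odds,
            hmm.t_mm,
            hmm.t_mi,
            hmm.t_md,
            hmm.t_im,
            hmm.t_ii,
            hmm.t_dm,
            hmm.t_dd,
            hmm.entry_probabilities(),
            hmm.exit_probabilities(),
            use_max,
        )
    )


def forward_score(hmm: ProfileHMM, sequence: str) -> float:
    """All-path log-odds score in bits: log2 P(seq | hmm) / P(seq | null)."""
    return _score(hmm, sequence, use_max=False)


def viterbi_score(hmm: ProfileHMM, sequence: str) -> float:
    """Best-path log-odds score in bits (diagnostic; forward >= viterbi)."""
    return _score(hmm, sequence, use_max=True)


def calibrate_evalue(
    hmm: ProfileHMM,
    n_random: int = 1000,
    length_distribution: Sequence[int] = (100, 400),
    seed: int = 0,
) -> ProfileHMM:
    """Fit a Gumbel null to forward scores of random background sequences.

    ``length_distribution`` is an inclusive (low, high) range sampled
    uniformly.  Returns a copy with ``gumbel_mu``/``gumbel_lambda`` set; the
    E-value of a score s against N sequences is N * P_gumbel(S >= s).
    """
    if n_random < 1000:
        raise InputError("calibration needs n_random >= 1000")
    rng = np.random.default_rng(seed)
    lo, hi = length_distribution
    scores = np.empty(n_random)
    for i in range(n_random):
        length = int(rng.integers(lo, hi + 1))
        seq = rng.choice(20, size=length, p=BACKGROUND).astype(np.int8)
        em = hmm.match_emissions / hmm.background[None, :]
        odds = em[:, seq].T.copy()
        scores[i] = _forward_odds(
            odds,
            hmm.t_mm,
            hmm.t_mi,
            hmm.t_md,
            hmm.t_im,
            hmm.t_ii,
            hmm.t_dm,
            hmm.t_dd,
            hmm.entry_probabilities(),
            hmm.exit_probabilities(),
            False,
        )
    if np.ptp(scores) < 1e-9:
        raise CalibrationError("degenerate null score distribution")
    mu, beta = stats.gumbel_r.fit(scores)
    return replace(hmm, gumbel_mu=float(mu), gumbel_lambda=float(1.0 / beta))


def hmm_evalue(hmm: ProfileHMM, score: float, database_size: int) -> float:
    """E-value of a forward score against ``database_size`` sequences."""
    if not hmm.calibrated:
        raise CalibrationError(f"HMM {hmm.hmm_id!r} is not calibrated")
    sf = stats.gumbel_r.sf(score, loc=hmm.gumbel_mu, scale=1.0 / hmm.gumbel_lambda)
    return float(database_size * sf)


def screen_proteome(
    hmms: Sequence[ProfileHMM],
    proteome: Dict[str, str],
    genome_id: str = "",
    max_evalue: float = 1e-25,
) -> List[HmmHit]:
    """Score every (model, protein) pair; keep hits with E <= ``max_evalue``.

    All models must be calibrated.  The database size for E-values is the
    number of proteins screened.
    """
    for hmm in hmms:
        if not hmm.calibrated:
            raise CalibrationError(f"HMM {hmm.hmm_id!r} is not calibrated")
    n = len(proteome)
    hits: List[HmmHit] = []
    for hmm in hmms:
        for pid in sorted(proteome):
            s = forward_score(hmm, proteome[pid])
            ev = hmm_evalue(hmm, s, n)
            if ev <= max_evalue:
                hits.append(
                    HmmHit(
                        hmm_id=hmm.hmm_id,
                        protein_id=pid,
                        genome_id=genome_id,
                        log_odds_score=s,
                        evalue=ev,
                    )
                )
    return hits
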