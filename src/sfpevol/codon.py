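"""Codon state space and GY94-style codon substitution machinery.

The state space is the 61 sense codons of the universal genetic code; stop
codons are excluded.  Substitution follows the Goldman-Yang parameterization:
single-nucleotide changes only, with a transition/transversion ratio kappa,
a nonsynonymous/synonymous ratio omega, and target-codon stationary
frequencies pi.  Rate matrices are reversible with respect to pi, which lets
transition probabilities be computed through a symmetric eigendecomposition.
"""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable

BASES = "TCAG"
_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_TABLE.stop_codons)

#: the 61 sense codons, in TCAG lexicographic order
CODONS: tuple[str, ...] = tuple(
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in STOP_CODONS
)
N_STATES = len(CODONS)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}
AMINO_ACID: tuple[str, ...] = tuple(_TABLE.forward_table[c] for c in CODONS)

_TRANSITION_PAIRS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

# pair classification codes
PAIR_NONE = 0          # identical or multi-nucleotide change
PAIR_SYN_TV = 1
PAIR_SYN_TS = 2
PAIR_NONSYN_TV = 3
PAIR_NONSYN_TS = 4


def _classify_pairs() -> np.ndarray:
    T = np.zeros((N_STATES, N_STATES), dtype=np.int8)
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            is_ts = diffs[0] in _TRANSITION_PAIRS
            is_syn = AMINO_ACID[i] == AMINO_ACID[j]
            T[i, j] = (PAIR_SYN_TS if is_ts else PAIR_SYN_TV) if is_syn else (
                PAIR_NONSYN_TS if is_ts else PAIR_NONSYN_TV
            )
    return T


PAIR_TYPE: np.ndarray = _classify_pairs()
_IS_TS = (PAIR_TYPE == PAIR_SYN_TS) | (PAIR_TYPE == PAIR_NONSYN_TS)
_IS_NONSYN = (PAIR_TYPE == PAIR_NONSYN_TS) | (PAIR_TYPE == PAIR_NONSYN_TV)
_IS_SINGLE = PAIR_TYPE != PAIR_NONE


def uniform_frequencies() -> np.ndarray:
    """Equal frequency 1/61 for every sense codon."""
    return np.full(N_STATES, 1.0 / N_STATES)


def codon_rate_matrix(
    kappa: float,
    omega: float,
    pi: np.ndarray,
    normalize: bool = True,
) -> tuple[np.ndarray, float]:
    """Build the 61x61 GY94 generator.

    q_ij is zero for multi-nucleotide changes and otherwise proportional to
    pi_j, multiplied by kappa for transitions and omega for nonsynonymous
    changes.  Returns ``(Q, rate)`` where ``rate`` is the expected number of
    substitutions per codon site per unit time of the *unnormalized* matrix
    (``-sum_i pi_i q_ii``).  With ``normalize=True`` the returned Q is divided
    by that rate, so branch lengths are expected substitutions per codon.

    Raises ``ValueError`` for invalid kappa/omega/pi.
    """
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (N_STATES,) or np.any(pi < 0) or not np.isclose(pi.sum(), 1.0):
        raise ValueError("pi must be a 61-vector of non-negative values summing to 1")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if omega < 0:
        raise ValueError("omega must be non-negative")
    Q = np.where(_IS_SINGLE, pi[None, :], 0.0)
    Q = Q * np.where(_IS_TS, kappa, 1.0) * np.where(_IS_NONSYN, omega, 1.0)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = float(-np.dot(pi, np.diag(Q)))
    if normalize:
        if rate <= 0:
            raise ValueError("degenerate rate matrix (zero total rate)")
        Q = Q / rate
    return Q, rate


class Propagator:
    """Eigendecomposed (unnormalized) GY94 generator for one (kappa, omega, pi).

    Because Q is reversible w.r.t. pi, ``B = D^{1/2} Q D^{-1/2}`` (with
    ``D = diag(pi)``) is symmetric; its eigendecomposition gives
    ``P(t) = A exp(diag(lam) t) C`` with ``A = D^{-1/2} V`` and
    ``C = V^T D^{1/2}``.
    """

    def __init__(self, kappa: float, omega: float, pi: np.ndarray):
        Q, rate = codon_rate_matrix(kappa, omega, pi, normalize=False)
        sq = np.sqrt(np.clip(pi, 1e-300, None))
        B = Q * (sq[:, None] / sq[None, :])
        lam, V = np.linalg.eigh((B + B.T) / 2.0)
        self.lam = lam
        self.A = V / sq[:, None]
        self.C = V.T * sq[None, :]
        self.rate = rate
        self.pi = np.asarray(pi, float)

    def matrices(self, t) -> np.ndarray:
        """Transition probability matrices for an array of times (unnormalized
        generator time scale).  Returns shape ``(len(t), 61, 61)``."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        E = np.exp(np.multiply.outer(t, self.lam))
        P = (self.A[None, :, :] * E[:, None, :]) @ self.C
        np.clip(P, 0.0, None, out=P)
        return P

    def matrix(self, t: float) -> np.ndarray:
        return self.matrices([t])[0]


def f3x4_frequencies(codon_idx: np.ndarray) -> np.ndarray:
    """F3x4 codon frequencies from observed codons.

    ``codon_idx`` is an integer array of codon state indices (negative =
    missing).  Position-specific nucleotide frequencies are estimated from
    all non-missing codons; the codon frequency is their product with stop
    codons removed and renormalized.
    """
    codon_idx = np.asarray(codon_idx)
    obs = codon_idx[codon_idx >= 0].ravel()
    if obs.size == 0:
        return uniform_frequencies()
    pos_freq = np.zeros((3, 4))
    base_idx = {b: k for k, b in enumerate(BASES)}
    counts = np.bincount(obs, minlength=N_STATES)
    for ci, n in enumerate(counts):
        if n == 0:
            continue
        for p, b in enumerate(CODONS[ci]):
            pos_freq[p, base_idx[b]] += n
    pos_freq = pos_freq / pos_freq.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            pos_freq[0, base_idx[c[0]]]
            * pos_freq[1, base_idx[c[1]]]
            * pos_freq[2, base_idx[c[2]]]
            for c in CODONS
        ]
    )
    # guard against unobserved nucleotides producing exact zeros
    pi = np.clip(pi, 1e-10, None)
    return pi / pi.sum()


def encode_codons(seq: str) -> np.ndarray:
    """Encode an in-frame nucleotide string as codon state indices.

    Gap codons (any codon containing ``-``) and ambiguous codons map to -1
    (missing).  Internal stop codons raise ``ValueError``.
    """
    seq = seq.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} is not divisible by 3")
    out = np.empty(len(seq) // 3, dtype=np.int16)
    for k in range(out.size):
        cod = seq[3 * k : 3 * k + 3]
        if cod in CODON_INDEX:
            out[k] = CODON_INDEX[cod]
        elif cod in STOP_CODONS:
            raise ValueError(f"internal stop codon {cod} at codon position {k + 1}")
        else:
            out[k] = -1
    return out


def decode_codons(idx: np.ndarray, missing: str = "---") -> str:
    return "".join(CODONS[i] if i >= 0 else missing for i in idx)
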