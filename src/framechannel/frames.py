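"""Projection of the coding-frame codon process into all six reading frames.

Two adjacent codons of the coding frame (+1) evolve independently; their
joint generator on ordered sense-codon pairs (di-codons, 61*61 = 3721
states) is the Kronecker sum Q (+) Q = Q x I + I x Q.  Every alternative
reading frame reads one full codon inside such a 6-nucleotide window:

    window n1..n6   (+1: n1 n2 n3 | second codon: n4 n5 n6)

    +1 -> (n1, n2, n3)        -1 -> (c(n6), c(n5), c(n4))
    +2 -> (n2, n3, n4)        -2 -> (c(n5), c(n4), c(n3))
    +3 -> (n3, n4, n5)        -3 -> (c(n4), c(n3), c(n2))

with c the complement.  Marginalizing the di-codon chain over the flanking
positions -- weighting each di-codon by its stationary probability
conditional on the frame sub-codon -- yields an effective generator Q^f
and stationary distribution pi^f per frame.  Frames +-1 live on 61 states
(the sense codons, respectively their reverse complements); frames +-2 and
+-3 live on the full 64-codon space, where stop codons are ordinary,
reachable states.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import scipy.sparse as sp

from .codon_model import RateMatrix, TransitionMatrix, transition_matrix
from .genetic_code import (
    CODONS64,
    SENSE_CODONS,
    InvalidCodonError,
    reverse_complement,
)

FRAMES: tuple[str, ...] = ("+1", "+2", "+3", "-1", "-2", "-3")
ALTERNATIVE_FRAMES: tuple[str, ...] = ("+2", "+3", "-1", "-2", "-3")

#: frame -> (start, stop) slice of the forward window, reverse-complemented
#: for the minus frames
_WINDOW_SLICE = {
    "+1": (0, 3),
    "+2": (1, 4),
    "+3": (2, 5),
    "-1": (3, 6),
    "-2": (2, 5),
    "-3": (1, 4),
}


def extract_frame_codon(window: str, frame: str) -> str:
    """The frame-f codon inside a 6-nucleotide di-codon window."""
    if frame not in FRAMES:
        raise ValueError(f"unknown frame {frame!r}")
    if len(window) != 6:
        raise InvalidCodonError(f"window must have 6 nucleotides: {window!r}")
    lo, hi = _WINDOW_SLICE[frame]
    sub = window[lo:hi]
    return reverse_complement(sub) if frame.startswith("-") else sub.upper()


def frame_states(frame: str) -> tuple[str, ...]:
    """State labels of the frame process, in lexicographic order."""
    if frame == "+1":
        return SENSE_CODONS
    if frame == "-1":
        return tuple(sorted(reverse_complement(c) for c in SENSE_CODONS))
    if frame in FRAMES:
        return CODONS64
    raise ValueError(f"unknown frame {frame!r}")


@dataclass(frozen=True)
class DicodonModel:
    """Joint generator of two independent codon chains.

    ``matrix`` is sparse (each of the 3721 di-codon states has at most 18
    single-nucleotide neighbours); ``pi`` is the product distribution
    pi x pi.
    """

    matrix: sp.spmatrix
    pi: np.ndarray
    states: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.states)


def dicodon_rate_matrix(Q: RateMatrix) -> DicodonModel:
    """Kronecker sum of a scaled 61x61 generator with itself.

    Exactly one codon of the pair changes per event; the stationary
    distribution of the joint chain is the outer product of the marginal
    stationary distribution with itself.
    """
    n = len(Q.states)
    from .codon_model import stationary_distribution

    pi = Q.pi if Q.pi is not None else stationary_distribution(Q)
    eye = sp.identity(n, format="csr")
    qs = sp.csr_matrix(Q.matrix)
    ksum = sp.kron(qs, eye, format="csr") + sp.kron(eye, qs, format="csr")
    joint_pi = np.outer(pi, pi).ravel()
    states = tuple(l + r for l, r in product(Q.states, Q.states))
    return DicodonModel(ksum, joint_pi, states)


@dataclass(frozen=True)
class FrameModel:
    """Effective evolutionary model of one reading frame.

    rate        : generator Q^f on the frame's state space
    pi          : stationary distribution pi^f (marginal of pi x pi over
                  the frame sub-codon)
    unreachable : states with zero stationary support (kept in the
                  container, zero rows in the generator)
    """

    frame: str
    rate: RateMatrix
    pi: np.ndarray
    unreachable: tuple[str, ...] = ()

    @property
    def states(self) -> tuple[str, ...]:
        return self.rate.states

    @property
    def supported(self) -> np.ndarray:
        """Boolean mask of states with positive stationary probability."""
        return self.pi > 0

    def transition(self, t: float) -> TransitionMatrix:
        return transition_matrix(self.rate, t)


def _subcodon_indices(dm: DicodonModel, frame: str) -> np.ndarray:
    states = frame_states(frame)
    index = {c: i for i, c in enumerate(states)}
    return np.array(
        [index[extract_frame_codon(w, frame)] for w in dm.states], dtype=int
    )


def project_rate_matrix(dm: DicodonModel, frame: str) -> FrameModel:
    """Marginalize the di-codon generator onto one reading frame.

    For frame states x != y the projected rate is the stationary-
    conditional average, over di-codons d carrying sub-codon x, of the
    total di-codon rate from d into states carrying sub-codon y:

        q^f_xy = sum_{d: s(d)=x} [ pi(d) / pi^f(x) ] * sum_{d': s(d')=y} A(d, d')

    The diagonal is set so rows sum to zero.  With this weighting pi^f is
    exactly stationary for Q^f.  States never visited under the given
    usage (zero marginal mass) keep zero rows and are flagged.
    """
    states = frame_states(frame)
    nf = len(states)
    sub = _subcodon_indices(dm, frame)

    member = np.zeros((dm.n, nf))
    member[np.arange(dm.n), sub] = 1.0

    pi_f = dm.pi @ member
    with np.errstate(divide="ignore", invalid="ignore"):
        weights = np.where(pi_f[sub] > 0, dm.pi / pi_f[sub], 0.0)
    cond = member * weights[:, None]  # (d, x): pi(d | s(d)=x)

    flux = dm.matrix @ member  # (d, y): total rate from d into sub-codon y
    qf = cond.T @ flux
    np.fill_diagonal(qf, 0.0)
    qf[np.abs(qf) < 1e-15] = 0.0  # sweep round-off in structural zeros
    np.fill_diagonal(qf, -qf.sum(axis=1))

    unreachable = tuple(s for s, p in zip(states, pi_f) if p == 0)
    return FrameModel(frame, RateMatrix(qf, states, pi=pi_f), pi_f, unreachable)


def frame_stationary(fm: FrameModel) -> np.ndarray:
    """Stationary distribution of Q^f, computed from the generator.

    Restricted to the supported states (unreachable states get 0); must
    coincide with the direct marginal ``fm.pi`` of the di-codon
    distribution.
    """
    from .codon_model import stationary_distribution

    mask = fm.supported
    q_sub = fm.rate.matrix[np.ix_(mask, mask)]
    pi_sub = stationary_distribution(q_sub)
    out = np.zeros(len(fm.states))
    out[mask] = pi_sub
    return out


def frame_model(
    Q: RateMatrix, frame: str, dm: DicodonModel | None = None
) -> FrameModel:
    """Build the FrameModel of any frame from the coding-frame generator.

    Frame +1 is the input model itself; the remaining frames are obtained
    by di-codon projection.
    """
    if frame == "+1":
        from .codon_model import stationary_distribution

        pi = Q.pi if Q.pi is not None else stationary_distribution(Q)
        return FrameModel("+1", Q, pi)
    if dm is None:
        dm = dicodon_rate_matrix(Q)
    return project_rate_matrix(dm, frame)


def all_frame_models(Q: RateMatrix) -> dict[str, FrameModel]:
    """FrameModels for all six frames, sharing one di-codon construction."""
    dm = dicodon_rate_matrix(Q)
    return {f: frame_model(Q, f, dm) for f in FRAMES}
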