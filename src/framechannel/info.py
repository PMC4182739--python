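"""Information-theoretic noise measures on the amino-acid channel.

The frame transition matrix P^f(t) = expm(Q^f t), viewed as a noisy
channel from ancestral to descendant codons, is aggregated to an
amino-acid channel: stop rows/columns are removed (rows renormalized),
and codons of each amino acid are pooled with weights proportional to
their stationary probabilities.

Genetic noise is the conditional entropy with uniform weighting over the
amino-acid alphabet,

    H^f(Y|X) = (1/|A|) sum_a H(Y | X = a),   H in bits,

bounded by log2(20); sequence similarity is the mutual information of the
uniform-input channel, I^f(X;Y) = H(Y) - H^f(Y|X).  The half-information
time is the t at which H^f reaches log2(20)/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frames import FrameModel
from .genetic_code import GeneticCode, STANDARD_CODE, STOP_LABEL

LOG2_20 = float(np.log2(20.0))


@dataclass(frozen=True)
class AAChannel:
    """Row-stochastic amino-acid transition matrix for one frame/time.

    ``dropped`` lists amino acids without stationary support in the frame
    (the alphabet then shrinks below 20 and the entropy bound becomes
    log2 of the realized alphabet).
    """

    frame: str
    t: float
    matrix: np.ndarray
    alphabet: tuple[str, ...]
    dropped: tuple[str, ...] = ()

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if np.abs(m.sum(axis=1) - 1.0).max() > 1e-10:
            raise ValueError("channel rows must sum to 1")
        object.__setattr__(self, "matrix", m)

    @property
    def max_entropy(self) -> float:
        """log2 of the realized alphabet size."""
        return float(np.log2(len(self.alphabet)))


def aa_channel_from_matrix(
    P: np.ndarray,
    states: tuple[str, ...],
    pi: np.ndarray,
    code: GeneticCode = STANDARD_CODE,
    frame: str = "?",
    t: float = np.nan,
) -> AAChannel:
    """Aggregate any codon-level stochastic matrix to amino acids.

    Weights within an amino acid are the stationary codon probabilities
    conditional on that amino acid; stop codons are removed first and the
    remaining rows renormalized.
    """
    labels = np.array([code.translate(s) for s in states])
    keep = labels != STOP_LABEL
    P = np.asarray(P, float)[np.ix_(keep, keep)]
    rows = P.sum(axis=1)
    if np.any(rows <= 0):
        raise ValueError("a codon row lost all probability mass")
    P = P / rows[:, None]
    labels = labels[keep]
    pi = np.asarray(pi, float)[keep]

    alphabet = tuple(sorted(set(labels)))
    support = {a: pi[labels == a].sum() for a in alphabet}
    realized = tuple(a for a in alphabet if support[a] > 0)
    dropped = tuple(a for a in alphabet if support[a] == 0)

    k = len(realized)
    out = np.zeros((k, k))
    for i, a in enumerate(realized):
        sel = labels == a
        w = pi[sel] / support[a]
        pooled = w @ P[sel]
        for j, b in enumerate(realized):
            out[i, j] = pooled[labels == b].sum()
    out = out / out.sum(axis=1, keepdims=True)
    return AAChannel(frame, t, out, realized, dropped)


def aa_channel(
    fm: FrameModel, t: float, code: GeneticCode = STANDARD_CODE
) -> AAChannel:
    """Amino-acid channel of a frame model after evolutionary time t."""
    P = fm.transition(t)
    return aa_channel_from_matrix(
        P.matrix, fm.states, fm.pi, code, frame=fm.frame, t=t
    )


def _row_entropies(m: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(m > 0, m * np.log2(m), 0.0)
    return -term.sum(axis=1)


def conditional_entropy(ch: AAChannel) -> float:
    """Mean row entropy in bits (uniform weighting over the alphabet)."""
    return float(_row_entropies(ch.matrix).mean())


def mutual_information(ch: AAChannel) -> float:
    """I(X;Y) = H(Y) - H(Y|X) for X uniform over the channel alphabet."""
    p_y = ch.matrix.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        h_y = -float(np.where(p_y > 0, p_y * np.log2(p_y), 0.0).sum())
    return h_y - conditional_entropy(ch)


@dataclass(frozen=True)
class InfoProfile:
    """Conditional-entropy and mutual-information time series of a frame."""

    frame: str
    times: np.ndarray
    conditional_entropy: np.ndarray
    mutual_information: np.ndarray


def info_profile(
    fm: FrameModel, times, code: GeneticCode = STANDARD_CODE
) -> InfoProfile:
    times = np.asarray(list(times), float)
    h = np.empty_like(times)
    mi = np.empty_like(times)
    for i, t in enumerate(times):
        ch = aa_channel(fm, t, code)
        h[i] = conditional_entropy(ch)
        mi[i] = mutual_information(ch)
    return InfoProfile(fm.frame, times, h, mi)


class NoCrossingError(RuntimeError):
    """Conditional entropy does not reach the half-information threshold
    on the search bracket."""


def half_information_time(
    fm: FrameModel,
    code: GeneticCode = STANDARD_CODE,
    threshold: float | None = None,
    t_max: float = 20.0,
    xtol: float = 1e-4,
) -> float:
    """Time at which H^f(Y|X) = log2(20)/2, by bisection on [0, t_max].

    The default threshold uses the full 20-letter bound even if the
    frame's realized alphabet is smaller; pass
    ``threshold=aa_channel(fm, 0).max_entropy / 2`` for the
    reduced-alphabet variant.
    """
    thr = LOG2_20 / 2.0 if threshold is None else threshold

    def h(t: float) -> float:
        return conditional_entropy(aa_channel(fm, t, code))

    lo, hi = 0.0, float(t_max)
    h_lo, h_hi = h(lo), h(hi)
    if not (h_lo < thr <= h_hi):
        raise NoCrossingError(
            f"H ranges [{h_lo:.4f}, {h_hi:.4f}] on [0, {t_max}]; "
            f"threshold {thr:.4f} not bracketed"
        )
    while hi - lo > xtol:
        mid = 0.5 * (lo + hi)
        if h(mid) < thr:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
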