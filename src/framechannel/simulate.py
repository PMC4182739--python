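"""Monte-Carlo verification of the analytic frame predictions.

Codon sites of the coding frame are independent (a discrete memoryless
channel), so a stationary sequence is an i.i.d. draw from the codon
usage, and evolution over a fixed horizon t replaces each codon by a draw
from its row of P(t) = expm(Q t).  Sliding a 6-nucleotide window over
consecutive codon pairs and extracting the frame sub-codon gives
empirical alternative-frame codon frequencies, to be compared with the
analytic stationary distributions pi^f.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .codon_model import TransitionMatrix
from .frames import extract_frame_codon, frame_states
from .genetic_code import SENSE_CODONS, CodonUsage


@dataclass(frozen=True)
class SimConfig:
    """Scale and reproducibility settings of a verification run."""

    n_codons: int = 200_000
    seed: int = 1
    replicates: int = 3

    def __post_init__(self):
        if self.n_codons < 2:
            raise ValueError("need at least 2 codons")


def sample_stationary_sequence(
    n: int, usage: CodonUsage, seed: int | np.random.Generator
) -> np.ndarray:
    """i.i.d. sense-codon indices (0..60 in lexicographic sense order)."""
    rng = np.random.default_rng(seed)
    return rng.choice(len(SENSE_CODONS), size=n, p=usage.freqs)


def evolve_sequence(
    seq: np.ndarray, P: TransitionMatrix | np.ndarray, seed
) -> np.ndarray:
    """Evolve each codon independently by one draw from its row of P(t).

    Row-sampling from P(t) has the same law as simulating the
    continuous-time chain over horizon t.
    """
    rng = np.random.default_rng(seed)
    p = P.matrix if isinstance(P, TransitionMatrix) else np.asarray(P, float)
    out = np.empty_like(seq)
    for state in range(p.shape[0]):
        sel = seq == state
        k = int(sel.sum())
        if k:
            out[sel] = rng.choice(p.shape[1], size=k, p=p[state])
    return out


def _frame_lookup(frame: str) -> np.ndarray:
    """(61, 61) table: frame-state index of the window formed by a pair of
    sense codons."""
    states = frame_states(frame)
    index = {c: i for i, c in enumerate(states)}
    lut = np.empty((61, 61), dtype=int)
    for i, l in enumerate(SENSE_CODONS):
        for j, r in enumerate(SENSE_CODONS):
            lut[i, j] = index[extract_frame_codon(l + r, frame)]
    return lut


def empirical_frame_frequencies(seq: np.ndarray, frame: str) -> np.ndarray:
    """Frequencies of the frame sub-codon over all consecutive codon-pair
    windows, aligned to ``frame_states(frame)``."""
    if len(seq) < 2:
        raise ValueError("sequence must hold at least 2 codons")
    lut = _frame_lookup(frame)
    codes = lut[seq[:-1], seq[1:]]
    counts = np.bincount(codes, minlength=len(frame_states(frame)))
    return counts / counts.sum()


def empirical_frame_transitions(
    seq_before: np.ndarray, seq_after: np.ndarray, frame: str
) -> np.ndarray:
    """Row-normalized frame-codon transition frequencies between paired
    windows of an ancestral and an evolved sequence (rows with no
    observations are left as zeros)."""
    lut = _frame_lookup(frame)
    a = lut[seq_before[:-1], seq_before[1:]]
    b = lut[seq_after[:-1], seq_after[1:]]
    n = len(frame_states(frame))
    counts = np.zeros((n, n))
    np.add.at(counts, (a, b), 1.0)
    rows = counts.sum(axis=1, keepdims=True)
    return np.divide(counts, rows, out=np.zeros_like(counts), where=rows > 0)
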