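"""Robustness mode: project an externally supplied empirical codon
substitution probability matrix into the six reading frames.

Instead of an M0 generator, the coding-frame channel is a discrete
stochastic matrix (e.g. an empirical codon substitution matrix estimated
from alignments).  Time points are realized as integer matrix powers.
Two adjacent codons transition independently (product channel); the
di-codon channel is then marginalized to each frame's sub-codon with the
same flank weighting as the rate-matrix projection, conditional on the
frame sub-codon under the supplied codon usage.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .codon_model import read_matrix_tsv, write_matrix_tsv
from .frames import FRAMES, extract_frame_codon
from .genetic_code import (
    CODON_INDEX,
    CODONS64,
    GeneticCode,
    STANDARD_CODE,
    CodonUsage,
)


@dataclass(frozen=True)
class EmpiricalChannel:
    """A row-stochastic codon substitution matrix with its state labels."""

    matrix: np.ndarray
    states: tuple[str, ...]
    label: str = "empirical"

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.states)
        if m.shape != (n, n):
            raise ValueError(f"matrix shape {m.shape} != ({n}, {n})")
        bad = np.abs(m.sum(axis=1) - 1.0)
        if bad.max() > 1e-8:
            raise ValueError(
                f"row sums deviate from 1 by up to {bad.max():.3g}"
            )
        if m.min() < -1e-12:
            raise ValueError("negative transition probability")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "states", tuple(self.states))

    @property
    def matrix64(self) -> np.ndarray:
        """The channel embedded in the full 64-codon order; codons absent
        from the state list are absorbing (identity rows)."""
        full = np.eye(64)
        idx = [CODON_INDEX[s] for s in self.states]
        full[np.ix_(idx, idx)] = self.matrix
        return full


def load_codon_matrix(
    path: str | Path, drop_stops: bool = False, label: str | None = None
) -> EmpiricalChannel:
    """Read a labelled TSV codon matrix and validate it.

    ``drop_stops`` removes stop rows/columns and renormalizes the
    remaining rows.
    """
    m, states = read_matrix_tsv(path)
    for s in states:
        if s not in CODON_INDEX:
            raise ValueError(f"unknown codon label {s!r}")
    if drop_stops:
        keep = np.array([s not in STANDARD_CODE.stops for s in states])
        m = m[np.ix_(keep, keep)]
        m = m / m.sum(axis=1, keepdims=True)
        states = tuple(s for s, k in zip(states, keep) if k)
    return EmpiricalChannel(m, states, label or Path(path).stem)


def save_codon_matrix(path: str | Path, ch: EmpiricalChannel) -> None:
    write_matrix_tsv(path, ch.matrix, ch.states)


@dataclass(frozen=True)
class FrameChannel:
    """Projected per-frame channel on the full 64-codon container.

    ``pi`` is the flank-weighting marginal over the frame sub-codon;
    rows of states without support are identity placeholders and listed
    in ``unsupported``.
    """

    frame: str
    steps: int
    matrix: np.ndarray
    pi: np.ndarray
    unsupported: tuple[str, ...]

    states: tuple[str, ...] = CODONS64

    def supported_block(self) -> tuple[np.ndarray, tuple[str, ...], np.ndarray]:
        """(matrix, states, pi) restricted to supported states, rows
        renormalized."""
        mask = self.pi > 0
        m = self.matrix[np.ix_(mask, mask)]
        m = m / m.sum(axis=1, keepdims=True)
        states = tuple(s for s, k in zip(self.states, mask) if k)
        return m, states, self.pi[mask]


def _window_tables(frame: str) -> tuple[np.ndarray, np.ndarray]:
    """sub[l, r]: 64-codon index of the frame sub-codon of window l+r;
    onehot[l, r, y] one-hot of the same (float)."""
    sub = np.empty((64, 64), dtype=int)
    for i, l in enumerate(CODONS64):
        for j, r in enumerate(CODONS64):
            sub[i, j] = CODON_INDEX[extract_frame_codon(l + r, frame)]
    onehot = np.zeros((64, 64, 64))
    ii, jj = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
    onehot[ii, jj, sub] = 1.0
    return sub, onehot


def project_transition_matrix(
    ch: EmpiricalChannel,
    usage: CodonUsage,
    frame: str,
    steps: int = 1,
) -> FrameChannel:
    """Per-frame transition matrix of the ``steps``-fold composed channel.

    Both codons of a di-codon window transition independently by
    ch^steps; the joint channel is marginalized onto the frame sub-codon,
    with the source window weighted by its usage-product probability
    conditional on the sub-codon.
    """
    if frame not in FRAMES:
        raise ValueError(f"unknown frame {frame!r}")
    if steps < 1:
        raise ValueError("steps must be >= 1")
    M = np.linalg.matrix_power(ch.matrix64, steps)
    sub, onehot = _window_tables(frame)

    # T[l, r, y] = sum_{l', r'} M[l, l'] M[r, r'] 1{sub(l', r') = y}
    U = np.einsum("al,lry->ary", M, onehot)
    T = np.einsum("br,ary->aby", M, U)

    u64 = usage.vector64
    w = np.outer(u64, u64)
    pi_f = np.zeros(64)
    np.add.at(pi_f, sub.ravel(), w.ravel())

    P = np.zeros((64, 64))
    flat_sub = sub.ravel()
    flat_w = w.ravel()
    flat_T = T.reshape(64 * 64, 64)
    np.add.at(P, flat_sub, flat_w[:, None] * flat_T)
    mask = pi_f > 0
    P[mask] /= pi_f[mask, None]
    P[~mask] = np.eye(64)[~mask]  # placeholder rows, flagged below

    unsupported = tuple(c for c, s in zip(CODONS64, mask) if not s)
    return FrameChannel(frame, steps, P, pi_f, unsupported)


def frame_channel_entropy(
    fc: FrameChannel, code: GeneticCode = STANDARD_CODE
) -> tuple[float, float]:
    """(conditional entropy, mutual information) in bits of the projected
    channel aggregated to amino acids on its supported states."""
    from .info import (
        aa_channel_from_matrix,
        conditional_entropy,
        mutual_information,
    )

    m, states, pi = fc.supported_block()
    ch = aa_channel_from_matrix(m, states, pi, code, frame=fc.frame)
    return conditional_entropy(ch), mutual_information(ch)
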