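"""Goldman-Yang (M0) codon substitution model.

The instantaneous rate from sense codon x to y (x != y) is

    q_xy = 0                      if x and y differ at more than one site
    q_xy = pi_y                   synonymous transversion
    q_xy = kappa * pi_y           synonymous transition
    q_xy = omega * pi_y           nonsynonymous transversion
    q_xy = omega * kappa * pi_y   nonsynonymous transition

over the 61 sense codons (rates into stop codons are excluded: premature
stops are not tolerated in a functional protein).  The generator is
rescaled so that the expected number of substitutions per codon per unit
time at stationarity is one, making the time parameter t directly
comparable across parameter settings.  The chain is reversible with
stationary distribution pi.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.linalg import expm, null_space

from .genetic_code import (
    GeneticCode,
    STANDARD_CODE,
    SENSE_CODONS,
    CodonUsage,
    is_transition,
    single_nucleotide_difference,
)


class DegenerateModelError(ValueError):
    """Raised when a generator carries no substitution flux."""


class NonErgodicModelError(ValueError):
    """Raised when a generator has more than one stationary distribution."""


@dataclass(frozen=True)
class ModelParams:
    """M0 parameters.

    kappa : transition/transversion rate ratio (>= 0)
    omega : nonsynonymous/synonymous rate ratio (>= 0); <1 purifying,
            =1 neutral, >1 adaptive selection
    t     : evolutionary time, expected substitutions per codon (>= 0)
    """

    kappa: float = 1.0
    omega: float = 1.0
    t: float = 1.0

    def __post_init__(self):
        for name in ("kappa", "omega", "t"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class RateMatrix:
    """A CTMC generator together with its state labels.

    ``scaling`` records the factor the raw matrix was divided by (1.0 for
    an unscaled matrix); matrices always carry their state list to prevent
    index drift between 61- and 64-state objects.
    """

    matrix: np.ndarray
    states: tuple[str, ...]
    scaling: float = 1.0
    #: known stationary distribution, when available by construction
    #: (e.g. reversibility); lets downstream code handle reducible
    #: generators such as the omega = 0 model
    pi: np.ndarray | None = None

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.states)
        if m.shape != (n, n):
            raise ValueError(f"matrix shape {m.shape} != ({n}, {n})")
        off = m - np.diag(np.diag(m))
        if off.min() < -1e-12:
            raise ValueError("negative off-diagonal rate")
        if np.abs(m.sum(axis=1)).max() > 1e-10:
            raise ValueError("generator rows must sum to 0")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "states", tuple(self.states))
        if self.pi is not None:
            p = np.asarray(self.pi, dtype=float)
            if p.shape != (n,) or not np.isclose(p.sum(), 1.0, atol=1e-9):
                raise ValueError("pi must be a length-n probability vector")
            object.__setattr__(self, "pi", p)


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic codon transition probabilities P(t) = expm(Q t)."""

    matrix: np.ndarray
    states: tuple[str, ...]
    t: float

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if np.abs(m.sum(axis=1) - 1.0).max() > 1e-8:
            raise ValueError("transition matrix rows must sum to 1")
        if m.min() < -1e-12 or m.max() > 1 + 1e-12:
            raise ValueError("transition probabilities must lie in [0, 1]")
        object.__setattr__(self, "matrix", np.clip(m, 0.0, 1.0))
        object.__setattr__(self, "states", tuple(self.states))


def build_rate_matrix(
    params: ModelParams,
    usage: CodonUsage,
    code: GeneticCode = STANDARD_CODE,
    scale: bool = True,
) -> RateMatrix:
    """Construct the (by default scaled) 61x61 M0 generator."""
    pi = usage.freqs
    n = len(SENSE_CODONS)
    q = np.zeros((n, n))
    for i, x in enumerate(SENSE_CODONS):
        for j, y in enumerate(SENSE_CODONS):
            if i == j:
                continue
            pos = single_nucleotide_difference(x, y)
            if pos is None:
                continue
            rate = pi[j]
            if is_transition(x[pos], y[pos]):
                rate *= params.kappa
            if not code.synonymous(x, y):
                rate *= params.omega
            q[i, j] = rate
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    rm = RateMatrix(q, SENSE_CODONS, scaling=1.0, pi=pi)
    return scale_rate_matrix(rm, usage) if scale else rm


def scale_rate_matrix(Q: RateMatrix, usage: CodonUsage) -> RateMatrix:
    """Normalize the expected substitution rate at stationarity to one.

    Divides by sum_x pi_x * (-q_xx); invariant under pre-multiplication of
    Q by any positive constant.
    """
    pi = usage.freqs
    if len(pi) != len(Q.states):
        raise ValueError("usage dimension does not match state space")
    total = float(-pi @ np.diag(Q.matrix))
    if total <= 0:
        raise DegenerateModelError("zero total substitution rate")
    return RateMatrix(
        Q.matrix / total, Q.states, scaling=Q.scaling * total, pi=Q.pi
    )


def transition_matrix(Q: RateMatrix, t: float) -> TransitionMatrix:
    """P(t) = expm(Q t) via scaling-and-squaring."""
    if t < 0:
        raise ValueError(f"time must be >= 0, got {t}")
    p = expm(Q.matrix * t)
    return TransitionMatrix(p, Q.states, t)


def stationary_distribution(
    Q: RateMatrix | np.ndarray, rtol: float = 1e-9
) -> np.ndarray:
    """Left null-vector of the generator, normalized to a probability
    vector.  Raises if the null space is multi-dimensional (non-ergodic
    chain); warns via clipping for tiny negative round-off entries."""
    m = Q.matrix if isinstance(Q, RateMatrix) else np.asarray(Q, float)
    ns = null_space(m.T, rcond=rtol)
    if ns.shape[1] != 1:
        raise NonErgodicModelError(
            f"stationary distribution is not unique (null dim {ns.shape[1]})"
        )
    v = ns[:, 0]
    v = v * np.sign(v.sum())
    if v.min() < -1e-8:
        raise NonErgodicModelError("null vector has significant negative mass")
    v = np.clip(v, 0.0, None)
    return v / v.sum()


# -- plain-text matrix round trip ---------------------------------------


def write_matrix_tsv(
    path: str | Path, matrix: np.ndarray, states: tuple[str, ...]
) -> None:
    """TSV with a header row and a leading label column, 12 significant
    digits (shared dialect for all Q and P matrices)."""
    with open(path, "w") as fh:
        fh.write("codon\t" + "\t".join(states) + "\n")
        for label, row in zip(states, np.asarray(matrix)):
            fh.write(label + "\t" + "\t".join(f"{v:.12g}" for v in row) + "\n")


def read_matrix_tsv(path: str | Path) -> tuple[np.ndarray, tuple[str, ...]]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = tuple(header[1:])
        rows = []
        labels = []
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    if tuple(labels) != cols:
        raise ValueError("row and column labels disagree")
    m = np.asarray(rows, dtype=float)
    if m.shape[0] != m.shape[1]:
        raise ValueError(f"matrix is not square: {m.shape}")
    return m, cols
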