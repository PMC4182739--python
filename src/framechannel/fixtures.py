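"""Deterministic synthetic inputs for tests and examples.

Every generator is a pure function of its seed, so fixture files are
byte-identical across runs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .codon_model import RateMatrix, transition_matrix
from .empirical import EmpiricalChannel
from .genetic_code import SENSE_CODONS, CODONS64, CodonUsage


def uniform_usage() -> CodonUsage:
    return CodonUsage.uniform()


def dirichlet_usage(seed: int = 1, concentration: float = 2.0) -> CodonUsage:
    """A realistic non-uniform codon usage: Dirichlet-distributed over the
    61 sense codons.  The default concentration gives the few-fold
    frequency spread typical of bacterial codon bias."""
    rng = np.random.default_rng(seed)
    return CodonUsage(rng.dirichlet(np.full(61, concentration)))


def synthetic_cds(
    n_codons: int, usage: CodonUsage, seed: int = 1
) -> list[str]:
    """CDS strings sampled from a usage vector (ATG start, TAA stop) whose
    pooled codon counts recover the planted draw exactly."""
    rng = np.random.default_rng(seed)
    idx = rng.choice(61, size=n_codons, p=usage.freqs)
    body = "".join(SENSE_CODONS[i] for i in idx)
    return [body + "TAA"]


def write_cds_fasta(
    path: str | Path, n_codons: int, usage: CodonUsage, seed: int = 1
) -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(synthetic_cds(n_codons, usage, seed)):
            fh.write(f">synthetic_cds_{i} seed={seed}\n")
            for j in range(0, len(seq), 70):
                fh.write(seq[j : j + 70] + "\n")


def random_reversible_generator(
    n: int, seed: int = 1, states: tuple[str, ...] | None = None
) -> tuple[RateMatrix, np.ndarray]:
    """Random reversible CTMC generator (GTR-style: symmetric
    exchangeabilities times a random stationary distribution), scaled to
    unit expected rate.  Returns (Q, pi)."""
    rng = np.random.default_rng(seed)
    pi = rng.dirichlet(np.full(n, 5.0))
    s = rng.uniform(0.1, 1.0, size=(n, n))
    s = (s + s.T) / 2
    q = s * pi[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    q /= -(pi @ np.diag(q))
    if states is None:
        states = tuple(f"s{i}" for i in range(n))
    return RateMatrix(q, states), pi


def synthetic_empirical_matrix(
    seed: int = 1, t: float = 0.5
) -> EmpiricalChannel:
    """A synthetic stand-in for an empirical codon substitution matrix:
    the transition matrix of a random reversible 64-state generator.

    This is NOT an estimate from alignments; it only mimics the format
    and stochasticity of one.
    """
    Q, _ = random_reversible_generator(64, seed=seed, states=CODONS64)
    P = transition_matrix(Q, t)
    return EmpiricalChannel(P.matrix, CODONS64, label=f"synthetic-seed{seed}")
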