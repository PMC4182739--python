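"""Per-frame nonsynonymous/synonymous rate ratio (omega^f).

Working directly on rate matrices (rather than P(t)) removes any time
dependence.  For a frame model with generator Q^f and stationary pi^f:

    rho_S = sum_{x != y, aa_x == aa_y} pi^f_x q^f_xy      (synonymous flux)
    rho_N = sum_{x != y, aa_x != aa_y} pi^f_x q^f_xy      (nonsynonymous flux)

Site proportions come from a neutral reference: an M0-form matrix with
omega = 1, the frame's own stationary distribution and the shared kappa.
Then d_N = rho_N / rho_N^ref, d_S = rho_S / rho_S^ref and
omega^f = d_N / d_S; all scaling factors cancel.

Stop handling: in alternative frames stop codons are ordinary states (no
protein is being preserved there), so the stop label acts as a 21st
symbol -- stop<->stop counts as synonymous, stop<->amino-acid as
nonsynonymous -- and the neutral reference does not zero stop transitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .codon_model import RateMatrix
from .frames import FrameModel
from .genetic_code import (
    GeneticCode,
    STANDARD_CODE,
    is_transition,
    single_nucleotide_difference,
)


@dataclass(frozen=True)
class SelectionSummary:
    """Substitution-flux decomposition and omega for one frame."""

    frame: str
    rho_syn: float
    rho_nonsyn: float
    rho_syn_ref: float
    rho_nonsyn_ref: float
    d_s: float
    d_n: float
    omega_f: float


def _synonymy_mask(
    states: tuple[str, ...], code: GeneticCode
) -> np.ndarray:
    """Boolean matrix: True where two states encode the same symbol (stop
    is a symbol of its own)."""
    labels = [code.translate(s) for s in states]
    arr = np.array(labels)
    return arr[:, None] == arr[None, :]


def substitution_proportions(
    fm: FrameModel, code: GeneticCode = STANDARD_CODE
) -> tuple[float, float]:
    """(rho_syn, rho_nonsyn): stationary flux through synonymous and
    nonsynonymous substitutions.  Their sum is the total substitution
    flux sum_x pi^f_x (-q^f_xx)."""
    return _proportions(fm.rate.matrix, fm.pi, fm.states, code)


def _proportions(q, pi, states, code):
    syn = _synonymy_mask(states, code)
    off = q - np.diag(np.diag(q))
    flux = pi[:, None] * off
    rho_syn = float(flux[syn].sum())
    rho_nonsyn = float(flux[~syn].sum())
    return rho_syn, rho_nonsyn


def reference_matrix(
    states: tuple[str, ...],
    pi: np.ndarray,
    kappa: float,
    code: GeneticCode = STANDARD_CODE,
) -> RateMatrix:
    """Neutral (omega = 1) M0-form generator on an arbitrary codon state
    space, used only to measure site proportions.

    Unlike the coding-frame model, transitions involving stop codons are
    kept wherever stops are part of the state space.
    """
    n = len(states)
    q = np.zeros((n, n))
    for i, x in enumerate(states):
        for j, y in enumerate(states):
            if i == j:
                continue
            pos = single_nucleotide_difference(x, y)
            if pos is None:
                continue
            q[i, j] = pi[j] * (kappa if is_transition(x[pos], y[pos]) else 1.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return RateMatrix(q, states)


def omega_per_frame(
    fm: FrameModel, kappa: float, code: GeneticCode = STANDARD_CODE
) -> SelectionSummary:
    """d_N/d_S of one reading frame.

    kappa is shared across frames (known from the coding frame).  If the
    synonymous flux of the frame vanishes, omega^f is reported as +inf.
    """
    rho_s, rho_n = substitution_proportions(fm, code)
    ref = reference_matrix(fm.states, fm.pi, kappa, code)
    ref_s, ref_n = _proportions(ref.matrix, fm.pi, fm.states, code)
    d_s = rho_s / ref_s if ref_s > 0 else np.nan
    d_n = rho_n / ref_n if ref_n > 0 else np.nan
    omega_f = d_n / d_s if d_s and d_s > 0 else float("inf")
    return SelectionSummary(
        fm.frame, rho_s, rho_n, ref_s, ref_n, d_s, d_n, omega_f
    )


def omega_table(
    usage,
    kappa: float,
    omega_grid,
    frames=None,
    code: GeneticCode = STANDARD_CODE,
):
    """omega^f for every frame over a grid of coding-frame omega values.

    Returns a dict {input_omega: {frame: omega_f}} -- the data behind the
    selection-pressure curves.
    """
    from .codon_model import ModelParams, build_rate_matrix
    from .frames import FRAMES, all_frame_models

    frames = tuple(frames or FRAMES)
    out: dict[float, dict[str, float]] = {}
    for w in omega_grid:
        Q = build_rate_matrix(ModelParams(kappa=kappa, omega=w), usage, code)
        models = all_frame_models(Q)
        out[float(w)] = {
            f: omega_per_frame(models[f], kappa, code).omega_f for f in frames
        }
    return out
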