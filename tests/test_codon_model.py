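"""M0 rate matrix construction, scaling, exponentiation, stationarity."""

import numpy as np
import pytest

import framechannel as fc
from framechannel.codon_model import (
    DegenerateModelError,
    NonErgodicModelError,
    read_matrix_tsv,
    write_matrix_tsv,
)
from framechannel.genetic_code import SENSE_CODONS

IDX = {c: i for i, c in enumerate(SENSE_CODONS)}


@pytest.fixture(scope="module")
def unscaled_uniform():
    """Unscaled Eq.-structure matrix: uniform pi, kappa=2, omega=0.5."""
    return fc.build_rate_matrix(
        fc.ModelParams(kappa=2.0, omega=0.5), fc.CodonUsage.uniform(),
        scale=False,
    )


class TestBuildRateMatrix:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ("AAA", "AAG", 2.0 / 61),    # synonymous transition (Lys)
            ("AAA", "AAC", 0.5 / 61),    # nonsynonymous transversion
            ("AAA", "AGG", 0.0),         # two positions differ
            ("AAA", "ACG", 0.0),
        ],
    )
    def test_rate_structure(self, unscaled_uniform, x, y, expected):
        q = unscaled_uniform.matrix
        assert q[IDX[x], IDX[y]] == pytest.approx(expected)

    def test_generator_validity(self, Q):
        m = Q.matrix
        off = m - np.diag(np.diag(m))
        assert off.min() >= 0
        assert np.abs(m.sum(axis=1)).max() < 1e-10

    def test_reversibility_detailed_balance(self, Q, usage):
        pi = usage.freqs
        flux = pi[:, None] * Q.matrix
        np.testing.assert_allclose(flux, flux.T, atol=1e-10)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            fc.ModelParams(kappa=-1.0)
        with pytest.raises(ValueError):
            fc.ModelParams(t=float("nan"))


class TestScaling:
    def test_unit_expected_substitution_rate(self, Q, usage):
        rate = -(usage.freqs @ np.diag(Q.matrix))
        assert rate == pytest.approx(1.0, abs=1e-10)

    def test_scale_invariance(self, usage):
        raw = fc.build_rate_matrix(
            fc.ModelParams(kappa=2.0, omega=0.5), usage, scale=False
        )
        tripled = fc.RateMatrix(raw.matrix * 3.0, raw.states, pi=raw.pi)
        a = fc.scale_rate_matrix(raw, usage)
        b = fc.scale_rate_matrix(tripled, usage)
        np.testing.assert_allclose(a.matrix, b.matrix, atol=1e-12)

    def test_omega_zero_still_normalizes(self, usage):
        Q0 = fc.build_rate_matrix(fc.ModelParams(kappa=1.0, omega=0.0), usage)
        rate = -(usage.freqs @ np.diag(Q0.matrix))
        assert rate == pytest.approx(1.0, abs=1e-10)

    def test_zero_rate_degenerate(self):
        zero = fc.RateMatrix(np.zeros((61, 61)), SENSE_CODONS)
        with pytest.raises(DegenerateModelError):
            fc.scale_rate_matrix(zero, fc.CodonUsage.uniform())


class TestTransitionMatrix:
    def test_t_zero_is_identity(self, Q):
        P = fc.transition_matrix(Q, 0.0)
        np.testing.assert_allclose(P.matrix, np.eye(61), atol=1e-12)

    def test_negative_time_raises(self, Q):
        with pytest.raises(ValueError):
            fc.transition_matrix(Q, -0.1)

    def test_semigroup_property(self, Q):
        P_half = fc.transition_matrix(Q, 0.5).matrix
        P_one = fc.transition_matrix(Q, 1.0).matrix
        np.testing.assert_allclose(P_half @ P_half, P_one, atol=1e-8)

    def test_stationarity_of_pi(self, Q, usage):
        P = fc.transition_matrix(Q, 1.0)
        np.testing.assert_allclose(
            usage.freqs @ P.matrix, usage.freqs, atol=1e-8
        )

    def test_rows_are_stochastic(self, Q):
        P = fc.transition_matrix(Q, 2.0)
        assert np.abs(P.matrix.sum(axis=1) - 1).max() < 1e-8
        assert P.matrix.min() >= 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_uniformization_oracle(self, seed):
        """expm vs an independent truncated uniformization series on
        random small reversible generators."""
        from framechannel.fixtures import random_reversible_generator

        Qs, _ = random_reversible_generator(6, seed=seed)
        t = 0.7
        lam = -Qs.matrix.diagonal().min() * 1.05
        B = np.eye(6) + Qs.matrix / lam
        term = np.eye(6) * np.exp(-lam * t)
        acc = term.copy()
        for k in range(1, 200):
            term = term @ B * (lam * t / k)
            acc += term
        P = fc.transition_matrix(Qs, t).matrix
        np.testing.assert_allclose(P, acc, atol=1e-6)


class TestStationaryDistribution:
    def test_recovers_usage_for_model_matrix(self, Q, usage):
        pi = fc.stationary_distribution(Q)
        np.testing.assert_allclose(pi, usage.freqs, atol=1e-9)

    def test_two_state_closed_form(self):
        q = fc.RateMatrix(np.array([[-1.0, 1.0], [2.0, -2.0]]), ("a", "b"))
        np.testing.assert_allclose(
            fc.stationary_distribution(q), [2 / 3, 1 / 3], atol=1e-12
        )

    def test_sums_to_one_and_nonnegative(self, Q):
        pi = fc.stationary_distribution(Q)
        assert pi.sum() == pytest.approx(1.0, abs=1e-12)
        assert pi.min() >= 0

    def test_reducible_generator_raises(self):
        block = np.zeros((4, 4))
        block[:2, :2] = [[-1, 1], [1, -1]]
        block[2:, 2:] = [[-2, 2], [2, -2]]
        q = fc.RateMatrix(block, ("a", "b", "c", "d"))
        with pytest.raises(NonErgodicModelError):
            fc.stationary_distribution(q)


class TestMatrixTsv:
    def test_round_trip(self, Q, tmp_path):
        p = tmp_path / "q.tsv"
        write_matrix_tsv(p, Q.matrix, Q.states)
        m, states = read_matrix_tsv(p)
        assert states == Q.states
        np.testing.assert_allclose(m, Q.matrix, rtol=1e-11)

    def test_label_mismatch_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("codon\tAAA\tAAC\nAAA\t0\t0\nAAG\t0\t0\n")
        with pytest.raises(ValueError, match="labels"):
            read_matrix_tsv(p)
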