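import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from calvingmc import (
    CooccurrenceMatrix,
    InputError,
    StateDistribution,
    TransitionMatrix,
    augment_absorbing,
    diagonal_trajectory,
    fixtures,
    propagate,
    read_transition,
    row_normalize,
    stationary,
    write_transition,
)

PRINT_TOL = 5.001e-4  # "rounds to the same 3 decimals"


class TestRowNormalize:
    def test_id11_row_L_matches_printed(self):
        P = row_normalize(fixtures.load_counts("ID11"))
        np.testing.assert_allclose(
            P.probs[0], [0.971, 0.028, 0, 0, 0.001], atol=PRINT_TOL
        )

    def test_id27_row_S_matches_printed(self):
        P = row_normalize(fixtures.load_counts("ID27"))
        assert P.probs[2, 2] == pytest.approx(0.990, abs=PRINT_TOL)

    def test_identity_counts_give_identity(self):
        P = row_normalize(CooccurrenceMatrix(np.diag([7, 3, 9, 2, 1])))
        assert np.array_equal(P.probs, np.eye(5))

    def test_rows_sum_to_one(self, rng):
        C = CooccurrenceMatrix(rng.integers(1, 50, size=(5, 5)))
        P = row_normalize(C)
        np.testing.assert_allclose(P.probs.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_row_error_names_state(self):
        counts = np.ones((5, 5), dtype=int)
        counts[1] = 0
        with pytest.raises(InputError, match="LS"):
            row_normalize(CooccurrenceMatrix(counts))

    def test_zero_row_self_loop_policy(self):
        counts = np.ones((5, 5), dtype=int)
        counts[1] = 0
        P = row_normalize(CooccurrenceMatrix(counts),
                          zero_row_policy="self_loop")
        assert P.probs[1, 1] == 1.0

    def test_zero_row_uniform_policy(self):
        counts = np.ones((5, 5), dtype=int)
        counts[3] = 0
        P = row_normalize(CooccurrenceMatrix(counts), zero_row_policy="uniform")
        np.testing.assert_allclose(P.probs[3], 0.2)

    def test_zero_calve_row_becomes_absorbing(self):
        """Truthful counting leaves the CALVE row empty; normalization
        installs the absorbing self-loop there under any policy."""
        counts = np.ones((5, 5), dtype=int)
        counts[4] = 0
        P = row_normalize(CooccurrenceMatrix(counts))
        assert P.probs[4].tolist() == [0, 0, 0, 0, 1]


class TestAugmentAbsorbing:
    def test_calve_row_becomes_unit(self, rng):
        C = CooccurrenceMatrix(rng.integers(1, 50, size=(5, 5)))
        P = augment_absorbing(row_normalize(C))
        assert P.probs[4].tolist() == [0, 0, 0, 0, 1]

    def test_idempotent(self, printed_P):
        once = augment_absorbing(printed_P)
        twice = augment_absorbing(once)
        assert np.array_equal(once.probs, twice.probs)

    def test_identity_on_already_absorbing_fixture(self):
        P = fixtures.load_transition("ID2")
        assert np.array_equal(augment_absorbing(P).probs, P.probs)

    def test_other_rows_untouched(self, printed_P):
        out = augment_absorbing(printed_P)
        assert np.array_equal(out.probs[:4], printed_P.probs[:4])


def two_state_chain(a, b):
    return TransitionMatrix(
        np.array([[1 - a, a], [b, 1 - b]]), state_order=("A", "B")
    )


class TestPropagate:
    def test_zero_steps_is_identity(self, chain_P):
        p0 = StateDistribution.point_mass("L")
        assert np.array_equal(propagate(p0, chain_P, 0).probs, p0.probs)

    def test_identity_chain_is_fixed(self):
        P = TransitionMatrix(np.eye(5))
        p0 = StateDistribution(np.array([0.2, 0.3, 0.1, 0.25, 0.15]))
        for t in (1, 7, 100):
            np.testing.assert_allclose(propagate(p0, P, t).probs, p0.probs,
                                       atol=1e-12)

    @pytest.mark.parametrize("a,b,t", [(0.3, 0.1, 5), (0.05, 0.4, 17),
                                       (0.9, 0.8, 3)])
    def test_two_state_closed_form(self, a, b, t):
        """p1(t) = b/(a+b) + (p1(0) - b/(a+b)) (1-a-b)^t."""
        P = two_state_chain(a, b)
        p0 = StateDistribution(np.array([0.7, 0.3]), state_order=("A", "B"))
        pt = propagate(p0, P, t)
        limit = b / (a + b)
        expected = limit + (0.7 - limit) * (1 - a - b) ** t
        assert pt.probs[0] == pytest.approx(expected, abs=1e-12)
        assert pt.step_index == t

    def test_negative_steps_rejected(self, chain_P):
        with pytest.raises(InputError):
            propagate(StateDistribution.point_mass("L"), chain_P, -1)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(s=st.integers(0, 20), t=st.integers(0, 20), seed=st.integers(0, 100))
    def test_chapman_kolmogorov(self, s, t, seed):
        from conftest import random_stochastic

        P = random_stochastic(np.random.default_rng(seed))
        p0 = StateDistribution(np.full(5, 0.2))
        direct = propagate(p0, P, s + t)
        staged = propagate(propagate(p0, P, s), P, t)
        np.testing.assert_allclose(direct.probs, staged.probs, atol=1e-10)
        assert direct.step_index == staged.step_index


class TestDiagonalTrajectory:
    def test_t1_is_the_diagonal_of_P(self, printed_P):
        table = diagonal_trajectory(printed_P, [1])
        np.testing.assert_allclose(
            table.loc[0, ["p11", "p22", "p33", "p44"]].to_numpy(),
            np.diag(printed_P.probs)[:4],
        )

    def test_matches_brute_force_matrix_power(self):
        """Independent oracle: explicit repeated 5x5 multiplication."""
        P = fixtures.load_transition("ID2")
        table = diagonal_trajectory(P, [2, 4, 6])
        M = np.eye(5)
        by_t = {}
        for t in range(1, 7):
            M = M @ P.probs
            by_t[t] = np.diag(M)[:4]
        for row in table.itertuples(index=False):
            np.testing.assert_allclose(
                [row.p11, row.p22, row.p33, row.p44], by_t[row.t], atol=1e-12
            )

    def test_values_in_unit_interval(self, printed_P):
        table = diagonal_trajectory(printed_P, list(range(25)))
        vals = table[["p11", "p22", "p33", "p44"]].to_numpy()
        assert np.all(vals >= 0) and np.all(vals <= 1)

    def test_posture_probabilities_decrease_toward_calving(self, printed_P):
        """The lying (p11) and standing (p33) diagonals fall strictly over
        t = 1..24 for every published chain."""
        table = diagonal_trajectory(printed_P, list(range(1, 25)))
        assert np.all(np.diff(table["p11"]) < 0)
        assert np.all(np.diff(table["p33"]) < 0)


class TestStationary:
    def test_symmetric_two_state_is_uniform(self):
        pi = stationary(two_state_chain(0.3, 0.3))
        np.testing.assert_allclose(pi.probs, [0.5, 0.5], atol=1e-12)
        assert not pi.reducible

    def test_absorbing_chain_concentrates_on_calve(self, chain_P):
        pi = stationary(chain_P)
        assert pi.reducible
        np.testing.assert_allclose(pi.probs, [0, 0, 0, 0, 1], atol=1e-9)

    def test_matches_power_iteration_oracle(self, rng):
        """Independent oracle: long-run propagation p0 P^t."""
        from conftest import random_stochastic

        P = random_stochastic(rng)
        pi = stationary(P)
        p0 = StateDistribution(np.full(5, 0.2))
        p_inf = propagate(p0, P, 10**6)
        np.testing.assert_allclose(pi.probs, p_inf.probs, atol=1e-9)
        assert pi.residual < 1e-10


class TestTransitionIO:
    def test_round_trip(self, chain_P):
        buf = io.StringIO()
        write_transition(chain_P, buf)
        buf.seek(0)
        again = read_transition(buf)
        np.testing.assert_allclose(again.probs, chain_P.probs, atol=1e-15)

    def test_bad_row_sum_rejected(self):
        bad = np.eye(5)
        bad[0, 0] = 0.9
        with pytest.raises(InputError, match="sum to 1"):
            TransitionMatrix(bad)

    def test_estimator_error_shrinks_with_sequence_length(self):
        """Transition estimates from longer simulated paths get closer to
        the truth, consistent with an n^-1/2 rate (seeded)."""
        from calvingmc import SimulationSpec, count_transitions, simulate_sequence
        from conftest import fold_calving_hazard

        # calving hazard folded away so arbitrarily long paths exist
        P = fold_calving_hazard(fixtures.load_transition("ID27",
                                                         renormalize=True))
        errors = {}
        for n in (10**3, 10**4, 10**5):
            spec = SimulationSpec(P=P, start="L", max_steps=n, seed=7)
            seq = simulate_sequence(spec)
            C = count_transitions(seq)
            est = row_normalize(C, zero_row_policy="self_loop")
            entered = C.row_totals() > 0
            err = np.abs(est.probs - P.probs)[entered].max()
            errors[n] = err
        assert errors[10**5] < errors[10**3]
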