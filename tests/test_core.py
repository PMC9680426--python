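"""Unit and property tests for the selection-weight model."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import expit

from foragekit.core import (
    CLASS_A,
    CLASS_B,
    Display,
    ForagingParams,
    Item,
    SelectionSequence,
    SequenceCache,
    TrialState,
    angular_difference,
    class_stick_weight,
    direction_cost,
    direction_kernel,
    proximity_kernel,
    selection_probabilities,
    selection_weights,
    sequence_log_likelihood,
    state_selection_probabilities,
)
from foragekit.exceptions import (
    DegenerateGeometryError,
    EmptyChoiceSetError,
    InvalidArgumentError,
    SequenceMismatchError,
)

from conftest import make_display

finite_angles = st.floats(-50.0, 50.0, allow_nan=False)


class TestAngularDifference:
    @pytest.mark.parametrize(
        "phi1,phi2,expected",
        [
            (0.0, 0.0, 0.0),
            (0.0, math.pi, math.pi),
            (0.1, 2 * math.pi + 0.1, 0.0),
            (-math.pi / 2, math.pi / 2, math.pi),
        ],
    )
    def test_examples(self, phi1, phi2, expected):
        assert angular_difference(phi1, phi2) == pytest.approx(expected, abs=1e-12)

    @given(finite_angles, finite_angles)
    def test_symmetric_periodic_and_bounded(self, a, b):
        d = angular_difference(a, b)
        assert 0.0 <= d <= math.pi + 1e-12
        assert d == pytest.approx(angular_difference(b, a), abs=1e-9)
        assert d == pytest.approx(angular_difference(a + 2 * math.pi, b), abs=1e-7)

    def test_rejects_nonfinite(self):
        with pytest.raises(InvalidArgumentError):
            angular_difference(float("nan"), 0.0)


class TestDirectionCost:
    def _item(self, x, y):
        return Item(item_id=hash((x, y)) % 10**6, x=x, y=y, item_class=CLASS_A)

    @pytest.mark.parametrize(
        "cand,expected",
        [((1.0, 0.0), 0.0), ((0.0, 0.0), 1.0), ((0.5, 0.5), 0.5)],
    )
    def test_straight_reversal_right_angle(self, cand, expected):
        prev, cur = self._item(0.0, 0.0), self._item(0.5, 0.0)
        assert direction_cost(self._item(*cand), cur, prev) == pytest.approx(expected)

    def test_coincident_positions_rejected(self):
        a = self._item(0.3, 0.3)
        with pytest.raises(DegenerateGeometryError):
            direction_cost(self._item(0.5, 0.5), a, self._item(0.3, 0.3))


class TestKernels:
    def test_proximity_closed_forms(self):
        assert proximity_kernel(0.0, 5.0) == 1.0
        assert proximity_kernel(0.3, 0.0) == 1.0
        assert proximity_kernel(math.log(2), 1.0) == pytest.approx(0.5)

    def test_proximity_rejects_negative_distance(self):
        with pytest.raises(InvalidArgumentError):
            proximity_kernel(-0.1, 1.0)

    def test_direction_closed_forms(self):
        assert direction_kernel(0.0, 3.0) == 1.0
        assert direction_kernel(1.0, 0.0) == 1.0
        assert direction_kernel(1.0, math.log(4)) == pytest.approx(0.25)

    def test_direction_rejects_out_of_range(self):
        with pytest.raises(InvalidArgumentError):
            direction_kernel(1.5, 1.0)

    def test_proximity_strictly_decreasing(self):
        d = np.linspace(0, 1, 11)
        vals = [proximity_kernel(x, 2.0) for x in d]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestClassStickWeight:
    def test_zero_params_give_half(self):
        p = ForagingParams()
        assert class_stick_weight(CLASS_B, None, p) == pytest.approx(0.5)
        assert class_stick_weight(CLASS_A, CLASS_A, p) == pytest.approx(0.5)

    def test_logistic_at_two(self):
        p = ForagingParams(b_class=1.0, b_stick=1.0)
        assert class_stick_weight(CLASS_A, CLASS_A, p) == pytest.approx(
            1.0 / (1.0 + math.exp(-2.0))
        )

    def test_stick_only_applies_to_matching_class(self):
        p = ForagingParams(b_class=0.0, b_stick=2.0)
        assert class_stick_weight(CLASS_B, CLASS_A, p) == pytest.approx(0.5)
        assert class_stick_weight(CLASS_B, CLASS_B, p) == pytest.approx(expit(2.0))


class TestSelectionWeights:
    def test_all_zero_params_uniform_half(self, square_display, uniform_params):
        state = TrialState.initial(square_display).advance(0)
        w = selection_weights(state, uniform_params)
        assert set(w) == {1, 2, 3}
        assert all(v == pytest.approx(0.5) for v in w.values())

    def test_proximity_only_closed_form(self):
        # remaining items at distances 0.1 and 0.2 from the last selection
        disp = make_display(
            [(0.5, 0.5), (0.6, 0.5), (0.7, 0.5)],
            [CLASS_A, CLASS_A, CLASS_B],
        )
        state = TrialState.initial(disp).advance(0)
        w = selection_weights(state, ForagingParams(sigma_d=10.0))
        assert w[1] == pytest.approx(0.5 * math.exp(-1.0))
        assert w[2] == pytest.approx(0.5 * math.exp(-2.0))

    def test_first_selection_salience_only(self, square_display):
        state = TrialState.initial(square_display)
        w = selection_weights(state, ForagingParams(b_class=2.0))
        assert w[0] == pytest.approx(expit(2.0))  # class A
        assert w[1] == pytest.approx(0.5)  # class B

    def test_empty_remaining_rejected(self, square_display, uniform_params):
        state = TrialState(display=square_display, remaining=frozenset(), last=0)
        with pytest.raises(EmptyChoiceSetError):
            selection_weights(state, uniform_params)


class TestSelectionProbabilities:
    def test_uniform_normalization(self):
        p = selection_probabilities({k: 2.5 for k in range(8)})
        assert all(v == pytest.approx(1 / 8) for v in p.values())

    def test_two_weight_example(self):
        w = {0: 0.5 * math.exp(-1.0), 1: 0.5 * math.exp(-2.0)}
        p = selection_probabilities(w)
        assert p[0] == pytest.approx(math.e / (math.e + 1))
        assert p[1] == pytest.approx(1 / (math.e + 1))

    def test_single_item(self):
        assert selection_probabilities({7: 0.2}) == {7: 1.0}

    def test_rejects_nonpositive(self):
        with pytest.raises(InvalidArgumentError):
            selection_probabilities({0: 0.0, 1: 1.0})

    @given(st.lists(st.floats(1e-6, 1e6), min_size=1, max_size=20))
    def test_sums_to_one(self, weights):
        p = selection_probabilities(dict(enumerate(weights)))
        assert sum(p.values()) == pytest.approx(1.0, abs=1e-12)


class TestSequenceLogLikelihood:
    def test_uniform_three_items_excluding_first(self, uniform_params):
        disp = make_display([(0.1, 0.1), (0.5, 0.5), (0.9, 0.9)])
        ll = sequence_log_likelihood(
            disp, SelectionSequence((0, 1, 2)), uniform_params, include_first=False
        )
        assert ll == pytest.approx(-math.log(2))

    def test_uniform_including_first_is_log_factorial(
        self, square_display, uniform_params
    ):
        ll = sequence_log_likelihood(
            square_display, SelectionSequence((2, 0, 3, 1)), uniform_params,
            include_first=True,
        )
        assert ll == pytest.approx(-math.log(math.factorial(4)))

    def test_invalid_sequence_rejected(self, square_display, uniform_params):
        with pytest.raises(SequenceMismatchError):
            sequence_log_likelihood(
                square_display, SelectionSequence((0, 99)), uniform_params
            )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_brute_force_total_probability(self, square_display, seed):
        """Over all complete orders the model is a probability distribution."""
        rng = np.random.default_rng(seed)
        params = ForagingParams.from_array(rng.normal(0, 1.5, 4))
        ids = square_display.item_ids
        total_incl = sum(
            math.exp(
                sequence_log_likelihood(
                    square_display, SelectionSequence(perm), params, include_first=True
                )
            )
            for perm in itertools.permutations(ids)
        )
        assert total_incl == pytest.approx(1.0, abs=1e-9)
        total_excl = sum(
            math.exp(
                sequence_log_likelihood(
                    square_display, SelectionSequence(perm), params, include_first=False
                )
            )
            for perm in itertools.permutations(ids)
        )
        # without the first selection, each of the n first items starts a
        # conditional distribution summing to 1
        assert total_excl == pytest.approx(len(ids), abs=1e-9)


class TestLimitsAndInvariants:
    def test_uniform_limit_exact(self, square_display, uniform_params):
        state = TrialState.initial(square_display).advance(0).advance(1)
        p = state_selection_probabilities(state, uniform_params)
        assert all(v == pytest.approx(0.5, abs=1e-15) for v in p.values())

    def test_nearest_neighbour_limit(self, rng):
        disp = make_display(rng.uniform(0.05, 0.95, size=(8, 2)))
        state = TrialState.initial(disp).advance(0)
        dists = {
            i: np.hypot(*(disp.positions[disp.index(i)] - disp.positions[0]))
            for i in state.remaining
        }
        nearest = min(dists, key=dists.get)
        p = state_selection_probabilities(state, ForagingParams(sigma_d=500.0))
        assert p[nearest] == pytest.approx(1.0, abs=1e-9)

    def test_class_preference_limit(self):
        # two remaining items, one per class: p(A) -> g(b)/(g(b)+0.5) -> 2/3
        disp = make_display(
            [(0.1, 0.1), (0.4, 0.4), (0.9, 0.9)], [CLASS_B, CLASS_A, CLASS_B]
        )
        state = TrialState.initial(disp).advance(0)
        p = state_selection_probabilities(state, ForagingParams(b_class=50.0))
        assert p[1] == pytest.approx(2.0 / 3.0, abs=1e-6)

    @given(st.floats(-5, 5))
    def test_first_selection_exchange_preserves_preference(self, b_class):
        """Relabelling A<->B and negating b_class preserves which items are
        favoured first.  (The logistic link makes the two distributions
        order-equivalent, not identical: g(b)*g(-b) != 1/4 for b != 0.)"""
        positions = [(0.1, 0.2), (0.6, 0.3), (0.4, 0.8), (0.9, 0.9)]
        classes = [CLASS_A, CLASS_B, CLASS_B, CLASS_A]
        flipped = [CLASS_B if c == CLASS_A else CLASS_A for c in classes]
        p1 = state_selection_probabilities(
            TrialState.initial(make_display(positions, classes)),
            ForagingParams(b_class=b_class),
        )
        p2 = state_selection_probabilities(
            TrialState.initial(make_display(positions, flipped)),
            ForagingParams(b_class=-b_class),
        )
        for i in p1:
            for j in p1:
                assert (p1[i] - p1[j]) * (p2[i] - p2[j]) >= -1e-15
        # the two items of the same original class always stay tied
        assert p1[0] == pytest.approx(p1[3], abs=1e-12)
        assert p2[0] == pytest.approx(p2[3], abs=1e-12)

    def test_cache_gradient_matches_finite_differences(self, rng):
        disp = make_display(rng.uniform(0.02, 0.98, size=(10, 2)))
        seq = SelectionSequence(tuple(rng.permutation(10).tolist()))
        cache = SequenceCache.build(disp, seq, include_first=True)
        x = np.array([0.4, -0.8, 3.0, 0.7])
        _, g = cache.log_likelihood_grad(x)
        eps = 1e-6
        for i in range(4):
            e = np.zeros(4)
            e[i] = eps
            num = (cache.log_likelihood(x + e) - cache.log_likelihood(x - e)) / (2 * eps)
            assert g[i] == pytest.approx(num, abs=1e-5)


class TestDomainTypes:
    def test_display_rejects_duplicate_ids(self):
        items = [
            Item(0, 0.1, 0.1, CLASS_A),
            Item(0, 0.5, 0.5, CLASS_B),
        ]
        with pytest.raises(InvalidArgumentError):
            Display(items)

    def test_display_rejects_coincident_items(self):
        items = [Item(0, 0.5, 0.5, CLASS_A), Item(1, 0.5, 0.5, CLASS_B)]
        with pytest.raises(DegenerateGeometryError):
            Display(items)

    def test_item_rejects_out_of_square(self):
        with pytest.raises(InvalidArgumentError):
            Item(0, 1.2, 0.5, CLASS_A)

    def test_sequence_rejects_repeats(self):
        with pytest.raises(SequenceMismatchError):
            SelectionSequence((1, 2, 1))

    def test_state_advance_removes_and_tracks_history(self, square_display):
        state = TrialState.initial(square_display).advance(3).advance(1)
        assert state.last == 1 and state.second_last == 3
        assert state.remaining == {0, 2}
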