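"""The attention pipeline primitives: worked examples, errors and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from attnkit.functional import (
    GCLIConfig,
    GCLIParams,
    context_weighted_map,
    context_weights,
    gate,
    gcli_a_forward,
    gcli_b_forward,
    global_avg_descriptor,
    global_max_descriptor,
    local_interaction,
    partial_split,
    select_features,
)
from oracles import conv1d_2row_loops, conv1d_loops, silu, softmax_2d_loops

finite_floats = st.floats(-10, 10, allow_nan=False, allow_infinity=False)


class TestContextWeights:
    def test_uniform_logits_give_uniform_weights(self):
        alpha = context_weights(np.random.default_rng(0).normal(size=(2, 2, 3)),
                                np.zeros(3))
        np.testing.assert_allclose(alpha, 0.25)

    def test_single_position_gets_all_mass(self):
        alpha = context_weights(np.ones((1, 1, 4)), np.ones(4))
        np.testing.assert_allclose(alpha, 1.0)

    def test_hand_evaluated_two_position_softmax(self):
        # logits 0 and ln 3 -> masses 1/(1+3) and 3/(1+3)
        x = np.array([[[0.0]], [[np.log(3.0)]]])
        alpha = context_weights(x, np.ones(1))
        np.testing.assert_allclose(alpha.ravel(), [0.25, 0.75], atol=1e-12)

    def test_channel_mismatch_rejected(self):
        with pytest.raises(ValueError):
            context_weights(np.zeros((2, 2, 3)), np.zeros(4))

    def test_nonfinite_input_rejected(self):
        x = np.zeros((2, 2, 1))
        x[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            context_weights(x, np.zeros(1))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        x=hnp.arrays(np.float64, (3, 4, 2), elements=finite_floats),
        wk=hnp.arrays(np.float64, (2,), elements=finite_floats),
        shift=finite_floats,
    )
    def test_sums_to_one_and_shift_invariant(self, x, wk, shift):
        alpha = context_weights(x, wk, 0.0)
        assert alpha.min() >= 0
        assert abs(alpha.sum() - 1.0) < 1e-6
        # adding a constant to all logits (via the bias) changes nothing
        np.testing.assert_allclose(alpha, context_weights(x, wk, shift), atol=1e-9)

    def test_matches_loop_softmax(self, rng):
        x = rng.standard_normal((3, 3, 5))
        wk = rng.standard_normal(5)
        alpha = context_weights(x, wk, 0.3)
        np.testing.assert_allclose(alpha, softmax_2d_loops(x @ wk + 0.3), atol=1e-10)


class TestContextWeightedMap:
    def test_uniform_alpha_scales_by_positions(self):
        x = np.full((2, 3, 4), 7.0)
        out = context_weighted_map(x, np.full((2, 3), 1.0 / 6))
        np.testing.assert_allclose(out, 7.0 / 6)
        np.testing.assert_allclose(out.sum(axis=(0, 1)), 7.0)

    def test_one_hot_alpha_selects_one_position(self, rng):
        x = rng.standard_normal((2, 2, 3))
        alpha = np.zeros((2, 2))
        alpha[0, 0] = 1.0
        out = context_weighted_map(x, alpha)
        np.testing.assert_allclose(out[0, 0], x[0, 0])
        assert np.all(out[alpha == 0] == 0)

    def test_hand_example_and_context_vector_consistency(self):
        x = np.array([[[1.0]], [[2.0]]])
        alpha = np.array([[0.25], [0.75]])
        out = context_weighted_map(x, alpha)
        np.testing.assert_allclose(out.ravel(), [0.25, 1.5])
        np.testing.assert_allclose(out.sum(axis=(0, 1)), [1.75])

    def test_spatial_sum_equals_context_vector(self, rng):
        """The weighted map and the context vector are two readings of the
        same quantity: summing the map over space must give the vector."""
        x = rng.standard_normal((4, 3, 6))
        wk = rng.standard_normal(6)
        alpha = context_weights(x, wk, 0.1)
        vec = np.einsum("ij,ijc->c", alpha, x)
        np.testing.assert_allclose(
            context_weighted_map(x, alpha).sum(axis=(0, 1)), vec, atol=1e-6
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            context_weighted_map(np.zeros((2, 2, 1)), np.zeros((3, 2)))


class TestDescriptors:
    def test_constant_map(self):
        m = np.full((3, 2, 4), 2.5)
        np.testing.assert_allclose(global_max_descriptor(m), 2.5)
        np.testing.assert_allclose(global_avg_descriptor(m), 2.5)

    def test_hand_examples(self):
        m = np.array([[[1.0], [2.0]], [[3.0], [4.0]]])
        assert global_max_descriptor(m)[0] == 4.0
        assert global_avg_descriptor(m)[0] == 2.5
        neg = np.array([[[-3.0]], [[-1.0]]])
        assert global_max_descriptor(neg)[0] == -1.0

    def test_descriptors_invariant_to_spatial_permutation(self, rng):
        x = rng.standard_normal((4, 4, 3))
        perm = rng.permutation(16)
        xp = x.reshape(16, 3)[perm].reshape(4, 4, 3)
        np.testing.assert_allclose(
            global_max_descriptor(x), global_max_descriptor(xp)
        )
        np.testing.assert_allclose(
            global_avg_descriptor(x), global_avg_descriptor(xp), atol=1e-12
        )


class TestSelectionAndInteraction:
    def test_zero_kernel_gives_zero(self):
        out = select_features(np.ones(5), np.ones(5), np.zeros((2, 7)))
        np.testing.assert_allclose(out, 0.0)  # SiLU(0) = 0

    def test_single_column_kernel_on_length_one(self):
        k = np.zeros((2, 7))
        k[0, 3], k[1, 3] = 0.4, -0.2
        a, b = 1.5, 2.0
        z = 0.4 * a - 0.2 * b
        np.testing.assert_allclose(
            select_features(np.array([a]), np.array([b]), k), silu(np.array([z]))
        )

    def test_silu_asymptotic_identity_on_delta_kernel(self):
        k = np.zeros((2, 7))
        k[0, 3] = 1.0
        big = 50.0
        out = select_features(np.array([big]), np.array([0.0]), k)
        np.testing.assert_allclose(out, big, rtol=1e-12)

    def test_interaction_identity_kernel(self, rng):
        row = rng.standard_normal(6)
        np.testing.assert_allclose(
            local_interaction(row, np.array([0.0, 1.0, 0.0])), row
        )

    def test_interaction_hand_sum(self):
        out = local_interaction(np.array([1.0, 2.0, 3.0]), np.ones(3))
        np.testing.assert_allclose(out, [3.0, 6.0, 5.0])

    def test_zero_input_zero_output(self):
        np.testing.assert_allclose(
            local_interaction(np.zeros(4), np.array([1.0, 2.0, 3.0])), 0.0
        )

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        row=hnp.arrays(
            np.float64,
            st.integers(1, 16).map(lambda n: (n,)),
            elements=finite_floats,
        ),
        kernel=hnp.arrays(
            np.float64,
            st.sampled_from([(3,), (5,), (7,)]),
            elements=finite_floats,
        ),
    )
    def test_conv1d_matches_loop_oracle(self, row, kernel):
        np.testing.assert_allclose(
            local_interaction(row, kernel), conv1d_loops(row, kernel), atol=1e-10
        )

    def test_selection_conv_matches_loop_oracle(self, rng):
        top, bot = rng.standard_normal((2, 11))
        k = rng.standard_normal((2, 7))
        np.testing.assert_allclose(
            select_features(top, bot, k),
            silu(conv1d_2row_loops(top, bot, k)),
            atol=1e-10,
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            select_features(np.ones(3), np.ones(4), np.zeros((2, 7)))


class TestGate:
    def test_zero_attention_halves_input(self, rng):
        x = rng.standard_normal((2, 3, 4))
        np.testing.assert_allclose(gate(x, np.zeros(4)), x / 2)

    def test_saturated_gate_passes_input(self, rng):
        x = rng.standard_normal((2, 2, 2))
        np.testing.assert_allclose(gate(x, np.full(2, 1e3)), x)

    def test_hand_value(self):
        out = gate(np.full((1, 1, 1), 2.0), np.array([np.log(3.0)]))
        np.testing.assert_allclose(out, 1.5)

    def test_output_never_exceeds_input_magnitude(self, rng):
        x = rng.standard_normal((3, 3, 5))
        out = gate(x, rng.standard_normal(5) * 10)
        assert np.all(np.abs(out) <= np.abs(x) + 1e-15)


class TestPartialSplit:
    def test_half_of_four(self, rng):
        x = rng.standard_normal((2, 2, 4))
        inter, rest = partial_split(x, 0.5)
        np.testing.assert_array_equal(inter, x[:, :, :2])
        np.testing.assert_array_equal(rest, x[:, :, 2:])

    def test_full_fraction_leaves_nothing(self, rng):
        x = rng.standard_normal((2, 2, 3))
        inter, rest = partial_split(x, 1.0)
        assert rest.shape[2] == 0
        np.testing.assert_array_equal(inter, x)

    def test_floor_rule_on_odd_widths(self, rng):
        x = rng.standard_normal((1, 1, 5))
        inter, rest = partial_split(x, 0.5)
        assert inter.shape[2] == 2 and rest.shape[2] == 3

    def test_concatenation_restores_input(self, rng):
        x = rng.standard_normal((3, 2, 7))
        inter, rest = partial_split(x, 0.3)
        np.testing.assert_array_equal(np.concatenate([inter, rest], axis=2), x)

    @pytest.mark.parametrize("f", [0.0, -0.5, 1.5])
    def test_invalid_fraction_rejected(self, f):
        with pytest.raises(ValueError):
            partial_split(np.zeros((1, 1, 4)), f)

    def test_zero_interacted_width_rejected(self):
        with pytest.raises(ValueError):
            partial_split(np.zeros((1, 1, 3)), 0.1)


class TestComposedForward:
    def test_all_zero_parameters_halve_input(self, rng):
        x = rng.standard_normal((3, 3, 4))
        p = GCLIParams(np.zeros(4), 0.0, np.zeros((2, 7)), np.zeros(3))
        np.testing.assert_allclose(gcli_a_forward(x, p), x / 2, atol=1e-12)

    def test_shape_preserved(self, rng):
        x = rng.standard_normal((8, 8, 16))
        p = GCLIParams.init(16, rng)
        assert gcli_a_forward(x, p).shape == x.shape

    def test_module_b_reduces_to_module_a_at_full_fraction(self, rng):
        x = rng.standard_normal((2, 3, 4))
        p = GCLIParams.init(4, rng)
        cfg = GCLIConfig(fraction=1.0)
        np.testing.assert_array_equal(
            gcli_b_forward(x, p, cfg), gcli_a_forward(x, p, cfg)
        )

    def test_module_b_untouched_channels_pass_through(self, rng):
        x = rng.standard_normal((4, 4, 6))
        p = GCLIParams.init(3, rng)
        out = gcli_b_forward(x, p, GCLIConfig(fraction=0.5))
        np.testing.assert_array_equal(out[:, :, 3:], x[:, :, 3:])
        # interacted slice equals a 3-channel module-A pass
        np.testing.assert_array_equal(
            out[:, :, :3], gcli_a_forward(x[:, :, :3], p)
        )

    def test_gates_shrink_magnitudes(self, rng):
        x = rng.standard_normal((3, 3, 5))
        p = GCLIParams.init(5, rng)
        out = gcli_a_forward(x, p)
        assert np.all(np.abs(out) <= np.abs(x) + 1e-15)

    def test_spatial_permutation_leaves_gates_unchanged(self, rng):
        """Descriptors are order-free pools, so permuting pixels rescales every
        position by the same per-channel gate."""
        x = rng.standard_normal((2, 3, 4))
        p = GCLIParams.init(4, rng)
        out = gcli_a_forward(x, p)
        gates = out / x
        perm = rng.permutation(6)
        xp = x.reshape(6, 4)[perm].reshape(2, 3, 4)
        outp = gcli_a_forward(xp, p)
        np.testing.assert_allclose(outp / xp, gates.reshape(6, 4)[perm].reshape(2, 3, 4),
                                   atol=1e-9)
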