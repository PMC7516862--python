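"""Encoder/decoder contracts: relaxed sampling, head selection, determinism."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_linear_head
from ibtreat.errors import InvalidArgumentError, ShapeError
from ibtreat.model import (
    LatentConfig,
    ModelParams,
    decode_outcome,
    decode_treatment,
    encode,
    gumbel_softmax,
)


class TestGumbelSoftmax:
    def test_zero_noise_unit_temperature_recovers_probabilities(self):
        pi = np.array([0.2, 0.3, 0.5])
        w = gumbel_softmax(np.log(pi), temperature=1.0, noise=np.zeros(3))
        np.testing.assert_allclose(w, pi, atol=1e-12)

    def test_low_temperature_converges_to_hard_argmax(self):
        rng = np.random.default_rng(4)
        logits = np.array([0.0, 1.5, -2.0, 3.0])  # gaps >= 1 after noise below
        noise = np.zeros(4)
        w = gumbel_softmax(logits, temperature=1e-4, noise=noise)
        hard = np.eye(4)[np.argmax(logits + noise)]
        assert np.max(np.abs(w - hard)) < 1e-3
        # also with noise: the winner is argmax(logits + g)
        g = -np.log(-np.log(rng.uniform(size=4)))
        w = gumbel_softmax(logits, temperature=1e-4, noise=g)
        assert np.argmax(w) == np.argmax(logits + g)

    @pytest.mark.parametrize("temperature", [0.0, -1.0])
    def test_non_positive_temperature_rejected(self, temperature):
        with pytest.raises(InvalidArgumentError):
            gumbel_softmax(np.zeros(3), temperature, np.zeros(3))

    def test_nan_inputs_rejected(self):
        with pytest.raises(InvalidArgumentError):
            gumbel_softmax(np.array([0.0, np.nan]), 1.0, np.zeros(2))

    @given(
        logits=st.lists(st.floats(-10, 10), min_size=2, max_size=6),
        temperature=st.floats(0.05, 5.0),
        seed=st.integers(0, 1000),
    )
    def test_output_is_on_the_simplex(self, logits, temperature, seed):
        logits = np.array(logits)
        noise = -np.log(-np.log(
            np.random.default_rng(seed).uniform(1e-12, 1.0, size=logits.size)
        ))
        w = gumbel_softmax(logits, temperature, noise)
        assert np.all(w >= 0)
        assert abs(w.sum() - 1.0) < 1e-6


class TestEncode:
    def test_single_category_is_degenerate(self):
        params = ModelParams.init(
            d1=2, d2=2, latent=LatentConfig(k1=1, k2=1, embed_dim=2),
            seed=0, hidden=4, depth=3,
        )
        code = encode(np.array([0.3, -0.4]), 1, params, temperature=0.5,
                      seed=3, hard=True)
        np.testing.assert_allclose(code.probs, [1.0])
        np.testing.assert_allclose(code.hard, [1.0])
        np.testing.assert_allclose(code.z, params.means1.data[0])

    def test_same_seed_same_code(self, small_params, rng):
        x = rng.standard_normal(3)
        a = encode(x, 1, small_params, 0.7, seed=11)
        b = encode(x, 1, small_params, 0.7, seed=11)
        for f in ("probs", "gumbels", "relaxed", "hard", "z"):
            np.testing.assert_array_equal(getattr(a, f), getattr(b, f))

    def test_zeroed_encoder_gives_uniform_posterior(self, small_params, rng):
        for w, b in small_params.encoder1:
            w.data[...] = 0.0
            b.data[...] = 0.0
        for x in rng.standard_normal((5, 3)):
            code = encode(x, 1, small_params, 1.0, seed=0)
            np.testing.assert_allclose(code.probs, np.full(3, 1 / 3), atol=1e-12)

    def test_dimension_mismatch_raises(self, small_params):
        with pytest.raises(ShapeError):
            encode(np.zeros(5), 1, small_params, 1.0)

    def test_simplex_and_one_hot_invariants(self, small_params, rng):
        x = rng.standard_normal((20, 3))
        code = encode(x, 1, small_params, 0.6, seed=2)
        assert np.all(code.probs >= 0) and np.all(code.relaxed >= 0)
        np.testing.assert_allclose(code.probs.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_allclose(code.relaxed.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(code.hard.sum(axis=1) == 1.0)
        assert np.all(np.isfinite(code.z))


class TestDecode:
    def test_head_selection_is_exact(self, small_params, rng):
        z = rng.standard_normal(4)
        treated = decode_outcome(z, 1, small_params)
        control = decode_outcome(z, 0, small_params)
        f2 = small_params.head_treated
        f3 = small_params.head_control
        from ibtreat.model import Tensor, _mlp_forward

        assert treated.mean == pytest.approx(
            _mlp_forward(f2, Tensor(z[None])).data.item(), abs=0
        )
        assert control.mean == pytest.approx(
            _mlp_forward(f3, Tensor(z[None])).data.item(), abs=0
        )

    def test_identical_heads_give_zero_effect(self, small_params, rng):
        small_params.head_control = small_params.head_treated
        for z in rng.standard_normal((10, 4)):
            a = decode_outcome(z, 1, small_params)
            b = decode_outcome(z, 0, small_params)
            assert a.mean == b.mean

    def test_hand_set_linear_heads_match_manual_affine(self, small_params):
        slope = np.array([1.0, -2.0, 0.5, 3.0])
        small_params.head_treated = make_linear_head(slope, 0.25)
        z = np.array([0.1, 0.2, -0.3, 1.0])
        expected = float(slope @ z + 0.25)  # manual matrix arithmetic
        assert decode_outcome(z, 1, small_params).mean == pytest.approx(expected)

    def test_tarnet_difference_identity(self, small_params, rng):
        from ibtreat.model import Tensor, _mlp_forward

        for z in rng.standard_normal((8, 4)):
            diff = (decode_outcome(z, 1, small_params).mean
                    - decode_outcome(z, 0, small_params).mean)
            f2 = _mlp_forward(small_params.head_treated, Tensor(z[None])).data.item()
            f3 = _mlp_forward(small_params.head_control, Tensor(z[None])).data.item()
            assert diff == pytest.approx(f2 - f3, rel=1e-12)

    def test_invalid_treatment_rejected(self, small_params):
        with pytest.raises(InvalidArgumentError):
            decode_outcome(np.zeros(4), 2, small_params)

    def test_bernoulli_family_returns_probability(self):
        params = ModelParams.init(
            d1=2, d2=2, latent=LatentConfig(k1=2, k2=2, embed_dim=2),
            outcome_family="bernoulli", seed=1, hidden=4,
        )
        p = decode_outcome(np.zeros(4), 1, params)
        assert 0.0 < p.mean < 1.0
        assert p.variance == pytest.approx(p.mean * (1 - p.mean))


class TestDecodeTreatment:
    def test_zero_logit_gives_half(self, small_params):
        small_params.head_treatment = make_linear_head(np.zeros(4), 0.0)
        assert decode_treatment(np.ones(4), small_params) == pytest.approx(0.5)

    def test_log_three_gives_three_quarters(self, small_params):
        small_params.head_treatment = make_linear_head(np.zeros(4), np.log(3.0))
        assert decode_treatment(np.ones(4), small_params) == pytest.approx(0.75)

    def test_monotone_in_logit(self, small_params):
        small_params.head_treatment = make_linear_head(
            np.array([1.0, 0, 0, 0]), 0.0
        )
        values = [decode_treatment(np.array([v, 0, 0, 0.0]), small_params)
                  for v in np.linspace(-3, 3, 13)]
        assert np.all(np.diff(values) > 0)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"k1": 0}, {"embed_dim": 0},
        {"temperature_init": 0.5, "temperature_final": 1.0},
        {"temperature_final": 0.0},
    ])
    def test_invalid_latent_config_rejected(self, kwargs):
        with pytest.raises(InvalidArgumentError):
            LatentConfig(**kwargs)

    def test_temperature_schedule_is_geometric_and_clamped(self):
        cfg = LatentConfig(temperature_init=1.0, temperature_final=0.25,
                           anneal_epochs=10)
        assert cfg.temperature_at(0) == pytest.approx(1.0)
        assert cfg.temperature_at(5) == pytest.approx(0.5)
        assert cfg.temperature_at(10) == pytest.approx(0.25)
        assert cfg.temperature_at(99) == pytest.approx(0.25)
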