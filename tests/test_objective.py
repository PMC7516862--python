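"""Compression KL, teacher-forced relevance terms, and the combined loss."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_linear_head
from ibtreat.errors import InfiniteKLError, InvalidArgumentError
from ibtreat.model import LatentConfig, ModelParams
from ibtreat.objective import (
    LOG_2PI,
    branch_posteriors,
    compression_kl,
    ib_loss,
    ib_loss_graph,
    relevance_terms,
)


def simplex_from(values):
    v = np.array(values) + 1e-3
    return v / v.sum()


class TestCompressionKL:
    @pytest.mark.parametrize("p", [
        [0.5, 0.5], [0.2, 0.3, 0.5], [1.0], [0.01, 0.99],
    ])
    def test_zero_iff_posterior_equals_prior(self, p):
        p = np.array(p)
        assert compression_kl(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_point_mass_against_uniform_binary_is_log_two(self):
        assert compression_kl([1.0, 0.0], [0.5, 0.5]) == pytest.approx(np.log(2))

    def test_matches_elementwise_sum_oracle(self):
        q = np.array([0.5, 0.5])
        p = np.array([0.25, 0.75])
        expected = 0.5 * np.log(0.5 / 0.25) + 0.5 * np.log(0.5 / 0.75)
        assert compression_kl(q, p) == pytest.approx(expected, rel=1e-12)

    def test_zero_posterior_entries_contribute_nothing(self):
        assert compression_kl([0.0, 1.0], [0.3, 0.7]) == pytest.approx(-np.log(0.7))

    def test_prior_zero_mass_raises_rather_than_inf(self):
        with pytest.raises(InfiniteKLError):
            compression_kl([0.5, 0.5], [1.0, 0.0])

    def test_non_simplex_rejected(self):
        with pytest.raises(InvalidArgumentError):
            compression_kl([0.5, 0.6], [0.5, 0.5])

    @given(
        q=st.lists(st.floats(0.0, 1.0), min_size=3, max_size=3),
        p=st.lists(st.floats(0.05, 1.0), min_size=3, max_size=3),
    )
    def test_non_negative_for_any_pair(self, q, p):
        assert compression_kl(simplex_from(q), simplex_from(p)) >= -1e-12


class TestRelevanceTerms:
    def test_gaussian_at_its_mean_with_unit_variance(self, small_params, rng):
        small_params.outcome_logvar.data = np.asarray(0.0)
        z = rng.standard_normal((4, 4))
        t = np.array([0, 1, 0, 1])
        from ibtreat.model import decode_outcome

        y = decode_outcome(z, t, small_params).mean
        nll_y, _ = relevance_terms((None, t, y), small_params, z)
        assert nll_y == pytest.approx(0.5 * LOG_2PI, rel=1e-12)

    def test_coin_flip_propensity_costs_log_two(self, small_params, rng):
        small_params.head_treatment = make_linear_head(np.zeros(4), 0.0)
        z = rng.standard_normal((6, 4))
        t = np.array([0, 1, 1, 0, 1, 0])
        _, nll_t = relevance_terms((None, t, np.zeros(6)), small_params, z)
        assert nll_t == pytest.approx(np.log(2), rel=1e-12)

    def test_two_record_batch_matches_manual_log_densities(self, small_params):
        slope2 = np.array([1.0, 0.0, -1.0, 2.0])
        slope3 = np.array([0.5, 0.5, 0.0, 0.0])
        slope1 = np.array([0.0, 1.0, 0.0, -1.0])
        small_params.head_treated = make_linear_head(slope2, 1.0)
        small_params.head_control = make_linear_head(slope3, -0.5)
        small_params.head_treatment = make_linear_head(slope1, 0.2)
        small_params.outcome_logvar.data = np.asarray(np.log(0.8))
        z = np.array([[0.3, -0.2, 0.4, 1.1], [-0.6, 0.9, 0.0, -0.4]])
        t = np.array([1, 0])
        y = np.array([2.0, -1.0])

        mu = np.array([slope2 @ z[0] + 1.0, slope3 @ z[1] - 0.5])
        var = 0.8
        manual_nll_y = np.mean(0.5 * (np.log(2 * np.pi * var) + (y - mu) ** 2 / var))
        logit = z @ slope1 + 0.2
        p = 1 / (1 + np.exp(-logit))
        manual_nll_t = -np.mean(t * np.log(p) + (1 - t) * np.log(1 - p))

        nll_y, nll_t = relevance_terms((None, t, y), small_params, z)
        assert nll_y == pytest.approx(manual_nll_y, rel=1e-10)
        assert nll_t == pytest.approx(manual_nll_t, rel=1e-10)

    def test_empty_batch_rejected(self, small_params):
        with pytest.raises(InvalidArgumentError):
            relevance_terms((None, np.array([]), np.array([])), small_params,
                            np.zeros((0, 4)))


class TestLoss:
    def batch(self, rng, n=6):
        return (rng.standard_normal((n, 3)), rng.standard_normal((n, 2)),
                rng.integers(0, 2, n), rng.standard_normal(n))

    def test_lambda_zero_ignores_relevance(self, small_params, rng):
        x1, x2, t, y = self.batch(rng)
        comps = ib_loss((x1, x2, t, y), small_params, lam=0.0,
                        temperature=0.8, seed=5)
        assert comps.total == pytest.approx(comps.kl_branch1 + comps.kl_branch2)

    def test_zero_logits_make_compression_free(self, small_params, rng):
        for net in (small_params.encoder1, small_params.encoder2):
            for w, b in net:
                w.data[...] = 0.0
                b.data[...] = 0.0
        x1, x2, t, y = self.batch(rng)
        comps = ib_loss((x1, x2, t, y), small_params, lam=2.0,
                        temperature=0.8, seed=5)
        assert comps.kl_branch1 == pytest.approx(0.0, abs=1e-12)
        assert comps.kl_branch2 == pytest.approx(0.0, abs=1e-12)

    def test_bitwise_reproducible(self, small_params, rng):
        batch = self.batch(rng)
        a = ib_loss(batch, small_params, 1.5, 0.7, seed=99)
        b = ib_loss(batch, small_params, 1.5, 0.7, seed=99)
        assert a == b

    def test_negative_lambda_rejected(self, small_params, rng):
        with pytest.raises(InvalidArgumentError):
            ib_loss(self.batch(rng), small_params, -0.1, 0.7, seed=0)

    def test_kl_terms_non_negative_and_total_consistent(self, small_params, rng):
        for seed in range(5):
            comps = ib_loss(self.batch(rng), small_params, 3.0, 0.5, seed=seed)
            assert comps.kl_branch1 >= 0 and comps.kl_branch2 >= 0
            assert comps.total == pytest.approx(
                comps.kl_branch1 + comps.kl_branch2
                + comps.lam * (comps.nll_outcome + comps.nll_treatment)
            )

    @pytest.mark.parametrize("family", ["gaussian", "bernoulli"])
    def test_gradients_match_finite_differences(self, family, rng):
        params = ModelParams.init(
            d1=3, d2=2, latent=LatentConfig(k1=3, k2=2, embed_dim=2),
            outcome_family=family, seed=5, hidden=6, depth=3,
        )
        x1 = rng.standard_normal((2, 3))
        x2 = rng.standard_normal((2, 2))
        t = np.array([0, 1])
        y = np.array([0.0, 1.0]) if family == "bernoulli" else np.array([0.3, -1.2])

        def loss_value():
            total, _ = ib_loss_graph(params, x1, x2, t, y, 2.5, 0.7, seed=42)
            return float(total.data)

        total, _ = ib_loss_graph(params, x1, x2, t, y, 2.5, 0.7, seed=42)
        for p in params.tensors():
            p.zero_grad()
        total.backward()
        check_rng = np.random.default_rng(0)
        for p in params.tensors():
            grad = p.grad if p.grad is not None else np.zeros_like(p.data)
            flat = p.data.ravel()
            for i in check_rng.choice(flat.size, size=min(4, flat.size),
                                      replace=False):
                h = 1e-5 * max(1.0, abs(flat[i]))
                old = flat[i]
                flat[i] = old + h
                up = loss_value()
                flat[i] = old - h
                down = loss_value()
                flat[i] = old
                fd = (up - down) / (2 * h)
                ga = grad.ravel()[i]
                assert abs(fd - ga) <= 1e-4 * max(1e-6, abs(fd), abs(ga))

    def test_branch_posteriors_rows_are_simplexes(self, small_params, rng):
        probs = branch_posteriors(small_params, 1, rng.standard_normal((7, 3)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(probs > 0)
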