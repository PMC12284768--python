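import numpy as np
import pytest

from scgraphclust import (
    GANConfig,
    discriminator_loss,
    generator_loss,
    relabel_all,
    train_gan,
)
from scgraphclust.adversarial_refine import (
    Discriminator,
    DiscriminatorOutput,
    Generator,
    RefinedAssignment,
    TrainedDiscriminator,
    _MinMaxScaler,
    discriminator_forward,
    generator_forward,
    scheduled_lr,
)
from scgraphclust.confidence import ConfidenceSet
from scgraphclust.metrics import adjusted_rand_index


def blob_confidence_set(rng, d=6, per_class=30, K=3, spread=0.5):
    centers = rng.standard_normal((K, d)) * 5
    x = np.vstack([centers[c] + spread * rng.standard_normal((per_class, d)) for c in range(K)])
    y = np.repeat(np.arange(K), per_class)
    return ConfidenceSet(indices=np.arange(K * per_class), x_real=x, y_real=y, fraction=0.3)


class TestGenerator:
    def test_hidden_layers_have_specified_widths(self, rng):
        gen = Generator(8, 8, GANConfig(seed=0), rng)
        assert gen.hidden_widths == (1024, 512, 256, 8)

    def test_output_bounded_for_extreme_inputs(self, rng):
        gen = Generator(4, 4, GANConfig(seed=0), rng)
        out = generator_forward(np.full(4, 1e6), np.full(4, -1e6), gen)
        assert np.all(out >= -1.0) and np.all(out <= 1.0)

    def test_deterministic_given_fixed_inputs(self, rng):
        gen = Generator(3, 3, GANConfig(seed=1), np.random.default_rng(1))
        x, z = rng.standard_normal(3), np.zeros(3)
        np.testing.assert_array_equal(
            generator_forward(x, z, gen), generator_forward(x, z, gen)
        )

    def test_rejects_non_finite_input(self, rng):
        gen = Generator(3, 3, GANConfig(seed=0), rng)
        with pytest.raises(ValueError):
            generator_forward(np.array([np.nan, 0, 0]), np.zeros(3), gen)


class TestDiscriminator:
    def test_zero_input_zero_bias_gives_half_probability(self):
        disc = Discriminator(4, 3, GANConfig(seed=0), np.random.default_rng(0))
        out = discriminator_forward(np.zeros(4), disc)
        # zero input through bias-zero affine layers stays zero; σ(0)=0.5
        np.testing.assert_allclose(out.adv_prob, 0.5)

    def test_class_posterior_sums_to_one(self, rng):
        from scipy.special import softmax

        disc = Discriminator(5, 4, GANConfig(seed=2), rng)
        out = discriminator_forward(rng.standard_normal((6, 5)), disc)
        np.testing.assert_allclose(softmax(out.class_logits, axis=1).sum(axis=1), 1.0, atol=1e-9)

    def test_batch_equals_per_row_calls(self, rng):
        disc = Discriminator(5, 3, GANConfig(seed=3), rng)
        x = rng.standard_normal((5, 5))
        batch = discriminator_forward(x, disc)
        for i in range(5):
            single = discriminator_forward(x[i], disc)
            np.testing.assert_allclose(single.adv_prob[0], batch.adv_prob[i], atol=1e-12)
            np.testing.assert_allclose(single.class_logits[0], batch.class_logits[i], atol=1e-12)


class TestLosses:
    def test_perfect_discriminator_limit(self):
        K = 2
        real = DiscriminatorOutput(np.array([1 - 1e-12]), np.array([[60.0, -60.0]]))
        fake = DiscriminatorOutput(np.array([1e-12]), np.array([[0.0, 0.0]]))
        assert discriminator_loss(real, fake, np.array([0])) < 1e-9

    def test_uniform_posterior_worked_value_discriminator(self):
        # adv 0.5 on both sides and a uniform 2-class posterior: 2·ln2 + ln2
        real = DiscriminatorOutput(np.array([0.5, 0.5]), np.zeros((2, 2)))
        fake = DiscriminatorOutput(np.array([0.5, 0.5]), np.zeros((2, 2)))
        got = discriminator_loss(real, fake, np.array([0, 1]))
        np.testing.assert_allclose(got, 3 * np.log(2), atol=1e-12)

    def test_uniform_posterior_worked_value_generator(self):
        # fooled at 0.5 with uniform 4-class posterior: ln2 + ln4
        fake = DiscriminatorOutput(np.array([0.5]), np.zeros((1, 4)))
        np.testing.assert_allclose(
            generator_loss(fake, np.array([2])), np.log(2) + np.log(4), atol=1e-12
        )

    def test_fully_fooled_generator_limit(self):
        fake = DiscriminatorOutput(np.array([1 - 1e-12]), np.array([[80.0, -80.0, -80.0]]))
        assert generator_loss(fake, np.array([0])) < 1e-9

    @pytest.mark.parametrize("batch_size", [1, 5, 16])
    def test_matches_scalar_loop_oracle(self, rng, batch_size):
        K = 3
        p_r = rng.uniform(0.05, 0.95, batch_size)
        p_f = rng.uniform(0.05, 0.95, batch_size)
        logits_r = rng.standard_normal((batch_size, K))
        logits_f = rng.standard_normal((batch_size, K))
        y = rng.integers(0, K, batch_size)

        def ce_scalar(logits, label):
            exps = [np.exp(v) for v in logits]
            return -np.log(exps[label] / sum(exps))

        d_ref = (
            -sum(np.log(p) for p in p_r) / batch_size
            - sum(np.log(1 - p) for p in p_f) / batch_size
            + sum(ce_scalar(logits_r[i], y[i]) for i in range(batch_size)) / batch_size
        )
        g_ref = (
            -sum(np.log(p) for p in p_f) / batch_size
            + sum(ce_scalar(logits_f[i], y[i]) for i in range(batch_size)) / batch_size
        )
        d_got = discriminator_loss(
            DiscriminatorOutput(p_r, logits_r), DiscriminatorOutput(p_f, logits_f), y
        )
        g_got = generator_loss(DiscriminatorOutput(p_f, logits_f), y)
        np.testing.assert_allclose(d_got, d_ref, atol=1e-8)
        np.testing.assert_allclose(g_got, g_ref, atol=1e-8)

    def test_invalid_label_rejected(self):
        real = DiscriminatorOutput(np.array([0.5]), np.zeros((1, 2)))
        fake = DiscriminatorOutput(np.array([0.5]), np.zeros((1, 2)))
        with pytest.raises(ValueError):
            discriminator_loss(real, fake, np.array([5]))


class TestScheduler:
    def test_halves_every_five_epochs(self):
        assert scheduled_lr(2e-4, 10, 5) == pytest.approx(5e-5)
        assert scheduled_lr(2e-4, 4, 5) == pytest.approx(2e-4)

    def test_non_increasing_and_exact_halving_points(self):
        lrs = [scheduled_lr(1e-3, e, 5) for e in range(30)]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))
        for e in range(1, 6):
            assert lrs[5 * e] == pytest.approx(lrs[5 * e - 1] / 2)


class TestTrainGan:
    def test_missing_class_rejected(self, rng):
        conf = blob_confidence_set(rng, K=2)
        with pytest.raises(ValueError, match="classes \\[2\\]"):
            train_gan(conf, 3, GANConfig(seed=0, epochs=1))

    def test_seeded_runs_reproduce_traces(self, rng):
        conf = blob_confidence_set(rng)
        cfg = GANConfig(seed=4, epochs=5)
        _, _, t1 = train_gan(conf, 3, cfg)
        _, _, t2 = train_gan(conf, 3, cfg)
        np.testing.assert_allclose(t1["d_loss"], t2["d_loss"], atol=1e-6)
        np.testing.assert_allclose(t1["g_loss"], t2["g_loss"], atol=1e-6)

    def test_classification_improves_on_separable_blobs(self, rng):
        conf = blob_confidence_set(rng)
        _, _, traces = train_gan(conf, 3, GANConfig(seed=0, epochs=50))
        assert traces["real_ce"][-1] < traces["real_ce"][0]
        assert traces["real_ce"][-1] < 0.3

    def test_trace_lengths_match_epochs(self, rng):
        conf = blob_confidence_set(rng, per_class=10)
        _, _, traces = train_gan(conf, 3, GANConfig(seed=0, epochs=7))
        assert all(len(v) == 7 for v in traces.values())


class TestRelabel:
    def test_one_hot_logits_pick_that_class(self, rng):
        probs = np.array([[0.1, 0.8, 0.1], [0.7, 0.2, 0.1]])
        r = RefinedAssignment(labels=np.array([1, 0]), class_probabilities=probs)
        assert r.labels.tolist() == [1, 0]

    def test_exact_tie_resolves_to_lower_class(self):
        probs = np.array([[0.5, 0.5]])
        r = RefinedAssignment(labels=np.array([0]), class_probabilities=probs)
        assert r.labels[0] == 0
        with pytest.raises(ValueError):
            RefinedAssignment(labels=np.array([1]), class_probabilities=probs)

    def test_refinement_preserves_separable_structure(self, rng):
        conf = blob_confidence_set(rng, per_class=40, spread=0.3)
        trained, _, _ = train_gan(conf, 3, GANConfig(seed=0, epochs=40))
        refined = relabel_all(conf.x_real, trained)
        assert adjusted_rand_index(conf.y_real, refined.labels) >= 0.98

    def test_wrong_k_rejected(self, rng):
        conf = blob_confidence_set(rng, per_class=10)
        trained, _, _ = train_gan(conf, 3, GANConfig(seed=0, epochs=2))
        with pytest.raises(ValueError):
            relabel_all(conf.x_real, trained, K=4)


class TestScaler:
    def test_maps_to_unit_interval_and_zeroes_flat_dims(self, rng):
        x = rng.standard_normal((20, 3))
        x[:, 2] = 7.0
        s = _MinMaxScaler(x)
        y = s.transform(x)
        assert y[:, :2].min() == pytest.approx(-1.0)
        assert y[:, :2].max() == pytest.approx(1.0)
        np.testing.assert_array_equal(y[:, 2], 0.0)
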