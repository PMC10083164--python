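"""Adversarial and patchwise contrastive losses against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from octpt.cutgan import (adversarial_loss, generator_gan_loss, nce_term,
                          patchwise_nce_loss, sample_patch_features,
                          PatchFeatureSet, LayerPatchFeatures, DomainError,
                          ResnetGenerator, ProjectionHeads)


# --------------------------------------------------------------------------
# independent oracles: direct summation, no log-sum-exp tricks
# --------------------------------------------------------------------------

def adversarial_oracle(d_real, d_fake):
    total = sum(np.log(v) for v in d_real) / len(d_real)
    total += sum(np.log(1.0 - v) for v in d_fake) / len(d_fake)
    return total


def nce_oracle(q, q_plus, q_minus, tau):
    num = np.exp(np.dot(q, q_plus) / tau)
    den = num + sum(np.exp(np.dot(q, qn) / tau) for qn in q_minus)
    return -np.log(num / den)


def unit_vectors(rng, n, d):
    v = rng.normal(size=(n, d))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


class TestAdversarialLoss:
    def test_half_scores(self):
        v = adversarial_loss(np.full(4, 0.5), np.full(4, 0.5))
        assert v == pytest.approx(-2 * np.log(2), abs=1e-12)

    def test_perfect_discrimination_limit(self):
        prev = None
        for eps in (1e-2, 1e-4, 1e-6):
            v = adversarial_loss(np.array([1 - eps]), np.array([eps]))
            assert v < 0
            if prev is not None:
                assert v > prev  # approaches the supremum 0 from below
            prev = v
        assert abs(prev) < 1e-5

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            d_real = rng.uniform(0.01, 0.99, rng.integers(1, 9))
            d_fake = rng.uniform(0.01, 0.99, rng.integers(1, 9))
            got = adversarial_loss(d_real, d_fake)
            assert got == pytest.approx(adversarial_oracle(d_real, d_fake),
                                        abs=1e-6)

    def test_vanilla_domain_error(self):
        with pytest.raises(DomainError):
            adversarial_loss(np.array([1.0]), np.array([0.5]))
        with pytest.raises(DomainError):
            generator_gan_loss(np.array([0.0]))

    def test_least_squares_mode(self):
        v = adversarial_loss(np.array([1.0]), np.array([0.0]),
                             mode="least_squares")
        assert v == pytest.approx(0.0)
        assert generator_gan_loss(np.array([1.0]), mode="least_squares") == 0.0


class TestNCETerm:
    def test_uniform_similarity_n1(self):
        z = np.zeros(8)
        assert nce_term(z, z, z[None, :]) == pytest.approx(np.log(2), abs=1e-12)

    def test_uniform_similarity_n255(self):
        z = np.zeros(8)
        negs = np.zeros((255, 8))
        assert nce_term(z, z, negs) == pytest.approx(np.log(256), abs=1e-12)

    def test_matches_naive_evaluation(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            d = rng.integers(2, 6)
            q = unit_vectors(rng, 1, d)[0]
            qp = unit_vectors(rng, 1, d)[0]
            qm = unit_vectors(rng, 4, d)
            tau = rng.uniform(0.05, 1.0)
            assert nce_term(q, qp, qm, tau) == pytest.approx(
                nce_oracle(q, qp, qm, tau), abs=1e-6)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            nce_term(np.zeros(3), np.zeros(4), np.zeros((2, 3)))

    def test_tau_must_be_positive(self):
        with pytest.raises(DomainError):
            nce_term(np.zeros(3), np.zeros(3), np.zeros((1, 3)), tau=0.0)

    @given(st.floats(-0.95, 0.95), st.floats(-0.95, 0.95))
    def test_nonnegative_and_monotone(self, sim_pos, sim_neg):
        """l >= 0 and l strictly decreases as the positive similarity grows
        with negatives fixed."""
        d = 2
        q = np.array([1.0, 0.0])

        def term(sp):
            qp = np.array([sp, np.sqrt(1 - sp ** 2)])
            qm = np.array([[sim_neg, np.sqrt(1 - sim_neg ** 2)]])
            return nce_term(q, qp, qm)

        assert term(sim_pos) >= 0.0
        assert term(min(sim_pos + 0.02, 0.99)) < term(sim_pos)

    def test_monotone_on_grid(self):
        grid = np.linspace(-0.9, 0.9, 19)
        q = np.array([1.0, 0.0])
        qm = unit_vectors(np.random.default_rng(0), 5, 2)
        vals = [nce_term(q, np.array([s, np.sqrt(1 - s * s)]), qm)
                for s in grid]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert all(v >= 0 for v in vals)


class TestPatchwiseNCELoss:
    def random_pfs(self, rng, n_layers=3, s=6, d=4, tau=0.07):
        layers = []
        for li in range(n_layers):
            layers.append(LayerPatchFeatures(
                layer_index=li,
                queries=unit_vectors(rng, s, d),
                positives=unit_vectors(rng, s, d),
                locations=np.arange(s)))
        return PatchFeatureSet(tuple(layers), tau=tau)

    def test_uniform_similarities_give_log2(self):
        # single layer, two locations, all-zero embeddings: uniform softmax
        layer = LayerPatchFeatures(0, np.zeros((2, 4)), np.zeros((2, 4)),
                                   np.arange(2))
        got = patchwise_nce_loss(PatchFeatureSet((layer,)))
        assert got == pytest.approx(np.log(2), abs=1e-12)

    def test_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            pfs = self.random_pfs(rng, n_layers=int(rng.integers(1, 4)),
                                  s=int(rng.integers(2, 7)))
            oracle = np.mean([
                nce_oracle(lf.queries[s], lf.positives[s], lf.negatives_for(s),
                           pfs.tau)
                for lf in pfs.layers for s in range(len(lf.queries))])
            assert patchwise_nce_loss(pfs) == pytest.approx(oracle, abs=1e-6)

    def test_layer_duplication_invariance(self):
        rng = np.random.default_rng(13)
        pfs = self.random_pfs(rng)
        doubled = PatchFeatureSet(pfs.layers + pfs.layers, tau=pfs.tau)
        assert patchwise_nce_loss(doubled) == pytest.approx(
            patchwise_nce_loss(pfs), rel=1e-12)

    def test_empty_layers_rejected(self):
        with pytest.raises(ValueError):
            patchwise_nce_loss(PatchFeatureSet(()))


@pytest.fixture(scope="module")
def small_net():
    rng = np.random.default_rng(3)
    gen = ResnetGenerator(base_width=4, n_res_blocks=1, stem_kernel=3,
                          rng=rng)
    heads = ProjectionHeads(gen, (0, 4, 8), embed_dim=8, rng=rng)
    return gen, heads


class TestSamplePatchFeatures:
    def test_counts_norms_and_negatives(self, small_net):
        gen, heads = small_net
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 1, (16, 16))
        xh = rng.uniform(0, 1, (16, 16))
        pfs = sample_patch_features(x, xh, gen, heads, (0, 4, 8), 16, seed=0)
        assert len(pfs.layers) == 3
        for lf in pfs.layers:
            assert lf.queries.shape == lf.positives.shape == (16, 8)
            assert lf.negatives_for(0).shape == (15, 8)
            np.testing.assert_allclose(
                np.linalg.norm(lf.queries, axis=1), 1.0, atol=1e-6)
            np.testing.assert_allclose(
                np.linalg.norm(lf.positives, axis=1), 1.0, atol=1e-6)

    def test_seed_reproduces_locations(self, small_net):
        gen, heads = small_net
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 1, (16, 16))
        xh = rng.uniform(0, 1, (16, 16))
        a = sample_patch_features(x, xh, gen, heads, (0, 4), 8, seed=9)
        b = sample_patch_features(x, xh, gen, heads, (0, 4), 8, seed=9)
        for la, lb in zip(a.layers, b.layers):
            np.testing.assert_array_equal(la.locations, lb.locations)
            np.testing.assert_array_equal(la.queries, lb.queries)

    def test_too_many_patches_rejected(self, small_net):
        gen, heads = small_net
        x = np.zeros((16, 16))
        with pytest.raises(ValueError, match="locations"):
            sample_patch_features(x, x, gen, heads, (8,), 1000, seed=0)
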