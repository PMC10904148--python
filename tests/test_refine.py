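import math

import numpy as np
import pytest

from graphannot import (
    RefinementConfig,
    denoised_gcn_layer,
    knn_pseudo_labels,
    refine_features,
    supcon_loss,
)
from graphannot.errors import ParameterError
from graphannot.refine import _batch_loss_and_phi_grad


def supcon_bruteforce(Z, codes, tau):
    """Independent enumeration of every (anchor, positive, negative) term."""
    total = 0.0
    n = Z.shape[0]
    valid = [np.linalg.norm(Z[i]) > 0 for i in range(n)]
    for i in range(n):
        if not valid[i]:
            continue
        pos = [j for j in range(n) if j != i and valid[j] and codes[j] == codes[i]]
        neg = [k for k in range(n) if valid[k] and codes[k] != codes[i]]
        if not pos:
            continue
        for j in pos:
            num = math.exp(float(Z[i] @ Z[j]) / tau)
            den = num + sum(math.exp(float(Z[i] @ Z[k]) / tau) for k in neg)
            total += -math.log(num / den) / len(pos)
    return total


def _unit_rows(rng, n, d):
    Z = rng.normal(size=(n, d))
    return Z / np.linalg.norm(Z, axis=1, keepdims=True)


class TestSupConLoss:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        Z = _unit_rows(rng, n, 5)
        codes = rng.integers(0, 3, size=n)
        expected = supcon_bruteforce(Z, codes, tau=0.5)
        assert supcon_loss(Z, codes, tau=0.5) == pytest.approx(expected, abs=1e-10)

    def test_no_negative_anchor_contributes_zero(self):
        rng = np.random.default_rng(1)
        Z = _unit_rows(rng, 3, 4)
        assert supcon_loss(Z, np.zeros(3, dtype=int), tau=0.5) == pytest.approx(0.0)

    def test_equal_similarity_single_positive_three_negatives_gives_log4(self):
        # all pairwise dot products equal (identical unit rows); labels A,A,B,C,D:
        # each of the two A-anchors has |P|=1, |M|=3 and contributes log 4
        Z = np.tile(np.array([[1.0, 0.0]]), (5, 1))
        codes = np.array([0, 0, 1, 2, 3])
        loss = supcon_loss(Z, codes, tau=0.5)
        assert loss == pytest.approx(2.0 * math.log(4.0), abs=1e-12)
        assert loss / 2.0 == pytest.approx(math.log(4.0))

    @pytest.mark.parametrize("seed", range(5))
    def test_loss_non_negative(self, seed):
        rng = np.random.default_rng(seed + 100)
        Z = _unit_rows(rng, 7, 3)
        codes = rng.integers(0, 2, size=7)
        assert supcon_loss(Z, codes, tau=0.5) >= 0.0

    def test_tiny_batch_rejected(self):
        with pytest.raises(ParameterError):
            supcon_loss(np.array([[1.0, 0.0]]), np.array([0]), tau=0.5)

    def test_zero_rows_excluded_from_all_roles(self):
        rng = np.random.default_rng(2)
        Z = _unit_rows(rng, 4, 3)
        Zz = np.vstack([Z, np.zeros((1, 3))])
        codes = np.array([0, 0, 1, 1, 0])
        assert supcon_loss(Zz, codes, tau=0.5) == pytest.approx(
            supcon_bruteforce(Z, codes[:4], 0.5), abs=1e-10
        )


class TestGcnLayer:
    def test_identity_propagation_identity_weights(self):
        X = np.abs(np.random.default_rng(0).normal(size=(4, 3)))
        out = denoised_gcn_layer(np.eye(4), X, np.eye(3))
        np.testing.assert_allclose(out, X)

    def test_zero_input_gives_zero(self):
        out = denoised_gcn_layer(np.eye(3), np.zeros((3, 2)), np.ones((2, 2)))
        np.testing.assert_array_equal(out, np.zeros((3, 2)))

    def test_two_by_two_hand_instance(self):
        S = np.array([[0.75, 0.25], [0.25, 0.75]])
        X = np.array([[1.0, 0.0], [0.0, 2.0]])
        Phi = np.array([[1.0, -1.0], [0.5, 1.0]])
        # S X = [[.75, .5], [.25, 1.5]]; S X Phi = [[1.0, -0.25], [1.0, 1.25]]
        expected = np.array([[1.0, 0.0], [1.0, 1.25]])
        np.testing.assert_allclose(denoised_gcn_layer(S, X, Phi), expected)


class TestPhiGradient:
    @pytest.mark.parametrize("seed", range(3))
    def test_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        b, n = 6, 4
        Mb = rng.normal(size=(b, n))
        Phi = rng.normal(size=(n, n)) * 0.5
        codes = rng.integers(0, 2, size=b)

        loss, grad = _batch_loss_and_phi_grad(Mb, Phi, codes, tau=0.5)

        def loss_at(P):
            return _batch_loss_and_phi_grad(Mb, P, codes, tau=0.5)[0]

        eps = 1e-6
        numeric = np.zeros_like(Phi)
        for i in range(n):
            for j in range(n):
                Pp, Pm = Phi.copy(), Phi.copy()
                Pp[i, j] += eps
                Pm[i, j] -= eps
                numeric[i, j] = (loss_at(Pp) - loss_at(Pm)) / (2 * eps)
        np.testing.assert_allclose(grad, numeric, atol=1e-5)


class TestRefineFeatures:
    def test_shape_preserved_and_non_negative(self, tiny_chain):
        X, truth, split = tiny_chain["X"], tiny_chain["truth"], tiny_chain["split"]
        pseudo = knn_pseudo_labels(
            tiny_chain["denoised"], truth.subset_labels(split.train), k=1
        )
        cfg = RefinementConfig(epochs=2, batch_size=20, seed=0)
        out = refine_features(tiny_chain["denoised"], X, pseudo, cfg)
        assert out.values.shape == X.values.shape
        assert np.all(out.values >= 0)
        norms = np.linalg.norm(out.normalized, axis=1)
        nz = norms > 0
        np.testing.assert_allclose(norms[nz], 1.0, atol=1e-6)

    def test_seeded_determinism(self, tiny_chain):
        X, truth, split = tiny_chain["X"], tiny_chain["truth"], tiny_chain["split"]
        pseudo = knn_pseudo_labels(
            tiny_chain["denoised"], truth.subset_labels(split.train), k=1
        )
        cfg = RefinementConfig(epochs=2, batch_size=20, seed=5)
        a = refine_features(tiny_chain["denoised"], X, pseudo, cfg)
        b = refine_features(tiny_chain["denoised"], X, pseudo, cfg)
        np.testing.assert_array_equal(a.projection, b.projection)

    def test_epochs_zero_returns_initial_projection(self, tiny_chain):
        X, truth, split = tiny_chain["X"], tiny_chain["truth"], tiny_chain["split"]
        pseudo = knn_pseudo_labels(
            tiny_chain["denoised"], truth.subset_labels(split.train), k=1
        )
        cfg = RefinementConfig(epochs=0, seed=3)
        out = refine_features(tiny_chain["denoised"], X, pseudo, cfg)
        rng = np.random.default_rng(3)
        bound = 1.0 / np.sqrt(X.n_genes)
        Phi0 = rng.uniform(-bound, bound, size=(X.n_genes, X.n_genes))
        np.testing.assert_array_equal(out.projection, Phi0)

    def test_training_tightens_within_type_cosine(self, tiny_chain):
        """Separation improvement on easy data, measured across 5 seeds."""
        X, truth = tiny_chain["X"], tiny_chain["truth"]
        denoised = tiny_chain["denoised"]
        pseudo = knn_pseudo_labels(
            denoised, truth.subset_labels(tiny_chain["split"].train), k=1
        )

        def margin(normalized):
            G = normalized @ normalized.T
            codes = truth.codes
            within, between = [], []
            for t in np.unique(codes):
                mask = codes == t
                within.append(G[np.ix_(mask, mask)].mean())
                between.append(G[np.ix_(mask, ~mask)].mean())
            return float(np.mean(within) - np.mean(between))

        improved = 0
        for seed in range(5):
            before = refine_features(
                denoised, X, pseudo, RefinementConfig(epochs=0, seed=seed)
            )
            after = refine_features(
                denoised, X, pseudo,
                RefinementConfig(epochs=10, batch_size=20, seed=seed),
            )
            if margin(after.normalized) > margin(before.normalized):
                improved += 1
        assert improved >= 4
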