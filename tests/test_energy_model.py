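"""Graph building, radial basis, network invariances, Siamese delta."""

import numpy as np
import pytest

from tautrank.chem import Conformer3D
from tautrank.nn.autodiff import Tensor
from tautrank.nn.model import (
    EnergyTriple,
    GraphBatch,
    ModelConfig,
    RBFConfig,
    build_graph,
    forward,
    forward_batch,
    init_params,
    predict_pair_delta,
    rbf_expand,
)


class TestBuildGraph:
    def test_two_atoms_within_cutoff(self):
        g = build_graph(Conformer3D([[0, 0, 0], [5, 0, 0]]), atomic_numbers=[6, 8])
        assert len(g.distances) == 2  # both directed edges
        assert np.allclose(g.distances, 5.0)

    def test_two_atoms_beyond_cutoff(self):
        g = build_graph(Conformer3D([[0, 0, 0], [12, 0, 0]]), atomic_numbers=[6, 8])
        assert len(g.distances) == 0

    def test_equilateral_triangle(self):
        s = 4.0
        coords = [[0, 0, 0], [s, 0, 0], [s / 2, s * np.sqrt(3) / 2, 0]]
        g = build_graph(Conformer3D(coords), atomic_numbers=[6, 6, 6])
        assert len(g.distances) == 6
        assert np.allclose(g.distances, 4.0)

    def test_coincident_atoms_rejected(self):
        with pytest.raises(ValueError, match="zero distance"):
            build_graph(Conformer3D([[0, 0, 0], [0, 0, 0]]), atomic_numbers=[6, 6])


class TestRBF:
    def test_vanishes_at_cutoff(self):
        cfg = RBFConfig(n_basis=16, cutoff=10.0)
        assert np.abs(rbf_expand([10.0], cfg)).max() < 1e-12

    def test_length_and_bounds(self):
        cfg = RBFConfig(n_basis=16)
        for r in [0.5, 2.0, 9.9]:
            v = rbf_expand([r], cfg)[0]
            assert v.shape == (16,)
            assert (v >= 0).all() and (v <= 1).all()

    def test_pure_function(self):
        cfg = RBFConfig(n_basis=8)
        assert np.array_equal(rbf_expand([2.0], cfg), rbf_expand([2.0], cfg))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            rbf_expand([0.0], RBFConfig())


class TestForwardInvariances:
    TOL = 1e-6  # kcal/mol

    def test_permutation_invariance(self, small_model_config, small_params, random_graph_factory):
        g, coords, z = random_graph_factory(n_atoms=6, seed=1)
        base = forward(small_params, g, small_model_config).as_array()
        rng = np.random.default_rng(2)
        for _ in range(3):
            perm = rng.permutation(len(z))
            gp = build_graph(Conformer3D(coords[perm]), atomic_numbers=z[perm])
            out = forward(small_params, gp, small_model_config).as_array()
            assert np.abs(out - base).max() < self.TOL

    def test_rigid_motion_invariance(self, small_model_config, small_params, random_graph_factory):
        g, coords, z = random_graph_factory(n_atoms=6, seed=3)
        base = forward(small_params, g, small_model_config).as_array()
        theta = 1.1
        rot = np.array(
            [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
        )
        moved = coords @ rot.T + np.array([3.0, -7.0, 2.0])
        out = forward(
            small_params, build_graph(Conformer3D(moved), atomic_numbers=z), small_model_config
        ).as_array()
        assert np.abs(out - base).max() < self.TOL

    def test_extensivity_on_disjoint_union(self, small_model_config, small_params, random_graph_factory):
        ga, ca, za = random_graph_factory(n_atoms=4, seed=4)
        gb, cb, zb = random_graph_factory(n_atoms=5, seed=5)
        union = build_graph(
            Conformer3D(np.vstack([ca, cb + 100.0])),
            atomic_numbers=np.concatenate([za, zb]),
        )
        ea = forward(small_params, ga, small_model_config).as_array()
        eb = forward(small_params, gb, small_model_config).as_array()
        eu = forward(small_params, union, small_model_config).as_array()
        assert np.abs(eu - (ea + eb)).max() < self.TOL

    def test_unknown_element_rejected(self, small_model_config, small_params):
        g = build_graph(Conformer3D([[0, 0, 0], [1.5, 0, 0]]), atomic_numbers=[6, 14])
        with pytest.raises(ValueError, match="embedding"):
            forward(small_params, g, small_model_config)


class TestSiameseDelta:
    def test_self_delta_exactly_zero(self, small_model_config, small_params, random_graph_factory):
        g, *_ = random_graph_factory(n_atoms=5, seed=6)
        assert predict_pair_delta(g, g, small_params, small_model_config) == 0.0

    def test_antisymmetry_exact(self, small_model_config, small_params, random_graph_factory):
        ga, *_ = random_graph_factory(n_atoms=5, seed=7)
        gb, *_ = random_graph_factory(n_atoms=6, seed=8)
        ab = predict_pair_delta(ga, gb, small_params, small_model_config)
        ba = predict_pair_delta(gb, ga, small_params, small_model_config)
        assert ab == -ba

    def test_consistency_with_forward(self, small_model_config, small_params, random_graph_factory):
        ga, *_ = random_graph_factory(n_atoms=5, seed=9)
        gb, *_ = random_graph_factory(n_atoms=4, seed=10)
        delta = predict_pair_delta(ga, gb, small_params, small_model_config)
        ea = forward(small_params, ga, small_model_config).E_water
        eb = forward(small_params, gb, small_model_config).E_water
        assert delta == pytest.approx(eb - ea, abs=1e-9)


class TestGradients:
    def test_parameter_gradients_match_finite_differences(
        self, small_model_config, small_params, random_graph_factory
    ):
        """Analytic loss gradients vs central differences on a 3-atom fixture."""
        g, *_ = random_graph_factory(n_atoms=3, seed=11)
        target = np.array([[1.0, -2.0, 0.5]])

        def loss_value():
            from tautrank.training import pretrain_loss

            out = forward_batch(small_params, GraphBatch.from_graphs([g]), small_model_config)
            return pretrain_loss(out, target)

        loss = loss_value()
        loss.backward()
        eps = 1e-5
        for name in ["embed", "int0.Wg", "int0.Wm", "int1.Ws", "int0.gate", "out.W", "out.res0.W1"]:
            p = small_params[name]
            idx = tuple(np.unravel_index(np.argmax(np.abs(p.grad)), p.shape))
            analytic = p.grad[idx]
            p.data[idx] += eps
            up = float(loss_value().data)
            p.data[idx] -= 2 * eps
            down = float(loss_value().data)
            p.data[idx] += eps
            fd = (up - down) / (2 * eps)
            assert analytic == pytest.approx(fd, rel=1e-4), name
            for q in small_params.values():
                q.zero_grad()
            loss_value().backward()


class TestEnergyTriple:
    def test_roundtrip(self):
        t = EnergyTriple(1.0, 2.0, 1.0)
        assert EnergyTriple.from_array(t.as_array()) == t

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            EnergyTriple.from_array([np.nan, 0, 0])


def test_model_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(n_interaction=0)
    with pytest.raises(ValueError):
        ModelConfig(n_heads=2)


def test_checkpoint_roundtrip(tmp_path, small_model_config, small_params, random_graph_factory):
    from tautrank.nn.model import load_checkpoint, save_checkpoint

    g, *_ = random_graph_factory(n_atoms=4, seed=12)
    before = forward(small_params, g, small_model_config).as_array()
    path = tmp_path / "model.npz"
    shifts = np.arange(len(small_model_config.elements) * 3, dtype=float).reshape(-1, 3)
    save_checkpoint(path, small_params, small_model_config, shifts, {"seed": 1})
    params2, cfg2, shifts2, prov = load_checkpoint(path)
    after = forward(params2, g, cfg2).as_array()
    assert np.array_equal(before, after)
    assert np.array_equal(shifts, shifts2)
    assert prov["seed"] == 1
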