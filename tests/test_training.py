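"""Losses against brute-force oracles, the optimizer, and training loops."""

import numpy as np
import pytest

from tautrank.nn.autodiff import Tensor, parameter
from tautrank.training import (
    EmaAmsGrad,
    FinetuneConfig,
    PairRecord,
    PretrainConfig,
    SplitPlan,
    finetune_loss,
    pretrain_loss,
)


def brute_pretrain_loss(pred, target):
    """Independent evaluation: per-head L1 means, summed, with plain loops."""
    pred, target = np.asarray(pred), np.asarray(target)
    total = 0.0
    for head in range(3):
        s = 0.0
        for i in range(len(pred)):
            s += abs(pred[i, head] - target[i, head])
        total += s / len(pred)
    return total


def brute_finetune_loss(dg_pred, dg_exp, gas_pred, gas_target, alpha, beta):
    s = sum(abs(p - e) for p, e in zip(dg_pred, dg_exp)) / len(dg_pred)
    out = alpha * s
    if gas_pred is not None:
        g = sum(abs(p - t) for p, t in zip(gas_pred, gas_target)) / len(gas_pred)
        out += beta * g
    return out


class TestPretrainLoss:
    def test_perfect_zero(self):
        y = np.random.default_rng(0).normal(size=(4, 3))
        assert float(pretrain_loss(y, y).data) == 0.0

    def test_unit_error_everywhere_gives_three(self):
        y = np.zeros((5, 3))
        assert float(pretrain_loss(y + 1.0, y).data) == pytest.approx(3.0)

    def test_single_head_error(self):
        y = np.zeros((4, 3))
        pred = y.copy()
        pred[:, 0] += 2.0  # only the gas head off by 2
        assert float(pretrain_loss(pred, y).data) == pytest.approx(2.0)

    def test_matches_brute_force_on_random_batches(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            pred = rng.normal(scale=10, size=(7, 3))
            target = rng.normal(scale=10, size=(7, 3))
            assert float(pretrain_loss(pred, target).data) == pytest.approx(
                brute_pretrain_loss(pred, target), abs=1e-10
            )

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            pretrain_loss(np.zeros((3, 3)), np.zeros((4, 3)))


class TestFinetuneLoss:
    def test_exact_zero(self):
        dg = np.array([1.0, -2.0])
        gas = np.array([0.5, 1.5, -1.0, 2.0])
        assert float(finetune_loss(dg, dg, gas, gas).data) == 0.0

    def test_pair_term_only(self):
        dg_exp = np.zeros(4)
        gas = np.array([1.0, 2.0])
        loss = finetune_loss(dg_exp + 1.0, dg_exp, gas, gas, alpha=0.8, beta=0.2)
        assert float(loss.data) == pytest.approx(0.8)

    def test_gas_term_only(self):
        dg = np.array([1.0])
        gas_t = np.array([0.0, 0.0])
        loss = finetune_loss(dg, dg, gas_t + 1.0, gas_t, alpha=0.8, beta=0.2)
        assert float(loss.data) == pytest.approx(0.2)

    def test_beta_term_skipped_without_gas(self):
        dg_exp = np.zeros(3)
        loss = finetune_loss(dg_exp + 1.0, dg_exp, None, None)
        assert float(loss.data) == pytest.approx(0.8)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            dg_p, dg_e = rng.normal(size=5), rng.normal(size=5)
            gas_p, gas_t = rng.normal(size=10), rng.normal(size=10)
            got = float(finetune_loss(dg_p, dg_e, gas_p, gas_t, 0.8, 0.2).data)
            want = brute_finetune_loss(dg_p, dg_e, gas_p, gas_t, 0.8, 0.2)
            assert got == pytest.approx(want, abs=1e-10)

    def test_gradient_flows(self):
        dg_pred = parameter([1.0, -1.0])
        loss = finetune_loss(dg_pred, np.zeros(2))
        loss.backward()
        assert np.allclose(dg_pred.grad, [0.4, -0.4])  # alpha * sign / n


class TestEmaAmsGrad:
    def test_zero_gradients_leave_live_unchanged(self):
        p = parameter([1.0, 2.0])
        opt = EmaAmsGrad({"w": p}, lr=0.01, decay_start=0.5, decay_end=0.5)
        p.grad = np.zeros(2)
        opt.step()
        assert np.array_equal(p.data, [1.0, 2.0])
        assert np.array_equal(opt.shadow["w"], [1.0, 2.0])

    def test_shadow_moves_toward_live(self):
        p = parameter([0.0])
        opt = EmaAmsGrad({"w": p}, lr=0.1, decay_start=0.5, decay_end=0.5)
        p.grad = np.array([1.0])
        opt.step()
        # shadow = 0.5*0 + 0.5*live
        assert opt.shadow["w"][0] == pytest.approx(0.5 * p.data[0])

    def test_single_step_hand_calculation(self):
        # m = (1-b1)*g, v = (1-b2)*g^2, vhat = v, step = lr*m/(sqrt(vhat)+eps)
        lr, b1, b2, eps, g = 0.001, 0.9, 0.999, 1e-8, 1.0
        p = parameter([0.0])
        opt = EmaAmsGrad({"w": p}, lr=lr, beta1=b1, beta2=b2, eps=eps)
        p.grad = np.array([g])
        opt.step()
        expected = -lr * (1 - b1) * g / (np.sqrt((1 - b2) * g**2) + eps)
        assert p.data[0] == pytest.approx(expected, rel=1e-12)

    def test_vhat_nondecreasing(self):
        p = parameter([0.0])
        opt = EmaAmsGrad({"w": p}, lr=0.01)
        rng = np.random.default_rng(3)
        prev = 0.0
        for _ in range(20):
            p.grad = rng.normal(size=1)
            opt.step()
            assert opt.vhat["w"][0] >= prev
            prev = opt.vhat["w"][0]

    def test_nonfinite_gradient_names_parameter(self):
        p = parameter([0.0])
        opt = EmaAmsGrad({"bad_param": p})
        p.grad = np.array([np.nan])
        with pytest.raises(ValueError, match="bad_param"):
            opt.step()

    def test_decay_warmup_ramp(self):
        p = parameter([0.0])
        opt = EmaAmsGrad({"w": p}, decay_start=0.0, decay_end=0.99, warmup_steps=10)
        assert opt.current_decay() == 0.0
        opt.t = 5
        assert opt.current_decay() == pytest.approx(0.495)
        opt.t = 50
        assert opt.current_decay() == pytest.approx(0.99)


class TestSplitPlan:
    def test_8to2_sizes(self):
        assert SplitPlan().split_sizes(383) == (306, 77)

    def test_folds_partition(self):
        plan = SplitPlan(n_folds=5)
        folds = plan.folds(83, seed=4)
        seen = np.concatenate([val for _, val in folds])
        assert sorted(seen.tolist()) == list(range(83))

    def test_fold_val_fraction(self):
        plan = SplitPlan(n_folds=5)
        for train, val in plan.folds(100, seed=0):
            assert len(val) == 20 and len(train) == 80


class TestConfigs:
    def test_pretrain_validation(self):
        with pytest.raises(ValueError):
            PretrainConfig(learning_rate=0.0)
        with pytest.raises(ValueError):
            PretrainConfig(epochs=0)

    def test_finetune_validation(self):
        with pytest.raises(ValueError):
            FinetuneConfig(alpha=-0.1)

    def test_pair_record_needs_label(self):
        from tautrank.chem import Conformer3D

        conf = Conformer3D([[0.0, 0.0, 0.0]])
        with pytest.raises(ValueError):
            PairRecord("C", "C", conf, conf, np.array([6]), np.array([6]))
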