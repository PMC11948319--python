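"""End-to-end ranking workflow and dataset evaluation.

These tests train nothing: they use a checkpoint whose untrained (zero
head) network predicts identical energies, plus oracle-labeled records, to
check the plumbing: state enumeration, ranking order, populations, cutoff
flags, determinism, and metric composition.
"""

import numpy as np
import pytest

from tautrank.nn.model import ModelConfig, init_params
from tautrank.synthetic import make_pair_dataset
from tautrank.thermo import mae, ranking_success_rate, rmse
from tautrank.training import Checkpoint
from tautrank.workflow import RunConfig, evaluate_dataset, rank_tautomers

CFG = ModelConfig(embedding_dim=8, n_interaction=1, n_residual=1, n_output_residual=1, n_rbf=8)


@pytest.fixture(scope="module")
def zero_checkpoint():
    """Untrained network with zero output head: every state gets energy 0."""
    params = init_params(CFG, seed=0)
    shifts = np.zeros((len(CFG.elements), 3))
    return Checkpoint(params, CFG, shifts, provenance={"seed": 0})


@pytest.fixture(scope="module")
def biased_checkpoint():
    """Network whose element shifts make O-rich states lower in water."""
    params = init_params(CFG, seed=0)
    shifts = np.zeros((len(CFG.elements), 3))
    shifts[CFG.elements.index(1), 1] = -1.0  # each H lowers E_water
    return Checkpoint(params, CFG, shifts, provenance={"seed": 0})


RUN = RunConfig(n_conformers=2, seed=3)


class TestRankTautomers:
    def test_single_state_molecule(self, zero_checkpoint):
        report = rank_tautomers("CCO", zero_checkpoint, cfg=RUN)
        assert len(report.states) == 1
        assert report.states[0].relative_energy == 0.0
        assert report.states[0].population == 1.0
        assert report.states[0].low_energy

    def test_ranked_and_flagged(self, zero_checkpoint):
        report = rank_tautomers("CC(C)=O", zero_checkpoint, cfg=RUN)
        assert len(report.states) == 2
        rels = [s.relative_energy for s in report.states]
        assert rels == sorted(rels)
        assert report.states[0].relative_energy == 0.0
        assert sum(s.population for s in report.states) == pytest.approx(1.0)

    def test_spelling_invariance(self, zero_checkpoint):
        a = rank_tautomers("CC(C)=O", zero_checkpoint, cfg=RUN)
        b = rank_tautomers("O=C(C)C", zero_checkpoint, cfg=RUN)
        assert [s.smiles for s in a.states] == [s.smiles for s in b.states]
        assert [s.relative_energy for s in a.states] == [s.relative_energy for s in b.states]

    def test_determinism(self, zero_checkpoint):
        a = rank_tautomers("CC(N)=O", zero_checkpoint, cfg=RUN).to_dict()
        b = rank_tautomers("CC(N)=O", zero_checkpoint, cfg=RUN).to_dict()
        assert a == b

    def test_charged_input_rejected(self, zero_checkpoint):
        with pytest.raises(ValueError, match="neutral"):
            rank_tautomers("CC(=O)[O-]", zero_checkpoint, cfg=RUN)

    def test_unsupported_element_rejected(self, zero_checkpoint):
        with pytest.raises(ValueError, match="element"):
            rank_tautomers("C[Si](C)C", zero_checkpoint, cfg=RUN)

    def test_shift_only_model_orders_by_composition(self, biased_checkpoint):
        # keto vs enol have identical formula -> identical shift sum -> tie,
        # broken deterministically by canonical text
        report = rank_tautomers("CC(C)=O", biased_checkpoint, cfg=RUN)
        assert [s.smiles for s in report.states] == sorted(s.smiles for s in report.states)

    def test_relative_energies_translation_invariant(self, zero_checkpoint, biased_checkpoint):
        # a constant added to every absolute energy must not change relatives
        a = rank_tautomers("CC(C)=O", zero_checkpoint, cfg=RUN)
        shifted = Checkpoint(
            zero_checkpoint.params,
            CFG,
            zero_checkpoint.shifts + 100.0,  # +100 per atom on every head
            provenance={},
        )
        b = rank_tautomers("CC(C)=O", shifted, cfg=RUN)
        assert [s.relative_energy for s in a.states] == pytest.approx(
            [s.relative_energy for s in b.states], abs=1e-9
        )


@pytest.fixture(scope="module")
def pairs():
    return make_pair_dataset(8, noise_sd=0.0, seed=12, n_conformers=2)


class TestEvaluateDataset:

    def test_zero_model_scores_zero_everywhere(self, zero_checkpoint, pairs):
        report = evaluate_dataset(pairs, zero_checkpoint)
        dg = np.array([p.dG_exp for p in pairs])
        assert report["rmse"] == pytest.approx(rmse(np.zeros(len(dg)), dg))
        assert report["mae"] == pytest.approx(mae(np.zeros(len(dg)), dg))
        assert report["ranking_success_rate"] == 0.0  # zero predictions never rank

    def test_metrics_compose_with_thermo_ops(self, zero_checkpoint, pairs):
        report = evaluate_dataset(pairs, zero_checkpoint)
        preds = np.array([r["dG_pred"] for r in report["records"]])
        dg = np.array([r["dG_exp"] for r in report["records"]])
        pref = [r["preferred"] for r in report["records"]]
        assert report["rmse"] == pytest.approx(rmse(preds, dg))
        assert report["ranking_success_rate"] == pytest.approx(
            ranking_success_rate(preds, pref)
        )

    def test_empty_rejected(self, zero_checkpoint):
        with pytest.raises(ValueError):
            evaluate_dataset([], zero_checkpoint)


class TestOracleEquivalence:
    def test_oracle_as_model_gives_perfect_metrics(self):
        """A 'model' that emits the oracle labels scores RMSE 0 and success 1."""
        from tautrank.synthetic import SurrogateOracle
        from tautrank.chem import parse_structure

        oracle = SurrogateOracle()
        recs = make_pair_dataset(8, noise_sd=0.0, seed=12, n_conformers=2, oracle=oracle)
        preds = []
        for rec in recs:
            ta = oracle.label(parse_structure(rec.smiles_a), rec.conf_a)
            tb = oracle.label(parse_structure(rec.smiles_b), rec.conf_b)
            preds.append(tb.E_water - ta.E_water)
        dg = [r.dG_exp for r in recs]
        pref = [r.preferred for r in recs]
        assert rmse(preds, dg) == pytest.approx(0.0, abs=1e-10)
        assert ranking_success_rate(preds, pref) == 1.0
        assert ranking_success_rate([-p for p in preds], pref) == 0.0
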