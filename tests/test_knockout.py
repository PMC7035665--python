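"""Knockout screens: deletion semantics, support-set reduction, oracles."""

from __future__ import annotations

import numpy as np
import pytest

import fluxtk as fk

from conftest import exhaustive_gene_ko, exhaustive_met_ko


class TestDeletionSemantics:
    def test_gene_deletion_overrides(self, toy3, toylin):
        assert fk.apply_gene_deletion(toy3, {"g1"}) == {"R1": (0.0, 0.0)}
        assert fk.apply_gene_deletion(toy3, set()) == {}
        assert fk.apply_gene_deletion(toylin, {"g2"}) == {"R1": (0.0, 0.0)}

    def test_unknown_gene_errors(self, toy3):
        with pytest.raises(KeyError):
            fk.apply_gene_deletion(toy3, {"gX"})

    def test_metabolite_deletion_blocks_all_touching(self, toy3):
        assert fk.apply_metabolite_deletion(toy3, {"B"}) == {
            "R1": (0.0, 0.0),
            "R2": (0.0, 0.0),
            "EX_B": (0.0, 0.0),
        }
        assert fk.apply_metabolite_deletion(toy3, {"A"}) == {
            "EX_A": (0.0, 0.0),
            "R1": (0.0, 0.0),
            "R2": (0.0, 0.0),
        }
        assert fk.apply_metabolite_deletion(toy3, set()) == {}

    def test_substrate_only_option(self, toy3):
        # consumers of B only: the export reaction
        assert fk.apply_metabolite_deletion(toy3, {"B"}, substrate_only=True) == {
            "EX_B": (0.0, 0.0)
        }

    def test_unknown_metabolite_errors(self, toy3):
        with pytest.raises(KeyError):
            fk.apply_metabolite_deletion(toy3, {"Z"})


class TestCandidateSets:
    def test_toylin(self, toylin):
        support = fk.candidate_sets(toylin)
        assert support.genes == {"g1", "g2"}

    def test_dead_branch_gene_excluded(self, toybr):
        support = fk.candidate_sets(toybr)
        assert "g4" not in support.genes

    def test_zero_objective_empty(self, toy3):
        from dataclasses import replace

        zero = fk.MetabolicModel(
            id="zero",
            metabolites=toy3.metabolites,
            reactions=[replace(r, objective_coefficient=0.0) for r in toy3.reactions],
            S=toy3.S,
            genes=toy3.genes,
        )
        support = fk.candidate_sets(zero)
        assert support.reactions == frozenset()


class TestSingleGeneKO:
    def test_toy3_reroutes(self, toy3):
        table = fk.single_gene_ko(toy3)[0]
        assert table.record("g1").ratio == pytest.approx(1.0, abs=1e-6)
        assert table.record("g2").ratio == pytest.approx(1.0, abs=1e-6)
        assert table.lethals() == []

    def test_toylin_chain_severed(self, toylin):
        table = fk.single_gene_ko(toylin)[0]
        rec = table.record("g1")
        assert rec.ratio == pytest.approx(0.0, abs=1e-9)
        assert rec.is_lethal()

    def test_noncandidate_skipped(self, toybr):
        table = fk.single_gene_ko(toybr)[0]
        rec = table.record("g4")
        assert not rec.evaluated
        assert rec.ratio == 1.0
        assert rec.mutant_objective == rec.wild_type_objective

    def test_empty_deletion_is_wild_type(self, toy3):
        wt = fk.solve_fba(toy3).objective_value
        table = fk.single_gene_ko(toy3)[0]
        assert table.wild_type_objective == pytest.approx(wt, abs=1e-9)

    def test_reduction_soundness(self):
        """Every gene lethal under exhaustive single KO is a candidate,
        hence evaluated by the reduced screen."""

        for name in fk.fixtures.TOY_NAMES:
            model = fk.make_toy(name)
            oracle = exhaustive_gene_ko(model)
            table = fk.single_gene_ko(model)[0]
            for g, mutant in oracle["singles"].items():
                if mutant < 0.01 * oracle["wt"]:
                    assert table.record(g).evaluated, (name, g)


def _models_for_oracle():
    models = [fk.make_toy(n) for n in fk.fixtures.TOY_NAMES]
    models.append(fk.make_random_model(2, 2, reversible_frac=0.0, seed=7))
    models.append(fk.make_random_model(3, 2, reversible_frac=0.4, seed=9))
    return models


class TestDoubleGeneKO:
    def test_toy3_synthetic_lethal_pair(self, toy3):
        table = fk.double_gene_ko(toy3)[0]
        rec = table.record(("g1", "g2"))
        assert rec.evaluated
        assert rec.ratio == pytest.approx(0.0, abs=1e-9)
        assert table.synthetic_lethals() == [("g1", "g2")]

    def test_toylin_pair_not_synthetic(self, toylin):
        table = fk.double_gene_ko(toylin)[0]
        rec = table.record(("g1", "g2"))
        assert rec.ratio == pytest.approx(0.0, abs=1e-9)
        assert table.synthetic_lethals() == []  # singles already lethal

    def test_dead_branch_pairs_unevaluated(self, toybr):
        table = fk.double_gene_ko(toybr)[0]
        assert not table.record(("g1", "g4")).evaluated

    def test_contains_single_records(self, toy3):
        table = fk.double_gene_ko(toy3)[0]
        singles = [r for r in table.records if isinstance(r.target, str)]
        assert {r.target for r in singles} == set(toy3.genes)

    def test_symmetry_one_record_per_pair(self, toy3):
        table = fk.double_gene_ko(toy3)[0]
        pairs = [r.target for r in table.records if isinstance(r.target, tuple)]
        assert len(pairs) == len(set(pairs))
        assert all(a < b for a, b in pairs)
        assert table.record(("g2", "g1")) is table.record(("g1", "g2"))

    @pytest.mark.parametrize("model", _models_for_oracle(), ids=lambda m: m.id)
    def test_oracle_equivalence(self, model):
        """Evaluated pair ratios equal unreduced exhaustive enumeration,
        and no synthetic-lethal pair hides among the unevaluated ones."""

        oracle = exhaustive_gene_ko(model)
        table = fk.double_gene_ko(model)[0]
        wt = oracle["wt"]
        cutoff = table.lethality_cutoff
        for rec in table.records:
            if not isinstance(rec.target, tuple):
                continue
            expected = oracle["pairs"][rec.target]
            if rec.evaluated:
                assert rec.mutant_objective == pytest.approx(
                    expected, abs=1e-6
                ), rec.target
            else:
                a, b = rec.target
                synthetic = (
                    expected < cutoff * wt
                    and oracle["singles"][a] >= cutoff * wt
                    and oracle["singles"][b] >= cutoff * wt
                )
                assert not synthetic, rec.target

    def test_workers_identical(self, toy3):
        a = fk.double_gene_ko(toy3, workers=1)[0].to_frame().to_csv()
        b = fk.double_gene_ko(toy3, workers=4)[0].to_frame().to_csv()
        assert a == b


class TestMetaboliteKO:
    def test_toy3_b_is_lethal(self, toy3):
        table = fk.single_met_ko(toy3)[0]
        rec = table.record("B")
        assert rec.evaluated and rec.ratio == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize(
        "model",
        [fk.make_toy("TOY3"), fk.make_toy("TOYBR"), fk.make_toy("TOY3X2")],
        ids=lambda m: m.id,
    )
    def test_double_oracle_equivalence(self, model):
        oracle = exhaustive_met_ko(model)
        table = fk.double_met_ko(model)[0]
        wt = oracle["wt"]
        cutoff = table.lethality_cutoff
        for rec in table.records:
            if not isinstance(rec.target, tuple):
                continue
            expected = oracle["pairs"][rec.target]
            if rec.evaluated:
                assert rec.mutant_objective == pytest.approx(expected, abs=1e-6)
            else:
                a, b = rec.target
                synthetic = (
                    expected < cutoff * wt
                    and oracle["singles"][a] >= cutoff * wt
                    and oracle["singles"][b] >= cutoff * wt
                )
                assert not synthetic, rec.target

    def test_zero_objective_all_unevaluated(self, toy3):
        from dataclasses import replace

        zero = fk.MetabolicModel(
            id="zero",
            metabolites=toy3.metabolites,
            reactions=[replace(r, objective_coefficient=0.0) for r in toy3.reactions],
            S=toy3.S,
            genes=toy3.genes,
        )
        table = fk.single_met_ko(zero)[0]
        assert all(not r.evaluated for r in table.records)


class TestMultipleObjectives:
    def test_one_table_per_objective(self, toy3):
        tables = fk.single_gene_ko(toy3, objectives=["EX_B", "EX_A"])
        assert [t.objective_id for t in tables] == ["EX_B", "EX_A"]
        for t in tables:
            assert t.wild_type_objective == pytest.approx(10.0, abs=1e-6)


class TestLPBudget:
    def test_worked_example(self):
        naive, reduced = fk.lp_budget(2194, 251)
        assert reduced == 63001
        assert naive == 4813636
        assert round(naive / 1e6, 1) == 4.8

    def test_degenerate_counts(self):
        assert fk.lp_budget(5, 5) == (25, 25)
        assert fk.lp_budget(5, 0) == (25, 0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            fk.lp_budget(-1, 0)
        with pytest.raises(ValueError):
            fk.lp_budget(3, 4)
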