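"""Model data structures, GPR algebra and the two serialization dialects."""

from __future__ import annotations

from dataclasses import replace
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fluxtk as fk
from fluxtk.gpr import GPRParseError, GPRRule
from fluxtk.io import ModelFormatError

from conftest import eval_rule


class TestGPR:
    @pytest.mark.parametrize(
        "text,deleted,expected",
        [
            ("g1 or g2", {"g1"}, True),
            ("g1 and g2", {"g1"}, False),
            ("g1 and (g2 or g3)", {"g2", "g3"}, False),
            ("g1 and (g2 or g3)", {"g2"}, True),
            ("", {"g1"}, True),
            ("G1 AND g2", {"g2"}, False),  # case-insensitive operators
        ],
    )
    def test_evaluate(self, text, deleted, expected):
        assert GPRRule.parse(text).evaluate(frozenset(deleted)) is expected

    def test_brute_force_truth_table(self):
        """Parsed rule agrees with the independent evaluator on every
        deletion subset."""

        rule = GPRRule.parse("g1 and (g2 or (g3 and g4)) or g5")
        genes = sorted(rule.genes())
        for bits in product([False, True], repeat=len(genes)):
            deleted = {g for g, b in zip(genes, bits) if b}
            assert rule.evaluate(frozenset(deleted)) == eval_rule(rule.root, deleted)

    @pytest.mark.parametrize(
        "bad", ["g1 and", "and g2", "(g1 or g2", "g1 g2)", "()"]
    )
    def test_parse_errors(self, bad):
        with pytest.raises(GPRParseError):
            GPRRule.parse(bad)

    @given(
        st.recursive(
            st.sampled_from([f"g{i}" for i in range(1, 6)]),
            lambda inner: st.tuples(
                st.sampled_from(["and", "or"]),
                st.lists(inner, min_size=2, max_size=3).map(list),
            ),
            max_leaves=8,
        )
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_roundtrip_logical_equivalence(self, tree):
        """serialize -> parse preserves the rule's truth table."""

        rule = GPRRule(tree)
        back = GPRRule.parse(rule.to_string())
        genes = sorted(rule.genes())
        assert back.genes() == rule.genes()
        for bits in product([False, True], repeat=len(genes)):
            deleted = frozenset(g for g, b in zip(genes, bits) if b)
            assert back.evaluate(deleted) == rule.evaluate(deleted)


class TestValidate:
    def test_toys_are_clean(self):
        for name in fk.fixtures.TOY_NAMES:
            assert fk.validate(fk.make_toy(name)) == []

    def test_reversed_bounds_named(self, toy3):
        bad = replace(toy3.reactions[1], lower_bound=5.0, upper_bound=1.0)
        model = fk.MetabolicModel(
            id=toy3.id,
            metabolites=toy3.metabolites,
            reactions=[bad if r.id == "R1" else r for r in toy3.reactions],
            S=toy3.S,
            genes=toy3.genes,
        )
        violations = fk.validate(model)
        assert len(violations) == 1 and "R1" in violations[0]

    def test_gpr_gene_not_declared(self, toy3):
        model = fk.MetabolicModel(
            id=toy3.id,
            metabolites=toy3.metabolites,
            reactions=toy3.reactions,
            S=toy3.S,
            genes=["g1"],  # g2 missing
        )
        violations = fk.validate(model)
        assert len(violations) == 1 and "g2" in violations[0]


def _models_equal(a: fk.MetabolicModel, b: fk.MetabolicModel) -> bool:
    if [m.id for m in a.metabolites] != [m.id for m in b.metabolites]:
        return False
    if not np.allclose(a.S.toarray(), b.S.toarray()):
        return False
    for ra, rb in zip(a.reactions, b.reactions):
        if (
            ra.id != rb.id
            or ra.lower_bound != rb.lower_bound
            or ra.upper_bound != rb.upper_bound
            or ra.objective_coefficient != rb.objective_coefficient
        ):
            return False
        genes = sorted(ra.gpr.genes() | rb.gpr.genes())
        for bits in product([False, True], repeat=len(genes)):
            deleted = frozenset(g for g, bit in zip(genes, bits) if bit)
            if ra.gpr.evaluate(deleted) != rb.gpr.evaluate(deleted):
                return False
    return sorted(a.genes) == sorted(b.genes)


class TestJSONDialect:
    def test_fixture_shape(self, fixture_dir):
        model = fk.read_model_json(fixture_dir / "TOY3.json")
        assert model.n_reactions == 4 and model.n_metabolites == 2

    @pytest.mark.parametrize("name", fk.fixtures.TOY_NAMES)
    def test_roundtrip(self, name, tmp_path):
        model = fk.make_toy(name)
        path = tmp_path / "m.json"
        fk.write_model_json(model, path)
        assert _models_equal(model, fk.read_model_json(path))

    def test_duplicate_reaction_id(self, tmp_path, toy3):
        import json

        path = tmp_path / "m.json"
        fk.write_model_json(toy3, path)
        doc = json.loads(path.read_text())
        doc["reactions"].append(dict(doc["reactions"][0]))
        path.write_text(json.dumps(doc))
        with pytest.raises(ModelFormatError, match="duplicate"):
            fk.read_model_json(path)

    def test_missing_key_named(self, tmp_path):
        path = tmp_path / "m.json"
        path.write_text('{"metabolites": [], "reactions": []}')
        with pytest.raises(ModelFormatError, match="'S'"):
            fk.read_model_json(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            fk.read_model_json(tmp_path / "nope.json")


class TestSBML:
    def test_fixture_shape(self, fixture_dir):
        model = fk.read_sbml(fixture_dir / "TOY3.xml")
        assert model.n_reactions == 4 and model.n_metabolites == 2
        assert sorted(model.genes) == ["g1", "g2"]

    @pytest.mark.parametrize("name", fk.fixtures.TOY_NAMES)
    def test_roundtrip(self, name, tmp_path):
        model = fk.make_toy(name)
        path = tmp_path / "m.xml"
        fk.write_sbml(model, path)
        assert _models_equal(model, fk.read_sbml(path))

    def test_deterministic_read(self, fixture_dir):
        a = fk.read_sbml(fixture_dir / "TOYBR.xml")
        b = fk.read_sbml(fixture_dir / "TOYBR.xml")
        assert _models_equal(a, b)

    def test_truncated_file(self, tmp_path, toy3):
        path = tmp_path / "m.xml"
        fk.write_sbml(toy3, path)
        path.write_text(path.read_text()[: len(path.read_text()) // 2])
        with pytest.raises((ModelFormatError, ValueError)):
            fk.read_sbml(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            fk.read_sbml(tmp_path / "nope.xml")

    def test_cross_dialect_agreement(self, fixture_dir):
        """The same fixture read through both dialects is the same model."""

        a = fk.read_sbml(fixture_dir / "TOY3X2.xml")
        b = fk.read_model_json(fixture_dir / "TOY3X2.json")
        assert _models_equal(a, b)
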