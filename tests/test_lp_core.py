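"""FBA, flux-sum minimization and FVA against independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

import fluxtk as fk
from fluxtk.lp import LPError

from conftest import dense_fba, to_cobra


class TestFBA:
    def test_toy3_optimum_capped_by_exchange(self, toy3):
        sol = fk.solve_fba(toy3)
        assert sol.optimal
        assert sol.objective_value == pytest.approx(10.0, abs=1e-7)
        # solution feasibility: mass balance and bounds
        assert np.abs(toy3.S @ sol.fluxes).max() < 1e-7
        lb, ub = toy3.bounds_arrays()
        assert np.all(sol.fluxes >= lb - 1e-7) and np.all(sol.fluxes <= ub + 1e-7)
        c = toy3.objective_array()
        assert c @ sol.fluxes == pytest.approx(sol.objective_value, abs=1e-7)

    def test_blocked_exchange_gives_zero(self, toy3):
        sol = fk.solve_fba(toy3, bound_overrides={"EX_A": (0.0, 0.0)})
        assert sol.optimal and sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_unsatisfiable_mass_balance(self, toy3):
        sol = fk.solve_fba(
            toy3, bound_overrides={"EX_B": (5.0, 5.0), "EX_A": (0.0, 4.0)}
        )
        assert sol.status == "infeasible"

    def test_nan_bound_rejected(self, toy3):
        with pytest.raises((LPError, ValueError)):
            fk.solve_fba(toy3, bound_overrides={"EX_A": (float("nan"), 1.0)})

    def test_unknown_override_rejected(self, toy3):
        with pytest.raises(KeyError):
            fk.solve_fba(toy3, bound_overrides={"NOPE": (0.0, 1.0)})

    @pytest.mark.parametrize("seed", [3, 11, 42])
    def test_backend_agreement_on_random_models(self, seed):
        """Our HiGHS solve matches both a dense formulation and cobra's
        GLPK solve to 1e-7 in objective value."""

        model = fk.make_random_model(2, 2, reversible_frac=0.3, seed=seed)
        sol = fk.solve_fba(model)
        assert sol.optimal
        assert sol.objective_value == pytest.approx(dense_fba(model), abs=1e-7)
        cm = to_cobra(model)
        cobra_sol = cm.optimize()
        assert sol.objective_value == pytest.approx(
            cobra_sol.objective_value, abs=1e-7
        )


class TestMinimizeTotalFlux:
    def test_toy3_flux_sum(self, toy3):
        f = fk.solve_fba(toy3).objective_value
        sol, support = fk.minimize_total_flux(toy3, f)
        # any split of 10 units across the parallel branches costs 10+10+10
        assert sol.objective_value == pytest.approx(30.0, abs=1e-3)
        # the minimizer is itself FBA-feasible and attains the optimum
        assert np.abs(toy3.S @ sol.fluxes).max() < 1e-6
        c = toy3.objective_array()
        assert c @ sol.fluxes >= f - 1e-6 * max(1.0, abs(f))

    def test_zero_target_empty_support(self, toy3):
        sol, support = fk.minimize_total_flux(toy3, 0.0)
        assert sol.objective_value == pytest.approx(0.0, abs=1e-6)
        assert support.reactions == frozenset()

    def test_toylin_unique_support(self, toylin):
        f = fk.solve_fba(toylin).objective_value
        _, support = fk.minimize_total_flux(toylin, f)
        assert support.reactions == {"EX_A", "R1", "EX_B"}
        assert support.genes == {"g1", "g2"}
        assert support.metabolites == {"A", "B"}

    def test_inconsistent_target_errors(self, toy3):
        with pytest.raises(LPError):
            fk.minimize_total_flux(toy3, 1e6)

    def test_support_subsets_model(self, toy3x2):
        f = fk.solve_fba(toy3x2).objective_value
        _, support = fk.minimize_total_flux(toy3x2, f)
        assert support.reactions <= set(toy3x2.reaction_ids)
        assert support.genes <= set(toy3x2.genes)
        assert support.metabolites <= set(toy3x2.metabolite_ids)


class TestFVA:
    def test_toy3_full_optimum(self, toy3):
        res = fk.fva(toy3, 1.0)
        assert res["EX_A"] == pytest.approx((10.0, 10.0), abs=1e-6)
        assert res["EX_B"] == pytest.approx((10.0, 10.0), abs=1e-6)
        assert res["R1"] == pytest.approx((0.0, 10.0), abs=1e-6)
        assert res["R2"] == pytest.approx((0.0, 10.0), abs=1e-6)

    def test_toy3_unconstrained_objective(self, toy3):
        res = fk.fva(toy3, 0.0)
        assert res["EX_A"] == pytest.approx((0.0, 10.0), abs=1e-6)

    def test_monotone_in_fraction(self, toy3, toy3x2):
        """Lowering fraction_of_optimum never shrinks any interval."""

        for model in (toy3, toy3x2):
            prev = None
            for frac in (1.0, 0.5, 0.0):
                res = fk.fva(model, frac)
                if prev is not None:
                    assert np.all(res.min_flux <= prev.min_flux + 1e-9)
                    assert np.all(res.max_flux >= prev.max_flux - 1e-9)
                prev = res

    def test_min_below_max_and_within_bounds(self, toybr):
        res = fk.fva(toybr, 0.7)
        assert np.all(res.min_flux <= res.max_flux + 1e-9)
        lb, ub = toybr.bounds_arrays()
        assert np.all(res.min_flux >= lb - 1e-9)
        assert np.all(res.max_flux <= ub + 1e-9)

    def test_workers_do_not_change_results(self, toy3):
        a = fk.fva(toy3, 0.9, workers=1).to_frame().to_csv()
        b = fk.fva(toy3, 0.9, workers=4).to_frame().to_csv()
        assert a == b

    def test_subset_selection(self, toy3):
        res = fk.fva(toy3, 1.0, reactions=["R1"])
        assert res.reaction_ids == ["R1"]

    def test_cobra_agreement(self):
        from cobra.flux_analysis import flux_variability_analysis

        model = fk.make_random_model(3, 2, reversible_frac=0.5, seed=5)
        ours = fk.fva(model, 1.0)
        theirs = flux_variability_analysis(
            to_cobra(model), fraction_of_optimum=1.0
        )
        for rid in model.reaction_ids:
            lo, hi = ours[rid]
            assert lo == pytest.approx(theirs.loc[rid, "minimum"], abs=1e-6)
            assert hi == pytest.approx(theirs.loc[rid, "maximum"], abs=1e-6)

    def test_infeasible_wild_type_aborts(self, toy3):
        with pytest.raises(LPError):
            fk.fva(toy3, 1.0, bound_overrides={"EX_B": (5.0, 5.0), "EX_A": (0.0, 4.0)})
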