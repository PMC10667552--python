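"""Cross merit, ILP selection, and strategy comparison."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import clonalmate as cm
from clonalmate.allocation import InfeasibleError, validate_plan
from clonalmate.containers import InvalidParameterError


def merit_frame(females, males, u, g=None, mean_f=0.0):
    crosses = cm.enumerate_crosses(females, males)
    return pd.DataFrame({
        "female_id": [c[0] for c in crosses],
        "male_id": [c[1] for c in crosses],
        "u_cross": np.asarray(u, dtype=float),
        "g_cross": np.asarray(g if g is not None else u, dtype=float),
        "mean_f": mean_f,
        "n_progeny": 50,
    })


def brute_force_best(mt, col, n_select, max_per_parent):
    best = -np.inf
    n = len(mt)
    for sub in combinations(range(n), n_select):
        sel = np.zeros(n, dtype=bool)
        sel[list(sub)] = True
        ok = all(mt.loc[sel, c].value_counts().max() <= max_per_parent
                 for c in ("female_id", "male_id"))
        if ok:
            best = max(best, float(mt.loc[sel, col].sum()))
    return best


class TestEnumerateCrosses:
    @pytest.mark.parametrize("nf,nm,expected", [(35, 35, 1225), (1, 1, 1),
                                                (3, 4, 12)])
    def test_counts(self, nf, nm, expected):
        crosses = cm.enumerate_crosses([f"F{i}" for i in range(nf)],
                                       [f"M{i}" for i in range(nm)])
        assert len(crosses) == expected
        assert len(set(crosses)) == expected

    def test_female_major_order(self):
        crosses = cm.enumerate_crosses(["F1", "F2"], ["M1", "M2"])
        assert crosses == [("F1", "M1"), ("F1", "M2"),
                           ("F2", "M1"), ("F2", "M2")]

    def test_overlapping_parent_sets_rejected(self):
        with pytest.raises(InvalidParameterError):
            cm.enumerate_crosses(["A", "B"], ["B", "C"])

    def test_empty_rejected(self):
        with pytest.raises(InvalidParameterError):
            cm.enumerate_crosses([], ["M1"])


class TestCrossMerit:
    def _preds(self, values_by_family, g_values=None):
        rows, fam = [], []
        for (f, m), vals in values_by_family.items():
            for i, v in enumerate(vals):
                pid = f"{f}x{m}_p{i}"
                gv = g_values[(f, m)][i] if g_values else v
                rows.append({"clone_id": pid, "u_hat": v, "g_hat": gv})
                fam.append({"progeny_id": pid, "female_id": f,
                            "male_id": m})
        return pd.DataFrame(rows), pd.DataFrame(fam)

    def test_top_decile_of_fifty(self):
        vals = np.arange(50, dtype=float)
        preds, fam = self._preds({("F1", "M1"): vals})
        mt = cm.cross_merit(preds, fam, top_fraction=0.10)
        assert mt["u_cross"][0] == pytest.approx(np.mean([45, 46, 47, 48, 49]))
        assert mt["n_progeny"][0] == 50

    def test_constant_family_any_fraction(self):
        preds, fam = self._preds({("F1", "M1"): [3.3] * 20})
        for frac in (0.05, 0.5, 1.0):
            mt = cm.cross_merit(preds, fam, top_fraction=frac)
            assert mt["u_cross"][0] == pytest.approx(3.3)

    def test_full_fraction_is_family_mean(self):
        vals = [1.0, 2.0, 6.0]
        preds, fam = self._preds({("F1", "M1"): vals})
        mt = cm.cross_merit(preds, fam, top_fraction=1.0)
        assert mt["u_cross"][0] == pytest.approx(3.0)

    def test_u_and_g_ranked_independently(self):
        u = [0.0, 1.0, 2.0, 3.0]
        g = [3.0, 2.0, 1.0, 0.0]
        preds, fam = self._preds({("F1", "M1"): u},
                                 g_values={("F1", "M1"): g})
        mt = cm.cross_merit(preds, fam, top_fraction=0.25)
        assert mt["u_cross"][0] == 3.0
        assert mt["g_cross"][0] == 3.0

    def test_invalid_fraction(self):
        preds, fam = self._preds({("F1", "M1"): [1.0]})
        with pytest.raises(InvalidParameterError):
            cm.cross_merit(preds, fam, top_fraction=0.0)


class TestSelectCrossesILP:
    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(111)
        mt = merit_frame([f"F{i}" for i in range(3)],
                         [f"M{i}" for i in range(3)],
                         rng.normal(size=9))
        plan = cm.select_crosses_ilp(mt, "u_cross", n_select=2,
                                     max_per_parent=1)
        assert plan.objective == pytest.approx(
            brute_force_best(mt, "u_cross", 2, 1))
        assert validate_plan(plan, mt, 2, 1)

    def test_equal_merits_feasible_objective(self):
        mt = merit_frame(["F1", "F2"], ["M1", "M2"], [2.0] * 4)
        plan = cm.select_crosses_ilp(mt, "u_cross", n_select=3,
                                     max_per_parent=2)
        assert plan.n_selected == 3
        assert plan.objective == pytest.approx(6.0)

    def test_select_all_with_slack_constraints(self):
        mt = merit_frame(["F1", "F2"], ["M1", "M2"], [1.0, 2.0, 3.0, 4.0])
        plan = cm.select_crosses_ilp(mt, "u_cross", n_select=4,
                                     max_per_parent=2)
        assert plan.selected.all()

    def test_infeasible_reported(self):
        mt = merit_frame(["F1"], ["M1", "M2"], [1.0, 2.0])
        with pytest.raises(InfeasibleError):
            cm.select_crosses_ilp(mt, "u_cross", n_select=2,
                                  max_per_parent=1)

    def test_monotone_in_merit_improvement(self):
        rng = np.random.default_rng(113)
        mt = merit_frame([f"F{i}" for i in range(3)],
                         [f"M{i}" for i in range(4)],
                         rng.normal(size=12))
        plan = cm.select_crosses_ilp(mt, "u_cross", n_select=4,
                                     max_per_parent=2)
        unselected = np.flatnonzero(~plan.selected)
        mt2 = mt.copy()
        mt2.loc[unselected[0], "u_cross"] = mt["u_cross"].max() + 5.0
        plan2 = cm.select_crosses_ilp(mt2, "u_cross", n_select=4,
                                      max_per_parent=2)
        assert plan2.objective >= plan.objective

    def test_deterministic_tie_break(self):
        mt = merit_frame(["F1", "F2"], ["M1", "M2"], [1.0] * 4)
        a = cm.select_crosses_ilp(mt, "u_cross", n_select=2,
                                  max_per_parent=2)
        b = cm.select_crosses_ilp(mt, "u_cross", n_select=2,
                                  max_per_parent=2)
        assert np.array_equal(a.selected, b.selected)


class TestExpectedGain:
    def test_whole_set_zero_gain(self):
        mt = merit_frame(["F1", "F2"], ["M1", "M2"], [1.0, 2.0, 3.0, 4.0])
        plan = cm.select_crosses_ilp(mt, "u_cross", n_select=4,
                                     max_per_parent=2)
        assert plan.delta_u == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        mt = merit_frame(["F1", "F2"], ["M1", "M2"], [5.0, 1.0, 1.0, 1.0])
        plan = cm.select_crosses_ilp(mt, "u_cross", n_select=1,
                                     max_per_parent=1)
        assert plan.delta_u == pytest.approx(5.0 - 2.0)

    def test_optimal_selection_nonnegative_gain(self):
        rng = np.random.default_rng(127)
        mt = merit_frame([f"F{i}" for i in range(4)],
                         [f"M{i}" for i in range(4)],
                         rng.normal(size=16))
        plan = cm.select_crosses_ilp(mt, "u_cross", n_select=4,
                                     max_per_parent=2)
        assert plan.delta_u >= 0.0


class TestStrategyComparison:
    def test_identical_plans_full_overlap(self):
        rng = np.random.default_rng(131)
        mt = merit_frame([f"F{i}" for i in range(3)],
                         [f"M{i}" for i in range(3)],
                         rng.normal(size=9))
        plan = cm.select_crosses_ilp(mt, "u_cross", n_select=3,
                                     max_per_parent=2)
        rep = cm.strategy_comparison(mt, plan, plan)
        assert rep["overlap"] == 3

    def test_matched_objective_dominance(self):
        rng = np.random.default_rng(137)
        mt = merit_frame([f"F{i}" for i in range(4)],
                         [f"M{i}" for i in range(4)],
                         rng.normal(size=16), g=rng.normal(size=16))
        gebv = cm.select_crosses_ilp(mt, "u_cross", n_select=4,
                                     max_per_parent=2)
        gpcp = cm.select_crosses_ilp(mt, "g_cross", n_select=4,
                                     max_per_parent=2)
        assert gpcp.delta_g >= gebv.delta_g - 1e-12
        assert gebv.delta_u >= gpcp.delta_u - 1e-12

    @pytest.mark.parametrize("epv_gebv,epv_gpcp,expected_pct",
                             [(5.29, 8.28, 57), (0.50, 0.56, 12),
                              (1.16, 1.34, 16)])
    def test_relative_improvement_from_epv_pairs(self, epv_gebv, epv_gpcp,
                                                 expected_pct):
        """Percent improvement of clonal-value-based selection over
        breeding-value-based selection from the two strategies' average
        expected progeny values."""
        mt = merit_frame(["F1", "F2"], ["M1", "M2"],
                         u=[epv_gebv, epv_gebv, 0.0, 0.0],
                         g=[0.0, 0.0, epv_gpcp, epv_gpcp])
        plan_gebv = cm.select_crosses_ilp(mt, "u_cross", n_select=2,
                                          max_per_parent=2)
        plan_gpcp = cm.select_crosses_ilp(mt, "g_cross", n_select=2,
                                          max_per_parent=2)
        rep = cm.strategy_comparison(mt, plan_gebv, plan_gpcp)
        assert rep["epv_gebv"] == pytest.approx(epv_gebv)
        assert rep["epv_gpcp"] == pytest.approx(epv_gpcp)
        assert round(rep["gpcp_improvement"] * 100) == expected_pct
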