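import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import optimize

import barfit as bf
from barfit.stats import (
    PowerSpec,
    classify_cost,
    classify_lineages,
    constant_treatment_slopes,
    cost_of_generalization,
    fit_treatment_effects,
    genetic_correlation_slope,
    min_detectable_effect,
    no_cost_line,
    orthogonal_cost,
    summarize_costs,
    t_test_power,
)


class TestPower:
    def test_normal_limit_at_half_power(self):
        """At power 1/2 and large n the detectable effect is 1.96 sd/sqrt(n)."""
        mde = min_detectable_effect(1.0, 10_000, alpha=0.05, power=0.5)
        assert mde == pytest.approx(1.96 / 100.0, rel=1e-3)

    def test_monte_carlo_frozen_value(self):
        """sd=2.419, n=11: MDE 2.268 pp, frozen from a 1e5-rep Monte-Carlo
        power inversion (simulated one-sample t-tests at that effect reject
        at rate 0.799)."""
        assert min_detectable_effect(2.419, 11) == pytest.approx(2.2683, abs=2e-3)

    def test_power_at_mde_equals_target(self):
        mde = min_detectable_effect(3.0, 8, alpha=0.05, power=0.80)
        assert t_test_power(mde, 3.0, 8) == pytest.approx(0.80, abs=1e-9)

    def test_effect_decreases_with_n(self):
        effects = [min_detectable_effect(2.419, n) for n in (4, 8, 16, 64, 256)]
        assert all(a > b for a, b in zip(effects, effects[1:]))

    def test_two_sample_needs_larger_effect(self):
        assert min_detectable_effect(1.0, 10, test="two_sample") > min_detectable_effect(
            1.0, 10, test="one_sample"
        )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            min_detectable_effect(0.0, 10)
        with pytest.raises(ValueError):
            min_detectable_effect(1.0, 1)
        with pytest.raises(ValueError):
            PowerSpec(alpha=1.5)


class TestClassifyLineages:
    def test_detection_limit_boundaries(self):
        dw = [2.163, -2.163, 0.0, 2.162, -2.162, np.nan]
        got = list(classify_lineages(dw, limit=2.163))
        assert got == [
            "increased", "decreased", "unchanged", "unchanged", "unchanged",
            "unclassified",
        ]

    @given(st.lists(st.floats(min_value=-10, max_value=10), min_size=1, max_size=50))
    def test_partition_every_value_once(self, dw):
        got = classify_lineages(dw)
        assert got.isin(["increased", "decreased", "unchanged"]).all()

    def test_nonpositive_limit_rejected(self):
        with pytest.raises(ValueError):
            classify_lineages([0.0], limit=0.0)


def _simulate_dw(rng, treatment_means, line_sd=1.0, resid_sd=0.5, n_lines=6, n_rep=4):
    rows = []
    for t, mu in treatment_means.items():
        for i in range(n_lines):
            line = rng.normal(0, line_sd)
            for _ in range(n_rep):
                rows.append((t, f"{t}_l{i}", mu + line + rng.normal(0, resid_sd)))
    return pd.DataFrame(rows, columns=["treatment", "line_id", "dw"])


class TestTreatmentEffects:
    def test_noise_free_estimates_equal_means(self):
        df = pd.DataFrame(
            {
                "treatment": ["a"] * 4 + ["b"] * 4,
                "line_id": ["a1", "a1", "a2", "a2", "b1", "b1", "b2", "b2"],
                "dw": [3.0] * 4 + [-2.0] * 4,
            }
        )
        est = fit_treatment_effects(df).set_index("term")["estimate"]
        assert est["a"] == pytest.approx(3.0, abs=1e-6)
        assert est["b"] == pytest.approx(-2.0, abs=1e-6)

    def test_single_treatment_grand_mean(self):
        df = pd.DataFrame(
            {
                "treatment": "a",
                "line_id": ["l1", "l1", "l2", "l2"],
                "dw": [1.0, 2.0, 3.0, 4.0],
            }
        )
        est = fit_treatment_effects(df)
        assert est["estimate"].iloc[0] == pytest.approx(2.5, abs=1e-6)

    def test_recovery_within_two_se(self):
        """Known treatment means (+3 / 0 / -2) with line effects: estimates land
        within 2 s.e. of truth at close to the nominal ~95% rate.  With six
        lines per treatment the band's exact coverage is a small-df t, a bit
        under 95%, so the bound allows for that plus Monte-Carlo error."""
        truth = {"a": 3.0, "b": 0.0, "c": -2.0}
        hits = total = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            df = _simulate_dw(rng, truth)
            est = fit_treatment_effects(df).set_index("term")
            for t, mu in truth.items():
                total += 1
                hits += abs(est.loc[t, "estimate"] - mu) <= 2 * est.loc[t, "se"]
        assert hits / total >= 0.90

    def test_intercept_mode_gives_contrasts(self):
        rng = np.random.default_rng(0)
        df = _simulate_dw(rng, {"a": 0.0, "b": 5.0}, line_sd=0.1, resid_sd=0.1)
        est = fit_treatment_effects(df, include_intercept=True).set_index("term")
        assert est.loc["b", "estimate"] == pytest.approx(5.0, abs=0.5)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fit_treatment_effects(
                pd.DataFrame({"treatment": ["a"], "line_id": ["l"], "dw": [np.nan]})
            )


class TestSlopes:
    def test_hand_computed_negative_slope(self):
        res = genetic_correlation_slope((3.0, -2.0), (1.0, 1.0))
        assert res.slope == pytest.approx(-1.5)
        assert res.direction == "negative"

    def test_hand_computed_positive_slope(self):
        res = genetic_correlation_slope((1.0, 1.0), (3.0, 3.0))
        assert res.slope == pytest.approx(1.0)
        assert res.direction == "positive"

    def test_coincident_x_rejected(self):
        with pytest.raises(ValueError):
            genetic_correlation_slope((1.0, 0.0), (1.0, 5.0))

    @given(
        ax=st.floats(-5, 5), ay=st.floats(-5, 5),
        bx=st.floats(-5, 5), by=st.floats(-5, 5),
    )
    def test_axis_swap_inverts_slope(self, ax, ay, bx, by):
        if ax == bx or ay == by:
            return
        s = genetic_correlation_slope((ax, ay), (bx, by)).slope
        s_swapped = genetic_correlation_slope((ay, ax), (by, bx)).slope
        if s != 0:
            assert s_swapped == pytest.approx(1.0 / s, rel=1e-9)


class TestNoCostLine:
    def test_diagonal_line_geometry(self):
        line = no_cost_line((4.0, 0.0), (0.0, 4.0))
        np.testing.assert_allclose(line.normal, np.array([1.0, 1.0]) / np.sqrt(2))
        d_origin = orthogonal_cost([(0.0, 0.0)], line)[0]
        assert d_origin == pytest.approx(-2 * np.sqrt(2))
        assert classify_cost([d_origin], limit=0.634).iloc[0] == "cost"
        d_far = orthogonal_cost([(4.0, 4.0)], line)[0]
        assert d_far == pytest.approx(2 * np.sqrt(2))
        assert classify_cost([d_far], limit=0.634).iloc[0] == "benefit"

    def test_horizontal_line_normal_points_up(self):
        line = no_cost_line((1.0, 0.0), (0.0, 0.0))
        np.testing.assert_allclose(line.normal, (0.0, 1.0))

    def test_point_on_line_has_zero_cost(self):
        line = no_cost_line((4.0, 0.0), (0.0, 4.0))
        d = orthogonal_cost([(2.0, 2.0)], line)[0]
        assert d == pytest.approx(0.0, abs=1e-12)
        assert classify_cost([d], limit=0.634).iloc[0] == "no_cost"

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            no_cost_line((1.0, 1.0), (1.0, 1.0))

    @given(
        p1=st.tuples(st.floats(-10, 10), st.floats(-10, 10)),
        p2=st.tuples(st.floats(-10, 10), st.floats(-10, 10)),
    )
    def test_normal_is_unit_length_toward_benefit_side(self, p1, p2):
        if p1 == p2:
            return
        line = no_cost_line(p1, p2)
        n = np.asarray(line.normal)
        assert np.hypot(*n) == pytest.approx(1.0, abs=1e-12)
        s = n @ [1.0, 1.0]
        assert s > 0 or (s == 0 and n[0] > 0)

    def test_distance_agrees_with_nearest_point_search(self):
        """|signed distance| matches a brute-force minimization of Euclidean
        distance along the line on 100 random instances (< 1e-6)."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            p1, p2 = rng.normal(0, 5, 2), rng.normal(0, 5, 2)
            if np.allclose(p1, p2):
                continue
            p = rng.normal(0, 5, 2)
            line = no_cost_line(p1, p2)
            d = np.asarray(line.direction)

            def euclid(t):
                return np.hypot(*(np.asarray(p1) + t * d - p))

            res = optimize.minimize_scalar(euclid, bounds=(-100, 100), method="bounded",
                                           options={"xatol": 1e-12})
            assert abs(abs(orthogonal_cost([p], line)[0]) - res.fun) < 1e-6

    @given(
        shift=st.tuples(st.floats(-20, 20), st.floats(-20, 20)),
        theta=st.floats(0, 2 * np.pi),
    )
    def test_translation_invariance_and_rotation_equivariance(self, shift, theta):
        p1, p2, p = np.array([1.0, 2.0]), np.array([4.0, -1.0]), np.array([0.5, 3.0])
        base = orthogonal_cost([p], no_cost_line(p1, p2))[0]
        moved = orthogonal_cost([p + shift], no_cost_line(p1 + shift, p2 + shift))[0]
        assert moved == pytest.approx(base, abs=1e-9)
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        rotated = orthogonal_cost([rot @ p], no_cost_line(rot @ p1, rot @ p2))[0]
        assert abs(rotated) == pytest.approx(abs(base), abs=1e-9)


class TestSummaries:
    def test_counts_and_fractions(self):
        df = pd.DataFrame(
            {
                "treatment": "EH0_80",
                "distance": [-3.0, -2.5, 4.0],
                "category": ["cost", "cost", "benefit"],
            }
        )
        out = summarize_costs(df).set_index("treatment")
        assert out.loc["all", "cost"] == 2
        assert out.loc["all", "frac_cost"] == pytest.approx(2 / 3)

    def test_empty_input(self):
        out = summarize_costs(pd.DataFrame(columns=["treatment", "distance", "category"]))
        assert out.empty

    def test_effects_on_the_line_are_no_cost(self):
        """With true effects on the no-cost line and noise tiny vs the limit,
        essentially every lineage is called no-cost."""
        rng = np.random.default_rng(8)
        rows = []
        for i in range(300):
            x = rng.uniform(-3, 3)
            y = 4.0 - x + rng.normal(0, 0.1)  # on the x+y=4 line, s.d. << 2.163
            rows.append((f"l{i}", "EH0_80", x, y))
        wide = pd.DataFrame(rows, columns=["lineage", "treatment", "x", "y"])
        line = no_cost_line((4.0, 0.0), (0.0, 4.0))
        cats = classify_cost(orthogonal_cost(wide[["x", "y"]].to_numpy(), line), 2.163)
        assert (cats == "no_cost").all()

    def test_known_category_fractions_recovered(self):
        """Planted cost/no-cost/benefit fractions are recovered within the
        binomial 95% interval."""
        rng = np.random.default_rng(21)
        n = 600
        true_d = rng.choice([-5.0, 0.0, 5.0], size=n, p=[0.5, 0.3, 0.2])
        line = no_cost_line((4.0, 0.0), (0.0, 4.0))
        u = np.asarray(line.normal)
        t = rng.uniform(-3, 3, size=n)
        pts = (np.asarray(line.point) + np.outer(t, line.direction)
               + np.outer(true_d + rng.normal(0, 0.3, n), u))
        cats = classify_cost(orthogonal_cost(pts, line), limit=2.163)
        for cat, p in (("cost", 0.5), ("no_cost", 0.3), ("benefit", 0.2)):
            frac = (cats == cat).mean()
            assert abs(frac - p) < 1.96 * np.sqrt(p * (1 - p) / n) + 1e-9


class TestCostOfGeneralization:
    def test_pipeline_table(self):
        rng = np.random.default_rng(3)
        rows = []
        for t, (mx, my) in {
            "EH0": (4.0, 0.0), "EH80": (0.0, 4.0), "EH0_80": (0.0, 0.0),
        }.items():
            for i in range(10):
                for frac, mu in ((0.0, mx), (0.8, my)):
                    rows.append((f"{t}_l{i}", t, frac, mu + rng.normal(0, 0.05)))
        dw = pd.DataFrame(rows, columns=["lineage", "treatment", "stress_fraction", "dw"])
        res = cost_of_generalization(dw)
        assert set(res.lineages["treatment"]) == {"EH0_80"}
        assert (res.lineages["category"] == "cost").all()
        trow = res.treatments.iloc[0]
        assert trow["distance"] == pytest.approx(-2 * np.sqrt(2), abs=0.1)
        assert trow["category"] == "cost"

    def test_missing_anchor_treatment_rejected(self):
        dw = pd.DataFrame(
            {"lineage": ["l"], "treatment": ["EH0"], "stress_fraction": [0.0], "dw": [1.0]}
        )
        with pytest.raises(ValueError):
            cost_of_generalization(dw)

    def test_constant_treatment_slopes_all_pairs(self):
        rows = []
        means = {"EH0": {0.0: 4, 0.4: 1, 0.8: -2}, "EH40": {0.0: 1, 0.4: 3, 0.8: 1},
                 "EH80": {0.0: -2, 0.4: 1, 0.8: 4}}
        for t, envs in means.items():
            for frac, mu in envs.items():
                rows.append((f"{t}_l", t, frac, float(mu)))
        dw = pd.DataFrame(rows, columns=["lineage", "treatment", "stress_fraction", "dw"])
        out = constant_treatment_slopes(dw).set_index(["env_low", "env_high"])
        # (0, 0.8): points EH0=(4,-2), EH80=(-2,4) -> slope -1
        assert out.loc[(0.0, 0.8), "slope"] == pytest.approx(-1.0)
        assert out.loc[(0.0, 0.8), "direction"] == "negative"
        # (0, 0.4): EH0=(4,1), EH40=(1,3) -> slope (3-1)/(1-4) = -2/3
        assert out.loc[(0.0, 0.4), "slope"] == pytest.approx(-2 / 3)
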