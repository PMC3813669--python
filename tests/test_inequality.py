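import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ginitrend.errors import UndefinedGiniError
from ginitrend.inequality import (
    adjust_small_sample,
    build_lorenz,
    gini_from_lorenz,
    gini_pairwise,
    gini_panel,
)

units_strategy = st.lists(
    st.tuples(st.integers(1, 10**6), st.integers(0, 10**4)),
    min_size=2,
    max_size=40,
).filter(lambda us: sum(p for _, p in us) > 0)


class TestLorenz:
    def test_perfect_evenness_is_diagonal(self):
        curve = build_lorenz([1, 1], [5, 5])
        assert np.allclose(curve.x, [0, 0.5, 1])
        assert np.allclose(curve.y, [0, 0.5, 1])

    def test_full_concentration_hugs_floor(self):
        curve = build_lorenz([1, 1], [0, 10])
        assert np.allclose(curve.x, [0, 0.5, 1])
        assert np.allclose(curve.y, [0, 0.0, 1])

    @given(units_strategy)
    def test_invariants_on_random_instances(self, units):
        pop, prov = zip(*units)
        curve = build_lorenz(pop, prov)
        curve.validate()

    def test_zero_providers_undefined(self):
        with pytest.raises(UndefinedGiniError):
            build_lorenz([1, 2], [0, 0])

    def test_zero_population_rejected(self):
        with pytest.raises(ValueError):
            build_lorenz([0, 0], [1, 2])


class TestGini:
    def test_evenness_gives_zero(self):
        assert float(gini_from_lorenz(build_lorenz([3, 3, 3], [7, 7, 7]))) == 0.0

    @pytest.mark.parametrize("n", range(2, 11))
    def test_single_holder_equal_populations(self, n):
        """All providers in one of n equal units gives G = (n-1)/n exactly."""
        pop = np.ones(n)
        prov = np.zeros(n)
        prov[-1] = 13
        g = float(gini_from_lorenz(build_lorenz(pop, prov)))
        assert g == pytest.approx((n - 1) / n, abs=1e-15)

    def test_pairwise_single_unit_is_zero(self):
        assert float(gini_pairwise([10], [3])) == 0.0

    def test_pairwise_two_equal_units_closed_form(self):
        # equal populations, ratios (r, 0): G = 1/2 for any r > 0
        assert float(gini_pairwise([4, 4], [12, 0])) == pytest.approx(0.5)

    @given(units_strategy)
    def test_trapezoid_equals_pairwise(self, units):
        pop, prov = zip(*units)
        a = float(gini_from_lorenz(build_lorenz(pop, prov)))
        b = float(gini_pairwise(pop, prov))
        assert a == pytest.approx(b, abs=1e-12)

    @given(units_strategy, st.floats(0.001, 1000.0))
    def test_scale_invariance_in_providers(self, units, c):
        pop, prov = map(np.asarray, zip(*units))
        a = float(gini_pairwise(pop, prov.astype(float)))
        b = float(gini_pairwise(pop, prov * c))
        assert a == pytest.approx(b, rel=1e-9, abs=1e-12)

    @given(units_strategy)
    def test_population_replication_invariance(self, units):
        """Splitting every unit into two identical halves leaves G unchanged."""
        pop, prov = map(lambda v: np.asarray(v, dtype=float), zip(*units))
        a = float(gini_from_lorenz(build_lorenz(pop, prov)))
        split_pop = np.repeat(pop / 2, 2)
        split_prov = np.repeat(prov / 2, 2)
        b = float(gini_from_lorenz(build_lorenz(split_pop, split_prov)))
        assert a == pytest.approx(b, abs=1e-12)

    def test_tie_order_invariance(self, rng):
        pop = np.array([5.0, 5.0, 5.0, 2.0])
        prov = np.array([1.0, 1.0, 1.0, 3.0])  # three tied ratios
        base = float(gini_from_lorenz(build_lorenz(pop, prov)))
        for _ in range(10):
            perm = rng.permutation(len(pop))
            assert float(
                gini_from_lorenz(build_lorenz(pop[perm], prov[perm]))
            ) == pytest.approx(base, abs=1e-15)

    def test_merging_units_never_increases_gini(self, random_units, rng):
        """Aggregation loses within-group inequality, so any merge is <=."""
        for _ in range(50):
            pop, prov = random_units()
            g_before = float(gini_pairwise(pop, prov))
            k = max(2, len(pop) // 2)
            groups = rng.integers(0, k, size=len(pop))
            pop_m = np.bincount(groups, weights=pop, minlength=k)
            prov_m = np.bincount(groups, weights=prov, minlength=k)
            keep = pop_m > 0
            g_after = float(gini_pairwise(pop_m[keep], prov_m[keep]))
            assert g_after <= g_before + 1e-12

    def test_upper_bound_one_minus_smallest_share(self):
        """G <= 1 - w_min, attained when the smallest unit holds everything."""
        pop = np.array([1.0, 4.0, 5.0])
        prov = np.array([9.0, 0.0, 0.0])
        w_min = pop.min() / pop.sum()
        g = float(gini_from_lorenz(build_lorenz(pop, prov)))
        assert g == pytest.approx(1 - w_min, abs=1e-15)


class TestAdjustment:
    @pytest.mark.parametrize("g, n, expected", [(0.3, 2, 0.6), (0.3, 10, 0.3 * 10 / 9)])
    def test_exact_factor(self, g, n, expected):
        adj = adjust_small_sample(g, n)
        assert adj.value == pytest.approx(expected, abs=1e-15)
        assert adj.adjusted

    def test_factor_vanishes_for_large_n(self):
        g = 0.95
        adj = adjust_small_sample(g, 1000)
        assert abs(adj.value - g) < 1e-3

    def test_requires_two_units(self):
        with pytest.raises(ValueError):
            adjust_small_sample(0.3, 1)


class TestGiniPanel:
    def test_equal_ratio_region_gives_zero_series(self):
        rows = []
        for year in range(1996, 2011, 2):
            for i, (pop, ratio) in enumerate([(100, 0.01), (400, 0.01), (50, 0.01)]):
                rows.append(("A", f"u{i}", year, pop, pop // 5, pop * ratio, 1))
        df = pd.DataFrame(
            rows,
            columns=[
                "region_id", "unit_id", "year", "population",
                "child_population", "physicians", "pediatricians",
            ],
        )
        panel = gini_panel(df)
        assert (panel["gini"] == 0).all()
        assert len(panel) == 8

    def test_matches_direct_pairwise_per_region_year(self, small_panel):
        panel = gini_panel(small_panel)
        for _, row in panel.iterrows():
            grp = small_panel[
                (small_panel["region_id"] == row["region_id"])
                & (small_panel["year"] == row["year"])
            ]
            direct = float(gini_pairwise(grp["population"], grp["physicians"]))
            assert row["gini"] == pytest.approx(direct, abs=1e-12)

    def test_pediatricians_use_child_population(self, small_panel):
        panel = gini_panel(small_panel, provider_field="pediatricians")
        row = panel.iloc[0]
        grp = small_panel[
            (small_panel["region_id"] == row["region_id"])
            & (small_panel["year"] == row["year"])
        ]
        expected = float(gini_pairwise(grp["child_population"], grp["pediatricians"]))
        assert row["gini"] == pytest.approx(expected, abs=1e-12)
        wrong = float(gini_pairwise(grp["population"], grp["pediatricians"]))
        assert row["gini"] != pytest.approx(wrong, abs=1e-6)

    def test_zero_provider_region_year_is_missing_not_zero(self, small_panel, caplog):
        df = small_panel.copy()
        mask = (df["region_id"] == "Hokkaido") & (df["year"] == 1998)
        df.loc[mask, "physicians"] = 0.0
        with caplog.at_level("WARNING", logger="ginitrend.inequality"):
            panel = gini_panel(df)
        cell = panel[(panel["region_id"] == "Hokkaido") & (panel["year"] == 1998)]
        assert np.isnan(cell["gini"].iloc[0])
        assert any("zero physicians" in r.message for r in caplog.records)

    def test_zero_population_units_excluded_with_warning(self, small_panel, caplog):
        df = small_panel.copy()
        first_unit = df["unit_id"].iloc[0]
        df.loc[df["unit_id"] == first_unit, "population"] = 0
        with caplog.at_level("WARNING", logger="ginitrend.inequality"):
            panel = gini_panel(df)
        region = df["region_id"].iloc[0]
        assert (
            panel.loc[panel["region_id"] == region, "n_units"]
            == df[df["region_id"] == region]["unit_id"].nunique() - 1
        ).all()
        assert any("excluding" in r.message for r in caplog.records)

    def test_adjusted_panel_applies_factor(self, small_panel):
        raw = gini_panel(small_panel)
        adj = gini_panel(small_panel, adjusted=True)
        n = raw["n_units"]
        assert np.allclose(adj["gini"], raw["gini"] * n / (n - 1))
        assert adj["adjusted"].all()
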