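import numpy as np
import pytest

from bymtrend import (
    PriorConfig,
    SamplerConfig,
    classification_report,
    classify_areas,
    classify_risk,
    classify_trend,
    excess_risk_probability,
    risk_surface,
    run_chains,
    trend_probability,
)
from bymtrend.sampler import PosteriorSamples
from bymtrend.simulate import ScenarioConfig, simulate_panel


def _samples_from_fields(s, u, d1, alpha=0.0, d0=0.0):
    """Hand-build a PosteriorSamples whose s/u/d1 draws are given arrays."""
    m, n = s.shape
    t = 3
    years = (2011, 2012, 2013)
    areas = tuple(f"a{i}" for i in range(n))
    names = (
        ["alpha", "d0"]
        + [f"s[{a}]" for a in areas] + [f"u[{a}]" for a in areas]
        + [f"v[{y}]" for y in years] + [f"d1[{a}]" for a in areas]
        + [f"eps[{a},{y}]" for a in areas for y in years]
        + [f"sigma2_{c}" for c in ("s", "u", "v", "d", "eps")]
    )
    p = len(names)
    draws = np.zeros((1, m, p))
    draws[0, :, 0] = alpha
    draws[0, :, 1] = d0
    draws[0, :, 2 : 2 + n] = s
    draws[0, :, 2 + n : 2 + 2 * n] = u
    draws[0, :, 2 + 2 * n + t : 2 + 3 * n + t] = d1
    draws[0, :, -5:] = 1.0
    return PosteriorSamples(
        draws=draws, names=tuple(names), area_ids=areas, years=years,
        config=SamplerConfig(n_iterations=m + 1, n_burnin=1, n_chains=1, seed=0),
        rhat=np.full(p, np.nan), acceptance=[], chain_seeds=(0,),
    )


class TestExceedanceProbabilities:
    def test_counting_example(self):
        s = np.array([[-1.0], [1.0], [1.0], [1.0]])
        samples = _samples_from_fields(s, np.zeros((4, 1)), np.zeros((4, 1)))
        assert excess_risk_probability(samples, 0) == pytest.approx(0.75)

    def test_all_negative_boundary(self):
        s = -np.ones((5, 1))
        samples = _samples_from_fields(s, np.zeros((5, 1)), np.zeros((5, 1)))
        assert excess_risk_probability(samples, 0) == 0.0

    def test_matches_indicator_oracle(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=(200, 3))
        u = rng.normal(size=(200, 3))
        d1 = rng.normal(size=(200, 3))
        samples = _samples_from_fields(s, u, d1)
        for i in range(3):
            brute = sum(1 for k in range(200) if s[k, i] + u[k, i] > 0) / 200
            assert excess_risk_probability(samples, i) == pytest.approx(brute)
            brute_t = sum(1 for k in range(200) if d1[k, i] > 0) / 200
            assert trend_probability(samples, i) == pytest.approx(brute_t)

    def test_trend_counting_example(self):
        d1 = np.array([[-0.1], [-0.2], [0.3], [-0.4]])
        samples = _samples_from_fields(np.zeros((4, 1)), np.zeros((4, 1)), d1)
        assert trend_probability(samples, 0) == pytest.approx(0.25)

    def test_monotone_in_draw_shift(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=(100, 1))
        base = _samples_from_fields(s, np.zeros((100, 1)), np.zeros((100, 1)))
        shifted = _samples_from_fields(s + 0.5, np.zeros((100, 1)), np.zeros((100, 1)))
        assert excess_risk_probability(shifted, 0) >= excess_risk_probability(base, 0)


class TestThresholdRules:
    @pytest.mark.parametrize("p,expected", [
        (0.9, "high"), (0.81, "high"), (0.5, "medium"), (0.2, "medium"),
        (0.8, "medium"), (0.19, "low"), (0.0, "low"), (1.0, "high"),
    ])
    def test_risk_rule(self, p, expected):
        assert classify_risk(p) == expected

    @pytest.mark.parametrize("p,expected", [
        (0.85, "increasing"), (0.1, "decreasing"), (0.2, "stable"),
        (0.8, "stable"), (0.5, "stable"), (1.0, "increasing"),
    ])
    def test_trend_rule(self, p, expected):
        assert classify_trend(p) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_risk(1.2)
        with pytest.raises(ValueError):
            classify_trend(-0.1)


class TestClassification:
    def test_partition_and_codes(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=(500, 3)) + np.array([2.0, 0.0, -2.0])
        samples = _samples_from_fields(s, np.zeros((500, 3)), rng.normal(size=(500, 3)))
        cls = classify_areas(samples)
        assert list(cls.table["risk_category"]) == ["high", "medium", "low"]
        assert list(cls.table["risk_code"]) == [1, 3, 2]
        counts = classification_report(cls)
        top = counts[counts["trend_category"] == "all"]
        assert top["count"].sum() == 3

    def test_report_percentage_rounding(self):
        # 27 of 75 areas high -> 36%
        rng = np.random.default_rng(3)
        n = 75
        shift = np.concatenate([np.full(27, 3.0), np.full(29, 0.0), np.full(19, -3.0)])
        s = rng.normal(size=(400, n)) * 0.1 + shift
        m = 400
        t = 3
        years = (2011, 2012, 2013)
        areas = tuple(f"a{i:03d}" for i in range(n))
        names = (
            ["alpha", "d0"]
            + [f"s[{a}]" for a in areas] + [f"u[{a}]" for a in areas]
            + [f"v[{y}]" for y in years] + [f"d1[{a}]" for a in areas]
            + [f"eps[{a},{y}]" for a in areas for y in years]
            + [f"sigma2_{c}" for c in ("s", "u", "v", "d", "eps")]
        )
        draws = np.zeros((1, m, len(names)))
        draws[0, :, 2 : 2 + n] = s
        draws[0, :, -5:] = 1.0
        samples = PosteriorSamples(
            draws=draws, names=tuple(names), area_ids=areas, years=years,
            config=SamplerConfig(n_iterations=m + 1, n_burnin=1, n_chains=1, seed=0),
            rhat=np.full(len(names), np.nan), acceptance=[], chain_seeds=(0,),
        )
        counts = classification_report(classify_areas(samples))
        top = counts[counts["trend_category"] == "all"].set_index("risk_category")
        assert top.loc["high", "count"] == 27
        assert top.loc["high", "percent"] == 36
        assert top.loc["medium", "count"] == 29
        assert top.loc["low", "count"] == 19
        assert top["count"].sum() == n

    def test_within_category_trend_counts_partition(self):
        rng = np.random.default_rng(4)
        s = rng.normal(size=(300, 3))
        d1 = rng.normal(size=(300, 3))
        cls = classify_areas(_samples_from_fields(s, np.zeros((300, 3)), d1))
        counts = classification_report(cls)
        for risk in ("high", "medium", "low"):
            sub = counts[counts["risk_category"] == risk].set_index("trend_category")
            assert sub.drop("all")["count"].sum() == sub.loc["all", "count"]

    def test_reclassification_is_deterministic(self):
        rng = np.random.default_rng(5)
        s = rng.normal(size=(300, 3))
        samples = _samples_from_fields(s, rng.normal(size=(300, 3)),
                                       rng.normal(size=(300, 3)))
        t1 = classify_areas(samples).table
        t2 = classify_areas(samples).table
        assert t1.equals(t2)


class TestRiskSurface:
    def test_degenerate_draws_give_zero_width_ci(self):
        ds = simulate_panel(ScenarioConfig(n_rows=2, n_cols=2, n_years=3, seed=6))
        samples = _samples_from_fields(
            np.zeros((50, 4)), np.zeros((50, 4)), np.zeros((50, 4)), alpha=-4.0)
        surf = risk_surface(_rename(samples, ds), ds.panel, ds.time_index)
        np.testing.assert_allclose(surf.cells["risk_lo"], surf.cells["risk_hi"])
        np.testing.assert_allclose(surf.cells["risk_mean_per1000"],
                                   1000 / (1 + np.exp(4.0)))
        np.testing.assert_allclose(surf.trend["rel_trend"], 1.0)

    def test_ci_brackets_mean(self):
        ds = simulate_panel(ScenarioConfig(n_rows=3, n_cols=3, n_years=5, seed=7,
                                           births_range=(5_000, 20_000)))
        samples = run_chains(ds.panel, ds.adj, ds.time_index, PriorConfig(),
                             SamplerConfig(n_iterations=400, n_burnin=100, seed=2))
        surf = risk_surface(samples, ds.panel, ds.time_index)
        assert (surf.cells["risk_lo"] <= surf.cells["risk_mean_per1000"] + 1e-12).all()
        assert (surf.cells["risk_hi"] >= surf.cells["risk_mean_per1000"] - 1e-12).all()


def _rename(samples, ds):
    """Remap a hand-built samples object onto a dataset's area ids/years."""
    mapping = dict(zip(("a0", "a1", "a2", "a3"), ds.panel.area_ids))
    years = dict(zip((2011, 2012, 2013), ds.panel.years))
    names = []
    for nm in samples.names:
        for old, new in mapping.items():
            nm = nm.replace(f"[{old},", f"[{new},").replace(f"[{old}]", f"[{new}]")
        names.append(nm)
    return PosteriorSamples(
        draws=samples.draws, names=tuple(names), area_ids=ds.panel.area_ids,
        years=ds.panel.years, config=samples.config, rhat=samples.rhat,
        acceptance=[], chain_seeds=(0,),
    )


def test_attach_to_geojson_merges_categories():
    from bymtrend.classify import attach_to_geojson

    rng = np.random.default_rng(9)
    s = rng.normal(size=(200, 3)) + np.array([2.0, 0.0, -2.0])
    cls = classify_areas(_samples_from_fields(s, np.zeros((200, 3)),
                                              np.zeros((200, 3))))
    gj = {"type": "FeatureCollection", "features": [
        {"type": "Feature", "properties": {"area_id": f"a{i}"},
         "geometry": {"type": "Point", "coordinates": [i, 0]}} for i in range(3)]}
    out = attach_to_geojson(cls, gj)
    cats = [f["properties"]["risk_category"] for f in out["features"]]
    assert cats == ["high", "medium", "low"]
    # original untouched
    assert "risk_category" not in gj["features"][0]["properties"]
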