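"""Power-law model fitting, node-to-tip distances, HPD intervals, posterior dating."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cophylodate.cospeciation import CospeciationEvent, map_cospeciations
from cophylodate.simulate import SimulationConfig, simulate
from cophylodate.tdrp import (
    CalibrationPoint,
    QueryDef,
    TDRPModel,
    average_node_to_tip_distance,
    date_nodes_posterior,
    fit_tdrp,
    hpd_interval,
    node_to_tip_distances,
    predict_time,
)

from conftest import tree_from_newick


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def ols_normal_equations(x, y):
    """Closed-form simple OLS via the normal equations."""
    x, y = np.asarray(x), np.asarray(y)
    xbar, ybar = x.mean(), y.mean()
    slope = np.sum((x - xbar) * (y - ybar)) / np.sum((x - xbar) ** 2)
    intercept = ybar - slope * xbar
    resid = y - (intercept + slope * x)
    ss_res = np.sum(resid**2)
    ss_tot = np.sum((y - ybar) ** 2)
    r2 = 1 - ss_res / ss_tot
    return slope, intercept, r2


def hpd_brute_force(samples, mass):
    """All ceil(mass*n)-length windows of the sorted samples; shortest wins,
    ties toward the lowest start."""
    x = sorted(samples)
    n = len(x)
    k = math.ceil(mass * n)
    best = None
    for i in range(n - k + 1):
        width = x[i + k - 1] - x[i]
        if best is None or width < best[0]:
            best = (width, x[i], x[i + k - 1])
    return best[1], best[2]


# ---------------------------------------------------------------------------
# average_node_to_tip_distance
# ---------------------------------------------------------------------------


class TestAverageNodeToTip:
    def test_cherry_mean(self):
        tree = tree_from_newick("((A:0.1,B:0.3):0.5,C:1.0);")
        node = tree.mrca({"A", "B"})
        assert average_node_to_tip_distance(tree, node) == pytest.approx(0.2)

    def test_erv_tip_excluded_from_both_sides_of_mean(self):
        tree = tree_from_newick("((A:0.1,B:0.3):0.5,C:1.0);")
        node = tree.mrca({"A", "B"})
        assert average_node_to_tip_distance(tree, node, {"B"}) == pytest.approx(0.1)

    def test_all_tips_excluded_is_an_error(self):
        tree = tree_from_newick("((A:0.1,B:0.3):0.5,C:1.0);")
        with pytest.raises(ValueError, match="excluded"):
            average_node_to_tip_distance(tree, tree.mrca({"A", "B"}), {"A", "B"})

    def test_seven_tip_nested_fixture_matches_path_enumeration(self):
        tree = tree_from_newick(
            "(((A:0.1,B:0.2):0.3,(C:0.15,(D:0.05,E:0.07):0.1):0.2):0.4,"
            "(F:0.6,G:0.9):0.1);"
        )
        # hand-enumerated node-to-tip path sums from the root
        expected = {
            "A": 0.4 + 0.3 + 0.1,
            "B": 0.4 + 0.3 + 0.2,
            "C": 0.4 + 0.2 + 0.15,
            "D": 0.4 + 0.2 + 0.1 + 0.05,
            "E": 0.4 + 0.2 + 0.1 + 0.07,
            "F": 0.1 + 0.6,
            "G": 0.1 + 0.9,
        }
        assert node_to_tip_distances(tree.root) == pytest.approx(expected)
        assert average_node_to_tip_distance(tree, tree.root) == pytest.approx(
            np.mean(list(expected.values()))
        )
        assert average_node_to_tip_distance(
            tree, tree.root, {"B", "G"}
        ) == pytest.approx(
            np.mean([v for k, v in expected.items() if k not in {"B", "G"}])
        )

    def test_adding_an_excluded_tip_never_changes_s(self):
        base = tree_from_newick("((A:0.1,B:0.3):0.5,C:1.0);")
        grown = tree_from_newick("((A:0.1,(B:0.2,X:9.9):0.1):0.5,C:1.0);")
        s_base = average_node_to_tip_distance(base, base.mrca({"A", "B"}))
        s_grown = average_node_to_tip_distance(
            grown, grown.mrca({"A", "B"}), {"X"}
        )
        assert s_grown == pytest.approx(s_base)


# ---------------------------------------------------------------------------
# fit / predict
# ---------------------------------------------------------------------------


class TestFitTDRP:
    def test_exact_square_root_curve(self):
        points = [
            CalibrationPoint("a", 1, 2),
            CalibrationPoint("b", 4, 4),
            CalibrationPoint("c", 9, 6),
        ]
        model = fit_tdrp(points)
        assert model.alpha == pytest.approx(2.0, abs=1e-9)
        assert model.beta == pytest.approx(0.5, abs=1e-9)
        assert model.adj_r2 == pytest.approx(1.0, abs=1e-9)

    def test_identity_model(self):
        points = [CalibrationPoint(str(i), s, s) for i, s in enumerate([0.5, 1, 2, 7])]
        model = fit_tdrp(points)
        assert model.alpha == pytest.approx(1.0, abs=1e-9)
        assert model.beta == pytest.approx(1.0, abs=1e-9)

    def test_nonpositive_points_rejected(self):
        with pytest.raises(ValueError):
            CalibrationPoint("bad", 0.0, 5.0)
        with pytest.raises(ValueError):
            CalibrationPoint("bad", 1.0, -2.0)

    def test_all_equal_s_is_singular(self):
        points = [CalibrationPoint(str(i), 2.0, t) for i, t in enumerate([1, 2, 3])]
        with pytest.raises(ValueError, match="singular"):
            fit_tdrp(points)

    def test_matches_normal_equations_oracle_on_noisy_points(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(3, 15))
            s = rng.uniform(0.01, 50, size=n)
            t = 3.0 * s**0.7 * rng.lognormal(0, 0.3, size=n)
            model = fit_tdrp(
                [CalibrationPoint(str(i), si, ti) for i, (si, ti) in enumerate(zip(s, t))]
            )
            slope, intercept, r2 = ols_normal_equations(np.log(s), np.log(t))
            assert model.beta == pytest.approx(slope, abs=1e-9)
            assert model.alpha == pytest.approx(math.exp(intercept), rel=1e-9)
            assert model.adj_r2 == pytest.approx(
                1 - (1 - r2) * (n - 1) / (n - 2), abs=1e-9
            )

    def test_two_point_fit_has_undefined_adj_r2(self):
        model = fit_tdrp([CalibrationPoint("a", 1, 2), CalibrationPoint("b", 4, 4)])
        assert math.isnan(model.adj_r2)


class TestPredict:
    def test_closed_form_examples(self):
        assert predict_time(TDRPModel(2, 0.5, 1.0, 3), 9) == pytest.approx(6)
        assert predict_time(TDRPModel(1, 1, 1.0, 3), 0.37) == pytest.approx(0.37)

    def test_nonpositive_s_rejected(self):
        with pytest.raises(ValueError):
            predict_time(TDRPModel(2, 0.5, 1.0, 3), 0.0)

    def test_matches_log_space_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            alpha, beta = rng.uniform(0.1, 10), rng.uniform(0.1, 2)
            s = rng.uniform(1e-3, 1e3)
            model = TDRPModel(alpha, beta, 1.0, 3)
            assert predict_time(model, s) == pytest.approx(
                math.exp(math.log(alpha) + beta * math.log(s)), rel=1e-12
            )

    def test_prediction_strictly_increasing_in_s(self):
        model = TDRPModel(3.0, 0.6, 1.0, 5)
        grid = np.linspace(0.01, 100, 500)
        preds = [predict_time(model, s) for s in grid]
        assert np.all(np.diff(preds) > 0)

    def test_perfect_fit_returns_calibration_times(self):
        points = [CalibrationPoint(str(i), s, 2 * s**0.5) for i, s in enumerate([1, 4, 9, 16])]
        model = fit_tdrp(points)
        for p in points:
            assert predict_time(model, p.s) == pytest.approx(p.t, rel=1e-9)


# ---------------------------------------------------------------------------
# HPD
# ---------------------------------------------------------------------------


class TestHPD:
    def test_degenerate_samples(self):
        assert hpd_interval([5.0] * 10) == (5.0, 5.0)

    def test_uniform_grid_lowest_start_wins(self):
        assert hpd_interval(list(range(1, 101)), 0.95) == (1.0, 95.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hpd_interval([])

    def test_matches_brute_force_on_skewed_samples(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(5, 200))
            samples = rng.lognormal(0, rng.uniform(0.2, 1.5), size=n)
            mass = float(rng.uniform(0.3, 1.0))
            assert hpd_interval(samples, mass) == pytest.approx(
                hpd_brute_force(samples, mass)
            )

    @settings(derandomize=True, max_examples=200)
    @given(
        samples=st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=1,
            max_size=60,
        ),
        mass=st.floats(min_value=0.05, max_value=1.0),
    )
    def test_any_sample_matches_brute_force(self, samples, mass):
        assert hpd_interval(samples, mass) == pytest.approx(
            hpd_brute_force(samples, mass)
        )

    def test_interval_grows_with_mass(self):
        rng = np.random.default_rng(3)
        samples = rng.gamma(2.0, 3.0, size=150)
        previous = None
        for mass in (0.3, 0.5, 0.75, 0.9, 0.95, 1.0):
            lo, hi = hpd_interval(samples, mass)
            if previous is not None:
                assert lo <= previous[0] + 1e-12 and hi >= previous[1] - 1e-12
            previous = (lo, hi)


# ---------------------------------------------------------------------------
# Posterior propagation
# ---------------------------------------------------------------------------


def _calibration_events(dataset):
    return [
        CospeciationEvent(e.event_id, e.virus_tips, e.host_tips, e.t, 1.0, "detected")
        for e in dataset.true_events
    ]


class TestDateNodesPosterior:
    def test_identical_samples_give_zero_width_hpds(self):
        ds = simulate(
            SimulationConfig(
                noise_sd=0.0, jitter_sd=0.0, switch_count=0, erv_fraction=0.0,
                ensemble_size=20, seed=8,
            )
        )
        events = _calibration_events(ds)
        queries = [QueryDef("root", frozenset(ds.virus_true.tip_labels))]
        result = date_nodes_posterior(ds.ensemble, ds.association, events, queries)
        for summary in result.model.values():
            assert summary.hpd_low == pytest.approx(summary.hpd_high)
        d = result.dates[0]
        assert d.hpd_low == pytest.approx(d.hpd_high)
        assert d.median_t == pytest.approx(ds.host.root_age, rel=1e-9)
        assert d.fraction_monophyletic == 1.0

    def test_parameter_recovery_at_small_jitter(self):
        ds = simulate(
            SimulationConfig(
                alpha=4.0, beta=0.6, noise_sd=0.01, jitter_sd=0.01,
                switch_count=0, erv_fraction=0.0, ensemble_size=100, seed=21,
            )
        )
        result = date_nodes_posterior(
            ds.ensemble, ds.association, _calibration_events(ds), []
        )
        assert result.model["alpha"].median == pytest.approx(4.0, rel=0.05)
        assert result.model["beta"].median == pytest.approx(0.6, rel=0.05)
        assert result.n_skipped == 0

    def test_erv_exclusion_makes_s_invariant_to_erv_rate(self):
        base = dict(
            noise_sd=0.02, jitter_sd=0.0, switch_count=0, erv_fraction=0.4,
            ensemble_size=5, seed=13,
        )
        results = []
        for scale in (1.0, 0.5, 0.05):
            ds = simulate(SimulationConfig(erv_rate_scale=scale, **base))
            res = date_nodes_posterior(
                ds.ensemble, ds.association, _calibration_events(ds), []
            )
            results.append({k: v.median for k, v in res.event_s.items()})
        assert results[0].keys() == results[1].keys() == results[2].keys()
        for key in results[0]:
            assert results[0][key] == pytest.approx(results[1][key], rel=1e-12)
            assert results[0][key] == pytest.approx(results[2][key], rel=1e-12)

    def test_all_erv_calibration_node_dropped_with_warning(self):
        # the (V1,V2) cherry is entirely endogenous: its point must be dropped
        from conftest import association_from_pairs

        from cophylodate.trees import PosteriorEnsemble

        virus = tree_from_newick(
            "(((V1:0.1,V2:0.12)1.0:0.2,V3:0.31)1.0:0.15,V4:0.5)1.0;"
        )
        assoc = association_from_pairs(
            [("V1", "H1"), ("V2", "H2"), ("V3", "H3"), ("V4", "H4")],
            erv=("V1", "V2"),
        )
        events = [
            CospeciationEvent("a", frozenset({"V1", "V2"}), frozenset({"H1", "H2"}), 10.0, 1.0, "detected"),
            CospeciationEvent("b", frozenset({"V1", "V2", "V3"}), frozenset({"H1", "H2", "H3"}), 30.0, 1.0, "detected"),
            CospeciationEvent("c", frozenset({"V1", "V2", "V3", "V4"}), frozenset({"H1", "H2", "H3", "H4"}), 45.0, 1.0, "detected"),
        ]
        result = date_nodes_posterior(
            PosteriorEnsemble([virus, virus.clone()]), assoc, events, []
        )
        assert "a" not in result.event_s
        assert {"b", "c"} <= set(result.event_s)
        assert any("only endogenous" in w for w in result.warnings)

    def test_excluded_events_do_not_calibrate(self):
        ds = simulate(
            SimulationConfig(
                noise_sd=0.0, jitter_sd=0.0, switch_count=0, erv_fraction=0.0,
                ensemble_size=2, seed=4,
            )
        )
        events = _calibration_events(ds)
        excluded = CospeciationEvent(
            "XVI", events[0].virus_tips, events[0].host_tips,
            events[0].t, 1.0, "excluded",
        )
        result = date_nodes_posterior(
            ds.ensemble, ds.association, [excluded] + events[1:], []
        )
        assert "XVI" not in result.event_s
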