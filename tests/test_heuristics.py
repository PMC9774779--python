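"""Closed-form selection ratios, outcome prediction, bottleneck arithmetic."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phagerange as pr
from phagerange import (
    BottleneckSpec,
    ConfigurationError,
    GrowthNumbers,
    KineticParams,
    ProtocolConfig,
    bottleneck_survival,
    measure_growth_numbers,
    parallel_descendants,
    parallel_ratios,
    predict_parallel_outcome,
    run_protocol,
    sequential_descendants,
    sequential_ratios,
    tyranny_report,
)

positive_n = st.floats(1.1, 1e6)


class TestGrowthNumbers:
    def test_nonpermissive_entries_default_to_survival(self):
        g = GrowthNumbers.canonical(100, 50, 60, 40)
        assert g.n("phiA", "B") == 1.0
        assert g.n("phiB", "A") == 1.0
        assert g.n("phiA", "A") == 100.0

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            GrowthNumbers.canonical(-1, 1, 1, 1)

    def test_missing_permissive_entry_rejected(self):
        with pytest.raises(ConfigurationError, match="missing"):
            GrowthNumbers(values={("phiA", "A"): 10.0})


class TestParallelRatios:
    def test_constructed_tie_is_neutral(self):
        g = GrowthNumbers.canonical(109, 1, 60, 50)
        assert parallel_ratios(g).specialist_A == pytest.approx(1.0)

    def test_generalist_arithmetic_advantage_at_equal_growth(self):
        # equal per-host growth, yet the generalist wins on pooled output
        g = GrowthNumbers.canonical(100, 100, 100, 100)
        r = parallel_ratios(g)
        assert r.specialist_A == pytest.approx(0.505)
        assert r.specialist_B == pytest.approx(0.505)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(n_A=positive_n, n_B=positive_n, x=positive_n, y=positive_n)
    def test_ratios_equal_pooled_descendant_ratios(self, n_A, n_B, x, y):
        g = GrowthNumbers.canonical(n_A, n_B, x, y)
        d = parallel_descendants(g)
        r = parallel_ratios(g)
        assert r.specialist_A == pytest.approx(d["phiA"] / d["phiAB"])
        assert r.specialist_B == pytest.approx(d["phiB"] / d["phiAB"])
        assert d["phiA"] == pytest.approx(n_A + 1)
        assert d["phiAB"] == pytest.approx(x + y)


class TestSequentialRatios:
    def test_specialist_neutral_when_matching_generalist_product(self):
        g = GrowthNumbers.canonical(100, 1, 10, 10)
        assert sequential_ratios(g).specialist_A == pytest.approx(1.0)

    def test_generalist_multiplicative_advantage(self):
        g = GrowthNumbers.canonical(100, 1, 60, 50)
        assert sequential_ratios(g).specialist_A == pytest.approx(100 / 3000)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(n_A=positive_n, n_B=positive_n, x=positive_n, y=positive_n)
    def test_sequential_beats_parallel_for_generalist_when_it_doubles(self, n_A, n_B, x, y):
        # the multiplicative advantage dominates the arithmetic one whenever
        # (x-1)(y-1) >= 1, i.e. the generalist at least roughly doubles on
        # each host; for x, y barely above 1 the inequality can reverse
        g = GrowthNumbers.canonical(n_A, n_B, x, y)
        if (x - 1) * (y - 1) >= 1:
            seq, par = sequential_ratios(g), parallel_ratios(g)
            assert seq.specialist_A <= par.specialist_A * (1 + 1e-9)
            assert seq.specialist_B <= par.specialist_B * (1 + 1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(n_A=positive_n, n_B=positive_n, x=positive_n, y=positive_n,
           c=st.floats(0.01, 100))
    def test_scaling_algebra(self, n_A, n_B, x, y, c):
        # sequential ratios are homogeneous of degree -1 in a joint rescale;
        # the +1 survival term breaks homogeneity for parallel
        g = GrowthNumbers.canonical(n_A, n_B, x, y)
        gc = GrowthNumbers.canonical(c * n_A, c * n_B, c * x, c * y)
        assert sequential_ratios(gc).specialist_A == pytest.approx(
            sequential_ratios(g).specialist_A / c, rel=1e-9
        )
        assert parallel_ratios(gc).specialist_A == pytest.approx(
            (c * n_A + 1) / (c * (x + y)), rel=1e-9
        )


class TestOutcomePrediction:
    def test_specialist_below_one_predicted_lost(self):
        g = GrowthNumbers.canonical(10, 200, 50, 50)  # ratio_A = 11/100 < 1
        out = predict_parallel_outcome(g)
        assert not out["phiA"]
        assert out["phiB"]
        assert out["phiAB"]  # one winning specialist does not doom it

    def test_generalist_lost_only_when_both_specialists_win(self):
        g = GrowthNumbers.canonical(300, 300, 50, 50)
        out = predict_parallel_outcome(g)
        assert out["phiA"] and out["phiB"] and not out["phiAB"]

    def test_tyranny_flagged_on_poor_host(self):
        # specialist B beats the generalist on host B (50 > 10) yet is
        # displaced by the generalist's output on the productive host A
        g = GrowthNumbers.canonical(1000, 50, 900, 10)
        rep = tyranny_report(g)
        assert rep.any_tyranny
        assert rep.tyrannized_hosts == ("B",)
        assert rep.per_host_superiority["B"]
        assert not rep.tyrannized_hosts == ("A",)


class TestMeasuredGrowthNumbers:
    def test_inert_phage_measures_unity(self):
        # zero adsorption: the B-specialist neither grows nor decays
        p = KineticParams.from_bursts(
            burst={
                ("phiA", "A"): 15.0,
                ("phiB", "B"): 15.0,
                ("phiAB", "A"): 15.0,
                ("phiAB", "B"): 15.0,
            },
            cell_growth=0.3,
            adsorption={("phiB", "B"): 0.0},
            lysis_rate=1.0,
        )
        res = run_protocol(ProtocolConfig(n_cycles=1), p)
        g = measure_growth_numbers(res, 0)
        assert g.n("phiB", "B") == pytest.approx(1.0)
        assert g.n("phiA", "A") > 1.0

    def test_values_match_stored_trajectory_endpoints(self):
        fx = pr.fixture("fig3")
        cfg = dataclasses.replace(fx.config, n_cycles=1)
        res = run_protocol(cfg, fx.params, record_trajectories=True)
        g = measure_growth_numbers(res, 0)
        for phage, host in (("phiA", "A"), ("phiAB", "B")):
            traj = res.trajectories[(0, f"host_{host}")]
            start = res.cycles[0].start_free_phage[phage]
            assert g.n(phage, host) == pytest.approx(
                traj.final.phage_density(phage) / start
            )

    @pytest.mark.parametrize(
        "generalist_bursts", [(25.0, 25.0), (5.0, 5.0), (20.0, 8.0)]
    )
    def test_ratio_sign_predicts_short_horizon_winner(self, generalist_bursts):
        # measured-N ratio from cycle 1 predicts the relative change of the
        # A-specialist vs the generalist over cycle 2 (clear-cut cases away
        # from selective ties)
        fx = pr.fixture("fig2")
        cfg = dataclasses.replace(fx.config, n_cycles=2)
        p = fx.params.with_generalist_bursts(*generalist_bursts)
        res = run_protocol(cfg, p)
        predicted = parallel_ratios(measure_growth_numbers(res, 0)).specialist_A
        c2 = res.cycles[1]
        realized = (c2.end_free_phage["phiA"] / c2.start_free_phage["phiA"]) / (
            c2.end_free_phage["phiAB"] / c2.start_free_phage["phiAB"]
        )
        assert (predicted > 1) == (realized > 1)

    def test_mixed_culture_cannot_be_decomposed(self):
        fx = pr.fixture("fig9")
        cfg = dataclasses.replace(fx.config, n_cycles=1)
        res = run_protocol(cfg, fx.params)
        with pytest.raises(ConfigurationError, match="Mixed"):
            measure_growth_numbers(res, 0)


class TestBottleneck:
    def test_no_bottleneck_is_certain_survival(self):
        spec = BottleneckSpec(
            volumes_pooled=8, volumes_used=8, n_cultures=8, n_useful_cultures=8
        )
        assert bottleneck_survival(spec) == 1.0

    def test_pool_and_placement_odds_multiply(self):
        spec = BottleneckSpec(
            volumes_pooled=10, volumes_used=5, n_cultures=10, n_useful_cultures=1
        )
        assert bottleneck_survival(spec) == pytest.approx(0.05)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            BottleneckSpec(volumes_pooled=4, volumes_used=5, n_cultures=8, n_useful_cultures=2)
        with pytest.raises(ValueError):
            BottleneckSpec(volumes_pooled=8, volumes_used=4, n_cultures=8, n_useful_cultures=9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        pooled=st.floats(1.0, 100.0),
        used_frac=st.floats(0.01, 1.0),
        delta=st.floats(0.0, 0.5),
        n=st.integers(1, 20),
        useful=st.integers(0, 20),
    )
    def test_monotone_in_volume_and_useful_cultures(self, pooled, used_frac, delta, n, useful):
        useful = min(useful, n)
        used = used_frac * pooled
        base = BottleneckSpec(pooled, used, n, useful)
        more_volume = BottleneckSpec(pooled, min(pooled, used + delta * pooled), n, useful)
        assert bottleneck_survival(more_volume) >= bottleneck_survival(base)
        if useful < n:
            more_useful = BottleneckSpec(pooled, used, n, useful + 1)
            assert bottleneck_survival(more_useful) >= bottleneck_survival(base)
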