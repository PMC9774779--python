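"""Serial-transfer orchestration: culture seeding, pooling, dilution, runs."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phagerange as pr
from phagerange import (
    CANONICAL,
    ConfigurationError,
    CultureState,
    KineticParams,
    ProtocolConfig,
    apply_dilution,
    build_cycle_cultures,
    fold_growth,
    pool_cultures,
    run_protocol,
)


def params(b_A=15.0, b_B=15.0, b_AB_A=15.0, b_AB_B=15.0, r=0.3, **kw):
    return KineticParams.from_bursts(
        burst={
            ("phiA", "A"): b_A,
            ("phiB", "B"): b_B,
            ("phiAB", "A"): b_AB_A,
            ("phiAB", "B"): b_AB_B,
        },
        cell_growth=r,
        **kw,
    )


def end_state(culture_id, host, free_phage, time=20.0):
    return CultureState.from_densities(
        free_phage=free_phage,
        cells={host: 0.0},
        hosts_present=frozenset({host}),
        time=time,
        culture_id=culture_id,
    )


class TestConfigValidation:
    def test_per_host_dilution_requires_parallel(self):
        with pytest.raises(ConfigurationError, match="parallel"):
            ProtocolConfig(presentation="sequential", dilution_mode="fixed_count_by_host")

    @pytest.mark.parametrize(
        "field,value",
        [
            ("cycle_length", 0.0),
            ("n_cycles", 0),
            ("transfer_fraction", 1.5),
            ("dilution_count", 0.0),
            ("initial_total_phage", -1.0),
        ],
    )
    def test_scalar_bounds(self, field, value):
        with pytest.raises(ConfigurationError):
            ProtocolConfig(**{field: value})


class TestBuildCultures:
    def test_parallel_one_culture_per_host_full_phage_map(self):
        incoming = {"phiA": 333.3, "phiB": 333.3, "phiAB": 333.3}
        cultures = build_cycle_cultures(ProtocolConfig(), 0, incoming)
        assert len(cultures) == 2
        for culture in cultures:
            assert len(culture.hosts_present) == 1
            host = next(iter(culture.hosts_present))
            assert culture.cell_density(host) == 1e7
            for p, v in incoming.items():
                assert culture.phage_density(p) == v
            assert np.all(culture.infected == 0)

    def test_sequential_hosts_alternate(self):
        cfg = ProtocolConfig(presentation="sequential")
        hosts = [
            next(iter(build_cycle_cultures(cfg, c, {"phiA": 1.0})[0].hosts_present))
            for c in range(3)
        ]
        assert hosts == ["A", "B", "A"]

    def test_sequential_first_host_configurable(self):
        cfg = ProtocolConfig(presentation="sequential", sequential_first_host="B")
        hosts = [
            next(iter(build_cycle_cultures(cfg, c, {"phiA": 1.0})[0].hosts_present))
            for c in range(2)
        ]
        assert hosts == ["B", "A"]

    def test_mixed_single_culture_both_hosts(self):
        cultures = build_cycle_cultures(ProtocolConfig(presentation="mixed"), 3, {"phiA": 10.0})
        assert len(cultures) == 1
        assert cultures[0].cell_density("A") == 1e7
        assert cultures[0].cell_density("B") == 1e7


class TestPooling:
    def test_single_culture_pools_to_itself(self):
        s = end_state("c", "A", {"phiA": 123.0, "phiB": 0.0, "phiAB": 7.0})
        assert pool_cultures([s]) == {"phiA": 123.0, "phiB": 0.0, "phiAB": 7.0}

    def test_equal_volume_pooling_sums_densities(self):
        a = end_state("host_A", "A", {"phiA": 2e8})
        b = end_state("host_B", "B", {"phiA": 1000.0})
        assert pool_cultures([a, b])["phiA"] == pytest.approx(2e8 + 1000.0)

    def test_specialist_survival_term_in_pooled_fold(self):
        # growth factor 100 on the permissive host, 1 (survival) on the other:
        # pooled descendants per phage = 100 + 1
        start = 1000.0
        a = end_state("host_A", "A", {"phiA": start * 100})
        b = end_state("host_B", "B", {"phiA": start * 1})
        assert pool_cultures([a, b])["phiA"] / start == pytest.approx(101.0)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pool_cultures([])

    def test_mismatched_end_times_rejected(self):
        a = end_state("x", "A", {"phiA": 1.0}, time=20.0)
        b = end_state("y", "B", {"phiA": 1.0}, time=40.0)
        with pytest.raises(ValueError, match="end time"):
            pool_cultures([a, b])


class TestDilution:
    def test_fixed_count_pool_already_at_target_unchanged(self):
        pool = {"phiA": 800.0, "phiB": 150.0, "phiAB": 50.0}
        out = apply_dilution(pool, None, ProtocolConfig())
        assert out.densities == pytest.approx(pool)
        assert not out.extinct

    def test_fixed_volume_transfers_five_percent(self):
        cfg = ProtocolConfig(dilution_mode="fixed_volume")
        out = apply_dilution({"phiA": 1e6}, None, cfg)
        assert sum(out.densities.values()) == pytest.approx(5e4)

    def test_fixed_count_from_a_million_is_thousandfold(self):
        out = apply_dilution({"phiA": 6e5, "phiAB": 4e5}, None, ProtocolConfig())
        assert out.densities["phiA"] == pytest.approx(600.0)
        assert out.densities["phiAB"] == pytest.approx(400.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1e12), min_size=2, max_size=4))
    def test_fixed_count_preserves_ratios_and_hits_target(self, values):
        pool = {f"p{i}": v for i, v in enumerate(values)}
        out = apply_dilution(pool, None, ProtocolConfig()).densities
        assert sum(out.values()) == pytest.approx(1000.0, rel=1e-12)
        keys = list(pool)
        for k1, k2 in zip(keys, keys[1:]):
            if pool[k2] > 0:
                assert out[k1] / out[k2] == pytest.approx(pool[k1] / pool[k2], rel=1e-12)

    def test_per_host_dilution_rescales_each_culture_then_combines(self):
        cfg = ProtocolConfig(dilution_mode="fixed_count_by_host")
        per_culture = {
            "host_A": {"phiA": 9e6, "phiB": 1e6},  # rescaled to 900 + 100
            "host_B": {"phiA": 1e3, "phiB": 3e3},  # rescaled to 250 + 750
        }
        pooled = {"phiA": 9e6 + 1e3, "phiB": 1e6 + 3e3}
        out = apply_dilution(pooled, per_culture, cfg)
        assert out.densities["phiA"] == pytest.approx(900.0 + 250.0)
        assert out.densities["phiB"] == pytest.approx(100.0 + 750.0)
        assert sum(out.densities.values()) == pytest.approx(2 * cfg.dilution_count)

    def test_per_host_dilution_requires_per_culture_pools(self):
        cfg = ProtocolConfig(dilution_mode="fixed_count_by_host")
        with pytest.raises(ConfigurationError, match="per-culture"):
            apply_dilution({"phiA": 1.0}, None, cfg)

    def test_zero_pool_flags_extinction_without_dividing(self):
        out = apply_dilution({"phiA": 0.0, "phiB": 0.0}, None, ProtocolConfig())
        assert out.extinct
        assert all(v == 0 for v in out.densities.values())


class TestRunProtocol:
    def test_symmetric_specialists_without_generalist_tie(self):
        # generalist with zero bursts produces nothing: pure phiA-vs-phiB
        # symmetry, so their final frequencies must be equal
        p = params(b_A=15.0, b_B=15.0).with_generalist_bursts(0.0, 0.0)
        cfg = ProtocolConfig(n_cycles=10)
        res = run_protocol(cfg, p)
        assert res.final_frequencies["phiA"] == pytest.approx(
            res.final_frequencies["phiB"], rel=1e-9
        )
        assert res.final_frequencies["phiAB"] < 1e-6

    def test_cycle_records_are_complete_and_ordered(self, fig5B_run):
        res = fig5B_run
        assert len(res.cycles) == res.config.n_cycles
        assert [c.cycle_index for c in res.cycles] == list(range(res.config.n_cycles))
        assert sum(res.final_frequencies.values()) == pytest.approx(1.0)

    def test_fold_growth_accessor(self, fig5B_run):
        rec = fig5B_run.cycles[-1]
        assert fold_growth(rec) == pytest.approx(rec.fold_growth_total)

    def test_fold_growth_undefined_for_empty_start(self):
        rec = dataclasses.replace(
            dataclasses.replace(fig_record()), start_free_phage={"phiA": 0.0}
        )
        with pytest.raises(ValueError, match="undefined"):
            fold_growth(rec)

    def test_fixed_volume_steady_state_fold_is_inverse_transfer_fraction(self, fig6_run):
        # at a quasi-steady state, growth must exactly offset the 5% transfer
        late = [c.fold_growth_total for c in fig6_run.cycles[-5:]]
        for f in late:
            assert f == pytest.approx(1 / fig6_run.config.transfer_fraction, rel=1e-6)

    def test_nongrowing_phages_diluted_to_extinction(self):
        # bursts below one cannot offset a 5% volume transfer
        p = params(b_A=0.5, b_B=0.5, b_AB_A=0.5, b_AB_B=0.5, r=0.1)
        cfg = ProtocolConfig(dilution_mode="fixed_volume", n_cycles=45)
        res = run_protocol(cfg, p)
        assert res.extinct
        assert res.final_total_phage == 0.0

    def test_carry_infected_runs_and_changes_little(self):
        p = params(b_A=20.0, b_B=10.0, b_AB_A=17.0, b_AB_B=17.0, r=0.3)
        base = ProtocolConfig(n_cycles=5)
        res_a = run_protocol(base, p)
        res_b = run_protocol(dataclasses.replace(base, carry_infected=True), p)
        for phage in CANONICAL.phage_ids:
            fa, fb = res_a.final_frequencies[phage], res_b.final_frequencies[phage]
            assert fa == pytest.approx(fb, abs=0.05)


def fig_record():
    return pr.CycleRecord(
        cycle_index=0,
        host_schedule={"host_A": ("A",)},
        start_free_phage={"phiA": 1000.0},
        end_free_phage={"phiA": 1000.0},
        per_culture_end={"host_A": {"phiA": 1000.0}},
        end_cells={"A": 0.0},
        fold_growth_total=1.0,
    )
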