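"""Shared fixtures: cached simulation results reused across test modules.

The expensive objects are full serial-transfer runs and burst-size sweeps;
they are deterministic, so a single session-scoped instance serves every
test that needs them.
"""

from __future__ import annotations

import pytest

import phagerange as pr
from phagerange.sweep import SweepConfig, run_sweep

#: coarse burst-size axis used for qualitative regime sweeps
GRID5 = (5.0, 10.0, 15.0, 20.0, 25.0)
#: 11-point axis (5..25 step 2) used for the retained-fraction measurement
GRID11 = tuple(float(b) for b in range(5, 26, 2))


def coarse_sweep(scenario: str, grid: tuple[float, ...] = GRID5) -> "pr.GridResult":
    fx = pr.fixture(scenario)
    cfg = SweepConfig(
        base_protocol=fx.config, base_params=fx.params, grid_A=grid, grid_B=grid
    )
    return run_sweep(cfg)


@pytest.fixture(scope="session")
def grid5_sweeps() -> dict[str, "pr.GridResult"]:
    """5x5 generalist burst-size sweeps of the qualitative-regime scenarios."""
    return {name: coarse_sweep(name) for name in ("fig3", "fig4", "fig7", "fig8", "fig9")}


@pytest.fixture(scope="session")
def fig2_grid11() -> "pr.GridResult":
    """11x11 sweep of the symmetric-specialist baseline scenario."""
    return coarse_sweep("fig2", GRID11)


def run_with_generalist(scenario: str, burst_A: float, burst_B: float) -> "pr.RunResult":
    fx = pr.fixture(scenario)
    params = fx.params.with_generalist_bursts(burst_A, burst_B)
    return pr.run_protocol(fx.config, params)


@pytest.fixture(scope="session")
def fig5A_run() -> "pr.RunResult":
    """Low bacterial growth (r=0.1), fixed-count dilution, generalist 17/17."""
    fx = pr.fixture("fig5A")
    return pr.run_protocol(fx.config, fx.params)


@pytest.fixture(scope="session")
def fig5B_run() -> "pr.RunResult":
    """High bacterial growth (r=0.3), fixed-count dilution, generalist 17/17."""
    fx = pr.fixture("fig5B")
    return pr.run_protocol(fx.config, fx.params)


@pytest.fixture(scope="session")
def fig6_run() -> "pr.RunResult":
    """Fixed-volume 5% dilution, r=0.1, generalist 17/17."""
    return run_with_generalist("fig6", 17.0, 17.0)
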