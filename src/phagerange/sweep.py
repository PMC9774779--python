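"""Burst-size sweeps over the generalist's two burst sizes.

For a fixed protocol and fixed specialist burst sizes, the sweep runs one
serial-transfer simulation per point of a (b_AB|A, b_AB|B) grid and records
each phage's final frequency, a retention classification (frequency at or
above a small threshold), the final total phage density and an extinction
flag.  The result is the data behind a heat map of phage fate across
generalist burst sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import EULER_DEFAULT, IntegrationError, SolverSettings
from .protocols import ProtocolConfig, run_protocol
from .strains import ConfigurationError, KineticParams

__all__ = [
    "SweepConfig",
    "GridPoint",
    "GridResult",
    "run_sweep",
    "classify_retention",
    "fraction_retained",
    "DEFAULT_GRID",
]

#: Default burst-size axis: the standard range 5..25 in steps of 1.
DEFAULT_GRID: tuple[float, ...] = tuple(float(b) for b in range(5, 26))


@dataclass(frozen=True)
class SweepConfig:
    """A burst-size grid over the generalist for a fixed protocol."""

    base_protocol: ProtocolConfig
    base_params: KineticParams
    grid_A: tuple[float, ...] = DEFAULT_GRID
    grid_B: tuple[float, ...] = DEFAULT_GRID
    retention_threshold: float = 0.01
    generalist: str = "phiAB"

    def __post_init__(self) -> None:
        for name, grid in (("grid_A", self.grid_A), ("grid_B", self.grid_B)):
            grid = tuple(float(g) for g in grid)
            object.__setattr__(self, name, grid)
            if not grid:
                raise ConfigurationError(f"{name} is empty")
            if any(b2 <= b1 for b1, b2 in zip(grid, grid[1:])):
                raise ConfigurationError(f"{name} must be strictly increasing")
        if not (0 < self.retention_threshold < 1):
            raise ConfigurationError("retention_threshold must be in (0, 1)")


@dataclass
class GridPoint:
    """Outcome of one sweep grid point."""

    burst_A: float
    burst_B: float
    frequencies: dict[str, float]
    retained: dict[str, bool]
    total_phage: float
    extinct: bool
    error: str | None = None


@dataclass
class GridResult:
    """All grid points of one sweep, in row-major (grid_A outer) order."""

    config: SweepConfig
    points: list[GridPoint] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table, one row per grid point."""
        phages = self.config.base_params.strains.phage_ids
        rows = []
        for pt in self.points:
            row: dict[str, object] = {"b_AB_A": pt.burst_A, "b_AB_B": pt.burst_B}
            for p in phages:
                row[f"freq_{p}"] = pt.frequencies.get(p, np.nan)
            for p in phages:
                row[f"retained_{p}"] = bool(pt.retained.get(p, False))
            row["total_phage"] = pt.total_phage
            row["extinct"] = pt.extinct
            row["error"] = pt.error if pt.error is not None else ""
            rows.append(row)
        return pd.DataFrame(rows)

    def frequency_matrix(self, phage: str) -> np.ndarray:
        """Final-frequency matrix shaped (len(grid_A), len(grid_B))."""
        nA, nB = len(self.config.grid_A), len(self.config.grid_B)
        out = np.full((nA, nB), np.nan)
        for idx, pt in enumerate(self.points):
            out[idx // nB, idx % nB] = pt.frequencies.get(phage, np.nan)
        return out


def classify_retention(
    frequencies: dict[str, float], threshold: float
) -> dict[str, bool]:
    """Classify each phage as retained (True) or lost (False).

    A phage is retained when its final frequency is at or above the
    threshold.  The threshold stands in for the detection floor of a
    heat-map colour scale; classifications are insensitive to its exact
    value over a wide range.
    """
    return {p: f >= threshold for p, f in frequencies.items()}


def run_sweep(
    config: SweepConfig, solver: SolverSettings = EULER_DEFAULT
) -> GridResult:
    """Run one protocol simulation per grid point.

    The generalist's burst sizes are substituted point by point; everything
    else is fixed.  The sweep is deterministic and its outcome independent
    of evaluation order.  An integration failure at one point is recorded in
    that point's ``error`` field without aborting the sweep.
    """
    result = GridResult(config=config)
    phages = config.base_params.strains.phage_ids
    for bA in config.grid_A:
        for bB in config.grid_B:
            params = config.base_params.with_generalist_bursts(
                bA, bB, generalist=config.generalist
            )
            try:
                run = run_protocol(config.base_protocol, params, solver)
            except (IntegrationError, FloatingPointError) as exc:
                result.points.append(
                    GridPoint(
                        burst_A=bA,
                        burst_B=bB,
                        frequencies={p: np.nan for p in phages},
                        retained={p: False for p in phages},
                        total_phage=np.nan,
                        extinct=False,
                        error=str(exc),
                    )
                )
                continue
            result.points.append(
                GridPoint(
                    burst_A=bA,
                    burst_B=bB,
                    frequencies=run.final_frequencies,
                    retained=classify_retention(
                        run.final_frequencies, config.retention_threshold
                    ),
                    total_phage=run.final_total_phage,
                    extinct=run.extinct,
                )
            )
    return result


def fraction_retained(grid: GridResult, phage: str) -> float:
    """Fraction of grid points at which ``phage`` is classified retained."""
    if not grid.points:
        raise ValueError("empty grid")
    kept = sum(1 for pt in grid.points if pt.retained.get(phage, False))
    return kept / len(grid.points)
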