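"""Serial-transfer protocols: grow, pool, dilute, repeat.

A protocol run alternates a within-culture growth phase (integrated by
:mod:`phagerange.dynamics`) with a sampling/dilution/transfer step, for a
fixed number of cycles.  Protocols differ along two axes:

* **Host presentation** — how the hosts are offered to the phage pool each
  cycle.  *Parallel*: one culture per host, all phages seeded into each, free
  phage pooled at cycle's end.  *Sequential*: a single culture whose host
  alternates between cycles.  *Mixed*: a single culture containing both
  hosts.

* **Dilution** — how the pooled phage is reduced before the next cycle.
  *fixed_count*: the pool is rescaled so its total density equals a set
  target (1000 by default), preserving proportions.  *fixed_volume*: a set
  fraction (5% by default) of every density is transferred.
  *fixed_count_by_host* (parallel only): each host culture's phage pool is
  rescaled to the target separately before the pools are combined, which
  protects phages growing on a poor host from being diluted away by growth
  on the good host.

Cells are renewed at a fixed density every cycle; infected cells are
discarded at transfer by default (mimicking recovery of cell-free phage
lysate), optionally carried over at the same dilution as free phage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, NamedTuple, Sequence

import numpy as np

from .dynamics import (
    EULER_DEFAULT,
    CultureState,
    IntegrationError,
    SolverSettings,
    Trajectory,
    integrate_culture,
)
from .strains import CANONICAL, ConfigurationError, KineticParams, StrainSet

__all__ = [
    "ProtocolConfig",
    "CycleRecord",
    "RunResult",
    "DilutionResult",
    "build_cycle_cultures",
    "pool_cultures",
    "apply_dilution",
    "run_protocol",
    "fold_growth",
]

Presentation = Literal["parallel", "sequential", "mixed"]
DilutionMode = Literal["fixed_count", "fixed_volume", "fixed_count_by_host"]

_PRESENTATIONS = ("parallel", "sequential", "mixed")
_DILUTION_MODES = ("fixed_count", "fixed_volume", "fixed_count_by_host")


@dataclass(frozen=True)
class ProtocolConfig:
    """Configuration of one serial-transfer experiment.

    Defaults follow the standard conditions: 20-time-unit cycles, 50 cycles,
    cell renewal at 1e7 per host, fixed-count dilution to total density 1000,
    total starting phage 1000 split equally among the phages.
    """

    presentation: Presentation = "parallel"
    dilution_mode: DilutionMode = "fixed_count"
    cycle_length: float = 20.0
    n_cycles: int = 50
    cell_renewal_density: float = 1e7
    dilution_count: float = 1000.0
    transfer_fraction: float = 0.05
    carry_infected: bool = False
    initial_total_phage: float = 1000.0
    sequential_first_host: str = "A"
    extinction_floor: float = 1e-30

    def __post_init__(self) -> None:
        if self.presentation not in _PRESENTATIONS:
            raise ConfigurationError(f"unknown presentation {self.presentation!r}")
        if self.dilution_mode not in _DILUTION_MODES:
            raise ConfigurationError(f"unknown dilution_mode {self.dilution_mode!r}")
        if self.dilution_mode == "fixed_count_by_host" and self.presentation != "parallel":
            raise ConfigurationError("fixed_count_by_host dilution requires parallel presentation")
        if self.cycle_length <= 0:
            raise ConfigurationError("cycle_length must be positive")
        if self.n_cycles < 1:
            raise ConfigurationError("n_cycles must be at least 1")
        if not (0 < self.transfer_fraction <= 1):
            raise ConfigurationError("transfer_fraction must be in (0, 1]")
        if self.dilution_count <= 0:
            raise ConfigurationError("dilution_count must be positive")
        if self.cell_renewal_density <= 0:
            raise ConfigurationError("cell_renewal_density must be positive")
        if self.initial_total_phage <= 0:
            raise ConfigurationError("initial_total_phage must be positive")
        if self.extinction_floor < 0:
            raise ConfigurationError("extinction_floor must be non-negative")


@dataclass
class CycleRecord:
    """Per-cycle bookkeeping.

    ``start_free_phage`` is the post-dilution density map seeded into every
    culture of the cycle; ``end_free_phage`` is the pooled pre-dilution map
    at cycle's end.  ``per_culture_end`` keeps each culture's own end
    densities (needed for per-host growth numbers and per-host dilution).
    """

    cycle_index: int
    host_schedule: dict[str, tuple[str, ...]]  # culture_id -> hosts in it
    start_free_phage: dict[str, float]
    end_free_phage: dict[str, float]
    per_culture_end: dict[str, dict[str, float]]
    end_cells: dict[str, float]
    fold_growth_total: float


class DilutionResult(NamedTuple):
    """Post-dilution density map plus an extinction flag."""

    densities: dict[str, float]
    extinct: bool


@dataclass
class RunResult:
    """Outcome of a full serial-transfer run."""

    config: ProtocolConfig
    params: KineticParams
    cycles: list[CycleRecord]
    final_frequencies: dict[str, float]
    final_total_phage: float
    extinct: bool = False
    trajectories: dict[tuple[int, str], Trajectory] = field(default_factory=dict)

    @property
    def strains(self) -> StrainSet:
        return self.params.strains


def _sequential_host(config: ProtocolConfig, strains: StrainSet, cycle_index: int) -> str:
    hosts = list(strains.host_ids)
    if config.sequential_first_host not in hosts:
        raise ConfigurationError(
            f"sequential_first_host {config.sequential_first_host!r} not among hosts {hosts}"
        )
    start = hosts.index(config.sequential_first_host)
    order = hosts[start:] + hosts[:start]
    return order[cycle_index % len(order)]


def build_cycle_cultures(
    config: ProtocolConfig,
    cycle_index: int,
    incoming_phage: Mapping[str, float],
    strains: StrainSet = CANONICAL,
    carried_infected: Mapping[str, np.ndarray] | None = None,
) -> list[CultureState]:
    """Seed the culture(s) for one cycle from the incoming phage pool.

    Parallel presentation builds one culture per host, each receiving the
    full incoming phage density map and fresh cells at the renewal density.
    Sequential builds a single culture whose host alternates each cycle;
    Mixed builds a single culture with every host at the renewal density.
    ``carried_infected`` maps host id to an infected-density vector (indexed
    by phage) to seed into whichever culture contains that host.
    """
    if any(v < 0 for v in incoming_phage.values()):
        raise ValueError("incoming phage densities must be non-negative")
    t0 = cycle_index * config.cycle_length
    renewal = config.cell_renewal_density
    if config.presentation == "parallel":
        host_sets = [(f"host_{h}", (h,)) for h in strains.host_ids]
    elif config.presentation == "sequential":
        host_sets = [("culture", (_sequential_host(config, strains, cycle_index),))]
    else:  # mixed
        host_sets = [("culture", tuple(strains.host_ids))]
    cultures = []
    for culture_id, hosts in host_sets:
        infected: dict[tuple[str, str], float] = {}
        if carried_infected:
            for host in hosts:
                vec = carried_infected.get(host)
                if vec is not None:
                    for i, phage in enumerate(strains.phage_ids):
                        if vec[i] > 0:
                            infected[(phage, host)] = float(vec[i])
        cultures.append(
            CultureState.from_densities(
                free_phage=dict(incoming_phage),
                cells={h: renewal for h in hosts},
                strains=strains,
                infected=infected,
                hosts_present=frozenset(hosts),
                time=t0,
                culture_id=culture_id,
            )
        )
    return cultures


def pool_cultures(cultures: Sequence[CultureState]) -> dict[str, float]:
    """Pool end-of-cycle free phage across equal-volume cultures.

    Equal-volume pooling sums densities: a phage's pooled density is the sum
    of its free-phage densities over all cultures.  Infected compartments
    are not pooled here (they are discarded, or carried separately when the
    protocol retains them).
    """
    if not cultures:
        raise ValueError("cannot pool an empty set of cultures")
    strains = cultures[0].strains
    end_time = cultures[0].time
    for c in cultures[1:]:
        if c.strains != strains:
            raise ValueError("cultures use different strain sets")
        if abs(c.time - end_time) > 1e-9 * max(1.0, abs(end_time)):
            raise ValueError("cultures are not at the same end time")
    pooled = np.zeros(strains.n_phages)
    for c in cultures:
        pooled += c.free_phage
    return {p: float(v) for p, v in zip(strains.phage_ids, pooled)}


def apply_dilution(
    pooled: Mapping[str, float],
    per_culture_pools: Mapping[str, Mapping[str, float]] | None,
    config: ProtocolConfig,
) -> DilutionResult:
    """Dilute the pooled phage for transfer into the next cycle.

    ``fixed_count`` rescales the pool so its total equals
    ``config.dilution_count``, preserving relative proportions exactly.
    ``fixed_volume`` multiplies every density by ``config.transfer_fraction``.
    ``fixed_count_by_host`` rescales each culture's pool to the target total
    separately and then sums across cultures (so the combined seed totals
    n_cultures x dilution_count).  A pool with zero total phage comes back
    all-zero with the extinction flag set.
    """
    if any(v < 0 for v in pooled.values()):
        raise ValueError("pooled densities must be non-negative")
    if config.dilution_mode == "fixed_count_by_host":
        if per_culture_pools is None:
            raise ConfigurationError("fixed_count_by_host dilution needs per-culture pools")
        out = {p: 0.0 for p in pooled}
        any_phage = False
        for pool in per_culture_pools.values():
            total = sum(pool.values())
            if total <= 0:
                continue
            any_phage = True
            scale = config.dilution_count / total
            for p, v in pool.items():
                out[p] += v * scale
        return DilutionResult(out, extinct=not any_phage)
    total = sum(pooled.values())
    if config.dilution_mode == "fixed_count":
        if total <= 0:
            return DilutionResult({p: 0.0 for p in pooled}, extinct=True)
        scale = config.dilution_count / total
        return DilutionResult({p: v * scale for p, v in pooled.items()}, extinct=False)
    # fixed_volume
    out = {p: v * config.transfer_fraction for p, v in pooled.items()}
    return DilutionResult(out, extinct=total <= 0)


def fold_growth(record: CycleRecord) -> float:
    """Total end-of-cycle free phage divided by the total at cycle start."""
    start = sum(record.start_free_phage.values())
    if start <= 0:
        raise ValueError(f"fold growth undefined: cycle {record.cycle_index} started with no phage")
    return sum(record.end_free_phage.values()) / start


def _dilution_scale_factors(
    pooled_total: float,
    per_culture_pools: Mapping[str, Mapping[str, float]],
    config: ProtocolConfig,
) -> dict[str, float]:
    """Per-culture dilution factor applied to carried-over infected cells."""
    factors: dict[str, float] = {}
    for culture_id, pool in per_culture_pools.items():
        if config.dilution_mode == "fixed_volume":
            factors[culture_id] = config.transfer_fraction
        elif config.dilution_mode == "fixed_count":
            factors[culture_id] = config.dilution_count / pooled_total if pooled_total > 0 else 0.0
        else:  # fixed_count_by_host
            total = sum(pool.values())
            factors[culture_id] = config.dilution_count / total if total > 0 else 0.0
    return factors


def run_protocol(
    config: ProtocolConfig,
    params: KineticParams,
    solver: SolverSettings = EULER_DEFAULT,
    record_trajectories: bool = False,
) -> RunResult:
    """Execute a full serial-transfer run.

    The initial pool splits ``config.initial_total_phage`` equally among the
    phages.  Each cycle builds cultures per the presentation mode, integrates
    them for ``cycle_length``, pools the free phage, records the cycle, and
    dilutes into the next cycle.  Final frequencies are taken from the pooled
    free phage at the end of the last growth phase, before the final
    dilution.  Densities below ``config.extinction_floor`` are zeroed after
    each dilution; a pool reaching zero total sets the ``extinct`` flag (the
    run continues, all subsequent densities remaining zero).
    """
    strains = params.strains
    n = strains.n_phages
    incoming = {p: config.initial_total_phage / n for p in strains.phage_ids}
    carried: dict[str, np.ndarray] | None = None
    cycles: list[CycleRecord] = []
    trajectories: dict[tuple[int, str], Trajectory] = {}
    extinct = False
    for cycle_index in range(config.n_cycles):
        cultures = build_cycle_cultures(config, cycle_index, incoming, strains, carried)
        finals: list[CultureState] = []
        for culture in cultures:
            try:
                traj = integrate_culture(culture, params, config.cycle_length, solver)
            except IntegrationError as exc:
                raise IntegrationError(
                    f"cycle {cycle_index}, culture {culture.culture_id!r}: {exc}"
                ) from exc
            finals.append(traj.final)
            if record_trajectories:
                trajectories[(cycle_index, culture.culture_id)] = traj
        pooled = pool_cultures(finals)
        per_culture_end = {s.culture_id: s.free_phage_map() for s in finals}
        start_total = sum(incoming.values())
        pooled_total = sum(pooled.values())
        record = CycleRecord(
            cycle_index=cycle_index,
            host_schedule={s.culture_id: tuple(sorted(s.hosts_present)) for s in finals},
            start_free_phage=dict(incoming),
            end_free_phage=pooled,
            per_culture_end=per_culture_end,
            end_cells={
                h: float(sum(s.cell_density(h) for s in finals)) for h in strains.host_ids
            },
            fold_growth_total=pooled_total / start_total if start_total > 0 else 0.0,
        )
        cycles.append(record)
        diluted = apply_dilution(pooled, per_culture_end, config)
        extinct = extinct or diluted.extinct
        incoming = {
            p: (0.0 if v < config.extinction_floor else v) for p, v in diluted.densities.items()
        }
        if config.carry_infected:
            factors = _dilution_scale_factors(pooled_total, per_culture_end, config)
            carried = {}
            for state in finals:
                f = factors[state.culture_id]
                for host in state.hosts_present:
                    j = strains.host_index(host)
                    vec = state.infected[:, j] * f
                    vec[vec < config.extinction_floor] = 0.0
                    carried[host] = carried.get(host, 0.0) + vec
    last = cycles[-1]
    final_total = sum(last.end_free_phage.values())
    if final_total > 0:
        final_frequencies = {p: v / final_total for p, v in last.end_free_phage.items()}
    else:
        final_frequencies = {p: 0.0 for p in strains.phage_ids}
    return RunResult(
        config=config,
        params=params,
        cycles=cycles,
        final_frequencies=final_frequencies,
        final_total_phage=final_total,
        extinct=extinct,
        trajectories=trajectories,
    )
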