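"""Within-culture infection dynamics for lytic phages on exponentially
growing bacteria.

The model tracks, in a single well-mixed culture, the density ``P_i`` of each
free phage strain, the density ``I_ij`` of host-``j`` cells infected by phage
``i``, and the density ``C_j`` of uninfected host-``j`` cells:

    dP_i/dt = sum_j ( b_ij * lambda_ij * I_ij  -  k_ij * P_i * C_j )
    dI_ij/dt = k_ij * P_i * C_j  -  lambda_ij * I_ij
    dC_j/dt  = r_j * C_j  -  sum_i k_ij * P_i * C_j

Adsorption removes a free phage and creates an infected cell term by term;
lysis destroys an infected cell and releases ``b`` progeny.  Bacteria grow
exponentially (no resource limitation) and are lost only to infection.  The
sums run over the hosts actually present in the culture: host-presentation
protocols differ precisely in which hosts share a culture.

Two integrators are provided: a fixed-step explicit Euler method (step 0.001
by default), and an adaptive high-accuracy method (LSODA) used as an
independent reference.  Endpoints from the two agree to well under 1%
relative error across the standard parameter ranges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Literal, Mapping

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from ._euler import CLAMP_REL, NEGATIVE, NONFINITE, OK, euler_advance
from .strains import CANONICAL, ConfigurationError, KineticParams, StrainSet

__all__ = [
    "CultureState",
    "CultureDerivatives",
    "SolverSettings",
    "Trajectory",
    "IntegrationError",
    "derivatives",
    "integrate_culture",
    "exponential_invasion_rate",
    "EULER_DEFAULT",
    "ADAPTIVE_REFERENCE",
]


class IntegrationError(RuntimeError):
    """Integration failed (non-finite state or negative density undershoot)."""


@dataclass
class CultureState:
    """Instantaneous densities in one culture.

    ``free_phage`` is indexed by phage, ``infected`` by (phage, host) and
    ``cells`` by host, following the orderings in ``strains``.
    ``hosts_present`` lists the hosts stocked in this culture; absent hosts
    carry zero cells and zero infected cells by invariant.
    """

    strains: StrainSet
    time: float
    free_phage: np.ndarray
    infected: np.ndarray
    cells: np.ndarray
    hosts_present: frozenset[str]
    culture_id: str = ""

    def __post_init__(self) -> None:
        self.free_phage = np.asarray(self.free_phage, dtype=float)
        self.infected = np.asarray(self.infected, dtype=float)
        self.cells = np.asarray(self.cells, dtype=float)
        self.hosts_present = frozenset(self.hosts_present)

    @classmethod
    def from_densities(
        cls,
        free_phage: Mapping[str, float],
        cells: Mapping[str, float],
        strains: StrainSet = CANONICAL,
        infected: Mapping[tuple[str, str], float] | None = None,
        hosts_present: frozenset[str] | None = None,
        time: float = 0.0,
        culture_id: str = "",
    ) -> "CultureState":
        """Build a state from density maps; unmentioned entries are zero."""
        P = np.zeros(strains.n_phages)
        for phage, dens in free_phage.items():
            P[strains.phage_index(phage)] = dens
        C = np.zeros(strains.n_hosts)
        for host, dens in cells.items():
            C[strains.host_index(host)] = dens
        I = np.zeros((strains.n_phages, strains.n_hosts))
        for (phage, host), dens in (infected or {}).items():
            I[strains.phage_index(phage), strains.host_index(host)] = dens
        if hosts_present is None:
            hosts_present = frozenset(h for h in cells if cells[h] > 0)
        return cls(
            strains=strains,
            time=time,
            free_phage=P,
            infected=I,
            cells=C,
            hosts_present=frozenset(hosts_present),
            culture_id=culture_id,
        )

    # -- accessors ---------------------------------------------------------
    def phage_density(self, phage: str) -> float:
        return float(self.free_phage[self.strains.phage_index(phage)])

    def infected_density(self, phage: str, host: str) -> float:
        return float(
            self.infected[self.strains.phage_index(phage), self.strains.host_index(host)]
        )

    def cell_density(self, host: str) -> float:
        return float(self.cells[self.strains.host_index(host)])

    def total_free_phage(self) -> float:
        return float(self.free_phage.sum())

    def free_phage_map(self) -> dict[str, float]:
        return {p: float(v) for p, v in zip(self.strains.phage_ids, self.free_phage)}

    def validate(self) -> None:
        """Raise if any state invariant is violated."""
        if np.any(self.free_phage < 0) or np.any(self.infected < 0) or np.any(self.cells < 0):
            raise ValueError("densities must be non-negative")
        perm = self.strains.permissivity_matrix()
        if np.any(self.infected[~perm] != 0):
            raise ValueError("infected density on a non-permissive (phage, host) pair")
        for j, host in enumerate(self.strains.host_ids):
            if host not in self.hosts_present:
                if self.cells[j] != 0 or np.any(self.infected[:, j] != 0):
                    raise ValueError(f"host {host!r} absent but carries cells or infections")

    def copy(self) -> "CultureState":
        return CultureState(
            strains=self.strains,
            time=self.time,
            free_phage=self.free_phage.copy(),
            infected=self.infected.copy(),
            cells=self.cells.copy(),
            hosts_present=self.hosts_present,
            culture_id=self.culture_id,
        )


@dataclass
class CultureDerivatives:
    """Rates of change of a :class:`CultureState` (same array layout)."""

    strains: StrainSet
    d_free_phage: np.ndarray
    d_infected: np.ndarray
    d_cells: np.ndarray

    def phage_rate(self, phage: str) -> float:
        return float(self.d_free_phage[self.strains.phage_index(phage)])

    def infected_rate(self, phage: str, host: str) -> float:
        return float(
            self.d_infected[self.strains.phage_index(phage), self.strains.host_index(host)]
        )

    def cell_rate(self, host: str) -> float:
        return float(self.d_cells[self.strains.host_index(host)])


def _check_compatible(state: CultureState, params: KineticParams) -> None:
    if state.strains != params.strains:
        raise ConfigurationError("state and params use different strain sets")
    for phage, host in state.strains.permissive_pairs():
        if host not in state.hosts_present:
            continue
        i = state.strains.phage_index(phage)
        j = state.strains.host_index(host)
        if not (
            np.isfinite(params.burst[i, j])
            and np.isfinite(params.lysis_rate[i, j])
            and np.isfinite(params.adsorption[i, j])
        ):
            raise ConfigurationError(f"undefined kinetic parameter for pair ({phage!r}, {host!r})")


def derivatives(state: CultureState, params: KineticParams) -> CultureDerivatives:
    """Evaluate the infection ODE right-hand side at ``state``.

    The adsorption flux ``k_ij * P_i * C_j`` appears with opposite signs in
    the free-phage and infected-cell equations, so free-phage loss to a host
    equals infected-cell gain on that host term by term.  Hosts absent from
    the culture contribute nothing (their cell and infected densities are
    zero by invariant).
    """
    _check_compatible(state, params)
    ads = params.adsorption * state.free_phage[:, None] * state.cells[None, :]
    lysis = params.lysis_rate * state.infected
    dP = (params.burst * lysis - ads).sum(axis=1)
    dI = ads - lysis
    dC = params.cell_growth * state.cells - ads.sum(axis=0)
    return CultureDerivatives(
        strains=state.strains, d_free_phage=dP, d_infected=dI, d_cells=dC
    )


@dataclass(frozen=True)
class SolverSettings:
    """Numerical integration settings.

    ``method='euler'`` is the fixed-step explicit Euler scheme with step
    ``step`` (default 0.001).  ``method='adaptive'`` uses LSODA with relative
    tolerance ``rtol`` and absolute tolerance ``atol``.  Trajectories are
    sampled every ``sample_interval`` time units plus at the endpoint.
    """

    method: Literal["euler", "adaptive"] = "euler"
    step: float = 1e-3
    rtol: float = 1e-8
    atol: float = 1e-6
    sample_interval: float = 1.0

    def __post_init__(self) -> None:
        if self.method not in ("euler", "adaptive"):
            raise ConfigurationError(f"unknown solver method {self.method!r}")
        if self.step <= 0 or self.sample_interval <= 0:
            raise ConfigurationError("step and sample_interval must be positive")


EULER_DEFAULT = SolverSettings(method="euler", step=1e-3)
ADAPTIVE_REFERENCE = SolverSettings(method="adaptive", rtol=1e-10, atol=1e-8)


@dataclass
class Trajectory:
    """Sampled time course of one culture phase.

    Arrays are indexed ``[sample, ...]``; the first sample is the initial
    state and the last the endpoint.
    """

    strains: StrainSet
    times: np.ndarray
    free_phage: np.ndarray  # (nT, nP)
    infected: np.ndarray  # (nT, nP, nH)
    cells: np.ndarray  # (nT, nH)
    hosts_present: frozenset[str]
    culture_id: str = ""

    @property
    def final(self) -> CultureState:
        return self.state_at(-1)

    def state_at(self, index: int) -> CultureState:
        return CultureState(
            strains=self.strains,
            time=float(self.times[index]),
            free_phage=self.free_phage[index].copy(),
            infected=self.infected[index].copy(),
            cells=self.cells[index].copy(),
            hosts_present=self.hosts_present,
            culture_id=self.culture_id,
        )

    def states(self) -> Iterator[CultureState]:
        for idx in range(len(self.times)):
            yield self.state_at(idx)

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: time, culture_id, P_*, I_*_* (permissive), C_*."""
        data: dict[str, object] = {"time": self.times, "culture_id": self.culture_id}
        for i, p in enumerate(self.strains.phage_ids):
            data[f"P_{p}"] = self.free_phage[:, i]
        for p, h in self.strains.permissive_pairs():
            i, j = self.strains.phage_index(p), self.strains.host_index(h)
            data[f"I_{p}_{h}"] = self.infected[:, i, j]
        for j, h in enumerate(self.strains.host_ids):
            data[f"C_{h}"] = self.cells[:, j]
        return pd.DataFrame(data)


def _sample_times(t0: float, duration: float, interval: float) -> np.ndarray:
    n_whole = int(math.floor(duration / interval + 1e-9))
    times = [t0 + k * interval for k in range(n_whole + 1)]
    if times[-1] < t0 + duration - 1e-9 * max(1.0, duration):
        times.append(t0 + duration)
    else:
        times[-1] = t0 + duration
    return np.array(times)


def _pack(state: CultureState) -> np.ndarray:
    return np.concatenate([state.free_phage, state.infected.ravel(), state.cells])


def _integrate_euler(
    state: CultureState, params: KineticParams, times: np.ndarray, settings: SolverSettings
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    nP, nH = state.strains.n_phages, state.strains.n_hosts
    P = state.free_phage.copy()
    I = state.infected.copy()
    C = state.cells.copy()
    out_P = np.empty((len(times), nP))
    out_I = np.empty((len(times), nP, nH))
    out_C = np.empty((len(times), nH))
    out_P[0], out_I[0], out_C[0] = P, I, C
    b = np.ascontiguousarray(params.burst)
    lam = np.ascontiguousarray(params.lysis_rate)
    k = np.ascontiguousarray(params.adsorption)
    r = np.ascontiguousarray(params.cell_growth)
    for idx in range(1, len(times)):
        span = times[idx] - times[idx - 1]
        nsteps = max(1, int(round(span / settings.step)))
        status, step_idx = euler_advance(P, I, C, b, lam, k, r, settings.step, nsteps)
        if status == NONFINITE:
            t_bad = times[idx - 1] + step_idx * settings.step
            raise IntegrationError(f"non-finite density near t = {t_bad:.4f}")
        if status == NEGATIVE:
            t_bad = times[idx - 1] + step_idx * settings.step
            raise IntegrationError(
                f"density undershot zero near t = {t_bad:.4f}; reduce the Euler step"
            )
        out_P[idx], out_I[idx], out_C[idx] = P, I, C
    return out_P, out_I, out_C


def _integrate_adaptive(
    state: CultureState, params: KineticParams, times: np.ndarray, settings: SolverSettings
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    nP, nH = state.strains.n_phages, state.strains.n_hosts
    b, lam, k, r = params.burst, params.lysis_rate, params.adsorption, params.cell_growth

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        P = y[:nP]
        I = y[nP : nP + nP * nH].reshape(nP, nH)
        C = y[nP + nP * nH :]
        ads = k * P[:, None] * C[None, :]
        lysis = lam * I
        dP = (b * lysis - ads).sum(axis=1)
        dI = ads - lysis
        dC = r * C - ads.sum(axis=0)
        return np.concatenate([dP, dI.ravel(), dC])

    sol = solve_ivp(
        rhs,
        (times[0], times[-1]),
        _pack(state),
        method="LSODA",
        t_eval=times,
        rtol=settings.rtol,
        atol=settings.atol,
    )
    if not sol.success:
        raise IntegrationError(f"adaptive integration failed: {sol.message}")
    y = sol.y.T  # (nT, nvar)
    if not np.all(np.isfinite(y)):
        bad = np.argwhere(~np.isfinite(y))[0]
        raise IntegrationError(f"non-finite density at t = {times[bad[0]]:.4f}")
    # clamp solver-tolerance-scale negative excursions, reject anything larger
    totals = np.abs(y).sum(axis=1, keepdims=True)
    tol = np.maximum(10 * settings.atol, CLAMP_REL * totals)
    below = y < -tol
    if np.any(below):
        bad = np.argwhere(below)[0]
        raise IntegrationError(
            f"density undershot zero at t = {times[bad[0]]:.4f} beyond solver tolerance"
        )
    y = np.where(y < 0, 0.0, y)
    out_P = y[:, :nP]
    out_I = y[:, nP : nP + nP * nH].reshape(len(times), nP, nH)
    out_C = y[:, nP + nP * nH :]
    return out_P, out_I, out_C


def integrate_culture(
    state: CultureState,
    params: KineticParams,
    duration: float,
    settings: SolverSettings = EULER_DEFAULT,
) -> Trajectory:
    """Integrate one culture phase of length ``duration``.

    Returns a :class:`Trajectory` sampled at every ``sample_interval`` (unit
    times by default) plus the endpoint.  Densities stay non-negative: tiny
    roundoff undershoots are clamped to zero, larger ones raise
    :class:`IntegrationError`.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    state.validate()
    _check_compatible(state, params)
    times = _sample_times(state.time, duration, settings.sample_interval)
    if settings.method == "euler":
        out_P, out_I, out_C = _integrate_euler(state, params, times, settings)
    else:
        out_P, out_I, out_C = _integrate_adaptive(state, params, times, settings)
    return Trajectory(
        strains=state.strains,
        times=times,
        free_phage=out_P,
        infected=out_I,
        cells=out_C,
        hosts_present=state.hosts_present,
        culture_id=state.culture_id,
    )


def exponential_invasion_rate(
    params: KineticParams, phage: str, host: str, cell_density: float
) -> float:
    """Asymptotic exponential growth rate of a phage invading excess cells.

    With cell density ``C`` held fixed, free and infected phage obey a linear
    2x2 system whose dominant eigenvalue ``s`` is the positive root of

        s**2 + (k*C + lambda) * s - k*C*lambda*(b - 1) = 0.

    The rate is positive exactly when the burst size exceeds one (each lysed
    cell more than replaces the adsorbed phage).  Useful as a diagnostic in
    the regime where bacteria are never exhausted and phages grow
    exponentially for the whole culture phase.
    """
    if cell_density <= 0:
        raise ValueError("cell_density must be positive")
    if not params.strains.is_permissive(phage, host):
        raise ConfigurationError(f"({phage!r}, {host!r}) is not permissive")
    i = params.strains.phage_index(phage)
    j = params.strains.host_index(host)
    kC = params.adsorption[i, j] * cell_density
    lam = params.lysis_rate[i, j]
    b = params.burst[i, j]
    half_trace = (kC + lam) / 2.0
    return float(-half_trace + math.sqrt(half_trace**2 + kC * lam * (b - 1.0)))
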