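"""Closed-form selection heuristics and mutant bottleneck-survival arithmetic.

The heuristics reduce a phage's growth in one culture to a single number
``N_i|j`` — descendants per phage of strain ``i`` on host ``j`` over one
cycle, measured immediately before dilution — with the convention ``N = 1``
on a non-permissive host (the phage survives without growing).  From these
numbers the per-cycle change of each specialist relative to the generalist
follows in closed form:

* Parallel presentation pools the host cultures, so descendants add:
  specialist ``phiA`` leaves ``N_A|A + 1`` descendants per cycle against the
  generalist's ``N_AB|A + N_AB|B`` (an *arithmetic* advantage from growth on
  both hosts).

* Sequential presentation alternates hosts, so descendants multiply across
  the two-culture alternation: ``N_A|A * 1`` against
  ``N_AB|A * N_AB|B`` (a *multiplicative* advantage, far stronger).

A ratio above 1 means the specialist gains on the generalist per cycle.

The bottleneck calculator covers the fate of a newly arisen single mutant at
transfer: the chance it makes it into the next round at all (volumes used /
volumes pooled) times the chance it lands in a culture whose host it can
grow on (useful cultures / total cultures).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple

from .protocols import RunResult
from .strains import CANONICAL, ConfigurationError, StrainSet

__all__ = [
    "GrowthNumbers",
    "BottleneckSpec",
    "SelectionRatios",
    "parallel_ratios",
    "sequential_ratios",
    "parallel_descendants",
    "sequential_descendants",
    "predict_parallel_outcome",
    "tyranny_report",
    "measure_growth_numbers",
    "bottleneck_survival",
]


def _split_roles(strains: StrainSet) -> tuple[dict[str, str], str]:
    """Return ({specialist phage -> its host}, generalist phage id)."""
    specialists: dict[str, str] = {}
    generalists: list[str] = []
    for phage in strains.phage_ids:
        hosts = strains.permissivity[phage]
        if len(hosts) == 1:
            specialists[phage] = next(iter(hosts))
        elif len(hosts) == len(strains.host_ids) == 2:
            generalists.append(phage)
        else:
            raise ConfigurationError(
                "heuristic ratios are defined for two hosts with single-host "
                f"specialists and one two-host generalist; {phage!r} does not fit"
            )
    if len(generalists) != 1 or len(specialists) != 2:
        raise ConfigurationError(
            "heuristic ratios require exactly two specialists and one generalist"
        )
    return specialists, generalists[0]


@dataclass(frozen=True)
class GrowthNumbers:
    """Per-cycle descendants per phage, ``N_i|j``, indexed (phage, host).

    Permissive entries are supplied; non-permissive entries default to 1
    (survival without growth) and may not be set to anything else.
    """

    values: Mapping[tuple[str, str], float]
    strains: StrainSet = CANONICAL

    def __post_init__(self) -> None:
        vals = dict(self.values)
        for (phage, host), v in vals.items():
            if phage not in self.strains.phage_ids or host not in self.strains.host_ids:
                raise ConfigurationError(f"unknown pair ({phage!r}, {host!r})")
            if v < 0:
                raise ValueError(f"growth number N[{phage}|{host}] = {v} is negative")
            if not self.strains.is_permissive(phage, host) and v != 1.0:
                raise ValueError(
                    f"non-permissive entry N[{phage}|{host}] must be 1 (survival without growth)"
                )
        missing = [pair for pair in self.strains.permissive_pairs() if pair not in vals]
        if missing:
            raise ConfigurationError(f"growth numbers missing for permissive pairs {missing}")
        object.__setattr__(self, "values", vals)

    @classmethod
    def canonical(
        cls, n_A: float, n_B: float, n_AB_A: float, n_AB_B: float
    ) -> "GrowthNumbers":
        """Growth numbers for the canonical strain set.

        ``n_A`` is the A-specialist's growth on host A, ``n_B`` the
        B-specialist's on host B, ``n_AB_A``/``n_AB_B`` the generalist's on
        hosts A and B.
        """
        return cls(
            values={
                ("phiA", "A"): n_A,
                ("phiB", "B"): n_B,
                ("phiAB", "A"): n_AB_A,
                ("phiAB", "B"): n_AB_B,
            }
        )

    def n(self, phage: str, host: str) -> float:
        if self.strains.is_permissive(phage, host):
            return float(self.values[(phage, host)])
        return 1.0


class SelectionRatios(NamedTuple):
    """Per-cycle gain of each specialist relative to the generalist."""

    specialist_A: float
    specialist_B: float


def parallel_descendants(g: GrowthNumbers) -> dict[str, float]:
    """Pooled descendants per phage per cycle under Parallel presentation.

    Each phage sits in every host culture, so its pooled output is the sum
    of its growth numbers over hosts (with 1s on non-permissive hosts).
    """
    return {
        phage: sum(g.n(phage, host) for host in g.strains.host_ids)
        for phage in g.strains.phage_ids
    }


def sequential_descendants(g: GrowthNumbers) -> dict[str, float]:
    """Descendants per phage over one full host alternation (Sequential).

    Growth compounds across the alternation, so outputs multiply over hosts.
    """
    out: dict[str, float] = {}
    for phage in g.strains.phage_ids:
        prod = 1.0
        for host in g.strains.host_ids:
            prod *= g.n(phage, host)
        out[phage] = prod
    return out


def _ratios(descendants: dict[str, float], strains: StrainSet) -> SelectionRatios:
    specialists, generalist = _split_roles(strains)
    denom = descendants[generalist]
    if denom <= 0:
        raise ZeroDivisionError("generalist descendant count is zero; ratios undefined")
    by_host = {host: descendants[phage] / denom for phage, host in specialists.items()}
    hosts = sorted(by_host)
    return SelectionRatios(specialist_A=by_host[hosts[0]], specialist_B=by_host[hosts[1]])


def parallel_ratios(g: GrowthNumbers) -> SelectionRatios:
    """Specialist-vs-generalist per-cycle ratios under Parallel presentation.

    For the canonical strains: ``(N_A|A + 1) / (N_AB|A + N_AB|B)`` and
    ``(N_B|B + 1) / (N_AB|A + N_AB|B)``.  A value above 1 means that
    specialist gains on the generalist each cycle.
    """
    return _ratios(parallel_descendants(g), g.strains)


def sequential_ratios(g: GrowthNumbers) -> SelectionRatios:
    """Specialist-vs-generalist ratios over one Sequential host alternation.

    For the canonical strains: ``N_A|A / (N_AB|A * N_AB|B)`` and
    ``N_B|B / (N_AB|A * N_AB|B)``.
    """
    return _ratios(sequential_descendants(g), g.strains)


def predict_parallel_outcome(g: GrowthNumbers) -> dict[str, bool]:
    """Predicted retention per phage under Parallel presentation.

    A specialist whose ratio falls below 1 loses ground every cycle and is
    predicted lost.  The generalist is predicted lost only when *both*
    specialists have ratios above 1 — superiority of a single specialist
    does not doom the generalist, which can persist on the other host.  This
    asymmetry favours generalists.
    """
    specialists, generalist = _split_roles(g.strains)
    ratios = parallel_ratios(g)
    by_host = dict(zip(sorted(h for h in specialists.values()), ratios))
    out: dict[str, bool] = {}
    for phage, host in specialists.items():
        out[phage] = by_host[host] >= 1.0
    out[generalist] = not all(by_host[h] > 1.0 for h in by_host)
    return out


@dataclass(frozen=True)
class TyrannyReport:
    """Flags hosts on which a winning generalist is locally inferior.

    'Tyranny of generalists': the generalist displaces a specialist that is
    better than it on the specialist's own host, because the generalist's
    pooled output is dominated by a different, more productive host.
    """

    tyrannized_hosts: tuple[str, ...]
    per_host_superiority: dict[str, bool]  # specialist beats generalist on its host
    specialist_displaced: dict[str, bool]  # pooled ratio < 1

    @property
    def any_tyranny(self) -> bool:
        return bool(self.tyrannized_hosts)


def tyranny_report(g: GrowthNumbers) -> TyrannyReport:
    """Compare per-host growth with pooled Parallel ratios to flag tyranny."""
    specialists, generalist = _split_roles(g.strains)
    ratios = parallel_ratios(g)
    by_host = dict(zip(sorted(specialists.values()), ratios))
    superiority = {
        host: g.n(phage, host) > g.n(generalist, host) for phage, host in specialists.items()
    }
    displaced = {host: by_host[host] < 1.0 for host in by_host}
    tyrannized = tuple(h for h in sorted(by_host) if displaced[h] and superiority[h])
    return TyrannyReport(
        tyrannized_hosts=tyrannized,
        per_host_superiority=superiority,
        specialist_displaced=displaced,
    )


def measure_growth_numbers(result: RunResult, cycle_index: int) -> GrowthNumbers:
    """Extract ``N_i|j`` from a simulated cycle's records.

    ``N_i|j`` is the end density of phage ``i`` in the culture containing
    host ``j``, divided by its (post-dilution) start density in that
    culture.  Only presentations with one host per culture are supported
    (Parallel, Sequential); in a Mixed culture the generalist's growth on
    the two hosts cannot be separated.  Non-permissive entries are reported
    as 1 by convention.
    """
    record = result.cycles[cycle_index]
    strains = result.strains
    host_to_culture: dict[str, str] = {}
    for culture_id, hosts in record.host_schedule.items():
        if len(hosts) != 1:
            raise ConfigurationError(
                "growth numbers are per-host; a Mixed culture cannot be decomposed"
            )
        host_to_culture[hosts[0]] = culture_id
    values: dict[tuple[str, str], float] = {}
    for phage, host in strains.permissive_pairs():
        culture_id = host_to_culture.get(host)
        if culture_id is None:
            raise ValueError(
                f"no culture contained host {host!r} in cycle {cycle_index} "
                "(Sequential presentation offers one host per cycle)"
            )
        start = record.start_free_phage[phage]
        if start <= 0:
            raise ValueError(
                f"N[{phage}|{host}] undefined: phage started cycle {cycle_index} at density 0"
            )
        values[(phage, host)] = record.per_culture_end[culture_id][phage] / start
    return GrowthNumbers(values=values, strains=strains)


@dataclass(frozen=True)
class BottleneckSpec:
    """Geometry of the transfer bottleneck faced by a rare mutant.

    ``volumes_pooled`` culture volumes are combined into the phage pool, of
    which ``volumes_used`` are carried into the next round and distributed
    among ``n_cultures`` cultures, ``n_useful_cultures`` of which contain a
    host the mutant can grow on.
    """

    volumes_pooled: float
    volumes_used: float
    n_cultures: int
    n_useful_cultures: int

    def __post_init__(self) -> None:
        if self.volumes_pooled <= 0 or self.volumes_used <= 0:
            raise ValueError("volumes must be positive")
        if self.volumes_used > self.volumes_pooled:
            raise ValueError("volumes_used cannot exceed volumes_pooled")
        if self.n_cultures < 1:
            raise ValueError("n_cultures must be at least 1")
        if not (0 <= self.n_useful_cultures <= self.n_cultures):
            raise ValueError("n_useful_cultures must lie in [0, n_cultures]")

    @property
    def transfer_fraction(self) -> float:
        return self.volumes_used / self.volumes_pooled

    @property
    def placement_probability(self) -> float:
        return self.n_useful_cultures / self.n_cultures


def bottleneck_survival(spec: BottleneckSpec) -> float:
    """Probability a single mutant survives transfer and lands on a usable host.

    The product of the transfer fraction (volumes used / volumes pooled) and
    the placement probability (useful cultures / total cultures).  Monotone
    nondecreasing in both.
    """
    return spec.transfer_fraction * spec.placement_probability
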