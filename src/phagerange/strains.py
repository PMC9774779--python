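"""Strain sets and kinetic parameters for phage-bacteria competition models.

A :class:`StrainSet` names the phages and bacterial hosts in play and records
which phage can productively infect which host (the permissivity map).  The
canonical set used throughout is two hosts ``A``/``B``, two specialist phages
``phiA``/``phiB`` (each permissive on its namesake host only) and one
generalist ``phiAB`` permissive on both.

A :class:`KineticParams` bundle holds, per (phage, host) pair, the burst size
``b`` (progeny per lysed cell), the lysis rate ``lambda`` (per time unit; its
reciprocal is the mean latent period), the adsorption rate constant ``k``
(volume per phage per time), and per host the intrinsic bacterial growth rate
``r``.  Adsorption is forced to zero on non-permissive pairs, which models a
free phage that neither infects nor decays in a culture of a host it cannot
use.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "StrainSet",
    "KineticParams",
    "CANONICAL",
    "ConfigurationError",
    "DEFAULT_LYSIS_RATE",
    "DEFAULT_ADSORPTION",
]

#: Default lysis rate (per time unit).
DEFAULT_LYSIS_RATE = 1.0
#: Default adsorption rate constant (volume per phage per time unit).
DEFAULT_ADSORPTION = 1e-9


class ConfigurationError(ValueError):
    """A parameter set or protocol configuration is invalid or incomplete."""


@dataclass(frozen=True)
class StrainSet:
    """Named phages and hosts plus the phage-by-host permissivity map.

    Parameters
    ----------
    phage_ids
        Ordered phage strain identifiers.
    host_ids
        Ordered bacterial host identifiers.
    permissivity
        Map from phage id to the set of host ids on which that phage can
        complete its infection cycle.  The map must mention every phage, and
        every phage must be permissive on at least one host.
    """

    phage_ids: tuple[str, ...]
    host_ids: tuple[str, ...]
    permissivity: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        if len(set(self.phage_ids)) != len(self.phage_ids):
            raise ConfigurationError("duplicate phage identifiers")
        if len(set(self.host_ids)) != len(self.host_ids):
            raise ConfigurationError("duplicate host identifiers")
        perm = {p: frozenset(h) for p, h in dict(self.permissivity).items()}
        object.__setattr__(self, "permissivity", perm)
        for phage in self.phage_ids:
            hosts = perm.get(phage)
            if hosts is None:
                raise ConfigurationError(f"no permissivity entry for phage {phage!r}")
            if not hosts:
                raise ConfigurationError(f"phage {phage!r} is permissive on no host")
            unknown = hosts - set(self.host_ids)
            if unknown:
                raise ConfigurationError(
                    f"phage {phage!r} permissive on unknown hosts {sorted(unknown)}"
                )
        extra = set(perm) - set(self.phage_ids)
        if extra:
            raise ConfigurationError(f"permissivity given for unknown phages {sorted(extra)}")

    @property
    def n_phages(self) -> int:
        return len(self.phage_ids)

    @property
    def n_hosts(self) -> int:
        return len(self.host_ids)

    def phage_index(self, phage: str) -> int:
        return self.phage_ids.index(phage)

    def host_index(self, host: str) -> int:
        return self.host_ids.index(host)

    def is_permissive(self, phage: str, host: str) -> bool:
        return host in self.permissivity[phage]

    def permissive_pairs(self) -> list[tuple[str, str]]:
        """All (phage, host) pairs on which infection can proceed, in order."""
        return [
            (p, h)
            for p in self.phage_ids
            for h in self.host_ids
            if self.is_permissive(p, h)
        ]

    def permissivity_matrix(self) -> np.ndarray:
        """Boolean (n_phages, n_hosts) matrix of the permissivity map."""
        out = np.zeros((self.n_phages, self.n_hosts), dtype=bool)
        for i, p in enumerate(self.phage_ids):
            for j, h in enumerate(self.host_ids):
                out[i, j] = self.is_permissive(p, h)
        return out


#: The canonical two-host, three-phage strain set: specialists phiA and phiB
#: plus the generalist phiAB.
CANONICAL = StrainSet(
    phage_ids=("phiA", "phiB", "phiAB"),
    host_ids=("A", "B"),
    permissivity={
        "phiA": frozenset({"A"}),
        "phiB": frozenset({"B"}),
        "phiAB": frozenset({"A", "B"}),
    },
)


def _pair_table(
    strains: StrainSet,
    values: Mapping[tuple[str, str], float] | float,
    default: float,
) -> np.ndarray:
    table = np.full((strains.n_phages, strains.n_hosts), default, dtype=float)
    if isinstance(values, Mapping):
        for (phage, host), value in values.items():
            if phage not in strains.phage_ids or host not in strains.host_ids:
                raise ConfigurationError(f"unknown (phage, host) pair ({phage!r}, {host!r})")
            table[strains.phage_index(phage), strains.host_index(host)] = value
    else:
        table[:] = float(values)
    return table


@dataclass(frozen=True)
class KineticParams:
    """Rate constants and burst sizes indexed by phage strain x host strain.

    Arrays are indexed ``[phage, host]`` following the ordering of
    ``strains.phage_ids`` and ``strains.host_ids``.  Adsorption is exactly
    zero on every non-permissive pair; burst sizes on non-permissive pairs
    are irrelevant (no infected class ever forms) and stored as zero.
    """

    strains: StrainSet
    burst: np.ndarray
    lysis_rate: np.ndarray
    adsorption: np.ndarray
    cell_growth: np.ndarray
    # cached contiguous copies handed to the integrator
    _frozen: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        nP, nH = self.strains.n_phages, self.strains.n_hosts
        for name, arr, shape in (
            ("burst", self.burst, (nP, nH)),
            ("lysis_rate", self.lysis_rate, (nP, nH)),
            ("adsorption", self.adsorption, (nP, nH)),
            ("cell_growth", self.cell_growth, (nH,)),
        ):
            arr = np.asarray(arr, dtype=float)
            if arr.shape != shape:
                raise ConfigurationError(f"{name} must have shape {shape}, got {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise ConfigurationError(f"{name} contains non-finite values")
            if np.any(arr < 0):
                raise ConfigurationError(f"{name} contains negative values")
            object.__setattr__(self, name, arr)
        perm = self.strains.permissivity_matrix()
        if np.any(self.adsorption[~perm] != 0.0):
            raise ConfigurationError("adsorption must be 0 on non-permissive pairs")
        active = self.adsorption > 0
        if np.any(self.lysis_rate[active] <= 0):
            raise ConfigurationError("lysis_rate must be > 0 wherever adsorption > 0")

    @classmethod
    def from_bursts(
        cls,
        burst: Mapping[tuple[str, str], float],
        cell_growth: Mapping[str, float] | float,
        strains: StrainSet = CANONICAL,
        lysis_rate: Mapping[tuple[str, str], float] | float = DEFAULT_LYSIS_RATE,
        adsorption: Mapping[tuple[str, str], float] | float = DEFAULT_ADSORPTION,
    ) -> "KineticParams":
        """Build a parameter set from per-pair burst sizes.

        ``burst`` must cover every permissive pair.  ``cell_growth`` may be a
        single rate shared by all hosts or a map per host.  Lysis rate and
        adsorption default to the standard values (1.0 and 1e-9) on every
        permissive pair; adsorption on non-permissive pairs is forced to 0.
        """
        b = _pair_table(strains, burst, default=np.nan)
        lam = _pair_table(strains, lysis_rate, default=DEFAULT_LYSIS_RATE)
        k = _pair_table(strains, adsorption, default=DEFAULT_ADSORPTION)
        perm = strains.permissivity_matrix()
        if np.any(np.isnan(b[perm])):
            missing = [
                (p, h)
                for p, h in strains.permissive_pairs()
                if np.isnan(b[strains.phage_index(p), strains.host_index(h)])
            ]
            raise ConfigurationError(f"burst size missing for permissive pairs {missing}")
        b = np.where(perm, b, 0.0)
        b = np.nan_to_num(b, nan=0.0)
        k = np.where(perm, k, 0.0)
        if isinstance(cell_growth, Mapping):
            r = np.array([cell_growth[h] for h in strains.host_ids], dtype=float)
        else:
            r = np.full(strains.n_hosts, float(cell_growth))
        return cls(strains=strains, burst=b, lysis_rate=lam, adsorption=k, cell_growth=r)

    def burst_of(self, phage: str, host: str) -> float:
        return float(self.burst[self.strains.phage_index(phage), self.strains.host_index(host)])

    def with_burst(self, phage: str, host: str, value: float) -> "KineticParams":
        """Return a copy with one burst size replaced."""
        if value < 0:
            raise ConfigurationError(f"negative burst size {value} for ({phage!r}, {host!r})")
        if not self.strains.is_permissive(phage, host):
            raise ConfigurationError(f"({phage!r}, {host!r}) is not permissive")
        b = self.burst.copy()
        b[self.strains.phage_index(phage), self.strains.host_index(host)] = value
        return replace(self, burst=b)

    def with_generalist_bursts(
        self, burst_on_A: float, burst_on_B: float, generalist: str = "phiAB"
    ) -> "KineticParams":
        """Return a copy with the generalist's two burst sizes replaced."""
        hosts = sorted(self.strains.permissivity[generalist])
        if len(hosts) != 2:
            raise ConfigurationError(f"{generalist!r} is not a two-host generalist")
        return self.with_burst(generalist, hosts[0], burst_on_A).with_burst(
            generalist, hosts[1], burst_on_B
        )
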