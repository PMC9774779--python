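"""Configuration parsing, canonical scenario fixtures, and output writers.

Configuration is a single YAML document with three sections::

    schema_version: 1
    protocol:            # any ProtocolConfig field
      presentation: parallel
      dilution_mode: fixed_count
    kinetics:
      burst:             # per phage, per host; permissive pairs only
        phiA: {A: 20}
        phiB: {B: 10}
        phiAB: {A: 17, B: 17}
      cell_growth: 0.3   # scalar shared by hosts, or a per-host map
      lysis_rate: 1.0    # optional, scalar or per-pair map
      adsorption: 1.0e-9 # optional, scalar or per-pair map
    sweep:               # optional
      grid_A: {start: 5, stop: 25, step: 1}   # or an explicit list
      grid_B: [5, 10, 15, 20, 25]
      retention_threshold: 0.01

Unknown keys are rejected with their key path.  Omitting ``kinetics``
selects the symmetric baseline (all burst sizes 15, r = 0.3); omitting any
``protocol`` field selects the standard defaults (cycle 20, 50 cycles,
renewal 1e7, fixed-count 1000).

Output writers emit deterministic TSV (10 significant digits, fixed row
order) plus a JSON metadata sidecar echoing the full effective
configuration, so identical inputs produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .protocols import ProtocolConfig, RunResult
from .strains import CANONICAL, ConfigurationError, KineticParams, StrainSet
from .sweep import DEFAULT_GRID, GridResult, SweepConfig

__all__ = [
    "ScenarioFixture",
    "fixture",
    "fixture_names",
    "load_config",
    "write_outputs",
    "read_grid_tsv",
    "plot_heatmaps",
]

_FLOAT_FMT = "%.10g"


# ---------------------------------------------------------------------------
# canonical scenario fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScenarioFixture:
    """One canonical simulation scenario (protocol + kinetics + optional sweep)."""

    name: str
    description: str
    config: ProtocolConfig
    params: KineticParams
    sweep: SweepConfig | None = None


def _params(
    b_A: float, b_B: float, b_AB_A: float, b_AB_B: float, r: float
) -> KineticParams:
    return KineticParams.from_bursts(
        burst={
            ("phiA", "A"): b_A,
            ("phiB", "B"): b_B,
            ("phiAB", "A"): b_AB_A,
            ("phiAB", "B"): b_AB_B,
        },
        cell_growth=r,
    )


def _scenarios() -> dict[str, ScenarioFixture]:
    out: dict[str, ScenarioFixture] = {}

    def add(
        name: str,
        description: str,
        presentation: str,
        dilution: str,
        r: float,
        b_A: float,
        b_B: float,
        generalist: tuple[float, float] = (15.0, 15.0),
        sweep: bool = True,
        **protocol_kw: Any,
    ) -> None:
        config = ProtocolConfig(
            presentation=presentation, dilution_mode=dilution, **protocol_kw
        )
        params = _params(b_A, b_B, *generalist, r)
        sweep_cfg = (
            SweepConfig(base_protocol=config, base_params=params) if sweep else None
        )
        out[name] = ScenarioFixture(name, description, config, params, sweep_cfg)

    add(
        "fig2",
        "Parallel, fixed-count 1000, r=0.3, symmetric specialists 15/15; "
        "generalist burst-size sweep",
        "parallel", "fixed_count", 0.3, 15, 15,
    )
    add(
        "fig3",
        "Parallel, fixed-count 1000, r=0.3, asymmetric specialists 20/10; "
        "generalist burst-size sweep",
        "parallel", "fixed_count", 0.3, 20, 10,
    )
    add(
        "fig4",
        "Parallel, fixed-count 1000, low bacterial growth r=0.1, specialists "
        "20/10; demographic-extinction regime",
        "parallel", "fixed_count", 0.1, 20, 10,
    )
    add(
        "fig5A",
        "Single run of the fig4 conditions with generalist bursts 17/17 "
        "(phages never exhaust cells; plateau regime)",
        "parallel", "fixed_count", 0.1, 20, 10, generalist=(17, 17), sweep=False,
    )
    add(
        "fig5B",
        "Single run of the fig3 conditions with generalist bursts 17/17 "
        "(cells exhausted each cycle)",
        "parallel", "fixed_count", 0.3, 20, 10, generalist=(17, 17), sweep=False,
    )
    add(
        "fig6",
        "Parallel, fixed-volume 5%, r=0.1, specialists 20/10; dilution-regime "
        "contrast with fig4",
        "parallel", "fixed_volume", 0.1, 20, 10,
    )
    add(
        "fig7",
        "Parallel, per-host fixed-count 1000, r=0.1, specialists 20/10; "
        "per-host dilution rescues coexistence",
        "parallel", "fixed_count_by_host", 0.1, 20, 10,
    )
    add(
        "fig8",
        "Sequential (alternating hosts), fixed-count 1000, r=0.3, specialists "
        "20/10; generalist strongly favoured",
        "sequential", "fixed_count", 0.3, 20, 10,
    )
    add(
        "fig9",
        "Mixed (both hosts in one culture), fixed-count 1000, r=0.3, "
        "specialists 20/10; intermediate outcome",
        "mixed", "fixed_count", 0.3, 20, 10,
    )
    return out


_SCENARIOS = _scenarios()


def fixture(name: str) -> ScenarioFixture:
    """Return a canonical scenario by name (``fig2`` ... ``fig9``)."""
    try:
        return _SCENARIOS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {', '.join(sorted(_SCENARIOS))}"
        ) from None


def fixture_names() -> list[str]:
    return sorted(_SCENARIOS)


# ---------------------------------------------------------------------------
# config loading
# ---------------------------------------------------------------------------


def _reject_unknown(section: Mapping[str, Any], allowed: set[str], path: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) {sorted(unknown)} under {path!r}; allowed: {sorted(allowed)}"
        )


def _pair_map(
    node: Mapping[str, Any] | float, path: str, strains: StrainSet
) -> dict[tuple[str, str], float] | float:
    if not isinstance(node, Mapping):
        return float(node)
    out: dict[tuple[str, str], float] = {}
    _reject_unknown(node, set(strains.phage_ids), path)
    for phage, hosts in node.items():
        if not isinstance(hosts, Mapping):
            raise ConfigurationError(f"{path}.{phage} must map hosts to values")
        _reject_unknown(hosts, set(strains.host_ids), f"{path}.{phage}")
        for host, value in hosts.items():
            value = float(value)
            if value < 0:
                raise ConfigurationError(f"{path}.{phage}.{host} is negative ({value})")
            out[(phage, host)] = value
    return out


def _grid_axis(node: Any, path: str) -> tuple[float, ...]:
    if isinstance(node, Mapping):
        _reject_unknown(node, {"start", "stop", "step"}, path)
        start, stop = float(node["start"]), float(node["stop"])
        step = float(node.get("step", 1.0))
        if step <= 0 or stop < start:
            raise ConfigurationError(f"{path}: need start <= stop and step > 0")
        n = int(round((stop - start) / step))
        return tuple(start + i * step for i in range(n + 1))
    return tuple(float(v) for v in node)


_DEFAULT_KINETICS = {
    "burst": {
        "phiA": {"A": 15.0},
        "phiB": {"B": 15.0},
        "phiAB": {"A": 15.0, "B": 15.0},
    },
    "cell_growth": 0.3,
}


def load_config(
    source: str | Path,
) -> tuple[ProtocolConfig, KineticParams, SweepConfig | None]:
    """Parse and validate a YAML configuration.

    ``source`` may be a path to a YAML file or YAML text itself.  Returns
    the validated protocol configuration, kinetic parameters, and sweep
    configuration (None when no ``sweep`` section is present).
    """
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).exists()
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    doc = yaml.safe_load(text)
    if doc is None:
        doc = {}
    if not isinstance(doc, Mapping):
        raise ConfigurationError("configuration must be a YAML mapping")
    _reject_unknown(doc, {"schema_version", "protocol", "kinetics", "sweep"}, "<root>")
    version = doc.get("schema_version", 1)
    if version != 1:
        raise ConfigurationError(f"unsupported schema_version {version!r}")

    protocol_node = dict(doc.get("protocol") or {})
    allowed = {f.name for f in dataclasses.fields(ProtocolConfig)}
    _reject_unknown(protocol_node, allowed, "protocol")
    config = ProtocolConfig(**protocol_node)

    kin_node = dict(doc.get("kinetics") or _DEFAULT_KINETICS)
    _reject_unknown(
        kin_node, {"burst", "cell_growth", "lysis_rate", "adsorption"}, "kinetics"
    )
    strains = CANONICAL
    burst = _pair_map(kin_node.get("burst", _DEFAULT_KINETICS["burst"]), "kinetics.burst", strains)
    if not isinstance(burst, Mapping):
        raise ConfigurationError("kinetics.burst must be a per-phage, per-host map")
    kwargs: dict[str, Any] = {}
    if "lysis_rate" in kin_node:
        kwargs["lysis_rate"] = _pair_map(kin_node["lysis_rate"], "kinetics.lysis_rate", strains)
    if "adsorption" in kin_node:
        kwargs["adsorption"] = _pair_map(kin_node["adsorption"], "kinetics.adsorption", strains)
    cell_growth = kin_node.get("cell_growth", _DEFAULT_KINETICS["cell_growth"])
    if isinstance(cell_growth, Mapping):
        _reject_unknown(cell_growth, set(strains.host_ids), "kinetics.cell_growth")
        cell_growth = {h: float(v) for h, v in cell_growth.items()}
    else:
        cell_growth = float(cell_growth)
    params = KineticParams.from_bursts(
        burst=burst, cell_growth=cell_growth, strains=strains, **kwargs
    )

    sweep_cfg: SweepConfig | None = None
    if "sweep" in doc and doc["sweep"] is not None:
        sweep_node = dict(doc["sweep"])
        _reject_unknown(sweep_node, {"grid_A", "grid_B", "retention_threshold"}, "sweep")
        sweep_cfg = SweepConfig(
            base_protocol=config,
            base_params=params,
            grid_A=_grid_axis(sweep_node.get("grid_A", DEFAULT_GRID), "sweep.grid_A"),
            grid_B=_grid_axis(sweep_node.get("grid_B", DEFAULT_GRID), "sweep.grid_B"),
            retention_threshold=float(sweep_node.get("retention_threshold", 0.01)),
        )
    return config, params, sweep_cfg


# ---------------------------------------------------------------------------
# output writers
# ---------------------------------------------------------------------------


def _params_dict(params: KineticParams) -> dict[str, Any]:
    s = params.strains
    return {
        "phage_ids": list(s.phage_ids),
        "host_ids": list(s.host_ids),
        "permissivity": {p: sorted(s.permissivity[p]) for p in s.phage_ids},
        "burst": {
            p: {h: params.burst[i, j] for j, h in enumerate(s.host_ids)}
            for i, p in enumerate(s.phage_ids)
        },
        "lysis_rate": {
            p: {h: params.lysis_rate[i, j] for j, h in enumerate(s.host_ids)}
            for i, p in enumerate(s.phage_ids)
        },
        "adsorption": {
            p: {h: params.adsorption[i, j] for j, h in enumerate(s.host_ids)}
            for i, p in enumerate(s.phage_ids)
        },
        "cell_growth": {h: params.cell_growth[j] for j, h in enumerate(s.host_ids)},
    }


def _metadata(kind: str, config: ProtocolConfig, params: KineticParams, extra: dict) -> dict:
    return {
        "phagerange_version": __version__,
        "type": kind,
        "protocol": dataclasses.asdict(config),
        "kinetics": _params_dict(params),
        **extra,
    }


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _run_frame(result: RunResult) -> pd.DataFrame:
    phages = result.strains.phage_ids
    hosts = result.strains.host_ids
    rows = []
    for rec in result.cycles:
        row: dict[str, Any] = {"cycle_index": rec.cycle_index}
        for p in phages:
            row[f"start_{p}"] = rec.start_free_phage[p]
        for p in phages:
            row[f"end_{p}"] = rec.end_free_phage[p]
        row["fold_growth"] = rec.fold_growth_total
        for h in hosts:
            row[f"end_cells_{h}"] = rec.end_cells[h]
        rows.append(row)
    return pd.DataFrame(rows)


def write_outputs(result: RunResult | GridResult, destination: str | Path) -> list[Path]:
    """Write a run or sweep result as TSV plus a JSON metadata sidecar.

    Returns the list of files written.  Output is deterministic: fixed
    column and row order and 10-significant-digit numeric formatting make
    repeated runs byte-identical.
    """
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if isinstance(result, RunResult):
        cycles_path = dest / "cycles.tsv"
        _write_tsv(_run_frame(result), cycles_path)
        written.append(cycles_path)
        if result.trajectories:
            frames = [
                result.trajectories[key].to_frame()
                for key in sorted(result.trajectories.keys())
            ]
            traj_path = dest / "trajectory.tsv"
            _write_tsv(pd.concat(frames, ignore_index=True), traj_path)
            written.append(traj_path)
        meta = _metadata(
            "run",
            result.config,
            result.params,
            {
                "final_frequencies": result.final_frequencies,
                "final_total_phage": result.final_total_phage,
                "extinct": result.extinct,
            },
        )
    elif isinstance(result, GridResult):
        grid_path = dest / "grid.tsv"
        _write_tsv(result.to_frame(), grid_path)
        written.append(grid_path)
        meta = _metadata(
            "sweep",
            result.config.base_protocol,
            result.config.base_params,
            {
                "grid_A": list(result.config.grid_A),
                "grid_B": list(result.config.grid_B),
                "retention_threshold": result.config.retention_threshold,
            },
        )
    else:
        raise TypeError(f"cannot write outputs for {type(result).__name__}")
    meta_path = dest / "metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True, default=float) + "\n")
    written.append(meta_path)
    return written


def read_grid_tsv(path: str | Path) -> pd.DataFrame:
    """Read back a sweep grid TSV written by :func:`write_outputs`."""
    return pd.read_csv(path, sep="\t")


def plot_heatmaps(grid: GridResult, destination: str | Path, prefix: str = "heatmap") -> list[Path]:
    """Render one final-frequency heat map per phage (PNG, colour scale 0-1)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    cfg = grid.config
    written: list[Path] = []
    def span(axis: tuple[float, ...]) -> tuple[float, float]:
        if axis[0] == axis[-1]:  # degenerate single-point axis
            return axis[0] - 0.5, axis[0] + 0.5
        return axis[0], axis[-1]

    for phage in cfg.base_params.strains.phage_ids:
        mat = grid.frequency_matrix(phage)
        fig, ax = plt.subplots(figsize=(4.5, 4))
        im = ax.imshow(
            mat.T,
            origin="lower",
            vmin=0.0,
            vmax=1.0,
            aspect="auto",
            extent=(*span(cfg.grid_A), *span(cfg.grid_B)),
            cmap="viridis",
        )
        ax.set_xlabel("generalist burst size on host A")
        ax.set_ylabel("generalist burst size on host B")
        ax.set_title(f"final frequency of {phage}")
        fig.colorbar(im, ax=ax, label="frequency")
        path = dest / f"{prefix}_{phage}.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(path)
    return written
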