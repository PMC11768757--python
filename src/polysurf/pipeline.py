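"""Run orchestration: build -> simulate -> analyze -> report.

A run matrix covers polymers x steering modes x replicates.  Every output
row carries full provenance (polymer, mode, replicate, seed, package
version, every parameter actually used), and each matrix cell runs
independently — a failing cell is logged and skipped, the rest continue.

The default configuration reproduces the study conditions (20x32x2 slab,
12-/48-mer chains, 0.006 M NaCl, four-stage steering protocol at 300 K);
``RunConfig.quick()`` gives a desk-scale configuration for smoke tests.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assembly import PlacementRules, assemble
from .crystal import build_slab, make_brucite_cell
from .dynamics import (
    END_GRAFTED,
    U_SHAPED,
    default_protocol,
    plant_configuration,
    run_protocol,
)
from .forcefield import ForceFieldParams
from .metrics import AnalysisParams, RunReport, aggregate, analyze_frame, frame_table
from .polymers import DEFAULT_N_MONOMERS, POLYMER_NAMES, build_chain

log = logging.getLogger("polysurf")


@dataclass(frozen=True)
class RunConfig:
    polymers: tuple[str, ...] = POLYMER_NAMES
    modes: tuple[str, ...] = (END_GRAFTED, U_SHAPED)
    replicates: int = 3
    master_seed: int = 0
    slab_replication: tuple[int, int, int] = (20, 32, 2)
    n_monomers: dict[str, int] = field(default_factory=dict)  # overrides
    rules: PlacementRules = field(default_factory=PlacementRules)
    ff: ForceFieldParams = field(default_factory=ForceFieldParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    equilibration_steps: int = 500
    steering_steps: int = 4000
    release_steps: int = 2000
    dt: float = 0.005  # ps
    temperature: float = 300.0  # K
    friction: float = 1.0  # 1/ps
    sample_every: int = 10
    planted: bool = False  # pose geometrically instead of running dynamics
    output_dir: str | None = None

    @classmethod
    def quick(cls, **overrides) -> "RunConfig":
        """Desk-scale configuration: small slab, short chains, short stages."""
        defaults = dict(
            polymers=("PAM",),
            modes=(END_GRAFTED,),
            replicates=1,
            slab_replication=(10, 18, 1),
            n_monomers={name: 12 if name in ("PAM", "HPAM", "PAA") else 6
                        for name in POLYMER_NAMES},
            equilibration_steps=50,
            steering_steps=800,
            release_steps=300,
            sample_every=20,
        )
        defaults.update(overrides)
        return cls(**defaults)

    def chain_length(self, polymer: str) -> int:
        return self.n_monomers.get(polymer, DEFAULT_N_MONOMERS[polymer])

    def cell_seed(self, polymer: str, mode: str, replicate: int) -> int:
        """Deterministic per-cell seed below 2**31."""
        h = (
            self.master_seed * 1_000_003
            + POLYMER_NAMES.index(polymer) * 10_007
            + (0 if mode == END_GRAFTED else 1) * 101
            + replicate
        )
        return h % (2**31 - 1)


def build_system(config: RunConfig, polymer: str, seed: int):
    slab = build_slab(make_brucite_cell(), config.slab_replication)
    chain = build_chain(polymer, config.chain_length(polymer), seed=seed)
    return assemble(slab, chain, config.rules, seed=seed)


def run_cell(config: RunConfig, polymer: str, mode: str, replicate: int) -> RunReport:
    """One matrix cell: build, steer (or plant), analyze the release stage."""
    seed = config.cell_seed(polymer, mode, replicate)
    state = build_system(config, polymer, seed)
    if config.planted:
        n = state.n_monomers
        contact = {0} if mode == END_GRAFTED else {n // 2}
        posed = plant_configuration(state, mode, contact)
        rep_frame = analyze_frame(posed, ff=config.ff, params=config.analysis)
        frames = frame_table([rep_frame])
        frames["replicate_id"] = replicate
        report = RunReport(
            replicate_id=replicate,
            frames=frames,
            means={k: float(frames[k].iloc[0]) for k in
                   ("min_distance", "n_contacts", "n_hbonds", "n_bridges",
                    "n_cation_surface", "e_lj", "e_coul")},
            sems={k: 0.0 for k in
                  ("min_distance", "n_contacts", "n_hbonds", "n_bridges",
                   "n_cation_surface", "e_lj", "e_coul")},
            mode_proportions={m: (1.0 if m == rep_frame.mode else 0.0)
                              for m in ("end_grafted", "u_shaped", "mixed", "desorbed")},
            n_frames=1,
            single_frame=True,
        )
        return report
    protocol = default_protocol(
        mode=mode,
        equilibration_steps=config.equilibration_steps,
        steering_steps=config.steering_steps,
        release_steps=config.release_steps,
    )
    traj = run_protocol(
        state,
        config.ff,
        protocol,
        seed=seed,
        thermostat=(config.temperature, config.friction),
        dt=config.dt,
        sample_every=config.sample_every,
        replicate_id=replicate,
    )
    return aggregate(traj, ff=config.ff, params=config.analysis, stage="release")


def run_matrix(config: RunConfig) -> pd.DataFrame:
    """Execute the full matrix; returns the summary table (one row/cell).

    Cells that raise are recorded with ``status='failed'`` and a diagnostic
    message; the remaining cells still run.
    """
    rows = []
    for polymer in config.polymers:
        for mode in config.modes:
            for replicate in range(config.replicates):
                seed = config.cell_seed(polymer, mode, replicate)
                base = {
                    "polymer": polymer,
                    "mode": mode,
                    "replicate": replicate,
                    "seed": seed,
                    "version": __version__,
                    "planted": config.planted,
                }
                log.info("cell %s/%s/r%d (seed %d)", polymer, mode, replicate, seed)
                try:
                    rep = run_cell(config, polymer, mode, replicate)
                except Exception as exc:  # noqa: BLE001 — matrix must continue
                    log.error("cell %s failed: %s", base, exc)
                    rows.append({**base, "status": "failed", "error": str(exc)})
                    continue
                e = abs(rep.means["e_lj"]) + abs(rep.means["e_coul"])
                rows.append(
                    {
                        **base,
                        "status": "ok",
                        "error": "",
                        "n_frames": rep.n_frames,
                        "mean_contacts": rep.means["n_contacts"],
                        "sem_contacts": rep.sems["n_contacts"],
                        "mean_hbonds": rep.means["n_hbonds"],
                        "sem_hbonds": rep.sems["n_hbonds"],
                        "mean_bridges": rep.means["n_bridges"],
                        "sem_bridges": rep.sems["n_bridges"],
                        "mean_cation_surface": rep.means["n_cation_surface"],
                        "e_lj": rep.means["e_lj"],
                        "e_coul": rep.means["e_coul"],
                        "prop_lj": abs(rep.means["e_lj"]) / e if e else 0.0,
                        "prop_coul": abs(rep.means["e_coul"]) / e if e else 0.0,
                        "prop_end_grafted": rep.mode_proportions["end_grafted"],
                        "prop_u_shaped": rep.mode_proportions["u_shaped"],
                        "prop_mixed": rep.mode_proportions["mixed"],
                        "prop_desorbed": rep.mode_proportions["desorbed"],
                    }
                )
    summary = pd.DataFrame(rows)
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / "matrix_summary.csv", index=False)
        (out / "matrix_report.md").write_text(report(summary))
    return summary


def report(summary: pd.DataFrame) -> str:
    """Markdown summary shaped like the study's figure tables.

    Per-polymer mean contacts, hydrogen bonds, cationic bridges, energy
    proportions and pose-mode proportions, with standard errors over
    replicates where available.
    """
    lines = ["# Polymer–surface adsorption summary", ""]
    if summary.empty:
        lines += ["| polymer | mode | replicates |", "|---|---|---|", ""]
        return "\n".join(lines)
    ok = summary[summary["status"] == "ok"] if "status" in summary else summary
    if ok.empty:
        lines.append("_All cells failed._")
        return "\n".join(lines)

    def sem(x: pd.Series) -> float:
        return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0

    def table(title: str, cols: dict[str, str]) -> None:
        lines.append(f"## {title}")
        lines.append("")
        header = "| polymer | mode | " + " | ".join(cols.values()) + " |"
        lines.append(header)
        lines.append("|" + "---|" * (2 + len(cols)))
        for (polymer, mode), grp in ok.groupby(["polymer", "mode"], sort=False):
            cells = [
                f"{grp[c].mean():.3g} ± {sem(grp[c]):.2g}" for c in cols
            ]
            lines.append(f"| {polymer} | {mode} | " + " | ".join(cells) + " |")
        lines.append("")

    table("Polymer–surface contacts (0.5 nm shell)",
          {"mean_contacts": "contacts", "mean_cation_surface": "cation–surface"})
    table("Hydrogen bonds and cationic bridges",
          {"mean_hbonds": "H-bonds", "mean_bridges": "bridges"})
    table("Short-range energy proportions",
          {"prop_lj": "LJ fraction", "prop_coul": "Coulomb fraction"})
    table("Pose-mode proportions over release frames",
          {"prop_end_grafted": "end-grafted", "prop_u_shaped": "u-shaped",
           "prop_mixed": "mixed", "prop_desorbed": "desorbed"})
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# configuration files
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> RunConfig:
    """Hierarchical YAML config; unknown top-level keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs: dict = {}
    for key, value in raw.items():
        if key == "rules":
            kwargs[key] = PlacementRules(**value)
        elif key == "ff":
            kwargs[key] = ForceFieldParams(**value)
        elif key == "analysis":
            kwargs[key] = AnalysisParams(**value)
        elif key in ("polymers", "modes", "slab_replication"):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


def dump_config(config: RunConfig, path: str | Path) -> None:
    data = asdict(config)
    data["rules"] = asdict(config.rules)
    data["ff"] = {
        "cutoff": config.ff.cutoff,
        "bond_k": config.ff.bond_k,
        "angle_k": config.ff.angle_k,
    }
    data["analysis"] = asdict(config.analysis)
    for key in ("polymers", "modes", "slab_replication"):
        data[key] = list(data[key])
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
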