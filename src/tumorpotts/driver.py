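"""Configuration, initialization, the per-MCS schedule and parameter scans.

A run starts from a single quiescent stem cell (3x3 voxels by default) in
the middle of an all-Medium lattice with the glucose field at its stromal
equilibrium alpha/epsilon.  Each MCS then executes, in fixed order:

1. one Monte Carlo step of voxel-copy attempts;
2. a steady-state glucose re-solve every ``solve_every`` MCS;
3. after the initial relaxation window (``MCSThr`` MCS) the biology:
   starvation/health accumulation -> state transitions -> growth and
   necrotic shrinkage -> mitosis (with fate and mutation);
4. a snapshot every ``snapshot_interval`` MCS.

A (config, seed) pair fully determines every output byte: all randomness
flows through one seeded generator in a fixed call order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .adhesion import AdhesionModel
from .analysis import snapshot_record, write_snapshots
from .cell_state import TransitionThresholds, accumulate, apply_transitions
from .cpm_core import (
    SimState,
    TYPE_QSTEM,
    check_integrity,
    monte_carlo_step,
)
from .glucose import GlucoseField, solve_steady_state
from .growth_death import GrowthParams, grow_and_shrink_all
from .mitosis_evolution import EvolutionParams, step_mitosis

__all__ = ["RunConfig", "ConfigError", "Simulation", "initialize", "run", "parameter_scan"]

logger = logging.getLogger("tumorpotts")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(name)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass
class RunConfig:
    """Flat reference parameter set (key names follow the model's parameter
    table); see the methods note for units and provenance of defaults."""

    # lattice / engine
    dim_x: int = 500
    dim_y: int = 500
    Tm: float = 50.0
    neighbor_order: int = 3
    steps: int = 1000000
    seed: int = 2284322
    # adhesion
    FN0: float = 16.0
    Cad0: float = 8.0
    Int0: float = 8.0
    kCadCad: float = 2.0
    kIntFN: float = 0.2
    # glucose transport
    D_G: float = 13500.0
    eps: float = 0.45
    alpha: float = 0.145
    PUgMax: float = 2.25
    QUgMax: float = 1.69
    SUgMax: float = 2.25
    QSUgMax: float = 1.69
    GluK: float = 0.00256
    solve_every: int = 10
    # volume/surface constraints
    V0: float = 16.0
    S0: float = 16.0
    LBD_V0: float = 15.0
    LBD_S0: float = 5.0
    ktgs: float = 4.0
    # growth / death
    incvol: float = 0.2
    decvol: float = 0.01
    PGrThr0: float = 0.032
    SGrThr0: float = 0.032
    # state transitions
    GluD: float = 0.032
    PNeThr0: float = 102.0
    QNeThr0: float = 204.0
    SNeThr0: float = 408.0
    QSNeThr0: float = 916.0
    QPThr0: float = 79.5
    QSSThr0: float = 79.5
    MCSThr: int = 50
    # mitosis / evolution
    volmaxmit: float = 32.0
    Svolmaxmit: float = 32.0
    maxdiv: float = 8.0
    divstdev: float = 2.0
    probstem: float = 0.2
    probmut: float = 0.1
    cadhstdev: float = 2.0
    # bookkeeping
    snapshot_interval: int = 1000
    initial_cell_size: int = 3

    def __post_init__(self) -> None:
        if self.dim_x < 4 or self.dim_y < 4:
            raise ConfigError("lattice dimensions must be at least 4x4")
        if self.Tm <= 0:
            raise ConfigError("Tm must be > 0")
        if self.steps < 0 or self.snapshot_interval < 1 or self.solve_every < 1:
            raise ConfigError("steps, snapshot_interval and solve_every must be valid")
        if self.initial_cell_size not in (3, 8):
            raise ConfigError("initial_cell_size must be 3 (default) or 8")

    # -- serialization ---------------------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    # -- views into the module parameter objects -------------------------

    def adhesion_model(self) -> AdhesionModel:
        return AdhesionModel(k={("Cad", "Cad"): self.kCadCad, ("Int", "FN"): self.kIntFN})

    def thresholds(self) -> TransitionThresholds:
        return TransitionThresholds(
            GluD=self.GluD, PNeThr0=self.PNeThr0, QNeThr0=self.QNeThr0,
            SNeThr0=self.SNeThr0, QSNeThr0=self.QSNeThr0,
            QPThr0=self.QPThr0, QSSThr0=self.QSSThr0,
            PUgMax=self.PUgMax, QUgMax=self.QUgMax,
            SUgMax=self.SUgMax, QSUgMax=self.QSUgMax, GluK=self.GluK,
        )

    def growth_params(self) -> GrowthParams:
        return GrowthParams(
            incvol=self.incvol, PGrThr0=self.PGrThr0, SGrThr0=self.SGrThr0,
            ktgs=self.ktgs, decvol=self.decvol, V0=self.V0, S0=self.S0,
        )

    def evolution_params(self) -> EvolutionParams:
        return EvolutionParams(
            volmaxmit=self.volmaxmit, Svolmaxmit=self.Svolmaxmit,
            maxdiv=self.maxdiv, div_sd=self.divstdev,
            probstem=self.probstem, probmut=self.probmut,
            cadhstdev=self.cadhstdev, V0=self.V0, S0=self.S0,
            LBD_V0=self.LBD_V0, LBD_S0=self.LBD_S0, ktgs=self.ktgs,
        )

    def glucose_field(self) -> GlucoseField:
        from .cpm_core import TYPE_PCANCER, TYPE_PSTEM, TYPE_QCANCER, TYPE_QSTEM

        return GlucoseField(
            dims=(self.dim_x, self.dim_y), D_G=self.D_G, epsilon=self.eps,
            alpha=self.alpha, solve_every=self.solve_every,
            uptake_params={
                TYPE_PCANCER: (self.PUgMax, self.GluK),
                TYPE_PSTEM: (self.SUgMax, self.GluK),
                TYPE_QCANCER: (self.QUgMax, self.GluK),
                TYPE_QSTEM: (self.QSUgMax, self.GluK),
            },
        )


@dataclass
class Simulation:
    """A live replica: lattice state, glucose field and parameter views."""

    config: RunConfig
    seed: int
    state: SimState
    field: GlucoseField
    thresholds: TransitionThresholds
    growth: GrowthParams
    evolution: EvolutionParams


def initialize(config: RunConfig, seed: int | None = None) -> Simulation:
    """Build the initial condition: one quiescent stem cell (a
    ``initial_cell_size``-square) centered in an all-Medium lattice."""
    seed = config.seed if seed is None else int(seed)
    state = SimState(
        (config.dim_x, config.dim_y),
        model=config.adhesion_model(),
        Tm=config.Tm,
        rng=np.random.default_rng(seed),
        copy_neighbor_order=config.neighbor_order,
    )
    w = config.initial_cell_size
    cid = state.cells.new_cell(
        TYPE_QSTEM,
        target_volume=config.V0,
        target_surface=config.S0,
        lambda_vol=config.LBD_V0,
        lambda_sur=config.LBD_S0,
        cad=config.Cad0,
        intg=config.Int0,
        fn=0.0,
    )
    x0 = config.dim_x // 2 - w // 2
    y0 = config.dim_y // 2 - w // 2
    state.paint_rect(cid, x0, y0, w, h=w)
    state.rebuild_bookkeeping()
    return Simulation(
        config=config,
        seed=seed,
        state=state,
        field=config.glucose_field(),
        thresholds=config.thresholds(),
        growth=config.growth_params(),
        evolution=config.evolution_params(),
    )


def _retire_empty(state: SimState) -> None:
    c = state.cells
    empty = np.flatnonzero(c.alive[: c.n] & (c.volume[: c.n] == 0))
    for cid in empty:
        if cid != 0:
            c.retire(int(cid))


def run(
    config: RunConfig,
    seed: int | None = None,
    out_dir: str | Path | None = None,
    progress: bool = False,
) -> tuple[pd.DataFrame, Simulation]:
    """Execute a full replica; returns (snapshot series, final simulation).

    With ``out_dir`` the snapshot series, the config copy and a completion
    marker are written there.
    """
    sim = initialize(config, seed)
    state, field = sim.state, sim.field
    frames = [snapshot_record(state)]
    for mcs in range(1, config.steps + 1):
        monte_carlo_step(state)
        _retire_empty(state)
        if mcs % config.solve_every == 0:
            solve_steady_state(field, state)
        if mcs > config.MCSThr:
            accumulate(state, field, sim.thresholds)
            apply_transitions(state, sim.thresholds)
            grow_and_shrink_all(state, field, sim.growth)
            step_mitosis(state, sim.evolution, state.rng)
        if mcs % config.snapshot_interval == 0:
            frames.append(snapshot_record(state))
            if progress:
                n_cells = int(state.cells.living_ids().size)
                logger.info("mcs %d: %d cells", mcs, n_cells)
    series = pd.concat(frames, ignore_index=True)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")
        write_snapshots(
            out / "snapshots.csv",
            series,
            meta={"seed": sim.seed, "config_hash": config.config_hash()},
        )
        (out / "run_meta.json").write_text(
            json.dumps({"seed": sim.seed, "steps": config.steps, "status": "complete"})
        )
    check_integrity(state)
    return series, sim


def parameter_scan(
    base_config: RunConfig,
    pm_values,
    dam_values,
    n_replicas: int,
    out_dir: str | Path,
    seed0: int | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Run a (probmut x cadhstdev) grid with ``n_replicas`` replicas each.

    One directory per (P_m, delta_am, replica) holds the config copy and
    snapshot series; completed runs (marked by run_meta.json) are skipped
    on resume.  Returns the scan manifest (also written as manifest.csv).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed0 = base_config.seed if seed0 is None else int(seed0)
    rows = []
    idx = 0
    for pm in pm_values:
        for dam in dam_values:
            for rep in range(n_replicas):
                seed = seed0 + idx
                idx += 1
                rep_dir = out / f"pm_{pm}" / f"dam_{dam}" / f"rep_{rep}"
                cfg = dataclasses.replace(
                    base_config, probmut=float(pm), cadhstdev=float(dam), seed=seed
                )
                marker = rep_dir / "run_meta.json"
                if not marker.exists():
                    run(cfg, seed=seed, out_dir=rep_dir, progress=progress)
                elif progress:
                    logger.info("skipping completed %s", rep_dir)
                rows.append(
                    {
                        "probmut": float(pm),
                        "cadhstdev": float(dam),
                        "replica": rep,
                        "seed": seed,
                        "path": str(rep_dir),
                    }
                )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
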