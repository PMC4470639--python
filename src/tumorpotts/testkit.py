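"""Deterministic fixtures: tiny lattices, synthetic point clouds and
scaled-down run profiles, so every module is testable without a long run.

Scaled profiles shrink the lattice and the duration but keep every rate
constant, so local dynamics (growth rates, starvation clocks, mutation
statistics) are unchanged; only globally supply-limited quantities such as
the maximum tumor size scale with the lattice.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .adhesion import AdhesionModel
from .cpm_core import SimState, TYPE_CODES
from .driver import RunConfig

__all__ = ["make_small_lattice", "make_point_cloud", "make_scaled_config"]


def make_small_lattice(
    cell_specs: list[dict],
    dims: tuple[int, int] = (12, 12),
    model: AdhesionModel | None = None,
    Tm: float = 50.0,
    rng: np.random.Generator | int | None = 0,
) -> SimState:
    """Build a consistent state from rectangle specs.

    Each spec is a dict with keys ``x0, y0, w, h`` and optional ``type``
    (name or code, default PCancer), ``cad``, ``int``, ``fn``, ``V``, ``S``,
    ``lambda_vol``, ``lambda_sur``.  Rectangles are painted in order (later
    ones overwrite) and all bookkeeping is recounted, never assumed.
    """
    state = SimState(dims, model=model, Tm=Tm, rng=rng)
    for spec in cell_specs:
        t = spec.get("type", "PCancer")
        code = TYPE_CODES[t] if isinstance(t, str) else int(t)
        cid = state.cells.new_cell(
            code,
            target_volume=spec.get("V", 16.0),
            target_surface=spec.get("S", 16.0),
            lambda_vol=spec.get("lambda_vol", 15.0),
            lambda_sur=spec.get("lambda_sur", 5.0),
            cad=spec.get("cad", 8.0),
            intg=spec.get("int", 8.0),
            fn=spec.get("fn", 0.0),
        )
        state.paint_rect(cid, spec["x0"], spec["y0"], spec["w"], spec["h"])
    state.rebuild_bookkeeping()
    return state


def make_random_lattice(
    dims: tuple[int, int],
    n_cells: int,
    rng: np.random.Generator,
    model: AdhesionModel | None = None,
    Tm: float = 50.0,
) -> SimState:
    """Random blobby configuration for property tests: each cell is seeded
    as a small rectangle with random densities and targets."""
    W, H = dims
    specs = []
    for _ in range(n_cells):
        w = int(rng.integers(1, max(2, W // 3)))
        h = int(rng.integers(1, max(2, H // 3)))
        specs.append(
            {
                "x0": int(rng.integers(0, W)),
                "y0": int(rng.integers(0, H)),
                "w": w,
                "h": h,
                "type": "PCancer",
                "cad": float(rng.uniform(0, 16)),
                "int": float(rng.uniform(0, 16)),
                "V": float(rng.uniform(1, 20)),
                "S": float(rng.uniform(1, 20)),
                "lambda_vol": float(rng.uniform(0, 20)),
                "lambda_sur": float(rng.uniform(0, 10)),
            }
        )
    state = make_small_lattice(specs, dims=dims, model=model, Tm=Tm, rng=rng)
    return state


def make_point_cloud(
    blobs: list[tuple[tuple[float, float], int, float]],
    rng: np.random.Generator | int | None = 0,
) -> np.ndarray:
    """Gaussian blobs of cell centers: each entry is (center, n, spread)."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    parts = [
        np.asarray(center, dtype=float) + spread * rng.standard_normal((n, 2))
        for center, n, spread in blobs
    ]
    return np.vstack(parts) if parts else np.empty((0, 2))


_PROFILES = {
    "smoke": dict(dim_x=50, dim_y=50, steps=500, snapshot_interval=100),
    "desk": dict(dim_x=100, dim_y=100, steps=5000, snapshot_interval=250),
    "reference": dict(),
}


def make_scaled_config(profile: str = "desk", **overrides) -> RunConfig:
    """Run profiles: ``smoke`` (50x50, 500 MCS), ``desk`` (100x100,
    5000 MCS) and ``reference`` (the full published parameter set,
    500x500, 10^6 MCS).  Keyword overrides are applied last."""
    if profile not in _PROFILES:
        raise ValueError(f"unknown profile {profile!r}; choose from {sorted(_PROFILES)}")
    cfg = RunConfig(**_PROFILES[profile])
    if overrides:
        cfg = dataclasses.replace(cfg, **overrides)
    return cfg
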