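"""Steady-state glucose transport with Michaelis-Menten tumor uptake.

The field G (fmol/voxel) obeys, on the periodic lattice,

    0 = D_G lap(G) - eps*G + alpha*[voxel is Medium] - u(G)*[voxel in living tumor cell]

with u(G) = u_max * G / (G + K).  Secretion alpha acts only in Medium;
first-order decay eps acts everywhere; Michaelis-Menten uptake acts
per-voxel in living tumor cells (Necrotic cells take up nothing).  Because
glucose diffuses fast relative to cell rearrangement, the field is solved
to steady state every ``solve_every`` MCS and held frozen in between.

The nonlinear system is solved by damped Newton iteration on the discrete
residual with a sparse direct solve of the Jacobian (the uptake derivative
u_max*K/(G+K)^2 makes the problem stiff near depleted regions, where simple
relaxation sweeps stall).  Convergence is measured as the max-norm residual
relative to the source scale.

Units: a voxel is a 4 um x 4 um x 4 um slab element (so 5 mM corresponds to
0.32 fmol/voxel), a cell is 16 voxels, and 1 MCS is 6 minutes (set by
matching simulated to experimental migration speeds).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .cpm_core import (
    SimState,
    TYPE_PCANCER,
    TYPE_PSTEM,
    TYPE_QCANCER,
    TYPE_QSTEM,
)

__all__ = [
    "GlucoseField",
    "SolverError",
    "mm_uptake",
    "solve_steady_state",
    "concentration_at_com",
    "convert_units",
    "VOXEL_SIDE_UM",
    "MCS_MINUTES",
]

# Spatial and temporal calibration shared by all unit conversions.
VOXEL_SIDE_UM = 4.0          # voxel side; area 16 um^2, slab depth 4 um
VOXEL_VOLUME_L = (VOXEL_SIDE_UM * 1e-6) ** 3 * 1e3   # 6.4e-14 L
CELL_VOXELS = 16.0           # reference cell footprint
SIM_SPEED_VOXEL_PER_MCS = 0.1   # typical simulated migration speed
MCS_MINUTES = 6.0            # from matching 0.1 voxel/MCS to 4 um/h
MCS_SECONDS = MCS_MINUTES * 60.0
MM_PER_FMOL_VOXEL = 1.0 / 0.064   # 5 mM <-> 0.32 fmol/voxel


class SolverError(RuntimeError):
    """Steady-state solver failed to converge; message reports the residual."""


@dataclass
class GlucoseField:
    """Per-voxel glucose concentration and its transport parameters.

    Reference values: D_G = 13500 voxel^2/MCS (600 um^2/s), decay
    eps = 0.45 /MCS, Medium secretion alpha = 0.145 fmol/voxel/MCS, uptake
    u_max = 2.25 (proliferating) / 1.69 (quiescent) fmol/voxel/MCS with
    K = 0.00256 fmol/voxel (0.04 mM).
    """

    dims: tuple[int, int]
    D_G: float = 13500.0
    epsilon: float = 0.45
    alpha: float = 0.145
    uptake_params: dict = dataclass_field(
        default_factory=lambda: {
            TYPE_PCANCER: (2.25, 0.00256),
            TYPE_PSTEM: (2.25, 0.00256),
            TYPE_QCANCER: (1.69, 0.00256),
            TYPE_QSTEM: (1.69, 0.00256),
        }
    )
    solve_every: int = 10
    tol: float = 1e-6
    max_newton: int = 50
    conc: np.ndarray | None = None

    def __post_init__(self) -> None:
        if min(self.D_G, self.epsilon, self.alpha) < 0:
            raise ValueError("glucose transport rates must be >= 0")
        if self.conc is None:
            # uniform stromal equilibrium alpha/eps before the first solve
            g0 = self.alpha / self.epsilon if self.epsilon > 0 else 0.0
            self.conc = np.full(self.dims, g0, dtype=np.float64)

    def uptake_maps(self, state: SimState) -> tuple[np.ndarray, np.ndarray]:
        """Per-voxel (u_max, K) maps from the current lattice configuration."""
        c = state.cells
        umax_by_code = np.zeros(6)
        k_by_code = np.zeros(6)
        for code, (um, kk) in self.uptake_params.items():
            umax_by_code[code] = um
            k_by_code[code] = max(kk, 1e-300)
        codes = c.type_code[state.sigma]
        return umax_by_code[codes], k_by_code[codes]


def mm_uptake(G, u_max, K):
    """Michaelis-Menten rate u_max * G / (G + K); 0 at G = K = 0."""
    G = np.asarray(G, dtype=np.float64)
    if np.any(G < 0) or np.any(np.asarray(u_max) < 0) or np.any(np.asarray(K) < 0):
        raise ValueError("mm_uptake arguments must be non-negative")
    denom = G + K
    out = np.divide(u_max * G, denom, out=np.zeros_like(G, dtype=np.float64),
                    where=denom > 0)
    return float(out) if out.ndim == 0 else out


_LAPLACIANS: dict[tuple[int, int], sp.csr_matrix] = {}


def periodic_laplacian(dims: tuple[int, int]) -> sp.csr_matrix:
    """5-point Laplacian on a periodic (W, H) grid, cached per shape."""
    if dims not in _LAPLACIANS:
        W, H = dims
        ex = sp.diags([np.ones(W - 1)], [1], shape=(W, W), format="lil")
        ex[0, W - 1] = 1
        ey = sp.diags([np.ones(H - 1)], [1], shape=(H, H), format="lil")
        ey[0, H - 1] = 1
        ax = (ex + ex.T).tocsr()
        ay = (ey + ey.T).tocsr()
        lap = sp.kron(ax, sp.identity(H)) + sp.kron(sp.identity(W), ay)
        lap = lap - 4.0 * sp.identity(W * H)
        _LAPLACIANS[dims] = lap.tocsr()
    return _LAPLACIANS[dims]


def solve_steady_state(field: GlucoseField, state: SimState) -> GlucoseField:
    """Solve the steady-state transport equation in place; returns the field.

    Warm-started from the current concentration; a field whose residual is
    already below tolerance is returned untouched.
    """
    W, H = field.dims
    lap = periodic_laplacian(field.dims)
    medium = (state.sigma == 0).ravel().astype(np.float64)
    um_map, k_map = field.uptake_maps(state)
    um = um_map.ravel()
    kk = k_map.ravel()
    g = field.conc.ravel().copy()

    scale = max(field.alpha, field.epsilon * float(np.abs(g).max(initial=0.0)), 1e-12)

    def residual(gv: np.ndarray) -> np.ndarray:
        gp = np.maximum(gv, 0.0)
        uptake = np.divide(um * gp, gp + kk, out=np.zeros_like(gp), where=(gp + kk) > 0)
        return field.D_G * (lap @ gv) - field.epsilon * gv + field.alpha * medium - uptake

    def refactor(gv: np.ndarray):
        gp = np.maximum(gv, 0.0)
        dup = np.divide(um * kk, (gp + kk) ** 2, out=np.zeros_like(gp), where=(gp + kk) > 0)
        jac = (field.D_G * lap - sp.diags(field.epsilon + dup)).tocsc()
        return spla.splu(jac)

    # Quasi-Newton: the Jacobian factorization is cached on the field and
    # reused across re-solves (the uptake-derivative diagonal changes only
    # where the tumor moved); it is rebuilt whenever contraction stalls.
    lu = getattr(field, "_lu_cache", None)
    r = residual(g)
    for _ in range(field.max_newton):
        r_norm = np.abs(r).max()
        if r_norm <= field.tol * scale:
            break
        if lu is None:
            lu = refactor(g)
        step = lu.solve(-r)
        # backtracking with sufficient decrease (Armijo-style); keep the best
        # candidate if no step qualifies
        lam = 1.0
        best = None
        for _ in range(30):
            # projected step: concentrations live in G >= 0, and the MM
            # uptake degenerates outside it
            g_new = np.maximum(g + lam * step, 0.0)
            r_new = residual(g_new)
            if best is None or np.abs(r_new).max() < np.abs(best[1]).max():
                best = (g_new, r_new)
            if np.abs(r_new).max() <= (1.0 - 0.3 * lam) * r_norm:
                break
            lam *= 0.5
        g_new, r_new = best
        if np.abs(r_new).max() > 0.25 * r_norm:
            lu = refactor(g_new)  # stalled: rebuild at the current iterate
        g, r = g_new, r_new
    else:
        raise SolverError(
            f"steady-state glucose solver did not converge: residual "
            f"{np.abs(r).max():.3e} vs tolerance {field.tol * scale:.3e}"
        )
    field._lu_cache = lu
    field.conc = np.maximum(g, 0.0).reshape(W, H)
    return field


def concentration_at_com(field: GlucoseField, state: SimState, cid: int) -> float:
    """Concentration at the voxel containing the cell's (wrapped) center of
    mass; coordinates on a voxel boundary round down."""
    c = state.cells
    if not c.alive[cid] or c.volume[cid] == 0:
        raise KeyError(f"cell {cid} is retired or empty")
    cx, cy = c.com(cid, wrapped_dims=state.dims)
    ix = int(np.floor(cx)) % state.dims[0]
    iy = int(np.floor(cy)) % state.dims[1]
    return float(field.conc[ix, iy])


def concentrations_at_coms(field: GlucoseField, state: SimState, ids: np.ndarray) -> np.ndarray:
    """Vectorized :func:`concentration_at_com` for an id array."""
    c = state.cells
    W, H = state.dims
    vols = c.volume[ids].astype(np.float64)
    cx = (c.comx_sum[ids] / vols) % W
    cy = (c.comy_sum[ids] / vols) % H
    ix = np.floor(cx).astype(np.int64) % W
    iy = np.floor(cy).astype(np.int64) % H
    return field.conc[ix, iy]


_CONVERTERS = {
    "mM_to_fmol_per_voxel": lambda v: v / MM_PER_FMOL_VOXEL,
    "fmol_per_voxel_to_mM": lambda v: v * MM_PER_FMOL_VOXEL,
    "um2_per_s_to_voxel2_per_mcs": lambda v: v * MCS_SECONDS / VOXEL_SIDE_UM**2,
    "voxel2_per_mcs_to_um2_per_s": lambda v: v * VOXEL_SIDE_UM**2 / MCS_SECONDS,
    "fmol_per_cell_s_to_fmol_per_voxel_mcs": lambda v: v * MCS_SECONDS / CELL_VOXELS,
    "fmol_per_voxel_mcs_to_fmol_per_cell_s": lambda v: v * CELL_VOXELS / MCS_SECONDS,
}


def convert_units(kind: str, value: float) -> float:
    """Exact arithmetic unit conversions used to calibrate the model.

    Kinds: ``mM_to_fmol_per_voxel`` (and inverse), ``um2_per_s_to_voxel2_per_mcs``
    (and inverse), ``fmol_per_cell_s_to_fmol_per_voxel_mcs`` (and inverse),
    and ``um_per_h_speed_to_minutes_per_mcs`` which returns the MCS duration
    implied by matching the simulated migration speed (0.1 voxel/MCS) to an
    experimental speed in um/h.
    """
    if kind == "um_per_h_speed_to_minutes_per_mcs":
        if value <= 0:
            raise ValueError("experimental speed must be positive")
        return SIM_SPEED_VOXEL_PER_MCS * VOXEL_SIDE_UM * 60.0 / value
    try:
        return _CONVERTERS[kind](value)
    except KeyError:
        raise ValueError(f"unknown conversion kind: {kind!r}") from None
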