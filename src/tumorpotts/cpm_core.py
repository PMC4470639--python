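"""Glazier-Graner-Hogeweg (Cellular Potts) lattice engine.

Generalized cells are domains of voxels sharing one index on a 2D periodic
square lattice; index 0 is the Medium (stroma + ECM), which carries no
volume or surface constraint.  The effective energy is

    H = E_adh + sum_c lambda_vol_c (v_c - V_c)^2 + sum_c lambda_sur_c (s_c - S_c)^2

with the adhesion term from :mod:`tumorpotts.adhesion`.  Dynamics are a
series of voxel-copy attempts: a target voxel and a source voxel from its
order-3 neighborhood are drawn uniformly, and the source index overwrites
the target with Metropolis probability 1 for dH <= 0 and exp(-dH/Tm)
otherwise.  One Monte Carlo step (MCS) is N attempts, N the voxel count.

The attempt loop is a numba kernel operating on a structure-of-arrays cell
registry; volume, surface and center of mass are maintained incrementally
and can be verified against full recounts.  Centers of mass are kept in
unwrapped coordinates (each added/removed voxel is taken at its periodic
image nearest the cell's current center), so they do not jump when a cell
crosses the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .adhesion import AdhesionModel, contact_energy_total, neighbor_offsets

__all__ = [
    "TYPE_MEDIUM",
    "TYPE_PCANCER",
    "TYPE_QCANCER",
    "TYPE_NECROTIC",
    "TYPE_PSTEM",
    "TYPE_QSTEM",
    "TYPE_NAMES",
    "TYPE_CODES",
    "LIVING_TUMOR_TYPES",
    "TUMOR_TYPES",
    "EngineParams",
    "CellRegistry",
    "SimState",
    "IntegrityError",
    "total_energy",
    "delta_H",
    "acceptance_probability",
    "attempt_voxel_copy",
    "monte_carlo_step",
    "check_integrity",
]

# Cell-type taxonomy: Medium plus proliferating/quiescent cancer and
# stem-like cells and Necrotic debris.
TYPE_MEDIUM = 0
TYPE_PCANCER = 1
TYPE_QCANCER = 2
TYPE_NECROTIC = 3
TYPE_PSTEM = 4
TYPE_QSTEM = 5

TYPE_NAMES = ("Medium", "PCancer", "QCancer", "Necrotic", "PStem", "QStem")
TYPE_CODES = {name: code for code, name in enumerate(TYPE_NAMES)}
LIVING_TUMOR_TYPES = (TYPE_PCANCER, TYPE_QCANCER, TYPE_PSTEM, TYPE_QSTEM)
TUMOR_TYPES = LIVING_TUMOR_TYPES + (TYPE_NECROTIC,)


class IntegrityError(RuntimeError):
    """Lattice and cell registry disagree (volume/surface/COM mismatch)."""


@dataclass
class EngineParams:
    """Membrane-fluctuation amplitude and RNG seed for one replica."""

    Tm: float = 50.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.Tm <= 0:
            raise ValueError(f"Tm must be > 0, got {self.Tm}")


class CellRegistry:
    """Structure-of-arrays record of all generalized cells, indexed by id.

    Row 0 is the Medium: unconstrained, carries the Medium adhesion-molecule
    densities (fibronectin).  Rows are never reused; a cell whose volume
    reaches zero is retired (``alive = False``).
    """

    _FLOAT_FIELDS = (
        "target_volume",
        "target_surface",
        "lambda_vol",
        "lambda_sur",
        "starv",
        "health",
        "comx_sum",
        "comy_sum",
    )

    def __init__(self, model: AdhesionModel, capacity: int = 64):
        self.model = model
        cap = max(int(capacity), 2)
        self.type_code = np.zeros(cap, dtype=np.int64)
        self.volume = np.zeros(cap, dtype=np.int64)
        self.surface = np.zeros(cap, dtype=np.int64)
        self.counter = np.zeros(cap, dtype=np.int64)
        self.alive = np.zeros(cap, dtype=bool)
        self.dens = np.zeros((cap, 3), dtype=np.float64)
        for name in self._FLOAT_FIELDS:
            setattr(self, name, np.zeros(cap, dtype=np.float64))
        # Medium row.
        self.n = 1
        self.alive[0] = True
        self.dens[0] = model.medium_density_vector()

    @property
    def capacity(self) -> int:
        return self.type_code.size

    def _grow(self, need: int) -> None:
        cap = self.capacity
        new_cap = max(cap * 2, need)
        for name in ("type_code", "volume", "surface", "counter", "alive") + self._FLOAT_FIELDS:
            arr = getattr(self, name)
            grown = np.zeros(new_cap, dtype=arr.dtype)
            grown[:cap] = arr
            setattr(self, name, grown)
        dens = np.zeros((new_cap, 3), dtype=np.float64)
        dens[:cap] = self.dens
        self.dens = dens

    def new_cell(
        self,
        type_code: int,
        *,
        target_volume: float = 16.0,
        target_surface: float = 16.0,
        lambda_vol: float = 15.0,
        lambda_sur: float = 5.0,
        cad: float = 8.0,
        intg: float = 8.0,
        fn: float = 0.0,
    ) -> int:
        if self.n + 1 > self.capacity:
            self._grow(self.n + 1)
        cid = self.n
        self.n += 1
        self.type_code[cid] = type_code
        self.alive[cid] = True
        self.target_volume[cid] = target_volume
        self.target_surface[cid] = target_surface
        self.lambda_vol[cid] = lambda_vol
        self.lambda_sur[cid] = lambda_sur
        self.dens[cid] = (cad, intg, fn)
        return cid

    def retire(self, cid: int) -> None:
        if self.volume[cid] != 0:
            raise IntegrityError(f"cannot retire cell {cid} with volume {self.volume[cid]}")
        self.alive[cid] = False
        self.comx_sum[cid] = 0.0
        self.comy_sum[cid] = 0.0

    def living_ids(self, include_medium: bool = False) -> np.ndarray:
        ids = np.flatnonzero(self.alive[: self.n])
        if not include_medium:
            ids = ids[ids != 0]
        return ids

    def com(self, cid: int, wrapped_dims: tuple[int, int] | None = None) -> tuple[float, float]:
        """Center of mass; unwrapped by default, wrapped into the lattice if
        ``wrapped_dims`` is given."""
        v = self.volume[cid]
        if v == 0:
            raise IntegrityError(f"cell {cid} has no voxels")
        cx = self.comx_sum[cid] / v
        cy = self.comy_sum[cid] / v
        if wrapped_dims is not None:
            cx %= wrapped_dims[0]
            cy %= wrapped_dims[1]
        return cx, cy


class SimState:
    """Lattice + cell registry + engine parameters: one simulation replica."""

    def __init__(
        self,
        dims: tuple[int, int],
        model: AdhesionModel | None = None,
        Tm: float = 50.0,
        rng: np.random.Generator | int | None = None,
        copy_neighbor_order: int = 3,
    ):
        if Tm <= 0:
            raise ValueError(f"Tm must be > 0, got {Tm}")
        self.dims = (int(dims[0]), int(dims[1]))
        self.model = model if model is not None else AdhesionModel()
        self.sigma = np.zeros(self.dims, dtype=np.int64)
        self.cells = CellRegistry(self.model)
        self.Tm = float(Tm)
        if isinstance(rng, np.random.Generator):
            self.rng = rng
        else:
            self.rng = np.random.default_rng(rng)
        self.copy_offsets = neighbor_offsets(copy_neighbor_order)
        self.contact_offsets = neighbor_offsets(self.model.contact_neighbor_order)
        self.mcs = 0
        nzm, nzn, nzk = self.model.nonzero_terms()
        self._nzm, self._nzn, self._nzk = nzm, nzn, nzk

    # -- lattice editing -------------------------------------------------

    def paint_rect(self, cid: int, x0: int, y0: int, w: int, h: int) -> None:
        """Assign a (possibly wrapping) rectangle of voxels to cell ``cid``;
        bookkeeping is rebuilt afterwards with :meth:`rebuild_bookkeeping`."""
        xs = np.arange(x0, x0 + w) % self.dims[0]
        ys = np.arange(y0, y0 + h) % self.dims[1]
        self.sigma[np.ix_(xs, ys)] = cid

    def rebuild_bookkeeping(self) -> None:
        """Recount volumes, surfaces and centers of mass from the lattice."""
        c = self.cells
        c.volume[: c.n] = recount_volumes(self.sigma, c.n)
        c.surface[: c.n] = recount_surfaces(self.sigma, c.n)
        comx, comy = recount_com_sums(self.sigma, c.n, self.dims)
        c.comx_sum[: c.n] = comx
        c.comy_sum[: c.n] = comy


# ---------------------------------------------------------------------------
# Recount oracles (vectorized, used for initialization and integrity checks)
# ---------------------------------------------------------------------------


def recount_volumes(sigma: np.ndarray, n_cells: int) -> np.ndarray:
    return np.bincount(sigma.ravel(), minlength=n_cells)[:n_cells]


def recount_surfaces(sigma: np.ndarray, n_cells: int) -> np.ndarray:
    """Surface = per-cell count of directed first-order links to unlike voxels."""
    s = np.zeros(n_cells, dtype=np.int64)
    for dx, dy in neighbor_offsets(1):
        other = np.roll(np.roll(sigma, -dx, axis=0), -dy, axis=1)
        unlike = sigma != other
        s += np.bincount(sigma[unlike].ravel(), minlength=n_cells)[:n_cells]
    return s


def recount_com_sums(
    sigma: np.ndarray, n_cells: int, dims: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Recount unwrapped center-of-mass coordinate sums.

    Each cell's voxels are unwrapped to the periodic image nearest a
    reference voxel of that cell (its first voxel in scan order), which is
    exact for cells smaller than half the lattice in each direction.
    """
    W, H = dims
    comx = np.zeros(n_cells)
    comy = np.zeros(n_cells)
    flat = sigma.ravel()
    order = np.argsort(flat, kind="stable")
    sorted_ids = flat[order]
    xs = (order // H).astype(np.float64)
    ys = (order % H).astype(np.float64)
    starts = np.searchsorted(sorted_ids, np.arange(n_cells), side="left")
    ends = np.searchsorted(sorted_ids, np.arange(n_cells), side="right")
    for cid in range(n_cells):
        lo, hi = starts[cid], ends[cid]
        if lo == hi:
            continue
        rx, ry = xs[lo], ys[lo]
        ux = xs[lo:hi] - W * np.round((xs[lo:hi] - rx) / W)
        uy = ys[lo:hi] - H * np.round((ys[lo:hi] - ry) / H)
        # second pass relative to the provisional mean for stability
        mx, my = ux.mean(), uy.mean()
        ux = xs[lo:hi] - W * np.round((xs[lo:hi] - mx) / W)
        uy = ys[lo:hi] - H * np.round((ys[lo:hi] - my) / H)
        comx[cid] = ux.sum()
        comy[cid] = uy.sum()
    return comx, comy


def check_integrity(state: SimState) -> None:
    """Raise :class:`IntegrityError` if incremental bookkeeping has drifted."""
    c = state.cells
    vols = recount_volumes(state.sigma, c.n)
    if not np.array_equal(vols, c.volume[: c.n]):
        raise IntegrityError("volume bookkeeping disagrees with lattice recount")
    if vols.sum() != state.dims[0] * state.dims[1]:
        raise IntegrityError("voxel conservation violated")
    surfs = recount_surfaces(state.sigma, c.n)
    live = c.alive[: c.n].copy()
    live[0] = False
    if not np.array_equal(surfs[live], c.surface[: c.n][live]):
        raise IntegrityError("surface bookkeeping disagrees with lattice recount")
    if np.any(vols[~c.alive[: c.n]] != 0):
        raise IntegrityError("retired cell still owns voxels")


# ---------------------------------------------------------------------------
# Energy
# ---------------------------------------------------------------------------


def total_energy(state: SimState) -> float:
    """Full effective energy: adhesion + volume + surface constraints.

    Medium contributes no constraint terms.  Raises on registry/lattice
    volume mismatch.
    """
    c = state.cells
    vols = recount_volumes(state.sigma, c.n)
    if not np.array_equal(vols, c.volume[: c.n]):
        raise IntegrityError("volume bookkeeping disagrees with lattice recount")
    e = contact_energy_total(state.sigma, c.dens[: c.n], state.model)
    live = c.alive[: c.n].copy()
    live[0] = False
    dv = c.volume[: c.n][live] - c.target_volume[: c.n][live]
    ds = c.surface[: c.n][live] - c.target_surface[: c.n][live]
    e += float(np.sum(c.lambda_vol[: c.n][live] * dv * dv))
    e += float(np.sum(c.lambda_sur[: c.n][live] * ds * ds))
    return e


def delta_H(state: SimState, target: tuple[int, int], source: tuple[int, int]) -> float:
    """Energy change of copying the source voxel's index onto the target.

    Computed from local terms only (adhesion pairs involving the target,
    volume terms of the two cells, surface terms of the two cells and the
    target's first-order neighbors); no state is mutated.
    """
    W, H = state.dims
    tx, ty = int(target[0]) % W, int(target[1]) % H
    sx, sy = int(source[0]) % W, int(source[1]) % H
    st = int(state.sigma[tx, ty])
    ss = int(state.sigma[sx, sy])
    if st == ss:
        raise ValueError("target and source voxels belong to the same cell")
    c = state.cells
    ids = np.empty(6, dtype=np.int64)
    dsv = np.empty(6, dtype=np.int64)
    dh, _ = _local_delta(
        state.sigma,
        W,
        H,
        tx,
        ty,
        ss,
        c.dens,
        state._nzm,
        state._nzn,
        state._nzk,
        c.volume,
        c.target_volume,
        c.lambda_vol,
        c.surface,
        c.target_surface,
        c.lambda_sur,
        state.contact_offsets,
        ids,
        dsv,
    )
    return dh


def acceptance_probability(dH: float, Tm: float) -> float:
    """Metropolis acceptance: 1 for dH <= 0, exp(-dH/Tm) otherwise."""
    if Tm <= 0:
        raise ValueError(f"Tm must be > 0, got {Tm}")
    if dH <= 0:
        return 1.0
    return math.exp(-dH / Tm)


# ---------------------------------------------------------------------------
# Numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _pair_binding(ci, cj, dens, nzm, nzn, nzk):
    b = 0.0
    for t in range(nzk.size):
        di = dens[ci, nzm[t]]
        dj = dens[cj, nzn[t]]
        b += nzk[t] * (di if di < dj else dj)
    return b


@njit(cache=True)
def _local_delta(
    sigma,
    W,
    H,
    tx,
    ty,
    ss,
    dens,
    nzm,
    nzn,
    nzk,
    vol,
    tv,
    lv,
    surf,
    ts,
    ls,
    offsets,
    ids,
    dsv,
):
    """dH of writing cell index ``ss`` into voxel (tx, ty).

    ``ids``/``dsv`` are caller-provided scratch buffers (length >= 6) that
    receive the per-cell surface deltas needed to apply the move; the
    number of affected cells is returned alongside dH."""
    st = sigma[tx, ty]
    dh = 0.0
    # Adhesion: all directed pairs (target, neighbor) within the contact shell.
    for i in range(offsets.shape[0]):
        nx = (tx + offsets[i, 0]) % W
        ny = (ty + offsets[i, 1]) % H
        sn = sigma[nx, ny]
        if sn != st:
            dh += _pair_binding(st, sn, dens, nzm, nzn, nzk)
        if sn != ss:
            dh -= _pair_binding(ss, sn, dens, nzm, nzn, nzk)
    # Volume constraints.
    if st != 0:
        v = vol[st]
        dh += lv[st] * ((v - 1 - tv[st]) ** 2 - (v - tv[st]) ** 2)
    if ss != 0:
        v = vol[ss]
        dh += lv[ss] * ((v + 1 - tv[ss]) ** 2 - (v - tv[ss]) ** 2)
    # Surface constraints: links incident to the target voxel change for the
    # two copy cells and for the owners of the four first-order neighbors.
    nid = 0
    for i in range(4):  # first 4 offsets are the first-order shell
        nx = (tx + offsets[i, 0]) % W
        ny = (ty + offsets[i, 1]) % H
        cn = sigma[nx, ny]
        if cn != st:
            nid = _acc(ids, dsv, nid, st, -1)
            nid = _acc(ids, dsv, nid, cn, -1)
        if cn != ss:
            nid = _acc(ids, dsv, nid, ss, 1)
            nid = _acc(ids, dsv, nid, cn, 1)
    for j in range(nid):
        cid = ids[j]
        if cid != 0 and dsv[j] != 0:
            s = surf[cid]
            dh += ls[cid] * ((s + dsv[j] - ts[cid]) ** 2 - (s - ts[cid]) ** 2)
    return dh, nid


@njit(cache=True)
def _acc(ids, dsv, nid, cid, d):
    for j in range(nid):
        if ids[j] == cid:
            dsv[j] += d
            return nid
    ids[nid] = cid
    dsv[nid] = d
    return nid + 1


@njit(cache=True)
def _attempt_loop(
    sigma,
    W,
    H,
    vol,
    surf,
    tv,
    ts,
    lv,
    ls,
    dens,
    nzm,
    nzn,
    nzk,
    comx,
    comy,
    Tm,
    tidx,
    src_choice,
    unif,
    copy_offsets,
    contact_offsets,
):
    """Run a batch of voxel-copy attempts in order; returns
    (n_accepted, last evaluated dH)."""
    accepted = 0
    last_dh = np.nan
    ids = np.empty(6, dtype=np.int64)
    dsv = np.empty(6, dtype=np.int64)
    for a in range(tidx.size):
        tx = tidx[a] // H
        ty = tidx[a] % H
        o = src_choice[a]
        sx = (tx + copy_offsets[o, 0]) % W
        sy = (ty + copy_offsets[o, 1]) % H
        st = sigma[tx, ty]
        ss = sigma[sx, sy]
        if st == ss:
            continue
        dh, nid = _local_delta(
            sigma, W, H, tx, ty, ss, dens, nzm, nzn, nzk,
            vol, tv, lv, surf, ts, ls, contact_offsets, ids, dsv,
        )
        last_dh = dh
        if dh > 0.0 and unif[a] >= np.exp(-dh / Tm):
            continue
        # Apply the copy: sigma, volumes, surfaces, unwrapped COM sums
        # (Medium's volume is tracked too; its COM is not meaningful).
        if st != 0:
            mx = comx[st] / vol[st]
            my = comy[st] / vol[st]
            comx[st] -= tx + W * math.floor((mx - tx) / W + 0.5)
            comy[st] -= ty + H * math.floor((my - ty) / H + 0.5)
            if vol[st] == 1:
                comx[st] = 0.0
                comy[st] = 0.0
        if ss != 0:
            if vol[ss] > 0:
                mx = comx[ss] / vol[ss]
                my = comy[ss] / vol[ss]
                comx[ss] += tx + W * math.floor((mx - tx) / W + 0.5)
                comy[ss] += ty + H * math.floor((my - ty) / H + 0.5)
            else:
                comx[ss] += tx
                comy[ss] += ty
        vol[st] -= 1
        vol[ss] += 1
        for j in range(nid):
            if ids[j] != 0:
                surf[ids[j]] += dsv[j]
        sigma[tx, ty] = ss
        accepted += 1
    return accepted, last_dh


def _run_attempts(state: SimState, n: int) -> int:
    """Draw ``n`` attempts from the state's RNG and execute them."""
    W, H = state.dims
    c = state.cells
    tidx = state.rng.integers(0, W * H, size=n)
    src = state.rng.integers(0, state.copy_offsets.shape[0], size=n)
    unif = state.rng.random(n)
    accepted, _ = _attempt_loop(
        state.sigma, W, H,
        c.volume, c.surface, c.target_volume, c.target_surface,
        c.lambda_vol, c.lambda_sur, c.dens,
        state._nzm, state._nzn, state._nzk,
        c.comx_sum, c.comy_sum,
        state.Tm, tidx, src, unif, state.copy_offsets, state.contact_offsets,
    )
    return int(accepted)


def attempt_voxel_copy(state: SimState, rng: np.random.Generator | None = None) -> bool:
    """One voxel-copy attempt; returns True if the copy was accepted.

    Same-cell draws are no-ops that still consume the attempt.  Copies
    involving Medium use the global fluctuation amplitude Tm, as do all
    others.
    """
    if rng is not None:
        state.rng = rng
    return _run_attempts(state, 1) == 1


def monte_carlo_step(state: SimState, rng: np.random.Generator | None = None) -> int:
    """One MCS = dims.x * dims.y voxel-copy attempts; returns accept count."""
    if rng is not None:
        state.rng = rng
    n = state.dims[0] * state.dims[1]
    accepted = _run_attempts(state, n)
    state.mcs += 1
    return accepted
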