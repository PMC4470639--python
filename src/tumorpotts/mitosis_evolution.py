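"""Mitosis, senescence, stem-cell fate and heritable adhesion mutation.

A cell past its doubling volume is split along a line through its center
of mass at a uniformly random angle into two roughly equal halves.  After
division both products reset their volume/surface targets, constraint
strengths and accumulators.  Non-stem lineages senesce: on each PCancer
(or quiescent-caught) division a limit R ~ N(maxdiv, div_sd) is drawn and
the lineage necroses once its completed-division counter exceeds it.  Stem
divisions are exempt; the parent re-enters quiescence as QStem and the
daughter is QStem (probability probstem, counter reset to 0) or QCancer
otherwise.  Finally, independently for cadherin and integrin, the parent
mutates its expression level with probability probmut by a Gaussian step
of s.d. cadhstdev, rejected if it leaves [0, 16] (rejection, not clamping,
avoids piling mass at the interval ends); the daughter inherits the
(possibly mutated) levels exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cpm_core import (
    SimState,
    TYPE_NECROTIC,
    TYPE_PCANCER,
    TYPE_PSTEM,
    TYPE_QCANCER,
    TYPE_QSTEM,
)

__all__ = [
    "EvolutionParams",
    "mitosis_candidates",
    "divide_random_orientation",
    "post_mitosis_fate",
    "mutate_adhesion",
    "step_mitosis",
]

_CAD, _INT, _FN = 0, 1, 2


@dataclass
class EvolutionParams:
    """Doubling volumes, senescence, stem fate and mutation parameters."""

    volmaxmit: float = 32.0    # cancer-cell doubling volume (voxels)
    Svolmaxmit: float = 32.0   # stem-cell doubling volume (voxels)
    maxdiv: float = 8.0        # senescence mean m_d
    div_sd: float = 2.0        # senescence s.d. delta_d
    probstem: float = 0.2      # stem-daughter probability
    probmut: float = 0.1       # per-molecule mutation probability P_m
    cadhstdev: float = 2.0     # mutation step s.d. delta_am
    density_bounds: tuple[float, float] = (0.0, 16.0)
    V0: float = 16.0
    S0: float = 16.0
    LBD_V0: float = 15.0
    LBD_S0: float = 5.0
    ktgs: float = 4.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.probstem <= 1.0 and 0.0 <= self.probmut <= 1.0):
            raise ValueError("probstem and probmut must lie in [0, 1]")
        if self.density_bounds[0] > self.density_bounds[1]:
            raise ValueError("density bounds must be ordered")


def mitosis_candidates(state: SimState, params: EvolutionParams) -> np.ndarray:
    """Cells due to divide: cancer cells with v > volmaxmit, stem cells with
    v > Svolmaxmit (strict).  Quiescent cells qualify too — a proliferating
    cell may cross the doubling volume and then be caught quiescent."""
    c = state.cells
    ids = c.living_ids()
    tc = c.type_code[ids]
    v = c.volume[ids]
    cancer = np.isin(tc, (TYPE_PCANCER, TYPE_QCANCER)) & (v > params.volmaxmit)
    stem = np.isin(tc, (TYPE_PSTEM, TYPE_QSTEM)) & (v > params.Svolmaxmit)
    return ids[cancer | stem]


def divide_random_orientation(
    state: SimState,
    cid: int,
    rng: np.random.Generator,
    angle: float | None = None,
) -> tuple[int, int] | None:
    """Split a cell by a line through its COM at a random angle.

    Voxels are ordered by signed distance to the line (ties broken by scan
    order) and the lower half keeps the parent id while the upper half
    becomes a fresh child cell, so the two parts always differ by at most
    one voxel and are both nonempty.  Returns (parent_id, child_id), or
    None when the cell has fewer than 2 voxels (skipped with a warning).
    """
    c = state.cells
    v = int(c.volume[cid])
    if v < 2:
        warnings.warn(f"cell {cid} has volume {v} < 2; division skipped")
        return None
    if angle is None:
        angle = rng.uniform(0.0, np.pi)
    W, H = state.dims
    vox = np.argwhere(state.sigma == cid)
    cx, cy = c.com(cid)
    # unwrap voxels to the image nearest the (unwrapped) COM
    ux = vox[:, 0] - W * np.round((vox[:, 0] - cx % W) / W) + (cx - cx % W)
    uy = vox[:, 1] - H * np.round((vox[:, 1] - cy % H) / H) + (cy - cy % H)
    d = (ux - cx) * np.cos(angle) + (uy - cy) * np.sin(angle)
    order = np.argsort(d, kind="stable")
    child_rows = vox[order[v // 2:]]

    child = c.new_cell(
        int(c.type_code[cid]),
        target_volume=c.target_volume[cid],
        target_surface=c.target_surface[cid],
        lambda_vol=c.lambda_vol[cid],
        lambda_sur=c.lambda_sur[cid],
        cad=c.dens[cid, _CAD],
        intg=c.dens[cid, _INT],
        fn=c.dens[cid, _FN],
    )
    state.sigma[child_rows[:, 0], child_rows[:, 1]] = child

    # Rebuild bookkeeping for the two products (other cells are unaffected:
    # their links stay unlike).
    for pid in (cid, child):
        rows = np.argwhere(state.sigma == pid)
        c.volume[pid] = rows.shape[0]
        rx = rows[:, 0] - W * np.round((rows[:, 0] - cx % W) / W) + (cx - cx % W)
        ry = rows[:, 1] - H * np.round((rows[:, 1] - cy % H) / H) + (cy - cy % H)
        c.comx_sum[pid] = rx.sum()
        c.comy_sum[pid] = ry.sum()
        s = 0
        for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            nx = (rows[:, 0] + dx) % W
            ny = (rows[:, 1] + dy) % H
            s += int(np.count_nonzero(state.sigma[nx, ny] != pid))
        c.surface[pid] = s
    return cid, child


def post_mitosis_fate(
    state: SimState,
    parent: int,
    child: int,
    params: EvolutionParams,
    rng: np.random.Generator,
    senescence_draw: float | None = None,
    stem_draw: float | None = None,
) -> None:
    """Reset targets, run senescence or stem-fate branching, reset clocks.

    ``senescence_draw`` / ``stem_draw`` override the random draws (testing).
    """
    c = state.cells
    for cid in (parent, child):
        c.target_volume[cid] = params.V0
        c.target_surface[cid] = params.ktgs * np.sqrt(params.V0)
        c.lambda_vol[cid] = params.LBD_V0
        c.lambda_sur[cid] = params.LBD_S0

    ptype = int(c.type_code[parent])
    if ptype in (TYPE_PCANCER, TYPE_QCANCER):
        r = senescence_draw if senescence_draw is not None else rng.normal(
            params.maxdiv, params.div_sd
        )
        if c.counter[parent] <= r:
            c.type_code[parent] = TYPE_QCANCER
            c.type_code[child] = TYPE_QCANCER
            c.counter[parent] += 1
            c.counter[child] = c.counter[parent]
        else:
            c.type_code[parent] = TYPE_NECROTIC
            c.type_code[child] = TYPE_NECROTIC
    elif ptype in (TYPE_PSTEM, TYPE_QSTEM):
        c.counter[parent] += 1
        c.type_code[parent] = TYPE_QSTEM
        u = stem_draw if stem_draw is not None else rng.random()
        if u <= params.probstem:
            c.type_code[child] = TYPE_QSTEM
            c.counter[child] = 0
        else:
            c.type_code[child] = TYPE_QCANCER

    for cid in (parent, child):
        c.starv[cid] = 0.0
        c.health[cid] = 0.0


def mutate_adhesion(
    state: SimState,
    parent: int,
    child: int,
    params: EvolutionParams,
    rng: np.random.Generator,
    forced_draws: dict | None = None,
) -> None:
    """Mutate cadherin then integrin with independent probability gates.

    A Gaussian proposal outside the density bounds is rejected (level kept);
    the final levels are written to both parent and child.  Necrotic parents
    (a senesced pair) are skipped.  ``forced_draws`` may supply
    ``{"cad": value, "int": value}`` proposals for testing.
    """
    c = state.cells
    if c.type_code[parent] == TYPE_NECROTIC:
        return
    lo, hi = params.density_bounds
    levels = [c.dens[parent, _CAD], c.dens[parent, _INT]]
    for slot, key in ((0, "cad"), (1, "int")):
        if rng.random() < params.probmut:
            if forced_draws is not None and key in forced_draws:
                proposal = forced_draws[key]
            else:
                proposal = rng.normal(levels[slot], params.cadhstdev)
            if lo <= proposal <= hi:
                levels[slot] = proposal
    for cid in (parent, child):
        c.dens[cid, _CAD] = levels[0]
        c.dens[cid, _INT] = levels[1]


def step_mitosis(state: SimState, params: EvolutionParams, rng: np.random.Generator) -> int:
    """One per-MCS mitosis pass: collect all candidates first, then divide
    each (two-phase, so a division cannot trigger another in the same MCS).
    Returns the number of divisions performed."""
    n = 0
    for cid in mitosis_candidates(state, params):
        result = divide_random_orientation(state, int(cid), rng)
        if result is None:
            continue
        parent, child = result
        post_mitosis_fate(state, parent, child, params, rng)
        mutate_adhesion(state, parent, child, params, rng)
        n += 1
    return n
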