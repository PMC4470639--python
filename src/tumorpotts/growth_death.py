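"""Target-volume growth of proliferating cells and necrotic shrinkage.

Proliferating cells (PCancer, PStem) enlarge their target volume by
k_growth * max(0, G - G_thresh) per MCS, with G read at the cell's center
of mass; the target surface tracks the target volume as S = q_sv * sqrt(V)
(q_sv = 4, slightly above the circular 2*sqrt(pi), which permits mildly
elongated shapes).  Quiescent cells neither grow nor shrink.  Necrotic
cells lose min(decvol, V) of target volume per MCS, independent of
nutrients, and are retired once neighbors have overwritten their last voxel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cpm_core import (
    SimState,
    TYPE_NECROTIC,
    TYPE_PCANCER,
    TYPE_PSTEM,
)
from .glucose import GlucoseField, concentrations_at_coms

__all__ = [
    "GrowthParams",
    "growth_increment",
    "target_surface_for",
    "necrotic_step",
    "grow_and_shrink_all",
]


@dataclass
class GrowthParams:
    """Growth/shrinkage rates and post-mitosis reference targets."""

    incvol: float = 0.2        # target-volume gain per unit excess concentration
    PGrThr0: float = 0.032     # growth concentration threshold, PCancer
    SGrThr0: float = 0.032     # growth concentration threshold, PStem
    ktgs: float = 4.0          # target surface = ktgs * sqrt(target volume)
    decvol: float = 0.01       # necrotic target-volume loss per MCS
    V0: float = 16.0
    S0: float = 16.0

    def __post_init__(self) -> None:
        if min(self.incvol, self.PGrThr0, self.SGrThr0, self.ktgs, self.decvol) < 0:
            raise ValueError("growth parameters must be >= 0")


def growth_increment(G: float, params: GrowthParams, cell_type: int) -> float:
    """Per-MCS target-volume increment for a proliferating cell."""
    if cell_type == TYPE_PCANCER:
        thr = params.PGrThr0
    elif cell_type == TYPE_PSTEM:
        thr = params.SGrThr0
    else:
        raise ValueError("growth applies only to PCancer and PStem cells")
    return params.incvol * max(0.0, G - thr)


def target_surface_for(V: float, q_sv: float = 4.0) -> float:
    """Target surface for a target volume, S = q_sv * sqrt(V)."""
    if V < 0:
        raise ValueError("target volume must be >= 0")
    return q_sv * np.sqrt(V)


def necrotic_step(state: SimState, cid: int, params: GrowthParams) -> None:
    """One MCS of necrotic shrinkage: V -= min(decvol, V), S follows."""
    c = state.cells
    if c.type_code[cid] != TYPE_NECROTIC:
        raise ValueError(f"cell {cid} is not Necrotic")
    c.target_volume[cid] -= min(params.decvol, c.target_volume[cid])
    c.target_surface[cid] = target_surface_for(c.target_volume[cid], params.ktgs)


def grow_and_shrink_all(state: SimState, field: GlucoseField, params: GrowthParams) -> None:
    """Apply growth to PC/PS and shrinkage to Necrotic cells, one MCS.

    Quiescent cells are untouched; each cell is independent, so the update
    is order-free.
    """
    c = state.cells
    ids = c.living_ids()
    ids = ids[c.volume[ids] > 0]
    if ids.size == 0:
        return
    tc = c.type_code[ids]
    nec = ids[tc == TYPE_NECROTIC]
    if nec.size:
        c.target_volume[nec] -= np.minimum(params.decvol, c.target_volume[nec])
        c.target_surface[nec] = params.ktgs * np.sqrt(c.target_volume[nec])
    for code, thr in ((TYPE_PCANCER, params.PGrThr0), (TYPE_PSTEM, params.SGrThr0)):
        grow = ids[tc == code]
        if grow.size:
            conc = concentrations_at_coms(field, state, grow)
            c.target_volume[grow] += params.incvol * np.maximum(0.0, conc - thr)
            c.target_surface[grow] = params.ktgs * np.sqrt(c.target_volume[grow])
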