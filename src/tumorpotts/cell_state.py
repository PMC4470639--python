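"""Starvation/health accounting and the nutrient-driven cell-state machine.

Once per MCS the glucose concentration G at each living tumor cell's center
of mass is compared with the starvation threshold x_thresh.  Below it the
cell accrues damage, above (or at) it the cell accrues health, both through
the saturating rate M(x) = m*x/(x+k) with the cell's own uptake constants:

    dS = |M(G) - M(x_thresh)|   if G <  x_thresh   (damage)
    dQ =  M(G) - M(x_thresh)    if G >= x_thresh   (health; >= 0 by monotonicity)

Transitions (all thresholds strict ``>``, necrosis irreversible):
proliferating and quiescent cells necrose when damage passes their
type-specific threshold; quiescent cells whose health passes the
proliferation threshold return to the proliferating state (refractory
behavior).  Health resets to zero on every transition.
"""

from __future__ import annotations

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
from .glucose import GlucoseField, concentrations_at_coms, mm_uptake

__all__ = [
    "TransitionThresholds",
    "saturating_rate",
    "starvation_increment",
    "health_increment",
    "accumulate",
    "apply_transitions",
]


@dataclass
class TransitionThresholds:
    """Starvation threshold, damage/health thresholds and per-type MM constants.

    GluD is the starvation concentration threshold x_thresh.  The default
    0.032 fmol/voxel is the 0.5 mM value from the model's own calibration
    (0.5 mM x 0.064 fmol/voxel per mM); the reference table also circulates
    a 0.0032 reading, available as a plain override of this field.
    """

    GluD: float = 0.032
    PNeThr0: float = 102.0
    QNeThr0: float = 204.0
    SNeThr0: float = 408.0
    QSNeThr0: float = 916.0
    QPThr0: float = 79.5
    QSSThr0: float = 79.5
    PUgMax: float = 2.25
    QUgMax: float = 1.69
    SUgMax: float = 2.25
    QSUgMax: float = 1.69
    GluK: float = 0.00256

    def __post_init__(self) -> None:
        for name in ("PNeThr0", "QNeThr0", "SNeThr0", "QSNeThr0", "QPThr0", "QSSThr0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def m_k(self, type_code: int) -> tuple[float, float]:
        m = {
            TYPE_PCANCER: self.PUgMax,
            TYPE_QCANCER: self.QUgMax,
            TYPE_PSTEM: self.SUgMax,
            TYPE_QSTEM: self.QSUgMax,
        }.get(int(type_code))
        if m is None:
            raise ValueError(f"no MM constants for cell type code {type_code}")
        return m, self.GluK


def saturating_rate(x, m, k):
    """M(x) = m*x/(x+k): M(k) = m/2, ~ (m/k)*x for x << k, ~ m for x >> k."""
    return mm_uptake(x, m, k)


def starvation_increment(G: float, thresholds: TransitionThresholds, cell_type: int) -> float:
    """Per-MCS damage increment: |M(G) - M(x_thresh)| below threshold, else 0."""
    if G >= thresholds.GluD:
        return 0.0
    m, k = thresholds.m_k(cell_type)
    return abs(saturating_rate(G, m, k) - saturating_rate(thresholds.GluD, m, k))


def health_increment(G: float, thresholds: TransitionThresholds, cell_type: int) -> float:
    """Per-MCS health increment: M(G) - M(x_thresh) at or above threshold, else 0."""
    if G < thresholds.GluD:
        return 0.0
    m, k = thresholds.m_k(cell_type)
    return saturating_rate(G, m, k) - saturating_rate(thresholds.GluD, m, k)


def accumulate(state: SimState, field: GlucoseField, thresholds: TransitionThresholds) -> None:
    """Add one MCS of starvation or health to every living tumor cell.

    Exactly one of the two accumulators changes per cell; Necrotic cells are
    untouched.
    """
    c = state.cells
    ids = c.living_ids()
    ids = ids[(c.type_code[ids] != TYPE_NECROTIC) & (c.volume[ids] > 0)]
    if ids.size == 0:
        return
    conc = concentrations_at_coms(field, state, ids)
    m = np.empty(ids.size)
    for code, mval in (
        (TYPE_PCANCER, thresholds.PUgMax),
        (TYPE_QCANCER, thresholds.QUgMax),
        (TYPE_PSTEM, thresholds.SUgMax),
        (TYPE_QSTEM, thresholds.QSUgMax),
    ):
        m[c.type_code[ids] == code] = mval
    k = thresholds.GluK
    rate = m * conc / (conc + k)
    rate_thr = m * thresholds.GluD / (thresholds.GluD + k)
    starving = conc < thresholds.GluD
    c.starv[ids[starving]] += np.abs(rate - rate_thr)[starving]
    c.health[ids[~starving]] += (rate - rate_thr)[~starving]


def apply_transitions(state: SimState, thresholds: TransitionThresholds) -> None:
    """Run the state machine over all living tumor cells.

    PCancer: damage > PNeThr0 -> Necrotic.  QCancer: damage > QNeThr0 ->
    Necrotic, else health > QPThr0 -> PCancer.  PStem: damage > SNeThr0 ->
    Necrotic.  QStem: damage > QSNeThr0 -> Necrotic, else health > QSSThr0
    -> PStem.  Health resets to zero on every transition taken.
    """
    c = state.cells
    ids = c.living_ids()
    tc = c.type_code
    for cid in ids:
        t = tc[cid]
        if t == TYPE_PCANCER:
            if c.starv[cid] > thresholds.PNeThr0:
                tc[cid] = TYPE_NECROTIC
                c.health[cid] = 0.0
        elif t == TYPE_QCANCER:
            if c.starv[cid] > thresholds.QNeThr0:
                tc[cid] = TYPE_NECROTIC
                c.health[cid] = 0.0
            elif c.health[cid] > thresholds.QPThr0:
                tc[cid] = TYPE_PCANCER
                c.health[cid] = 0.0
        elif t == TYPE_PSTEM:
            if c.starv[cid] > thresholds.SNeThr0:
                tc[cid] = TYPE_NECROTIC
                c.health[cid] = 0.0
        elif t == TYPE_QSTEM:
            if c.starv[cid] > thresholds.QSNeThr0:
                tc[cid] = TYPE_NECROTIC
                c.health[cid] = 0.0
            elif c.health[cid] > thresholds.QSSThr0:
                tc[cid] = TYPE_PSTEM
                c.health[cid] = 0.0
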