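"""Adhesion-molecule contact energetics and the surface-tension diagnostic.

Cells carry surface densities of three adhesion-molecule classes: cadherin
(``Cad``, homotypic cell-cell binding), integrin (``Int``, binds stromal
fibronectin) and fibronectin (``FN``, carried only by the Medium).  The
binding energy per unit contact area between two cells is

    b(i, j) = sum_{m,n} k_{m,n} * min(N_m^i, N_n^j)

where ``k`` is a symmetric affinity matrix and the ``min`` expresses that
each molecule binds at most once.  Bond formation *lowers* the effective
energy, so the contribution of an unlike voxel pair to the Hamiltonian is
``-b``; this sign is what makes the cell-Medium surface tension

    gamma = b(cell, cell)/2 - b(cell, Medium)

positive for cohesive cells and negative for invasive ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Tuple

import numpy as np

__all__ = [
    "AdhesionModel",
    "binding_per_unit_contact",
    "contact_energy_total",
    "surface_tension",
]

MOLECULES: Tuple[str, str, str] = ("Cad", "Int", "FN")
_MOL_INDEX = {name: i for i, name in enumerate(MOLECULES)}


def _canonical_k(k: Mapping[Tuple[str, str], float]) -> Dict[Tuple[str, str], float]:
    """Symmetrize and validate a binding-parameter mapping."""
    out: Dict[Tuple[str, str], float] = {}
    for (m, n), v in k.items():
        if m not in _MOL_INDEX or n not in _MOL_INDEX:
            raise ValueError(f"unknown adhesion molecule in pair ({m}, {n})")
        if v < 0:
            raise ValueError(f"binding parameter k[{m},{n}] must be >= 0, got {v}")
        key = (m, n) if _MOL_INDEX[m] <= _MOL_INDEX[n] else (n, m)
        if key in out and out[key] != v:
            raise ValueError(f"conflicting values for symmetric pair {key}")
        out[key] = float(v)
    return out


@dataclass
class AdhesionModel:
    """Molecule catalogue, binding matrix and density bounds.

    Reference values: homotypic cadherin affinity ``k[Cad,Cad] = 2.0``,
    heterotypic integrin-fibronectin affinity ``k[Int,FN] = 0.2``, all other
    pairs zero; densities bounded to [0, 16]; Medium carries only
    fibronectin at density 16.
    """

    k: Dict[Tuple[str, str], float] = field(
        default_factory=lambda: {("Cad", "Cad"): 2.0, ("Int", "FN"): 0.2}
    )
    density_bounds: Tuple[float, float] = (0.0, 16.0)
    contact_neighbor_order: int = 3
    medium_densities: Dict[str, float] = field(
        default_factory=lambda: {"Cad": 0.0, "Int": 0.0, "FN": 16.0}
    )

    def __post_init__(self) -> None:
        self.k = _canonical_k(self.k)

    def k_value(self, m: str, n: str) -> float:
        key = (m, n) if _MOL_INDEX[m] <= _MOL_INDEX[n] else (n, m)
        return self.k.get(key, 0.0)

    def nonzero_terms(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Ordered (m, n) index pairs with nonzero affinity, for fast kernels.

        The binding sum runs over *ordered* class pairs, so an off-diagonal
        symmetric entry appears twice: once as (m, n) and once as (n, m).
        """
        ms, ns, ks = [], [], []
        for (m, n), v in sorted(self.k.items()):
            if v == 0.0:
                continue
            ms.append(_MOL_INDEX[m])
            ns.append(_MOL_INDEX[n])
            ks.append(v)
            if m != n:
                ms.append(_MOL_INDEX[n])
                ns.append(_MOL_INDEX[m])
                ks.append(v)
        return (
            np.asarray(ms, dtype=np.int64),
            np.asarray(ns, dtype=np.int64),
            np.asarray(ks, dtype=np.float64),
        )

    def medium_density_vector(self) -> np.ndarray:
        return np.array([self.medium_densities.get(m, 0.0) for m in MOLECULES])

    def density_vector(self, densities: Mapping[str, float]) -> np.ndarray:
        return np.array([densities.get(m, 0.0) for m in MOLECULES])


def binding_per_unit_contact(
    densities_i: Mapping[str, float] | np.ndarray,
    densities_j: Mapping[str, float] | np.ndarray,
    model: AdhesionModel,
) -> float:
    """Binding energy magnitude per unit contact between two cells.

    The value returned is positive; the contribution to the Hamiltonian per
    unlike voxel pair is ``-b``.
    """
    di = densities_i if isinstance(densities_i, np.ndarray) else model.density_vector(densities_i)
    dj = densities_j if isinstance(densities_j, np.ndarray) else model.density_vector(densities_j)
    if np.any(np.asarray(di) < 0) or np.any(np.asarray(dj) < 0):
        raise ValueError("adhesion-molecule densities must be non-negative")
    ms, ns, ks = model.nonzero_terms()
    b = 0.0
    for m, n, kv in zip(ms, ns, ks):
        b += kv * min(di[m], dj[n])
    return b


def binding_matrix(dens: np.ndarray, model: AdhesionModel) -> np.ndarray:
    """Pairwise binding magnitude b[i, j] for a (n_cells, 3) density table."""
    ms, ns, ks = model.nonzero_terms()
    n = dens.shape[0]
    b = np.zeros((n, n))
    for m, nn, kv in zip(ms, ns, ks):
        b += kv * np.minimum(dens[:, m][:, None], dens[:, nn][None, :])
    return b


def contact_energy_total(sigma: np.ndarray, dens: np.ndarray, model: AdhesionModel) -> float:
    """Total adhesion energy of a periodic lattice configuration.

    ``sigma`` maps voxels to cell indices (0 = Medium); ``dens`` is the
    (n_cells, 3) density table indexed by cell id.  Each unordered unlike
    voxel pair within the contact neighborhood contributes ``-b`` once,
    implemented as half the directed sum over the full neighbor shell.
    """
    b = binding_matrix(dens, model)
    e = 0.0
    for dx, dy in neighbor_offsets(model.contact_neighbor_order):
        other = np.roll(np.roll(sigma, -dx, axis=0), -dy, axis=1)
        unlike = sigma != other
        if unlike.any():
            e += -b[sigma[unlike], other[unlike]].sum()
    return 0.5 * e


def neighbor_offsets(order: int) -> np.ndarray:
    """Square-lattice neighbor shells: order 1 = squared distance 1 (4 sites),
    order 2 adds squared distance 2 (4 sites), order 3 adds squared distance 4
    (4 sites); "order N" is the union of shells 1..N."""
    shells = {
        1: [(1, 0), (-1, 0), (0, 1), (0, -1)],
        2: [(1, 1), (1, -1), (-1, 1), (-1, -1)],
        3: [(2, 0), (-2, 0), (0, 2), (0, -2)],
    }
    if order not in (1, 2, 3):
        raise ValueError(f"neighbor order must be 1, 2 or 3, got {order}")
    offs: list[tuple[int, int]] = []
    for o in range(1, order + 1):
        offs.extend(shells[o])
    return np.asarray(offs, dtype=np.int64)


def surface_tension(cell_densities: Mapping[str, float] | np.ndarray, model: AdhesionModel) -> float:
    """Cell-Medium surface tension from the cell's adhesion-molecule levels.

    gamma = b(cell, cell)/2 - b(cell, Medium).  The homotypic cohesion term
    evaluates the cell against itself, i.e. min(Cad, Cad) = Cad.  Positive
    gamma marks cohesive cells, negative gamma invasive ones.
    """
    d = (
        cell_densities
        if isinstance(cell_densities, np.ndarray)
        else model.density_vector(cell_densities)
    )
    med = model.medium_density_vector()
    return binding_per_unit_contact(d, d, model) / 2.0 - binding_per_unit_contact(d, med, model)
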