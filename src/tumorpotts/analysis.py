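"""Snapshot serialization and the post-hoc metrics computed from snapshots.

Every fixed interval the simulation emits one row per living cell (id,
type, volume, surface, cadherin and integrin levels, center-of-mass
position) into a single delimited text table per run with an ``mcs``
column; all analyses here are pure functions of those tables.

The cluster census implements the verbal contract "a cluster is a group of
at least five cells whose centers of mass are at most 6 voxels from their
nearest cluster-mate": single-linkage connected components of the
<=eps-distance graph, filtered by size.  A DBSCAN-parameterized mode
(eps=6, min_samples=5) is available behind a flag; the two differ on
chain-like point sets.  Groups of 2-4 cells are transient associations,
lone cells singletons.  Periodic distances use the minimal-image
convention.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from . import adhesion as _adhesion
from .cpm_core import SimState, TYPE_NAMES, TYPE_NECROTIC

__all__ = [
    "SNAPSHOT_COLUMNS",
    "ClusterCensus",
    "snapshot_record",
    "write_snapshots",
    "read_snapshots",
    "cluster_census",
    "populations_by_type",
    "mean_surface_tension",
    "lifetime_and_travel",
    "envelope",
    "first_invasion_time",
]

SNAPSHOT_COLUMNS = ["mcs", "id", "type", "volume", "surface", "cad", "int", "com_x", "com_y"]


def snapshot_record(state: SimState, mcs: int | None = None) -> pd.DataFrame:
    """One row per living non-Medium cell; COM wrapped into the lattice."""
    c = state.cells
    ids = c.living_ids()
    ids = ids[c.volume[ids] > 0]
    W, H = state.dims
    vols = c.volume[ids].astype(float)
    return pd.DataFrame(
        {
            "mcs": (state.mcs if mcs is None else mcs),
            "id": ids,
            "type": [TYPE_NAMES[t] for t in c.type_code[ids]],
            "volume": c.volume[ids],
            "surface": c.surface[ids],
            "cad": c.dens[ids, 0],
            "int": c.dens[ids, 1],
            "com_x": np.where(vols > 0, c.comx_sum[ids] / vols, 0.0) % W,
            "com_y": np.where(vols > 0, c.comy_sum[ids] / vols, 0.0) % H,
        },
        columns=SNAPSHOT_COLUMNS,
    )


def write_snapshots(path, frames: pd.DataFrame | list[pd.DataFrame], meta: dict | None = None) -> None:
    """Write a snapshot series as one CSV with '#'-prefixed header lines
    carrying run metadata (seed, config hash)."""
    df = frames if isinstance(frames, pd.DataFrame) else pd.concat(frames, ignore_index=True)
    with open(path, "w", encoding="utf-8") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)


def read_snapshots(path) -> tuple[pd.DataFrame, dict]:
    """Read a snapshot series; returns (table, metadata).  Malformed content
    raises a ValueError naming the offending line."""
    meta: dict[str, str] = {}
    lines: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    meta[k.strip()] = v.strip()
                continue
            lines.append(line)
    try:
        df = pd.read_csv(io.StringIO("".join(lines)))
    except Exception as exc:  # surface a parse error with a line number
        raise ValueError(f"malformed snapshot file {path}: {exc}") from exc
    missing = [col for col in SNAPSHOT_COLUMNS if col not in df.columns]
    if missing:
        raise ValueError(f"snapshot file {path} lacks columns {missing} (header line)")
    return df, meta


# ---------------------------------------------------------------------------
# Cluster census
# ---------------------------------------------------------------------------


@dataclass
class ClusterCensus:
    """Counts and memberships partitioning a point cloud of cell centers."""

    n_clusters: int = 0
    n_assoc: int = 0
    n_singletons: int = 0
    clusters: list = field(default_factory=list)      # member index lists, size >= 5
    associations: list = field(default_factory=list)  # member index lists, size 2-4

    @property
    def n_points(self) -> int:
        return (
            sum(len(m) for m in self.clusters)
            + sum(len(m) for m in self.associations)
            + self.n_singletons
        )


def _eps_graph_components(points: np.ndarray, eps: float, box) -> np.ndarray:
    tree = cKDTree(points if box is None else np.mod(points, box), boxsize=box)
    pairs = tree.query_pairs(eps, output_type="ndarray")
    n = len(points)
    adj = sp.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, labels = connected_components(adj, directed=False)
    return labels


def cluster_census(
    points: np.ndarray,
    eps: float = 6.0,
    min_size: int = 5,
    box: tuple[float, float] | None = None,
    mode: str = "single_linkage",
) -> ClusterCensus:
    """Census of clusters (>= min_size), transient associations (2 to
    min_size-1) and singletons among cell centers.

    ``box`` enables periodic minimal-image distances.  ``mode`` selects the
    cluster definition: ``single_linkage`` (the default contract) or
    ``dbscan`` (core-point semantics with min_samples = min_size); the
    association/singleton partition always comes from the single-linkage
    components of the non-cluster points.
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    points = np.asarray(points, dtype=float)
    if points.size == 0:
        return ClusterCensus()
    labels = _eps_graph_components(points, eps, box)
    census = ClusterCensus()
    if mode == "single_linkage":
        for lab in np.unique(labels):
            members = np.flatnonzero(labels == lab)
            if members.size >= min_size:
                census.clusters.append(members.tolist())
            elif members.size >= 2:
                census.associations.append(members.tolist())
            else:
                census.n_singletons += 1
    elif mode == "dbscan":
        from sklearn.cluster import DBSCAN

        if box is None:
            db = DBSCAN(eps=eps, min_samples=min_size).fit(points)
        else:
            d = _minimal_image_distances(points, box)
            db = DBSCAN(eps=eps, min_samples=min_size, metric="precomputed").fit(d)
        for lab in np.unique(db.labels_):
            if lab < 0:
                continue
            census.clusters.append(np.flatnonzero(db.labels_ == lab).tolist())
        noise = np.flatnonzero(db.labels_ < 0)
        if noise.size:
            sub = _eps_graph_components(points[noise], eps, box)
            for lab in np.unique(sub):
                members = noise[sub == lab]
                if members.size >= 2:
                    census.associations.append(members.tolist())
                else:
                    census.n_singletons += 1
    else:
        raise ValueError(f"unknown census mode {mode!r}")
    census.n_clusters = len(census.clusters)
    census.n_assoc = len(census.associations)
    return census


def _minimal_image_distances(points: np.ndarray, box) -> np.ndarray:
    delta = np.abs(points[:, None, :] - points[None, :, :])
    delta = np.minimum(delta, np.asarray(box) - delta)
    return np.sqrt((delta**2).sum(axis=-1))


# ---------------------------------------------------------------------------
# Snapshot metrics
# ---------------------------------------------------------------------------


def populations_by_type(snapshot: pd.DataFrame) -> dict[str, int]:
    """Cell counts per type in one snapshot (zero for absent types)."""
    counts = snapshot["type"].value_counts()
    return {name: int(counts.get(name, 0)) for name in TYPE_NAMES if name != "Medium"}


def mean_surface_tension(snapshot: pd.DataFrame, model: _adhesion.AdhesionModel) -> float:
    """Mean cell-Medium surface tension over living tumor cells (Necrotic
    excluded); NaN for an empty selection."""
    living = snapshot[snapshot["type"] != TYPE_NAMES[TYPE_NECROTIC]]
    if living.empty:
        return float("nan")
    gammas = [
        _adhesion.surface_tension({"Cad": cad, "Int": intg}, model)
        for cad, intg in zip(living["cad"], living["int"])
    ]
    return float(np.mean(gammas))


def lifetime_and_travel(
    series: pd.DataFrame,
    interval: int,
    box: tuple[float, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell lifetime and total travel distance from a snapshot series.

    A cell is binned by the type it had when it first appeared in a
    snapshot.  lifetime = (last snapshot - first snapshot + 1 interval);
    travel = summed minimal-image COM displacement between consecutive
    snapshots containing the cell.  Returns (per-cell table, aggregate of
    min/median/max per initial type for both metrics).
    """
    records = []
    for cid, grp in series.sort_values("mcs").groupby("id"):
        xy = grp[["com_x", "com_y"]].to_numpy()
        steps = np.diff(xy, axis=0)
        if box is not None:
            b = np.asarray(box, dtype=float)
            steps = steps - b * np.round(steps / b)
        travel = float(np.sqrt((steps**2).sum(axis=1)).sum())
        records.append(
            {
                "id": cid,
                "initial_type": grp["type"].iloc[0],
                "lifetime": int(grp["mcs"].iloc[-1] - grp["mcs"].iloc[0] + interval),
                "travel": travel,
            }
        )
    per_cell = pd.DataFrame(records, columns=["id", "initial_type", "lifetime", "travel"])
    if per_cell.empty:
        return per_cell, pd.DataFrame()
    agg = per_cell.groupby("initial_type")[["lifetime", "travel"]].agg(
        ["min", "median", "max"]
    )
    return per_cell, agg


def envelope(series_list) -> pd.DataFrame:
    """Min/median/max across replicas at each time point.

    Accepts a list of equal-length 1D arrays (one per replica) or a 2D
    array with replicas in rows.
    """
    arr = np.asarray(series_list, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    return pd.DataFrame(
        {
            "min": arr.min(axis=0),
            "median": np.median(arr, axis=0),
            "max": arr.max(axis=0),
        }
    )


def first_invasion_time(
    series: pd.DataFrame,
    eps: float = 6.0,
    min_size: int = 5,
    box: tuple[float, float] | None = None,
) -> float:
    """First snapshot time with a tumor cell detached from every cluster.

    Detachment means the census finds at least one cluster and at least one
    living tumor cell outside all clusters (by single linkage such a cell
    is > eps from every cluster member).  Returns +inf if never observed.
    """
    necrotic = TYPE_NAMES[TYPE_NECROTIC]
    for mcs, snap in series.groupby("mcs"):
        living = snap[snap["type"] != necrotic]
        if len(living) <= min_size:
            continue
        census = cluster_census(
            living[["com_x", "com_y"]].to_numpy(), eps=eps, min_size=min_size, box=box
        )
        if census.n_clusters >= 1 and (census.n_assoc > 0 or census.n_singletons > 0):
            return float(mcs)
    return float("inf")
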