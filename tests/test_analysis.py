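"""Snapshot round-trips, cluster census, population/tension/lifetime metrics."""

import numpy as np
import pandas as pd
import pytest

from tumorpotts.adhesion import AdhesionModel
from tumorpotts.analysis import (
    cluster_census,
    envelope,
    first_invasion_time,
    lifetime_and_travel,
    mean_surface_tension,
    populations_by_type,
    read_snapshots,
    snapshot_record,
    write_snapshots,
)
from tumorpotts.testkit import make_point_cloud, make_small_lattice


def _single_linkage_oracle(points, eps):
    """Brute-force components of the <=eps graph by repeated expansion."""
    n = len(points)
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    labels = -np.ones(n, dtype=int)
    lab = 0
    for i in range(n):
        if labels[i] >= 0:
            continue
        frontier = [i]
        labels[i] = lab
        while frontier:
            j = frontier.pop()
            for k in np.flatnonzero((d[j] <= eps) & (labels < 0)):
                labels[k] = lab
                frontier.append(k)
        lab += 1
    return labels


class TestSnapshotIO:
    def test_empty_population_round_trip(self, tmp_path):
        state = make_small_lattice([], dims=(8, 8))
        df = snapshot_record(state)
        path = tmp_path / "snap.csv"
        write_snapshots(path, df, meta={"seed": 0})
        back, meta = read_snapshots(path)
        assert back.empty
        assert meta["seed"] == "0"

    def test_three_cell_round_trip_exact(self, tmp_path, three_cell_state):
        df = snapshot_record(three_cell_state)
        path = tmp_path / "snap.csv"
        write_snapshots(path, df, meta={"seed": 7, "config_hash": "abc"})
        back, meta = read_snapshots(path)
        for col in ("mcs", "id", "volume", "surface"):
            assert np.array_equal(back[col].to_numpy(), df[col].to_numpy())
        for col in ("cad", "int", "com_x", "com_y"):
            assert np.allclose(back[col], df[col], atol=1e-12)
        assert list(back["type"]) == list(df["type"])

    def test_large_synthetic_round_trip(self, tmp_path, rng):
        n = 1000
        df = pd.DataFrame(
            {
                "mcs": 1000,
                "id": np.arange(1, n + 1),
                "type": rng.choice(["PCancer", "QCancer", "Necrotic"], n),
                "volume": rng.integers(1, 40, n),
                "surface": rng.integers(4, 60, n),
                "cad": rng.uniform(0, 16, n),
                "int": rng.uniform(0, 16, n),
                "com_x": rng.uniform(0, 500, n),
                "com_y": rng.uniform(0, 500, n),
            }
        )
        path = tmp_path / "big.csv"
        write_snapshots(path, df)
        back, _ = read_snapshots(path)
        assert np.allclose(back["cad"], df["cad"], atol=1e-12)

    def test_malformed_file_reports_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("not,a,snapshot\n1,2\n")
        with pytest.raises(ValueError):
            read_snapshots(path)


class TestClusterCensus:
    def test_four_close_points_are_an_association(self):
        pts = make_point_cloud([((10, 10), 4, 0.5)], rng=0)
        cen = cluster_census(pts)
        assert (cen.n_clusters, cen.n_assoc, cen.n_singletons) == (0, 1, 0)

    def test_five_close_points_are_a_cluster(self):
        pts = make_point_cloud([((10, 10), 5, 0.5)], rng=0)
        cen = cluster_census(pts)
        assert (cen.n_clusters, cen.n_assoc, cen.n_singletons) == (1, 0, 0)

    def test_empty_input(self):
        cen = cluster_census(np.empty((0, 2)))
        assert cen.n_points == 0
        assert (cen.n_clusters, cen.n_assoc, cen.n_singletons) == (0, 0, 0)

    def test_two_separated_blobs(self):
        pts = make_point_cloud([((10, 10), 10, 2.0), ((60, 60), 10, 2.0)], rng=1)
        cen = cluster_census(pts)
        assert cen.n_clusters == 2

    def test_periodic_minimal_image_merges_across_boundary(self):
        pts = np.array([[1.0, 50.0], [99.0, 50.0], [2.0, 51.0], [98.0, 49.0], [0.5, 49.0]])
        cen = cluster_census(pts, box=(100, 100))
        assert cen.n_clusters == 1

    @pytest.mark.parametrize("mode", ["single_linkage", "dbscan"])
    def test_partition_property(self, rng, mode):
        """Census classes partition the population exactly."""
        for _ in range(10):
            n = int(rng.integers(0, 200))
            pts = rng.uniform(0, 80, size=(n, 2))
            cen = cluster_census(pts, mode=mode)
            assert cen.n_points == n

    def test_matches_single_linkage_oracle(self, rng):
        for _ in range(10):
            pts = rng.uniform(0, 60, size=(int(rng.integers(2, 200)), 2))
            cen = cluster_census(pts)
            labels = _single_linkage_oracle(pts, 6.0)
            sizes = np.bincount(labels)
            assert cen.n_clusters == int(np.count_nonzero(sizes >= 5))
            assert cen.n_assoc == int(np.count_nonzero((sizes >= 2) & (sizes < 5)))
            assert cen.n_singletons == int(np.count_nonzero(sizes == 1))


class TestSnapshotMetrics:
    def _snap(self, rows):
        return pd.DataFrame(
            rows,
            columns=["mcs", "id", "type", "volume", "surface", "cad", "int", "com_x", "com_y"],
        )

    def test_populations(self):
        snap = self._snap(
            [
                [0, 1, "PCancer", 16, 16, 8, 8, 1, 1],
                [0, 2, "PCancer", 16, 16, 8, 8, 5, 5],
                [0, 3, "Necrotic", 10, 14, 8, 8, 9, 9],
            ]
        )
        pops = populations_by_type(snap)
        assert pops["PCancer"] == 2 and pops["Necrotic"] == 1 and pops["QStem"] == 0

    def test_populations_match_tally_on_synthetic_snapshot(self, rng):
        types = rng.choice(["PCancer", "QCancer", "Necrotic", "PStem", "QStem"], 500)
        snap = self._snap(
            [[0, i, t, 16, 16, 8, 8, 0, 0] for i, t in enumerate(types, 1)]
        )
        pops = populations_by_type(snap)
        for name in pops:
            assert pops[name] == int(np.count_nonzero(types == name))

    def test_mean_surface_tension_reference_and_empty(self):
        model = AdhesionModel()
        snap = self._snap(
            [
                [0, 1, "PCancer", 16, 16, 8.0, 8.0, 1, 1],
                [0, 2, "QStem", 16, 16, 8.0, 8.0, 5, 5],
                [0, 3, "Necrotic", 16, 16, 0.0, 16.0, 9, 9],  # excluded
            ]
        )
        assert mean_surface_tension(snap, model) == pytest.approx(6.4)
        assert np.isnan(mean_surface_tension(snap.iloc[:0], model))

    def test_lifetime_single_and_stationary(self):
        snap = self._snap(
            [[k, 1, "PCancer", 16, 16, 8, 8, 10.0, 10.0] for k in (0, 100, 200, 300, 400)]
            + [[200, 2, "QCancer", 16, 16, 8, 8, 40.0, 40.0]]
        )
        per_cell, agg = lifetime_and_travel(snap, interval=100)
        c1 = per_cell.set_index("id").loc[1]
        assert c1["lifetime"] == 500 and c1["travel"] == 0.0
        c2 = per_cell.set_index("id").loc[2]
        assert c2["lifetime"] == 100 and c2["travel"] == 0.0

    def test_travel_sums_minimal_image_displacements(self, rng):
        xs = [5.0, 95.0, 90.0, 10.0]  # walks across the periodic boundary
        snap = self._snap(
            [[100 * k, 1, "PStem", 16, 16, 8, 8, x, 50.0] for k, x in enumerate(xs)]
        )
        per_cell, _ = lifetime_and_travel(snap, interval=100, box=(100, 100))
        # hops: 5->95 is 10 backwards, 95->90 is 5, 90->10 is 20 forward
        assert per_cell["travel"].iloc[0] == pytest.approx(10 + 5 + 20)
        assert per_cell["initial_type"].iloc[0] == "PStem"


class TestEnvelope:
    def test_single_replica_collapses(self):
        series = np.array([1.0, 5.0, 2.0])
        env = envelope([series])
        assert np.array_equal(env["min"], series)
        assert np.array_equal(env["median"], series)
        assert np.array_equal(env["max"], series)

    def test_median_matches_sort_oracle(self, rng):
        arr = rng.normal(size=(11, 30))
        env = envelope(arr)
        med = np.sort(arr, axis=0)[5]
        assert np.allclose(env["median"], med)
        assert np.all(env["min"] <= env["median"])
        assert np.all(env["median"] <= env["max"])


class TestInvasion:
    def _series(self, frames):
        rows = []
        for mcs, pts in frames:
            for i, (x, y) in enumerate(pts, 1):
                rows.append([mcs, i, "PCancer", 16, 16, 8, 8, x, y])
        return pd.DataFrame(
            rows,
            columns=["mcs", "id", "type", "volume", "surface", "cad", "int", "com_x", "com_y"],
        )

    def test_detached_cell_marks_invasion(self):
        blob = [(10 + i, 10 + j) for i in range(3) for j in range(2)]
        series = self._series(
            [
                (0, blob),
                (1000, blob + [(11, 14)]),       # still attached
                (2000, blob + [(40.0, 40.0)]),   # detached beyond 6 voxels
            ]
        )
        assert first_invasion_time(series) == 2000.0

    def test_never_invading_series(self):
        blob = [(10 + i, 10 + j) for i in range(3) for j in range(2)]
        series = self._series([(0, blob), (1000, blob)])
        assert first_invasion_time(series) == float("inf")
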