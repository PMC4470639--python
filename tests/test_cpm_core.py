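"""Lattice engine: energy, local dH, Metropolis acceptance, bookkeeping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tumorpotts.cpm_core import (
    IntegrityError,
    SimState,
    acceptance_probability,
    attempt_voxel_copy,
    check_integrity,
    delta_H,
    monte_carlo_step,
    recount_com_sums,
    recount_surfaces,
    recount_volumes,
    total_energy,
)
from tumorpotts.testkit import make_random_lattice, make_small_lattice


def _random_unlike_copy(state, rng):
    """Draw a (target, source) pair with different owners, source from the
    target's order-3 copy neighborhood."""
    W, H = state.dims
    while True:
        tx, ty = int(rng.integers(0, W)), int(rng.integers(0, H))
        o = state.copy_offsets[int(rng.integers(0, len(state.copy_offsets)))]
        sx, sy = (tx + o[0]) % W, (ty + o[1]) % H
        if state.sigma[tx, ty] != state.sigma[sx, sy]:
            return (tx, ty), (sx, sy)


class TestTotalEnergy:
    def test_relaxed_lone_cell_zero_constraint_energy(self):
        # v=V=16, s=S=16, Cad/Int zero: only zero terms remain
        state = make_small_lattice(
            [{"x0": 8, "y0": 8, "w": 4, "h": 4, "cad": 0.0, "int": 0.0}], dims=(20, 20)
        )
        assert total_energy(state) == pytest.approx(0.0)

    def test_volume_excess_costs_lambda_vol(self):
        # v=17, V=16, lambda=15, surface matched, no adhesion
        state = make_small_lattice(
            [
                {"x0": 8, "y0": 8, "w": 4, "h": 4, "cad": 0.0, "int": 0.0},
                {"x0": 8, "y0": 12, "w": 1, "h": 1, "cad": 0.0, "int": 0.0},
            ],
            dims=(20, 20),
        )
        # merge the extra voxel into cell 1 to make a 17-voxel cell
        state.sigma[state.sigma == 2] = 1
        state.cells.n = 2
        state.rebuild_bookkeeping()
        state.cells.target_surface[1] = state.cells.surface[1]
        assert total_energy(state) == pytest.approx(15.0 * (17 - 16) ** 2)

    def test_inconsistent_registry_raises(self, lone_cell_state):
        lone_cell_state.cells.volume[1] += 1
        with pytest.raises(IntegrityError):
            total_energy(lone_cell_state)


class TestDeltaH:
    def test_closed_form_volume_gain(self):
        state = make_small_lattice(
            [{"x0": 8, "y0": 8, "w": 4, "h": 4, "cad": 0.0, "int": 0.0}], dims=(20, 20)
        )
        c = state.cells
        c.lambda_sur[1] = 0.0  # isolate the volume term
        lam, v, V = c.lambda_vol[1], c.volume[1], c.target_volume[1]
        # copy a cell voxel onto an adjacent Medium voxel: v -> v + 1
        dh = delta_H(state, (12, 8), (11, 8))
        assert dh == pytest.approx(lam * ((v + 1 - V) ** 2 - (v - V) ** 2))

    def test_closed_form_last_voxel_removal(self):
        state = make_small_lattice(
            [{"x0": 5, "y0": 5, "w": 1, "h": 1, "cad": 0.0, "int": 0.0, "V": 16.0}],
            dims=(12, 12),
        )
        state.cells.lambda_sur[1] = 0.0
        dh = delta_H(state, (5, 5), (6, 5))  # Medium overwrites the lone voxel
        assert dh == pytest.approx(15.0 * ((0 - 16.0) ** 2 - (1 - 16.0) ** 2))

    def test_same_cell_pair_rejected(self, lone_cell_state):
        with pytest.raises(ValueError):
            delta_H(lone_cell_state, (8, 8), (9, 8))

    def test_matches_full_energy_difference(self, rng):
        """dH from local terms equals the full before/after energy difference."""
        for _ in range(20):
            state = make_random_lattice((10, 10), 4, rng)
            for _ in range(5):
                (tx, ty), (sx, sy) = _random_unlike_copy(state, rng)
                dh = delta_H(state, (tx, ty), (sx, sy))
                e0 = total_energy(state)
                old = state.sigma[tx, ty]
                state.sigma[tx, ty] = state.sigma[sx, sy]
                state.rebuild_bookkeeping()
                e1 = total_energy(state)
                state.sigma[tx, ty] = old
                state.rebuild_bookkeeping()
                assert dh == pytest.approx(e1 - e0, abs=1e-9)


class TestAcceptance:
    @pytest.mark.parametrize(
        "dh, tm, expected",
        [
            (-3.0, 50.0, 1.0),
            (0.0, 50.0, 1.0),
            (50.0, 50.0, math.exp(-1.0)),
            (1e9, 50.0, 0.0),
        ],
    )
    def test_metropolis_values(self, dh, tm, expected):
        assert acceptance_probability(dh, tm) == pytest.approx(expected, abs=1e-12)

    @given(
        dh=st.floats(-200, 200, allow_nan=False),
        tm=st.floats(0.1, 500, allow_nan=False),
    )
    @settings(deadline=None, max_examples=200)
    def test_metropolis_functional_form(self, dh, tm):
        p = acceptance_probability(dh, tm)
        assert 0.0 <= p <= 1.0
        if dh <= 0:
            assert p == 1.0
        else:
            assert p == pytest.approx(math.exp(-dh / tm))

    def test_nonpositive_tm_rejected(self):
        with pytest.raises(ValueError):
            acceptance_probability(1.0, 0.0)


class TestVoxelCopies:
    def test_bookkeeping_matches_recount_after_many_attempts(self, rng):
        """Incremental volume/surface/COM stay exact over 10^4 attempts."""
        state = make_random_lattice((20, 20), 5, rng)
        for _ in range(10_000 // (20 * 20)):
            monte_carlo_step(state)
        for _ in range(10_000 % (20 * 20)):
            attempt_voxel_copy(state)
        c = state.cells
        assert np.array_equal(recount_volumes(state.sigma, c.n), c.volume[: c.n])
        assert np.array_equal(
            recount_surfaces(state.sigma, c.n)[1:], c.surface[1 : c.n]
        )
        comx, comy = recount_com_sums(state.sigma, c.n, state.dims)
        live = c.volume[: c.n] > 0
        live[0] = False
        W, H = state.dims
        for arr, ref, L in ((c.comx_sum, comx, W), (c.comy_sum, comy, H)):
            a = (arr[: c.n][live] / c.volume[: c.n][live]) % L
            b = (ref[live] / c.volume[: c.n][live]) % L
            d = np.abs(a - b)
            assert np.minimum(d, L - d).max() < 1e-8

    def test_voxel_conservation(self, rng):
        state = make_random_lattice((15, 15), 4, rng)
        for _ in range(20):
            monte_carlo_step(state)
            assert state.cells.volume[: state.cells.n].sum() == 15 * 15

    def test_mcs_counts_attempts_and_increments_clock(self, lone_cell_state):
        assert lone_cell_state.mcs == 0
        monte_carlo_step(lone_cell_state)
        assert lone_cell_state.mcs == 1

    def test_zero_temperature_limit_never_raises_energy(self, rng):
        state = make_random_lattice((12, 12), 3, rng, Tm=1e-9)
        e0 = total_energy(state)
        for _ in range(5):
            monte_carlo_step(state)
        assert total_energy(state) <= e0 + 1e-9

    def test_long_run_volume_equilibrium(self):
        """A lone 16-voxel cell at Tm=50 fluctuates around its target volume."""
        state = make_small_lattice(
            [{"x0": 8, "y0": 8, "w": 4, "h": 4, "cad": 0.0, "int": 0.0}],
            dims=(20, 20),
            rng=3,
        )
        vols = []
        for _ in range(500):
            monte_carlo_step(state)
            vols.append(state.cells.volume[1])
        assert abs(np.mean(vols) - 16.0) < 2.0


class TestCohesion:
    def test_adhesive_cells_gain_contact(self):
        """Two mutually adhesive cells (gamma > 0) end up touching more than
        they start, averaged over seeds."""

        def contact_links(state):
            n = 0
            W, H = state.dims
            for dx, dy in ((1, 0), (0, 1)):
                other = np.roll(np.roll(state.sigma, -dx, axis=0), -dy, axis=1)
                n += np.count_nonzero((state.sigma == 1) & (other == 2))
                n += np.count_nonzero((state.sigma == 2) & (other == 1))
            return n

        gains = []
        for seed in range(20):
            state = make_small_lattice(
                [
                    {"x0": 6, "y0": 8, "w": 3, "h": 3, "cad": 12.0, "int": 2.0,
                     "V": 9.0, "S": 12.0},
                    {"x0": 12, "y0": 8, "w": 3, "h": 3, "cad": 12.0, "int": 2.0,
                     "V": 9.0, "S": 12.0},
                ],
                dims=(20, 20),
                rng=seed,
            )
            initial = contact_links(state)
            for _ in range(300):
                monte_carlo_step(state)
            gains.append(contact_links(state) - initial)
        assert np.mean(gains) > 0

    def test_low_cadherin_cells_sort_to_boundary(self):
        """Differential adhesion pushes below-median-Cad cells to the cluster
        surface (more Medium contact), the engine of adhesion evolution."""
        boundary_bias = []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            cads = rng.uniform(3.0, 13.0, size=9)
            specs = []
            for i in range(3):
                for j in range(3):
                    specs.append(
                        {"x0": 6 + 4 * i, "y0": 6 + 4 * j, "w": 4, "h": 4,
                         "cad": float(cads[3 * i + j]), "int": 4.0}
                    )
            state = make_small_lattice(specs, dims=(26, 26), rng=seed)
            for _ in range(1500):
                monte_carlo_step(state)
            medium_contact = np.zeros(10)
            for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                other = np.roll(np.roll(state.sigma, -dx, axis=0), -dy, axis=1)
                for cid in range(1, 10):
                    medium_contact[cid] += np.count_nonzero(
                        (state.sigma == cid) & (other == 0)
                    )
            low = cads < np.median(cads)
            boundary_bias.append(
                medium_contact[1:][low].mean() - medium_contact[1:][~low].mean()
            )
        assert np.mean(boundary_bias) > 0
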