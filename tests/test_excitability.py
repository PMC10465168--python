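"""Titration, TAC arithmetic, SoFPAN bounds and position selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from optoca1 import excitability as ex
from optoca1.excitability import (ThresholdMap, compute_TAC,
                                  optimal_worst_positions, position_grid,
                                  relative_error, sofpan, sweep_positions,
                                  titrate_threshold)


def _map_from_bool(true_nodes, pitch=np.pi / 2, tac=None):
    x, z = position_grid(pitch, nx=true_nodes.shape[0],
                         nz=true_nodes.shape[1])
    i_th = np.where(true_nodes, 1.0, 100.0)
    return ThresholdMap(x=x, z=z, i_th=i_th,
                        tac=tac if tac is not None
                        else np.ones_like(i_th), pitch=pitch)


class TestTitration:
    def test_bisection_arithmetic(self):
        # oracle threshold 3.7 with bracket [1, 10]: after seven bisections
        # the interval width is 9/2^7 and the midpoint sits within it
        calls = []

        def spike(i):
            calls.append(i)
            return i >= 3.7

        got = titrate_threshold(spike)
        a, b = 1.0, 10.0
        for _ in range(7):
            c = 0.5 * (a + b)
            if c >= 3.7:
                b = c
            else:
                a = c
        assert got == pytest.approx(0.5 * (a + b), rel=1e-12)
        assert (b - a) == pytest.approx(9.0 / 2 ** 7)
        assert abs(got - 3.7) < 9.0 / 2 ** 7

    def test_bracket_shifts_down_for_low_thresholds(self):
        got = titrate_threshold(lambda i: i >= 2e-4)
        assert abs(got - 2e-4) < 1e-3 / 2 ** 7 * 9

    def test_no_spike_returns_sentinel(self):
        assert np.isnan(titrate_threshold(lambda i: False))

    def test_half_decade_refinement_finds_narrow_window(self):
        # spiking only inside a window narrower than one decade
        got = titrate_threshold(lambda i: 200.0 <= i <= 500.0)
        assert np.isfinite(got)
        assert 100.0 <= got <= 500.0

    def test_spike_everywhere_reports_floor(self):
        assert titrate_threshold(lambda i: True) == ex._TITRATION_FLOOR


class TestTAC:
    def test_rectangular_pulse_closed_form(self):
        t = np.arange(0.0, 600.0, 0.5)
        pd, t0 = 20.0, 100.0
        i = np.zeros_like(t)
        i[(t >= t0) & (t < t0 + pd)] = -2.0    # mA/cm^2
        area = 1e5                              # um^2 = 1e-3 cm^2
        tac = compute_TAC(i[None, :], t, np.array([area]), pd, t0)
        # (1/pd)*A*i*pd = i*A = -2 mA/cm^2 * 1e-3 cm^2 = -2 uA... in uA
        assert tac == pytest.approx(-2.0 * 1e-3 * 1e3, rel=0.02)

    def test_zero_current(self):
        t = np.arange(0.0, 600.0, 1.0)
        assert compute_TAC(np.zeros((3, len(t))), t, np.ones(3), 10.0, 50.0) \
            == 0.0

    def test_inverse_pd_scaling(self):
        t = np.arange(0.0, 600.0, 0.5)
        i = np.zeros_like(t)
        i[(t >= 100.0) & (t < 105.0)] = -1.0
        area = np.array([1e4])
        tac5 = compute_TAC(i[None, :], t, area, 5.0, 100.0)
        tac10 = compute_TAC(i[None, :], t, area, 10.0, 100.0)
        assert tac5 == pytest.approx(2.0 * tac10, rel=1e-9)

    def test_mismatch_rejected(self):
        t = np.arange(0.0, 600.0, 1.0)
        with pytest.raises(ValueError):
            compute_TAC(np.zeros((3, len(t))), t, np.ones(2), 10.0, 50.0)
        with pytest.raises(ValueError):
            compute_TAC(np.zeros((1, 10)), t[:10], np.ones(1), 10.0, 50.0)


class TestSweep:
    def test_full_grid_has_121_positions(self):
        for pitch in (0.0, np.pi / 2, np.pi):
            x, z = position_grid(pitch)
            assert len(x) * len(z) == 121
            assert len(z) == 11
        x, z = position_grid(np.pi / 2)
        assert (x[0], x[-1], x[1] - x[0]) == (-1000.0, 4000.0, 500.0)
        x, z = position_grid(0.0)
        assert (x[0], x[-1], x[1] - x[0]) == (0.0, 2500.0, 250.0)
        assert (z[0], z[-1]) == (-400.0, 700.0)

    def test_map_independent_of_evaluation_order(self):
        def tfn(x, z):
            return abs(x) / 100.0 + abs(z) / 50.0 + 1.0, 0.5

        m1 = sweep_positions(tfn, np.pi / 2, nx=5, nz=5)
        m2 = sweep_positions(tfn, np.pi / 2, nx=5, nz=5)
        assert np.array_equal(m1.i_th, m2.i_th)

    def test_failures_become_sentinels(self):
        def tfn(x, z):
            if x > 0:
                raise RuntimeError("boom")
            return 1.0, 0.1

        m = sweep_positions(tfn, np.pi / 2, nx=5, nz=3)
        assert np.isnan(m.i_th[m.x > 0, :]).all()
        assert np.isfinite(m.i_th[m.x <= 0, :]).all()


class TestSofpan:
    def test_all_true_reaches_domain_area(self):
        full = _map_from_bool(np.ones((11, 11), bool), pitch=np.pi / 2)
        sp = sofpan(full, 10.0)
        assert sp.lower == sp.estimate == sp.upper == pytest.approx(5.5)

    def test_axial_pitches_doubled_to_same_maximum(self):
        for pitch in (0.0, np.pi):
            sp = sofpan(_map_from_bool(np.ones((11, 11), bool), pitch), 10.0)
            assert sp.upper == pytest.approx(5.5)
            assert sp.estimate == pytest.approx(5.5)

    def test_all_false_is_zero(self):
        sp = sofpan(_map_from_bool(np.zeros((11, 11), bool)), 10.0)
        assert sp.lower == sp.estimate == sp.upper == 0.0

    def test_single_interior_node(self):
        nodes = np.zeros((11, 11), bool)
        nodes[5, 5] = True
        sp = sofpan(_map_from_bool(nodes), 10.0)
        cell = 0.5 * 0.11  # mm^2
        assert sp.lower == 0.0
        assert sp.estimate == pytest.approx(cell)
        assert sp.upper == pytest.approx(4 * cell)  # dilation closes 4 cells

    def test_sentinels_never_activate(self):
        x, z = position_grid(np.pi / 2, 5, 5)
        i_th = np.full((5, 5), np.nan)
        m = ThresholdMap(x=x, z=z, i_th=i_th, tac=i_th.copy())
        assert sofpan(m, 1e9).estimate == 0.0

    @given(st.integers(0, 2 ** 25 - 1))
    @settings(max_examples=60, deadline=None)
    def test_bounds_ordered_on_random_maps(self, bits):
        nodes = np.array([(bits >> k) & 1 for k in range(25)],
                         dtype=bool).reshape(5, 5)
        sp = sofpan(_map_from_bool(nodes), 10.0)
        assert 0.0 <= sp.lower <= sp.estimate <= sp.upper <= 5.5 + 1e-9

    def test_monotone_in_fiber_intensity(self, rng):
        x, z = position_grid(np.pi / 2, 7, 7)
        i_th = 10 ** rng.uniform(-1, 3, size=(7, 7))
        m = ThresholdMap(x=x, z=z, i_th=i_th, tac=np.ones_like(i_th))
        prev = (0.0, 0.0, 0.0)
        for i_f in ex.I_FIBER_GRID:
            sp = sofpan(m, i_f)
            assert sp.lower >= prev[0] - 1e-12
            assert sp.estimate >= prev[1] - 1e-12
            assert sp.upper >= prev[2] - 1e-12
            prev = (sp.lower, sp.estimate, sp.upper)


class TestRelativeError:
    def test_identical_maps_zero(self):
        assert relative_error(1.23, 1.23) == 0.0

    def test_mc_zero_uniform_positive_is_infinite(self):
        assert relative_error(0.5, 0.0) == np.inf

    def test_uniform_zero_mc_positive_is_minus_one(self):
        assert relative_error(0.0, 0.5) == -1.0


class TestOptimalWorst:
    def test_fully_activated_row_is_optimal(self):
        nodes = np.zeros((5, 5), bool)
        nodes[:, 2] = True   # one z row fully activated
        m = _map_from_bool(nodes)
        z_opt, z_worst = optimal_worst_positions(m, 10.0)
        assert z_opt == m.z[2]
        assert z_worst != m.z[2]

    def test_tac_tie_break(self):
        nodes = np.zeros((5, 5), bool)
        nodes[:, 1] = True
        nodes[:, 3] = True
        tac = np.ones((5, 5))
        tac[:, 3] = 0.1   # lower TAC wins the optimal slot
        m = _map_from_bool(nodes, tac=tac)
        z_opt, _ = optimal_worst_positions(m, 10.0)
        assert z_opt == m.z[3]

    def test_constant_map_defaults_to_first_z(self):
        m = _map_from_bool(np.ones((5, 5), bool))
        z_opt, z_worst = optimal_worst_positions(m, 10.0)
        assert z_opt == z_worst == m.z[0]

    def test_all_sentinel_map_undefined(self):
        x, z = position_grid(np.pi / 2, 3, 3)
        nanmap = ThresholdMap(x=x, z=z, i_th=np.full((3, 3), np.nan),
                              tac=np.full((3, 3), np.nan))
        with pytest.raises(ValueError):
            optimal_worst_positions(nanmap, 1.0)
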