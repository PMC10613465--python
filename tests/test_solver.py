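"""k-space pseudospectral solver physics tests.

Oracles are analytic: the exact water sound speed for phase measurement,
the Beer-Lambert decay law for absorption, cap geometry for the bowl
discretisation, and exact energy conservation of the staggered scheme.
"""

import dataclasses

import numpy as np
import pytest

from tfusplan.properties import MediumMaps, attenuation_at_frequency
from tfusplan.pulse import PulseSequence
from tfusplan.solver import (
    KSpaceWaveSolver,
    SimulationGrid,
    SolverInstabilityError,
    SourceGeometry,
    TransducerSpec,
    amplitude_from_trace,
    discretize_bowl,
    make_grid,
    propagate,
    _ramped_sinusoid,
)

C_WATER = 1482.0
FF = 500e3


def _line_medium(n, dx, alpha0=0.0, y=1.51):
    med = MediumMaps.homogeneous_water((n,), spacing=(dx,))
    med.alpha_coeff = np.full(n, float(alpha0))
    med.power_law_exponent = y
    return med


def _line_solver(n, dx, alpha0=0.0, src_at=60, cfl=0.3):
    med = _line_medium(n, dx, alpha0)
    dt = cfl * dx * 1e-3 / C_WATER
    grid = SimulationGrid(shape=(n,), spacing=dx, dt=dt, cfl=cfl,
                          pml_width=(20,), reference_speed=C_WATER)
    src = SourceGeometry(
        indices=(np.array([src_at]),), weights=np.ones(1),
        apex_position=np.array([src_at * dx]), axis=np.array([1.0]),
        focus_point=np.array([(src_at + 10) * dx]),
    )
    return grid, med, src


def _fourier_amplitude(trace, dt, ff, window):
    t = np.arange(trace.size) * dt
    z = np.mean(trace[window] * np.exp(-2j * np.pi * ff * t[window]))
    return 2 * np.abs(z), np.angle(z)


class TestGrid:
    def test_cfl_rule_sets_dt(self):
        grid = make_grid((64.0,), 1.0, 3100.0, cfl=0.3)
        assert grid.dt == pytest.approx(0.3 * 1e-3 / 3100.0)  # ~9.677e-8 s

    def test_dt_scales_with_max_speed(self):
        g_bone = make_grid((64.0,), 1.0, 3100.0)
        g_water = make_grid((64.0,), 1.0, C_WATER)
        assert g_water.dt / g_bone.dt == pytest.approx(3100.0 / C_WATER)

    def test_unstable_cfl_rejected(self):
        with pytest.raises(ValueError):
            make_grid((64.0,), 1.0, C_WATER, cfl=1.5)

    def test_undersampled_wavelength_warns(self):
        with pytest.warns(UserWarning, match="points per wavelength"):
            make_grid((64.0,), 2.0, C_WATER, drive_frequency=500e3)


class TestBowlDiscretisation:
    def test_cap_half_angle(self):
        spec = TransducerSpec()
        assert np.degrees(spec.half_angle) == pytest.approx(24.62, abs=0.01)
        assert spec.cap_depth == pytest.approx(2.728, abs=0.005)
        assert spec.f_number == pytest.approx(30.0 / 25.0)

    def test_on_axis_cap_is_mirror_symmetric(self):
        grid = SimulationGrid(shape=(96, 96), spacing=0.5, dt=1e-7)
        src = discretize_bowl(TransducerSpec(), (8.0, 24.0), (38.0, 24.0), grid)
        pts = set(zip(src.indices[0].tolist(), src.indices[1].tolist()))
        mirrored = {(i, 96 - j) for i, j in pts}
        assert pts == mirrored

    def test_hemisphere_voxel_count_matches_cap_area(self):
        grid = SimulationGrid(shape=(128, 128, 128), spacing=0.5, dt=1e-7)
        spec = TransducerSpec(radius_of_curvature=20.0, aperture_diameter=40.0)
        src = discretize_bowl(spec, (12.0, 32.0, 32.0), (32.0, 32.0, 32.0), grid)
        analytic = 2 * np.pi * 20.0**2  # hemisphere area, mm^2
        assert src.n_active * 0.5**2 == pytest.approx(analytic, rel=0.10)

    def test_degenerate_and_clipped_bowls_rejected(self):
        grid = SimulationGrid(shape=(64, 64), spacing=1.0, dt=1e-7)
        spec = TransducerSpec()
        with pytest.raises(ValueError, match="degenerate"):
            discretize_bowl(spec, (10.0, 32.0), (10.0, 32.0), grid)
        with pytest.raises(ValueError, match="ROC"):
            discretize_bowl(spec, (10.0, 32.0), (20.0, 32.0), grid)
        with pytest.raises(ValueError, match="clipped"):
            discretize_bowl(spec, (-2.0, 32.0), (28.0, 32.0), grid)


class TestPropagationPhysics:
    def test_plane_wave_phase_speed_in_water(self):
        """Phase difference between two near probes gives c within 1%."""
        n, dx = 512, 0.25
        grid, med, src = _line_solver(n, dx)
        n_steps = 2000
        sig = _ramped_sinusoid(FF, 1e6, grid.dt, n_steps)
        solver = KSpaceWaveSolver(grid, med, src)
        res = solver.run(n_steps, drive_signal=sig,
                         probes={"a": (200,), "b": (205,)}, measure_start=1200)
        window = slice(1200, None)
        _, pa = _fourier_amplitude(res.probe_traces["a"], grid.dt, FF, window)
        _, pb = _fourier_amplitude(res.probe_traces["b"], grid.dt, FF, window)
        dphi = np.mod(pa - pb, 2 * np.pi)  # 5 voxels < half a wavelength
        c_meas = 2 * np.pi * FF * (5 * dx * 1e-3) / dphi
        assert c_meas == pytest.approx(C_WATER, rel=0.01)

    def test_beer_lambert_attenuation(self):
        """Amplitude ratio across distance d equals exp(-alpha d) within 2%."""
        alpha0 = 20.0  # Np/MHz^y/m, tissue-scale prefactor
        n, dx = 1024, 0.25
        grid, med, src = _line_solver(n, dx, alpha0=alpha0)
        n_steps = 4200
        sig = _ramped_sinusoid(FF, 1e6, grid.dt, n_steps)
        solver = KSpaceWaveSolver(grid, med, src)
        res = solver.run(n_steps, drive_signal=sig, measure_start=3800)
        amp_a, amp_b = res.amplitude[200], res.amplitude[600]
        alpha = attenuation_at_frequency(alpha0, FF, 1.51)
        expected = np.exp(-alpha * 400 * dx * 1e-3)
        assert amp_b / amp_a == pytest.approx(expected, rel=0.02)

    def test_energy_conservation_closed_lossless_domain(self):
        """PML off, no absorption: discrete energy constant to 0.5%."""
        n, dx = 64, 1.0
        med = MediumMaps.homogeneous_water((n, n), spacing=(dx, dx))
        med.alpha_coeff = np.zeros((n, n))
        grid = SimulationGrid(shape=(n, n), spacing=dx,
                              dt=0.3 * dx * 1e-3 / C_WATER,
                              pml_width=(0, 0), reference_speed=C_WATER)
        solver = KSpaceWaveSolver(grid, med)
        x = np.arange(n) - n / 2
        p0 = 1e5 * np.exp(-(x[:, None] ** 2 + x[None, :] ** 2) / (2 * 4.0**2))
        solver.reset(initial_pressure=p0)
        energies = []
        for _ in range(101):
            u_prev = [u.copy() for u in solver.u]
            p_prev = solver.p.copy()
            solver.step()
            energies.append(solver.energy(u_prev=u_prev, p=p_prev))
        energies = np.asarray(energies[1:])
        assert (energies.max() - energies.min()) / energies[0] < 0.005

    def test_linearity_in_source_pressure(self):
        """Doubling the drive doubles every amplitude to round-off."""
        n, dx = 256, 0.5
        grid, med, src = _line_solver(n, dx)
        n_steps = 600
        fields = []
        for amp in (1e5, 2e5):
            sig = _ramped_sinusoid(FF, amp, grid.dt, n_steps)
            solver = KSpaceWaveSolver(grid, med, src)
            fields.append(solver.run(n_steps, drive_signal=sig,
                                     measure_start=400).amplitude)
        np.testing.assert_allclose(fields[1], 2.0 * fields[0], rtol=1e-9,
                                   atol=1e-4)

    def test_3d_invariant_axis_matches_2d(self):
        """A z-invariant 3D run reproduces the 2D solution within 1%."""
        n, dx, nz = 64, 1.0, 8
        dt = 0.3 * dx * 1e-3 / C_WATER
        med2 = MediumMaps.homogeneous_water((n, n), spacing=(dx, dx))
        med2.alpha_coeff = np.zeros((n, n))
        grid2 = SimulationGrid(shape=(n, n), spacing=dx, dt=dt,
                               pml_width=(10, 10), reference_speed=C_WATER)
        line = np.arange(20, 44)
        src2 = SourceGeometry(
            indices=(np.full(line.size, 16), line), weights=np.ones(line.size),
            apex_position=np.array([16.0, 32.0]), axis=np.array([1.0, 0.0]),
            focus_point=np.array([46.0, 32.0]),
        )
        med3 = MediumMaps.homogeneous_water((n, n, nz), spacing=(dx,) * 3)
        med3.alpha_coeff = np.zeros((n, n, nz))
        grid3 = SimulationGrid(shape=(n, n, nz), spacing=dx, dt=dt,
                               pml_width=(10, 10, 0), reference_speed=C_WATER)
        iz = np.arange(nz)
        i0 = np.repeat(np.full(line.size, 16), nz)
        i1 = np.repeat(line, nz)
        i2 = np.tile(iz, line.size)
        src3 = SourceGeometry(
            indices=(i0, i1, i2), weights=np.ones(i0.size),
            apex_position=np.array([16.0, 32.0, 0.0]),
            axis=np.array([1.0, 0.0, 0.0]),
            focus_point=np.array([46.0, 32.0, 0.0]),
        )
        n_steps, ms = 700, 500
        sig = _ramped_sinusoid(FF, 1e6, dt, n_steps)
        f2 = KSpaceWaveSolver(grid2, med2, src2).run(
            n_steps, drive_signal=sig, measure_start=ms).amplitude
        f3 = KSpaceWaveSolver(grid3, med3, src3).run(
            n_steps, drive_signal=sig, measure_start=ms).amplitude
        sl = f3[:, :, nz // 2]
        scale = np.max(f2)
        sel = f2 > 0.05 * scale  # compare where the field is non-negligible
        assert np.max(np.abs(sl[sel] - f2[sel])) / scale < 0.01

    def test_grid_refinement_convergence_on_water_bowl(self):
        """Halving the spacing moves the 2D focal amplitude by < 5%.

        Run in the resolved regime (6 -> 12 points per wavelength at
        500 kHz), where source-staircasing effects are below the bound.
        """
        drive = PulseSequence()
        spec = TransducerSpec()
        peaks = []
        for dx in (0.5, 0.25):
            grid = make_grid((64.0, 56.0), dx, C_WATER, pml_width=10,
                             fft_friendly=True)
            med = MediumMaps.homogeneous_water(grid.shape, spacing=(dx, dx))
            med.alpha_coeff = np.zeros(grid.shape)
            cy = grid.shape[1] * dx / 2
            src = discretize_bowl(spec, (8.0, cy), (38.0, cy), grid)
            field = propagate(grid, med, src, drive,
                              settle_periods=20, measure_periods=6)
            peaks.append(field.amplitude.max())
        assert abs(peaks[1] - peaks[0]) / peaks[1] < 0.05

    def test_instability_guard_aborts(self):
        """Above-reference sound speed with an oversized dt must be caught:
        the k-space correction only guarantees stability up to c_ref."""
        n, dx = 128, 0.5
        med = _line_medium(n, dx)
        med.sound_speed = np.full(n, C_WATER)
        med.sound_speed[70:] = 3000.0
        grid = SimulationGrid(shape=(n,), spacing=dx,
                              dt=0.9 * dx * 1e-3 / C_WATER,  # stable only for water
                              pml_width=(10,), reference_speed=C_WATER)
        src = SourceGeometry(indices=(np.array([30]),), weights=np.ones(1),
                             apex_position=np.array([15.0]),
                             axis=np.array([1.0]),
                             focus_point=np.array([30.0]))
        solver = KSpaceWaveSolver(grid, med, src)
        sig = _ramped_sinusoid(FF, 1e6, grid.dt, 400)
        with pytest.raises(SolverInstabilityError):
            solver.run(400, drive_signal=sig)


class TestAmplitudeEstimator:
    def test_pure_sinusoid_recovers_amplitude(self):
        dt = 1 / (40 * FF)
        t = np.arange(4000) * dt
        trace = 3.3e5 * np.sin(2 * np.pi * FF * t)
        assert amplitude_from_trace(trace, dt, FF, 10) == pytest.approx(
            3.3e5, rel=0.01)

    def test_zero_signal(self):
        assert amplitude_from_trace(np.zeros(1000), 1e-8, FF, 5) == 0.0

    def test_settled_transient_ignored(self):
        dt = 1 / (40 * FF)
        t = np.arange(8000) * dt
        env = 1.0 + 4.0 * np.exp(-t / (20 / FF))  # settles well before the tail
        trace = 1e5 * env * np.sin(2 * np.pi * FF * t)
        est = amplitude_from_trace(trace, dt, FF, 10)
        assert est == pytest.approx(1e5, rel=0.02)

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(ValueError):
            amplitude_from_trace(np.zeros(10), 1e-8, FF, 1000)
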