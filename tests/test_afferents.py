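"""Receptive-field construction and SA/RA transduction filters."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from tactilesnn import (
    TransductionParams,
    afferent_response,
    build_population,
    input_current,
    ra_filter,
    sa_dynamic,
    sa_static,
)
from tactilesnn.afferents import N_SITES_PER_AFFERENT
from tactilesnn.stimulus import NOISELESS, IndentProfile, edge_template, make_indent_movie

P = TransductionParams()
DT = 0.1


class TestPopulations:
    def test_population_sizes(self, sa_pop, ra_pop):
        assert len(sa_pop) == 100
        assert len(ra_pop) == 196
        assert len(sa_pop) + len(ra_pop) == 296

    def test_innervation_counts_and_weights(self, sa_pop, ra_pop):
        for pop in (sa_pop, ra_pop):
            for rf in pop.receptive_fields:
                assert len(rf.sites) == N_SITES_PER_AFFERENT
                assert len(np.unique(rf.sites)) == N_SITES_PER_AFFERENT
                assert rf.weights.min() >= 0.1 and rf.weights.max() <= 1.0

    def test_sites_cluster_around_centre(self, grid):
        pop = build_population("SA", grid, rng=3)
        rf = pop.receptive_fields[55]  # interior afferent
        r, c = grid.site_rowcol(rf.sites)
        sigma_px = pop.sigma_d_mm / grid.pitch_mm
        assert abs(r.mean() - rf.center_rowcol[0]) < 3 * sigma_px
        assert np.std(r) < 3 * sigma_px

    def test_seeded_determinism(self, grid):
        p1 = build_population("RA", grid, rng=42)
        p2 = build_population("RA", grid, rng=42)
        p3 = build_population("RA", grid, rng=43)
        assert all(
            np.array_equal(a.sites, b.sites) and np.array_equal(a.weights, b.weights)
            for a, b in zip(p1.receptive_fields, p2.receptive_fields)
        )
        assert any(
            not np.array_equal(a.sites, b.sites)
            for a, b in zip(p1.receptive_fields, p3.receptive_fields)
        )

    def test_invalid_parameters(self, grid):
        with pytest.raises(ValueError):
            build_population("SA", grid, sigma_d_mm=-1.0, rng=0)
        with pytest.raises(ValueError):
            build_population("PC", grid, rng=0)

    def test_sigma_scale_spreads_fields(self, grid):
        small = build_population("SA", grid, rng=5, sigma_scale=1.0)
        big = build_population("SA", grid, rng=5, sigma_scale=4.0)
        def spread(pop):
            r, c = grid.site_rowcol(np.concatenate(
                [rf.sites for rf in pop.receptive_fields[40:60]]))
            centers = np.repeat(
                [rf.center_rowcol for rf in pop.receptive_fields[40:60]],
                N_SITES_PER_AFFERENT, axis=0)
            return np.hypot(r - centers[:, 0], c - centers[:, 1]).mean()
        assert spread(big) > 2 * spread(small)


class TestInputCurrent:
    def test_zero_frame_zero_current(self, sa_pop, grid):
        tpl = edge_template(10.0, grid=grid)
        movie = make_indent_movie(tpl, noise=NOISELESS)
        I = input_current(sa_pop, movie)
        assert np.all(I[0] == 0.0)  # envelope starts at zero

    def test_linearity_in_force(self, sa_pop, grid):
        tpl = edge_template(30.0, grid=grid)
        m1 = make_indent_movie(tpl, noise=NOISELESS, amplitude=1.0)
        m2 = make_indent_movie(tpl, noise=NOISELESS, amplitude=2.0)
        I1 = input_current(sa_pop, m1)
        I2 = input_current(sa_pop, m2)
        assert np.allclose(I2, 2 * I1, rtol=1e-5, atol=1e-5)

    def test_force_outside_rf_gives_zero(self, sa_pop, grid):
        # drive only the far corner; an afferent centred opposite stays silent
        rf = sa_pop.receptive_fields[0]  # bottom-left centre
        frame = np.zeros(grid.n_sites, dtype=np.float32)
        frame[-1] = 5.0  # top-right site
        from tactilesnn.stimulus import StimulusMovie

        movie = StimulusMovie(DT, frame[None, :], grid)
        I = input_current(sa_pop, movie)
        assert I[0, 0] == 0.0


class TestFilters:
    def test_static_gain(self):
        assert sa_static(np.array([100.0]))[0] == pytest.approx(5.0)  # k1 = 0.05
        assert sa_static(np.array([0.0]))[0] == 0.0
        # memoryless: a step maps to a step
        step = np.concatenate([np.zeros(10), np.full(10, 40.0)])
        assert np.array_equal(sa_static(step), 0.05 * step)

    def test_dynamic_sa_steady_state_matches_static(self):
        # frozen input held much longer than tau_d: I_SA -> k1 * C
        C = 80.0
        I_in = np.full((6000, 1), C)
        I_in[0] = 0.0
        out = sa_dynamic(I_in, DT)
        assert out[-1, 0] == pytest.approx(P.k1 * C, rel=1e-3)

    def test_dynamic_sa_zero_input(self):
        out = sa_dynamic(np.zeros((100, 2)), DT)
        assert np.all(out == 0.0)

    def test_dynamic_sa_onset_overshoot(self):
        # ramp-and-hold drive: the derivative term makes the ramp response
        # overshoot the hold plateau
        prof = IndentProfile()
        t = np.arange(0, 300, DT)
        I_in = 100.0 * prof.envelope(t)[:, None]
        out = sa_dynamic(I_in, DT)
        ramp_peak = out[: int(80 / DT)].max()
        plateau = out[int(240 / DT), 0]
        assert ramp_peak > 1.2 * plateau

    def test_dynamic_sa_matches_reference_integrator(self):
        """Euler at dt=0.1 ms within 1% sup-norm of a high-accuracy solver."""
        prof = IndentProfile()
        t_grid = np.arange(0, 300, DT)
        I_fn = lambda t: 100.0 * float(prof.envelope(np.array([t]))[0])
        dI_fn = lambda t: 100.0 / 50.0 * (1 if t < 50 else (-1 if 250 <= t < 300 else 0))

        def rhs(t, s):
            x, i_sa = s
            dx = (P.k2 * dI_fn(t) + P.k1 * I_fn(t) - x) / P.tau_r_sa_ms
            di = (x - i_sa) / P.tau_d_sa_ms
            return [dx, di]

        sol = solve_ivp(rhs, (0, 300), [0.0, 0.0], t_eval=t_grid, max_step=0.05,
                        rtol=1e-8, atol=1e-10)
        ours = sa_dynamic(100.0 * prof.envelope(t_grid)[:, None], DT)[:, 0]
        scale = np.abs(sol.y[1]).max()
        assert np.max(np.abs(ours - sol.y[1])) < 0.01 * scale

    def test_ra_decays_on_frozen_input(self):
        # a step excites RA transiently; it then decays with tau = 30 ms
        I_in = np.concatenate([np.zeros(10), np.full(3000, 50.0)])[:, None]
        out = ra_filter(I_in, DT)
        peak_idx = out[:, 0].argmax()
        peak = out[peak_idx, 0]
        one_tau = out[peak_idx + int(30 / DT), 0]
        assert peak > 0
        assert one_tau == pytest.approx(peak * np.exp(-1), rel=0.05)
        assert out[-1, 0] < 0.01 * peak

    def test_ra_ramp_equilibrium(self):
        # constant slope s held >> tau: I_RA -> k3 * s = 2 s
        s = 3.0  # per ms
        I_in = (s * np.arange(0, 400, DT))[:, None]
        out = ra_filter(I_in, DT)
        assert out[-1, 0] == pytest.approx(P.k3 * s, rel=1e-3)

    def test_ra_symmetric_in_sign_of_slope(self):
        up = np.concatenate([np.linspace(0, 100, 1000), np.full(2000, 100.0)])
        down = np.concatenate([np.full(1000, 100.0), np.linspace(100, 0, 1000),
                               np.zeros(1000)])
        r_up = ra_filter(up[:, None], DT)[:1000, 0]
        r_down = ra_filter(down[:, None], DT)[1000:2000, 0]
        assert np.allclose(r_up, r_down, rtol=1e-6, atol=1e-9)


class TestAfferentResponse:
    def test_sa_fires_through_hold_ra_only_at_transients(self, sa_pop, ra_pop, grid):
        tpl = edge_template(40.0, grid=grid)
        movie = make_indent_movie(tpl, noise=NOISELESS)
        sa = afferent_response(sa_pop, movie)
        ra = afferent_response(ra_pop, movie)
        t_sa = np.nonzero(sa.spikes.any(axis=1))[0] * DT
        t_ra = np.nonzero(ra.spikes.any(axis=1))[0] * DT
        # SA-I sustains through the 50-250 ms hold
        assert ((t_sa > 100) & (t_sa < 250)).sum() > 10
        # RA-I fires only near ramp onset/offset (within +-25 ms)
        on = (t_ra <= 75)
        off = (t_ra >= 225) & (t_ra <= 325)
        assert len(t_ra) > 0
        assert np.all(on | off)

    def test_sa_adaptation_rate_decreases_during_hold(self, sa_pop, grid):
        tpl = edge_template(40.0, grid=grid)
        movie = make_indent_movie(tpl, noise=NOISELESS)
        sa = afferent_response(sa_pop, movie)
        early = sa.spikes[int(50 / DT):int(150 / DT)].sum()
        late = sa.spikes[int(150 / DT):int(250 / DT)].sum()
        assert early >= late

    def test_static_vs_dynamic_same_steady_state_larger_onset(self, sa_pop, grid):
        tpl = edge_template(40.0, grid=grid)
        movie = make_indent_movie(tpl, noise=NOISELESS)
        dyn = afferent_response(sa_pop, movie, "dynamic", keep_currents=True)
        stat = afferent_response(sa_pop, movie, "static", keep_currents=True)
        unit = dyn.I_drive[:, :].max(axis=0).argmax()
        hold_idx = int(240 / DT)
        assert dyn.I_drive[hold_idx, unit] == pytest.approx(
            stat.I_drive[hold_idx, unit], rel=0.02
        )
        assert dyn.I_drive[: int(80 / DT), unit].max() > stat.I_drive[
            : int(80 / DT), unit
        ].max()

    def test_full_raster_reproducible(self, sa_pop, grid):
        tpl = edge_template(25.0, grid=grid)
        movie = make_indent_movie(tpl, noise=NOISELESS)
        r1 = afferent_response(sa_pop, movie, noise_sd=1.5, rng=3)
        r2 = afferent_response(sa_pop, movie, noise_sd=1.5, rng=3)
        assert np.array_equal(r1.spikes, r2.spikes)
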