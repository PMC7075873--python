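"""Flat-membrane analytical branch and the discretized Hamiltonian."""

import math

import numpy as np
import pytest

from mrebtwist.core_model import (
    DEFAULT_L_MAX,
    EnergyProfile,
    FilamentParams,
    FilamentState,
    PsiBoundError,
    asymptotic_density,
    energy_length_curve,
    flat_energy_at_length,
    flat_energy_of_psim,
    flat_length_of_psim,
    hamiltonian_energy,
    limit_length,
    psi_m_bound,
)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


class TestFilamentParams:
    def test_e0_is_recomputed_from_C_and_k0(self, wt):
        assert wt.e0 == 0.5 * wt.C * wt.k0**2
        assert wt.with_(C=2 * wt.C).e0 == 2 * wt.e0

    @pytest.mark.parametrize("bad", [{"C": -1.0}, {"K": -1.0}, {"V": -0.1},
                                     {"mu0": -2.0}, {"r": 0.0}, {"r": -5.0}])
    def test_invalid_values_rejected(self, wt, bad):
        with pytest.raises(ValueError):
            wt.with_(**bad)

    def test_toml_round_trip(self, wt_cyl, tmp_path):
        path = tmp_path / "params.toml"
        wt_cyl.to_toml(path)
        assert FilamentParams.from_toml(path) == wt_cyl


class TestFilamentState:
    def test_length_is_segments_times_spacing(self):
        st = FilamentState.uniform(100.0, segment_length=5.0)
        assert st.L == pytest.approx(100.0)
        assert st.n_segments == 20
        assert len(st.theta) == st.n_segments + 1

    def test_invalid_states_rejected(self):
        good = dict(segment_length=5.0, theta=np.full(5, 1.0), psi=np.zeros(5))
        with pytest.raises(ValueError):
            FilamentState(**{**good, "segment_length": 0.0})
        with pytest.raises(ValueError):
            FilamentState(**{**good, "theta": np.full(5, 4.0)})  # > pi
        with pytest.raises(ValueError):
            FilamentState(**{**good, "theta": np.full(5, np.nan)})
        with pytest.raises(ValueError):   # 2 pi jump in psi
            FilamentState(**{**good, "psi": np.array([0, 0, 2 * np.pi, 0, 0.0])})


# ---------------------------------------------------------------------------
# discretized Hamiltonian
# ---------------------------------------------------------------------------


class TestHamiltonian:
    def test_straight_untwisted_flat_filament_has_zero_energy(self, wt):
        p = wt.with_(k0=0.0, omega0=0.0, V=0.0)
        st = FilamentState.uniform(100.0)
        assert hamiltonian_energy(st, p) == 0.0

    def test_uniform_state_gives_constant_density_exactly(self, wt):
        # theta = 90 deg, psi = 0 on a flat membrane: density e0 + K w0^2 / 2
        st = FilamentState.uniform(100.0)
        expected = (wt.e0 + 0.5 * wt.K * wt.omega0**2) * 100.0
        assert hamiltonian_energy(st, wt) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("r", [math.inf, 400.0])
    def test_matches_fine_grid_quadrature_of_continuum_integrand(self, wt, r):
        # oracle: trapezoid quadrature of the continuum energy density for the
        # piecewise-linear interpolant of the state, at 10x finer resolution
        p = wt.with_(r=r)
        rng = np.random.default_rng(7)
        L, n = 200.0, 100
        s = np.linspace(-L / 2, L / 2, n + 1)
        theta = np.pi / 2 + 0.3 * np.sin(2 * np.pi * s / L) + 0.1 * np.cos(4 * np.pi * s / L)
        psi = 0.8 * np.sin(np.pi * s / L) + 0.05 * rng.standard_normal()
        st = FilamentState(segment_length=L / n, theta=theta, psi=psi)

        fine = np.linspace(-L / 2, L / 2, 10 * n + 1)
        th_f = np.interp(fine, s, theta)
        ps_f = np.interp(fine, s, psi)
        inv_r = 0.0 if math.isinf(r) else 1.0 / r
        mid_th = 0.5 * (th_f[1:] + th_f[:-1])
        mid_ps = 0.5 * (ps_f[1:] + ps_f[:-1])
        ds_f = fine[1] - fine[0]
        dens = (p.C * (np.sin(mid_th) ** 2 * inv_r - p.k0) ** 2
                + p.C * (np.diff(th_f) / ds_f) ** 2
                + p.K * (np.diff(ps_f) / ds_f - np.sin(2 * mid_th) * inv_r / 2 - p.omega0) ** 2
                + 2 * p.V * np.sin(mid_ps / 2) ** 2)
        oracle = 0.5 * float(np.sum(dens)) * ds_f
        assert hamiltonian_energy(st, p) == pytest.approx(oracle, rel=1e-4)


# ---------------------------------------------------------------------------
# flat-branch quadrature and elliptic paths
# ---------------------------------------------------------------------------


class TestFlatBranch:
    def test_length_vanishes_with_boundary_twist(self, wt):
        assert flat_length_of_psim(0.0, wt) == 0.0
        assert flat_length_of_psim(1e-6, wt) < 1e-3

    @pytest.mark.parametrize("psi_m", [0.2, 0.9, 1.6, 2.05])
    @pytest.mark.parametrize("scale", [1.0, 0.5])
    def test_elliptic_path_equals_quadrature(self, wt, psi_m, scale):
        p = wt.with_(K=wt.K * scale, V=wt.V * scale)
        Lq = flat_length_of_psim(psi_m, p)
        Le = flat_length_of_psim(psi_m, p, method="elliptic")
        assert Le == pytest.approx(Lq, rel=1e-6)
        Eq = flat_energy_of_psim(psi_m, p)
        Ee = flat_energy_of_psim(psi_m, p, method="elliptic")
        assert Ee == pytest.approx(Eq, rel=1e-6)

    def test_psi_m_at_bound_is_flagged_not_nan(self, wt):
        with pytest.raises(PsiBoundError):
            flat_length_of_psim(psi_m_bound(wt) + 1e-6, wt)

    def test_wild_type_curve_contains_160nm(self, wt):
        # a boundary twist exists whose filament length is 160 nm
        E = flat_energy_at_length(160.0, wt)
        assert np.isfinite(E) and E > 0

    def test_zero_intrinsic_twist_energy_is_linear(self, wt):
        p = wt.with_(omega0=0.0)
        prof = energy_length_curve(p, L_max=500.0)
        assert np.allclose(prof.E, p.e0 * prof.L_grid, rtol=1e-12)
        assert np.allclose(prof.dEdL, p.e0)

    def test_flat_energy_matches_brute_force_minimization(self, wt):
        # oracle: direct minimization of the discretized flat twist energy
        # over the psi profile (N = 200, free boundaries, zero-winding box)
        from scipy.optimize import minimize

        N = 200
        for L in (20.0, 60.0, 120.0, 250.0, 400.0):
            ds = L / N
            s = np.linspace(-L / 2, L / 2, N + 1)

            def energy(psi):
                dpsi = np.diff(psi) / ds
                pbar = 0.5 * (psi[1:] + psi[:-1])
                dens = wt.K * (dpsi - wt.omega0) ** 2 + 2 * wt.V * np.sin(pbar / 2) ** 2
                e = 0.5 * np.sum(dens) * ds + wt.e0 * L
                g = np.zeros_like(psi)
                tK = wt.K * (dpsi - wt.omega0)
                tV = 0.25 * wt.V * np.sin(pbar) * ds
                g[:-1] += -tK + tV
                g[1:] += tK + tV
                return e, g

            psi0 = np.clip(wt.omega0 * s * 0.8, -2.0, 2.0)
            res = minimize(energy, psi0, jac=True, method="L-BFGS-B",
                           bounds=[(-np.pi, np.pi)] * (N + 1),
                           options=dict(maxiter=20000, ftol=1e-15, gtol=1e-12))
            analytic = flat_energy_at_length(L, wt)
            assert res.fun == pytest.approx(analytic, rel=0.01), f"L={L}"

    def test_large_L_slope_approaches_interior_density(self, wt):
        prof = energy_length_curve(wt, L_max=1200.0)
        target = asymptotic_density(wt)
        assert prof.dEdL[-1] == pytest.approx(target, rel=5e-3)
        # and the slope never exceeds the fully-bound interior density
        # (tiny spline-derivative overshoot allowed)
        assert np.all(prof.dEdL <= target * (1 + 1e-5))


# ---------------------------------------------------------------------------
# energy-length curve and limit length
# ---------------------------------------------------------------------------


class TestEnergyLengthCurve:
    def test_curve_is_deterministic(self, wt):
        p1 = energy_length_curve(wt, L_max=400.0)
        p2 = energy_length_curve(wt, L_max=400.0)
        assert np.array_equal(p1.E, p2.E) and np.array_equal(p1.dEdL, p2.dEdL)

    def test_curve_is_increasing_and_slope_monotone(self, wt):
        prof = energy_length_curve(wt, L_max=500.0)
        assert np.all(np.diff(prof.E) > 0)
        assert np.all(np.diff(prof.dEdL) > -1e-9)

    def test_profile_invariants_enforced(self):
        with pytest.raises(ValueError):
            EnergyProfile(L_grid=[1.0, 1.0, 2.0], E=[0, 1, 2], dEdL=[0, 1, 1])
        with pytest.raises(ValueError):
            EnergyProfile(L_grid=[1.0, 2.0], E=[0, np.inf], dEdL=[0, 1])


class TestLimitLength:
    def test_unbounded_when_density_below_mu0(self, wt):
        # no twist frustration and e0 < mu0: slope constant below threshold
        p = wt.with_(omega0=0.0)
        prof = energy_length_curve(p, L_max=DEFAULT_L_MAX)
        assert limit_length(prof, p.mu0) == math.inf

    def test_finite_iff_interior_density_exceeds_mu0(self, wt):
        prof = energy_length_curve(wt, L_max=1000.0)
        assert asymptotic_density(wt) > wt.mu0
        assert math.isfinite(limit_length(prof, wt.mu0))

    def test_limit_length_increases_with_mu0(self, wt):
        prof = energy_length_curve(wt, L_max=1000.0)
        l1 = limit_length(prof, wt.mu0)
        l2 = limit_length(prof, 1.3 * wt.mu0)
        assert l2 > l1

    def test_energy_unit_invariance(self, wt):
        # jointly rescaling C, K, V, mu0 leaves the limit length unchanged
        prof = energy_length_curve(wt, L_max=600.0)
        l1 = limit_length(prof, wt.mu0)
        scaled = wt.with_(C=3 * wt.C, K=3 * wt.K, V=3 * wt.V, mu0=3 * wt.mu0)
        prof3 = energy_length_curve(scaled, L_max=600.0)
        l3 = limit_length(prof3, scaled.mu0)
        assert l3 == pytest.approx(l1, rel=1e-6)
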