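"""Simulators: exactness, limits, cross-level moment consistency."""

import math

import numpy as np
import pytest
from scipy.stats import kstest

import quasiburst as qb
from quasiburst.fpt import EnvelopeLaw


class TestGillespie:
    def test_pure_death_decays_to_absorption(self, table1):
        """With activation off, every neuron decays independently; the chain
        absorbs at (0, 0) and the decay of the mean follows exp(-alpha t)."""
        p = table1.with_overrides(beta_E=0.0, beta_I=0.0)
        with pytest.warns(UserWarning, match="absorbed"):
            res = qb.simulate_gillespie(p, duration=400.0, seed=1,
                                        initial=(800, 200), burn_in=0.0)
        assert res.meta["absorbed"]
        assert res["activity_E"].values[-1] == 0.0
        E = res["activity_E"].values
        t = res["activity_E"].times
        k = int(20.0 / 0.5)
        assert E[k] == pytest.approx(math.exp(-p.alpha_E * t[k]), abs=0.05)

    def test_mean_field_consistency_at_large_size(self, table1):
        """Time-averaged activity approaches the deterministic fixed point as
        the populations grow (finite-size corrections shrink like 1/N)."""
        p = table1.with_overrides(N_E=12800, N_I=3200)
        res = qb.simulate_gillespie(p, duration=40_500.0, seed=3)
        fp = qb.solve_fixed_point(p)
        # residual O(1/N) nonlinear shifts remain; the I population, being
        # four times smaller, carries the larger one
        assert res["activity_E"].values.mean() == pytest.approx(fp.E0, rel=0.015)
        assert res["activity_I"].values.mean() == pytest.approx(fp.I0, rel=0.04)

    def test_matches_rate_sde_moments_at_table_size(self, table1):
        """Level-crossing consistency: the microscopic chain and the nonlinear
        rate SDEs share mean and variance at the same population size."""
        g = qb.simulate_gillespie(table1, duration=100_500.0, seed=5)
        r = qb.simulate_rate_sde(table1, duration=100_500.0, dt=0.02, seed=6, dt_out=0.5)
        Eg, Er = g["activity_E"].values, r["activity_E"].values
        n_eff = Eg.size * 0.5 / 60.0  # ~1/nu decorrelation time
        se_mean = math.sqrt((Eg.var() + Er.var()) / n_eff)
        assert abs(Eg.mean() - Er.mean()) < 3 * se_mean
        se_var = math.sqrt(2.0 / n_eff) * max(Eg.var(), Er.var()) * math.sqrt(2)
        assert abs(Eg.var() - Er.var()) < 3 * se_var

    def test_burst_epochs_visible_in_envelope_variance(self, table1):
        """In transient synchrony the band-passed activity alternates between
        high- and low-amplitude epochs: the envelope is strongly modulated
        (its coefficient of variation is far above that of a constant-
        amplitude oscillation)."""
        res = qb.simulate_gillespie(table1, duration=60_500.0, seed=7)
        act = res["activity_E"]
        scaled = act.with_values((act.values - act.values.mean()) * math.sqrt(table1.N_E))
        lfp = qb.make_lfp(scaled)
        env = qb.analytic_signal(lfp).envelope.values
        assert env.std() / env.mean() > 0.3

    def test_seeded_determinism(self, table1):
        a = qb.simulate_gillespie(table1, duration=2_500.0, seed=9)
        b = qb.simulate_gillespie(table1, duration=2_500.0, seed=9)
        c = qb.simulate_gillespie(table1, duration=2_500.0, seed=10)
        assert np.array_equal(a["activity_E"].values, b["activity_E"].values)
        assert not np.array_equal(a["activity_E"].values, c["activity_E"].values)

    def test_raster_assignment_and_single_neuron_irregularity(self, table1):
        """The per-neuron raster reconstructed by exchangeability gives
        near-Poisson single-neuron activation statistics (interval CV
        near 1) while the population rhythm is strongly oscillatory."""
        res = qb.simulate_gillespie(table1, duration=60_500.0, seed=11, record="raster")
        times, ids = res.meta["raster"]
        assert len(times) > 0
        assert ids.min() >= 0 and ids.max() < table1.N_E + table1.N_I
        cvs = []
        for neuron in range(40):
            t = times[ids == neuron]
            if len(t) > 20:
                isi = np.diff(t)
                cvs.append(isi.std() / isi.mean())
        assert len(cvs) > 20
        assert 0.7 < np.mean(cvs) < 1.3

    def test_initial_bounds_validated(self, table1):
        with pytest.raises(ValueError, match="initial counts"):
            qb.simulate_gillespie(table1, duration=10.0, seed=0, initial=(10_000, 0))


class TestRateSDE:
    def test_deterministic_limit_reaches_fixed_point(self, table1):
        """With the populations effectively infinite the multiplicative noise
        vanishes and the flow settles on the deterministic fixed point."""
        p = table1.with_overrides(N_E=10**12, N_I=10**12)
        res = qb.simulate_rate_sde(p, duration=3_000.0, dt=0.01, seed=0,
                                   dt_out=1.0, initial=(0.3, 0.3))
        fp = qb.solve_fixed_point(table1)
        assert res["activity_E"].values[-1] == pytest.approx(fp.E0, abs=1e-5)
        assert res["activity_I"].values[-1] == pytest.approx(fp.I0, abs=1e-5)

    def test_variance_matches_lyapunov_at_large_size(self, table1):
        """Stationary variance of sqrt(N) (E - E0*) approaches the linear-
        noise (Lyapunov) prediction for large populations."""
        p = table1.with_overrides(N_E=80_000, N_I=20_000)
        res = qb.simulate_rate_sde(p, duration=60_500.0, dt=0.01, seed=3, dt_out=0.5)
        S = qb.stationary_covariance(qb.lna_coefficients(p))
        var_scaled = res["activity_E"].values.var() * p.N_E
        assert var_scaled == pytest.approx(S[0, 0], rel=0.12)

    def test_seeded_determinism(self, table1):
        a = qb.simulate_rate_sde(table1, duration=1_000.0, dt=0.05, seed=4)
        b = qb.simulate_rate_sde(table1, duration=1_000.0, dt=0.05, seed=4)
        assert np.array_equal(a["activity_E"].values, b["activity_E"].values)


class TestLNA:
    def test_stationary_covariance_exact_at_coarse_step(self, table1):
        """The exact Gaussian transition has no step-size bias: even at a
        coarse 0.5 ms step the sample covariance matches the Lyapunov
        solution within sampling error."""
        c = qb.lna_coefficients(table1)
        res = qb.simulate_lna(c, duration=400_500.0, dt=0.5, seed=8)
        S = qb.stationary_covariance(c)
        V = np.column_stack([res["lfp_E"].values, res["lfp_I"].values])
        emp = np.cov(V.T)
        n_eff = len(V) * 0.5 / 60.0
        tol = 3 * math.sqrt(2.0 / n_eff)
        assert emp[0, 0] == pytest.approx(S[0, 0], rel=tol)
        assert emp[1, 1] == pytest.approx(S[1, 1], rel=tol)

    def test_noise_free_decay_at_rate_nu_and_frequency_omega0(self, table1):
        """With the noise off the fluctuations spiral into the origin at
        rate nu while oscillating at omega0."""
        import dataclasses

        c = dataclasses.replace(qb.lna_coefficients(table1), sigma_E=0.0, sigma_I=0.0)
        red = qb.reduce_params(table1)
        res = qb.simulate_lna(c, duration=400.0, dt=0.1, seed=0, burn_in=0.0,
                              initial=(1.0, 0.0))
        x = res["lfp_E"].values
        # amplitude ratio over one damping time ~ exp(-nu T)
        T = 200.0
        i = int(T / 0.1)
        peak0 = np.max(np.abs(x[: i // 4]))
        peak1 = np.max(np.abs(x[i - i // 4: i]))
        # the two window maxima sit ~0.75 T apart (centres of the windows)
        assert peak1 / peak0 == pytest.approx(math.exp(-red.nu * 0.75 * T), rel=0.3)
        # zero-crossing count over the window gives omega0 / pi crossings per ms
        crossings = np.sum(np.diff(np.sign(x[:i])) != 0)
        assert crossings == pytest.approx(red.omega0 * T / math.pi, rel=0.05)

    def test_envelope_histogram_matches_rayleigh_law(self, table1):
        """The Hilbert envelope of the simulated linear fluctuations follows
        the stationary Rayleigh density with scale from the Lyapunov
        variance (KS distance on decorrelated samples)."""
        c = qb.lna_coefficients(table1)
        res = qb.simulate_lna(c, duration=400_500.0, dt=0.5, seed=12)
        env = qb.analytic_signal(res["lfp_E"]).envelope.values
        S = qb.stationary_covariance(c)
        scale = math.sqrt(S[0, 0])
        sub = env[:: int(50 / 0.5)]  # ~decorrelated
        stat = kstest(sub, lambda z: 1.0 - np.exp(-z**2 / (2 * scale**2))).statistic
        assert stat < 0.05


class TestSAM:
    def test_envelope_second_moment_and_component_sd(self, reduced_points):
        """E[Z^2] = 2 R^2 (each OU component has stationary SD R)."""
        red = reduced_points["point_b"]
        sim = qb.simulate_sam(red, duration=400_500.0, dt=0.5, seed=21)
        Z = sim["envelope"].values
        assert math.sqrt((Z**2).mean() / 2.0) == pytest.approx(red.R, rel=0.03)

    def test_envelope_histogram_matches_stationary_density(self, reduced_points):
        red = reduced_points["point_b"]
        law = EnvelopeLaw(red.nu, red.D)
        sim = qb.simulate_sam(red, duration=400_500.0, dt=0.5, seed=22)
        sub = sim["envelope"].values[:: int(50 / 0.5)]
        stat = kstest(sub, lambda z: 1.0 - np.exp(-law.nu * z**2 / law.D)).statistic
        assert stat < 0.03

    def test_reconstruction_consistency(self, reduced_points):
        """V_E = Z cos(omega0 t + phi) holds exactly for the OU-pair
        construction, and the envelope is positive throughout."""
        red = reduced_points["point_b"]
        sim = qb.simulate_sam(red, duration=5_500.0, dt=0.5, seed=23)
        Z, phi, V = (sim["envelope"].values, sim["phase"].values, sim["lfp_E"].values)
        t = sim["lfp_E"].times
        assert np.allclose(V, Z * np.cos(red.omega0 * t + phi), atol=1e-10)
        assert np.all(Z >= 0)

    def test_matches_lna_envelope_distribution(self, table1, reduced_points):
        """Reduced (envelope-phase) and linear dynamics are statistically
        equivalent at matched parameters."""
        from scipy.stats import ks_2samp

        red = reduced_points["point_b"]
        sam = qb.simulate_sam(red, duration=300_500.0, dt=0.5, seed=24)
        lna = qb.simulate_lna(qb.lna_coefficients(table1), duration=300_500.0,
                              dt=0.5, seed=25)
        env_l = qb.analytic_signal(lna["lfp_E"]).envelope.values
        sub = int(50 / 0.5)
        stat = ks_2samp(sam["envelope"].values[::sub], env_l[::sub]).statistic
        assert stat < 0.05

    def test_refuses_outside_transient_synchrony(self, table1):
        red = qb.reduce_params(table1.with_overrides(W_ee=32.0))  # high synchrony
        assert red.regime == "high_synchrony"
        with pytest.raises(ValueError, match="transient synchrony"):
            qb.simulate_sam(red, duration=100.0, seed=0)

    def test_seeded_determinism(self, reduced_points):
        red = reduced_points["point_b"]
        a = qb.simulate_sam(red, duration=2_000.0, dt=0.5, seed=3)
        b = qb.simulate_sam(red, duration=2_000.0, dt=0.5, seed=3)
        assert np.array_equal(a["envelope"].values, b["envelope"].values)
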