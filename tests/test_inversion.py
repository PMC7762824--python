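"""Variational-Laplace inversion: conjugate oracle, convergence, group scheme."""

import numpy as np
import pytest

from tcmodel.circuit_model import ParameterVector
from tcmodel.exceptions import StructuralError
from tcmodel.inversion import (Posterior, PriorSpec, default_priors,
                               free_energy, two_stage_group_fit,
                               variational_laplace)
from tcmodel.observer import Spectrum


def linear_problem(seed=3, m=24, p=3, tau=25.0, offset=10.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(m, p))
    theta_true = rng.normal(0, 0.4, p)
    y = offset + X @ theta_true + rng.normal(0, 1 / np.sqrt(tau), m)
    grid = np.arange(m, dtype=float) + 1.0
    names = tuple(f"b{i}" for i in range(p))
    pv = np.full(p, 0.5)
    priors = PriorSpec(ParameterVector(names, np.zeros(p)), pv,
                       noise_log_precision_mean=float(np.log(tau)),
                       noise_log_precision_variance=0.0)

    def forward(pvec):
        return Spectrum(grid, offset + X @ pvec.values)

    return X, theta_true, y, grid, priors, forward, tau, pv


class TestLinearGaussianOracle:
    """On a linear model the Laplace machinery is exact; conjugate formulas
    and the analytic log evidence are the oracle."""

    def setup_method(self):
        (self.X, self.theta_true, self.y, self.grid, self.priors,
         self.forward, self.tau, self.pv) = linear_problem()
        self.post = variational_laplace(None, Spectrum(self.grid, self.y),
                                        self.priors, forward=self.forward)
        Pi0 = np.diag(1 / self.pv)
        H = self.tau * self.X.T @ self.X + Pi0
        self.S = np.linalg.inv(H)
        self.mu = self.S @ (self.tau * self.X.T @ (self.y - 10.0))

    def test_posterior_mean_matches_conjugate(self):
        assert np.allclose(self.post.mean.values, self.mu, atol=1e-6)

    def test_posterior_covariance_matches_conjugate(self):
        assert np.allclose(self.post.covariance, self.S, atol=1e-8)

    def test_free_energy_equals_log_evidence(self):
        m = self.y.size
        C = self.X @ np.diag(self.pv) @ self.X.T + np.eye(m) / self.tau
        r = self.y - 10.0
        logev = -0.5 * (m * np.log(2 * np.pi) + np.linalg.slogdet(C)[1]
                        + r @ np.linalg.solve(C, r))
        assert self.post.free_energy == pytest.approx(logev, abs=1e-6)

    def test_accepted_f_sequence_is_nondecreasing(self):
        trace = np.array(self.post.f_trace)
        assert np.all(np.diff(trace) >= 0)

    def test_free_energy_function_matches_at_posterior(self):
        J = self.X
        F = free_energy(None, self.post.mean, Spectrum(self.grid, self.y),
                        self.priors, self.tau,
                        predicted=self.forward(self.post.mean),
                        posterior_cov=self.post.covariance, sensitivity=J)
        assert F == pytest.approx(self.post.free_energy, abs=1e-6)


class TestFreeEnergy:
    def test_zero_residual_at_prior_mean_has_zero_complexity(self):
        grid = np.arange(5.0)
        data = Spectrum(grid, np.ones(5))
        priors = PriorSpec(ParameterVector(("a",), np.zeros(1)), np.array([1.0]))
        F = free_energy(None, priors.mean, data, priors, 4.0, predicted=data)
        m = 5
        assert F == pytest.approx(0.5 * m * (np.log(4.0) - np.log(2 * np.pi)))

    def test_monotone_in_residual(self):
        grid = np.arange(5.0)
        data = Spectrum(grid, np.ones(5))
        priors = PriorSpec(ParameterVector(("a",), np.zeros(1)), np.array([1.0]))
        f_small = free_energy(None, priors.mean, data, priors, 4.0,
                              predicted=Spectrum(grid, np.ones(5) * 1.1))
        f_large = free_energy(None, priors.mean, data, priors, 4.0,
                              predicted=Spectrum(grid, np.ones(5) * 1.2))
        assert f_large < f_small

    def test_grid_mismatch_raises(self):
        priors = PriorSpec(ParameterVector(("a",), np.zeros(1)), np.array([1.0]))
        with pytest.raises(StructuralError):
            free_energy(None, priors.mean, Spectrum(np.arange(5.0), np.ones(5)),
                        priors, 1.0,
                        predicted=Spectrum(np.arange(6.0), np.ones(6)))


class TestVariationalLaplace:
    def test_zero_variance_priors_return_prior_mean(self):
        X, _, y, grid, priors, forward, tau, pv = linear_problem()
        pinned = PriorSpec(priors.mean, np.zeros_like(priors.variances),
                           priors.noise_log_precision_mean, 0.0)
        post = variational_laplace(None, Spectrum(grid, y), pinned,
                                   forward=forward)
        assert np.array_equal(post.mean.values, pinned.mean.values)
        assert post.n_iterations == 0
        assert post.converged

    def test_posterior_json_roundtrip(self):
        X, _, y, grid, priors, forward, tau, pv = linear_problem()
        post = variational_laplace(None, Spectrum(grid, y), priors,
                                   forward=forward)
        back = Posterior.from_json(post.to_json())
        assert np.allclose(back.mean.values, post.mean.values)
        assert np.allclose(back.covariance, post.covariance)
        assert back.free_energy == pytest.approx(post.free_energy)
        assert back.free_names == post.free_names

    def test_default_priors_free_set(self, tcm_spec):
        priors = default_priors(tcm_spec)
        free = set(np.array(priors.mean.names)[priors.free_mask])
        assert "gamma:GABA_A:DP->DP" in free
        assert "kappa:NMDA" in free
        assert "delay:CT" in free
        assert "C:SS" not in free
        assert "sigma:SP" not in free


class TestTwoStageGroupFit:
    def _datasets(self, n=4, seed=0, spread=0.0):
        X, theta_true, y, grid, priors, forward, tau, pv = linear_problem(seed)
        rng = np.random.default_rng(seed + 1)
        data = []
        for i in range(n):
            theta_i = theta_true + rng.normal(0, spread, theta_true.size)
            yi = 10.0 + X @ theta_i + rng.normal(0, 0.02, y.size)
            data.append(Spectrum(grid, yi, meta={"dataset": str(i)}))
        return data, priors, forward

    def test_identical_datasets_reproduce_stage1(self):
        data, priors, forward = self._datasets(n=3, spread=0.0)
        data = [Spectrum(data[0].frequencies, data[0].amplitudes.copy(),
                         meta={"dataset": str(i)}) for i in range(3)]
        posts = two_stage_group_fit(data, None, priors, forward=forward)
        ref = posts[0].mean.values
        for p in posts[1:]:
            assert np.allclose(p.mean.values, ref, atol=1e-3)

    def test_order_equivariance(self):
        data, priors, forward = self._datasets(n=4, spread=0.3)
        posts = two_stage_group_fit(data, None, priors, forward=forward)
        rev = two_stage_group_fit(data[::-1], None, priors, forward=forward)
        for a, b in zip(posts, rev[::-1]):
            assert np.allclose(a.mean.values, b.mean.values, atol=1e-10)

    def test_group_difference_recovered_with_sign(self):
        # Two sub-groups differing in one coefficient: the per-dataset
        # posteriors separate in that coefficient with the correct sign.
        X, theta_true, y, grid, priors, forward, tau, pv = linear_problem()
        rng = np.random.default_rng(9)
        lo, hi = [], []
        for i in range(3):
            t_lo = theta_true.copy()
            t_hi = theta_true.copy()
            t_hi[1] += 0.8
            lo.append(Spectrum(grid, 10.0 + X @ t_lo + rng.normal(0, 0.02, y.size)))
            hi.append(Spectrum(grid, 10.0 + X @ t_hi + rng.normal(0, 0.02, y.size)))
        posts = two_stage_group_fit(lo + hi, None, priors, forward=forward)
        b1_lo = np.mean([p.mean.values[1] for p in posts[:3]])
        b1_hi = np.mean([p.mean.values[1] for p in posts[3:]])
        assert b1_hi - b1_lo > 0.4

    def test_requires_common_grid(self):
        data, priors, forward = self._datasets(n=2)
        bad = Spectrum(data[0].frequencies + 1.0, data[0].amplitudes)
        with pytest.raises(StructuralError):
            two_stage_group_fit([data[0], bad], None, priors, forward=forward)

    def test_requires_two_datasets(self):
        data, priors, forward = self._datasets(n=1)
        with pytest.raises(StructuralError):
            two_stage_group_fit(data[:1], None, priors, forward=forward)


class TestCircuitRecovery:
    """Reduced nonlinear recovery: draw coefficients near the prior, fit, and
    check errors shrink with less measurement noise."""

    def test_recovery_error_decreases_with_noise(self, tcm_spec):
        from tcmodel.circuit_model import gamma_name, parameter_names
        from tcmodel.observer import predict_spectrum

        names = parameter_names(tcm_spec)
        free = [gamma_name("GABA_A", "DP", "DP"), gamma_name("NMDA", "SI", "SP")]
        variances = np.array([1 / 16 if n in free else 0.0 for n in names])
        kw = dict(duration=1.2, burn_in=0.3)
        rng = np.random.default_rng(17)
        errors = {0.02: [], 0.01: []}
        for rep in range(3):
            truth = rng.normal(0, 0.25, 2)
            p_true = ParameterVector.zeros(tcm_spec).updated(
                dict(zip(free, truth)))
            clean = predict_spectrum(tcm_spec, p_true, **kw)
            for noise in errors:
                y = np.maximum(clean.amplitudes
                               + rng.normal(0, noise, clean.amplitudes.size), 0)
                priors = PriorSpec(ParameterVector.zeros(tcm_spec), variances,
                                   noise_log_precision_variance=0.25)
                post = variational_laplace(
                    tcm_spec, Spectrum(clean.frequencies, y), priors,
                    max_iter=12, fd_step=0.05, n_starts=2, **kw)
                est = np.array([post.mean[n] for n in free])
                errors[noise].append(np.abs(est - truth).mean())
        # median error below the prior SD, and not worse with less noise
        assert np.median(errors[0.02]) < 0.25
        assert np.median(errors[0.01]) <= np.median(errors[0.02]) + 0.05
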