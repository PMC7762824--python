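"""Variational-Laplace (Gauss-Newton free-energy ascent) model inversion.

The observation model is ``y(f) = h(theta)(f) + eps`` with iid Gaussian noise
of precision ``tau = exp(lambda)`` across frequencies, Gaussian priors on the
log-scaling coefficients theta, and a Gaussian (log-normal in tau) hyperprior
on lambda.  The approximate posterior q(theta) = N(mu, Sigma) maximises the
Laplace free energy

    F = E_q[log p(y | theta)] - KL(q || prior)
      = -tau/2 (e'e + tr(J Sigma J')) + m/2 (log tau - log 2 pi)
        - 1/2 (d' Pi0 d + tr(Pi0 Sigma) - p + log|C0| - log|Sigma|)
        [- KL for the noise hyperparameter when it is estimated]

which is exact for linear h.  Optimisation is a regularised Gauss-Newton
ascent: sensitivities of the predicted spectrum are obtained by central finite
differences on the coefficients, steps are accepted only if they increase F,
and a Levenberg-Marquardt damping factor doubles on rejection and halves on
acceptance.  Forward integrations that diverge are treated as rejected
candidates, never as fatal errors.

The two-stage group scheme fits the across-dataset mean spectrum first and
re-centres every individual fit's priors on that group posterior mean.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np

from .circuit_model import CircuitSpec, ParameterVector, parameter_names
from .exceptions import InstabilityError, StructuralError
from .observer import Spectrum, predict_spectrum

__all__ = ["PriorSpec", "Posterior", "free_energy", "variational_laplace",
           "two_stage_group_fit", "default_priors"]

LOG2PI = np.log(2.0 * np.pi)


@dataclass
class PriorSpec:
    """Gaussian priors over coefficients plus a log-precision hyperprior.

    ``variances`` entries equal to zero pin the corresponding coefficient to
    the prior mean (it is excluded from the free subset).
    ``noise_log_precision_mean=None`` sets the hyperprior centre from the data
    at fit time so that the prior noise SD is about a tenth of the data RMS.
    """

    mean: ParameterVector
    variances: np.ndarray
    noise_log_precision_mean: Optional[float] = None
    noise_log_precision_variance: float = 1.0

    def __post_init__(self):
        self.variances = np.asarray(self.variances, dtype=float)
        if self.variances.shape != self.mean.values.shape:
            raise StructuralError("prior variance vector length mismatch")
        if np.any(self.variances < 0):
            raise StructuralError("prior variances must be >= 0")

    @property
    def free_mask(self) -> np.ndarray:
        return self.variances > 0

    def with_mean(self, mean: ParameterVector) -> "PriorSpec":
        return PriorSpec(mean.copy(), self.variances.copy(),
                         self.noise_log_precision_mean,
                         self.noise_log_precision_variance)


def default_priors(spec: CircuitSpec, free: Optional[Sequence[str]] = None,
                   variance: Optional[float] = None) -> PriorSpec:
    """Priors with zero means; free set defaults to the fitted quantities.

    By default the connectivity weights, receptor rates, conduction delays,
    input gain and observation scale are free; capacitances and firing
    dispersions are pinned.
    """
    names = parameter_names(spec)
    mean = ParameterVector.zeros(spec)
    if free is None:
        free = [n for n in names
                if n.startswith(("gamma:", "kappa:", "delay:"))
                or n in ("input_gain", "obs_scale")]
    v = spec.prior_variance if variance is None else variance
    variances = np.array([v if n in set(free) else 0.0 for n in names])
    return PriorSpec(mean, variances)


@dataclass
class Posterior:
    """Gaussian posterior for one dataset: mean, covariance and diagnostics."""

    mean: ParameterVector
    covariance: np.ndarray  # full coefficient space; zero rows for pinned ones
    free_energy: float
    accuracy: float
    complexity: float
    predicted: Spectrum
    n_iterations: int
    converged: bool
    noise_log_precision: float
    free_names: tuple = ()
    f_trace: tuple = ()  # accepted-step free-energy sequence (non-decreasing)

    def std(self, name: str) -> float:
        i = self.mean.index(name)
        return float(np.sqrt(self.covariance[i, i]))

    def to_json(self) -> str:
        return json.dumps({
            "names": list(self.mean.names),
            "mean": self.mean.values.tolist(),
            "covariance": self.covariance.tolist(),
            "free_energy": self.free_energy,
            "accuracy": self.accuracy,
            "complexity": self.complexity,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "noise_log_precision": self.noise_log_precision,
            "free_names": list(self.free_names),
            "f_trace": list(self.f_trace),
            "predicted": {"frequencies": self.predicted.frequencies.tolist(),
                          "amplitudes": self.predicted.amplitudes.tolist(),
                          "meta": self.predicted.meta},
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "Posterior":
        d = json.loads(text)
        pred = Spectrum(np.array(d["predicted"]["frequencies"]),
                        np.array(d["predicted"]["amplitudes"]),
                        meta=d["predicted"].get("meta", {}))
        return cls(ParameterVector(tuple(d["names"]), np.array(d["mean"])),
                   np.array(d["covariance"]), d["free_energy"], d["accuracy"],
                   d["complexity"], pred, d["n_iterations"], d["converged"],
                   d["noise_log_precision"], tuple(d["free_names"]),
                   tuple(d.get("f_trace", ())))


def _check_grid(data: Spectrum, predicted: Spectrum) -> None:
    if data.frequencies.shape != predicted.frequencies.shape or \
            not np.allclose(data.frequencies, predicted.frequencies):
        raise StructuralError("data and prediction frequency grids differ")


def free_energy(spec: Optional[CircuitSpec], params: ParameterVector,
                data: Spectrum, priors: PriorSpec, noise_precision: float,
                predicted: Optional[Spectrum] = None,
                posterior_cov: Optional[np.ndarray] = None,
                sensitivity: Optional[np.ndarray] = None) -> float:
    """Laplace free energy at a parameter point.

    Without ``posterior_cov`` the posterior is treated as a point mass, so the
    complexity term reduces to the prior Mahalanobis distance.  With
    ``posterior_cov`` (and ``sensitivity`` for the trace correction) the full
    Gaussian-posterior expression is used; for a linear forward model it then
    equals the log model evidence.  Returns ``-inf`` for unstable parameters.
    """
    if predicted is None:
        try:
            predicted = predict_spectrum(spec, params, frequencies=data.frequencies)
        except InstabilityError:
            return -np.inf
    _check_grid(data, predicted)
    e = data.amplitudes - predicted.amplitudes
    m = e.size
    tau = float(noise_precision)
    sse = float(e @ e)
    free = priors.free_mask
    d = (params.values - priors.mean.values)[free]
    pv = priors.variances[free]
    acc = -0.5 * tau * sse + 0.5 * m * (np.log(tau) - LOG2PI)
    if posterior_cov is None:
        comp = 0.5 * float(d @ (d / pv)) if d.size else 0.0
    else:
        S = np.asarray(posterior_cov)
        if S.shape[0] == params.values.size:
            S = S[np.ix_(free, free)]
        if sensitivity is not None:
            Jf = sensitivity[:, :] if sensitivity.shape[1] == free.sum() \
                else sensitivity[:, free]
            acc -= 0.5 * tau * float(np.trace(Jf @ S @ Jf.T))
        sign, logdet_S = np.linalg.slogdet(S)
        comp = 0.5 * (float(d @ (d / pv)) + float(np.trace(S / pv))
                      - d.size + float(np.sum(np.log(pv))) - logdet_S)
    return acc - comp


def _sensitivity(forward: Callable[[np.ndarray], np.ndarray], theta: np.ndarray,
                 step: float = 1e-3) -> np.ndarray:
    """Central finite-difference sensitivities d prediction / d coefficient."""
    cols = []
    for k in range(theta.size):
        tp = theta.copy(); tp[k] += step
        tm = theta.copy(); tm[k] -= step
        cols.append((forward(tp) - forward(tm)) / (2 * step))
    return np.column_stack(cols) if cols else np.zeros((0, 0))


def variational_laplace(spec: Optional[CircuitSpec], data: Spectrum,
                        priors: PriorSpec, max_iter: int = 64,
                        forward: Optional[Callable[[ParameterVector], Spectrum]] = None,
                        tol: float = 1e-2, fd_step: float = 1e-3,
                        max_rejections: int = 6, n_starts: int = 1,
                        start_jitter: float = 0.25, start_seed: int = 0,
                        probe_sweeps: int = 0, probe_branches: int = 3,
                        probe_steps: Sequence[float] = (2.0, 1.0, -1.0, -2.0),
                        **forward_kwargs) -> Posterior:
    """Fit one spectrum by regularised Gauss-Newton ascent on the free energy.

    ``forward`` maps a full :class:`ParameterVector` to a :class:`Spectrum`;
    when omitted it is the circuit's forward prediction on the data grid.
    Additional keyword arguments (``duration``, ``dt``, ``burn_in``, ...) are
    passed to :func:`tcmodel.observer.predict_spectrum`.

    Oscillatory forward models can have locally rough, multi-basin free-energy
    surfaces, so two deterministic global-search aids are available (neither
    moves the prior):

    * ``probe_sweeps > 0``: branched greedy coordinate search before the
      ascent.  Candidate moves offset one free coefficient by one of
      ``probe_steps``; moves are screened with a cheap (single-evaluation)
      free energy, the best move is applied, and up to ``probe_sweeps`` moves
      are chained.  Because near-degenerate explanations compete, the
      ``probe_branches`` best-scoring first moves (on distinct coordinates)
      each root their own chain and the best endpoint wins.  This lets the
      search cross ridges and compare basins that block purely local steps.
    * ``n_starts > 1``: additional ascents from the most promising of a pool
      of prior draws, keeping the highest-F result.
    """
    if forward is None:
        if spec is None:
            raise StructuralError("need a circuit spec or an explicit forward map")

        def forward(p: ParameterVector) -> Spectrum:
            return predict_spectrum(spec, p, frequencies=data.frequencies,
                                    **forward_kwargs)

    names = priors.mean.names
    free = priors.free_mask
    p_free = int(free.sum())
    y = data.amplitudes
    m = y.size

    def predict_free(theta_free: np.ndarray) -> np.ndarray:
        full = priors.mean.copy()
        full.values = priors.mean.values.copy()
        full.values[free] = theta_free
        pred = forward(ParameterVector(names, full.values))
        _check_grid(data, pred)
        return pred.amplitudes

    # Hyperprior centre: prior noise SD about a tenth of the data RMS.
    lam0 = priors.noise_log_precision_mean
    if lam0 is None:
        lam0 = float(np.log(100.0 / max(np.mean(y ** 2), 1e-12)))
    v_lam = priors.noise_log_precision_variance

    if p_free == 0:
        pred = predict_free(np.zeros(0))
        e = y - pred
        tau = float(np.exp(lam0))
        F = free_energy(spec, priors.mean, data, priors, tau,
                        predicted=Spectrum(data.frequencies, np.maximum(pred, 0.0)))
        cov = np.zeros((len(names), len(names)))
        return Posterior(priors.mean.copy(), cov, F, F, 0.0,
                         Spectrum(data.frequencies, np.maximum(pred, 0.0)),
                         0, True, lam0, ())

    m0 = priors.mean.values[free]
    pv = priors.variances[free]
    Pi0 = np.diag(1.0 / pv)
    logdet_C0 = float(np.sum(np.log(pv)))

    def evaluate(theta_free: np.ndarray, lam: float):
        """Predict, linearise and score one candidate; None if unstable."""
        try:
            pred = predict_free(theta_free)
            J = _sensitivity(predict_free, theta_free, step=fd_step)
        except InstabilityError:
            return None
        e = y - pred
        # Hyperparameter update: 1-D Newton ascent on F(lambda).
        if v_lam > 0:
            H_cached = None
            for _ in range(8):
                tau = np.exp(lam)
                H = tau * (J.T @ J) + Pi0
                S = np.linalg.inv(H)
                s2 = float(e @ e) + float(np.trace(J @ S @ J.T))
                grad = -0.5 * tau * s2 + 0.5 * m - (lam - lam0) / v_lam
                hess = -0.5 * tau * s2 - 1.0 / v_lam
                step = grad / hess
                lam = float(np.clip(lam - step, lam0 - 8, lam0 + 8))
                if abs(step) < 1e-6:
                    break
        tau = float(np.exp(lam))
        H = tau * (J.T @ J) + Pi0
        S = np.linalg.inv(H)
        d = theta_free - m0
        sse = float(e @ e)
        trace = float(np.trace(J @ S @ J.T))
        acc = -0.5 * tau * (sse + trace) + 0.5 * m * (np.log(tau) - LOG2PI)
        sign, logdet_S = np.linalg.slogdet(S)
        comp = 0.5 * (float(d @ Pi0 @ d) + float(np.trace(Pi0 @ S))
                      - p_free + logdet_C0 - logdet_S)
        F = acc - comp
        if v_lam > 0:
            v_post = 1.0 / (0.5 * tau * (sse + trace) + 1.0 / v_lam)
            comp_lam = 0.5 * ((lam - lam0) ** 2 / v_lam + v_post / v_lam
                              - 1.0 + np.log(v_lam / v_post))
            F -= comp_lam
        grad_theta = tau * (J.T @ e) - Pi0 @ d
        return {"F": float(F), "acc": float(acc), "comp": float(comp),
                "pred": pred, "J": J, "S": S, "H": H, "grad": grad_theta,
                "lam": lam, "theta": theta_free.copy()}

    def cheap_F(theta_free: np.ndarray, tau: float) -> float:
        """Screening objective: one forward evaluation, point-mass posterior."""
        try:
            pred = predict_free(theta_free)
        except InstabilityError:
            return -np.inf
        e = y - pred
        d = theta_free - m0
        return float(-0.5 * tau * (e @ e) + 0.5 * m * (np.log(tau) - LOG2PI)
                     - 0.5 * d @ Pi0 @ d)

    def ascend(theta0: np.ndarray):
        """One regularised Gauss-Newton ascent from a start point.

        Each iteration proposes LM steps at several damping levels, screens
        them with single forward evaluations, then fully evaluates (and
        accepts only if F increases) the most promising one.
        """
        best = evaluate(theta0, float(lam0))
        if best is None:
            return None
        trace = [best["F"]]
        rho = 0.25  # LM damping, x2 on rejection, /2 on acceptance
        n_accept = 0
        small_improvements = 0
        rejections = 0
        converged = False
        for _ in range(max_iter):
            tau_now = float(np.exp(best["lam"]))
            dH = np.diag(np.diag(best["H"]))
            candidates = []
            for scale in (0.25, 1.0, 4.0, 16.0):
                try:
                    delta = np.linalg.solve(best["H"] + rho * scale * dH,
                                            best["grad"])
                except np.linalg.LinAlgError:
                    continue
                candidates.append(best["theta"] + delta)
            if not candidates:
                break
            scores = [cheap_F(th, tau_now) for th in candidates]
            pick = int(np.argmax(scores))
            candidate = evaluate(candidates[pick], best["lam"]) \
                if np.isfinite(scores[pick]) else None
            if candidate is not None and candidate["F"] > best["F"]:
                dF = candidate["F"] - best["F"]
                best = candidate
                trace.append(best["F"])
                rho = max(rho / 2.0, 1.0 / 512.0)
                n_accept += 1
                rejections = 0
                small_improvements = small_improvements + 1 if dF < tol else 0
                if small_improvements >= 3:
                    converged = True
                    break
            else:
                rho *= 2.0
                rejections += 1
                if rejections >= max_rejections:
                    break
        else:
            converged = small_improvements >= 1
        return best, n_accept, converged, tuple(trace)

    cache: Dict[tuple, float] = {}
    tau0 = float(np.exp(lam0))

    def screened(th: np.ndarray) -> float:
        key = tuple(np.round(th, 6))
        if key not in cache:
            cache[key] = cheap_F(th, tau0)
        return cache[key]

    def expand(th: np.ndarray):
        """All single-coordinate moves with their screening scores."""
        out = []
        for k in range(p_free):
            for step in probe_steps:
                cand = th.copy()
                cand[k] += step
                out.append((screened(cand), k, cand))
        return out

    def chain(th: np.ndarray, score: float):
        for _ in range(probe_sweeps):
            moves = expand(th)
            best_move = max(moves, key=lambda m: m[0])
            if best_move[0] <= score + 0.5:  # no meaningful gain in nats
                break
            score, _, th = best_move
        return score, th

    def coordinate_polish(th: np.ndarray,
                          steps=(0.5, 0.25, 0.1, -0.1, -0.25, -0.5)):
        """Fine per-coordinate profile refinement on the cheap screen."""
        th = th.copy()
        score = screened(th)
        for _ in range(4):
            moved = False
            for k in range(p_free):
                best_local = None
                for step in steps:
                    cand = th.copy()
                    cand[k] += step
                    s = screened(cand)
                    if s > score + 0.1 and (best_local is None
                                            or s > best_local[0]):
                        best_local = (s, cand)
                if best_local is not None:
                    score, th = best_local
                    moved = True
            if not moved:
                break
        return th

    def branched_greedy(th0: np.ndarray) -> np.ndarray:
        """Greedy chains rooted at the most promising single moves."""
        root_score = screened(th0)
        root_moves = sorted(expand(th0), key=lambda m: -m[0])
        roots, seen = [], set()
        for s, k, cand in root_moves:
            if k in seen or s <= root_score + 0.5:
                continue
            seen.add(k)
            roots.append((s, cand))
            if len(roots) >= max(probe_branches, 1):
                break
        best_end = (root_score, th0)
        for s, cand in roots:
            end = chain(cand, s)
            if end[0] > best_end[0]:
                best_end = end
        return best_end[1]

    theta_start = m0.copy()
    if probe_sweeps > 0:
        theta_start = branched_greedy(theta_start)

    first = ascend(theta_start)
    if first is None and probe_sweeps > 0:
        first = ascend(m0.copy())
    if first is None:
        raise InstabilityError("forward model unstable at the prior mean",
                               params=priors.mean)
    best, n_accept, converged, f_trace = first

    if probe_sweeps > 0:
        # Alternate: the ascent refines within a basin; a further greedy pass
        # from the refined point can reveal a better basin.  Keep only
        # F-improving outcomes.
        for _ in range(2):
            jumped = branched_greedy(best["theta"])
            if np.allclose(jumped, best["theta"]):
                break
            result = ascend(jumped)
            if result is not None and result[0]["F"] > best["F"]:
                best, n_accept, converged, f_trace = result
            else:
                break
        # Fine coordinate-profile polish: pulls each coefficient to its
        # conditional optimum, which Gauss-Newton steps miss on locally
        # rough surfaces.
        polished = coordinate_polish(best["theta"])
        if not np.allclose(polished, best["theta"]):
            result = ascend(polished)
            if result is not None and result[0]["F"] > best["F"]:
                best, n_accept, converged, f_trace = result
    if n_starts > 1:
        # Additional starts: cheap-screen a pool of prior draws and ascend
        # from the most promising ones.
        rng = np.random.default_rng(start_seed)
        tau0 = float(np.exp(lam0))
        n_probes = 8 * (n_starts - 1)
        probes = m0 + rng.normal(0.0, 1.0, (n_probes, p_free)) * np.sqrt(pv)
        scores = np.array([cheap_F(th, tau0) for th in probes])
        order = np.argsort(scores)[::-1]
        for idx in order[:n_starts - 1]:
            if not np.isfinite(scores[idx]):
                continue
            result = ascend(probes[idx])
            if result is not None and result[0]["F"] > best["F"]:
                best, n_accept, converged, f_trace = result

    mean_full = priors.mean.copy()
    mean_full.values = priors.mean.values.copy()
    mean_full.values[free] = best["theta"]
    cov_full = np.zeros((len(names), len(names)))
    cov_full[np.ix_(free, free)] = best["S"]
    predicted = Spectrum(data.frequencies, np.maximum(best["pred"], 0.0),
                         meta=dict(data.meta))
    return Posterior(mean=ParameterVector(names, mean_full.values),
                     covariance=cov_full, free_energy=best["F"],
                     accuracy=best["acc"], complexity=best["comp"],
                     predicted=predicted, n_iterations=n_accept,
                     converged=converged, noise_log_precision=best["lam"],
                     free_names=tuple(np.array(names)[free]),
                     f_trace=f_trace)


def two_stage_group_fit(datasets: Sequence[Spectrum], spec: Optional[CircuitSpec],
                        base_priors: PriorSpec,
                        forward: Optional[Callable] = None,
                        **fit_kwargs) -> List[Posterior]:
    """Fit a group of spectra with empirically centred priors.

    Stage 1 inverts the across-dataset mean spectrum starting from
    ``base_priors``; stage 2 inverts every dataset with priors re-centred on
    the stage-1 posterior mean (prior variances unchanged).  Non-convergence
    of an individual fit is recorded on its posterior, not raised.
    """
    if len(datasets) < 2:
        raise StructuralError("group fitting needs at least 2 datasets")
    grid = datasets[0].frequencies
    for d in datasets[1:]:
        if not np.allclose(d.frequencies, grid):
            raise StructuralError("datasets must share a frequency grid")
    mean_spectrum = Spectrum(grid, np.mean([d.amplitudes for d in datasets], axis=0),
                             meta={"dataset": "group-mean"})
    stage1 = variational_laplace(spec, mean_spectrum, base_priors,
                                 forward=forward, **fit_kwargs)
    stage2_priors = base_priors.with_mean(stage1.mean)
    out = []
    for d in datasets:
        post = variational_laplace(spec, d, stage2_priors, forward=forward,
                                   **fit_kwargs)
        if not post.converged:
            label = d.meta.get("dataset") or " ".join(
                filter(None, (d.meta.get("subject_id"),
                              d.meta.get("condition")))) or "?"
            warnings.warn(f"fit did not converge for dataset {label}",
                          stacklevel=2)
        out.append(post)
    return out
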