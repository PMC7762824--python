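"""Delayed-Euler numerical integration of the circuit equations.

Conduction delays between cortex and thalamus are folded into a first-order
update through the delay operator

    Q = inv(I - D o J)

where D is the state-by-state matrix of delays (ms), J the system Jacobian
(1/ms) at the initial state, and "o" the element-wise product.  The update is
then ``y(t+dt) = y(t) + dt * Q f(y(t))``, which reduces bit-exactly to plain
Euler when D = 0.  Q is evaluated once at the start of the integration;
re-evaluation every N steps is available for sensitivity analysis.

Internally time is in milliseconds; the public API takes seconds (default
2 s duration at dt = 1/1200 s with a 0.3 s burn-in).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circuit_model import CircuitSpec, ParameterVector, PhysicalModel
from .exceptions import (DegenerateDelayError, InstabilityError, NumericalError,
                         StructuralError)

__all__ = ["DelayMatrix", "Trajectory", "build_delay_matrix", "delay_operator",
           "integrate", "jacobian", "resting_state"]

DEFAULT_DT = 1.0 / 1200.0  # s
DEFAULT_DURATION = 2.0  # s
DEFAULT_BURN_IN = 0.3  # s
VOLTAGE_GUARD = 200.0  # mV, divergence threshold

CORTICAL = ("SS", "SP", "SI", "DP", "DI", "TP")
THALAMIC = ("RT", "RL")


@dataclass
class DelayMatrix:
    """State-by-state conduction delays in ms.

    ``d_ct`` delays the influence of the thalamus-projecting cortical
    population (TP) on the thalamic populations; ``d_tc`` delays the influence
    of thalamic relay (RL) on cortical populations.  Within-area delays
    default to zero.
    """

    D: np.ndarray
    d_ct: float = 8.0
    d_tc: float = 3.0

    def __post_init__(self):
        if np.any(self.D < 0):
            raise StructuralError("delays must be non-negative")

    @property
    def total_loop_delay(self) -> float:
        return self.d_ct + self.d_tc


def _state_slice(spec: CircuitSpec, population: str) -> slice:
    i = spec.population_names.index(population)
    spp = spec.states_per_population
    return slice(i * spp, (i + 1) * spp)


def build_delay_matrix(spec: CircuitSpec, params: ParameterVector) -> DelayMatrix:
    """Delay matrix for the circuit at the given (log-scaled) delay coefficients."""
    D = np.zeros((spec.n_states, spec.n_states))
    if not spec.has_delays:
        return DelayMatrix(D, 0.0, 0.0)
    model = PhysicalModel(spec, params)
    d_ct, d_tc = model.delay_ct, model.delay_tc
    for tgt in THALAMIC:
        D[_state_slice(spec, tgt), _state_slice(spec, "TP")] = d_ct
    for tgt in CORTICAL:
        D[_state_slice(spec, tgt), _state_slice(spec, "RL")] = d_tc
    return DelayMatrix(D, d_ct, d_tc)


@dataclass
class Trajectory:
    """Post-burn-in state trajectory: times in s, states (n_states x n_times)."""

    times: np.ndarray
    states: np.ndarray
    dt: float
    burn_in: float
    duration: float
    labels: tuple = ()

    def voltages(self, spec: CircuitSpec) -> np.ndarray:
        spp = spec.states_per_population
        return self.states[::spp, :]


def jacobian(model_or_spec, params_or_state=None, state=None,
             rel_step: float = 1e-4):
    """Central finite-difference Jacobian of the equations of motion (1/ms).

    Accepts either ``jacobian(spec, params, state)`` or a prebuilt
    ``jacobian(model, state)``.
    """
    if isinstance(model_or_spec, PhysicalModel):
        model, y0 = model_or_spec, np.asarray(params_or_state, dtype=float)
    else:
        model = PhysicalModel(model_or_spec, params_or_state)
        y0 = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(y0)):
        raise NumericalError("non-finite state passed to jacobian")
    n = y0.size
    J = np.empty((n, n))
    for k in range(n):
        h = rel_step * max(1.0, abs(y0[k]))
        yp = y0.copy(); yp[k] += h
        ym = y0.copy(); ym[k] -= h
        try:
            col = (model.derivative(yp) - model.derivative(ym)) / (2 * h)
        except NumericalError as err:
            raise NumericalError(f"non-finite derivative at state index {k}") from err
        J[:, k] = col
    return J


def delay_operator(D, J) -> np.ndarray:
    """Delay operator Q = inv(I + D o J), with D in ms and J in 1/ms.

    First-order Taylor expansion of delayed influences: for
    ``dy_i/dt = f_i(y_j(t - D_ij))``, ``f(y(t-D)) ~ f(y) - (D o J) dy/dt``,
    so ``dy/dt = Q f(y)`` with ``Q = inv(I + D o J)`` for non-negative delays.
    """
    Dm = D.D if isinstance(D, DelayMatrix) else np.asarray(D, dtype=float)
    J = np.asarray(J, dtype=float)
    A = np.eye(J.shape[0]) + Dm * J
    try:
        return np.linalg.inv(A)
    except np.linalg.LinAlgError as err:
        raise DegenerateDelayError(
            "I - D*J is singular; reduce conduction delays or the time step"
        ) from err


def resting_state(model: PhysicalModel, tol: float = 1e-10,
                  max_iter: int = 500, with_input: bool = False) -> np.ndarray:
    """Deterministic resting state of the circuit (zero-input by default).

    Damped fixed-point iteration on the voltage balance: conductances are set
    to their drives at the current voltage, and each voltage moves to the
    conductance-weighted mean of the reversal potentials.  With
    ``with_input=True`` the constant drive current is included, giving the
    operating point about which the driven circuit oscillates.
    """
    n, spp = model.n, model.spp
    V = np.full(n, model.V_leak)
    u_over = (model.u if with_input else 0.0)
    for _ in range(max_iter):
        f = model.firing(V)
        drive = model.synaptic_drive(f)
        mg = 1.0 / (1.0 + 0.2 * np.exp(-model.mg_alpha * V))
        num = model.g_leak * model.V_leak + u_over
        den = np.full(n, model.g_leak)
        for ch, g in (("AMPA", drive["AMPA"]), ("GABA_A", drive["GABA_A"]),
                      ("GABA_B", drive["GABA_B"])):
            num = num + g * model.Vrev[ch]
            den = den + g
        gN = mg * drive["NMDA"]
        num = num + gN * model.Vrev["NMDA"]
        den = den + gN
        if model.has_mh:
            m_inf = model.m_gain / (1.0 + np.exp(-(V - model.spec.m_half) / model.spec.m_slope))
            h_inf = model.h_gain / (1.0 + np.exp((V - model.spec.h_half) / model.spec.h_slope))
            num = num + m_inf * model.Vrev["M"] + h_inf * model.Vrev["H"]
            den = den + m_inf + h_inf
        V_new = num / den
        # Damping keeps strongly recurrent circuits from oscillating in the map.
        V_next = 0.5 * (V + V_new)
        if np.max(np.abs(V_next - V)) < tol:
            V = V_next
            break
        V = V_next
    y = np.zeros(model.n_states).reshape(n, spp)
    y[:, 0] = V
    f = model.firing(V)
    drive = model.synaptic_drive(f)
    y[:, 1] = drive["AMPA"]
    y[:, 2] = drive["GABA_A"]
    y[:, 3] = drive["NMDA"]
    y[:, 4] = drive["GABA_B"]
    if model.has_mh:
        y[:, 5] = model.m_gain / (1.0 + np.exp(-(V - model.spec.m_half) / model.spec.m_slope))
        y[:, 6] = model.h_gain / (1.0 + np.exp((V - model.spec.h_half) / model.spec.h_slope))
    return y.reshape(-1)


def integrate(spec: CircuitSpec, params: ParameterVector,
              duration: float = DEFAULT_DURATION, dt: float = DEFAULT_DT,
              burn_in: float = DEFAULT_BURN_IN, initial_state=None,
              q_refresh_every: int = 0) -> Trajectory:
    """Integrate the circuit and return the post-burn-in trajectory.

    Starts at the deterministic resting state of the zero-input system, applies
    the constant direct-current input throughout, and advances with the
    delayed-Euler scheme.  Raises :class:`InstabilityError` if any membrane
    potential leaves +/-200 mV.
    """
    if not (duration > burn_in > 0):
        raise ValueError("require duration > burn_in > 0")
    if dt <= 0:
        raise ValueError("dt must be positive")
    model = PhysicalModel(spec, params)
    y = resting_state(model) if initial_state is None else \
        np.asarray(initial_state, dtype=float).copy()
    if y.shape != (spec.n_states,):
        raise StructuralError("initial state has wrong length")

    dt_ms = dt * 1000.0
    n_steps = int(round(duration / dt))
    n_keep = int(round((duration - burn_in) / dt))
    D = build_delay_matrix(spec, params)
    if np.any(D.D):
        # Linearise at the driven operating point: the zero-input rest is
        # silent (near-zero firing gradients), which would make Q trivial.
        y_op = resting_state(model, with_input=True)
        Q = delay_operator(D, jacobian(model, y_op))
        use_q = True
    else:
        Q = np.eye(spec.n_states)
        use_q = False

    out = np.empty((spec.n_states, n_keep))
    times = (np.arange(n_steps - n_keep + 1, n_steps + 1)) * dt

    if q_refresh_every:
        _integrate_python(model, y, n_steps, n_keep, dt_ms, D, Q if use_q else None,
                          q_refresh_every, out, params, dt)
    else:
        from ._kernel import integrate_loop

        kappa = np.array([model.kappa[ch] for ch in
                          ("AMPA", "NMDA", "GABA_A", "GABA_B", "M", "H")])
        vrev = np.array([model.Vrev[ch] for ch in
                         ("AMPA", "NMDA", "GABA_A", "GABA_B", "M", "H")])
        status = integrate_loop(
            y, n_steps, n_keep, dt_ms, Q, use_q,
            model.G_ampa, model.G_nmda, model.G_gaba, model.gaba_b_ratio,
            kappa, vrev, model.C, model.sqrt_disp, model.threshold,
            model.mg_alpha, model.u, model.g_leak, model.V_leak,
            np.asarray(model.m_gain, dtype=float),
            np.asarray(model.h_gain, dtype=float),
            spec.m_half, spec.m_slope, spec.h_half, spec.h_slope,
            model.has_mh, model.spp, model.n, VOLTAGE_GUARD, out)
        if status:
            raise InstabilityError(
                f"integration diverged at t = {status * dt:.4f} s", params=params)
    if not np.all(np.isfinite(out)):
        raise InstabilityError("integration produced non-finite states",
                               params=params)
    return Trajectory(times=times, states=out, dt=dt, burn_in=burn_in,
                      duration=duration, labels=tuple(spec.state_labels()))


def _integrate_python(model, y, n_steps, n_keep, dt_ms, D, Q, q_refresh_every,
                      out, params, dt):
    """Reference loop, used when Q is periodically re-evaluated."""
    vidx = model.voltage_indices
    k = 0
    for i in range(n_steps):
        f = model.derivative(y)
        if Q is not None:
            if q_refresh_every and i and i % q_refresh_every == 0:
                Q = delay_operator(D, jacobian(model, y))
            y = y + dt_ms * (Q @ f)
        else:
            y = y + dt_ms * f
        if np.max(np.abs(y[vidx])) > VOLTAGE_GUARD or not np.all(np.isfinite(y)):
            raise InstabilityError(
                f"integration diverged at t = {(i + 1) * dt:.4f} s", params=params)
        if i >= n_steps - n_keep:
            out[:, k] = y
            k += 1
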