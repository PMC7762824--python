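"""Conductance-based thalamo-cortical (TCM) and canonical cortical (CMC) circuits.

The TCM couples six cortical populations (layer 4 spiny stellates SS, layer 2/3
pyramidal SP and interneurons SI, layer 5 pyramidal DP and interneurons DI,
layer 6 thalamic-projection pyramidal TP) with two thalamic populations
(reticular RT and relay RL).  Each population obeys a Morris–Lecar-lineage
mean-field voltage equation

    C dV/dt = sum_n g_n (V_n - V) + g_L (V_L - V) + u

with first-order receptor kinetics for AMPA, NMDA, GABA_A, GABA_B and, on TP
and RL only, M- and H-currents:

    dg_n/dt = kappa_n (varsigma_n - g_n)

Synaptic drives are ``varsigma_i = sum_j gamma[i, j] * firing(j)`` where the firing of a source
population is the Gaussian CDF of its mean depolarisation about a fixed
threshold of -40 mV, and NMDA currents are gated by a sigmoidal magnesium
switch ``1 / (1 + 0.2 exp(-alpha V))``.

The CMC comparator keeps the four cortical populations SS, SP, SI, DP with
AMPA/NMDA/GABA_A/GABA_B channels and no M/H currents.

All free parameters are log-scaling coefficients on prior means
(value = mean * exp(theta)), so positivity is structural and theta = 0 is the
prior mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Tuple

import numpy as np
from scipy.special import ndtr

from .exceptions import InvalidParameterError, NumericalError, StructuralError

__all__ = [
    "CHANNEL_ORDER",
    "ChannelKinetics",
    "CircuitSpec",
    "ConnectivitySet",
    "FiringFunction",
    "ParameterVector",
    "PhysicalModel",
    "PopulationSpec",
    "build_cmc",
    "build_tcm",
    "conductance_drive",
    "firing_rate",
    "mg_switch",
    "state_derivative",
]

# Canonical channel ordering for the kappa parameter vector.
CHANNEL_ORDER: Tuple[str, ...] = ("AMPA", "NMDA", "GABA_A", "GABA_B", "M", "H")

# State layout within each population (M/H states exist only in the TCM).
STATE_CHANNELS_TCM: Tuple[str, ...] = ("AMPA", "GABA_A", "NMDA", "GABA_B", "M", "H")
STATE_CHANNELS_CMC: Tuple[str, ...] = ("AMPA", "GABA_A", "NMDA", "GABA_B")

POPULATIONS_TCM: Tuple[str, ...] = ("SS", "SP", "SI", "DP", "DI", "TP", "RT", "RL")
POPULATIONS_CMC: Tuple[str, ...] = ("SS", "SP", "SI", "DP")

_LAYERS = {
    "SS": "L4 spiny stellate",
    "SP": "L2/3 pyramidal",
    "SI": "L2/3 interneuron",
    "DP": "L5 pyramidal",
    "DI": "L5 interneuron",
    "TP": "L6 thalamic-projection pyramidal",
    "RT": "thalamic reticular",
    "RL": "thalamic relay",
}
_EXCITATORY = {"SS": True, "SP": True, "SI": False, "DP": True,
               "DI": False, "TP": True, "RT": False, "RL": True}

# Firing threshold, fixed (not a fitted parameter).
V_R: float = -40.0


@dataclass(frozen=True)
class PopulationSpec:
    """One neuronal population: identity, channel complement, capacitance prior."""

    name: str
    layer_label: str
    is_excitatory: bool
    channels: frozenset
    capacitance: float  # prior mean, conductance * ms units (tau_m = C / g_L)


@dataclass(frozen=True)
class ChannelKinetics:
    """Receptor/channel kinetics: reversal potential and decay rate prior."""

    kind: str
    reversal_potential: float  # mV
    rate_constant: float  # 1/ms, prior mean of kappa_n
    is_parameterised: bool = True

    def __post_init__(self):
        if self.rate_constant <= 0:
            raise InvalidParameterError(f"kappa must be > 0 for {self.kind}")


# Moran-lineage defaults; all overridable through CircuitSpec replacement.
DEFAULT_KINETICS: Dict[str, ChannelKinetics] = {
    "AMPA": ChannelKinetics("AMPA", 60.0, 1.0 / 2.2),
    "NMDA": ChannelKinetics("NMDA", 60.0, 1.0 / 100.0),
    "GABA_A": ChannelKinetics("GABA_A", -90.0, 1.0 / 5.0),
    "GABA_B": ChannelKinetics("GABA_B", -100.0, 1.0 / 300.0),
    "M": ChannelKinetics("M", -70.0, 1.0 / 160.0),
    "H": ChannelKinetics("H", -30.0, 1.0 / 100.0),
}

# Default intrinsic pathway lists (target, source).  The AMPA mask carries 13
# excitatory pathways, NMDA the same plus SP and DP recurrent self-gains, and
# the inhibitory GABA_A mask carries interneuron/reticular projections plus
# self-gain diagonals.  Together: 41 free connectivity parameters.
AMPA_EDGES_TCM: Tuple[Tuple[str, str], ...] = (
    ("SP", "SS"), ("SI", "SS"), ("SI", "SP"), ("DP", "SP"), ("SS", "SP"),
    ("DI", "DP"), ("TP", "DP"), ("SS", "TP"), ("RT", "TP"), ("RL", "TP"),
    ("SS", "RL"), ("SI", "RL"), ("RT", "RL"),
)
NMDA_EXTRA_EDGES_TCM: Tuple[Tuple[str, str], ...] = (("SP", "SP"), ("DP", "DP"))
GABA_A_EDGES_TCM: Tuple[Tuple[str, str], ...] = (
    ("SP", "SI"), ("SS", "SI"), ("SI", "SI"), ("DP", "DI"), ("TP", "DI"),
    ("DI", "DI"), ("RL", "RT"), ("RT", "RT"), ("SS", "SS"), ("SP", "SP"),
    ("DP", "DP"), ("TP", "TP"), ("RL", "RL"),
)


def _edges_to_mask(edges, populations):
    n = len(populations)
    idx = {p: i for i, p in enumerate(populations)}
    mask = np.zeros((n, n), dtype=bool)
    for tgt, src in edges:
        if tgt in idx and src in idx:
            mask[idx[tgt], idx[src]] = True
    return mask


@dataclass(frozen=True)
class ConnectivitySet:
    """Sparse intrinsic connectivity: boolean masks plus prior-mean weights.

    Masks are target-by-source.  GABA_B shares the GABA_A mask and weights
    (scaled by ``gaba_b_ratio`` on the physical scale); its prior means are
    therefore not separately parameterised.
    """

    populations: Tuple[str, ...]
    ampa_mask: np.ndarray
    nmda_mask: np.ndarray
    gaba_mask: np.ndarray
    gamma: Dict[str, np.ndarray]  # channel -> prior-mean weight matrix
    gaba_b_ratio: float = 1.0

    def __post_init__(self):
        n = len(self.populations)
        for name in ("ampa_mask", "nmda_mask", "gaba_mask"):
            m = getattr(self, name)
            if m.shape != (n, n):
                raise StructuralError(f"{name} must be {n}x{n}, got {m.shape}")
        for ch, w in self.gamma.items():
            if w.shape != (n, n):
                raise StructuralError(f"gamma[{ch}] must be {n}x{n}")

    @property
    def free_edges(self) -> List[Tuple[str, str, str]]:
        """Ordered (channel, target, source) triples of free weights."""
        out = []
        for ch, mask in (("AMPA", self.ampa_mask), ("NMDA", self.nmda_mask),
                         ("GABA_A", self.gaba_mask)):
            for i, j in zip(*np.nonzero(mask)):
                out.append((ch, self.populations[i], self.populations[j]))
        return out

    @property
    def n_free(self) -> int:
        return int(self.ampa_mask.sum() + self.nmda_mask.sum() + self.gaba_mask.sum())


@dataclass(frozen=True)
class FiringFunction:
    """Gaussian-CDF firing nonlinearity: fixed threshold, per-population dispersion."""

    threshold: float = V_R
    dispersion: np.ndarray = field(default_factory=lambda: np.full(8, 32.0))

    def __post_init__(self):
        if np.any(np.asarray(self.dispersion) <= 0):
            raise InvalidParameterError("firing dispersion must be positive")


@dataclass(frozen=True)
class CircuitSpec:
    """Full structural description of one model variant."""

    variant: str  # "TCM" or "CMC"
    populations: Tuple[PopulationSpec, ...]
    channels: Dict[str, ChannelKinetics]
    connectivity: ConnectivitySet
    firing: FiringFunction
    mg_alpha: float = 0.06  # 1/mV, NMDA magnesium-switch steepness
    input_gain: float = 80.0  # prior mean of the direct-current drive
    input_population: str = "RL"
    leak_conductance: float = 1.0
    leak_reversal: float = -70.0
    # M/H steady-state gating (TP/RL only): logistic in V.
    m_half: float = -35.0
    m_slope: float = 10.0
    m_gain: float = 1.0
    h_half: float = -75.0
    h_slope: float = 5.5
    h_gain: float = 1.0
    obs_scale: float = 1.0  # prior mean of the observation amplitude scale
    delay_ct: float = 8.0  # ms, cortex -> thalamus prior mean
    delay_tc: float = 3.0  # ms, thalamus -> cortex prior mean
    prior_variance: float = 1.0 / 16.0  # variance of each log-scaling coefficient

    @property
    def population_names(self) -> Tuple[str, ...]:
        return tuple(p.name for p in self.populations)

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    @property
    def state_channels(self) -> Tuple[str, ...]:
        return STATE_CHANNELS_TCM if self.variant == "TCM" else STATE_CHANNELS_CMC

    @property
    def states_per_population(self) -> int:
        return 1 + len(self.state_channels)

    @property
    def n_states(self) -> int:
        return self.n_populations * self.states_per_population

    @property
    def has_delays(self) -> bool:
        return self.variant == "TCM"

    def voltage_index(self, population: str) -> int:
        return self.population_names.index(population) * self.states_per_population

    def state_labels(self) -> List[str]:
        labels = []
        for p in self.population_names:
            labels.append(f"{p}:V")
            labels.extend(f"{p}:g_{ch}" for ch in self.state_channels)
        return labels


# ---------------------------------------------------------------------------
# Parameter vector


@dataclass
class ParameterVector:
    """Named log-scaling coefficients over the free parameters of one circuit.

    Coefficient 0 means the prior mean; physical value = mean * exp(theta).
    """

    names: Tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.names),):
            raise StructuralError("coefficient vector length mismatch")

    @classmethod
    def zeros(cls, spec: CircuitSpec) -> "ParameterVector":
        return cls(tuple(parameter_names(spec)), np.zeros(len(parameter_names(spec))))

    def copy(self) -> "ParameterVector":
        return ParameterVector(self.names, self.values.copy())

    def index(self, name: str) -> int:
        return self.names.index(name)

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.index(name)])

    def __setitem__(self, name: str, value: float) -> None:
        self.values[self.index(name)] = value

    def updated(self, shifts: Dict[str, float]) -> "ParameterVector":
        out = self.copy()
        for k, v in shifts.items():
            out[k] = out[k] + v
        return out

    def to_dict(self) -> Dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


def gamma_name(channel: str, target: str, source: str) -> str:
    return f"gamma:{channel}:{source}->{target}"


def parameter_names(spec: CircuitSpec) -> List[str]:
    """Canonical coefficient ordering for one circuit."""
    names = [gamma_name(ch, t, s) for ch, t, s in spec.connectivity.free_edges]
    names += [f"kappa:{ch}" for ch in CHANNEL_ORDER]
    names += [f"C:{p}" for p in spec.population_names]
    names += [f"sigma:{p}" for p in spec.population_names]
    if spec.has_delays:
        names += ["delay:CT", "delay:TC"]
    names += ["input_gain", "obs_scale"]
    return names


# ---------------------------------------------------------------------------
# Elementary operations


def firing_rate(mean_potential, firing: FiringFunction, population_index: int):
    """Expected proportion of cells firing: Gaussian CDF of V about threshold."""
    disp = np.asarray(firing.dispersion, dtype=float)[population_index]
    if np.any(disp <= 0):
        raise InvalidParameterError("firing dispersion must be positive")
    return ndtr((np.asarray(mean_potential, dtype=float) - firing.threshold)
                / np.sqrt(disp))


def mg_switch(V, alpha: float):
    """NMDA magnesium-block voltage switch, 1 / (1 + 0.2 exp(-alpha V))."""
    if alpha <= 0:
        raise InvalidParameterError("mg_switch steepness alpha must be > 0")
    return 1.0 / (1.0 + 0.2 * np.exp(-alpha * np.asarray(V, dtype=float)))


# ---------------------------------------------------------------------------
# Physical (compiled) model: prior means scaled by exp(coefficients)


class PhysicalModel:
    """Circuit with coefficients applied; evaluates the equations of motion fast.

    Precomputes dense weight matrices and channel constants so that
    ``derivative`` costs a handful of vector operations — this is the inner
    loop of the numerical integrator and of every model fit.
    """

    def __init__(self, spec: CircuitSpec, params: ParameterVector):
        if tuple(params.names) != tuple(parameter_names(spec)):
            raise StructuralError("parameter vector does not match circuit spec")
        self.spec = spec
        self.params = params
        n = spec.n_populations
        self.n = n
        self.spp = spec.states_per_population
        self.n_states = spec.n_states
        self.has_mh = "M" in spec.state_channels

        conn = spec.connectivity
        theta = dict(zip(params.names, params.values))

        def weight_matrix(channel, mask):
            W = np.zeros((n, n))
            prior = conn.gamma[channel]
            for i, j in zip(*np.nonzero(mask)):
                name = gamma_name(channel, conn.populations[i], conn.populations[j])
                W[i, j] = prior[i, j] * np.exp(theta[name])
            return W

        self.G_ampa = weight_matrix("AMPA", conn.ampa_mask)
        self.G_nmda = weight_matrix("NMDA", conn.nmda_mask)
        self.G_gaba = weight_matrix("GABA_A", conn.gaba_mask)
        self.gaba_b_ratio = conn.gaba_b_ratio

        self.kappa = {ch: spec.channels[ch].rate_constant * np.exp(theta[f"kappa:{ch}"])
                      for ch in CHANNEL_ORDER}
        self.Vrev = {ch: spec.channels[ch].reversal_potential for ch in CHANNEL_ORDER}
        self.C = np.array([p.capacitance for p in spec.populations]) * np.exp(
            np.array([theta[f"C:{p}"] for p in spec.population_names]))
        disp = np.asarray(spec.firing.dispersion, dtype=float) * np.exp(
            np.array([theta[f"sigma:{p}"] for p in spec.population_names]))
        if np.any(disp <= 0):
            raise InvalidParameterError("firing dispersion must be positive")
        self.sqrt_disp = np.sqrt(disp)
        self.threshold = spec.firing.threshold
        self.mg_alpha = spec.mg_alpha

        self.u = np.zeros(n)
        self.u[spec.population_names.index(spec.input_population)] = (
            spec.input_gain * np.exp(theta["input_gain"]))
        self.g_leak = spec.leak_conductance
        self.V_leak = spec.leak_reversal
        self.obs_scale = spec.obs_scale * np.exp(theta["obs_scale"])
        if spec.has_delays:
            self.delay_ct = spec.delay_ct * np.exp(theta["delay:CT"])
            self.delay_tc = spec.delay_tc * np.exp(theta["delay:TC"])
        else:
            self.delay_ct = self.delay_tc = 0.0

        # M/H gains restricted to populations carrying those channels.
        mh = np.array([("M" in p.channels) for p in spec.populations], dtype=float)
        self.m_gain = spec.m_gain * mh
        self.h_gain = spec.h_gain * mh

    def firing(self, V: np.ndarray) -> np.ndarray:
        return ndtr((V - self.threshold) / self.sqrt_disp)

    def synaptic_drive(self, f: np.ndarray) -> Dict[str, np.ndarray]:
        sg = self.G_gaba @ f
        return {"AMPA": self.G_ampa @ f, "NMDA": self.G_nmda @ f,
                "GABA_A": sg, "GABA_B": self.gaba_b_ratio * sg}

    def derivative(self, y: np.ndarray, t: float = 0.0,
                   with_input: bool = True) -> np.ndarray:
        if y.shape != (self.n_states,):
            raise StructuralError(
                f"state vector must have length {self.n_states}, got {y.shape}")
        Y = y.reshape(self.n, self.spp)
        V = Y[:, 0]
        gA, gGa, gN, gGb = Y[:, 1], Y[:, 2], Y[:, 3], Y[:, 4]
        f = self.firing(V)
        drive = self.synaptic_drive(f)
        mg = 1.0 / (1.0 + 0.2 * np.exp(-self.mg_alpha * V))

        current = (self.g_leak * (self.V_leak - V)
                   + gA * (self.Vrev["AMPA"] - V)
                   + gGa * (self.Vrev["GABA_A"] - V)
                   + mg * gN * (self.Vrev["NMDA"] - V)
                   + gGb * (self.Vrev["GABA_B"] - V))
        dY = np.empty_like(Y)
        dY[:, 1] = self.kappa["AMPA"] * (drive["AMPA"] - gA)
        dY[:, 2] = self.kappa["GABA_A"] * (drive["GABA_A"] - gGa)
        dY[:, 3] = self.kappa["NMDA"] * (drive["NMDA"] - gN)
        dY[:, 4] = self.kappa["GABA_B"] * (drive["GABA_B"] - gGb)
        if self.has_mh:
            gM, gH = Y[:, 5], Y[:, 6]
            m_inf = self.m_gain / (1.0 + np.exp(-(V - self.spec.m_half) / self.spec.m_slope))
            h_inf = self.h_gain / (1.0 + np.exp((V - self.spec.h_half) / self.spec.h_slope))
            dY[:, 5] = self.kappa["M"] * (m_inf - gM)
            dY[:, 6] = self.kappa["H"] * (h_inf - gH)
            current = current + gM * (self.Vrev["M"] - V) + gH * (self.Vrev["H"] - V)
        if with_input:
            current = current + self.u
        dY[:, 0] = current / self.C
        if not np.all(np.isfinite(dY)):
            raise NumericalError("non-finite state derivative")
        return dY.reshape(-1)

    @property
    def voltage_indices(self) -> np.ndarray:
        return np.arange(self.n) * self.spp


def conductance_drive(spec: CircuitSpec, params: ParameterVector,
                      firing_vector: np.ndarray) -> Dict[str, np.ndarray]:
    """Per-channel synaptic drive: masked gamma weights times source firing."""
    firing_vector = np.asarray(firing_vector, dtype=float)
    if firing_vector.shape != (spec.n_populations,):
        raise StructuralError(
            f"firing vector must have length {spec.n_populations}")
    return PhysicalModel(spec, params).synaptic_drive(firing_vector)


def state_derivative(spec: CircuitSpec, params: ParameterVector,
                     state: np.ndarray, t: float = 0.0) -> np.ndarray:
    """Equations of motion; convenience wrapper compiling the model each call.

    For repeated evaluation (integration, Jacobians) build a
    :class:`PhysicalModel` once and call its ``derivative`` method.
    """
    state = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(state)):
        raise NumericalError("non-finite state vector")
    return PhysicalModel(spec, params).derivative(state, t)


# ---------------------------------------------------------------------------
# Builders


def _make_populations(names, with_mh, capacitance=8.0):
    pops = []
    for name in names:
        channels = {"AMPA", "NMDA", "GABA_A", "GABA_B"}
        if with_mh and name in ("TP", "RL"):
            channels |= {"M", "H"}
        pops.append(PopulationSpec(name, _LAYERS[name], _EXCITATORY[name],
                                   frozenset(channels), capacitance))
    return tuple(pops)


# Default coupling strengths.  Between-population weights per channel, with
# self-gain diagonals kept at a separate (unit) weight so that large multiplicative
# modulations of recurrent gains stay in a graded, non-saturating regime.
DEFAULT_WEIGHTS = {"AMPA": 1.5, "NMDA": 0.5, "GABA_A": 1.5}
DEFAULT_SELF_GAIN = 0.5
DEFAULT_GABA_B_RATIO = 0.3


def _default_connectivity(populations: Tuple[str, ...],
                          weights=None, gaba_b_ratio=None,
                          self_gain=None) -> ConnectivitySet:
    ampa = _edges_to_mask(AMPA_EDGES_TCM, populations)
    nmda = _edges_to_mask(AMPA_EDGES_TCM + NMDA_EXTRA_EDGES_TCM, populations)
    gaba = _edges_to_mask(GABA_A_EDGES_TCM, populations)
    w = dict(DEFAULT_WEIGHTS, **(weights or {}))
    sg = DEFAULT_SELF_GAIN if self_gain is None else self_gain
    gamma = {"AMPA": np.where(ampa, w["AMPA"], 0.0),
             "NMDA": np.where(nmda, w["NMDA"], 0.0),
             "GABA_A": np.where(gaba, w["GABA_A"], 0.0)}
    for ch in ("NMDA", "GABA_A"):
        diag = np.diag(gamma[ch]) != 0
        np.fill_diagonal(gamma[ch], np.where(diag, sg, 0.0))
    ratio = DEFAULT_GABA_B_RATIO if gaba_b_ratio is None else gaba_b_ratio
    return ConnectivitySet(populations, ampa, nmda, gaba, gamma,
                           gaba_b_ratio=ratio)


def build_tcm(weights=None, gaba_b_ratio=None, self_gain=None,
              **overrides) -> CircuitSpec:
    """Default 8-population thalamo-cortical circuit (56 states, 41 free weights)."""
    spec = CircuitSpec(
        variant="TCM",
        populations=_make_populations(POPULATIONS_TCM, with_mh=True),
        channels=dict(DEFAULT_KINETICS),
        connectivity=_default_connectivity(POPULATIONS_TCM, weights,
                                           gaba_b_ratio, self_gain),
        firing=FiringFunction(dispersion=np.full(len(POPULATIONS_TCM), 32.0)),
        input_population="RL",
    )
    return replace(spec, **overrides) if overrides else spec


def build_cmc(weights=None, gaba_b_ratio=None, self_gain=None,
              **overrides) -> CircuitSpec:
    """Default 4-population cortical comparator (20 states, no M/H channels)."""
    spec = CircuitSpec(
        variant="CMC",
        populations=_make_populations(POPULATIONS_CMC, with_mh=False),
        channels=dict(DEFAULT_KINETICS),
        connectivity=_default_connectivity(POPULATIONS_CMC, weights,
                                           gaba_b_ratio, self_gain),
        firing=FiringFunction(dispersion=np.full(len(POPULATIONS_CMC), 32.0)),
        input_population="SS",
    )
    return replace(spec, **overrides) if overrides else spec
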