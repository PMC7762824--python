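"""Observation model: trajectories -> amplitude spectra via dynamic mode decomposition.

Each contributing population (SS, SP, DP and, for the TCM, TP) can express
several overlapping rhythms.  Exact DMD factors the multichannel voltage
record into spatial modes with complex eigenvalues; the spectrum is then an
energy-weighted combination of the amplitude spectra of the mode time series,
smoothed with a narrow Gaussian kernel and sampled on the 4-80 Hz grid that
the fitted data live on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .circuit_model import CircuitSpec, ParameterVector, PhysicalModel
from .exceptions import StructuralError
from . import integrator as _integrator

__all__ = ["DmdResult", "Spectrum", "contributing_states", "dmd",
           "default_frequency_grid", "mode_spectrum", "predict_spectrum"]

CONTRIBUTING = {"TCM": ("SS", "SP", "DP", "TP"), "CMC": ("SS", "SP", "DP")}


def default_frequency_grid() -> np.ndarray:
    """4-80 Hz inclusive at 1 Hz steps."""
    return np.arange(4.0, 81.0, 1.0)


@dataclass
class Spectrum:
    """Amplitude spectrum on a fixed frequency grid (the data/model currency)."""

    frequencies: np.ndarray
    amplitudes: np.ndarray
    meta: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.frequencies.shape != self.amplitudes.shape:
            raise StructuralError("frequency and amplitude grids differ in length")
        if np.any(np.diff(self.frequencies) <= 0):
            raise StructuralError("frequency grid must be strictly increasing")
        if np.any(self.amplitudes < 0):
            raise StructuralError("amplitudes must be non-negative")


@dataclass
class DmdResult:
    """Exact-DMD factorisation of a multichannel record."""

    modes: np.ndarray  # channels x rank, complex
    eigenvalues: np.ndarray  # rank, complex (discrete-time)
    mode_timeseries: np.ndarray  # rank x time, complex
    rank: int


def contributing_states(spec: CircuitSpec) -> List[int]:
    """Voltage-state indices of the populations feeding the observation model."""
    return [spec.voltage_index(p) for p in CONTRIBUTING[spec.variant]]


def dmd(X: np.ndarray, rank: Optional[int] = None) -> DmdResult:
    """Exact dynamic mode decomposition of ``X`` (channels x time).

    Fits the best rank-``rank`` linear propagator between the time-shifted
    snapshot matrices and returns its modes, discrete-time eigenvalues and the
    projected mode time series.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1 or X.shape[1] < 2:
        raise StructuralError("DMD needs a channels x time matrix with >= 2 samples")
    X1, X2 = X[:, :-1], X[:, 1:]
    U, s, Vh = np.linalg.svd(X1, full_matrices=False)
    data_rank = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 0
    if rank is None:
        rank = min(X.shape[0], X.shape[1] - 1)
    if rank > data_rank:
        warnings.warn(f"requested DMD rank {rank} exceeds data rank {data_rank}; "
                      "truncating", stacklevel=2)
        rank = max(data_rank, 1)
    U, s, Vh = U[:, :rank], s[:rank], Vh[:rank]
    Atilde = U.conj().T @ X2 @ Vh.conj().T / s
    eigvals, W = np.linalg.eig(Atilde)
    # Exact DMD modes live in the range of X2.
    modes = (X2 @ Vh.conj().T / s) @ W
    B = np.linalg.pinv(modes) @ X
    return DmdResult(modes=modes, eigenvalues=eigvals, mode_timeseries=B,
                     rank=rank)


def mode_spectrum(dmd_result: DmdResult, dt: float,
                  frequencies: Optional[np.ndarray] = None,
                  smoothing: float = 2.0,
                  leading_only: bool = False,
                  meta: Optional[Dict[str, str]] = None) -> Spectrum:
    """Smoothed amplitude spectrum of the DMD mode time series.

    Per-mode amplitude spectra (magnitude FFT of the real part of each mode
    series) are combined with energy weights, smoothed by a Gaussian kernel of
    ``smoothing`` frequency bins, and interpolated onto ``frequencies``.
    """
    B = np.asarray(dmd_result.mode_timeseries)
    if B.size == 0:
        raise StructuralError("empty mode time series")
    if frequencies is None:
        frequencies = default_frequency_grid()
    frequencies = np.asarray(frequencies, dtype=float)
    n = B.shape[1]
    native = np.fft.rfftfreq(n, dt)
    nyquist = 0.5 / dt
    if frequencies[0] < 0 or frequencies[-1] > nyquist:
        raise StructuralError(
            f"frequency grid [{frequencies[0]}, {frequencies[-1]}] outside "
            f"the Nyquist range [0, {nyquist:.1f}] Hz")
    series = np.real(B)
    amps = np.abs(np.fft.rfft(series, axis=1)) / n
    energy = np.sum(np.abs(B) ** 2, axis=1)
    if leading_only:
        weights = np.zeros_like(energy)
        weights[np.argmax(energy)] = 1.0
    else:
        total = energy.sum()
        weights = energy / total if total > 0 else np.full(energy.size, 1.0 / energy.size)
    combined = weights @ amps
    if smoothing > 0:
        combined = gaussian_filter1d(combined, smoothing, mode="nearest")
    out = np.interp(frequencies, native, combined)
    return Spectrum(frequencies, np.maximum(out, 0.0), meta=dict(meta or {}))


def predict_spectrum(spec: CircuitSpec, params: ParameterVector,
                     frequencies: Optional[np.ndarray] = None,
                     duration: float = _integrator.DEFAULT_DURATION,
                     dt: float = _integrator.DEFAULT_DT,
                     burn_in: float = _integrator.DEFAULT_BURN_IN,
                     smoothing: float = 2.0,
                     leading_only: bool = False) -> Spectrum:
    """Forward prediction: integrate, DMD the contributing voltages, transform.

    Deterministic; the observation-scale coefficient multiplies the amplitude.
    """
    traj = _integrator.integrate(spec, params, duration=duration, dt=dt,
                                 burn_in=burn_in)
    X = traj.states[contributing_states(spec), :]
    X = X - X.mean(axis=1, keepdims=True)
    result = dmd(X, rank=X.shape[0])
    spectrum = mode_spectrum(result, dt, frequencies=frequencies,
                             smoothing=smoothing, leading_only=leading_only)
    scale = PhysicalModel(spec, params).obs_scale
    return Spectrum(spectrum.frequencies, scale * spectrum.amplitudes,
                    meta=spectrum.meta)
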