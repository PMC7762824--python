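"""Bayesian model selection over fitted circuits.

Fixed-effects (FFX) selection treats the model identity as shared across
datasets: the group posterior is the softmax of summed free energies.
Random-effects (RFX) selection treats it as a dataset-level random variable
with Dirichlet-distributed population frequencies, estimated by the standard
variational scheme; exceedance probabilities are Monte-Carlo estimates of the
probability that each model is the most frequent, and the Bayesian omnibus
risk (BOR) is the posterior probability of the equal-frequencies null, used to
"protect" the exceedance probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np
from scipy.special import digamma, gammaln
from scipy.stats import pearsonr

from .exceptions import StructuralError, TcmodelError
from .observer import Spectrum

__all__ = ["EvidenceTable", "BmsResult", "ffx_bms", "rfx_bms",
           "per_frequency_correlation"]


@dataclass
class EvidenceTable:
    """Free energies (nats) for each dataset under each candidate model."""

    F: np.ndarray  # datasets x models
    model_names: Tuple[str, ...]
    dataset_ids: Tuple[str, ...] = ()

    def __post_init__(self):
        self.F = np.asarray(self.F, dtype=float)
        if self.F.ndim != 2 or self.F.shape[1] < 2:
            raise StructuralError("evidence table needs >= 2 models")
        if len(self.model_names) != self.F.shape[1]:
            raise StructuralError("model name count mismatch")
        if not np.all(np.isfinite(self.F)):
            raise StructuralError("evidence table must be finite")
        if not self.dataset_ids:
            self.dataset_ids = tuple(f"dataset{i}" for i in range(self.F.shape[0]))


@dataclass
class BmsResult:
    ffx_posterior: np.ndarray
    rfx_expected_frequency: np.ndarray
    exceedance: np.ndarray
    protected_exceedance: np.ndarray
    bor: float
    alpha: np.ndarray = field(default_factory=lambda: np.zeros(0))
    model_names: Tuple[str, ...] = ()

    def to_dict(self) -> Dict:
        return {"model_names": list(self.model_names),
                "ffx_posterior": self.ffx_posterior.tolist(),
                "rfx_expected_frequency": self.rfx_expected_frequency.tolist(),
                "exceedance": self.exceedance.tolist(),
                "protected_exceedance": self.protected_exceedance.tolist(),
                "bor": float(self.bor),
                "alpha": self.alpha.tolist()}


def _softmax(x: np.ndarray) -> np.ndarray:
    z = x - np.max(x)
    e = np.exp(z)
    return e / e.sum()


def ffx_bms(evidence: EvidenceTable) -> np.ndarray:
    """Fixed-effects posterior: softmax of per-model summed free energy."""
    return _softmax(evidence.F.sum(axis=0))


def _rfx_variational(F: np.ndarray, alpha0: float, max_iter: int = 10000,
                     tol: float = 1e-10):
    """Variational Dirichlet-multinomial estimation of model frequencies."""
    n, k = F.shape
    alpha = np.full(k, alpha0)
    logu_base = F - F.max(axis=1, keepdims=True)
    for it in range(max_iter):
        w = logu_base + (digamma(alpha) - digamma(alpha.sum()))
        g = np.exp(w - w.max(axis=1, keepdims=True))
        g /= g.sum(axis=1, keepdims=True)
        alpha_new = alpha0 + g.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            return alpha_new, g
        alpha = alpha_new
    raise TcmodelError("RFX variational loop failed to converge")


def _rfx_elbo(F: np.ndarray, alpha: np.ndarray, g: np.ndarray,
              alpha0: float) -> float:
    """Evidence lower bound of the RFX (H1) model."""
    k = F.shape[1]
    a0 = np.full(k, alpha0)
    psi = digamma(alpha) - digamma(alpha.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        entropy = -np.sum(np.where(g > 0, g * np.log(g), 0.0))
    e_like = float(np.sum(g * (F + psi))) + entropy
    dir_term = (gammaln(a0.sum()) - gammaln(a0).sum()
                - gammaln(alpha.sum()) + gammaln(alpha).sum()
                + float((a0 - alpha) @ psi))
    return e_like + dir_term


def _null_evidence(F: np.ndarray) -> float:
    """Log evidence of the equal-frequencies null: r fixed at uniform."""
    n, k = F.shape
    mx = F.max(axis=1)
    return float(np.sum(mx + np.log(np.mean(np.exp(F - mx[:, None]), axis=1))))


def rfx_bms(evidence: EvidenceTable, seed: int = 0, alpha0: float = 1.0,
            n_samples: int = 1_000_000) -> BmsResult:
    """Random-effects BMS with exceedance, protected exceedance and BOR."""
    F = evidence.F
    if F.shape[0] < 2:
        raise StructuralError("RFX BMS needs >= 2 datasets")
    alpha, g = _rfx_variational(F, alpha0)
    expected = alpha / alpha.sum()
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_samples)
    winners = np.argmax(draws, axis=1)
    exceedance = np.bincount(winners, minlength=F.shape[1]) / n_samples
    f1 = _rfx_elbo(F, alpha, g, alpha0)
    f0 = _null_evidence(F)
    bor = float(1.0 / (1.0 + np.exp(f1 - f0)))
    k = F.shape[1]
    protected = exceedance * (1.0 - bor) + bor / k
    return BmsResult(ffx_posterior=ffx_bms(evidence),
                     rfx_expected_frequency=expected,
                     exceedance=exceedance,
                     protected_exceedance=protected,
                     bor=bor, alpha=alpha,
                     model_names=tuple(evidence.model_names))


def per_frequency_correlation(real: Sequence[Spectrum],
                              predicted: Sequence[Spectrum]):
    """Across-dataset correlation of observed vs predicted amplitude per frequency.

    Returns (frequencies, r, p).  Frequencies where either side has zero
    variance across datasets get NaN with a warning-free flag (r = nan).
    """
    if len(real) != len(predicted):
        raise StructuralError("real and predicted lists must be paired")
    if len(real) < 3:
        raise StructuralError("need at least 3 dataset pairs")
    grid = real[0].frequencies
    for s in list(real) + list(predicted):
        if not np.allclose(s.frequencies, grid):
            raise StructuralError("all spectra must share a frequency grid")
    R = np.array([s.amplitudes for s in real])
    P = np.array([s.amplitudes for s in predicted])
    n_freq = grid.size
    r = np.full(n_freq, np.nan)
    p = np.full(n_freq, np.nan)
    for i in range(n_freq):
        if np.std(R[:, i]) == 0 or np.std(P[:, i]) == 0:
            continue  # undefined correlation flagged as NaN
        r[i], p[i] = pearsonr(R[:, i], P[:, i])
    return grid, r, p
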