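"""Synthetic study-shaped data: a drug-vs-placebo spectral group design.

Emulates the study layout the toolkit targets: 16 subjects measured in two
conditions (placebo, ketamine), 32 spectra in all.  The drug condition scales
a small set of connectivity parameters upward — by default the AMPA- and
NMDA-mediated SP->SI couplings (x5.7) and the NMDA- and GABA_A-mediated
DP->DP self-gains (x10 and x11) — which lowers theta/alpha amplitude and
raises gamma amplitude in the forward spectrum.  Subject-level variability
perturbs all free connectivity coefficients, and measurement noise is
additive Gaussian on amplitude, truncated at zero.

Every draw is deterministic under (seed, subject, condition) so regeneration
does not depend on call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .circuit_model import CircuitSpec, ParameterVector, gamma_name
from .exceptions import InstabilityError, StructuralError
from .observer import Spectrum, predict_spectrum

__all__ = ["GroupDesign", "default_effect_map", "generate_subject_spectrum",
           "generate_group", "simulate_group"]


def default_effect_map() -> Dict[str, float]:
    """Drug-condition log-scale shifts on the four affected pathways."""
    return {
        gamma_name("AMPA", "SI", "SP"): float(np.log(5.7)),
        gamma_name("NMDA", "SI", "SP"): float(np.log(5.7)),
        gamma_name("NMDA", "DP", "DP"): float(np.log(10.0)),
        gamma_name("GABA_A", "DP", "DP"): float(np.log(11.0)),
    }


@dataclass
class GroupDesign:
    """Study design: sample size, conditions, effects, variability, noise."""

    n_subjects: int = 16
    conditions: Tuple[str, str] = ("placebo", "ketamine")
    effect_map: Dict[str, float] = field(default_factory=default_effect_map)
    subject_sd: float = 0.05  # SD of between-subject coefficient offsets
    noise_sd: float = 0.02  # amplitude units; about a tenth of the spectral RMS
    seed: int = 0
    max_retries: int = 5
    # Coefficients receiving subject-level offsets; None = every free
    # connectivity weight.  Reduced designs restrict this to the fitted subset
    # so that subject variability stays inside the fitted model class.
    jitter_parameters: Optional[Tuple[str, ...]] = None

    def __post_init__(self):
        if self.n_subjects < 2:
            raise StructuralError("need at least 2 subjects")
        if self.noise_sd < 0 or self.subject_sd < 0:
            raise StructuralError("noise and subject SDs must be >= 0")


def _subject_offsets(spec: CircuitSpec, design: GroupDesign, subject: int,
                     retry: int = 0) -> np.ndarray:
    """Seeded coefficient offsets on the free connectivity weights."""
    names = ParameterVector.zeros(spec).names
    rng = np.random.default_rng(
        np.random.SeedSequence(design.seed, spawn_key=(subject, retry)))
    offsets = np.zeros(len(names))
    if design.jitter_parameters is None:
        gamma_idx = [i for i, n in enumerate(names) if n.startswith("gamma:")]
    else:
        gamma_idx = [i for i, n in enumerate(names)
                     if n in set(design.jitter_parameters)]
    offsets[gamma_idx] = rng.normal(0.0, design.subject_sd, len(gamma_idx))
    return offsets


def generate_subject_spectrum(spec: CircuitSpec, base_params: ParameterVector,
                              design: GroupDesign, subject: int,
                              condition: str,
                              frequencies: Optional[np.ndarray] = None,
                              **forward_kwargs) -> Tuple[Spectrum, ParameterVector]:
    """One synthetic spectrum plus the coefficients that generated it.

    Subject offsets are shared between conditions (the design is paired); the
    effect map applies only in the drug condition.  Unstable subject draws are
    re-sampled a bounded number of times.
    """
    if condition not in design.conditions:
        raise StructuralError(f"unknown condition {condition!r}")
    is_drug = condition == design.conditions[1]
    cond_idx = 1 if is_drug else 0
    last_err = None
    for retry in range(design.max_retries):
        params = base_params.copy()
        params.values = params.values + _subject_offsets(spec, design, subject,
                                                         retry)
        if is_drug:
            for name, shift in design.effect_map.items():
                params[name] = params[name] + shift
        try:
            clean = predict_spectrum(spec, params, frequencies=frequencies,
                                     **forward_kwargs)
        except InstabilityError as err:
            last_err = err
            continue
        noise_rng = np.random.default_rng(np.random.SeedSequence(
            design.seed, spawn_key=(subject, cond_idx, 1000 + retry)))
        amp = clean.amplitudes
        if design.noise_sd > 0:
            amp = np.maximum(amp + noise_rng.normal(0.0, design.noise_sd,
                                                    amp.size), 0.0)
        meta = {"subject_id": f"s{subject:02d}", "condition": condition}
        return Spectrum(clean.frequencies, amp, meta=meta), params
    raise InstabilityError(
        f"no stable draw for subject {subject} after {design.max_retries} retries",
        params=base_params) from last_err


def simulate_group(spec: CircuitSpec, design: GroupDesign,
                   base_params: Optional[ParameterVector] = None,
                   frequencies: Optional[np.ndarray] = None,
                   **forward_kwargs) -> List[Tuple[Spectrum, ParameterVector]]:
    """All n_subjects x 2 spectra with their generating coefficients."""
    if base_params is None:
        base_params = ParameterVector.zeros(spec)
    out = []
    for subject in range(design.n_subjects):
        for condition in design.conditions:
            out.append(generate_subject_spectrum(
                spec, base_params, design, subject, condition,
                frequencies=frequencies, **forward_kwargs))
    return out


def generate_group(spec: CircuitSpec, design: GroupDesign, out_dir,
                   base_params: Optional[ParameterVector] = None,
                   frequencies: Optional[np.ndarray] = None,
                   **forward_kwargs) -> pd.DataFrame:
    """Write spectrum files, a manifest and a truth table; returns the manifest."""
    from .cli_io import write_manifest, write_spectrum

    out_path = Path(out_dir)
    out_path.mkdir(parents=True, exist_ok=True)
    rows, truth_rows = [], []
    for spectrum, params in simulate_group(spec, design, base_params,
                                           frequencies, **forward_kwargs):
        sid, cond = spectrum.meta["subject_id"], spectrum.meta["condition"]
        fname = f"spectrum_{sid}_{cond}.tsv"
        write_spectrum(spectrum, out_path / fname)
        rows.append({"subject_id": sid, "condition": cond, "path": fname})
        truth_rows.append({"subject_id": sid, "condition": cond,
                           **params.to_dict()})
    manifest = pd.DataFrame(rows)
    write_manifest(manifest, out_path / "manifest.tsv")
    pd.DataFrame(truth_rows).to_csv(out_path / "truth.tsv", sep="\t",
                                    index=False)
    return manifest
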