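"""Synthetic-data generators emulating the two experimental designs.

The study's raw shift tables and thermograms are not deposited, so every
analysis stage is exercised against generated data with known ground truth:

* an 11-mixture continuous-variation NMR series at 4 mM constant total
  concentration of guest (DHTH) plus host (beta-cyclodextrin), traced on
  five protons (guest aromatics Hd/He/Hf and host cavity H3/H5), with
  fast-exchange shift averaging and Gaussian measurement noise on the
  observed shifts; and
* a 25 x 10 uL ITC titration of 3 mM guest into 0.75 mM host at 25 C,
  with Gaussian noise on the per-injection heats.

Generators are pure functions of (truth, seed): identical inputs give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .binding_core import ProtonAssignment, ShiftRecord, _hg
from .itc import ITCBindingParams, ITCDesign, Thermogram, simulate_thermogram
from .nmr import CVDesign, ShiftTable, build_cv_design

__all__ = [
    "FREE_SHIFTS_PPM",
    "PROTON_MOLECULE",
    "DEFAULT_DELTA_C",
    "CVGroundTruth",
    "ITCGroundTruth",
    "default_cv_design",
    "default_itc_design",
    "generate_cv_table",
    "generate_itc_thermogram",
]

# Free-state 1H shifts (ppm, D2O).  Guest protons a-h are the assigned
# aromatic/thiazole/ethyl resonances of DHTH; H3 and H5 are the protons
# lining the beta-cyclodextrin cavity (typical literature values).
FREE_SHIFTS_PPM = {
    "Ha": 6.97,
    "Hb": 7.79,
    "Hc": 6.88,
    "Hd": 6.96,
    "He": 6.98,
    "Hf": 6.90,
    "Hg": 1.24,
    "Hh": 4.00,
    "H3": 3.94,
    "H5": 3.84,
}

PROTON_MOLECULE = {p: ("host" if p in ("H3", "H5") else "guest") for p in FREE_SHIFTS_PPM}

# Limiting complexation shifts (ppm): plausible magnitudes for cyclodextrin
# inclusion, upfield (positive delta_free - delta_obs) for the cavity
# protons and downfield for the inserted guest aromatics.
DEFAULT_DELTA_C = {
    "H3": 0.055,
    "H5": 0.075,
    "Hd": -0.032,
    "He": -0.024,
    "Hf": -0.041,
}


def default_cv_design() -> CVDesign:
    """The study's mixing scheme: 11 mixtures, 4 mM constant total."""
    return build_cv_design(C_total=4.0e-3, n_samples=11)


def default_itc_design() -> ITCDesign:
    """The study's titration: 25 x 10 uL of 3 mM guest into 0.75 mM host, 25 C."""
    return ITCDesign(
        cell_volume=1.0e-3,
        cell_conc_initial=0.75e-3,
        syringe_conc=3.0e-3,
        injection_volumes=(1.0e-5,) * 25,
        temperature=298.15,
        spacing=300.0,
    )


@dataclass(frozen=True)
class CVGroundTruth:
    """Ground truth for a continuous-variation series.

    K in L/mol; delta_c / delta_free in ppm per proton; noise_sd is the
    Gaussian standard deviation added to each observed shift (ppm).
    """

    K: float = 81.97
    delta_c: dict = field(default_factory=lambda: dict(DEFAULT_DELTA_C))
    delta_free: dict = field(default_factory=lambda: dict(FREE_SHIFTS_PPM))
    noise_sd: float = 0.001
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        missing = set(self.delta_c) - set(self.delta_free)
        if missing:
            raise ValueError(f"delta_c protons missing free shifts: {sorted(missing)}")


@dataclass(frozen=True)
class ITCGroundTruth:
    """Ground truth for an ITC titration; noise_sd in cal (0.5 ucal = 5e-7)."""

    params: ITCBindingParams = field(
        default_factory=lambda: ITCBindingParams(K=1096.0, n=1.0, dH=-1013.0)
    )
    design: ITCDesign = field(default_factory=default_itc_design)
    noise_sd: float = 5.0e-7
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def generate_cv_table(truth: CVGroundTruth, design: CVDesign | None = None) -> ShiftTable:
    """Simulate observed shifts over a continuous-variation design.

    delta_obs(i, j) = delta_free(j) - ddelta_model(i, j) + eps with
    eps ~ N(0, noise_sd); noiseless (exactly reproducible by the fitter)
    when noise_sd = 0.
    """
    if design is None:
        design = default_cv_design()
    rng = np.random.default_rng(truth.seed)
    protons = sorted(truth.delta_c)
    assignments = {
        p: ProtonAssignment(
            proton_id=p,
            molecule=PROTON_MOLECULE[p],
            delta_free=truth.delta_free[p],
            delta_c=truth.delta_c[p],
        )
        for p in protons
    }
    records = []
    for i, (A, B) in enumerate(design.samples):
        hg = _hg(A, B, truth.K)
        for p in protons:
            asg = assignments[p]
            X = A if asg.molecule == "guest" else B
            dd_model = asg.delta_c * hg / X
            noise = rng.normal(0.0, truth.noise_sd) if truth.noise_sd > 0 else 0.0
            delta_obs = asg.delta_free - dd_model + noise
            records.append(
                ShiftRecord(
                    sample_index=i,
                    proton_id=p,
                    delta_obs=delta_obs,
                    delta_delta=asg.delta_free - delta_obs,
                )
            )
    return ShiftTable(records=records, assignments=assignments)


def generate_itc_thermogram(
    truth: ITCGroundTruth, with_control: bool = False
) -> Thermogram | tuple:
    """Simulate a thermogram (optionally with a matched noise-only control).

    Heats are the independent-sites forward model plus seeded Gaussian
    noise.  The control emulates titrant-into-solvent dilution: pure noise
    drawn from the same distribution, on the sample's molar-ratio axis.
    """
    rng = np.random.default_rng(truth.seed)
    clean = simulate_thermogram(truth.params, truth.design)
    n = len(clean.heats)
    noise = rng.normal(0.0, truth.noise_sd, size=n) if truth.noise_sd > 0 else np.zeros(n)
    sample = Thermogram(
        heats=tuple(np.asarray(clean.heats) + noise),
        molar_ratios=clean.molar_ratios,
    )
    if not with_control:
        return sample
    cnoise = rng.normal(0.0, truth.noise_sd, size=n) if truth.noise_sd > 0 else np.zeros(n)
    control = Thermogram(heats=tuple(cnoise), molar_ratios=clean.molar_ratios)
    return sample, control
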