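"""Thermodynamic linkage for binding equilibria.

dG = -R T ln K and dG = dH - T dS tie the association constant, enthalpy
and entropy of a binding process together at a single temperature.  Units
follow the calorimetric convention of the field: dG and dH in kcal/mol,
dS in cal/(mol*K), K in L/mol, T in kelvin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "R_CAL",
    "ThermoResult",
    "gibbs_from_K",
    "entropy_from_linkage",
    "check_consistency",
]

# gas constant, cal/(mol*K)
R_CAL = 1.98720425


@dataclass(frozen=True)
class ThermoResult:
    """A complete thermodynamic characterisation of one binding equilibrium.

    K in L/mol; dG, dH in kcal/mol; dS in cal/(mol*K); T in kelvin.
    R_const records the gas-constant convention binding the identities.
    """

    K: float
    dG: float
    dH: float
    dS: float
    T: float
    R_const: float = R_CAL


def gibbs_from_K(K: float, T: float) -> float:
    """Standard Gibbs energy of association, -R T ln K, in kcal/mol."""
    if K <= 0:
        raise ValueError(f"K must be positive, got {K}")
    if T <= 0:
        raise ValueError(f"T must be positive, got {T}")
    return -R_CAL * T * math.log(K) / 1000.0


def entropy_from_linkage(dH: float, dG: float, T: float) -> float:
    """Entropy change dS = (dH - dG)/T in cal/(mol*K); dH, dG in kcal/mol."""
    if T <= 0:
        raise ValueError(f"T must be positive, got {T}")
    return 1000.0 * (dH - dG) / T


def check_consistency(result: ThermoResult, tol_kcal: float = 0.01) -> dict:
    """Verify both linkage identities on a ThermoResult.

    Returns a report with the residuals (kcal/mol) of
    dG - (-R T ln K) and dG - (dH - T dS / 1000) and a pass flag for each
    at the given tolerance.
    """
    resid_K = result.dG - gibbs_from_K(result.K, result.T)
    resid_HS = result.dG - (result.dH - result.T * result.dS / 1000.0)
    return {
        "gibbs_from_K": {"residual_kcal": resid_K, "pass": abs(resid_K) <= tol_kcal},
        "enthalpy_entropy": {
            "residual_kcal": resid_HS,
            "pass": abs(resid_HS) <= tol_kcal,
        },
        "tolerance_kcal": tol_kcal,
        "all_pass": abs(resid_K) <= tol_kcal and abs(resid_HS) <= tol_kcal,
    }
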