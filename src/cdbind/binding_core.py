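"""Exact 1:1 complexation equilibrium and fast-exchange shift perturbation.

For a host H and guest G forming a 1:1 complex HG with association constant
K = [HG] / ([H][G])  (L/mol),

mass action at total concentrations A (guest) and B (host) gives the
quadratic whose physical root is

    [HG] = ( (A + B + 1/K) - sqrt((A + B + 1/K)^2 - 4AB) ) / 2.

Under fast exchange a traced proton shows one population-weighted peak, and
its perturbation relative to the free state is

    ddelta = ddelta_c * [HG] / X,

where X is the total concentration of the proton's own molecule (A for a
guest proton, B for a host proton) and ddelta_c is the limiting shift
difference between the free component and the pure complex.

All concentrations are mol/L; shifts are ppm.  The sign convention is
ddelta = delta_free - delta_obs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EquilibriumInput",
    "ProtonAssignment",
    "ShiftRecord",
    "complex_concentration",
    "predicted_shift_perturbation",
    "shift_perturbation_from_observed",
]

GUEST = "guest"
HOST = "host"


@dataclass(frozen=True)
class EquilibriumInput:
    """Total concentrations and association constant for one equilibrium.

    A_total : total guest concentration (mol/L), >= 0
    B_total : total host concentration (mol/L), >= 0
    K       : association constant (L/mol), >= 0; K = 0 means no binding
    """

    A_total: float
    B_total: float
    K: float

    def __post_init__(self) -> None:
        if self.A_total < 0 or self.B_total < 0:
            raise ValueError(
                f"concentrations must be non-negative, got "
                f"A={self.A_total}, B={self.B_total}"
            )
        if self.K < 0:
            raise ValueError(f"association constant must be non-negative, got K={self.K}")


@dataclass(frozen=True)
class ProtonAssignment:
    """A traced proton: which molecule it sits on and its shift parameters.

    molecule selects X in the isotherm: "guest" -> A_total, "host" -> B_total.
    delta_c is signed; no assumption is made about its direction.
    """

    proton_id: str
    molecule: str
    delta_free: float
    delta_c: float = 0.0

    def __post_init__(self) -> None:
        if self.molecule not in (GUEST, HOST):
            raise ValueError(f"molecule must be 'guest' or 'host', got {self.molecule!r}")


@dataclass(frozen=True)
class ShiftRecord:
    """One observation: proton j in sample i.

    delta_delta is the perturbation delta_free - delta_obs, recomputable
    from its parts.
    """

    sample_index: int
    proton_id: str
    delta_obs: float
    delta_delta: float


def _hg(A, B, K):
    """Vectorized 1:1 complex concentration (mol/L).

    Uses the conjugate form 2AB / (S + sqrt(S^2 - 4AB)), S = A + B + 1/K,
    which avoids the subtractive cancellation of the naive quadratic root
    when 4AB << S^2 (small K or dilute solutions).  K = 0 and A*B = 0 are
    taken as the continuous limit HG = 0.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    K = np.asarray(K, dtype=float)
    out = np.zeros(np.broadcast_shapes(A.shape, B.shape, K.shape))
    active = (K > 0) & (A > 0) & (B > 0)
    if np.any(active):
        a = np.broadcast_to(A, out.shape)[active]
        b = np.broadcast_to(B, out.shape)[active]
        k = np.broadcast_to(K, out.shape)[active]
        s = a + b + 1.0 / k
        disc = s * s - 4.0 * a * b
        out[active] = 2.0 * a * b / (s + np.sqrt(disc))
    return out if out.ndim else float(out)


def complex_concentration(eq: EquilibriumInput) -> float:
    """Equilibrium complex concentration [HG] (mol/L) for a 1:1 system.

    Satisfies 0 <= HG <= min(A, B) and K (A - HG)(B - HG) = HG.
    """
    return _hg(eq.A_total, eq.B_total, eq.K)


def predicted_shift_perturbation(eq: EquilibriumInput, proton: ProtonAssignment) -> float:
    """Fast-exchange shift perturbation ddelta (ppm) for one proton.

    ddelta = delta_c * HG / X with X the total concentration of the
    proton's molecule; bounded by |delta_c| and carrying its sign.
    """
    X = eq.A_total if proton.molecule == GUEST else eq.B_total
    if X <= 0:
        raise ValueError(
            f"total concentration of the {proton.molecule} is zero; the bound "
            f"fraction of proton {proton.proton_id!r} is undefined"
        )
    return proton.delta_c * complex_concentration(eq) / X


def shift_perturbation_from_observed(delta_free: float, delta_obs: float) -> float:
    """Observed perturbation ddelta = delta_free - delta_obs (ppm, signed)."""
    if not (np.isfinite(delta_free) and np.isfinite(delta_obs)):
        raise ValueError("chemical shifts must be finite")
    return delta_free - delta_obs
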