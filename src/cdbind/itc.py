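"""Independent-sites (single set of sites) ITC model: simulation and fitting.

An ITC titration injects guest (syringe, concentration X_syr) into host
(cell, initial concentration M0, active volume V0).  With an overfilled
perfusion cell each injection expels mixed cell liquid; after a cumulative
injected volume dV the standard displacement-corrected totals are

    M_k = M0 * (1 - dV/(2 V0)) / (1 + dV/(2 V0))
    X_k = X_syr * (dV/V0) / (1 + dV/(2 V0)).

The 1:1 equilibrium with an effective site concentration n * M_k gives the
bound concentration HG_k; the cell heat content is Q_k = dH * V0 * HG_k and
the measured per-injection heat includes the expelled-heat correction

    q_k = Q_k - Q_{k-1} + (dv_k / V0) * (Q_k + Q_{k-1}) / 2.

Heats are calories (exothermic negative); dH is cal/mol; K is L/mol.

The Wiseman parameter c = n * K * M0 governs identifiability: below c ~ 1
the isotherm is shallow and K, n and dH are strongly correlated, so the
fitter attaches a warning outside c in [0.01, 1e4].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin

from .binding_core import _hg
from .thermo import ThermoResult, entropy_from_linkage, gibbs_from_K

__all__ = [
    "ITCDesign",
    "Thermogram",
    "ITCBindingParams",
    "IndependentSitesITC",
    "simulate_thermogram",
    "fit_independent_model",
    "blank_subtract",
]

# Wiseman-c diagnostic windows: outside C_IDENTIFIABLE the isotherm carries
# essentially no information on K; outside C_RELIABLE (the classic 1-1000
# window) the fit is possible but K/n/dH estimates are strongly correlated.
C_IDENTIFIABLE = (0.01, 1e4)
C_RELIABLE = (1.0, 1e3)


@dataclass(frozen=True)
class ITCDesign:
    """Cell/syringe geometry and injection schedule.

    cell_volume in L; concentrations in mol/L; injection_volumes in L;
    temperature in K; spacing (s) is metadata only.
    """

    cell_volume: float
    cell_conc_initial: float
    syringe_conc: float
    injection_volumes: tuple
    temperature: float = 298.15
    spacing: float = 300.0

    def __post_init__(self):
        if self.cell_volume <= 0 or any(v <= 0 for v in self.injection_volumes):
            raise ValueError("all volumes must be positive")
        if self.cell_conc_initial <= 0 or self.syringe_conc <= 0:
            raise ValueError("concentrations must be positive")
        if len(self.injection_volumes) < 2:
            raise ValueError("need at least 2 injections")


@dataclass(frozen=True)
class Thermogram:
    """Per-injection heats (cal, exothermic negative) and molar ratios."""

    heats: tuple
    molar_ratios: tuple

    def __post_init__(self):
        if len(self.heats) != len(self.molar_ratios):
            raise ValueError("heats and molar_ratios must have equal length")


@dataclass(frozen=True)
class ITCBindingParams:
    """Independent-sites parameters: K (L/mol), n (sites), dH (cal/mol)."""

    K: float
    n: float
    dH: float

    def __post_init__(self):
        if self.K <= 0:
            raise ValueError(f"K must be positive, got {self.K}")
        if self.n <= 0:
            raise ValueError(f"n must be positive, got {self.n}")


def _cell_totals(design: ITCDesign, displacement: bool = True):
    """Total (guest, host) cell concentrations after each injection."""
    dv = np.asarray(design.injection_volumes, dtype=float)
    DV = np.cumsum(dv)
    V0 = design.cell_volume
    if displacement:
        M = design.cell_conc_initial * (1.0 - DV / (2 * V0)) / (1.0 + DV / (2 * V0))
        X = design.syringe_conc * (DV / V0) / (1.0 + DV / (2 * V0))
    else:
        M = np.full_like(DV, design.cell_conc_initial)
        X = design.syringe_conc * DV / V0
    return X, M, dv


def _bound_trace(params: ITCBindingParams | None, design, displacement, K=None, n=None):
    if params is not None:
        K, n = params.K, params.n
    X, M, dv = _cell_totals(design, displacement)
    HG = _hg(X, n * M, K)
    return HG, X, M, dv


def _heats_per_mole_bound(K, n, design, displacement):
    """Forward heats for dH = 1 cal/mol; the model is linear in dH."""
    HG, X, M, dv = _bound_trace(None, design, displacement, K=K, n=n)
    V0 = design.cell_volume
    Q = V0 * HG
    Qprev = np.concatenate([[0.0], Q[:-1]])
    g = Q - Qprev
    if displacement:
        g = g + (dv / V0) * (Q + Qprev) / 2.0
    return g, X / M


def simulate_thermogram(
    params: ITCBindingParams, design: ITCDesign, displacement: bool = True
) -> Thermogram:
    """Noiseless per-injection heats for the independent-sites model.

    With ``displacement=False`` the cell is treated as a closed fixed
    volume (no expelled liquid); then the heats telescope exactly to
    dH * V0 * HG_final, which serves as a conservation oracle.
    """
    total_injected = sum(design.injection_volumes)
    if total_injected > 0.5 * design.cell_volume:
        warnings.warn(
            f"cumulative injected volume ({total_injected:.2e} L) exceeds half "
            f"the cell volume; displacement corrections become large",
            RuntimeWarning,
        )
    g, ratios = _heats_per_mole_bound(params.K, params.n, design, displacement)
    return Thermogram(heats=tuple(params.dH * g), molar_ratios=tuple(ratios))


def blank_subtract(sample: Thermogram, control: Thermogram) -> Thermogram:
    """Subtract a control (titrant-into-solvent) titration, injection-wise."""
    if len(sample.heats) != len(control.heats):
        raise ValueError(
            f"injection count mismatch: sample has {len(sample.heats)}, "
            f"control has {len(control.heats)}"
        )
    heats = tuple(s - c for s, c in zip(sample.heats, control.heats))
    return Thermogram(heats=heats, molar_ratios=sample.molar_ratios)


class IndependentSitesITC(BaseEstimator, RegressorMixin):
    """Least-squares fit of (K, n, dH) to per-injection heats.

    Scikit-learn style estimator over the same forward model as
    ``simulate_thermogram``: X is the injection-volume array (L), y the
    per-injection heats (cal).  dH enters the model linearly and is profiled
    out; the outer search runs over (log10 K, ln n) — Nelder-Mead seeded
    from a coarse grid — or over log10 K alone when ``fix_n`` is set.

    Parameters
    ----------
    cell_volume, cell_conc, syringe_conc : experiment geometry (L, mol/L).
    temperature : K, used for the thermodynamic linkage of the result.
    fix_n : if not None, hold the site number at this value.
    displacement : apply the overfilled-cell correction (default True).
    discard_first : drop injection 1 from the fit (diffusion-artifact
        practice); default False.

    Attributes
    ----------
    K_, n_, dH_ : fitted parameters (L/mol, sites, cal/mol).
    dG_, dS_ : linked Gibbs energy (kcal/mol) and entropy (cal/(mol*K)).
    c_ : Wiseman parameter n * K * M0.
    warnings_ : identifiability notes attached to the result.
    """

    def __init__(
        self,
        cell_volume: float = 1.0e-3,
        cell_conc: float = 0.75e-3,
        syringe_conc: float = 3.0e-3,
        temperature: float = 298.15,
        fix_n: float | None = None,
        displacement: bool = True,
        discard_first: bool = False,
    ):
        self.cell_volume = cell_volume
        self.cell_conc = cell_conc
        self.syringe_conc = syringe_conc
        self.temperature = temperature
        self.fix_n = fix_n
        self.displacement = displacement
        self.discard_first = discard_first

    def _design(self, volumes):
        return ITCDesign(
            cell_volume=self.cell_volume,
            cell_conc_initial=self.cell_conc,
            syringe_conc=self.syringe_conc,
            injection_volumes=tuple(volumes),
            temperature=self.temperature,
        )

    def _profile(self, logK, ln_n, design, y, mask):
        g = _heats_per_mole_bound(10.0 ** logK, np.exp(ln_n), design, self.displacement)[0]
        g = g[mask]
        den = float(np.dot(g, g))
        if den <= 0:
            return float(np.dot(y, y)), 0.0
        dH = float(np.dot(g, y)) / den
        r = y - dH * g
        return float(np.dot(r, r)), dH

    def fit(self, X, y):
        volumes = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if len(volumes) != len(y):
            raise ValueError("injection volumes and heats have different lengths")
        design = self._design(volumes)
        mask = np.ones(len(y), dtype=bool)
        if self.discard_first:
            mask[0] = False
        yf = y[mask]
        if mask.sum() < 5:
            raise ValueError("need at least 5 usable injections")
        if np.all(np.abs(yf) < 1e-18):
            raise ValueError("flat thermogram: binding parameters are unidentifiable")

        if self.fix_n is not None:
            ln_n = np.log(self.fix_n)
            res = minimize_scalar(
                lambda lk: self._profile(lk, ln_n, design, yf, mask)[0],
                bounds=(-2.0, 8.0),
                method="bounded",
                options={"xatol": 1e-12},
            )
            logK, ln_n_hat = float(res.x), ln_n
        else:
            grid = [
                (lk, np.log(n0))
                for lk in (1.0, 2.0, 3.0, 4.0, 5.0)
                for n0 in (0.5, 1.0, 2.0)
            ]
            x0 = min(grid, key=lambda p: self._profile(*p, design, yf, mask)[0])
            res = minimize(
                lambda p: self._profile(p[0], p[1], design, yf, mask)[0],
                x0=np.array(x0),
                method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-24, "maxiter": 4000},
            )
            logK, ln_n_hat = float(res.x[0]), float(res.x[1])

        rss, dH = self._profile(logK, ln_n_hat, design, yf, mask)
        self.K_ = float(10.0 ** logK)
        self.n_ = float(np.exp(ln_n_hat))
        self.dH_ = float(dH)
        self.rss_ = float(rss)
        self.converged_ = bool(res.success)
        self.c_ = float(self.n_ * self.K_ * self.cell_conc)
        self.warnings_ = []
        lo, hi = C_IDENTIFIABLE
        if not (lo <= self.c_ <= hi):
            msg = (
                f"Wiseman c = {self.c_:.3g} outside [{lo}, {hi}]: the isotherm "
                "carries essentially no information on K"
            )
            self.warnings_.append(msg)
            warnings.warn(msg, RuntimeWarning)
        elif not (C_RELIABLE[0] <= self.c_ <= C_RELIABLE[1]):
            msg = (
                f"Wiseman c = {self.c_:.3g} outside the reliable window "
                f"[{C_RELIABLE[0]:g}, {C_RELIABLE[1]:g}]: the isotherm is "
                "weakly sigmoidal and K/n/dH estimates are correlated"
            )
            self.warnings_.append(msg)
            warnings.warn(msg, RuntimeWarning)
        self.dG_ = gibbs_from_K(self.K_, self.temperature)
        self.dS_ = entropy_from_linkage(self.dH_ / 1000.0, self.dG_, self.temperature)
        return self

    def predict(self, X):
        volumes = np.asarray(X, dtype=float).ravel()
        design = self._design(volumes)
        g = _heats_per_mole_bound(self.K_, self.n_, design, self.displacement)[0]
        return self.dH_ * g


def fit_independent_model(
    thermogram: Thermogram,
    design: ITCDesign,
    fix_n: float | None = None,
    displacement: bool = True,
    discard_first: bool = False,
) -> tuple:
    """Fit the independent-sites model; returns (ITCBindingParams, ThermoResult, est).

    The ThermoResult carries the full linkage dG = -RT ln K = dH - T dS at
    the design temperature.
    """
    est = IndependentSitesITC(
        cell_volume=design.cell_volume,
        cell_conc=design.cell_conc_initial,
        syringe_conc=design.syringe_conc,
        temperature=design.temperature,
        fix_n=fix_n,
        displacement=displacement,
        discard_first=discard_first,
    ).fit(np.asarray(design.injection_volumes), np.asarray(thermogram.heats))
    params = ITCBindingParams(K=est.K_, n=est.n_, dH=est.dH_)
    result = ThermoResult(
        K=est.K_,
        dG=est.dG_,
        dH=est.dH_ / 1000.0,
        dS=est.dS_,
        T=design.temperature,
    )
    return params, result, est
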