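"""Continuous-variation (Job plot) analysis and association-constant fitting.

A continuous-variation series holds the total concentration C = A + B fixed
while the mole ratio r = A / C sweeps (0, 1).  The Job response
ddelta(i, j) * [X]_i equals delta_c(j) * [HG]_i, so for a 1:1 complex it
peaks at r = 0.5 regardless of K.

The association constant is fitted globally over all traced protons by
variable projection: for a candidate K the model is linear in the limiting
shifts delta_c(j), which are solved exactly per proton; a 1-D bounded search
over log10 K minimizes the profiled sum of squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin

from .binding_core import GUEST, ProtonAssignment, ShiftRecord, _hg

__all__ = [
    "CVDesign",
    "ShiftTable",
    "JobCurve",
    "NMRBindingFit",
    "NMRTitration",
    "build_cv_design",
    "job_curve",
    "estimate_stoichiometry",
    "fit_association_constant",
    "bootstrap_K",
]


@dataclass(frozen=True)
class CVDesign:
    """A constant-total-concentration mixture series.

    samples: ordered (A_total, B_total) pairs in mol/L.
    C_total: the constant total A + B (mol/L).
    r_values: guest mole ratio A / C per sample.
    """

    samples: tuple
    C_total: float
    r_values: tuple

    def __post_init__(self):
        for a, b in self.samples:
            if abs(a + b - self.C_total) > 1e-12:
                raise ValueError(
                    f"sample ({a}, {b}) violates constant total {self.C_total}"
                )


@dataclass
class ShiftTable:
    """Shift observations over samples x protons plus proton assignments.

    records: one ShiftRecord per (sample, proton) pair.
    assignments: proton_id -> ProtonAssignment (delta_free, molecule).
    """

    records: list
    assignments: dict

    def __post_init__(self):
        seen = set()
        for rec in self.records:
            if rec.proton_id not in self.assignments:
                raise ValueError(f"record references unknown proton {rec.proton_id!r}")
            key = (rec.sample_index, rec.proton_id)
            if key in seen:
                raise ValueError(f"duplicate record for sample/proton {key}")
            seen.add(key)

    def protons(self):
        return sorted(self.assignments)


@dataclass(frozen=True)
class JobCurve:
    """Job response y_i = ddelta(i, j) * [X]_i against the mole ratio grid."""

    r_grid: np.ndarray
    y_values: np.ndarray
    r_max: float
    proton_id: str


@dataclass
class NMRBindingFit:
    """Result of the global K fit.

    K is in L/mol; delta_c maps proton_id -> fitted limiting shift (ppm);
    correlation is the Pearson R between observed and fitted ddelta pooled
    over all records.
    """

    K: float
    delta_c: dict
    correlation: float
    residuals: np.ndarray
    converged: bool
    n_iterations: int
    rss: float
    bootstrap_ci: tuple | None = None
    objective_history: list = field(default_factory=list, repr=False)


def build_cv_design(C_total: float, n_samples: int) -> CVDesign:
    """Evenly spaced interior mole ratios r_i = i/(n+1), i = 1..n.

    Endpoints r = 0, 1 are excluded: pure components provide the reference
    (free-state) spectra, not mixtures.
    """
    if n_samples < 3:
        raise ValueError(f"need at least 3 mixtures, got {n_samples}")
    if C_total <= 0:
        raise ValueError(f"total concentration must be positive, got {C_total}")
    r = np.arange(1, n_samples + 1) / (n_samples + 1)
    samples = tuple((ri * C_total, (1.0 - ri) * C_total) for ri in r)
    return CVDesign(samples=samples, C_total=C_total, r_values=tuple(r))


def _table_arrays(design: CVDesign, table: ShiftTable):
    """Flatten (design, table) into aligned record arrays for fitting."""
    A = np.empty(len(table.records))
    B = np.empty(len(table.records))
    is_guest = np.empty(len(table.records), dtype=bool)
    proton = np.empty(len(table.records), dtype=object)
    y = np.empty(len(table.records))
    for k, rec in enumerate(table.records):
        a, b = design.samples[rec.sample_index]
        A[k], B[k] = a, b
        asg = table.assignments[rec.proton_id]
        is_guest[k] = asg.molecule == GUEST
        proton[k] = rec.proton_id
        y[k] = rec.delta_delta
    return A, B, is_guest, proton, y


def job_curve(design: CVDesign, table: ShiftTable, proton_id: str) -> JobCurve:
    """Build the continuous-variation curve for one proton and locate its peak.

    y_i = ddelta(i, j) * [X]_i with [X] the total concentration of the
    proton's own molecule; the abscissa is that molecule's mole ratio.  The
    peak is refined by a parabola through the discrete maximum of |y| and
    its neighbours; ties resolve to the smallest r.
    """
    if proton_id not in table.assignments:
        raise KeyError(f"proton {proton_id!r} not in the shift table")
    asg = table.assignments[proton_id]
    recs = sorted(
        (r for r in table.records if r.proton_id == proton_id),
        key=lambda r: r.sample_index,
    )
    r_grid = np.empty(len(recs))
    y = np.empty(len(recs))
    for k, rec in enumerate(recs):
        a, b = design.samples[rec.sample_index]
        x = a if asg.molecule == GUEST else b
        r_grid[k] = x / design.C_total
        y[k] = rec.delta_delta * x
    order = np.argsort(r_grid)
    r_grid, y = r_grid[order], y[order]

    mag = np.abs(y)
    if np.all(mag < 1e-15):
        raise ValueError(
            f"flat Job curve for proton {proton_id!r}: all perturbations are "
            "zero, no maximum exists"
        )
    m = int(np.argmax(mag))  # argmax returns the first (smallest-r) tie
    if 0 < m < len(y) - 1:
        # parabolic vertex through the three points around the maximum
        y0, y1, y2 = mag[m - 1], mag[m], mag[m + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom < 0:
            shift = 0.5 * (y0 - y2) / denom
            r_max = r_grid[m] + shift * (r_grid[m + 1] - r_grid[m])
        else:
            r_max = r_grid[m]
    else:
        r_max = r_grid[m]
    return JobCurve(r_grid=r_grid, y_values=y, r_max=float(r_max), proton_id=proton_id)


def estimate_stoichiometry(curve: JobCurve, tolerance: float = 0.05) -> str:
    """Classify the complex ratio from the Job-curve peak position.

    A peak at r = 0.5 (within tolerance, boundary inclusive) is the 1:1
    signature; anything else is reported with its location.
    """
    if abs(curve.r_max - 0.5) <= tolerance:
        return "1:1"
    return f"non-1:1 (r_max = {curve.r_max:.3f})"


class NMRTitration(BaseEstimator, RegressorMixin):
    """Global 1:1 isotherm fit of K and per-proton limiting shifts.

    Scikit-learn style estimator.  X is a DataFrame (or record array) with
    columns ``A_total``, ``B_total``, ``molecule``, ``proton_id`` (one row
    per observation, concentrations in mol/L); y is the observed
    perturbation ddelta (ppm).

    Parameters
    ----------
    log10_k_bounds : search interval for log10 K (K in L/mol).
    xatol : absolute tolerance on log10 K for the outer bounded search;
        corresponds to a relative change in K below ~2.3 * xatol.
    max_iter : outer-iteration cap.

    Attributes
    ----------
    K_ : fitted association constant (L/mol).
    delta_c_ : dict proton_id -> fitted limiting shift (ppm).
    correlation_ : pooled Pearson R between observed and fitted ddelta.
    residuals_ : observed - fitted (ppm).
    converged_, n_iter_, rss_, objective_history_.
    """

    def __init__(self, log10_k_bounds=(-2.0, 8.0), xatol=1e-10, max_iter=500):
        self.log10_k_bounds = log10_k_bounds
        self.xatol = xatol
        self.max_iter = max_iter

    def _validate(self, X, y):
        X = pd.DataFrame(X)
        required = {"A_total", "B_total", "molecule", "proton_id"}
        missing = required - set(X.columns)
        if missing:
            raise ValueError(f"X is missing columns: {sorted(missing)}")
        y = np.asarray(y, dtype=float)
        if len(X) != len(y):
            raise ValueError("X and y have different lengths")
        if len(y) < 2:
            raise ValueError("need at least 2 observations to fit K")
        if np.all(np.abs(y) < 1e-15):
            raise ValueError(
                "all shift perturbations are zero: K is unidentifiable"
            )
        return X, y

    def _profile(self, logK, A, B, X_own, codes, n_protons, y):
        """Profiled SSR: solve each delta_c exactly, return residual info."""
        f = _hg(A, B, 10.0 ** logK) / X_own
        dc = np.zeros(n_protons)
        for j in range(n_protons):
            m = codes == j
            den = np.dot(f[m], f[m])
            dc[j] = np.dot(f[m], y[m]) / den if den > 0 else 0.0
        yhat = dc[codes] * f
        resid = y - yhat
        return float(np.dot(resid, resid)), dc, yhat

    def fit(self, X, y):
        X, y = self._validate(X, y)
        A = X["A_total"].to_numpy(dtype=float)
        B = X["B_total"].to_numpy(dtype=float)
        X_own = np.where(X["molecule"].to_numpy() == GUEST, A, B)
        if np.any(X_own <= 0):
            raise ValueError("zero total concentration for an observed proton")
        proton_ids, codes = np.unique(X["proton_id"].to_numpy(), return_inverse=True)

        history = []

        def obj(logK):
            ssr = self._profile(logK, A, B, X_own, codes, len(proton_ids), y)[0]
            history.append(ssr)
            return ssr

        res = minimize_scalar(
            obj,
            bounds=self.log10_k_bounds,
            method="bounded",
            options={"xatol": self.xatol, "maxiter": self.max_iter},
        )
        lo, hi = self.log10_k_bounds
        self.converged_ = bool(res.success and lo + 1e-6 < res.x < hi - 1e-6)
        if not self.converged_:
            warnings.warn(
                "K fit did not converge inside the search interval; returning "
                "the best point found",
                RuntimeWarning,
            )
        ssr, dc, yhat = self._profile(res.x, A, B, X_own, codes, len(proton_ids), y)
        self.K_ = float(10.0 ** res.x)
        self.delta_c_ = {p: float(d) for p, d in zip(proton_ids, dc)}
        self.residuals_ = y - yhat
        self.rss_ = ssr
        self.n_iter_ = int(res.nfev)
        self.objective_history_ = history
        if np.std(yhat) > 0 and np.std(y) > 0:
            self.correlation_ = float(np.corrcoef(y, yhat)[0, 1])
        else:
            self.correlation_ = float("nan")
        return self

    def predict(self, X):
        X = pd.DataFrame(X)
        A = X["A_total"].to_numpy(dtype=float)
        B = X["B_total"].to_numpy(dtype=float)
        X_own = np.where(X["molecule"].to_numpy() == GUEST, A, B)
        f = _hg(A, B, self.K_) / X_own
        dc = np.array([self.delta_c_.get(p, 0.0) for p in X["proton_id"]])
        return dc * f


def _table_to_xy(design: CVDesign, table: ShiftTable):
    A, B, is_guest, proton, y = _table_arrays(design, table)
    X = pd.DataFrame(
        {
            "A_total": A,
            "B_total": B,
            "molecule": np.where(is_guest, "guest", "host"),
            "proton_id": proton,
        }
    )
    return X, y


def fit_association_constant(
    design: CVDesign,
    table: ShiftTable,
    bootstrap: int = 0,
    seed: int | None = None,
) -> NMRBindingFit:
    """Fit K and all limiting shifts jointly from a continuous-variation table.

    Optionally attaches a nonparametric bootstrap 95% CI on K (resampling
    records with replacement).
    """
    X, y = _table_to_xy(design, table)
    est = NMRTitration().fit(X, y)
    ci = bootstrap_K(design, table, n_boot=bootstrap, seed=seed) if bootstrap else None
    return NMRBindingFit(
        K=est.K_,
        delta_c=est.delta_c_,
        correlation=est.correlation_,
        residuals=est.residuals_,
        converged=est.converged_,
        n_iterations=est.n_iter_,
        rss=est.rss_,
        bootstrap_ci=ci,
        objective_history=est.objective_history_,
    )


def bootstrap_K(
    design: CVDesign, table: ShiftTable, n_boot: int = 500, seed: int | None = None
) -> tuple:
    """Percentile 95% CI on K from bootstrap resampling of records."""
    X, y = _table_to_xy(design, table)
    rng = np.random.default_rng(seed)
    n = len(y)
    ks = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            ks[b] = NMRTitration().fit(X.iloc[idx], y[idx]).K_
        except ValueError:
            ks[b] = np.nan
    ks = ks[np.isfinite(ks)]
    return (float(np.percentile(ks, 2.5)), float(np.percentile(ks, 97.5)))
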