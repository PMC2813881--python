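"""Cooperative Hill fits to filter-partitioning binding data.

fraction RNA bound = A [P]^n / ([P]^n + K½^n)

where A is the total fraction of RNA bound (typically >= 0.95), [P] the
protein concentration, n the apparent Hill coefficient, and K½ the protein
concentration at half-maximal binding.  Fits are unweighted nonlinear least
squares with a deterministic multi-start over the Hill coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "BindingDataset",
    "HillFit",
    "hill_fraction_bound",
    "fit_hill",
    "goodness_of_fit",
]

# optimization bounds; the upper k bound prevents degenerate runaway
# solutions on flat data
_BOUNDS_LO = np.array([1e-9, 0.2, 1e-9])
_BOUNDS_HI = np.array([1.1, 6.0, 1e5])
_N_STARTS = (1.0, 2.0, 3.0)


@dataclass
class BindingDataset:
    """Filter-partitioning concentration series (nM) with fraction bound."""

    protein_concentration: np.ndarray
    fraction_bound: np.ndarray
    rna_concentration: float | None = None
    replicate: str | None = None

    def __post_init__(self) -> None:
        self.protein_concentration = np.asarray(self.protein_concentration, dtype=float)
        self.fraction_bound = np.asarray(self.fraction_bound, dtype=float)
        if len(self.protein_concentration) != len(self.fraction_bound):
            raise ValueError("concentration and fraction-bound lists differ in length")
        if np.any(self.protein_concentration <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.any(np.diff(self.protein_concentration) < 0):
            raise ValueError("concentrations must be sorted ascending")


@dataclass
class HillFit:
    """Fitted Hill parameters: A (total fraction bound), n (apparent Hill
    coefficient), K½ (nM), with the coefficient of determination."""

    A: float
    n: float
    k_half: float
    r_squared: float
    converged: bool
    message: str = ""

    def __post_init__(self) -> None:
        if self.converged:
            if not self.k_half > 0:
                raise ValueError("k_half must be > 0")
            if not self.n > 0:
                raise ValueError("n must be > 0")
            if not 0 < self.A <= 1.1:
                raise ValueError("A must lie in (0, 1.1]")
            if self.r_squared > 1 + 1e-12:
                raise ValueError("r_squared cannot exceed 1")


def _hill(p: np.ndarray, A: float, n: float, k_half: float) -> np.ndarray:
    pn = np.power(p, n)
    return A * pn / (pn + np.power(k_half, n))


def hill_fraction_bound(p, fit: HillFit) -> float | np.ndarray:
    """Evaluate the fitted Hill curve at protein concentration(s) ``p`` (nM)."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("protein concentration must be >= 0")
    out = np.where(p > 0, _hill(np.where(p > 0, p, 1.0), fit.A, fit.n, fit.k_half), 0.0)
    return float(out) if out.ndim == 0 else out


def fit_hill(data: BindingDataset, warn_rna_gate: bool = True) -> HillFit:
    """Least-squares Hill fit with deterministic multi-start initialization.

    Starting values: A0 = max observed fraction bound, K0 = the concentration
    whose response is nearest half-maximal, n0 in {1, 2, 3}.  The start with
    the lowest residual sum of squares wins; the ``converged`` flag reports
    the optimizer's own status honestly.
    """
    p = data.protein_concentration
    f = data.fraction_bound
    if len(p) < 5:
        raise ValueError("need >= 5 concentration points for a Hill fit")
    if p.max() / p.min() < 10:
        raise ValueError("concentrations must span at least one decade")

    a0 = float(np.clip(f.max(), 0.05, 1.1))
    k0 = float(p[np.argmin(np.abs(f - a0 / 2))])
    k0 = float(np.clip(k0, _BOUNDS_LO[2] * 10, _BOUNDS_HI[2] / 10))

    def resid(x: np.ndarray) -> np.ndarray:
        return _hill(p, *x) - f

    best = None
    for n0 in _N_STARTS:
        x0 = np.clip(np.array([a0, n0, k0]), _BOUNDS_LO + 1e-12, _BOUNDS_HI - 1e-12)
        try:
            res = least_squares(
                resid, x0, bounds=(_BOUNDS_LO, _BOUNDS_HI), method="trf",
                x_scale="jac", ftol=1e-13, xtol=1e-13, gtol=1e-13,
            )
        except Exception:  # a failed start is not fatal; others may converge
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        return HillFit(
            A=float("nan"), n=float("nan"), k_half=float("nan"),
            r_squared=float("nan"), converged=False,
            message="no multi-start converged",
        )
    A, n, k = (float(v) for v in best.x)
    ss_res = float(np.sum(best.fun**2))
    ss_tot = float(np.sum((f - f.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    fit = HillFit(A=A, n=n, k_half=k, r_squared=r2, converged=True, message=best.message)
    if warn_rna_gate and data.rna_concentration is not None:
        if data.rna_concentration > k / 5:
            fit.message += (
                f" [warning: RNA concentration {data.rna_concentration} nM exceeds "
                f"K1/2/5 = {k / 5:.3g} nM; binding regime, not titration regime]"
            )
    return fit


def goodness_of_fit(fit: HillFit, data: BindingDataset) -> float:
    """R² = 1 - SS_res/SS_tot of a converged fit against a dataset."""
    if not fit.converged:
        raise ValueError("fit did not converge; goodness of fit is undefined")
    f = data.fraction_bound
    ss_tot = float(np.sum((f - f.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero-variance data: R-squared is undefined")
    pred = _hill(data.protein_concentration, fit.A, fit.n, fit.k_half)
    ss_res = float(np.sum((f - pred) ** 2))
    return 1.0 - ss_res / ss_tot
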