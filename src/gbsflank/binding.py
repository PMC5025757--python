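"""Single-site equilibrium binding model and Kd estimation from EMSA data.

A protein P binding a single DNA site D with dissociation constant Kd
gives, when free protein is in excess over DNA (here 1.25 nM DNA against
micromolar protein, so total ~ free),

    fraction bound = [PD]/[D]t = 1 / (1 + Kd/[P]).

Kd is estimated by non-linear least squares on the isotherm, fitted in
log(Kd) so positivity needs no constraint.  A depletion-corrected variant
solves the quadratic mass balance exactly for cases where the free-ligand
approximation breaks down.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares


def fraction_bound(P, kd: float):
    """Fraction of DNA bound at free protein concentration(s) ``P`` (same units as kd)."""
    P = np.asarray(P, dtype=float)
    if kd <= 0:
        raise ValueError("kd must be positive")
    if np.any(P <= 0):
        raise ValueError("protein concentrations must be positive")
    return 1.0 / (1.0 + kd / P)


def fraction_bound_depleted(P_total, kd: float, d_total: float):
    """Depletion-corrected isotherm from the exact quadratic mass balance.

    With total protein ``P_total`` and total DNA ``d_total``,
    ``[PD] = ((Pt + Dt + Kd) - sqrt((Pt + Dt + Kd)^2 - 4*Pt*Dt)) / 2``.
    """
    P_total = np.asarray(P_total, dtype=float)
    if kd <= 0 or d_total <= 0:
        raise ValueError("kd and d_total must be positive")
    s = P_total + d_total + kd
    pd_ = (s - np.sqrt(s * s - 4.0 * P_total * d_total)) / 2.0
    return pd_ / d_total


@dataclass(frozen=True)
class KdFit:
    kd: float
    se: float
    rss: float
    converged: bool
    n_points: int


def _default_init(P, f) -> float:
    # Kd from the point nearest half-saturation; geometric mean fallback
    mask = (f > 0.02) & (f < 0.98)
    if mask.any():
        i = np.argmin(np.abs(f[mask] - 0.5))
        p0, f0 = P[mask][i], f[mask][i]
        return float(p0 * (1.0 / f0 - 1.0))
    return float(np.exp(np.mean(np.log(P))))


def fit_kd(
    P,
    f,
    kd_init: float | None = None,
    depletion_corrected: bool = False,
    d_total: float | None = None,
) -> KdFit:
    """Least-squares Kd from an isotherm ``(P, fraction bound)``.

    The optimisation runs in ``log(kd)``; the standard error comes from
    the Gauss-Newton curvature at the optimum.  Results are invariant to
    point ordering.  All-equal fractions are non-identifiable and return
    ``converged=False``.
    """
    P = np.asarray(P, dtype=float)
    f = np.asarray(f, dtype=float)
    if P.shape != f.shape or P.ndim != 1:
        raise ValueError("P and f must be 1-D arrays of equal length")
    if len(P) < 3:
        raise ValueError("need at least 3 titration points")
    if np.any(P <= 0):
        raise ValueError("protein concentrations must be positive")
    if not ((f < 0.5).any() and (f > 0.5).any()):
        warnings.warn("titration points do not bracket half-saturation; "
                      "Kd may be poorly constrained")
    if np.ptp(f) == 0:
        return KdFit(float("nan"), float("nan"),
                     float(np.sum((f - f.mean()) ** 2)), False, len(P))
    if depletion_corrected and d_total is None:
        raise ValueError("depletion-corrected fit needs d_total")

    def model(kd):
        if depletion_corrected:
            return fraction_bound_depleted(P, kd, d_total)
        return fraction_bound(P, kd)

    def resid(theta):
        return model(float(np.exp(theta[0]))) - f

    theta0 = np.log(kd_init if kd_init is not None else _default_init(P, f))
    sol = least_squares(resid, x0=[theta0], method="lm", xtol=1e-14, ftol=1e-14)
    kd = float(np.exp(sol.x[0]))
    rss = float(np.sum(sol.fun**2))
    jtj = float(np.sum(sol.jac**2))
    dof = max(len(P) - 1, 1)
    if jtj > 0:
        se_theta = np.sqrt(rss / dof / jtj)
        se = kd * float(se_theta)  # delta method from log-parameterisation
    else:
        se = float("nan")
    return KdFit(kd, se, rss, bool(sol.success), len(P))


def fit_kd_replicates(table: pd.DataFrame, **kwargs) -> tuple[pd.DataFrame, float, float]:
    """Fit each replicate separately; report per-replicate Kd and mean +/- sd.

    ``table`` has columns ``P_molar, fraction_bound, replicate``.
    """
    rows = []
    for rep, grp in table.groupby("replicate"):
        fit = fit_kd(grp["P_molar"].to_numpy(), grp["fraction_bound"].to_numpy(), **kwargs)
        rows.append((rep, fit.kd, fit.se, fit.rss, fit.converged, fit.n_points))
    fits = pd.DataFrame(rows, columns=["replicate", "kd", "se", "rss",
                                       "converged", "n_points"])
    good = fits.loc[fits["converged"], "kd"]
    mean = float(good.mean()) if len(good) else float("nan")
    sd = float(good.std(ddof=1)) if len(good) > 1 else float("nan")
    return fits, mean, sd
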