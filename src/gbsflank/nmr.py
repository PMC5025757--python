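"""Chemical shift perturbation (CSP) and titration line-broadening analysis.

A 1H-15N correlation spectrum gives one cross-peak per backbone amide.
Comparing two complex states, the per-residue CSP is the gyromagnetic-
ratio-normalised distance between peak positions,

    csp = sqrt(d_dH**2 + (gamma_ratio * d_dN)**2)        [ppm]

with ``gamma_ratio = |gamma_15N / gamma_1H|`` (0.1014 by default; an
optional overall 1/sqrt(2) factor covers the alternative convention).
Residues exceeding ``mean + k*sd`` of the defined CSPs (k = 1 by default)
are flagged significant.  Residues with more than one peak in a state
("split peaks", a signature of multiple conformations) are matched by
nearest neighbour in the normalised shift space and flagged.

Titration analysis follows imino-proton intensities along a protein:DNA
ratio series: all protons bound by the same complex broaden similarly, so
a proton whose normalised decay deviates from the cross-proton median by
more than ``k`` median absolute deviations is reported as an outlier
(specific extra broadening, e.g. a contacted base pair).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

GAMMA_RATIO_15N_1H = 0.1014


@dataclass(frozen=True)
class CspConfig:
    gamma_ratio: float = GAMMA_RATIO_15N_1H
    cutoff_sd: float = 1.0
    sqrt2_norm: bool = False  # divide by sqrt(2) (alternative convention)

    def __post_init__(self):
        if not 0 < self.gamma_ratio < 1:
            raise ValueError("gamma_ratio must be in (0, 1)")


def csp_value(d_dH: float, d_dN: float, config: CspConfig = CspConfig()) -> float:
    """Normalised CSP for given 1H and 15N shift differences (ppm)."""
    v = float(np.hypot(d_dH, config.gamma_ratio * d_dN))
    return v / np.sqrt(2.0) if config.sqrt2_norm else v


def csp_profile(
    list_a: pd.DataFrame,
    list_b: pd.DataFrame,
    config: CspConfig = CspConfig(),
) -> tuple[pd.DataFrame, float]:
    """Per-residue CSP between two assigned peak lists, with significance.

    Peak lists are frames with columns ``residue, dH, dN`` (``aa``,
    ``intensity`` optional).  When a residue carries several peaks in a
    state the CSP is taken from the nearest-neighbour pairing in
    ``(dH, gamma_ratio*dN)`` space (the minimal pairwise distance) and all
    pairwise distances are reported in ``all_pairings``; ``split_a`` /
    ``split_b`` flag multiplicity.  Residues present in only one list get
    NaN CSP.  The significance cutoff is ``mean + cutoff_sd * sd`` over
    defined CSPs; significant iff ``csp > cutoff``.

    Returns ``(records, cutoff)``.
    """
    res_a = set(list_a["residue"])
    res_b = set(list_b["residue"])
    if not res_a & res_b:
        raise ValueError("peak lists share no residues")
    aa_map = {}
    for df in (list_a, list_b):
        if "aa" in df.columns:
            aa_map.update(dict(zip(df["residue"], df["aa"])))
    rows = []
    for res in sorted(res_a | res_b):
        pa = list_a[list_a["residue"] == res]
        pb = list_b[list_b["residue"] == res]
        if pa.empty or pb.empty:
            rows.append((res, aa_map.get(res, ""), np.nan, False,
                         len(pa) > 1, len(pb) > 1, ""))
            continue
        d_h = pa["dH"].to_numpy()[:, None] - pb["dH"].to_numpy()[None, :]
        d_n = pa["dN"].to_numpy()[:, None] - pb["dN"].to_numpy()[None, :]
        dist = np.hypot(d_h, config.gamma_ratio * d_n)
        if config.sqrt2_norm:
            dist = dist / np.sqrt(2.0)
        csp = float(dist.min())
        pairings = ";".join(f"{v:.4f}" for v in sorted(dist.ravel()))
        rows.append((res, aa_map.get(res, ""), csp, False,
                     len(pa) > 1, len(pb) > 1, pairings))
    df = pd.DataFrame(rows, columns=["residue", "aa", "csp", "significant",
                                     "split_a", "split_b", "all_pairings"])
    defined = df["csp"].dropna()
    if len(defined) >= 2:
        cutoff = float(defined.mean() + config.cutoff_sd * defined.std(ddof=1))
    elif len(defined) == 1:
        cutoff = float(defined.iloc[0])
    else:
        cutoff = float("nan")
    df["significant"] = df["csp"] > cutoff
    return df, cutoff


# ------------------------------------------------------------- titration

def titration_broadening(
    series: pd.DataFrame,
    k_mad: float = 3.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summarise per-proton intensity decay along a titration and flag outliers.

    ``series`` is a long frame ``proton, ratio, intensity`` with at least
    three points per proton on a strictly increasing ratio grid; the first
    (lowest-ratio, typically free-DNA) point is the normalisation
    reference.  The summary statistic is the span-normalised area under
    the ``I(r)/I(0)`` curve; a proton is an outlier when its summary
    deviates from the cross-proton median by more than ``k_mad`` median
    absolute deviations.

    Returns ``(summary, curves)`` where curves carries the normalised
    intensities point by point.
    """
    summaries = []
    curves = []
    for proton, grp in series.groupby("proton", sort=False):
        grp = grp.sort_values("ratio")
        r = grp["ratio"].to_numpy(float)
        i = grp["intensity"].to_numpy(float)
        if len(r) < 3:
            raise ValueError(f"proton {proton!r}: need >= 3 titration points")
        if not np.all(np.diff(r) > 0):
            raise ValueError(f"proton {proton!r}: ratio grid not strictly increasing")
        if i[0] <= 0:
            raise ValueError(f"proton {proton!r}: reference intensity must be positive")
        norm = i / i[0]
        auc = float(np.trapezoid(norm, r) / (r[-1] - r[0]))
        summaries.append((proton, auc))
        for rr, nn in zip(r, norm):
            curves.append((proton, rr, nn))
    summary = pd.DataFrame(summaries, columns=["proton", "auc"])
    med = summary["auc"].median()
    mad = float(np.median(np.abs(summary["auc"] - med)))
    tol = k_mad * mad + 1e-9 * max(1.0, abs(med))
    summary["outlier"] = (summary["auc"] - med).abs() > tol
    curve_df = pd.DataFrame(curves, columns=["proton", "ratio", "normalized"])
    return summary, curve_df
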