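"""Responder stratification and peak-to-gene association.

Genes that respond to glucocorticoid treatment are split into *strong*
responders (the top fraction of significantly regulated genes ranked by
log2 fold change, ceiling rounding so that 20% of 1,447 genes gives 290)
and *weak* responders (significant genes whose absolute log2 fold change
stays at or below a small threshold, 0.72 by default).  ChIP-seq peaks are
then linked to a gene whenever the peak midpoint falls inside a window
(40 kb by default) centred on the gene's transcription start site.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_TOP_FRACTION = 0.2
DEFAULT_WEAK_ABS_LFC = 0.72
DEFAULT_ALPHA = 0.05
DEFAULT_WINDOW_BP = 40_000


@dataclass(frozen=True)
class GeneGroup:
    """A named set of gene ids with the stratification parameters attached."""

    label: str
    gene_ids: frozenset = field(default_factory=frozenset)
    params: tuple = ()

    def __len__(self) -> int:
        return len(self.gene_ids)


def stratify_genes(
    table: pd.DataFrame,
    top_fraction: float = DEFAULT_TOP_FRACTION,
    weak_abs_lfc: float = DEFAULT_WEAK_ABS_LFC,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[GeneGroup, GeneGroup]:
    """Split an expression table into strong and weak responder gene groups.

    Parameters
    ----------
    table
        DataFrame with columns ``gene_id``, ``log2_fc``, ``adj_p``.
    top_fraction
        Fraction of significant genes (ranked by ``log2_fc`` descending)
        forming the strong group; the cut uses ceiling rounding.
    weak_abs_lfc
        Weak responders satisfy ``|log2_fc| <= weak_abs_lfc``.
    alpha
        Only rows with ``adj_p < alpha`` are considered at all.

    Returns
    -------
    (strong, weak)
        Disjoint :class:`GeneGroup` objects; a gene qualifying for both by
        arithmetic accident is assigned to strong only.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    sig = table[table["adj_p"] < alpha]
    if len(sig) == 0:
        raise ValueError("no significant genes at adjusted p < %g" % alpha)
    n_strong = math.ceil(top_fraction * len(sig))
    # ties at the cut boundary broken by gene_id for determinism
    ranked = sig.sort_values(["log2_fc", "gene_id"], ascending=[False, True])
    strong_ids = frozenset(ranked["gene_id"].iloc[:n_strong])
    weak_mask = sig["log2_fc"].abs() <= weak_abs_lfc
    weak_ids = frozenset(sig.loc[weak_mask, "gene_id"]) - strong_ids
    params = (top_fraction, weak_abs_lfc, alpha)
    return (
        GeneGroup("strong", strong_ids, params),
        GeneGroup("weak", weak_ids, params),
    )


def tss_position(row) -> int:
    """TSS of a BED6 gene record: start for '+' strand, end-1 otherwise.

    For single-base TSS records (end == start + 1) the two conventions
    coincide.
    """
    return int(row["start"]) if row["strand"] != "-" else int(row["end"]) - 1


def associate_peaks_to_genes(
    peaks: pd.DataFrame,
    tss: pd.DataFrame,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> pd.DataFrame:
    """Associate ChIP-seq peaks with genes whose TSS window contains them.

    A peak (BED6 frame, ``name`` = peak id) is associated with a gene
    (BED6 frame of TSS records, ``name`` = gene id) iff its midpoint
    ``floor((start+end)/2)`` lies in the half-open interval
    ``[tss - window/2, tss + window/2)``.  A peak may associate with
    several genes and vice versa.

    Returns a DataFrame ``peak_id, gene_id, distance`` where distance is
    signed bp from TSS to peak midpoint, positive downstream of the TSS on
    the gene's strand.
    """
    if window_bp <= 0 or window_bp % 2:
        raise ValueError("window_bp must be positive and even")
    half = window_bp // 2

    peak_chroms = set(peaks["chrom"])
    tss_chroms = set(tss["chrom"])
    for c in sorted(peak_chroms - tss_chroms):
        warnings.warn(f"peak chromosome {c!r} absent from TSS annotation; "
                      "no associations emitted for it")

    out = []
    tss = tss.copy()
    tss["pos"] = [tss_position(r) for _, r in tss.iterrows()]
    for chrom, tgrp in tss.groupby("chrom"):
        pgrp = peaks[peaks["chrom"] == chrom]
        if pgrp.empty:
            continue
        order = np.argsort(tgrp["pos"].to_numpy(), kind="stable")
        tpos = tgrp["pos"].to_numpy()[order]
        tid = tgrp["name"].to_numpy()[order]
        tstrand = tgrp["strand"].to_numpy()[order]
        mids = ((pgrp["start"].to_numpy() + pgrp["end"].to_numpy()) // 2)
        # mid in [tss-half, tss+half)  <=>  tss in (mid-half, mid+half]
        lo = np.searchsorted(tpos, mids - half, side="right")
        hi = np.searchsorted(tpos, mids + half, side="right")
        for pk, mid, a, b in zip(pgrp["name"], mids, lo, hi):
            for j in range(a, b):
                d = int(mid - tpos[j])
                if tstrand[j] == "-":
                    d = -d
                out.append((pk, tid[j], d))
    return pd.DataFrame(out, columns=["peak_id", "gene_id", "distance"])


def association_summary(assoc: pd.DataFrame, strong: GeneGroup, weak: GeneGroup) -> pd.DataFrame:
    """Count distinct peaks associated with each responder group."""
    rows = []
    for grp in (strong, weak):
        sub = assoc[assoc["gene_id"].isin(grp.gene_ids)]
        rows.append((grp.label, len(grp), sub["peak_id"].nunique(), len(sub)))
    return pd.DataFrame(rows, columns=["group", "n_genes", "n_peaks", "n_associations"])
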