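"""Stratify responder genes and associate peaks within 40-kb TSS windows.

Splits the significantly regulated genes into strong responders (top 20%
by log2 fold change, ceiling rule) and weak responders (|log2FC| <= 0.72),
then links each peak to every gene whose TSS lies within 20 kb of the
peak midpoint.  Writes the association table and a per-group summary.
"""
import pandas as pd

import gbsflank as gf
from _common import RESULTS, cohort, ensure_dirs


def main():
    ensure_dirs()
    fx = cohort()
    strong, weak = gf.stratify_genes(fx.expression)
    n_sig = (fx.expression.adj_p < 0.05).sum()
    print(f"significant genes: {n_sig}; strong responders: {len(strong)} "
          f"(top 20%); weak responders: {len(weak)} (|log2FC| <= 0.72)")

    peaks = pd.concat([fx.strong_peaks, fx.weak_peaks], ignore_index=True)
    assoc = gf.associate_peaks_to_genes(peaks, fx.tss, window_bp=40_000)
    summary = gf.association_summary(assoc, strong, weak)
    print(summary.to_string(index=False))

    group_of = {g: "strong" for g in strong.gene_ids}
    group_of.update({g: "weak" for g in weak.gene_ids})
    assoc["group"] = assoc.gene_id.map(group_of).fillna("other")
    gf.io.write_tsv(RESULTS / "associations.tsv", assoc)
    gf.io.write_tsv(RESULTS / "association_summary.tsv", summary)
    print(f"wrote {RESULTS / 'associations.tsv'} ({len(assoc)} rows)")


if __name__ == "__main__":
    main()
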