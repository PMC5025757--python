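"""CSP profile between two complex states and imino-proton titration.

Plants chemical-shift perturbations at DBD residues reported to respond
to the flank swap (T456, C460, R488, N497, M505, L507, K511, T512, K514)
plus split peaks in the DNA-recognition helix (G458, C460, K461), runs
the CSP analysis with the mean + 1 s.d. cutoff, and checks recovery.
The titration stage plants one imino proton (G46-like, position -9) with
twice the generic line broadening and asks the MAD outlier rule to find it.
"""
import numpy as np
import pandas as pd

import gbsflank as gf
from _common import RESULTS, ensure_dirs

PLANTED = frozenset({456, 460, 488, 497, 505, 507, 511, 512, 514})
SPLIT = frozenset({458, 460, 461})


def main():
    ensure_dirs()
    spec = gf.NmrFixtureSpec(
        seed=1, shifted_residues=PLANTED, split_residues=SPLIT,
        planted_dH=0.08, planted_dN=0.5, noise_sd=0.008,
    )
    list_a, list_b = gf.make_nmr_fixture(spec)
    records, cutoff = gf.csp_profile(list_a, list_b)
    sig = sorted(records.loc[records.significant, "residue"])
    split = sorted(records.loc[records.split_b, "residue"])
    print(f"CSP cutoff (mean + 1 s.d.): {cutoff:.4f} ppm")
    print(f"significant residues: {sig}")
    print(f"recovered planted set: {set(sig) == set(PLANTED)}")
    print(f"split peaks flagged in state B: {split}")
    gf.io.write_tsv(RESULTS / "csp_profile.tsv", records, seed=spec.seed)

    # imino-proton titration along the published ratio grid
    ratios = np.array(gf.synthetic.TITRATION_RATIOS)
    protons = [f"pos{i}" for i in (-9, -6, -4, -3, 2, 4, 6, 8, 10, 12, 14)]
    rows = []
    rng = np.random.default_rng(2)
    for proton in protons:
        lam = 1.6 if proton == "pos-9" else 0.8  # G46-like extra broadening
        for r in ratios:
            rows.append((proton, r, float(np.exp(-lam * r)
                                          * (1 + rng.normal(0, 0.03)))))
    series = pd.DataFrame(rows, columns=["proton", "ratio", "intensity"])
    summary, _ = gf.titration_broadening(series)
    out = sorted(summary.loc[summary.outlier, "proton"])
    print(f"\ntitration outliers by the 3-MAD rule: {out}")
    print(f"planted fast-broadening proton pos-9 flagged: {'pos-9' in out}")
    if set(out) - {"pos-9"}:
        print("note: with only 11 protons the MAD of a homogeneous null is "
              "small, so borderline extras can cross 3 MAD")
    gf.io.write_tsv(RESULTS / "titration_broadening.tsv", summary, seed=2)


if __name__ == "__main__":
    main()
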