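"""Shared wiring for the numbered analysis drivers."""
from pathlib import Path

import gbsflank as gf

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

#: the stated cohort: 1,447 significantly regulated genes, 500 peaks per
#: responder group, one planted GBS per peak with 0.9 flank-class bias
COHORT_SPEC = gf.RegulatoryFixtureSpec(seed=1)


def cohort() -> gf.synthetic.RegulatoryFixture:
    """Deterministic in-memory regeneration of the analysis cohort."""
    return gf.make_regulatory_fixture(COHORT_SPEC)


def cgt_matrix():
    pwm = gf.build_pwm([COHORT_SPEC.motif_core], pseudocount=1.0)
    cutoff = gf.score_threshold(pwm, 1e-4)
    return pwm, cutoff


def ensure_dirs():
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
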