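import numpy as np
import pandas as pd
import pytest

from gbsflank import (
    CGT_CORE,
    RegulatoryFixtureSpec,
    build_pwm,
    make_regulatory_fixture,
    score_threshold,
    synthetic_shape_table,
)


@pytest.fixture(scope="session")
def cgt_pwm():
    """Single-site consensus matrix for the Cgt GBS core."""
    return build_pwm([CGT_CORE], pseudocount=1.0)


@pytest.fixture(scope="session")
def cgt_cutoff(cgt_pwm):
    return score_threshold(cgt_pwm, 1e-4)


@pytest.fixture(scope="session")
def small_fixture():
    """Desk-scale regulatory fixture shared across motif/shape tests."""
    spec = RegulatoryFixtureSpec(
        seed=3, n_genes=300, n_significant=150, chrom_length=2_000_000,
        n_peaks_per_group=40, peak_len=120,
    )
    return make_regulatory_fixture(spec)


@pytest.fixture(scope="session")
def mgw_table():
    return synthetic_shape_table("MGW")


def random_seqs(rng, n, length):
    return {
        f"s{i:04d}": "".join(rng.choice(list("ACGT"), size=length))
        for i in range(n)
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
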