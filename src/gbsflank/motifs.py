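"""Motif discovery, PWM scanning and flank-class enrichment.

The glucocorticoid receptor binding sequence (GBS) is a 15-bp core of two
6-bp inverted-repeat half-sites around a 3-bp spacer.  Positions are
labelled relative to the spacer centre (0): the core spans -7..+7 and the
*proximal flanks* are the single letters at -8 and +8.  A match is classed

* ``WW`` when both flanks are weak base pairs (A/T),
* ``SS`` when both are strong (G/C),
* ``mixed`` otherwise, and
* ``edge`` when the 17-letter window sticks out of the sequence.

Scanning uses a log-odds PWM with a score cutoff derived from an exact
null-score distribution (column-wise dynamic programming over the
background model), mirroring matrix-scan style p-value thresholds.
De novo discovery is a simplified spaced-dyad over-representation test
with a binomial null.
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

from ._seq import BASES, N_IDX, encode, revcomp

UNIFORM_BG = np.full(4, 0.25)

#: Cgt GBS core used throughout the worked examples (spacer TTT at -1..+1)
CGT_CORE = "AGAACATTTTGTACG"

SCAN_COLUMNS = ["seq_id", "offset", "strand", "score", "window17",
                "flank5", "flank3", "flank_class"]


# =================================================================== PWM

@dataclass(frozen=True)
class Pwm:
    """Position weight matrix (rows A, C, G, T) with background model.

    ``counts`` are raw (or fractional) observation counts; frequencies are
    regularised with ``pseudocount`` distributed according to the
    background: ``freq = (count + pseudocount*bg) / (n + pseudocount)``.
    Log-odds scores are in bits.
    """

    counts: np.ndarray
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BG.copy())
    pseudocount: float = 1.0

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x width matrix")
        if counts.min() < 0 or self.pseudocount < 0:
            raise ValueError("counts and pseudocount must be non-negative")
        if not math.isclose(bg.sum(), 1.0, abs_tol=1e-9) or bg.min() <= 0:
            raise ValueError("background must be a positive probability vector")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "background", bg)

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def frequencies(self) -> np.ndarray:
        n = self.counts.sum(axis=0)
        return (self.counts + self.pseudocount * self.background[:, None]) / (
            n + self.pseudocount
        )

    @property
    def log_odds(self) -> np.ndarray:
        """log2(freq/background); -inf where the frequency is zero."""
        with np.errstate(divide="ignore"):
            return np.log2(self.frequencies / self.background[:, None])

    @property
    def information_content(self) -> np.ndarray:
        """Per-column information content in bits (relative entropy to bg)."""
        f = self.frequencies
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(f > 0, f * np.log2(f / self.background[:, None]), 0.0)
        return term.sum(axis=0)

    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    def min_score(self) -> float:
        return float(self.log_odds.min(axis=0).sum())


def build_pwm(site_windows, pseudocount: float = 1.0, background=None) -> Pwm:
    """Build a PWM from equal-width aligned sites (list of strings)."""
    sites = list(site_windows)
    if not sites:
        raise ValueError("empty site set")
    w = len(sites[0])
    if any(len(s) != w for s in sites):
        raise ValueError("all site windows must have the same width")
    bg = UNIFORM_BG.copy() if background is None else np.asarray(background, float)
    counts = np.zeros((4, w))
    for s in sites:
        e = encode(s)
        if (e == N_IDX).any():
            raise ValueError(f"site contains non-ACGT letters: {s!r}")
        counts[e, np.arange(w)] += 1
    return Pwm(counts, bg, pseudocount)


def parse_transfac(text: str, pseudocount: float = 1.0, background=None) -> Pwm:
    """Parse a TRANSFAC-style count matrix (``P0``/``PO`` header, rows 01..)."""
    bg = UNIFORM_BG.copy() if background is None else np.asarray(background, float)
    rows = []
    order = None
    for line in text.splitlines():
        parts = line.split()
        if not parts:
            continue
        tag = parts[0].upper()
        if tag in ("P0", "PO"):
            order = [p.upper() for p in parts[1:5]]
        elif tag[:2].isdigit() and order is not None:
            rows.append([float(x) for x in parts[1:5]])
    if order is None or not rows:
        raise ValueError("not a TRANSFAC count matrix")
    mat = np.zeros((4, len(rows)))
    for j, vals in enumerate(rows):
        for letter, v in zip(order, vals):
            mat[BASES.index(letter), j] = v
    return Pwm(mat, bg, pseudocount)


def parse_tab_matrix(text: str, pseudocount: float = 1.0, background=None) -> Pwm:
    """Parse a simple tab matrix: four lines ``A/C/G/T <tab> counts...``."""
    bg = UNIFORM_BG.copy() if background is None else np.asarray(background, float)
    mat = {}
    for line in text.splitlines():
        parts = line.replace(":", " ").split()
        if parts and parts[0].upper() in "ACGT" and len(parts[0]) == 1:
            mat[parts[0].upper()] = [float(x) for x in parts[1:]]
    if set(mat) != set("ACGT"):
        raise ValueError("tab matrix must provide rows A, C, G and T")
    return Pwm(np.array([mat[b] for b in BASES]), bg, pseudocount)


def background_from_seqs(seqs: Mapping[str, str]) -> np.ndarray:
    """Zero-order background letter frequencies over both strands."""
    counts = np.zeros(4)
    for s in seqs.values():
        e = encode(s)
        counts += np.bincount(e[e < 4], minlength=4)
    counts += counts[::-1]  # strand symmetry: A<->T, C<->G under revcomp
    if counts.sum() == 0:
        raise ValueError("no ACGT letters in sequences")
    return counts / counts.sum()


# ============================================== exact score distribution

def score_distribution(pwm: Pwm, resolution: float = 0.01):
    """Exact discretised null distribution of PWM scores under background.

    Column scores are rounded to ``resolution``-bit bins and convolved
    across columns weighted by background probabilities.  Returns
    ``(scores, probs)`` sorted ascending; probabilities sum to 1.
    """
    lo = pwm.log_odds
    if not np.isfinite(lo).all():
        raise ValueError("log-odds contain -inf; use a positive pseudocount")
    bins = np.round(lo / resolution).astype(np.int64)
    bg = pwm.background
    offset = 0  # value of probs[0] in bins
    probs = np.array([1.0])
    for j in range(pwm.width):
        col = bins[:, j]
        lo_b, hi_b = col.min(), col.max()
        new = np.zeros(len(probs) + (hi_b - lo_b))
        for b in range(4):
            sh = col[b] - lo_b
            new[sh : sh + len(probs)] += probs * bg[b]
        probs = new
        offset += lo_b
    scores = (offset + np.arange(len(probs))) * resolution
    keep = probs > 0
    return scores[keep], probs[keep]


def score_threshold(pwm: Pwm, p_value: float, resolution: float = 0.01) -> float:
    """Smallest achievable score whose upper-tail probability is <= p_value.

    The null distribution is computed exactly by dynamic programming over
    the background model, with scores discretised at ``resolution`` bits.
    If ``p_value`` is below the smallest achievable tail mass the maximum
    score plus one bin is returned with a warning (nothing can match).
    """
    if not 0 < p_value <= 1:
        raise ValueError("p_value must be in (0, 1]")
    scores, probs = score_distribution(pwm, resolution)
    tail = np.cumsum(probs[::-1])[::-1]  # P(S >= scores[i])
    ok = tail <= p_value
    if not ok.any():
        warnings.warn(
            f"p_value={p_value:g} below minimal achievable tail "
            f"{tail[-1]:.3g}; returning max score + resolution"
        )
        return float(pwm.max_score() + resolution)
    return float(scores[np.argmax(ok)])


# =================================================================== scan

@dataclass(frozen=True)
class GbsPositionScheme:
    """Spacer-centred GBS coordinates: core -7..+7, flanks at +/-8."""

    half_width: int = 8

    @property
    def labels(self) -> list[int]:
        return list(range(-self.half_width, self.half_width + 1))

    def window_pad(self, pwm_width: int) -> int:
        """Extra letters needed on each side of the core."""
        if pwm_width % 2 == 0:
            raise ValueError("GBS core width must be odd (spacer centre at 0)")
        pad = self.half_width - (pwm_width - 1) // 2
        if pad < 0:
            raise ValueError("PWM wider than the position scheme")
        return pad


GBS_SCHEME = GbsPositionScheme()


def classify_flanks(flank5: str, flank3: str) -> str:
    both = flank5 + flank3
    if all(c in "AT" for c in both):
        return "WW"
    if all(c in "GC" for c in both):
        return "SS"
    return "mixed"


def _strand_scores(enc: np.ndarray, lo_ext: np.ndarray, width: int) -> np.ndarray:
    if len(enc) < width:
        return np.empty(0)
    win = sliding_window_view(enc, width)
    return lo_ext[win, np.arange(width)].sum(axis=1)


def scan_sequences(
    seqs: Mapping[str, str],
    pwm: Pwm,
    cutoff: float,
    scheme: GbsPositionScheme = GBS_SCHEME,
) -> pd.DataFrame:
    """Scan both strands for PWM matches scoring at or above ``cutoff``.

    Offsets are 0-based starts of the core on the forward strand; for
    minus-strand matches the reported window/flank letters are the
    reverse complement (i.e. read along the match orientation).  Windows
    extending past the sequence ends get ``flank_class='edge'``.
    N-containing cores score ``-inf`` and never match.  All overlapping
    matches are reported.
    """
    w = pwm.width
    pad = scheme.window_pad(w)
    lo_ext = np.vstack([pwm.log_odds, np.full((1, w), -np.inf)])
    rows = []
    for sid, seq in seqs.items():
        seq = seq.upper()
        L = len(seq)
        enc_f = encode(seq)
        for strand in "+-":
            enc = enc_f if strand == "+" else encode(revcomp(seq))
            scores = _strand_scores(enc, lo_ext, w)
            for off in np.nonzero(scores >= cutoff)[0]:
                fwd_off = int(off) if strand == "+" else L - w - int(off)
                a, b = int(off) - pad, int(off) + w + pad
                if a < 0 or b > L:
                    window = flank5 = flank3 = None
                    klass = "edge"
                else:
                    oriented = seq if strand == "+" else revcomp(seq)
                    window = oriented[a:b]
                    flank5, flank3 = window[0], window[-1]
                    klass = classify_flanks(flank5, flank3)
                rows.append((sid, fwd_off, strand, float(scores[off]),
                             window, flank5, flank3, klass))
    df = pd.DataFrame(rows, columns=SCAN_COLUMNS)
    return df.sort_values(["seq_id", "offset", "strand"], ignore_index=True)


# ================================================== spaced-dyad discovery

def _word_indices(enc: np.ndarray, k: int) -> np.ndarray:
    """Base-4 index of each k-mer; -1 where any letter is non-ACGT."""
    if len(enc) < k:
        return np.empty(0, dtype=np.int64)
    win = sliding_window_view(enc, k).astype(np.int64)
    bad = (win >= 4).any(axis=1)
    idx = (win * (4 ** np.arange(k - 1, -1, -1))).sum(axis=1)
    idx[bad] = -1
    return idx


def dyad_enrichment(
    seqs: Mapping[str, str],
    monad_len: int = 3,
    max_spacing: int = 20,
    background=None,
) -> pd.DataFrame:
    """Rank spaced dyads (word-N{s}-word) by binomial over-representation.

    Occurrences are counted on both strands over all sequences.  For each
    (monad5, monad3, spacing) the p-value is the upper-tail binomial with
    n = number of available positions and success probability the product
    of the zero-order background probabilities of the two words; the
    e-value multiplies by the number of dyads tested and
    ``sig = -log10(e_value)``.
    """
    need = 2 * monad_len + max_spacing
    for sid, s in seqs.items():
        if len(s) < need:
            raise ValueError(f"sequence {sid!r} shorter than 2*monad+max_spacing")
    bg = background_from_seqs(seqs) if background is None else np.asarray(background, float)
    if bg.min() <= 0:
        raise ValueError("degenerate background: zero-probability letter")
    n_words = 4 ** monad_len
    # zero-order word probabilities
    word_p = np.ones(n_words)
    for widx in range(n_words):
        x, p = widx, 1.0
        for _ in range(monad_len):
            p *= bg[x % 4]
            x //= 4
        word_p[widx] = p
    enc_both = []
    for s in seqs.values():
        enc_both.append(encode(s))
        enc_both.append(encode(revcomp(s)))
    widx_all = [_word_indices(e, monad_len) for e in enc_both]

    records = []
    n_dyads_tested = n_words * n_words * (max_spacing + 1)
    for spacing in range(max_spacing + 1):
        counts = np.zeros(n_words * n_words, dtype=np.int64)
        n_pos = 0
        gap = monad_len + spacing
        for widx in widx_all:
            if len(widx) <= gap:
                continue
            a = widx[: len(widx) - gap]
            b = widx[gap:]
            valid = (a >= 0) & (b >= 0)
            n_pos += int(valid.sum())
            combined = a[valid] * n_words + b[valid]
            counts += np.bincount(combined, minlength=n_words * n_words)
        p_dyad = np.repeat(word_p, n_words) * np.tile(word_p, n_words)
        pvals = stats.binom.sf(counts - 1, n_pos, p_dyad)
        evals = np.minimum(pvals * n_dyads_tested, np.inf)
        expected = n_pos * p_dyad
        for d in range(n_words * n_words):
            m5, m3 = _decode_word(d // n_words, monad_len), _decode_word(d % n_words, monad_len)
            records.append((m5, m3, spacing, int(counts[d]), expected[d],
                            float(pvals[d]), float(evals[d])))
    df = pd.DataFrame(records, columns=["monad5", "monad3", "spacing",
                                        "observed", "expected", "p_value", "e_value"])
    with np.errstate(divide="ignore"):
        df["sig"] = -np.log10(df["e_value"])
    return df.sort_values(["sig", "p_value", "monad5", "monad3", "spacing"],
                          ascending=[False, True, True, True, True],
                          ignore_index=True)


def _decode_word(idx: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[idx % 4])
        idx //= 4
    return "".join(reversed(out))


# =========================================== flank enrichment / peak height

@dataclass(frozen=True)
class FlankEnrichment:
    """Differential WW/SS match-rate statistic with permutation p-value.

    ``delta = (rate_strong_WW - rate_weak_WW) - (rate_strong_SS - rate_weak_SS)``
    where rates are matches per peak.  The null shuffles peak-group labels;
    ``perm_p`` uses the add-one correction.  This statistic stands in for
    RSAT matrix-quality normalized weight differences and is not identical
    to it.
    """

    rate_strong_W: float
    rate_weak_W: float
    rate_strong_S: float
    rate_weak_S: float
    delta: float
    perm_p: float
    n_perm: int
    seed: int


def _per_seq_class_counts(seqs: Mapping[str, str], pwm: Pwm, cutoff: float):
    hits = scan_sequences(seqs, pwm, cutoff)
    ww = np.zeros(len(seqs))
    ss = np.zeros(len(seqs))
    index = {sid: i for i, sid in enumerate(seqs)}
    for sid, klass in zip(hits["seq_id"], hits["flank_class"]):
        if klass == "WW":
            ww[index[sid]] += 1
        elif klass == "SS":
            ss[index[sid]] += 1
    return ww, ss


def _delta_stat(ww, ss, labels):
    s, k = labels, ~labels
    return (ww[s].mean() - ww[k].mean()) - (ss[s].mean() - ss[k].mean())


def flank_enrichment(
    strong_seqs: Mapping[str, str],
    weak_seqs: Mapping[str, str],
    pwm: Pwm,
    cutoff: float,
    n_perm: int = 1000,
    seed: int = 0,
) -> FlankEnrichment:
    """Test whether WW-flanked matches are enriched in strong-group peaks."""
    if not strong_seqs or not weak_seqs:
        raise ValueError("both peak sets must be non-empty")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse permutation p-value")
    ww_s, ss_s = _per_seq_class_counts(strong_seqs, pwm, cutoff)
    ww_w, ss_w = _per_seq_class_counts(weak_seqs, pwm, cutoff)
    ww = np.concatenate([ww_s, ww_w])
    ss = np.concatenate([ss_s, ss_w])
    labels = np.zeros(len(ww), dtype=bool)
    labels[: len(ww_s)] = True
    observed = _delta_stat(ww, ss, labels)
    rng = np.random.default_rng(seed)
    exceed = 0
    lab = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(lab)
        if _delta_stat(ww, ss, lab) >= observed:
            exceed += 1
    perm_p = (1 + exceed) / (n_perm + 1)
    return FlankEnrichment(
        rate_strong_W=float(ww_s.mean()), rate_weak_W=float(ww_w.mean()),
        rate_strong_S=float(ss_s.mean()), rate_weak_S=float(ss_w.mean()),
        delta=float(observed), perm_p=float(perm_p), n_perm=n_perm, seed=seed,
    )


def peak_height_by_flank(
    peaks: pd.DataFrame,
    seqs: Mapping[str, str],
    pwm: Pwm,
    cutoff: float,
) -> pd.DataFrame:
    """Median peak height for WW-only vs SS-only flanked peaks.

    ``peaks`` is a BED6-like frame whose ``name`` keys into ``seqs`` and
    whose ``score`` column carries the peak height.  Peaks with at least
    one WW match and no SS match form the WW group (symmetrically for SS);
    peaks with both classes, only mixed/edge matches, or no match at all
    are excluded.  Returns a frame ``flank_class, median_height, n_peaks``
    with NaN medians for empty classes.
    """
    if peaks["score"].isna().any():
        raise ValueError("peak heights missing")
    hits = scan_sequences(seqs, pwm, cutoff)
    has = hits.groupby("seq_id")["flank_class"].agg(set).to_dict()
    groups = {"WW": [], "SS": []}
    for _, row in peaks.iterrows():
        classes = has.get(row["name"], set())
        if "WW" in classes and "SS" not in classes:
            groups["WW"].append(float(row["score"]))
        elif "SS" in classes and "WW" not in classes:
            groups["SS"].append(float(row["score"]))
    rows = [
        (k, float(np.median(v)) if v else float("nan"), len(v))
        for k, v in groups.items()
    ]
    return pd.DataFrame(rows, columns=["flank_class", "median_height", "n_peaks"])


# ------------------------------------------------- worked-example duplexes

SIM_PAD5 = "CACC"
SIM_PAD3 = "CTC"


def simulation_duplex(flank5: str, flank3: str, core: str = CGT_CORE) -> str:
    """24-nt strand used in the structural simulations of the Cgt GBS.

    The 15-bp core is extended by the proximal flank letters and B-form
    padding (CACC- 5', -CTC 3'), giving e.g. the A/T variant
    ``CACCAAGAACATTTTGTACGTCTC``.
    """
    if len(flank5) != 1 or len(flank3) != 1:
        raise ValueError("flanks are single letters")
    return SIM_PAD5 + flank5 + core + flank3 + SIM_PAD3
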