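"""Seeded synthetic fixtures with the statistical structure of the study.

The regulatory fixture emulates a dexamethasone-response experiment in a
cell line: an expression table with a pool of significantly regulated
genes (1,447 by default, so the top-20% strong-responder cut yields 290),
ChIP-seq-like peaks placed near the TSSs of strong- and weak-responder
genes, and exactly one 15-bp GBS core planted per peak whose proximal
flank letters (+/-8) follow a group-specific bias: strong-group peaks
carry A/T flanks with probability ``strong_flank_bias`` (else G/C), and
weak-group peaks carry G/C flanks with probability ``weak_flank_bias``
(else A/T).  Background sequence is iid uniform A/C/G/T, a neutral null
for enrichment statistics.  A truth table records every planted motif.

The NMR fixture plants chemical-shift offsets and split peaks on a
synthetic amide peak list, and the titration fixture forward-simulates
the single-site binding isotherm.  Everything is deterministic given the
spec and its seed.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import BASES, revcomp
from .genomics import stratify_genes
from .motifs import CGT_CORE, classify_flanks

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"

TRUTH_COLUMNS = ["peak_id", "group", "chrom", "peak_start", "peak_end",
                 "offset", "strand", "flank5", "flank3", "flank_class", "height"]


# ================================================= regulatory fixture

@dataclass(frozen=True)
class RegulatoryFixtureSpec:
    seed: int = 1
    n_genes: int = 4000
    n_significant: int = 1447
    chrom_length: int = 50_000_000
    n_peaks_per_group: int = 500
    motif_core: str = CGT_CORE
    spacer_positions: tuple = (6, 7, 8)
    strong_flank_bias: float = 0.9
    weak_flank_bias: float = 0.9
    lfc_range: tuple = (0.0, 7.86)
    peak_len: int = 400
    chrom: str = "chr1"

    def __post_init__(self):
        if len(self.motif_core) != 15:
            raise ValueError("motif_core must be 15 letters")
        if any(c not in BASES for c in self.motif_core):
            raise ValueError("motif_core must be A/C/G/T")
        for p in (self.strong_flank_bias, self.weak_flank_bias):
            if not 0 <= p <= 1:
                raise ValueError("flank biases must be probabilities")
        if self.n_significant > self.n_genes:
            raise ValueError("n_significant cannot exceed n_genes")
        if len(self.spacer_positions) != 3:
            raise ValueError("spacer_positions must be an index triple")
        if self.lfc_range[0] >= self.lfc_range[1]:
            raise ValueError("lfc_range must be (min, max) with min < max")


@dataclass
class RegulatoryFixture:
    """In-memory fixture bundle; ``write`` emits the plain-text files."""

    spec: RegulatoryFixtureSpec
    genome: dict
    tss: pd.DataFrame          # BED6, name = gene_id
    expression: pd.DataFrame   # gene_id log2_fc adj_p
    strong_peaks: pd.DataFrame  # BED6, score = peak height
    weak_peaks: pd.DataFrame
    truth: pd.DataFrame

    def peak_sequences(self, group: str) -> dict:
        peaks = self.strong_peaks if group == "strong" else self.weak_peaks
        chrom_seq = self.genome[self.spec.chrom]
        return {
            r["name"]: chrom_seq[int(r["start"]):int(r["end"])]
            for _, r in peaks.iterrows()
        }

    def write(self, outdir) -> dict:
        from . import io

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        seed = self.spec.seed
        paths = {
            "genome": outdir / "genome.fa",
            "tss": outdir / "tss.bed",
            "expression": outdir / "expression.tsv",
            "strong_peaks": outdir / "peaks_strong.bed",
            "weak_peaks": outdir / "peaks_weak.bed",
            "truth": outdir / "truth.tsv",
        }
        io.write_fasta(paths["genome"], self.genome, seed=seed)
        io.write_bed6(paths["tss"], self.tss, seed=seed)
        io.write_expression(paths["expression"], self.expression, seed=seed)
        io.write_bed6(paths["strong_peaks"], self.strong_peaks, seed=seed)
        io.write_bed6(paths["weak_peaks"], self.weak_peaks, seed=seed)
        io.write_tsv(paths["truth"], self.truth, seed=seed)
        return paths


def make_expression_table(
    n_genes: int,
    n_significant: int,
    lfc_range: tuple = (0.0, 7.86),
    seed: int = 1,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Expression table with exactly ``n_significant`` rows at adj_p < 0.05.

    Significant genes draw log2 fold changes uniformly in ``lfc_range``
    (distinct with probability one, so top-fraction cuts have no ties);
    the remainder draw Normal(0, 0.2) fold changes and adj_p in
    [0.05, 1).
    """
    if n_significant > n_genes:
        raise ValueError("n_significant cannot exceed n_genes")
    rng = np.random.default_rng(seed) if rng is None else rng
    width = len(str(n_genes))
    ids = np.array([f"g{i + 1:0{width}d}" for i in range(n_genes)])
    sig_idx = rng.permutation(n_genes)[:n_significant]
    sig_mask = np.zeros(n_genes, dtype=bool)
    sig_mask[sig_idx] = True
    lfc = rng.normal(0.0, 0.2, size=n_genes)
    lfc[sig_mask] = rng.uniform(lfc_range[0], lfc_range[1], size=n_significant)
    adj_p = rng.uniform(0.05, 1.0, size=n_genes)
    adj_p[sig_mask] = rng.uniform(0.0, 0.05, size=n_significant)
    return pd.DataFrame({"gene_id": ids, "log2_fc": lfc, "adj_p": adj_p})


def _flank_letters(rng, group: str, spec: RegulatoryFixtureSpec) -> tuple[str, str]:
    weak_set, strong_set = "AT", "GC"
    r = float(rng.random())
    if group == "strong":
        pool = weak_set if r < spec.strong_flank_bias else strong_set
    else:
        pool = strong_set if r < spec.weak_flank_bias else weak_set
    return (pool[int(rng.integers(2))], pool[int(rng.integers(2))])


def make_regulatory_fixture(spec: RegulatoryFixtureSpec) -> RegulatoryFixture:
    """Generate the full regulatory fixture (genome, TSS, expression, peaks, truth)."""
    rng = np.random.default_rng(spec.seed)

    # 1. expression and the gene groups the peaks will be attached to
    expression = make_expression_table(
        spec.n_genes, spec.n_significant, spec.lfc_range, rng=rng
    )
    strong_grp, weak_grp = stratify_genes(expression)
    strong_genes = sorted(strong_grp.gene_ids)
    weak_genes = sorted(weak_grp.gene_ids)
    if not strong_genes or not weak_genes:
        raise ValueError("fixture needs non-empty strong and weak gene groups; "
                         "check lfc_range against the 0.72 weak threshold")

    # 2. background chromosome
    genome_arr = rng.integers(0, 4, size=spec.chrom_length, dtype=np.int8)

    # 3. peaks with planted motifs, strong/weak interleaved along the chromosome
    total = 2 * spec.n_peaks_per_group
    slot = spec.chrom_length // total
    margin = 3  # keeps the padded shape window inside the peak as well
    if slot < spec.peak_len + 2 or spec.peak_len < 17 + 2 * margin:
        raise ValueError("chrom_length too small to host all peaks "
                         f"({total} peaks of {spec.peak_len} bp)")
    base_lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    peak_rows = {"strong": [], "weak": []}
    truth_rows = []
    counters = {"strong": 0, "weak": 0}
    for i in range(total):
        group = "strong" if i % 2 == 0 else "weak"
        counters[group] += 1
        pid = f"{group}_{counters[group]:04d}"
        start = i * slot + int(rng.integers(0, slot - spec.peak_len + 1))
        end = start + spec.peak_len
        height = max(1.0, float(rng.normal(100.0, 20.0)))
        off_in_peak = int(rng.integers(1 + margin, spec.peak_len - 16 - margin + 1))
        flank5, flank3 = _flank_letters(rng, group, spec)
        strand = "+" if rng.random() < 0.5 else "-"
        piece = flank5 + spec.motif_core + flank3
        if strand == "-":
            piece = revcomp(piece)
        g0 = start + off_in_peak - 1  # genomic start of the 17-letter window
        genome_arr[g0:g0 + 17] = [BASES.index(c) for c in piece]
        peak_rows[group].append((spec.chrom, start, end, pid, round(height, 3), "."))
        truth_rows.append((pid, group, spec.chrom, start, end,
                           start + off_in_peak, strand, flank5, flank3,
                           classify_flanks(flank5, flank3), round(height, 3)))

    genome = {spec.chrom: base_lut[genome_arr].tobytes().decode("ascii")}
    bed_cols = ["chrom", "start", "end", "name", "score", "strand"]
    strong_peaks = pd.DataFrame(peak_rows["strong"], columns=bed_cols)
    weak_peaks = pd.DataFrame(peak_rows["weak"], columns=bed_cols)
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)

    # 4. TSS: peak-bearing genes sit inside the 40 kb window of their first
    #    peak; remaining genes land anywhere on the chromosome.
    gene_anchor = {}
    for group, genes in (("strong", strong_genes), ("weak", weak_genes)):
        peaks = strong_peaks if group == "strong" else weak_peaks
        for j, (_, prow) in enumerate(peaks.iterrows()):
            gene = genes[j % len(genes)]
            if gene not in gene_anchor:
                gene_anchor[gene] = (int(prow["start"]) + int(prow["end"])) // 2
    tss_rows = []
    max_off = max(1, 20_000 - spec.peak_len)
    for gene in expression["gene_id"]:
        strand = "+" if rng.random() < 0.5 else "-"
        if gene in gene_anchor:
            pos = gene_anchor[gene] + int(rng.integers(-max_off + 1, max_off))
            pos = int(np.clip(pos, 0, spec.chrom_length - 1))
        else:
            pos = int(rng.integers(0, spec.chrom_length))
        tss_rows.append((spec.chrom, pos, pos + 1, gene, 0, strand))
    tss = pd.DataFrame(tss_rows, columns=bed_cols)

    return RegulatoryFixture(spec, genome, tss, expression,
                             strong_peaks, weak_peaks, truth)


# ======================================================= NMR fixture

@dataclass(frozen=True)
class NmrFixtureSpec:
    seed: int = 1
    n_residues: int = 86          # GR DBD construct, residues 440-525
    residue_start: int = 440
    shifted_residues: frozenset = field(default_factory=frozenset)
    planted_dH: float = 0.08      # ppm
    planted_dN: float = 0.5       # ppm
    split_residues: frozenset = field(default_factory=frozenset)
    noise_sd: float = 0.0         # ppm, applied to non-shifted residues in B

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        valid = range(self.residue_start, self.residue_start + self.n_residues)
        for rs in (self.shifted_residues, self.split_residues):
            if any(r not in valid for r in rs):
                raise ValueError("shifted/split residue ids outside the construct")
        object.__setattr__(self, "shifted_residues", frozenset(self.shifted_residues))
        object.__setattr__(self, "split_residues", frozenset(self.split_residues))


def make_nmr_fixture(spec: NmrFixtureSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two assigned peak lists: state B = state A + planted perturbations.

    List B differs from A by exact ``(planted_dH, planted_dN)`` offsets at
    the shifted residues, iid Normal(0, noise_sd) jitter on both
    dimensions elsewhere, and a duplicated (split) peak displaced by the
    planted offsets at the split residues.
    """
    rng = np.random.default_rng(spec.seed)
    residues = np.arange(spec.residue_start, spec.residue_start + spec.n_residues)
    aa = rng.choice(list(AA_LETTERS), size=spec.n_residues)
    dh = rng.uniform(6.5, 10.5, size=spec.n_residues)
    dn = rng.uniform(103.0, 133.0, size=spec.n_residues)
    list_a = pd.DataFrame({"residue": residues, "aa": aa,
                           "dH": dh, "dN": dn, "intensity": 1.0})
    rows_b = []
    for i, res in enumerate(residues):
        if res in spec.shifted_residues:
            h, n = dh[i] + spec.planted_dH, dn[i] + spec.planted_dN
        else:
            h = dh[i] + rng.normal(0.0, spec.noise_sd)
            n = dn[i] + rng.normal(0.0, spec.noise_sd)
        rows_b.append((res, aa[i], h, n, 1.0))
        if res in spec.split_residues:
            rows_b.append((res, aa[i], h + spec.planted_dH, n + spec.planted_dN, 0.5))
    list_b = pd.DataFrame(rows_b, columns=["residue", "aa", "dH", "dN", "intensity"])
    return list_a, list_b


# ================================================== titration fixture

#: protein:DNA ratio series used in the imino-proton titrations
TITRATION_RATIOS = (0.25, 0.50, 0.75, 1.00, 1.25, 1.50, 1.75, 2.00, 2.50, 3.00)


def make_titration_fixture(
    kd: float,
    grid=None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Forward-simulated EMSA isotherm table ``P_molar, fraction_bound``.

    ``fraction_bound = 1/(1 + kd/P)`` plus iid Normal(0, noise_sd) noise,
    clipped to [0, 1].  The default grid spans kd/16 .. 16*kd
    geometrically (9 points), bracketing half-saturation.
    """
    if kd <= 0:
        raise ValueError("kd must be positive")
    if grid is None:
        grid = kd * np.geomspace(1 / 16, 16, 9)
    grid = np.asarray(grid, dtype=float)
    if np.any(grid <= 0):
        raise ValueError("grid concentrations must be positive")
    rng = np.random.default_rng(seed)
    f = 1.0 / (1.0 + kd / grid)
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, size=grid.shape)
    f = np.clip(f, 0.0, 1.0)
    return pd.DataFrame({"P_molar": grid, "fraction_bound": f})


def make_titration_replicates(kd, n_replicates=3, grid=None, noise_sd=0.03, seed=0):
    """Stacked replicate isotherms with a ``replicate`` column."""
    parts = []
    for r in range(n_replicates):
        t = make_titration_fixture(kd, grid=grid, noise_sd=noise_sd, seed=seed + r)
        t["replicate"] = r + 1
        parts.append(t)
    return pd.concat(parts, ignore_index=True)


# ================================================== ensemble fixture

def make_ensemble_fixture(
    n_frames: int = 60,
    n_residues: int = 30,
    atoms_per_residue: int = 1,
    flexible: tuple = (),
    base_sd: float = 0.3,
    flexible_sd: float = 1.2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Toy conformational ensemble: harmonic jitter about a helix-like mean.

    Residues listed in ``flexible`` (0-based) fluctuate with
    ``flexible_sd`` instead of ``base_sd`` — a crude stand-in for a mobile
    lever-arm segment.  Each frame additionally receives a random rigid
    rotation+translation, which downstream superposition must remove.
    Returns ``(frames, residue_ids)``.
    """
    rng = np.random.default_rng(seed)
    n_atoms = n_residues * atoms_per_residue
    t = np.linspace(0, 4 * np.pi, n_atoms)
    mean = np.stack([5 * np.cos(t), 5 * np.sin(t), np.linspace(0, 30, n_atoms)], axis=1)
    residue_ids = np.repeat(np.arange(n_residues), atoms_per_residue)
    sd = np.full(n_atoms, base_sd)
    for r in flexible:
        sd[residue_ids == r] = flexible_sd
    frames = mean[None] + rng.normal(0, 1, (n_frames, n_atoms, 3)) * sd[None, :, None]
    # random rigid motion per frame
    from scipy.spatial.transform import Rotation

    for k in range(n_frames):
        R = Rotation.random(rng=rng).as_matrix()
        frames[k] = frames[k] @ R.T + rng.normal(0, 10, 3)
    return frames, residue_ids
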