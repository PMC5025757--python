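"""Readers and writers for the plain-text formats used throughout the package.

Conventions
-----------
* BED6, 0-based half-open, columns ``chrom start end name score strand``.
* Expression tables are TSV with header ``gene_id log2_fc adj_p``.
* All writers can prepend a ``# seed=<n>`` comment line so that generated
  fixtures are self-describing; every reader skips ``#`` comment lines.
* FASTA goes through Biopython; a leading ``# seed=`` line is tolerated by
  its parser (text before the first ``>`` is ignored).
"""
from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
EXPRESSION_COLUMNS = ["gene_id", "log2_fc", "adj_p"]
PEAKLIST_COLUMNS = ["residue", "aa", "dH", "dN", "intensity"]


def _seed_line(seed) -> str:
    return f"# seed={seed}\n" if seed is not None else ""


# ---------------------------------------------------------------- FASTA

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` dict (upper-cased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, seqs: Mapping[str, str], seed=None, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(_seed_line(seed))
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------- BED / TSV

def read_bed6(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=BED6_COLUMNS,
        dtype={"chrom": str, "name": str, "strand": str},
    )
    return df


def write_bed6(path, df: pd.DataFrame, seed=None) -> None:
    with open(path, "w") as fh:
        fh.write(_seed_line(seed))
        df.loc[:, BED6_COLUMNS].to_csv(fh, sep="\t", header=False, index=False)


def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(EXPRESSION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"expression table missing columns: {sorted(missing)}")
    return df


def write_expression(path, df: pd.DataFrame, seed=None) -> None:
    with open(path, "w") as fh:
        fh.write(_seed_line(seed))
        df.loc[:, EXPRESSION_COLUMNS].to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    """Generic headered TSV with ``#`` comments (truth tables, reports...)."""
    return pd.read_csv(path, sep="\t", comment="#")


def write_tsv(path, df: pd.DataFrame, seed=None) -> None:
    with open(path, "w") as fh:
        fh.write(_seed_line(seed))
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------- shape table

def read_shape_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["pentamer", "value"], dtype={"pentamer": str})
    return df


def write_shape_table(path, mapping: Mapping[str, float], seed=None) -> None:
    with open(path, "w") as fh:
        fh.write(_seed_line(seed))
        for k in sorted(mapping):
            fh.write(f"{k}\t{mapping[k]:.4f}\n")


# ---------------------------------------------------------------- NMR peak lists

def read_peaklist(path) -> pd.DataFrame:
    """Assigned 2D peak list CSV: ``residue,aa,dH,dN[,intensity]``."""
    df = pd.read_csv(path, comment="#")
    if "intensity" not in df.columns:
        df["intensity"] = 1.0
    if "aa" not in df.columns:
        df["aa"] = "X"
    return df[PEAKLIST_COLUMNS]


def write_peaklist(path, df: pd.DataFrame, seed=None) -> None:
    with open(path, "w") as fh:
        fh.write(_seed_line(seed))
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------- XYZ ensembles

def read_xyz_frames(path) -> np.ndarray:
    """Read a multi-frame plain-text XYZ file into an (F, N, 3) array.

    Standard XYZ layout per frame: an atom count line, a comment line, then
    one ``name x y z`` (or bare ``x y z``) line per atom.
    """
    frames = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    i = 0
    while i < len(lines):
        n = int(lines[i].split()[0])
        block = lines[i + 2 : i + 2 + n]
        coords = []
        for ln in block:
            parts = ln.split()
            coords.append([float(x) for x in parts[-3:]])
        frames.append(coords)
        i += 2 + n
    arr = np.asarray(frames, dtype=float)
    if arr.ndim != 3:
        raise ValueError("inconsistent atom counts across XYZ frames")
    return arr


def write_xyz_frames(path, frames: np.ndarray, names=None, seed=None) -> None:
    frames = np.asarray(frames, dtype=float)
    f, n, _ = frames.shape
    if names is None:
        names = ["C"] * n
    with open(path, "w") as fh:
        for k in range(f):
            fh.write(f"{n}\n")
            fh.write(f"frame {k}" + (f" seed={seed}" if seed is not None else "") + "\n")
            for a in range(n):
                x, y, z = frames[k, a]
                fh.write(f"{names[a]} {x:.6f} {y:.6f} {z:.6f}\n")
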