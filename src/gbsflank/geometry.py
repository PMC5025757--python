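"""Rigid-body superposition, RMSD/RMSF and medoid frames for ensembles.

These are the standard trajectory summaries: Kabsch least-squares
superposition (proper rotations only), root-mean-square deviation between
two conformations, per-residue root-mean-square fluctuation about the
ensemble mean, and the medoid frame — the conformation minimising summed
pairwise RMSD — as a physically realisable stand-in for a "median"
structure.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

_DEGEN_TOL = 1e-9


@dataclass(frozen=True)
class SuperpositionResult:
    """Proper rotation + translation mapping the mobile set onto the reference."""

    rotation: np.ndarray  # 3x3, det = +1
    translation: np.ndarray  # 3-vector
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _check_points(X: np.ndarray, name: str) -> None:
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError(f"{name} must be an N x 3 array")
    if X.shape[0] < 3:
        raise ValueError("superposition needs at least 3 points")
    c = X - X.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    if s[1] <= _DEGEN_TOL * max(s[0], 1.0):
        raise ValueError(f"{name} is collinear/degenerate; rotation ill-defined")


def superpose(X: np.ndarray, Y: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of mobile ``Y`` onto reference ``X``.

    Kabsch algorithm with reflection excluded; returns the optimal proper
    rotation R and translation t with ``Y @ R.T + t ~ X`` and the
    minimised RMSD in the coordinate units.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise ValueError("point sets must have equal shapes")
    _check_points(X, "X")
    _check_points(Y, "Y")
    cx, cy = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - cx, Y - cy
    H = Yc.T @ Xc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cx - R @ cy
    diff = Xc - Yc @ R.T
    rmsd = float(np.sqrt((diff**2).sum() / len(X)))
    return SuperpositionResult(R, t, rmsd)


def pairwise_rmsd(X: np.ndarray, Y: np.ndarray) -> float:
    """Minimised RMSD between two conformations after superposition."""
    return superpose(X, Y).rmsd


def _align_frames(frames: np.ndarray, ref: np.ndarray) -> np.ndarray:
    return np.stack([superpose(ref, fr).apply(fr) for fr in frames])


def rmsf_profile(
    frames: np.ndarray,
    residue_ids=None,
    superpose_to: str = "mean",
    n_iter: int = 2,
) -> pd.DataFrame:
    """Per-residue RMSF after iterative superposition to the mean structure.

    ``frames`` is (F, N, 3).  With ``superpose_to='mean'`` the frames are
    aligned to the running mean for ``n_iter`` rounds (starting from the
    raw mean); ``'first'`` aligns once to frame 0.  The per-atom
    fluctuation is ``sqrt(mean_F |x - <x>|^2)``; per-residue values
    average the residue's atoms.  ``residue_ids`` defaults to one residue
    per atom.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[2] != 3:
        raise ValueError("frames must be an (F, N, 3) array")
    F, N, _ = frames.shape
    if residue_ids is None:
        residue_ids = np.arange(N)
    residue_ids = np.asarray(residue_ids)
    if F < 2:
        warnings.warn("single frame: RMSF profile is identically zero")
        aligned = frames
    else:
        if superpose_to == "first":
            aligned = _align_frames(frames, frames[0])
        elif superpose_to == "mean":
            aligned = frames
            for _ in range(n_iter):
                aligned = _align_frames(aligned, aligned.mean(axis=0))
        else:
            raise ValueError("superpose_to must be 'mean' or 'first'")
    mean = aligned.mean(axis=0)
    atom_rmsf = np.sqrt(((aligned - mean) ** 2).sum(axis=2).mean(axis=0))
    df = pd.DataFrame({"residue": residue_ids, "rmsf": atom_rmsf})
    return df.groupby("residue", as_index=False)["rmsf"].mean()


def medoid_structure(frames: np.ndarray, tail_fraction: float = 0.5) -> int:
    """Index of the medoid frame within the trailing ``tail_fraction``.

    Restricted to the last ``ceil(tail_fraction * F)`` frames, returns the
    original index of the frame minimising the summed pairwise superposed
    RMSD to every other retained frame (ties broken by lowest index).
    """
    frames = np.asarray(frames, dtype=float)
    F = frames.shape[0]
    if F < 1:
        raise ValueError("empty ensemble")
    if not 0 < tail_fraction <= 1:
        raise ValueError("tail_fraction must be in (0, 1]")
    keep = max(1, math.ceil(tail_fraction * F))
    start = F - keep
    sub = frames[start:]
    if keep == 1:
        return start
    cost = np.zeros(keep)
    for i in range(keep):
        for j in range(i + 1, keep):
            r = pairwise_rmsd(sub[i], sub[j])
            cost[i] += r
            cost[j] += r
    return start + int(np.argmin(cost))
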