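"""Independent oracles used by the test suite.

These deliberately re-derive results by different routes than the package
(exhaustive enumeration, quaternion eigen-decomposition, all-pairs scans)
so that agreement is meaningful.
"""

from __future__ import annotations

import itertools
from typing import Dict, List, Tuple

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def brute_force_global_score(
    a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0
) -> float:
    """Exhaustive enumeration of all global alignments (affine gaps).

    A gap of length L costs gap_open + (L - 1) * gap_extend, matching the
    aligner convention.  Exponential; only for short strings.
    """
    best = [-np.inf]

    def rec(i: int, j: int, prev: str, score: float) -> None:
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "M", score + _BLOSUM62[a[i], b[j]])
        if i < len(a):
            cost = gap_extend if prev == "I" else gap_open
            rec(i + 1, j, "I", score - cost)
        if j < len(b):
            cost = gap_extend if prev == "D" else gap_open
            rec(i, j + 1, "D", score - cost)

    rec(0, 0, "", 0.0)
    return float(best[0])


def quaternion_superpose_rmsd(A: np.ndarray, B: np.ndarray) -> float:
    """RMSD of the optimal superposition via Horn's quaternion method."""
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    n = A.shape[0]
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    M = Ac.T @ Bc
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam = np.linalg.eigvalsh(K)[-1]
    ga = (Ac**2).sum()
    gb = (Bc**2).sum()
    msd = max(0.0, (ga + gb - 2.0 * lam) / n)
    return float(np.sqrt(msd))


def brute_force_polar_pairs(
    lig_atoms: List[Tuple[str, np.ndarray]],
    protein_atoms: List[Tuple[str, str, str, np.ndarray]],
    cutoff: float,
) -> set:
    """All-pairs distance scan: {(ligand atom, residue, atom)} within cutoff."""
    pairs = set()
    for lname, lpos in lig_atoms:
        for cid, rlabel, aname, ppos in protein_atoms:
            if np.linalg.norm(lpos - ppos) <= cutoff:
                pairs.add((lname, cid, rlabel, aname))
    return pairs


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
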