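"""Fragment distance measures: hydrogen-bond, torsion, sequence, and RMSD.

Three distances drive the clustering, each min-max normalized over the set of
fragment pairs being clustered:

* hydrogen-bond distance ``d_HB = 1 - minmax(sim_HB)``, where ``sim_HB`` is a
  weighted count of shared bonds, ``w_MM*n_MM + w_SM*n_SM + w_SS*n_SS``; the
  default weights 0.0055 / 0.025 / 0.12 are the inverse occurrence counts of
  the three bond classes in the reference dataset, so the rare side-chain
  bonds dominate the similarity;
* torsion distance ``d_T = minmax( sum_i |dPhi_i| + |dPsi_i| )`` with circular
  angle differences in [0, 180] degrees;
* sequence distance ``d_S = minmax( -(1/n) * sum_k blosum50(f1[k], f2[k]) )``.

Two fragments share a hydrogen bond when the bond occupies the same relative
positions with the same atom names and main/side-chain flags in both.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
from Bio.Align import substitution_matrices

from tmmotif.fragments import Fragment


@dataclass
class HBWeights:
    """Weights for the three hydrogen-bond classes (all > 0)."""

    w_MM: float = 0.0055
    w_SM: float = 0.025
    w_SS: float = 0.12

    def __post_init__(self) -> None:
        if min(self.w_MM, self.w_SM, self.w_SS) <= 0:
            raise ValueError("hydrogen-bond weights must be positive")


@dataclass
class DistanceMatrix:
    """Symmetric normalized distance matrix over a list of fragment ids."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("shape mismatch")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite distances")
        if not np.allclose(v, v.T):
            raise ValueError("matrix not symmetric")

    def to_tsv(self) -> str:
        header = "\t" + "\t".join(self.ids)
        rows = [header]
        for i, name in enumerate(self.ids):
            rows.append(name + "\t" + "\t".join(f"{x:.6f}" for x in self.values[i]))
        return "\n".join(rows) + "\n"


def _load_blosum50():
    text = resources.files("tmmotif.data").joinpath("BLOSUM50.txt").read_text()
    import io

    return substitution_matrices.read(io.StringIO(text))


_BLOSUM50 = _load_blosum50()


def sim_hb(f1: Fragment, f2: Fragment, w: HBWeights | None = None) -> float:
    """Weighted number of hydrogen bonds shared by two same-length fragments."""
    if f1.length != f2.length:
        raise ValueError("fragments must have the same length")
    w = w or HBWeights()
    shared = f1.hbonds & f2.hbonds
    score = 0.0
    for b in shared:
        cls = b.bond_class
        if cls == "MM":
            score += w.w_MM
        elif cls == "SM":
            score += w.w_SM
        else:
            score += w.w_SS
    return score


def _minmax_to_distance(sim: np.ndarray, higher_is_closer: bool) -> np.ndarray:
    """Min-max normalize off-diagonal values; map to distances in [0, 1]."""
    n = sim.shape[0]
    mask = ~np.eye(n, dtype=bool)
    vals = sim[mask]
    lo, hi = vals.min(), vals.max()
    out = np.zeros_like(sim)
    if hi - lo < 1e-12:
        # degenerate spread: no ordering information in this measure
        warnings.warn("degenerate min-max normalization: all pairwise values equal")
        out[mask] = 1.0 if higher_is_closer else 0.0
    else:
        norm = (sim - lo) / (hi - lo)
        out = 1.0 - norm if higher_is_closer else norm
        out[~mask] = 0.0
        out[mask] = np.clip(out[mask], 0.0, 1.0)
    np.fill_diagonal(out, 0.0)
    return out


def dist_hb_matrix(frags: list[Fragment], w: HBWeights | None = None) -> DistanceMatrix:
    """Pairwise hydrogen-bond distances, d = 1 - minmax(sim_HB)."""
    if len(frags) < 2:
        raise ValueError("need at least 2 fragments")
    n = len(frags)
    sim = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            sim[i, j] = sim[j, i] = sim_hb(frags[i], frags[j], w)
    return DistanceMatrix([f.frag_id for f in frags], _minmax_to_distance(sim, True))


def circular_diff(a: float, b: float) -> float:
    """Absolute angular difference on the circle, in [0, 180] degrees."""
    d = abs(a - b) % 360.0
    return 360.0 - d if d > 180.0 else d


def dist_torsion(f1: Fragment, f2: Fragment) -> float:
    """Raw torsion distance: sum over residues of |dPhi| + |dPsi| (circular)."""
    if f1.length != f2.length:
        raise ValueError("fragments must have the same length")
    total = 0.0
    for (p1, s1), (p2, s2) in zip(f1.torsions, f2.torsions):
        if p1 is None or p2 is None or s1 is None or s2 is None:
            raise ValueError(
                "undefined torsion angle; exclude fragments without full torsions upstream"
            )
        total += circular_diff(p1, p2) + circular_diff(s1, s2)
    return total


def dist_torsion_matrix(frags: list[Fragment]) -> DistanceMatrix:
    """Min-max normalized pairwise torsion distances."""
    if len(frags) < 2:
        raise ValueError("need at least 2 fragments")
    n = len(frags)
    raw = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            raw[i, j] = raw[j, i] = dist_torsion(frags[i], frags[j])
    return DistanceMatrix([f.frag_id for f in frags], _minmax_to_distance(raw, False))


def dist_sequence(f1: Fragment, f2: Fragment) -> float:
    """Raw sequence distance: negative mean BLOSUM50 score over positions."""
    if f1.length != f2.length:
        raise ValueError("fragments must have the same length")
    total = 0.0
    for a, b in zip(f1.sequence, f2.sequence):
        a = a if a in _BLOSUM50.alphabet else "X"
        b = b if b in _BLOSUM50.alphabet else "X"
        total += _BLOSUM50[a, b]
    return -total / f1.length


def dist_sequence_matrix(frags: list[Fragment]) -> DistanceMatrix:
    """Min-max normalized pairwise sequence distances (identical pairs at 0)."""
    if len(frags) < 2:
        raise ValueError("need at least 2 fragments")
    n = len(frags)
    raw = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            raw[i, j] = raw[j, i] = dist_sequence(frags[i], frags[j])
    return DistanceMatrix([f.frag_id for f in frags], _minmax_to_distance(raw, False))


def superpose_rmsd(coords1: np.ndarray, coords2: np.ndarray) -> float:
    """Least-squares RMSD after optimal rigid-body superposition (Kabsch).

    Accepts (n_atoms, 3) arrays or the fragment (n_res, 3, 3) backbone layout.
    """
    x = np.asarray(coords1, dtype=float).reshape(-1, 3)
    y = np.asarray(coords2, dtype=float).reshape(-1, 3)
    if x.shape != y.shape or x.shape[0] < 3:
        raise ValueError("need equal coordinate sets of at least 3 atoms")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    h = xc.T @ yc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    diff = (rot @ xc.T).T - yc
    return float(np.sqrt((diff**2).sum() / x.shape[0]))


def rmsd_matrix(frags: list[Fragment]) -> np.ndarray:
    """Pairwise backbone RMSD matrix for fragments carrying coordinates."""
    n = len(frags)
    out = np.zeros((n, n))
    for i in range(n):
        if frags[i].coords is None:
            raise ValueError(f"fragment {frags[i].frag_id} has no coordinates")
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = superpose_rmsd(frags[i].coords, frags[j].coords)
    return out
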