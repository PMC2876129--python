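"""Fragment generation: sliding windows, torsion profiles, hydrogen bonds, regions.

Each chain is decomposed into all fixed-length windows of 3-14 residues.  A
fragment carries the window's sequence, its backbone phi/psi profile, the set
of intra-window hydrogen bonds re-indexed to window-relative positions, the
backbone coordinates (for structural superposition), and a single membrane
region label derived from its residues.

Hydrogen bonds are detected from heavy atoms only, using atom-type tables of
donor- and acceptor-capable atoms plus geometric criteria: a donor-acceptor
distance cutoff and, when the donor's antecedent atom is present, a minimum
antecedent-donor-acceptor angle.  Each bond partner is flagged M (main chain)
or S (side chain); the pattern notation is the tuple form
(donor_atom, donor_rel, M|S, acceptor_atom, acceptor_rel, M|S).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from tmmotif.structio import (
    CYTOPLASMIC,
    EXTRACELLULAR,
    HELIX_CORE,
    INTERFACE,
    REENTRANT,
    ChainModel,
)

MAIN_CHAIN_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

# side-chain donor atoms (N/O bearing a polar hydrogen) with their antecedent
SIDECHAIN_DONORS: dict[str, dict[str, str]] = {
    "S": {"OG": "CB"},
    "T": {"OG1": "CB"},
    "Y": {"OH": "CZ"},
    "N": {"ND2": "CG"},
    "Q": {"NE2": "CD"},
    "K": {"NZ": "CE"},
    "R": {"NE": "CD", "NH1": "CZ", "NH2": "CZ"},
    "H": {"ND1": "CG", "NE2": "CD2"},
    "W": {"NE1": "CD1"},
}

# side-chain acceptor atoms (lone-pair bearing O/N)
SIDECHAIN_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "D": ("OD1", "OD2"),
    "E": ("OE1", "OE2"),
    "N": ("OD1",),
    "Q": ("OE1",),
    "S": ("OG",),
    "T": ("OG1",),
    "Y": ("OH",),
    "H": ("ND1", "NE2"),
}


@dataclass(frozen=True)
class HBond:
    """One hydrogen bond between heavy atoms, positions relative to a window.

    ``donor_side``/``acceptor_side`` are 'M' for main-chain and 'S' for
    side-chain atoms.  ``bond_class`` collapses donor/acceptor order so that
    S->M and M->S both count as the single mixed class SM.
    """

    donor_rel: int
    donor_atom: str
    donor_side: str
    acceptor_rel: int
    acceptor_atom: str
    acceptor_side: str

    @property
    def bond_class(self) -> str:
        sides = self.donor_side + self.acceptor_side
        if sides == "MM":
            return "MM"
        if sides == "SS":
            return "SS"
        return "SM"

    def shifted(self, offset: int) -> "HBond":
        return HBond(
            self.donor_rel + offset,
            self.donor_atom,
            self.donor_side,
            self.acceptor_rel + offset,
            self.acceptor_atom,
            self.acceptor_side,
        )


@dataclass
class HBondGeometry:
    """Geometric criteria for hydrogen-bond detection.

    Membrane-protein hydrogen bonds are counted even at donor-acceptor
    distances around 4 A, so ``max_da_distance`` may be raised to 4.2 A;
    the default 3.6 A is the conventional heavy-atom cutoff.
    """

    max_da_distance: float = 3.6
    min_antecedent_angle: float = 90.0

    def __post_init__(self) -> None:
        if not 2.0 < self.max_da_distance <= 4.5:
            raise ValueError("max_da_distance must be in (2.0, 4.5] A")


@dataclass
class Fragment:
    """A fixed-length window of one chain."""

    source_id: str
    start: int
    length: int
    sequence: str
    torsions: list[tuple[float | None, float | None]]
    hbonds: frozenset[HBond] = frozenset()
    region: str = "Interface-unassigned"
    coords: np.ndarray | None = None  # (length, 3, 3) N/CA/C backbone coordinates

    def __post_init__(self) -> None:
        if not 3 <= self.length <= 14:
            raise ValueError("fragment length must be 3..14")
        if len(self.sequence) != self.length or len(self.torsions) != self.length:
            raise ValueError("sequence/torsion length mismatch")

    @property
    def frag_id(self) -> str:
        return f"{self.source_id}:{self.start}+{self.length}"

    def has_full_torsions(self) -> bool:
        return all(p is not None and s is not None for p, s in self.torsions)


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float | None:
    """Signed dihedral angle in degrees, in (-180, 180]; None when degenerate."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        return None
    b1u = b1 / np.linalg.norm(b1)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b1u))
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang


def compute_torsions(chain: ChainModel) -> list[tuple[float | None, float | None]]:
    """Backbone phi/psi per residue, degrees in (-180, 180].

    phi is undefined for the first residue and psi for the last; residues
    adjacent to a missing backbone atom get both angles undefined (warning).
    """
    n = len(chain.residues)
    out: list[tuple[float | None, float | None]] = []
    warned = False
    for i, res in enumerate(chain.residues):
        phi = psi = None
        prev_res = chain.residues[i - 1] if i > 0 else None
        next_res = chain.residues[i + 1] if i < n - 1 else None
        if res.has_backbone():
            if prev_res is not None and "C" in prev_res.atoms:
                phi = dihedral(
                    prev_res.atoms["C"], res.atoms["N"], res.atoms["CA"], res.atoms["C"]
                )
            if next_res is not None and "N" in next_res.atoms:
                psi = dihedral(
                    res.atoms["N"], res.atoms["CA"], res.atoms["C"], next_res.atoms["N"]
                )
        if not res.has_backbone() and not warned:
            warnings.warn(f"{chain.source_id}: missing backbone atoms at residue {i}")
            warned = True
        out.append((phi, psi))
    return out


def _donor_atoms(res) -> list[tuple[str, str, str | None]]:
    """(atom, side, antecedent) donor triples present in a residue."""
    out: list[tuple[str, str, str | None]] = []
    if "N" in res.atoms:
        out.append(("N", "M", "CA" if "CA" in res.atoms else None))
    for atom, ante in SIDECHAIN_DONORS.get(res.aa, {}).items():
        if atom in res.atoms:
            out.append((atom, "S", ante if ante in res.atoms else None))
    return out


def _acceptor_atoms(res) -> list[tuple[str, str]]:
    out: list[tuple[str, str]] = []
    for name in ("O", "OXT"):
        if name in res.atoms:
            out.append((name, "M"))
    for atom in SIDECHAIN_ACCEPTORS.get(res.aa, ()):
        if atom in res.atoms:
            out.append((atom, "S"))
    return out


def detect_hbonds(chain: ChainModel, geometry: HBondGeometry | None = None) -> list[HBond]:
    """Detect putative hydrogen bonds between heavy atoms of one chain.

    Positions in the returned bonds are chain-level seq_index values.  Bonds
    within one residue are excluded, as are main-chain/main-chain bonds
    between residues fewer than two positions apart (those reflect covalent
    geometry, not hydrogen bonding).
    """
    geom = geometry or HBondGeometry()
    bonds: list[HBond] = []
    residues = chain.residues
    cutoff = geom.max_da_distance
    cos_max = np.cos(np.radians(geom.min_antecedent_angle))
    for i, dres in enumerate(residues):
        for d_atom, d_side, ante in _donor_atoms(dres):
            d_xyz = dres.atoms[d_atom]
            for j, ares in enumerate(residues):
                if i == j:
                    continue
                for a_atom, a_side in _acceptor_atoms(ares):
                    if d_side == "M" and a_side == "M" and abs(i - j) < 2:
                        continue
                    a_xyz = ares.atoms[a_atom]
                    if np.linalg.norm(d_xyz - a_xyz) > cutoff:
                        continue
                    if ante is not None:
                        v1 = dres.atoms[ante] - d_xyz
                        v2 = a_xyz - d_xyz
                        denom = np.linalg.norm(v1) * np.linalg.norm(v2)
                        if denom > 1e-9:
                            # angle(antecedent-donor-acceptor) >= threshold
                            if float(np.dot(v1, v2)) / denom > cos_max:
                                continue
                    bonds.append(HBond(i, d_atom, d_side, j, a_atom, a_side))
    return bonds


def _window_coords(chain: ChainModel, start: int, length: int) -> np.ndarray | None:
    coords = np.empty((length, 3, 3))
    for k in range(length):
        res = chain.residues[start + k]
        if not res.has_backbone():
            return None
        for a, name in enumerate(("N", "CA", "C")):
            coords[k, a] = res.atoms[name]
    return coords


def make_fragments(
    chain: ChainModel,
    lengths: set[int] | list[int] = (3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14),
    chain_bonds: list[HBond] | None = None,
    torsions: list[tuple[float | None, float | None]] | None = None,
) -> list[Fragment]:
    """All sliding windows of the requested lengths, with bonds re-indexed.

    Chain-level hydrogen bonds whose both partners fall inside a window are
    attached to that fragment with window-relative positions; bonds straddling
    the window boundary are dropped from the fragment's pattern.  Torsions and
    hydrogen bonds are computed when not supplied.
    """
    if torsions is None:
        torsions = compute_torsions(chain)
    if chain_bonds is None:
        chain_bonds = detect_hbonds(chain)
    n = len(chain.residues)
    seq = chain.sequence
    regions = [r.region for r in chain.residues]
    frags: list[Fragment] = []
    for L in sorted(set(lengths)):
        if L > n:
            continue
        for start in range(n - L + 1):
            inside = frozenset(
                b.shifted(-start)
                for b in chain_bonds
                if start <= b.donor_rel < start + L and start <= b.acceptor_rel < start + L
            )
            frag = Fragment(
                source_id=chain.source_id,
                start=start,
                length=L,
                sequence=seq[start : start + L],
                torsions=torsions[start : start + L],
                hbonds=inside,
                coords=_window_coords(chain, start, L),
            )
            frag.region = assign_fragment_region_labels(regions[start : start + L])
            frags.append(frag)
    return frags


def assign_fragment_region_labels(labels: list[str]) -> str:
    """Collapse per-residue region labels to one fragment label.

    Precedence: a uniform label wins; any Reentrant residue makes the fragment
    Reentrant; mixing Helix core with an aqueous side gives Interface;
    otherwise the majority label, with ties going to Interface.
    """
    uniq = set(labels)
    if len(uniq) == 1:
        return labels[0]
    if REENTRANT in uniq:
        return REENTRANT
    if HELIX_CORE in uniq and (CYTOPLASMIC in uniq or EXTRACELLULAR in uniq):
        return INTERFACE
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    best = max(counts.values())
    winners = [lab for lab, c in counts.items() if c == best]
    return winners[0] if len(winners) == 1 else INTERFACE


def assign_fragment_region(fragment: Fragment, chain: ChainModel) -> str:
    """Region label for a fragment from its chain's per-residue labels."""
    labels = [r.region for r in chain.residues[fragment.start : fragment.start + fragment.length]]
    return assign_fragment_region_labels(labels)


def fragments_to_tsv(frags: list[Fragment]) -> str:
    """Fragment table: id, region, sequence, torsions, tuple-notation bonds."""
    rows = ["source_id\tstart\tlength\tregion\tsequence\ttorsions\thbonds"]
    for f in frags:
        tors = ";".join(
            f"{'' if p is None else format(p, '.2f')},{'' if s is None else format(s, '.2f')}"
            for p, s in f.torsions
        )
        bonds = ";".join(
            f"({b.donor_atom},{b.donor_rel},{b.donor_side},"
            f"{b.acceptor_atom},{b.acceptor_rel},{b.acceptor_side})"
            for b in sorted(f.hbonds, key=lambda b: (b.donor_rel, b.acceptor_rel, b.donor_atom))
        )
        rows.append(
            f"{f.source_id}\t{f.start}\t{f.length}\t{f.region}\t{f.sequence}\t{tors}\t{bonds}"
        )
    return "\n".join(rows) + "\n"
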