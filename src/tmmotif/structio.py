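"""Structure input, membrane-region annotation, and dataset filtering.

Chains are read from PDB-format text into lightweight :class:`ChainModel`
objects.  Membrane-region labels follow the five-region vocabulary used for
annotating alpha-helical membrane proteins relative to the lipid bilayer:
``Cytoplasmic`` and ``Extracellular`` (the two aqueous sides), ``Helix core``
(the membrane-embedded part), ``Reentrant`` (segments that dip into the
bilayer and exit on the same side), and the derived ``Interface`` label for
fragments straddling the core and one aqueous side.  Residues not covered by
any annotation interval carry ``Interface-unassigned``.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import is_aa
from Bio.SeqUtils import seq1

CYTOPLASMIC = "Cytoplasmic"
EXTRACELLULAR = "Extracellular"
HELIX_CORE = "Helix core"
REENTRANT = "Reentrant"
INTERFACE = "Interface"
UNASSIGNED = "Interface-unassigned"

#: labels a region annotation file may contain (Interface is derived, never annotated)
ANNOTATABLE_REGIONS = frozenset({CYTOPLASMIC, EXTRACELLULAR, HELIX_CORE, REENTRANT})
ALL_REGIONS = ANNOTATABLE_REGIONS | {INTERFACE, UNASSIGNED}

BACKBONE_ATOMS = ("N", "CA", "C")


class PDBParseError(ValueError):
    """Raised when an ATOM record cannot be parsed; names the offending line."""


@dataclass
class ResidueRecord:
    """One residue: 0-based chain position, one-letter code, atom coordinates (A)."""

    seq_index: int
    aa: str
    atoms: dict[str, np.ndarray]
    region: str = UNASSIGNED
    pdb_resseq: int | None = None  # original PDB residue number, metadata only

    def has_backbone(self) -> bool:
        return all(a in self.atoms for a in BACKBONE_ATOMS)


@dataclass
class ChainModel:
    """One protein chain with per-residue coordinates and region labels."""

    chain_id: str
    residues: list[ResidueRecord]
    resolution: float | None = None
    source_id: str = ""

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class RegionMap:
    """Membrane-region intervals: (chain_id, start, end inclusive, label), 0-based."""

    intervals: list[tuple[str, int, int, str]] = field(default_factory=list)

    @classmethod
    def from_tsv(cls, text: str) -> "RegionMap":
        """Parse a 4-column TSV: chain_id, start, end, region label."""
        intervals = []
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"region TSV line {lineno}: expected 4 columns, got {len(parts)}")
            chain_id, start, end, label = parts
            if label not in ANNOTATABLE_REGIONS:
                raise ValueError(f"region TSV line {lineno}: unknown region label {label!r}")
            intervals.append((chain_id, int(start), int(end), label))
        return cls(intervals)

    def to_tsv(self) -> str:
        return "\n".join(f"{c}\t{s}\t{e}\t{r}" for c, s, e, r in self.intervals) + "\n"


def _validate_atom_lines(pdb_text: str) -> None:
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: ATOM record too short: {line!r}")
        try:
            float(line[30:38])
            float(line[38:46])
            float(line[46:54])
        except ValueError as exc:
            raise PDBParseError(f"line {lineno}: bad coordinates in ATOM record: {line!r}") from exc


def read_structure(pdb_text: str, source_id: str = "struct") -> list[ChainModel]:
    """Parse PDB-format text into one ChainModel per chain (file order).

    Alternate locations are resolved to the highest-occupancy conformer and the
    resolution is taken from the REMARK 2 header when present.  Chains with
    fewer than three complete (N, CA, C) residues are skipped with a warning.
    """
    _validate_atom_lines(pdb_text)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(source_id, io.StringIO(pdb_text))
    resolution = structure.header.get("resolution")
    if resolution is not None and resolution <= 0:
        resolution = None

    chains: list[ChainModel] = []
    model = next(structure.get_models())
    for chain in model:
        residues: list[ResidueRecord] = []
        for res in chain:
            if not is_aa(res, standard=False):
                continue
            atoms: dict[str, np.ndarray] = {}
            for atom in res.get_unpacked_list():
                name = atom.get_name()
                if name in atoms:
                    # keep the highest-occupancy altloc
                    prev_occ = res[name].get_occupancy() if name in res else None
                    if atom.get_occupancy() is not None and prev_occ is not None:
                        if atom.get_occupancy() <= prev_occ:
                            continue
                atoms[name] = np.asarray(atom.get_coord(), dtype=float)
            aa = seq1(res.get_resname(), undef_code="X")
            if aa not in "ACDEFGHIKLMNPQRSTVWY":
                aa = "X"
            residues.append(
                ResidueRecord(
                    seq_index=len(residues),
                    aa=aa,
                    atoms=atoms,
                    pdb_resseq=res.id[1],
                )
            )
        n_complete = sum(1 for r in residues if r.has_backbone())
        if n_complete < 3:
            warnings.warn(
                f"chain {chain.id} of {source_id}: fewer than 3 complete residues, skipped"
            )
            continue
        chains.append(
            ChainModel(
                chain_id=chain.id,
                residues=residues,
                resolution=resolution,
                source_id=f"{source_id}_{chain.id}",
            )
        )
    return chains


def apply_region_map(chains: list[ChainModel], regions: RegionMap) -> list[ChainModel]:
    """Label residues from annotation intervals; uncovered residues stay unassigned.

    Overlapping intervals within a chain are an error (the conflict is listed).
    """
    by_chain: dict[str, list[tuple[int, int, str]]] = {}
    for chain_id, start, end, label in regions.intervals:
        by_chain.setdefault(chain_id, []).append((start, end, label))
    known = {c.chain_id for c in chains}
    missing = set(by_chain) - known
    if missing:
        raise ValueError(f"region map refers to unknown chains: {sorted(missing)}")
    for chain_id, ivals in by_chain.items():
        ivals.sort()
        for (s1, e1, l1), (s2, e2, l2) in zip(ivals, ivals[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"chain {chain_id}: overlapping region intervals "
                    f"({s1}-{e1} {l1}) and ({s2}-{e2} {l2})"
                )
    for chain in chains:
        ivals = by_chain.get(chain.chain_id, [])
        for res in chain.residues:
            res.region = UNASSIGNED
            for s, e, label in ivals:
                if s <= res.seq_index <= e:
                    res.region = label
                    break
    return chains


def slab_region_assign(
    chain: ChainModel,
    z_half_thickness: float,
    side1_label: str = CYTOPLASMIC,
    side2_label: str = EXTRACELLULAR,
) -> ChainModel:
    """Assign regions from a membrane-slab geometry (normal along z).

    Residues with CA |z| <= half-thickness become Helix core; residues above
    the slab get ``side2_label`` and below get ``side1_label``.  An in-slab run
    of at least three residues whose flanking residues lie on the same side is
    relabeled Reentrant (the chain dipped into the bilayer without crossing).
    """
    labels: list[str] = []
    for res in chain.residues:
        if "CA" not in res.atoms:
            labels.append(UNASSIGNED)
            continue
        z = res.atoms["CA"][2]
        if abs(z) <= z_half_thickness:
            labels.append(HELIX_CORE)
        elif z > 0:
            labels.append(side2_label)
        else:
            labels.append(side1_label)
    # reentrant detection: core runs entered and exited on the same side
    n = len(labels)
    i = 0
    while i < n:
        if labels[i] != HELIX_CORE:
            i += 1
            continue
        j = i
        while j < n and labels[j] == HELIX_CORE:
            j += 1
        run_len = j - i
        before = labels[i - 1] if i > 0 else None
        after = labels[j] if j < n else None
        if run_len >= 3 and before is not None and after is not None and before == after:
            for k in range(i, j):
                labels[k] = REENTRANT
        i = j
    for res, label in zip(chain.residues, labels):
        res.region = label
    return chain


def _ungapped_identity(s1: str, s2: str) -> float:
    """Best ungapped-alignment identity, as a fraction of the shorter length."""
    if len(s1) > len(s2):
        s1, s2 = s2, s1
    ls, ll = len(s1), len(s2)
    if ls == 0:
        return 0.0
    best = 0
    for off in range(ll - ls + 1):
        matches = sum(a == b for a, b in zip(s1, s2[off : off + ls]))
        best = max(best, matches)
    return best / ls


def filter_dataset(
    chains: list[ChainModel],
    max_resolution: float = 3.5,
    identity_threshold: float = 0.90,
) -> list[ChainModel]:
    """Resolution and redundancy filter for the input chain set.

    Chains solved at ``max_resolution`` or worse are dropped, then the
    survivors are greedily clustered at ``identity_threshold`` pairwise
    sequence identity (ungapped, over the shorter length) and one
    representative -- the best-resolution member -- is kept per cluster.
    Chains with no recorded resolution pass the resolution filter but lose
    representative ties to chains with one.
    """
    kept = [c for c in chains if c.resolution is None or c.resolution < max_resolution]
    if not kept:
        warnings.warn("filter_dataset: no chains survive the resolution filter")
        return []
    # greedy incremental clustering, longest chain first (deterministic tie-break on id)
    order = sorted(kept, key=lambda c: (-len(c), c.source_id))
    clusters: list[list[ChainModel]] = []
    for chain in order:
        for cluster in clusters:
            if _ungapped_identity(chain.sequence, cluster[0].sequence) >= identity_threshold:
                cluster.append(chain)
                break
        else:
            clusters.append([chain])
    reps = []
    for cluster in clusters:
        reps.append(
            min(
                cluster,
                key=lambda c: (
                    c.resolution if c.resolution is not None else float("inf"),
                    -len(c),
                    c.source_id,
                ),
            )
        )
    # preserve input order among representatives
    rep_ids = {id(c) for c in reps}
    return [c for c in kept if id(c) in rep_ids]


def chains_to_fasta(chains: list[ChainModel]) -> str:
    """Export chain sequences as FASTA text."""
    out = []
    for c in chains:
        out.append(f">{c.source_id}")
        out.append(c.sequence)
    return "\n".join(out) + "\n"
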