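"""Deterministic synthetic fixtures: helical chains, sequence databases, fragments.

Backbones are built from ideal bond lengths and angles with caller-supplied
phi/psi torsions (internal-coordinate chain growth), so a noise-free helix at
phi = -57, psi = -47 degrees reproduces those torsions exactly and exhibits
the i -> i+4 main-chain hydrogen-bond ladder.  Sequence databases emulate the
statistical structure of a transmembrane vs globular Swiss-Prot split:
residues drawn from a hydrophobic-enriched background composition, motifs
planted at controlled per-partition rates, and GO labels correlated with a
planted motif.  Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from Bio.SeqUtils import seq3

from tmmotif.fragments import Fragment, compute_torsions
from tmmotif.motifs import AA20, RegexMotif, parse_prosite
from tmmotif.structio import ChainModel, ResidueRecord, slab_region_assign

# ideal backbone geometry (A, degrees)
B_N_CA, B_CA_C, B_C_N, B_C_O, B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.521
A_N_CA_C, A_CA_C_N, A_C_N_CA, A_CA_C_O = 111.2, 116.2, 121.7, 120.8
OMEGA = 180.0

ALPHA_PHI, ALPHA_PSI = -57.0, -47.0
EXTENDED_PHI, EXTENDED_PSI = -120.0, 120.0

#: hydrophobic-enriched background composition typical of membrane proteins
MEMBRANE_FREQS: dict[str, float] = {
    "A": 0.095, "C": 0.015, "D": 0.025, "E": 0.025, "F": 0.070,
    "G": 0.075, "H": 0.015, "I": 0.085, "K": 0.025, "L": 0.135,
    "M": 0.030, "N": 0.025, "P": 0.035, "Q": 0.020, "R": 0.030,
    "S": 0.055, "T": 0.050, "V": 0.085, "W": 0.025, "Y": 0.035,
}

UNIFORM_FREQS: dict[str, float] = {aa: 0.05 for aa in AA20}


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, r: float, theta: float, phi: float
) -> np.ndarray:
    """Place atom D with |CD| = r, angle(B,C,D) = theta, dihedral(A,B,C,D) = phi."""
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    th, ph = np.radians(theta), np.radians(phi)
    d_local = np.array(
        [-r * np.cos(th), r * np.sin(th) * np.cos(ph), r * np.sin(th) * np.sin(ph)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(torsions: list[tuple[float, float]]) -> list[dict[str, np.ndarray]]:
    """Grow N/CA/C/O/CB coordinates from per-residue (phi, psi) values.

    phi of the first residue and psi of the last are not used by the
    construction but must still be supplied.
    """
    n_res = len(torsions)
    atoms: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([B_N_CA, 0.0, 0.0])
    th = np.radians(180.0 - A_N_CA_C)
    c0 = ca0 + B_CA_C * np.array([np.cos(th), np.sin(th), 0.0])
    atoms.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = atoms[-1]
        psi_prev = torsions[i - 1][1]
        n_i = place_atom(prev["N"], prev["CA"], prev["C"], B_C_N, A_CA_C_N, psi_prev)
        ca_i = place_atom(prev["CA"], prev["C"], n_i, B_N_CA, A_C_N_CA, OMEGA)
        c_i = place_atom(prev["C"], n_i, ca_i, B_CA_C, A_N_CA_C, torsions[i][0])
        atoms.append({"N": n_i, "CA": ca_i, "C": c_i})
    for i, res in enumerate(atoms):
        psi = torsions[i][1]
        res["O"] = place_atom(res["N"], res["CA"], res["C"], B_C_O, A_CA_C_O, psi + 180.0)
        res["CB"] = place_atom(res["C"], res["N"], res["CA"], B_CA_CB, 110.1, 122.55)
    return atoms


def _align_principal_axis_z(coord_sets: list[dict[str, np.ndarray]]) -> None:
    ca = np.array([r["CA"] for r in coord_sets])
    centered = ca - ca.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    axis = vt[0]
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s, c = np.linalg.norm(v), float(np.dot(axis, z))
    if s < 1e-12:
        rot = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    center = ca.mean(axis=0)
    for res in coord_sets:
        for name in res:
            res[name] = rot @ (res[name] - center)


def make_helix_chain(
    n_res: int,
    phi: float = ALPHA_PHI,
    psi: float = ALPHA_PSI,
    noise_sd: float = 0.0,
    seed: int = 0,
    sequence: str | None = None,
    chain_id: str = "A",
    source_id: str = "synth_A",
    resolution: float | None = 2.0,
    torsions: list[tuple[float, float]] | None = None,
    align_z: bool = False,
) -> ChainModel:
    """An ideal alpha-helical chain with optional Gaussian torsion noise.

    ``torsions`` overrides the constant (phi, psi) with a per-residue profile;
    ``align_z`` rotates the chain so the helix axis runs along z (membrane
    normal), centered on the origin.
    """
    if n_res < 4:
        raise ValueError("need at least 4 residues")
    rng = np.random.default_rng(seed)
    if torsions is None:
        torsions = [(phi, psi)] * n_res
    noisy = [
        (p + rng.normal(0.0, noise_sd), s + rng.normal(0.0, noise_sd)) if noise_sd > 0 else (p, s)
        for p, s in torsions
    ]
    coords = build_backbone(noisy)
    if align_z:
        _align_principal_axis_z(coords)
    if sequence is None:
        p = np.array([MEMBRANE_FREQS[a] for a in AA20])
        sequence = "".join(rng.choice(list(AA20), p=p / p.sum(), size=n_res))
    if len(sequence) != n_res:
        raise ValueError("sequence length mismatch")
    residues = [
        ResidueRecord(seq_index=i, aa=sequence[i], atoms=coords[i], pdb_resseq=i + 1)
        for i in range(n_res)
    ]
    return ChainModel(chain_id=chain_id, residues=residues, resolution=resolution, source_id=source_id)


def write_pdb(chains: list[ChainModel], resolution: float | None = None) -> str:
    """Serialize chains to PDB text with a REMARK 2 resolution header."""
    lines = []
    res = resolution if resolution is not None else chains[0].resolution if chains else None
    if res is not None:
        lines.append(f"REMARK   2 RESOLUTION. {res:7.2f} ANGSTROMS.")
    serial = 1
    for chain in chains:
        for r in chain.residues:
            resname = seq3(r.aa).upper()
            for name in ("N", "CA", "C", "O", "CB", *sorted(set(r.atoms) - {"N", "CA", "C", "O", "CB"})):
                if name not in r.atoms:
                    continue
                x, y, z = r.atoms[name]
                aname = name if len(name) == 4 else f" {name:<3}"
                lines.append(
                    f"ATOM  {serial:5d} {aname}{'':1}{resname} {chain.chain_id}"
                    f"{(r.pdb_resseq or r.seq_index + 1):4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                    f"          {name[0]:>2}"
                )
                serial += 1
        lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_fasta(records: list[tuple[str, str]]) -> str:
    return "".join(f">{rid}\n{seq}\n" for rid, seq in records)


def read_fasta(text: str) -> list[tuple[str, str]]:
    records: list[tuple[str, str]] = []
    rid, chunks = None, []
    for line in text.splitlines():
        if line.startswith(">"):
            if rid is not None:
                records.append((rid, "".join(chunks)))
            rid, chunks = line[1:].split()[0], []
        elif line.strip():
            chunks.append(line.strip())
    if rid is not None:
        records.append((rid, "".join(chunks)))
    return records


@dataclass
class PlantedMotif:
    """A motif planted into synthetic sequences at per-partition rates."""

    pattern: str
    tm_rate: float = 0.3
    glob_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.tm_rate <= 1 or not 0 <= self.glob_rate <= 1:
            raise ValueError("planting rates must be in [0, 1]")


@dataclass
class SynthSpec:
    """Stated world for the synthetic generators."""

    seed: int = 0
    n_tm: int = 60
    n_glob: int = 60
    length_range: tuple[int, int] = (80, 160)
    planted: list[PlantedMotif] = field(default_factory=list)
    background: dict[str, float] = field(default_factory=lambda: dict(MEMBRANE_FREQS))
    go_term: str = "GO:0006811"
    go_enrichment: float = 0.9  # P(term | carries first planted motif)
    go_background: float = 0.05  # P(term | does not carry it)
    n_chains: int = 5
    chain_length: int = 36
    z_half_thickness: float = 15.0
    torsion_noise_sd: float = 3.0
    irregular_fraction: float = 0.2


def _sample_instance(m: RegexMotif, rng: np.random.Generator) -> str:
    out = []
    for sym in m.symbols:
        reps = int(rng.integers(sym.repeat_min, sym.repeat_max + 1))
        choices = sorted(sym.residues)
        out.extend(str(rng.choice(choices)) for _ in range(reps))
    return "".join(out)


def make_sequence_db(
    spec: SynthSpec,
) -> tuple[
    list[tuple[str, str]],
    list[tuple[str, str]],
    list[dict],
    list[tuple[str, str]],
]:
    """Synthetic TM and globular sequence databases with planted ground truth.

    Returns (tm_records, glob_records, truth, go_table).  Each truth entry
    records the partition, sequence id, motif pattern, start, and the planted
    text; the GO table correlates ``spec.go_term`` with carriers of the first
    planted motif at the stated enrichment.
    """
    rng = np.random.default_rng(spec.seed)
    letters = sorted(spec.background)
    probs = np.array([spec.background[a] for a in letters])
    probs = probs / probs.sum()
    motifs = [(p, parse_prosite(p.pattern)) for p in spec.planted]
    truth: list[dict] = []
    go_table: list[tuple[str, str]] = []
    first_motif_carriers: set[str] = set()

    def gen_partition(n: int, tag: str, rate_of) -> list[tuple[str, str]]:
        records = []
        for i in range(n):
            length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
            seq = list(rng.choice(letters, p=probs, size=length))
            seq_id = f"{tag}{i:04d}"
            for k, (planted, motif) in enumerate(motifs):
                if rng.random() >= rate_of(planted):
                    continue
                inst = _sample_instance(motif, rng)
                if len(inst) > length:
                    continue
                start = int(rng.integers(0, length - len(inst) + 1))
                seq[start : start + len(inst)] = list(inst)
                truth.append(
                    {
                        "partition": tag,
                        "seq_id": seq_id,
                        "motif": planted.pattern,
                        "start": start,
                        "text": inst,
                    }
                )
                if k == 0 and tag == "tm":
                    first_motif_carriers.add(seq_id)
            records.append((seq_id, "".join(seq)))
        return records

    tm_records = gen_partition(spec.n_tm, "tm", lambda p: p.tm_rate)
    glob_records = gen_partition(spec.n_glob, "glob", lambda p: p.glob_rate)
    for seq_id, _ in tm_records:
        p = spec.go_enrichment if seq_id in first_motif_carriers else spec.go_background
        if rng.random() < p:
            go_table.append((seq_id, spec.go_term))
        if rng.random() < spec.go_background:
            go_table.append((seq_id, "GO:0000000"))
    return tm_records, glob_records, truth, go_table


def make_fragment_groups(
    k_groups: int,
    per_group: int,
    templates: list[list[tuple[float, float]]] | None = None,
    noise_sd: float = 2.0,
    seed: int = 0,
    length: int = 7,
) -> tuple[list[Fragment], list[int]]:
    """Planted-partition fragment fixture for clustering tests.

    Each group is generated around one torsion-profile template (default:
    alpha-helical, extended, and a helix with a central kink) with Gaussian
    torsion noise; the returned labels are the ground-truth group indices.
    """
    defaults = [
        [(ALPHA_PHI, ALPHA_PSI)] * length,
        [(EXTENDED_PHI, EXTENDED_PSI)] * length,
        [(ALPHA_PHI, ALPHA_PSI)] * (length // 2) + [(-90.0, 0.0)] + [(ALPHA_PHI, ALPHA_PSI)] * (length - length // 2 - 1),
    ]
    if templates is None:
        templates = defaults[:k_groups]
    if len(templates) != k_groups:
        raise ValueError("need one template per group")
    for a in range(k_groups):
        for b in range(a + 1, k_groups):
            if templates[a] == templates[b]:
                raise ValueError("templates must be distinct")
    frags: list[Fragment] = []
    labels: list[int] = []
    member = 0
    for g, template in enumerate(templates):
        for _ in range(per_group):
            chain = make_helix_chain(
                n_res=len(template),
                torsions=template,
                noise_sd=noise_sd,
                seed=seed * 100003 + member,
                source_id=f"grp{g}_m{member}",
            )
            torsions = compute_torsions(chain)
            # construction torsions are exact where defined; fill chain ends
            # from the template so the whole profile is usable downstream
            full = [
                (template[i][0] if t[0] is None else t[0], template[i][1] if t[1] is None else t[1])
                for i, t in enumerate(torsions)
            ]
            coords = np.array(
                [[chain.residues[i].atoms[a] for a in ("N", "CA", "C")] for i in range(len(template))]
            )
            frags.append(
                Fragment(
                    source_id=chain.source_id,
                    start=0,
                    length=len(template),
                    sequence=chain.sequence,
                    torsions=full,
                    coords=coords,
                )
            )
            labels.append(g)
            member += 1
    return frags, labels


def make_structure_set(spec: SynthSpec, planted_core: str = "LWSIPLG") -> tuple[list[ChainModel], str]:
    """Membrane-spanning synthetic chains with one core motif planted verbatim.

    Each chain is an alpha-helix long enough to cross a slab of half-thickness
    ``spec.z_half_thickness``; the ``planted_core`` subsequence is written at
    the chain center (inside the hydrophobic core after slab assignment).
    With probability ``spec.irregular_fraction`` a 4-residue flank segment
    gets extended torsions, emulating helix irregularities.  Regions are
    assigned by slab geometry.  Returns the chains and the planted sequence.
    """
    rng = np.random.default_rng(spec.seed)
    chains = []
    letters = sorted(spec.background)
    probs = np.array([spec.background[a] for a in letters])
    probs = probs / probs.sum()
    n = spec.chain_length
    mid = n // 2 - len(planted_core) // 2
    for c in range(spec.n_chains):
        seq = list(rng.choice(letters, p=probs, size=n))
        seq[mid : mid + len(planted_core)] = list(planted_core)
        torsions = [(ALPHA_PHI, ALPHA_PSI)] * n
        if rng.random() < spec.irregular_fraction:
            k = int(rng.integers(0, 5))
            for j in range(k, min(k + 4, mid)):
                torsions[j] = (EXTENDED_PHI, EXTENDED_PSI)
        chain = make_helix_chain(
            n_res=n,
            torsions=torsions,
            noise_sd=spec.torsion_noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
            sequence="".join(seq),
            chain_id=chr(ord("A") + c % 26),
            source_id=f"synth{c}_{chr(ord('A') + c % 26)}",
            align_z=True,
        )
        slab_region_assign(chain, spec.z_half_thickness)
        chains.append(chain)
    return chains, planted_core


def truth_to_json(truth: list[dict]) -> str:
    return json.dumps(truth, indent=1)
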