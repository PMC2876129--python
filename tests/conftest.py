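"""Shared fixtures: synthetic chains and random fragment generators."""

from __future__ import annotations

import numpy as np
import pytest

from tmmotif.fragments import Fragment, HBond
from tmmotif.motifs import AA20
from tmmotif.synth import make_helix_chain, write_pdb


@pytest.fixture(scope="session")
def ideal_helix():
    """Noise-free 16-residue alpha-helix at (-57, -47)."""
    return make_helix_chain(16, noise_sd=0.0, seed=7, source_id="helix_A")


@pytest.fixture(scope="session")
def helix_pdb_text(ideal_helix):
    return write_pdb([ideal_helix])


@pytest.fixture(scope="session")
def poly_ala_pdb_text():
    chain = make_helix_chain(5, noise_sd=0.0, sequence="AAAAA", source_id="pa_A")
    return write_pdb([chain])


def random_hbond(rng: np.random.Generator, length: int) -> HBond:
    d, a = rng.integers(0, length, size=2)
    while a == d:
        a = int(rng.integers(0, length))
    d_side, a_side = rng.choice(["M", "S"], size=2)
    d_atom = str(rng.choice(["N", "CA"])) if d_side == "M" else str(rng.choice(["OG", "NZ", "NE2"]))
    a_atom = str(rng.choice(["O", "C"])) if a_side == "M" else str(rng.choice(["OD1", "OE1", "OH"]))
    return HBond(int(d), d_atom, d_side, int(a), a_atom, a_side)


def random_fragment(rng: np.random.Generator, length: int, n_bonds: int | None = None) -> Fragment:
    if n_bonds is None:
        n_bonds = int(rng.integers(0, 4))
    seq = "".join(rng.choice(list(AA20), size=length))
    torsions = [
        (float(rng.uniform(-180, 180)), float(rng.uniform(-180, 180))) for _ in range(length)
    ]
    bonds = frozenset(random_hbond(rng, length) for _ in range(n_bonds))
    return Fragment(
        source_id=f"rf{rng.integers(1 << 30)}",
        start=0,
        length=length,
        sequence=seq,
        torsions=torsions,
        hbonds=bonds,
    )
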