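"""Shared helpers: in-memory structures and on-disk synthetic fixtures."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from saltbridger.structure_io import Atom, Residue, Structure
from saltbridger.synthetic_fixtures import FixtureSpec, PlantedBridge, generate_fixture

#: directory for optional real crystal structures (user-supplied; the
#: geometry checks against published values need them and skip otherwise)
RCSB_DIR = Path(__file__).parent / "data" / "rcsb"


def make_residue(chain, resnum, aa, atoms, b_factor=20.0, icode=""):
    """Residue from {atom_name: position} with a shared B-factor."""
    adict = {
        name: Atom(name=name, element=name[0], position=np.asarray(pos, dtype=float),
                   b_factor=b_factor)
        for name, pos in atoms.items()
    }
    return Residue(chain_id=chain, seq_number=resnum, insertion_code=icode,
                   aa=aa, name=aa, atoms=adict)


def ca_structure(coords, chain="A", aa="A", b_factors=None, start=1):
    """CA-only structure from an (n, 3) coordinate array."""
    coords = np.asarray(coords, dtype=float)
    residues = [
        make_residue(chain, start + i, aa, {"CA": c},
                     b_factor=20.0 if b_factors is None else float(b_factors[i]))
        for i, c in enumerate(coords)
    ]
    return Structure(id="MEM", chains={chain: residues})


def structure_from(residues, sid="MEM"):
    chains: dict[str, list] = {}
    for r in residues:
        chains.setdefault(r.chain_id, []).append(r)
    return Structure(id=sid, chains=chains)


@pytest.fixture
def two_bridge_fixture(tmp_path):
    """One intra-chain K-D and one inter-chain R-E bridge plus decoys, on disk."""
    spec = FixtureSpec(
        planted_bridges=[
            PlantedBridge("K-D", 8.0, 40.0, 60.0, 3.5, ("H", "C"), "exposed"),
            PlantedBridge("R-E", 14.0, 27.0, 9.5, 3.2, ("C", "H"), "exposed",
                          chain_i="A", chain_j="B"),
        ],
        n_decoys=3,
        seed=42,
    )
    fx = generate_fixture(spec)
    pdb, dssp = fx.write(tmp_path)
    return fx, pdb, dssp
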