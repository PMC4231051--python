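"""Synthetic PDB fixtures with fully known salt-bridge geometry.

The generator writes small multi-chain PDB files (plus matching classic-DSSP
annotation text) in which every salt bridge is planted with exact CA-CA
distance, pseudo-angles theta1/theta2, closest side-chain contact, secondary
structure and exposure class, alongside decoy residues guaranteed not to
form bridges. Residue "units" are laid out on a coarse 3D grid (30 A pitch)
so planted interactions are the only ones present. A fixed seed makes the
output byte-identical.

The fixtures use ideal local geometry and only the atoms the pipeline reads
(N, CA, C, O, CB and the charged-group atoms); they are not physically
realistic conformers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .bridge_survey import DEFAULT_BIN_EDGES
from .reference_data import ACIDIC_ATOMS, BASIC_ATOMS, MAX_ASA_GXG, ONE_TO_THREE

_X = np.array([1.0, 0.0, 0.0])
_Y = np.array([0.0, 1.0, 0.0])
_Z = np.array([0.0, 0.0, 1.0])

#: representative 8-state DSSP code per 3-state class, used when a fixture
#: plants a 3-state label
SS3_TO_SS8 = {"H": "H", "S": "E", "C": "T"}

#: target RSA per planted exposure class (both residues of a pair)
EXPOSURE_RSA = {"exposed": 1.0, "intermediate": 0.20, "buried": 0.05}


class FixtureSpecError(ValueError):
    """Raised for geometrically unrealizable or inconsistent fixture specs."""


@dataclass
class PlantedBridge:
    pair_type: str  # "K-D", "K-E", "R-D", "R-E"
    ca_distance: float
    theta1: float = 60.0
    theta2: float = 60.0
    min_atom_distance: float = 3.5
    ss: tuple[str, str] = ("H", "H")
    exposure: str = "exposed"
    chain_i: str = "A"
    chain_j: str = "A"
    b_factor_i: float = 20.0
    b_factor_j: float = 20.0

    def validate(self) -> None:
        if self.pair_type not in ("K-D", "K-E", "R-D", "R-E"):
            raise FixtureSpecError(f"unknown pair type {self.pair_type}")
        if not 0.5 < self.ca_distance < 100.0:
            raise FixtureSpecError(f"unrealizable CA-CA distance {self.ca_distance}")
        if not (0.0 <= self.theta1 <= 180.0 and 0.0 <= self.theta2 <= 180.0):
            raise FixtureSpecError("theta angles must lie in [0, 180] degrees")
        if not 0.5 < self.min_atom_distance < 4.0:
            raise FixtureSpecError(
                f"planted contact {self.min_atom_distance} A is not a salt bridge (< 4 A needed)"
            )
        if self.exposure not in EXPOSURE_RSA:
            raise FixtureSpecError(f"unknown exposure class {self.exposure}")
        if any(s not in SS3_TO_SS8 for s in self.ss):
            raise FixtureSpecError(f"SS labels must be H/S/C, got {self.ss}")


@dataclass
class FixtureSpec:
    planted_bridges: list[PlantedBridge] = field(default_factory=list)
    n_decoys: int = 0
    decoy_composition: str = "ALGSVKDER"
    seed: int = 0
    structure_id: str = "SYNTH"


@dataclass
class Fixture:
    pdb_text: str
    dssp_text: str
    truth: pd.DataFrame
    spec: FixtureSpec

    def write(self, directory: str | Path, stem: Optional[str] = None) -> tuple[Path, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        stem = stem or self.spec.structure_id.lower()
        pdb = directory / f"{stem}.pdb"
        dssp = directory / f"{stem}.dssp"
        pdb.write_text(self.pdb_text)
        dssp.write_text(self.dssp_text)
        return pdb, dssp


@dataclass
class _FixtureResidue:
    chain: str
    resnum: int
    aa: str
    atoms: list[tuple[str, np.ndarray]]
    b_factor: float
    ss3: str
    asa: float


class FixtureBuilder:
    """Residue-level assembly of a fixture PDB plus its DSSP annotation."""

    def __init__(self, structure_id: str = "SYNTH"):
        self.structure_id = structure_id
        self.residues: list[_FixtureResidue] = []
        self._next_resnum: dict[str, int] = {}

    def next_resnum(self, chain: str, gap: int = 1) -> int:
        n = self._next_resnum.get(chain, 0) + gap
        self._next_resnum[chain] = n
        return n

    def add_residue(
        self,
        chain: str,
        resnum: int,
        aa: str,
        ca: np.ndarray,
        cb_direction: Optional[np.ndarray] = None,
        side_atoms: Optional[Mapping[str, np.ndarray]] = None,
        b_factor: float = 20.0,
        ss3: str = "C",
        rsa: float = 1.0,
    ) -> None:
        """Place one residue: ideal backbone around `ca`, optional CB along
        `cb_direction` (1.53 A), plus explicit side-chain atom positions."""
        ca = np.asarray(ca, dtype=float)
        atoms: list[tuple[str, np.ndarray]] = [
            ("N", ca + 1.46 * (-0.40 * _X + 0.917 * _Z)),
            ("CA", ca),
            ("C", ca + 1.52 * (0.40 * _X + 0.917 * _Z)),
            ("O", ca + 1.52 * (0.40 * _X + 0.917 * _Z) + 1.23 * _Z),
        ]
        if aa != "G" and "CB" not in (side_atoms or {}):
            if cb_direction is None:
                cb_direction = -_Z
            d = np.asarray(cb_direction, dtype=float)
            norm = np.linalg.norm(d)
            if norm < 1e-9:
                raise FixtureSpecError("zero-length CB direction")
            atoms.append(("CB", ca + 1.53 * d / norm))
        for name, pos in (side_atoms or {}).items():
            atoms.append((name, np.asarray(pos, dtype=float)))
        self._next_resnum[chain] = max(self._next_resnum.get(chain, 0), resnum)
        self.residues.append(
            _FixtureResidue(chain, resnum, aa, atoms, b_factor, ss3,
                            rsa * MAX_ASA_GXG.get(aa, 150.0))
        )

    def pdb_text(self) -> str:
        lines = [f"HEADER    SYNTHETIC FIXTURE                       01-JAN-00   {self.structure_id[:4]:<4}"]
        serial = 1
        chains = sorted({r.chain for r in self.residues})
        for chain in chains:
            chain_res = sorted(
                (r for r in self.residues if r.chain == chain), key=lambda r: r.resnum
            )
            for res in chain_res:
                resname = ONE_TO_THREE[res.aa]
                for name, pos in res.atoms:
                    aname = name if len(name) >= 4 else f" {name:<3s}"
                    element = name[0]
                    lines.append(
                        f"ATOM  {serial:5d} {aname}{'':1s}{resname:<3s} {chain:1s}"
                        f"{res.resnum:4d}{'':1s}   "
                        f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}"
                        f"{1.00:6.2f}{res.b_factor:6.2f}          {element:>2s}"
                    )
                    serial += 1
            lines.append(f"TER   {serial:5d}      {ONE_TO_THREE[chain_res[-1].aa]:<3s} "
                         f"{chain:1s}{chain_res[-1].resnum:4d}")
            serial += 1
        lines.append("END")
        return "\n".join(lines) + "\n"

    def dssp_text(self) -> str:
        """Classic DSSP output covering every residue of the fixture."""
        lines = [
            "==== Secondary Structure Definition, synthetic fixture annotation ====",
            f"REFERENCE  {self.structure_id}",
            "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N    N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI    X-CA   Y-CA   Z-CA",
        ]
        idx = 1
        for chain in sorted({r.chain for r in self.residues}):
            chain_res = sorted(
                (r for r in self.residues if r.chain == chain), key=lambda r: r.resnum
            )
            for res in chain_res:
                ss8 = SS3_TO_SS8[res.ss3]
                line = f"{idx:5d}{res.resnum:5d} {chain:1s} {res.aa:1s}  {ss8:1s}"
                line += " " * (34 - len(line))
                line += f"{int(round(res.asa)):4d}"
                line += f"{0:7d},{0.0:4.1f}{0:6d},{0.0:4.1f}{0:6d},{0.0:4.1f}{0:6d},{0.0:4.1f}"
                line += " " * (103 - len(line))
                line += f"{-60.0:6.1f}{-45.0:6.1f}"
                lines.append(line)
                idx += 1
        return "\n".join(lines) + "\n"


def _place_bridge(
    builder: FixtureBuilder,
    bridge: PlantedBridge,
    origin: np.ndarray,
    resnum_i: int,
    resnum_j: int,
) -> dict:
    """Realize one planted bridge in the local frame at `origin`."""
    aa_i, aa_j = bridge.pair_type.split("-")
    r = bridge.ca_distance
    t1 = np.radians(bridge.theta1)
    t2 = np.radians(bridge.theta2)
    ca1 = origin
    ca2 = origin + r * _X
    cb1_dir = np.cos(t1) * _X + np.sin(t1) * _Y
    cb2_dir = -np.cos(t2) * _X + np.sin(t2) * _Y

    mid = origin + (r / 2.0) * _X + 2.0 * _Y
    half = bridge.min_atom_distance / 2.0
    a_basic = mid - half * _X
    a_acidic = mid + half * _X
    basic_atoms = {BASIC_ATOMS[aa_i][0]: a_basic}
    if aa_i == "R":
        basic_atoms["NH2"] = a_basic + 1.0 * _Y
    acid_names = ACIDIC_ATOMS[aa_j]
    acidic_atoms = {acid_names[0]: a_acidic, acid_names[1]: a_acidic + 1.0 * _Y}

    rsa = EXPOSURE_RSA[bridge.exposure]
    builder.add_residue(
        bridge.chain_i, resnum_i, aa_i, ca1, cb1_dir, basic_atoms,
        bridge.b_factor_i, bridge.ss[0], rsa,
    )
    builder.add_residue(
        bridge.chain_j, resnum_j, aa_j, ca2, cb2_dir, acidic_atoms,
        bridge.b_factor_j, bridge.ss[1], rsa,
    )
    return {
        "kind": "bridge",
        "chain_i": bridge.chain_i, "res_i": resnum_i, "aa_i": aa_i,
        "chain_j": bridge.chain_j, "res_j": resnum_j, "aa_j": aa_j,
        "pair_type": bridge.pair_type,
        "ca_distance": r, "theta1": bridge.theta1, "theta2": bridge.theta2,
        "min_atom_distance": bridge.min_atom_distance,
        "ss_i": bridge.ss[0], "ss_j": bridge.ss[1],
        "exposure": bridge.exposure,
        "inter_subunit": bridge.chain_i != bridge.chain_j,
    }


def _site_origin(index: int, pitch: float = 30.0) -> np.ndarray:
    i, rem = divmod(index, 100)
    j, k = divmod(rem, 10)
    return np.array([k, j, i], dtype=float) * pitch


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Build one fixture structure from its spec.

    Every planted bridge occupies its own grid site, so measuring the PDB
    with the survey machinery reproduces the requested geometry to PDB
    coordinate precision (0.001 A); decoy residues are isolated and can
    never satisfy the contact criterion. Output is a pure function of the
    spec (including its seed).
    """
    for b in spec.planted_bridges:
        b.validate()
    rng = np.random.default_rng(spec.seed)
    builder = FixtureBuilder(spec.structure_id)
    truth_rows = []
    site = 0
    for bridge in spec.planted_bridges:
        origin = _site_origin(site)
        # >= 10-residue numbering gap between units keeps planted pairs
        # clear of the sequence-separation design rule by default
        resnum_i = builder.next_resnum(bridge.chain_i, gap=10)
        if bridge.chain_j == bridge.chain_i:
            resnum_j = builder.next_resnum(bridge.chain_j, gap=10)
        else:
            resnum_j = builder.next_resnum(bridge.chain_j, gap=10)
        truth_rows.append(_place_bridge(builder, bridge, origin, resnum_i, resnum_j))
        site += 1
    comp = spec.decoy_composition
    for _ in range(spec.n_decoys):
        origin = _site_origin(site)
        aa = comp[int(rng.integers(len(comp)))]
        resnum = builder.next_resnum("A", gap=10)
        side = {}
        if aa in BASIC_ATOMS:
            side = {BASIC_ATOMS[aa][0]: origin + 2.5 * _Y}
        elif aa in ACIDIC_ATOMS:
            side = {ACIDIC_ATOMS[aa][0]: origin + 2.5 * _Y}
        builder.add_residue("A", resnum, aa, origin, None, side, 15.0, "C", 0.5)
        truth_rows.append(
            {"kind": "decoy", "chain_i": "A", "res_i": resnum, "aa_i": aa,
             "chain_j": "", "res_j": -1, "aa_j": "", "pair_type": "",
             "ca_distance": np.nan, "theta1": np.nan, "theta2": np.nan,
             "min_atom_distance": np.nan, "ss_i": "C", "ss_j": "",
             "exposure": "", "inter_subunit": False}
        )
        site += 1
    if not builder.residues:
        raise FixtureSpecError("fixture spec generates no residues")
    truth = pd.DataFrame(truth_rows)
    return Fixture(builder.pdb_text(), builder.dssp_text(), truth, spec)


def _nerf_place(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle: float, torsion: float,
) -> np.ndarray:
    """Natural-extension-of-reference-frame atom placement (internal coords)."""
    ang, tor = np.radians(angle), np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [-bond * np.cos(ang), bond * np.cos(tor) * np.sin(ang), bond * np.sin(tor) * np.sin(ang)]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def extended_tripeptide(x_aa: str = "A", structure_id: str = "GXG") -> str:
    """PDB text of an extended (phi = psi = 180 deg) Gly-X-Gly tripeptide.

    Built with ideal bond lengths/angles and a real peptide backbone; the
    central residue carries a CB (side chains beyond CB are not modelled, so
    the helper is meant for the Gly/Ala accessibility reference checks).
    """
    n1 = np.array([0.0, 0.0, 0.0])
    ca1 = np.array([1.458, 0.0, 0.0])
    c1 = _nerf_place(np.array([-0.5, 1.0, 0.0]), n1, ca1, 1.525, 111.0, 180.0)
    res = {1: {"N": n1, "CA": ca1, "C": c1}}
    prev = (n1, ca1, c1)
    for i in (2, 3):
        n = _nerf_place(*prev, 1.329, 117.0, 180.0)
        ca = _nerf_place(prev[1], prev[2], n, 1.458, 121.0, 180.0)
        c = _nerf_place(prev[2], n, ca, 1.525, 111.0, 180.0)
        res[i] = {"N": n, "CA": ca, "C": c}
        prev = (n, ca, c)
    for i in (1, 2, 3):
        d = res[i]
        res[i]["O"] = _nerf_place(d["N"], d["CA"], d["C"], 1.231, 121.0, 0.0 if i < 3 else 180.0)
    if x_aa != "G":
        d = res[2]
        res[2]["CB"] = _nerf_place(d["C"], d["N"], d["CA"], 1.53, 110.5, 122.5)

    lines = [f"HEADER    SYNTHETIC FIXTURE                       01-JAN-00   {structure_id[:4]:<4}"]
    serial = 1
    for i in (1, 2, 3):
        aa = x_aa if i == 2 else "G"
        resname = ONE_TO_THREE[aa]
        for name in ("N", "CA", "C", "O", "CB"):
            if name not in res[i]:
                continue
            p = res[i][name]
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s} {resname:<3s} A{i:4d}    "
                f"{p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}{1.00:6.2f}{20.00:6.2f}"
                f"          {name[0]:>2s}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def generate_survey_set(
    n_structures: int,
    category_counts: Mapping[tuple[str, str, str, int], int],
    seed: int = 0,
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
    out_dir: Optional[str | Path] = None,
) -> list[Fixture]:
    """A set of fixtures realizing exact bridge-category counts.

    `category_counts` maps (pair_type, ss_i, ss_j, distance-bin number) to
    the number of exposed bridges to plant in that category; bridges are
    spread round-robin over `n_structures` structures. Within a category the
    CA-CA distance, angles and contact distance are drawn from the seeded
    rng, so different seeds give different coordinates but identical
    category proportions — building a pair index over the set recovers
    100 * count / total exactly.
    """
    if n_structures < 1:
        raise FixtureSpecError("need at least one structure")
    edges = tuple(float(e) for e in bin_edges)
    rng = np.random.default_rng(seed)
    bridges: list[PlantedBridge] = []
    for (ptype, ss_i, ss_j, bin_), count in sorted(category_counts.items()):
        if not 0 <= bin_ < len(edges) - 1:
            raise FixtureSpecError(f"bin {bin_} outside edges {edges}")
        for _ in range(count):
            lo, hi = edges[bin_], edges[bin_ + 1]
            # keep a margin inside the bin so coordinate rounding cannot
            # move the bridge across a bin edge
            r = float(rng.uniform(lo + 0.05, hi - 0.05))
            bridges.append(
                PlantedBridge(
                    pair_type=ptype,
                    ca_distance=r,
                    theta1=float(rng.uniform(10.0, 100.0)),
                    theta2=float(rng.uniform(10.0, 100.0)),
                    min_atom_distance=float(rng.uniform(2.8, 3.8)),
                    ss=(ss_i, ss_j),
                    exposure="exposed",
                )
            )
    order = rng.permutation(len(bridges))
    per_structure: list[list[PlantedBridge]] = [[] for _ in range(n_structures)]
    for pos, idx in enumerate(order):
        per_structure[pos % n_structures].append(bridges[idx])
    fixtures = []
    for i, planted in enumerate(per_structure):
        spec = FixtureSpec(
            planted_bridges=planted,
            n_decoys=2,
            seed=int(rng.integers(2**31 - 1)),
            structure_id=f"SYN{i:03d}",
        )
        fixtures.append(generate_fixture(spec))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        truths = []
        for fx in fixtures:
            fx.write(out_dir)
            t = fx.truth.copy()
            t.insert(0, "structure_id", fx.spec.structure_id)
            truths.append(t)
        pd.concat(truths, ignore_index=True).to_csv(
            out_dir / "ground_truth.tsv", sep="\t", index=False
        )
    return fixtures
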