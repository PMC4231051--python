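"""Atomic-model input and secondary-structure/accessibility annotation.

Structures are read from PDB files (via gemmi) into a lightweight container
that preserves author chain/residue numbering. Secondary structure and
accessible surface area come from a DSSP output file when one is supplied;
otherwise an internal fallback computes ASA with the Shrake-Rupley method and
assigns secondary structure with the P-SEA C-alpha heuristic (both via
biotite). DSSP input always takes precedence over the fallback.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import gemmi
import numpy as np

from .reference_data import THREE_TO_ONE, ss8_to_ss3

logger = logging.getLogger(__name__)

#: (chain_id, seq_number, insertion_code) — the author-numbering residue key.
ResidueKey = tuple[str, int, str]


class StructureError(ValueError):
    """Raised for unreadable or residue-free structure files."""


class AnnotationError(ValueError):
    """Raised when a DSSP file cannot be matched to the structure."""


@dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray  # 3-vector, Angstrom
    b_factor: float = 0.0
    altloc: str = ""
    occupancy: float = 1.0


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    insertion_code: str
    aa: str  # one-letter code; 'X' for unmapped nonstandard
    name: str  # three-letter residue name as read
    atoms: dict[str, Atom] = field(default_factory=dict)
    is_standard: bool = True

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.seq_number, self.insertion_code)

    @property
    def label(self) -> str:
        return f"{self.chain_id}:{self.seq_number}{self.insertion_code}:{self.aa}"

    def atom(self, name: str) -> Optional[Atom]:
        return self.atoms.get(name)

    @property
    def ca(self) -> Optional[Atom]:
        return self.atoms.get("CA")


@dataclass
class Structure:
    id: str
    chains: dict[str, list[Residue]]
    source_path: Optional[str] = None

    def residues(self, require_ca: bool = False) -> Iterator[Residue]:
        for chain_residues in self.chains.values():
            for res in chain_residues:
                if require_ca and res.ca is None:
                    continue
                yield res

    def __len__(self) -> int:
        return sum(len(v) for v in self.chains.values())

    def get(self, key: ResidueKey) -> Optional[Residue]:
        for res in self.chains.get(key[0], []):
            if res.seq_number == key[1] and res.insertion_code == key[2]:
                return res
        return None


@dataclass
class SSAnnotation:
    """Per-residue 8-state/3-state secondary structure and ASA (A^2)."""

    ss8: dict[ResidueKey, str]
    ss3: dict[ResidueKey, str]
    asa: dict[ResidueKey, float]
    source: str = "dssp"  # "dssp" or "fallback"


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    """Highest occupancy wins; ties resolved by file order."""
    best = atoms[0]
    for a in atoms[1:]:
        if a.occ > best.occ:
            best = a
    return best


def parse_structure(
    path: str | Path,
    model_policy: str = "first",
    altloc_policy: str = "occupancy",
) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Only ATOM records (plus MSE, read as Met) of the selected model are kept;
    waters and other heteroatoms are dropped. Alternate locations are resolved
    to a single atom per name: with the default ``altloc_policy='occupancy'``
    the highest-occupancy conformer wins (ties -> first encountered);
    ``'first'`` always keeps the first conformer seen.

    Raises :class:`StructureError` for unreadable files and for files without
    any protein residue.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
    except (RuntimeError, ValueError, OSError) as exc:
        raise StructureError(f"cannot parse structure file {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"no models in {path}")
    if model_policy != "first":
        raise ValueError(f"unknown model_policy: {model_policy}")
    model = st[0]

    chains: dict[str, list[Residue]] = {}
    n_dropped_noca = 0
    for chain in model:
        for res in chain:
            if res.is_water():
                continue
            rname = res.name.upper()
            het = res.het_flag == "H"
            if het and rname != "MSE":
                continue
            aa = THREE_TO_ONE.get(rname)
            if aa is None:
                if not het:
                    logger.warning(
                        "%s: nonstandard residue %s %s/%d excluded from analysis",
                        path.name, rname, chain.name, res.seqid.num,
                    )
                continue
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in res:
                by_name.setdefault(atom.name, []).append(atom)
            atoms: dict[str, Atom] = {}
            for name, group in by_name.items():
                g = _pick_altloc(group) if altloc_policy == "occupancy" else group[0]
                atoms[name] = Atom(
                    name=name,
                    element=g.element.name,
                    position=np.array([g.pos.x, g.pos.y, g.pos.z], dtype=float),
                    b_factor=float(g.b_iso),
                    altloc=g.altloc or "",
                    occupancy=float(g.occ),
                )
            icode = res.seqid.icode.strip()
            residue = Residue(
                chain_id=chain.name,
                seq_number=res.seqid.num,
                insertion_code=icode,
                aa=aa,
                name=rname,
                atoms=atoms,
                is_standard=rname != "MSE",
            )
            if residue.ca is None:
                n_dropped_noca += 1
                logger.warning("%s: residue %s lacks CA; excluded", path.name, residue.label)
                continue
            chains.setdefault(chain.name, []).append(residue)

    structure = Structure(id=path.stem.upper(), chains=chains, source_path=str(path))
    if len(structure) == 0:
        raise StructureError(f"no protein residues with CA in {path}")
    return structure


def _parse_dssp(dssp_path: str | Path, structure: Structure) -> SSAnnotation:
    from Bio.PDB.DSSP import make_dssp_dict

    dssp_dict, _keys = make_dssp_dict(str(dssp_path))
    ss8: dict[ResidueKey, str] = {}
    ss3: dict[ResidueKey, str] = {}
    asa: dict[ResidueKey, float] = {}
    unmatched: list[ResidueKey] = []
    for res in structure.residues():
        hit = dssp_dict.get((res.chain_id, (" ", res.seq_number, res.insertion_code or " ")))
        if hit is None:
            unmatched.append(res.key)
            continue
        _aa, ss, acc = hit[0], hit[1], hit[2]
        code = "" if ss in ("-", " ") else ss
        ss8[res.key] = code
        ss3[res.key] = ss8_to_ss3(code)
        asa[res.key] = float(acc)
    if unmatched:
        raise AnnotationError(
            f"DSSP file {dssp_path} does not cover {len(unmatched)} structure "
            f"residues (first: {unmatched[:5]})"
        )
    return SSAnnotation(ss8=ss8, ss3=ss3, asa=asa, source="dssp")


def _biotite_atom_array(structure: Structure):
    import biotite.structure as struc

    atoms = []
    for res in structure.residues():
        for atom in res.atoms.values():
            atoms.append((res, atom))
    arr = struc.AtomArray(len(atoms))
    arr.coord = np.array([a.position for _r, a in atoms], dtype=np.float32)
    arr.chain_id = np.array([r.chain_id for r, _a in atoms])
    arr.res_id = np.array([r.seq_number for r, _a in atoms])
    arr.ins_code = np.array([r.insertion_code for r, _a in atoms])
    arr.res_name = np.array([r.name if r.is_standard else "MET" for r, _a in atoms])
    arr.atom_name = np.array([a.name for _r, a in atoms])
    arr.element = np.array([(a.element or a.name[0]).upper() for _r, a in atoms])
    arr.hetero = np.zeros(len(atoms), dtype=bool)
    return arr, atoms


def _fallback_annotation(structure: Structure) -> SSAnnotation:
    """Shrake-Rupley ASA plus P-SEA secondary structure, no DSSP needed."""
    import biotite.structure as struc

    arr, atoms = _biotite_atom_array(structure)
    # ProtOr united-atom radii: appropriate for heavy-atom-only models
    sasa = struc.sasa(arr, vdw_radii="ProtOr", point_number=500)
    asa: dict[ResidueKey, float] = {}
    for (res, _atom), value in zip(atoms, sasa):
        if np.isnan(value):
            value = 0.0
        asa[res.key] = asa.get(res.key, 0.0) + float(value)

    ss8: dict[ResidueKey, str] = {}
    ss3: dict[ResidueKey, str] = {}
    psea_to_3 = {"a": "H", "b": "S", "c": "C"}
    # P-SEA uses only CA positions; representative 8-state codes are recorded
    # so the 8->3 mapping stays consistent downstream.
    ss3_to_8 = {"H": "H", "S": "E", "C": ""}
    for chain_id, chain_residues in structure.chains.items():
        keys = [r.key for r in chain_residues if r.ca is not None]
        mask = arr.chain_id == chain_id
        sub = arr[mask]
        try:
            sse = struc.annotate_sse(sub)
        except Exception:  # very short chains etc.
            sse = np.array(["c"] * len(keys))
        if len(sse) != len(keys):  # defensive: P-SEA returns one label per CA
            sse = np.array(["c"] * len(keys))
        for key, label in zip(keys, sse):
            s3 = psea_to_3.get(str(label), "C")
            ss3[key] = s3
            ss8[key] = ss3_to_8[s3]
    for res in structure.residues():
        ss3.setdefault(res.key, "C")
        ss8.setdefault(res.key, "")
        asa.setdefault(res.key, 0.0)
    return SSAnnotation(ss8=ss8, ss3=ss3, asa=asa, source="fallback")


def annotate_structure(
    structure: Structure, dssp_path: Optional[str | Path] = None
) -> SSAnnotation:
    """Secondary structure and ASA for every residue of `structure`.

    When `dssp_path` is given the DSSP codes and ACC values are used verbatim
    (raising :class:`AnnotationError` on residue mismatch); otherwise the
    internal Shrake-Rupley/P-SEA fallback is used.
    """
    if dssp_path is not None:
        return _parse_dssp(dssp_path, structure)
    return _fallback_annotation(structure)
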