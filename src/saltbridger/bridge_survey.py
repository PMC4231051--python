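"""Salt-bridge detection, geometry, classification and the empirical pair index.

A salt bridge is an attractive pair between a basic side chain (Lys NZ;
Arg NH1/NH2) and an acidic one (Asp OD1/OD2; Glu OE1/OE2) with any qualifying
atom-atom distance below 4 A. His is excluded (ambiguous protonation at
pH 7). Each detected bridge carries its minimum atom distance, the CA-CA
distance r, the pseudo-angles theta1 = angle(CB1, CA1, CA2) and
theta2 = angle(CB2, CA2, CA1) describing the mutual orientation of the two
CA->CB vectors, the 3-state secondary-structure pair, and an exposure class
from per-residue RSA.

Aggregating exposed (surface) bridges over a structure set yields the pair
index: an empirical weight per (pair type, SS pair, CA-CA distance bin)
proportional to observed frequency, normalized to sum to 100. The weights
are the w terms of the weighted electrostatic attraction score used by the
design engine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import structure_io
from .geometry import GeometryError, angle_deg, virtual_cbeta
from .reference_data import ACIDIC_ATOMS, BASIC_ATOMS, PAIR_TYPES, pair_type
from .structure_io import Residue, ResidueKey, SSAnnotation, Structure

logger = logging.getLogger(__name__)

DEFAULT_ATOM_CUTOFF = 4.0  # A, strict upper bound on the closest atom pair
DEFAULT_BIN_EDGES = tuple(float(x) for x in range(3, 16))  # 1-A bins over [3, 15]

SS3_STATES = ("H", "S", "C")


class SurveyError(RuntimeError):
    """Raised when every structure of a survey fails."""


class IndexError_(ValueError):
    """Raised for empty or inconsistent pair-index input."""


@dataclass
class SaltBridge:
    """One attractive residue pair; i is the basic partner, j the acidic."""

    structure_id: str
    res_i: ResidueKey
    aa_i: str
    res_j: ResidueKey
    aa_j: str
    pair_type: str
    min_atom_distance: float
    ca_distance: float
    theta1: float
    theta2: float
    ss_i: str = ""
    ss_j: str = ""
    exposure: str = ""
    inter_subunit: bool = False


def _charged_group_positions(res: Residue) -> Optional[np.ndarray]:
    names = BASIC_ATOMS.get(res.aa) or ACIDIC_ATOMS.get(res.aa)
    if names is None:
        return None
    positions = [res.atoms[n].position for n in names if n in res.atoms]
    if not positions:
        logger.warning(
            "%s: charged residue missing side-chain atoms %s; skipped", res.label, names
        )
        return None
    return np.array(positions)


def _cbeta(res: Residue) -> np.ndarray:
    cb = res.atom("CB")
    if cb is not None:
        return cb.position
    n, ca, c = res.atom("N"), res.atom("CA"), res.atom("C")
    if n is None or ca is None or c is None:
        raise GeometryError(f"{res.label}: no CB and incomplete backbone")
    return virtual_cbeta(n.position, ca.position, c.position)


def compute_bridge_geometry(res_i: Residue, res_j: Residue) -> tuple[float, float, float]:
    """(theta1, theta2, ca_distance) for a residue pair.

    theta1 is the angle at CA_i between CA_i->CB_i and CA_i->CA_j; theta2 is
    the symmetric angle at CA_j. Glycine and CB-less residues use an ideal
    virtual CB built from backbone N/CA/C.
    """
    ca1, ca2 = res_i.ca.position, res_j.ca.position
    theta1 = angle_deg(ca1, _cbeta(res_i), ca2)
    theta2 = angle_deg(ca2, _cbeta(res_j), ca1)
    return theta1, theta2, float(np.linalg.norm(ca1 - ca2))


def detect_salt_bridges(
    structure: Structure,
    atom_cutoff: float = DEFAULT_ATOM_CUTOFF,
) -> list[SaltBridge]:
    """All attractive K/R vs D/E pairs with a side-chain contact < `atom_cutoff`.

    One record per residue pair (minimum over qualifying atom pairs), both
    within and across chains; charged residues missing their side-chain
    charge atoms are skipped with a warning.
    """
    basic, acidic = [], []
    for res in structure.residues(require_ca=True):
        if res.aa in BASIC_ATOMS:
            pos = _charged_group_positions(res)
            if pos is not None:
                basic.append((res, pos))
        elif res.aa in ACIDIC_ATOMS:
            pos = _charged_group_positions(res)
            if pos is not None:
                acidic.append((res, pos))

    bridges: list[SaltBridge] = []
    for res_b, pos_b in basic:
        for res_a, pos_a in acidic:
            diff = pos_b[:, None, :] - pos_a[None, :, :]
            dmin = float(np.sqrt((diff ** 2).sum(axis=2).min()))
            if dmin >= atom_cutoff:
                continue
            try:
                theta1, theta2, r = compute_bridge_geometry(res_b, res_a)
            except GeometryError as exc:
                logger.warning("%s: geometry failed (%s); pair skipped", structure.id, exc)
                continue
            bridges.append(
                SaltBridge(
                    structure_id=structure.id,
                    res_i=res_b.key,
                    aa_i=res_b.aa,
                    res_j=res_a.key,
                    aa_j=res_a.aa,
                    pair_type=pair_type(res_b.aa, res_a.aa),
                    min_atom_distance=dmin,
                    ca_distance=r,
                    theta1=theta1,
                    theta2=theta2,
                    inter_subunit=res_b.key[0] != res_a.key[0],
                )
            )
    bridges.sort(key=lambda b: (b.res_i, b.res_j))
    return bridges


def classify_exposure(
    rsa_i: float,
    rsa_j: float,
    exposed_hi: float = 0.35,
    exposed_lo: float = 0.25,
    buried_max: float = 0.09,
) -> str:
    """Exposure class of a bridge from its two residues' RSA.

    Exposed: one residue above 35% and the other above 25%. Buried: both
    below 9%. Everything else is intermediate; the three classes partition
    all bridges.
    """
    if max(rsa_i, rsa_j) > exposed_hi and min(rsa_i, rsa_j) > exposed_lo:
        return "exposed"
    if rsa_i < buried_max and rsa_j < buried_max:
        return "buried"
    return "intermediate"


def annotate_bridges(
    bridges: Iterable[SaltBridge],
    annotation: SSAnnotation,
    rsa: Mapping[ResidueKey, float],
) -> list[SaltBridge]:
    """Attach SS pair and exposure class to detected bridges."""
    out = []
    for b in bridges:
        ss_i = annotation.ss3.get(b.res_i, "C")
        ss_j = annotation.ss3.get(b.res_j, "C")
        exposure = ""
        if b.res_i in rsa and b.res_j in rsa:
            exposure = classify_exposure(rsa[b.res_i], rsa[b.res_j])
        out.append(replace(b, ss_i=ss_i, ss_j=ss_j, exposure=exposure))
    return out


class PairIndex:
    """Empirical pairing-preference weights w(pair_type, ss_i, ss_j, distance bin).

    Weights are 100 * count / total over the surveyed (exposed) bridges, so
    they sum to 100; categories never observed have weight 0, which is also
    what lookups outside the binned distance range return.
    """

    def __init__(
        self,
        weights: Mapping[tuple[str, str, str, int], float],
        bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
        n_bridges: int = 0,
    ):
        self.bin_edges = tuple(float(e) for e in bin_edges)
        if len(self.bin_edges) < 2 or any(
            b <= a for a, b in zip(self.bin_edges, self.bin_edges[1:])
        ):
            raise IndexError_("bin_edges must be strictly increasing, length >= 2")
        self.weights = {k: float(v) for k, v in weights.items() if v != 0.0}
        if any(v < 0 for v in self.weights.values()):
            raise IndexError_("negative weight in pair index")
        self.n_bridges = int(n_bridges)

    def bin_of(self, ca_distance: float) -> Optional[int]:
        """Bin number of a CA-CA distance, or None outside the edges."""
        edges = self.bin_edges
        if ca_distance < edges[0] or ca_distance >= edges[-1]:
            return None
        return int(np.searchsorted(edges, ca_distance, side="right") - 1)

    def weight(self, ptype: str, ss_i: str, ss_j: str, ca_distance: float) -> float:
        b = self.bin_of(ca_distance)
        if b is None:
            logger.warning("CA-CA distance %.2f A outside index bins; weight 0", ca_distance)
            return 0.0
        return self.weights.get((ptype, ss_i, ss_j, b), 0.0)

    @property
    def total(self) -> float:
        return sum(self.weights.values())

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# n_bridges={self.n_bridges}\n")
            fh.write("# bin_edges=" + ",".join(f"{e:g}" for e in self.bin_edges) + "\n")
            fh.write("pair_type\tss_i\tss_j\tbin_lo\tbin_hi\tweight\n")
            for (pt, si, sj, b), w in sorted(self.weights.items()):
                fh.write(
                    f"{pt}\t{si}\t{sj}\t{self.bin_edges[b]:g}\t{self.bin_edges[b + 1]:g}\t{w!r}\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PairIndex":
        n_bridges = 0
        bin_edges: Sequence[float] = DEFAULT_BIN_EDGES
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("# n_bridges="):
                    n_bridges = int(line.split("=", 1)[1])
                elif line.startswith("# bin_edges="):
                    bin_edges = [float(x) for x in line.split("=", 1)[1].split(",")]
                elif line and not line.startswith(("#", "pair_type")):
                    rows.append(line.split("\t"))
        edges = tuple(float(e) for e in bin_edges)
        weights: dict[tuple[str, str, str, int], float] = {}
        for pt, si, sj, lo, _hi, w in rows:
            b = int(np.searchsorted(edges, float(lo), side="right") - 1)
            weights[(pt, si, sj, b)] = float(w)
        return cls(weights, edges, n_bridges)


def build_pair_index(
    bridges: Iterable[SaltBridge],
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
) -> PairIndex:
    """Normalized frequency index over annotated (surface) bridges.

    Callers filter to the exposed class first; repulsive categories do not
    exist by construction (only attractive pairs are ever detected).
    """
    bridges = list(bridges)
    if not bridges:
        raise IndexError_("cannot build a pair index from zero bridges")
    edges = tuple(float(e) for e in bin_edges)
    probe = PairIndex({}, edges, 0)
    counts: dict[tuple[str, str, str, int], int] = {}
    n_used = 0
    for b in bridges:
        bin_ = probe.bin_of(b.ca_distance)
        if bin_ is None:
            logger.warning(
                "%s %s-%s: CA-CA %.2f A outside bins; not indexed",
                b.structure_id, b.res_i, b.res_j, b.ca_distance,
            )
            continue
        key = (b.pair_type, b.ss_i or "C", b.ss_j or "C", bin_)
        counts[key] = counts.get(key, 0) + 1
        n_used += 1
    if n_used == 0:
        raise IndexError_("no bridge fell inside the distance bins")
    weights = {k: 100.0 * c / n_used for k, c in counts.items()}
    return PairIndex(weights, edges, n_used)


def bridges_to_frame(bridges: Iterable[SaltBridge]) -> pd.DataFrame:
    rows = []
    for b in bridges:
        rows.append(
            {
                "structure_id": b.structure_id,
                "chain_i": b.res_i[0],
                "res_i": b.res_i[1],
                "icode_i": b.res_i[2],
                "aa_i": b.aa_i,
                "chain_j": b.res_j[0],
                "res_j": b.res_j[1],
                "icode_j": b.res_j[2],
                "aa_j": b.aa_j,
                "pair_type": b.pair_type,
                "min_atom_dist": b.min_atom_distance,
                "ca_dist": b.ca_distance,
                "theta1": b.theta1,
                "theta2": b.theta2,
                "ss_i": b.ss_i,
                "ss_j": b.ss_j,
                "exposure": b.exposure,
                "inter_subunit": b.inter_subunit,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "structure_id", "chain_i", "res_i", "icode_i", "aa_i",
            "chain_j", "res_j", "icode_j", "aa_j", "pair_type",
            "min_atom_dist", "ca_dist", "theta1", "theta2",
            "ss_i", "ss_j", "exposure", "inter_subunit",
        ],
    )


def survey(
    structure_paths: Sequence[str | Path],
    dssp_dir: Optional[str | Path] = None,
    atom_cutoff: float = DEFAULT_ATOM_CUTOFF,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, pd.DataFrame]]:
    """Detect and classify bridges over a structure set.

    Returns (per-bridge table, exposure summary by pair type, SS-pair
    frequency matrix per pair type computed over exposed bridges). Individual
    structure failures are logged and skipped; :class:`SurveyError` is raised
    only if every structure fails.
    """
    from .descriptors import compute_rsa

    all_bridges: list[SaltBridge] = []
    n_ok = 0
    for path in structure_paths:
        path = Path(path)
        try:
            st = structure_io.parse_structure(path)
            dssp_path = None
            if dssp_dir is not None:
                cand = Path(dssp_dir) / (path.stem + ".dssp")
                dssp_path = cand if cand.exists() else None
            ann = structure_io.annotate_structure(st, dssp_path)
            rsa = compute_rsa(ann, st)
            bridges = annotate_bridges(detect_salt_bridges(st, atom_cutoff), ann, rsa)
        except Exception as exc:
            logger.error("survey: %s failed: %s", path, exc)
            continue
        n_ok += 1
        all_bridges.extend(bridges)
    if n_ok == 0:
        raise SurveyError("all structures failed to parse/annotate")

    table = bridges_to_frame(all_bridges)
    summary_rows = []
    for exposure in ("all", "buried", "exposed", "intermediate"):
        sub = table if exposure == "all" else table[table["exposure"] == exposure]
        row = {"exposure": exposure, "total": len(sub)}
        for pt in PAIR_TYPES:
            row[pt] = int((sub["pair_type"] == pt).sum())
        summary_rows.append(row)
    summary = pd.DataFrame(summary_rows)

    exposed = table[table["exposure"] == "exposed"]
    ss_matrices = {}
    for pt in PAIR_TYPES:
        sub = exposed[exposed["pair_type"] == pt]
        mat = pd.DataFrame(0, index=list(SS3_STATES), columns=list(SS3_STATES))
        for _, r in sub.iterrows():
            mat.loc[r["ss_i"], r["ss_j"]] += 1
        ss_matrices[pt] = mat
    return table, summary, ss_matrices
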