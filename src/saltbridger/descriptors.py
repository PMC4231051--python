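"""Per-residue stability descriptors feeding the design pre-filters.

For each residue the pipeline needs: 3-state secondary structure, absolute
and relative solvent accessibility, the C-alpha B-factor, the weighted
contact number (WCN) and its reciprocal (rWCN), per-chain z-scores of
B-factor and rWCN, and an optional evolutionary conservation grade (ConSurf
1-9 convention). High z_B-factor marks above-average conformational
fluctuation; high z_rWCN marks below-average packing density — both favored
for stabilizing substitutions.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .reference_data import MAX_ASA_GXG
from .structure_io import ResidueKey, SSAnnotation, Structure

logger = logging.getLogger(__name__)


class DescriptorError(ValueError):
    """Raised for undefined descriptor computations."""


class DegenerateDistributionError(DescriptorError):
    """Raised when a z-score group has zero standard deviation."""


def compute_wcn(structure: Structure) -> tuple[dict[ResidueKey, float], dict[ResidueKey, float]]:
    """Weighted contact number and its reciprocal per residue.

    wcn_i = sum_{j != i} 1 / d(CA_i, CA_j)^2, summed over every residue of
    the whole assembly (all chains): packing at subunit interfaces counts.
    """
    residues = [r for r in structure.residues(require_ca=True)]
    if len(residues) < 2:
        raise DescriptorError("WCN undefined for structures with fewer than 2 CA atoms")
    coords = np.array([r.ca.position for r in residues])
    diff = coords[:, None, :] - coords[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    np.fill_diagonal(d2, np.inf)
    wcn_values = (1.0 / d2).sum(axis=1)
    wcn = {r.key: float(w) for r, w in zip(residues, wcn_values)}
    rwcn = {k: 1.0 / v for k, v in wcn.items()}
    return wcn, rwcn


def zscore(values: Mapping[ResidueKey, float] | np.ndarray, ddof: int = 0):
    """Z-scores of one normalization group: z = (x - mean) / sd.

    Population standard deviation by default. Raises
    :class:`DegenerateDistributionError` when sd is 0 (constant input) and
    :class:`DescriptorError` for groups of fewer than two finite values.
    """
    if isinstance(values, Mapping):
        keys = list(values.keys())
        x = np.array([values[k] for k in keys], dtype=float)
    else:
        keys = None
        x = np.asarray(values, dtype=float)
    if x.size < 2 or not np.all(np.isfinite(x)):
        raise DescriptorError("z-score group needs >= 2 finite values")
    sd = float(x.std(ddof=ddof))
    if sd == 0.0:
        raise DegenerateDistributionError("constant values: sd = 0")
    z = (x - x.mean()) / sd
    if keys is None:
        return z
    return {k: float(v) for k, v in zip(keys, z)}


def compute_rsa(
    annotation: SSAnnotation,
    structure: Structure,
    reference_table: Optional[Mapping[str, float]] = None,
) -> dict[ResidueKey, float]:
    """Relative solvent accessibility: ASA over the maximal Gly-X-Gly ASA.

    Values above 1 are retained (crystallographic ASA can exceed the extended
    tripeptide reference). Residues without a reference value are skipped
    with a warning.
    """
    ref = dict(reference_table) if reference_table is not None else MAX_ASA_GXG
    rsa: dict[ResidueKey, float] = {}
    for res in structure.residues():
        if res.key not in annotation.asa:
            continue
        max_asa = ref.get(res.aa)
        if max_asa is None:
            logger.warning("no RSA reference for %s (%s); skipped", res.label, res.aa)
            continue
        rsa[res.key] = annotation.asa[res.key] / max_asa
    return rsa


def load_conservation(path: str | Path) -> dict[tuple[str, int], int]:
    """Read a conservation table: columns chain, residue number, grade 1-9.

    Tab- or whitespace-delimited; an optional header line is detected and
    skipped. Duplicate residues and grades outside 1-9 raise ValueError.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
    if df.shape[1] < 3:
        raise ValueError(f"conservation table {path} needs 3 columns (chain resnum grade)")
    first = df.iloc[0]
    if not str(first[1]).lstrip("-").isdigit():
        df = df.iloc[1:]
    grades: dict[tuple[str, int], int] = {}
    for _, row in df.iterrows():
        chain, resnum_s, grade_s = str(row[0]), str(row[1]), str(row[2])
        resnum, grade = int(resnum_s), int(grade_s)
        if not 1 <= grade <= 9:
            raise ValueError(f"conservation grade {grade} for {chain}:{resnum} outside 1-9")
        if (chain, resnum) in grades:
            raise ValueError(f"duplicate conservation row for {chain}:{resnum}")
        grades[(chain, resnum)] = grade
    return grades


def compute_descriptors(
    structure: Structure,
    annotation: SSAnnotation,
    conservation: Optional[Mapping[tuple[str, int], int]] = None,
    reference_table: Optional[Mapping[str, float]] = None,
    zscore_group: str = "chain",
) -> pd.DataFrame:
    """Assemble the full per-residue descriptor table.

    One row per residue with CA, columns: chain, resnum, icode, aa, ss8, ss3,
    asa, rsa, b, wcn, rwcn, z_b, z_rwcn, conservation (NaN when absent).
    z-scores are normalized per chain by default (``zscore_group='structure'``
    pools the whole assembly).
    """
    wcn, rwcn = compute_wcn(structure)
    rsa = compute_rsa(annotation, structure, reference_table)

    rows = []
    for res in structure.residues(require_ca=True):
        rows.append(
            {
                "chain": res.chain_id,
                "resnum": res.seq_number,
                "icode": res.insertion_code,
                "aa": res.aa,
                "ss8": annotation.ss8.get(res.key, ""),
                "ss3": annotation.ss3.get(res.key, "C"),
                "asa": annotation.asa.get(res.key, np.nan),
                "rsa": rsa.get(res.key, np.nan),
                "b": res.ca.b_factor,
                "wcn": wcn[res.key],
                "rwcn": rwcn[res.key],
            }
        )
    df = pd.DataFrame(rows)

    df["z_b"] = np.nan
    df["z_rwcn"] = np.nan
    groups = df.groupby("chain").groups if zscore_group == "chain" else {"all": df.index}
    for name, idx in groups.items():
        for raw, col in (("b", "z_b"), ("rwcn", "z_rwcn")):
            try:
                df.loc[idx, col] = zscore(df.loc[idx, raw].to_numpy())
            except DescriptorError as exc:
                logger.warning("z-scores undefined for group %s/%s: %s", name, raw, exc)

    if conservation is not None:
        df["conservation"] = [
            float(conservation.get((c, n), np.nan))
            for c, n in zip(df["chain"], df["resnum"])
        ]
        unmatched = {k for k in conservation} - set(zip(df["chain"], df["resnum"]))
        if unmatched:
            logger.warning("%d conservation rows match no residue", len(unmatched))
    else:
        df["conservation"] = np.nan
    return df


def write_descriptors(df: pd.DataFrame, path: str | Path) -> None:
    """Dump the descriptor table as TSV (floats at fixed precision)."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
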