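"""Candidate selection and scoring of thermostabilizing charged substitutions.

The engine applies the pre-filter cascade to pick designable positions,
enumerates the four charged substitutions (K, R, D, E) at each position
against every charged neighbor within 15 A (including residues across
subunit interfaces), enforces the survey-derived angular constraint and the
sequence-separation rule, scores attractive pairings with the weighted
electrostatic attraction model

    E_i = sum_j w(pair_type(i, j), SS_i, SS_j, bin(r_ij))   for q_i * q_j < 0

(w = 0 for repulsive or neutral pairs), and emits ranked mutation
suggestions. Hypothetical substitutions reuse the native residue's CA/CB
geometry: no side-chain modelling is attempted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .bridge_survey import PairIndex, compute_bridge_geometry
from .reference_data import CHARGED_AA, DESIGNABLE_AA, charge, pair_type
from .structure_io import Residue, ResidueKey, Structure

logger = logging.getLogger(__name__)

DEFAULT_NEIGHBOR_RADIUS = 15.0  # A, CA-CA
DEFAULT_ANGLE_CUTOFF = 110.0  # deg
DEFAULT_ANGLE_DISTANCE_GATE = 7.0  # A; the angle rule only applies beyond this
DEFAULT_SEQ_SEP_MIN = 5  # residues
SUBSTITUTIONS = ("D", "E", "K", "R")


@dataclass
class CandidatePair:
    """One (position-as-substitution, charged partner) pairing."""

    position: ResidueKey
    position_aa: str
    substitution: str
    partner: ResidueKey
    partner_aa: str
    ca_distance: float
    theta1: float
    theta2: float
    seq_separation: float  # inf across chains
    angular_ok: bool
    score: float
    inter_subunit: bool


@dataclass
class DesignSuggestion:
    position: ResidueKey
    position_aa: str
    substitution: str
    partner: ResidueKey
    partner_aa: str
    score: float
    ca_distance: float
    theta1: float
    theta2: float
    seq_separation: float
    inter_subunit: bool
    alternative_rule: bool = False


def prefilter_positions(
    descriptors: pd.DataFrame,
    chain: Optional[str] = None,
    rsa_min: float = 0.35,
    z_b_min: float = 0.0,
    z_rwcn_min: float = 0.0,
    cons_max: float = 4.0,
) -> tuple[list[ResidueKey], dict[str, int]]:
    """Designable positions plus the surviving count after each filter.

    The cascade keeps polar/charged residues (S, T, C, N, Q / K, R, D, E),
    then requires RSA > 35% (surface), z_B-factor > 0 (above-average
    fluctuation), z_rWCN > 0 (below-average packing) and conservation
    grade < 4 (variable positions). Residues with no conservation grade fail
    the last filter.
    """
    df = descriptors if chain is None else descriptors[descriptors["chain"] == chain]
    cascade: dict[str, int] = {}
    df = df[df["aa"].isin(DESIGNABLE_AA)]
    cascade["polar_or_charged"] = len(df)
    df = df[df["rsa"] > rsa_min]
    cascade["rsa"] = len(df)
    df = df[df["z_b"] > z_b_min]
    cascade["z_b"] = len(df)
    df = df[df["z_rwcn"] > z_rwcn_min]
    cascade["z_rwcn"] = len(df)
    df = df[df["conservation"].notna() & (df["conservation"] < cons_max)]
    cascade["conservation"] = len(df)
    if cascade["conservation"] == 0 and descriptors["conservation"].isna().all():
        logger.warning("no residue carries a conservation grade; pre-filter is empty")
    positions = [
        (str(r["chain"]), int(r["resnum"]), str(r["icode"]))
        for _, r in df.iterrows()
    ]
    return positions, cascade


def find_neighbors(
    position: Residue,
    structure: Structure,
    radius: float = DEFAULT_NEIGHBOR_RADIUS,
) -> list[tuple[Residue, float]]:
    """Charged residues (K/R/D/E, any chain) with CA-CA <= `radius` A.

    The position itself is excluded; inter-subunit neighbors are first-class
    partners for oligomer design.
    """
    ca = position.ca.position
    out = []
    for res in structure.residues(require_ca=True):
        if res.key == position.key or res.aa not in CHARGED_AA:
            continue
        d = float(np.linalg.norm(res.ca.position - ca))
        if d <= radius:
            out.append((res, d))
    out.sort(key=lambda t: (t[0].key, t[1]))
    return out


def check_angular_constraint(
    theta1: float,
    theta2: float,
    ca_distance: float,
    angle_cutoff: float = DEFAULT_ANGLE_CUTOFF,
    distance_gate: float = DEFAULT_ANGLE_DISTANCE_GATE,
) -> bool:
    """Side-chain orientation gate from the survey statistics.

    Beyond the distance gate (CA-CA > 7 A) at least one of theta1/theta2 must
    be under 110 deg for the two charge groups to point at each other; at or
    below the gate any orientation passes.
    """
    if ca_distance <= distance_gate:
        return True
    return min(theta1, theta2) < angle_cutoff


def _pair_weight(
    substitution: str,
    partner_aa: str,
    ss_site: str,
    ss_partner: str,
    ca_distance: float,
    pair_index: PairIndex,
) -> float:
    if charge(substitution) * charge(partner_aa) >= 0:
        return 0.0
    if charge(substitution) > 0:
        pt, ss_i, ss_j = pair_type(substitution, partner_aa), ss_site, ss_partner
    else:
        pt, ss_i, ss_j = pair_type(partner_aa, substitution), ss_partner, ss_site
    return pair_index.weight(pt, ss_i, ss_j, ca_distance)


def electrostatic_score(
    substitution: str,
    ss_site: str,
    neighbors: Iterable[tuple[str, str, float]],
    pair_index: PairIndex,
) -> tuple[float, list[float]]:
    """Weighted electrostatic attraction of a hypothetical substitution.

    `neighbors` yields (amino acid, 3-state SS, CA-CA distance) for every
    charged residue within the neighborhood. Returns the position score
    E_i (sum over attractive pairs of the index weight; repulsive and
    neutral contribute 0) and the per-pair terms in input order.
    """
    per_pair = [
        _pair_weight(substitution, aa, ss_site, ss_nb, r, pair_index)
        for aa, ss_nb, r in neighbors
    ]
    return float(sum(per_pair)), per_pair


def enumerate_candidate_pairs(
    position: Residue,
    structure: Structure,
    pair_index: PairIndex,
    ss3: Mapping[ResidueKey, str],
    radius: float = DEFAULT_NEIGHBOR_RADIUS,
    angle_cutoff: float = DEFAULT_ANGLE_CUTOFF,
    distance_gate: float = DEFAULT_ANGLE_DISTANCE_GATE,
) -> list[CandidatePair]:
    """All (substitution, neighbor) pairings of one position, scored.

    Pairs failing the angular constraint are kept (flagged, score 0) so the
    full score matrix can be dumped; only angular-passing attractive pairs
    carry a nonzero score.
    """
    pairs: list[CandidatePair] = []
    ss_site = ss3.get(position.key, "C")
    for neighbor, r in find_neighbors(position, structure, radius):
        theta1, theta2, _ = compute_bridge_geometry(position, neighbor)
        ok = check_angular_constraint(theta1, theta2, r, angle_cutoff, distance_gate)
        same_chain = neighbor.key[0] == position.key[0]
        sep = abs(neighbor.seq_number - position.seq_number) if same_chain else math.inf
        for sub in SUBSTITUTIONS:
            score = (
                _pair_weight(sub, neighbor.aa, ss_site, ss3.get(neighbor.key, "C"), r, pair_index)
                if ok
                else 0.0
            )
            pairs.append(
                CandidatePair(
                    position=position.key,
                    position_aa=position.aa,
                    substitution=sub,
                    partner=neighbor.key,
                    partner_aa=neighbor.aa,
                    ca_distance=r,
                    theta1=theta1,
                    theta2=theta2,
                    seq_separation=sep,
                    angular_ok=ok,
                    score=score,
                    inter_subunit=not same_chain,
                )
            )
    return pairs


def _suggest_for_position(
    pairs: list[CandidatePair], seq_sep_min: int
) -> list[DesignSuggestion]:
    scored = [p for p in pairs if p.angular_ok and p.score > 0.0]
    if not scored:
        return []
    long_pairs = [p for p in scored if p.seq_separation >= seq_sep_min]
    if not long_pairs:
        return []  # every influential pairing is sequence-local
    best = max(scored, key=lambda p: p.score)

    def make(p: CandidatePair, alt: bool) -> DesignSuggestion:
        return DesignSuggestion(
            position=p.position,
            position_aa=p.position_aa,
            substitution=p.substitution,
            partner=p.partner,
            partner_aa=p.partner_aa,
            score=p.score,
            ca_distance=p.ca_distance,
            theta1=p.theta1,
            theta2=p.theta2,
            seq_separation=p.seq_separation,
            inter_subunit=p.inter_subunit,
            alternative_rule=alt,
        )

    if best.seq_separation >= seq_sep_min:
        top = max(p.score for p in long_pairs)
        return [make(p, False) for p in long_pairs if p.score == top]

    # The global best pairing is sequence-local: accept an alternative
    # substitution only if its qualifying pair outscores that same
    # substitution's short-separation pair.
    accepted: list[CandidatePair] = []
    for sub in SUBSTITUTIONS:
        sub_long = [p for p in long_pairs if p.substitution == sub]
        if not sub_long:
            continue
        best_long = max(sub_long, key=lambda p: p.score)
        short_scores = [
            p.score for p in scored
            if p.substitution == sub and p.seq_separation < seq_sep_min
        ]
        if best_long.score > max(short_scores, default=0.0):
            accepted.append(best_long)
    if not accepted:
        return []
    top = max(p.score for p in accepted)
    return [make(p, True) for p in accepted if p.score == top]


def suggest_mutations(
    positions: Sequence[ResidueKey],
    structure: Structure,
    pair_index: PairIndex,
    ss3: Mapping[ResidueKey, str],
    radius: float = DEFAULT_NEIGHBOR_RADIUS,
    angle_cutoff: float = DEFAULT_ANGLE_CUTOFF,
    distance_gate: float = DEFAULT_ANGLE_DISTANCE_GATE,
    seq_sep_min: int = DEFAULT_SEQ_SEP_MIN,
) -> tuple[list[DesignSuggestion], list[CandidatePair]]:
    """Ranked substitution suggestions for the pre-filtered positions.

    For each position every substitution/neighbor pairing is scored; the
    predicted pair is the highest-scoring one at sequence separation >= 5
    (inter-chain pairs always qualify), with the alternative-substitution
    rule applied when the globally best pairing is sequence-local. Exact
    score ties yield one suggestion per tied pairing. Returns the
    suggestions plus the complete candidate-pair matrix.
    """
    suggestions: list[DesignSuggestion] = []
    all_pairs: list[CandidatePair] = []
    for key in sorted(positions):
        res = structure.get(key)
        if res is None or res.ca is None:
            logger.warning("position %s not found or lacks CA; skipped", key)
            continue
        pairs = enumerate_candidate_pairs(
            res, structure, pair_index, ss3, radius, angle_cutoff, distance_gate
        )
        all_pairs.extend(pairs)
        suggestions.extend(_suggest_for_position(pairs, seq_sep_min))
    suggestions.sort(key=lambda s: (s.position, s.substitution, s.partner))
    return suggestions, all_pairs


def _fmt_pos(key: ResidueKey, aa: str) -> str:
    return f"{key[0]}:{key[1]}{key[2]}:{aa}"


def suggestions_to_frame(suggestions: Iterable[DesignSuggestion]) -> pd.DataFrame:
    rows = [
        {
            "position": _fmt_pos(s.position, s.position_aa),
            "substitution": s.substitution,
            "partner": _fmt_pos(s.partner, s.partner_aa),
            "score": s.score,
            "ca_dist": s.ca_distance,
            "theta1": s.theta1,
            "theta2": s.theta2,
            "seq_sep": s.seq_separation,
            "inter_subunit": s.inter_subunit,
            "alternative_rule": s.alternative_rule,
        }
        for s in suggestions
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "position", "substitution", "partner", "score", "ca_dist",
            "theta1", "theta2", "seq_sep", "inter_subunit", "alternative_rule",
        ],
    )


def pairs_to_frame(pairs: Iterable[CandidatePair]) -> pd.DataFrame:
    rows = [
        {
            "position": _fmt_pos(p.position, p.position_aa),
            "substitution": p.substitution,
            "partner": _fmt_pos(p.partner, p.partner_aa),
            "score": p.score,
            "ca_dist": p.ca_distance,
            "theta1": p.theta1,
            "theta2": p.theta2,
            "seq_sep": p.seq_separation,
            "angular_ok": p.angular_ok,
            "inter_subunit": p.inter_subunit,
        }
        for p in pairs
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "position", "substitution", "partner", "score", "ca_dist",
            "theta1", "theta2", "seq_sep", "angular_ok", "inter_subunit",
        ],
    )
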