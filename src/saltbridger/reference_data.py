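"""Amino-acid reference data shared across the pipeline.

Charge conventions, salt-bridge atom groups, the DSSP 8-state to 3-state
mapping, and the maximal-ASA normalization table used for relative solvent
accessibility.
"""

from __future__ import annotations

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # selenomethionine is kept and treated as Met
    "MSE": "M",
}

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items() if k != "MSE"}

STANDARD_AA = set(ONE_TO_THREE)

#: Basic side-chain nitrogen atoms that can donate a salt-bridge charge.
#: His is deliberately absent: its protonation state at pH 7 is ambiguous.
BASIC_ATOMS = {"K": ("NZ",), "R": ("NH1", "NH2")}

#: Acidic carboxylate oxygens that can accept a salt-bridge charge.
ACIDIC_ATOMS = {"D": ("OD1", "OD2"), "E": ("OE1", "OE2")}

BASIC_AA = frozenset(BASIC_ATOMS)
ACIDIC_AA = frozenset(ACIDIC_ATOMS)
CHARGED_AA = BASIC_AA | ACIDIC_AA

#: Amino acids eligible for design positions: polar (S, T, C, N, Q), which are
#: depleted in thermophiles, plus the four charged types (charge optimization).
DESIGNABLE_AA = frozenset("STCNQ") | CHARGED_AA

#: The four attractive pair types considered by the survey and the scorer.
PAIR_TYPES = ("K-D", "K-E", "R-D", "R-E")


def charge(aa: str) -> int:
    """Electrostatic charge function: +1 for K/R, -1 for D/E, 0 otherwise."""
    if aa in BASIC_AA:
        return 1
    if aa in ACIDIC_AA:
        return -1
    return 0


def pair_type(aa_basic: str, aa_acidic: str) -> str:
    """Canonical pair-type label for a (basic, acidic) amino-acid pair."""
    if aa_basic not in BASIC_AA or aa_acidic not in ACIDIC_AA:
        raise ValueError(f"not an attractive pair: {aa_basic}-{aa_acidic}")
    return f"{aa_basic}-{aa_acidic}"


# DSSP 8-state -> 3-state: helices (H, G, I) -> H; strands/bridges (B, E) -> S;
# turns, bends and unassigned -> C.
_SS8_TO_SS3 = {
    "H": "H", "G": "H", "I": "H",
    "B": "S", "E": "S",
    "T": "C", "S": "C",
}


def ss8_to_ss3(code: str) -> str:
    """Collapse an 8-state DSSP code to the 3-state class H/S/C.

    Any code outside the mapped set (blank, '-', 'U', PPII 'P', ...) is coil,
    so the mapping is total.
    """
    return _SS8_TO_SS3.get(code, "C")


#: Maximal accessible surface area (A^2) per residue X in an extended
#: Gly-X-Gly tripeptide; empirical values of Tien et al. (2013), which are
#: consistent with heavy-atom Shrake-Rupley calculations and DSSP ACC output
#: (the theoretical maxima of the same study are ~5-10% larger because they
#: maximize over all side-chain conformations).
MAX_ASA_GXG = {
    "A": 121.0, "R": 265.0, "N": 187.0, "D": 187.0, "C": 148.0,
    "Q": 214.0, "E": 214.0, "G": 97.0, "H": 216.0, "I": 195.0,
    "L": 191.0, "K": 230.0, "M": 203.0, "F": 228.0, "P": 154.0,
    "S": 143.0, "T": 163.0, "W": 264.0, "Y": 255.0, "V": 165.0,
}
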