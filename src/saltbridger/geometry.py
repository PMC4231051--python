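"""Vector geometry for salt-bridge orientation analysis."""

from __future__ import annotations

import numpy as np


class GeometryError(ValueError):
    """Raised for degenerate geometric input (zero-length vectors etc.)."""


def angle_deg(vertex: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Angle in degrees at `vertex` between rays vertex->a and vertex->b."""
    u = np.asarray(a, dtype=float) - vertex
    v = np.asarray(b, dtype=float) - vertex
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-9 or nv < 1e-9:
        raise GeometryError("zero-length vector in angle computation")
    cosang = float(np.dot(u, v) / (nu * nv))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


# Coefficients of the standard virtual-CB construction from backbone N/CA/C
# (ideal tetrahedral geometry, ~1.53 A CA-CB bond).
_CB_COEFF = (-0.58273431, 0.56802827, -0.54067466)


def virtual_cbeta(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal C-beta position reconstructed from backbone N, CA, C.

    Used for glycine (no CB) and for residues with a missing CB atom; the
    pseudo-angles theta1/theta2 only need the CA->CB direction.
    """
    n = np.asarray(n, dtype=float)
    ca = np.asarray(ca, dtype=float)
    c = np.asarray(c, dtype=float)
    b = ca - n
    cc = c - ca
    if np.linalg.norm(b) < 1e-9 or np.linalg.norm(cc) < 1e-9:
        raise GeometryError("degenerate backbone for virtual C-beta")
    a = np.cross(b, cc)
    ka, kb, kc = _CB_COEFF
    return ka * a + kb * b + kc * cc + ca


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3x3 rotation matrix (QR of a Gaussian matrix)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
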