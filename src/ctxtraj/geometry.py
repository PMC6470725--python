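"""Batched internal-coordinate geometry: torsions and NeRF atom placement.

All routines operate on arrays whose leading axes are arbitrary (typically
``frames``) and whose last axis is the Cartesian dimension, in nm.  Torsions
follow the IUPAC sign convention (clockwise positive when viewed from the
first atom toward the last).
"""

from __future__ import annotations

import numpy as np

__all__ = ["unit", "angle", "dihedral", "place_atom"]


def unit(v: np.ndarray) -> np.ndarray:
    """Normalize vectors along the last axis."""
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    return v / n


def angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Bond angle at ``b`` (radians), batched."""
    u = unit(a - b)
    v = unit(c - b)
    return np.arccos(np.clip(np.sum(u * v, axis=-1), -1.0, 1.0))


def dihedral(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Torsion angle a-b-c-d in (-pi, pi], batched, IUPAC sign convention."""
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, unit(b2))
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    return np.arctan2(y, x)


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    theta: float | np.ndarray,
    tau: float | np.ndarray,
) -> np.ndarray:
    """Place atom D bonded to ``c`` with bond length, angle b-c-D = ``theta``
    and torsion a-b-c-D = ``tau`` (NeRF construction), batched over leading axes.
    """
    batch = np.broadcast_shapes(np.shape(theta), np.shape(tau), np.shape(c)[:-1])
    theta = np.broadcast_to(theta, batch)
    tau = np.broadcast_to(tau, batch)
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = np.stack(
        [
            -bond * np.cos(theta),
            bond * np.sin(theta) * np.cos(tau),
            -bond * np.sin(theta) * np.sin(tau),
        ],
        axis=-1,
    )
    frame = np.stack([bc, m, n], axis=-1)  # columns are the local basis
    return c + np.einsum("...ij,...j->...i", frame, d_local)
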