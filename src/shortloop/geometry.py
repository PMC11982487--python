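"""Small internal-coordinate geometry helpers (NeRF atom placement)."""

from __future__ import annotations

import numpy as np


def normalize(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise ValueError("zero-length vector")
    return v / n


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, IUPAC sign convention."""
    b0 = p0 - p1
    b1 = normalize(p2 - p1)
    b2 = p3 - p2
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def bond_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    """Angle p0-p1-p2 in degrees."""
    u = normalize(p0 - p1)
    v = normalize(p2 - p1)
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    angle_deg: float,
    torsion_deg: float,
) -> np.ndarray:
    """Place atom d bonded to c with angle b-c-d and dihedral a-b-c-d.

    Standard natural-extension-of-reference-frame construction; the
    returned point satisfies |d-c| = bond, angle(b,c,d) = angle_deg and
    dihedral(a,b,c,d) = torsion_deg (up to float rounding).
    """
    theta = np.radians(angle_deg)
    chi = np.radians(torsion_deg)
    bc = normalize(c - b)
    n = normalize(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(theta),
            bond * np.sin(theta) * np.cos(chi),
            bond * np.sin(theta) * np.sin(chi),
        ]
    )
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3x3 rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately-equidistant unit vectors (Fibonacci lattice)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
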