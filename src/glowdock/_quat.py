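"""Unit-quaternion helpers in (w, x, y, z) convention.

All rotations in the package are stored as unit quaternions; ``rotate``
applies the rotation to row vectors. Composition follows the Hamilton
product, so ``multiply(a, b)`` represents rotation ``b`` followed by ``a``.
"""

from __future__ import annotations

import numpy as np

IDENTITY = np.array([1.0, 0.0, 0.0, 0.0])


def normalize(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    n = np.linalg.norm(q)
    if n == 0.0:
        raise ValueError("zero quaternion cannot be normalized")
    q = q / n
    # canonical sign: w >= 0 keeps serialized output stable
    if q[0] < 0:
        q = -q
    return q


def multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product a*b: rotation b applied first, then a."""
    aw, ax, ay, az = a
    bw, bx, by, bz = b
    return np.array(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ]
    )


def conjugate(q: np.ndarray) -> np.ndarray:
    return np.array([q[0], -q[1], -q[2], -q[3]])


def to_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def rotate(q: np.ndarray, vectors: np.ndarray) -> np.ndarray:
    """Rotate row vector(s) by q."""
    return np.asarray(vectors, dtype=float) @ to_matrix(q).T


def from_axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0.0:
        raise ValueError("zero rotation axis")
    axis = axis / n
    half = 0.5 * angle
    return normalize(np.concatenate([[np.cos(half)], np.sin(half) * axis]))


def geodesic_angle(a: np.ndarray, b: np.ndarray) -> float:
    """Angle (rad) of the relative rotation between two unit quaternions.

    Uses the chord/arcsin form, which stays accurate for tiny angles where
    arccos of the dot product loses precision.
    """
    diff = a - b if float(np.dot(a, b)) >= 0.0 else a + b
    return 4.0 * np.arcsin(min(1.0, 0.5 * float(np.linalg.norm(diff))))


def slerp(a: np.ndarray, b: np.ndarray, t: float) -> np.ndarray:
    """Spherical interpolation from a (t=0) to b (t=1), shortest arc."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    dot = float(np.dot(a, b))
    if dot < 0.0:
        b = -b
        dot = -dot
    if dot > 1.0 - 1e-12:
        return normalize(a + t * (b - a))
    theta = np.arccos(dot)
    s = np.sin(theta)
    return normalize((np.sin((1 - t) * theta) / s) * a + (np.sin(t * theta) / s) * b)


def random_unit(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation: a Gaussian 4-vector normalized to the 3-sphere."""
    q = rng.normal(size=4)
    while np.linalg.norm(q) < 1e-12:  # pragma: no cover
        q = rng.normal(size=4)
    return normalize(q)


def align_vectors_quat(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Quaternion of the minimal rotation taking unit vector source onto target."""
    a = np.asarray(source, dtype=float)
    b = np.asarray(target, dtype=float)
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    d = float(np.dot(a, b))
    if d < -1.0 + 1e-12:
        # antiparallel: rotate pi about any axis perpendicular to a
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        return from_axis_angle(perp, np.pi)
    return normalize(np.concatenate([[1.0 + d], np.cross(a, b)]))
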