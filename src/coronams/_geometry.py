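"""Vectorized internal-coordinate geometry: distances, angles, dihedrals,
and their analytic Cartesian gradients.

All functions accept displacement-vector arrays so callers can apply the
minimum-image convention before measuring.  Gradients follow the standard
molecular-mechanics formulations and are cross-checked against finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-12


def norms(v: np.ndarray) -> np.ndarray:
    return np.sqrt(np.einsum("ij,ij->i", v, v))


def bond_lengths(coords: np.ndarray, pairs: np.ndarray,
                 disp=None) -> np.ndarray:
    """Distances for index pairs (n, 2); `disp` maps raw displacement
    vectors to minimum-image ones."""
    d = coords[pairs[:, 1]] - coords[pairs[:, 0]]
    if disp is not None:
        d = disp(d)
    return norms(d)


def angles(coords: np.ndarray, triples: np.ndarray, disp=None) -> np.ndarray:
    """Angles at the middle bead of each (i, j, k) triple, radians."""
    u = coords[triples[:, 0]] - coords[triples[:, 1]]
    v = coords[triples[:, 2]] - coords[triples[:, 1]]
    if disp is not None:
        u, v = disp(u), disp(v)
    nu, nv = norms(u), norms(v)
    c = np.einsum("ij,ij->i", u, v) / np.maximum(nu * nv, _EPS)
    return np.arccos(np.clip(c, -1.0, 1.0))


def dihedrals(coords: np.ndarray, quads: np.ndarray, disp=None) -> np.ndarray:
    """Signed torsion angles for (i, j, k, l) quadruples, radians in (-π, π]."""
    b1 = coords[quads[:, 1]] - coords[quads[:, 0]]
    b2 = coords[quads[:, 2]] - coords[quads[:, 1]]
    b3 = coords[quads[:, 3]] - coords[quads[:, 2]]
    if disp is not None:
        b1, b2, b3 = disp(b1), disp(b2), disp(b3)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.maximum(norms(b2), _EPS)[:, None])
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m, n2)
    return np.arctan2(y, x)


def angle_gradients(coords: np.ndarray, triples: np.ndarray, disp=None):
    """Return (theta, dtheta/dri, dtheta/drj, dtheta/drk)."""
    u = coords[triples[:, 0]] - coords[triples[:, 1]]
    v = coords[triples[:, 2]] - coords[triples[:, 1]]
    if disp is not None:
        u, v = disp(u), disp(v)
    nu = np.maximum(norms(u), _EPS)
    nv = np.maximum(norms(v), _EPS)
    uh = u / nu[:, None]
    vh = v / nv[:, None]
    c = np.clip(np.einsum("ij,ij->i", uh, vh), -1.0, 1.0)
    theta = np.arccos(c)
    s = np.maximum(np.sqrt(1.0 - c * c), 1e-8)
    gi = -(vh - c[:, None] * uh) / (s * nu)[:, None]
    gk = -(uh - c[:, None] * vh) / (s * nv)[:, None]
    gj = -gi - gk
    return theta, gi, gj, gk


def dihedral_gradients(coords: np.ndarray, quads: np.ndarray, disp=None):
    """Return (phi, dphi/dri, dphi/drj, dphi/drk, dphi/drl)."""
    b1 = coords[quads[:, 1]] - coords[quads[:, 0]]
    b2 = coords[quads[:, 2]] - coords[quads[:, 1]]
    b3 = coords[quads[:, 3]] - coords[quads[:, 2]]
    if disp is not None:
        b1, b2, b3 = disp(b1), disp(b2), disp(b3)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.maximum(norms(b2), _EPS)
    m = np.cross(n1, b2 / nb2[:, None])
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m, n2)
    phi = np.arctan2(y, x)

    sq1 = np.maximum(np.einsum("ij,ij->i", n1, n1), _EPS)
    sq2 = np.maximum(np.einsum("ij,ij->i", n2, n2), _EPS)
    # signs fixed to the atan2 convention used in dihedrals()
    gi = (nb2 / sq1)[:, None] * n1
    gl = -(nb2 / sq2)[:, None] * n2
    f12 = np.einsum("ij,ij->i", b1, b2) / (nb2 * nb2)
    f32 = np.einsum("ij,ij->i", b3, b2) / (nb2 * nb2)
    gj = -(1.0 + f12)[:, None] * gi + f32[:, None] * gl
    gk = -(1.0 + f32)[:, None] * gl + f12[:, None] * gi
    return phi, gi, gj, gk, gl


def wrapped_angle(delta: np.ndarray) -> np.ndarray:
    """Map angle differences to (-π, π]."""
    return (delta + np.pi) % (2.0 * np.pi) - np.pi


def random_rotation_matrix(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation via QR decomposition with sign fix."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1.0
    return q
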