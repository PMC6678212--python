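"""Synthetic inputs for exercising every stage of the pipeline offline.

Three generators are provided, all pure functions of their seed:

* :func:`make_toy_protein` — compact Cα traces with ideal textbook geometry
  (α-helix: 1.5 Å rise, 100° twist, 2.3 Å radius; β-hairpin: two extended
  strands joined by a four-residue arc; coil: a self-avoiding random walk),
  with residue composition controlled per physico-chemical class.
* :func:`make_adsorption_series` — stretched-exponential saturation curves
  N(t) = N_max(1 − exp(−(t/τ)^α)) with optional Gaussian counting noise.
* :func:`make_contact_fixture` — residue×frame contact matrices with exact,
  known persistence fractions.

The toy folds are geometric idealizations, not realistic proteins; they give
the analysis operators inputs with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from . import _geometry as geom
from .analysis import ContactTrace
from .constants import RESIDUE_CLASS, CLASS_NAMES
from .curves import AdsorptionCurve
from .exceptions import InvalidSpecError
from .structure import CGProtein

__all__ = ["ToyProteinSpec", "SyntheticAdsorptionSpec", "make_toy_protein",
           "make_adsorption_series", "make_contact_fixture"]

# ideal polypeptide geometry (Å, degrees)
HELIX_RISE = 1.5
HELIX_TWIST_DEG = 100.0
HELIX_RADIUS = 2.3
CA_CA = 3.8
STRAND_STEP_X = 3.35           # per-residue advance along a strand
STRAND_ZIGZAG = np.sqrt(CA_CA ** 2 - STRAND_STEP_X ** 2) / 2.0
TURN_RESIDUES = 4

_MIN_RESIDUES = {"helix": 4, "hairpin": 12, "coil": 4, "mixed": 16}

_CLASS_ALPHABET = {c: sorted(aa for aa, cl in RESIDUE_CLASS.items()
                             if cl == c) for c in CLASS_NAMES}


@dataclass(frozen=True)
class ToyProteinSpec:
    """Specification for a synthetic Cα-trace protein.

    composition is (non-polar, polar, charged) fractions summing to 1.
    """

    n_residues: int
    motif: str = "helix"
    composition: tuple = (0.5, 0.3, 0.2)
    seed: int = 0

    def __post_init__(self):
        if self.motif not in _MIN_RESIDUES:
            raise InvalidSpecError(f"unknown motif {self.motif!r}")
        if self.n_residues < _MIN_RESIDUES[self.motif]:
            raise InvalidSpecError(
                f"{self.motif} needs at least {_MIN_RESIDUES[self.motif]} "
                f"residues, got {self.n_residues}")
        comp = np.asarray(self.composition, dtype=float)
        if comp.shape != (3,) or np.any(comp < 0) or np.any(comp > 1) \
                or abs(comp.sum() - 1.0) > 1e-9:
            raise InvalidSpecError(
                "composition must be three fractions in [0,1] summing to 1")


@dataclass(frozen=True)
class SyntheticAdsorptionSpec:
    """Specification for a synthetic stretched-exponential adsorption curve."""

    n_max: float
    tau: float
    alpha: float = 1.0
    n_points: int = 200
    noise_sd: float = 0.0
    seed: int = 0
    t_max: float | None = None   # defaults to 10·tau

    def __post_init__(self):
        if self.n_max <= 0 or self.tau <= 0:
            raise InvalidSpecError("n_max and tau must be positive")
        if not 0.0 < self.alpha <= 1.0:
            raise InvalidSpecError("alpha must be in (0, 1]")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be non-negative")
        if self.n_points < 2:
            raise InvalidSpecError("need at least 2 points")


# ---------------------------------------------------------------------------
# geometry builders
# ---------------------------------------------------------------------------

def _helix_coords(n: int) -> np.ndarray:
    # clockwise winding (viewed down +z) + positive rise = right-handed
    # helix, giving the characteristic +50° Cα pseudo-dihedral
    i = np.arange(n, dtype=float)
    ang = -np.deg2rad(HELIX_TWIST_DEG) * i
    return np.column_stack([HELIX_RADIUS * np.cos(ang),
                            HELIX_RADIUS * np.sin(ang),
                            HELIX_RISE * i])


def _strand_coords(n: int, x0: float = 0.0, direction: float = 1.0,
                   y: float = 0.0) -> np.ndarray:
    i = np.arange(n, dtype=float)
    z = STRAND_ZIGZAG * np.where(i.astype(int) % 2 == 0, 1.0, -1.0)
    return np.column_stack([x0 + direction * STRAND_STEP_X * i,
                            np.full(n, y), z])


def _turn_radius() -> float:
    """Radius of the 4-bead semicircular turn such that all five connecting
    virtual bonds have length 3.8 Å (the two boundary bonds carry the strand
    zigzag z-offset)."""
    c_b = np.sqrt(CA_CA ** 2 - STRAND_ZIGZAG ** 2)  # planar boundary chord

    def gap(r):
        return (4.0 * np.arcsin(c_b / (2.0 * r))
                + 6.0 * np.arcsin(CA_CA / (2.0 * r)) - np.pi)

    return brentq(gap, CA_CA, 50.0)


def _hairpin_coords(n: int) -> np.ndarray:
    ns = n - TURN_RESIDUES
    l1 = (ns + 1) // 2
    l2 = ns - l1
    s1 = _strand_coords(l1)
    x_e = s1[-1, 0]
    r = _turn_radius()
    c_b = np.sqrt(CA_CA ** 2 - STRAND_ZIGZAG ** 2)
    th_b = 2.0 * np.arcsin(c_b / (2.0 * r))
    th_i = 2.0 * np.arcsin(CA_CA / (2.0 * r))
    betas = th_b + th_i * np.arange(TURN_RESIDUES, dtype=float)
    turn = np.column_stack([x_e + r * np.sin(betas),
                            r * (1.0 - np.cos(betas)),
                            np.zeros(TURN_RESIDUES)])
    s2 = _strand_coords(l2, x0=x_e, direction=-1.0, y=2.0 * r)
    return np.vstack([s1, turn, s2])


def _place_from_internal(a, b, c, r, theta, phi):
    """NeRF placement of the next bead from bond length, angle, dihedral."""
    bc = c - b
    bc_hat = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc_hat)
    n_hat = n / np.linalg.norm(n)
    m_hat = np.cross(n_hat, bc_hat)
    d = r * (-np.cos(theta) * bc_hat
             + np.sin(theta) * np.cos(phi) * m_hat
             + np.sin(theta) * np.sin(phi) * n_hat)
    return c + d


def _coil_coords(n: int, rng: np.random.Generator,
                 min_separation: float = 4.0) -> np.ndarray:
    coords = np.zeros((n, 3))
    coords[1] = (CA_CA, 0.0, 0.0)
    if n > 2:
        th = rng.uniform(np.deg2rad(85.0), np.deg2rad(135.0))
        coords[2] = coords[1] + CA_CA * np.array(
            [-np.cos(th), np.sin(th), 0.0])
    for i in range(3, n):
        theta = rng.uniform(np.deg2rad(85.0), np.deg2rad(135.0))
        placed = None
        for _ in range(50):  # steer away from self-intersections
            phi = rng.uniform(-np.pi, np.pi)
            cand = _place_from_internal(coords[i - 3], coords[i - 2],
                                        coords[i - 1], CA_CA, theta, phi)
            d = np.linalg.norm(coords[:max(i - 1, 0)] - cand, axis=1)
            if len(d) == 0 or d.min() > min_separation:
                placed = cand
                break
        coords[i] = cand if placed is None else placed
    return coords


def _attach(prev: np.ndarray, seg: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
    """Append a segment after `prev` with a 3.8 Å connecting bond and a
    random orientation."""
    rot = geom.random_rotation_matrix(rng)
    seg = (seg - seg[0]) @ rot.T
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    return seg + prev[-1] + CA_CA * u


def _mixed_coords(n: int, rng: np.random.Generator) -> np.ndarray:
    n_h = max(4, int(round(0.4 * n)))
    n_c = max(3, int(round(0.3 * n)))
    n_s = n - n_h - n_c
    helix = _helix_coords(n_h)
    coil = _attach(helix, _coil_coords(n_c, rng), rng)
    strand = _attach(coil, _strand_coords(n_s), rng)
    return np.vstack([helix, coil, strand])


# ---------------------------------------------------------------------------
# sequence builder
# ---------------------------------------------------------------------------

def _draw_sequence(n: int, composition, rng: np.random.Generator) -> str:
    comp = np.asarray(composition, dtype=float)
    base = np.floor(comp * n).astype(int)
    rem = comp * n - base
    for k in np.argsort(-rem)[: n - base.sum()]:
        base[k] += 1
    letters = []
    for count, cls in zip(base, CLASS_NAMES):
        pool = _CLASS_ALPHABET[cls]
        letters.extend(rng.choice(pool, size=count))
    perm = rng.permutation(n)
    return "".join(np.array(letters)[perm])


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------

def make_toy_protein(spec: ToyProteinSpec) -> CGProtein:
    """Build a synthetic Cα-bead protein realizing the requested motif."""
    rng = np.random.default_rng(spec.seed)
    if spec.motif == "helix":
        coords = _helix_coords(spec.n_residues)
    elif spec.motif == "hairpin":
        coords = _hairpin_coords(spec.n_residues)
    elif spec.motif == "coil":
        coords = _coil_coords(spec.n_residues, rng)
    else:
        coords = _mixed_coords(spec.n_residues, rng)
    sequence = _draw_sequence(spec.n_residues, spec.composition, rng)
    return CGProtein(coords=coords, sequence=sequence)


def hairpin_strand_indices(n_residues: int) -> tuple[np.ndarray, np.ndarray]:
    """Bead index ranges of the two strands of a generated hairpin."""
    ns = n_residues - TURN_RESIDUES
    l1 = (ns + 1) // 2
    return (np.arange(l1), np.arange(l1 + TURN_RESIDUES, n_residues))


def make_adsorption_series(spec: SyntheticAdsorptionSpec) -> AdsorptionCurve:
    """Stretched-exponential adsorption series with Gaussian counting noise,
    rounded to whole proteins and clipped at zero."""
    rng = np.random.default_rng(spec.seed)
    t_max = spec.t_max if spec.t_max is not None else 10.0 * spec.tau
    t = np.linspace(0.0, t_max, spec.n_points)
    signal = spec.n_max * (1.0 - np.exp(-(t / spec.tau) ** spec.alpha))
    noise = rng.normal(0.0, spec.noise_sd, size=t.shape) \
        if spec.noise_sd > 0 else 0.0
    n = np.clip(np.round(signal + noise), 0.0, None)
    return AdsorptionCurve(times=t, total=n)


def make_contact_fixture(n_residues: int, persistence_fractions,
                         n_frames: int) -> ContactTrace:
    """Contact matrix in which residue i touches the NP in exactly
    round(fraction_i · n_frames) frames (the leading frames), with the
    protein flagged adsorbed in every frame."""
    frac = np.broadcast_to(np.asarray(persistence_fractions, dtype=float),
                           (n_residues,))
    if np.any(frac < 0) or np.any(frac > 1):
        raise InvalidSpecError("persistence fractions must be in [0, 1]")
    counts = np.round(frac * n_frames).astype(int)
    matrix = np.zeros((n_residues, n_frames), dtype=bool)
    for i, k in enumerate(counts):
        matrix[i, :k] = True
    return ContactTrace(matrix=matrix,
                        adsorbed=np.ones(n_frames, dtype=bool))
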