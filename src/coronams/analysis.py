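"""Trajectory analysis: contacts, binding sites, adsorption capacity,
geometric capacity estimators, and Cα secondary structure.

Conventions
-----------
* A residue is in *contact* with the nanoparticle in a frame when its Cα bead
  is strictly closer than 6.5 Å to the NP surface.
* The *binding site* is the set of residues in contact for at least 70% of
  the protein's total NP-interaction time (the number of adsorbed frames).
* The adsorption capacity N_max is estimated by fitting the bound-count
  series with the stretched exponential N(t) = N_max(1 − exp(−(t/τ)^α)).
* Secondary structure is assigned from Cα geometry alone, in the spirit of
  P-SEA: i→i+3 distances and pseudo-dihedrals identify helices, i→i+2
  distances and pseudo-angles identify strands, with short runs smoothed out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from . import _geometry as geom
from .constants import CLASS_NAMES, RESIDUE_CLASS
from .curves import AdsorptionCurve
from .exceptions import FitFailureError
from .structure import CGProtein

__all__ = [
    "ContactTrace", "BindingSite", "ContactProbability",
    "ResidueClassScheme", "SSAssignment", "CapacityFitResults",
    "StretchedExponentialModel",
    "contact_trace", "contact_probability", "binding_site", "n_bound_curve",
    "fit_capacity", "stretched_exponential",
    "nmax_wang", "nmax_calzolai", "nmax_dellorco",
    "assign_secondary_structure", "ss_change",
]

CONTACT_CUTOFF = 6.5       # Å, Cα to NP surface
PERSISTENCE_THRESHOLD = 0.70


@dataclass
class ContactTrace:
    """Boolean residue × frame contact matrix plus per-frame adsorbed flag."""

    matrix: np.ndarray
    adsorbed: np.ndarray = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=bool)
        if self.matrix.ndim != 2:
            raise ValueError("contact matrix must be residues × frames")
        if self.adsorbed is None:
            self.adsorbed = self.matrix.any(axis=0)
        self.adsorbed = np.asarray(self.adsorbed, dtype=bool)
        if self.adsorbed.shape != (self.matrix.shape[1],):
            raise ValueError("adsorbed flags must match the frame count")
        if np.any(self.matrix.any(axis=0) & ~self.adsorbed):
            raise ValueError("frame with residue contact not flagged adsorbed")

    @property
    def n_residues(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[1]

    @property
    def interaction_time(self) -> int:
        """Number of adsorbed frames."""
        return int(self.adsorbed.sum())


@dataclass(frozen=True)
class BindingSite:
    """Residues persistently in contact, with their persistence fractions."""

    residues: np.ndarray
    fractions: np.ndarray
    threshold: float = PERSISTENCE_THRESHOLD

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ResidueClassScheme:
    """Partition of the 20 residue types into non-polar/polar/charged."""

    mapping: dict = field(default_factory=lambda: dict(RESIDUE_CLASS))

    def __post_init__(self):
        labels = set(self.mapping.values())
        if not labels <= set(CLASS_NAMES):
            raise ValueError(f"unknown class labels {labels - set(CLASS_NAMES)}")
        if len(self.mapping) != 20:
            raise ValueError("partition must cover all 20 residue types")

    def classes(self, sequence: str) -> list[str]:
        return [self.mapping[aa] for aa in sequence]


@dataclass
class ContactProbability:
    """Per-residue contact probabilities and per-class contact shares."""

    per_residue: np.ndarray           # fraction of adsorbed frames in contact
    class_shares: dict                # % of all contact events per class
    n_adsorbed_frames: int


def contact_trace(traj, nano, cutoff: float = CONTACT_CUTOFF,
                  protein_index: int = 0) -> ContactTrace:
    """Contact matrix for one protein of a trajectory.

    `traj` may be an engine :class:`~coronams.cg.Trajectory` or a raw
    (n_frames, n_residues, 3) coordinate array.  A contact requires the
    bead-to-surface distance to be strictly below `cutoff`.
    """
    coords = getattr(traj, "protein_coords", None)
    coords = coords(protein_index) if callable(coords) else np.asarray(traj)
    if coords.ndim != 3:
        raise ValueError("expected (n_frames, n_residues, 3) coordinates")
    d = np.linalg.norm(coords - nano.center, axis=-1) - nano.radius
    matrix = (d < cutoff).T  # residues × frames
    return ContactTrace(matrix=matrix)


def contact_probability(trace: ContactTrace,
                        scheme: ResidueClassScheme | None = None,
                        sequence: str | None = None) -> ContactProbability:
    """Per-residue contact probability (normalized over adsorbed frames) and,
    if a sequence is given, the share of all contact events per residue
    class (shares sum to 100%)."""
    n_ads = trace.interaction_time
    if n_ads == 0:
        warnings.warn("protein never adsorbed; contact probabilities empty",
                      stacklevel=2)
        return ContactProbability(per_residue=np.zeros(trace.n_residues),
                                  class_shares={}, n_adsorbed_frames=0)
    per_residue = trace.matrix[:, trace.adsorbed].sum(axis=1) / n_ads
    shares = {}
    if sequence is not None:
        scheme = scheme or ResidueClassScheme()
        classes = np.array(scheme.classes(sequence))
        events = trace.matrix.sum(axis=1).astype(float)
        total = events.sum()
        if total > 0:
            shares = {c: 100.0 * events[classes == c].sum() / total
                      for c in CLASS_NAMES}
    return ContactProbability(per_residue=per_residue, class_shares=shares,
                              n_adsorbed_frames=n_ads)


def binding_site(trace: ContactTrace,
                 threshold: float = PERSISTENCE_THRESHOLD) -> BindingSite:
    """Residues in contact for at least `threshold` of the interaction time
    (inclusive comparison)."""
    n_ads = trace.interaction_time
    if n_ads == 0:
        return BindingSite(residues=np.empty(0, dtype=int),
                           fractions=np.empty(0), threshold=threshold)
    frac = trace.matrix.sum(axis=1) / n_ads
    members = np.flatnonzero(frac >= threshold)
    return BindingSite(residues=members, fractions=frac[members],
                       threshold=threshold)


def n_bound_curve(traj) -> AdsorptionCurve:
    """Bound-protein count per frame from a trajectory's adsorbed flags."""
    flags = np.asarray(traj.adsorbed_flags, dtype=bool)
    times = np.asarray(traj.times, dtype=float)
    if flags.size == 0:
        return AdsorptionCurve(times=np.empty(0), total=np.empty(0))
    total = flags.sum(axis=1).astype(float)
    per_type = {}
    labels = getattr(traj, "labels", None)
    if labels is not None:
        labels = np.asarray(labels)
        for lab in pd.unique(labels):
            per_type[str(lab)] = flags[:, labels == lab].sum(axis=1)
    return AdsorptionCurve(times=times, total=total, per_type=per_type)


# ---------------------------------------------------------------------------
# adsorption capacity: stretched-exponential model
# ---------------------------------------------------------------------------

def stretched_exponential(t, n_max, tau, alpha):
    """N(t) = N_max (1 − exp(−(t/τ)^α))."""
    t = np.asarray(t, dtype=float)
    return n_max * (1.0 - np.exp(-np.power(np.maximum(t, 0.0) / tau, alpha)))


@dataclass
class CapacityFitResults:
    """Estimates from a stretched-exponential capacity fit.

    ``params`` are (N_max, τ, α); ``bse`` their standard errors from the
    asymptotic covariance; ``resid_norm`` the RMS residual.  ``success`` is
    False for degenerate input or non-convergence, in which case the best
    candidate found (if any) is still reported.
    """

    n_max: float
    tau: float
    alpha: float
    bse: np.ndarray
    resid_norm: float
    success: bool
    n_points: int
    curve: AdsorptionCurve = None

    @property
    def params(self) -> np.ndarray:
        return np.array([self.n_max, self.tau, self.alpha])

    def summary(self) -> str:
        rows = [
            ("N_max (proteins)", self.n_max, self.bse[0]),
            ("tau (time)", self.tau, self.bse[1]),
            ("alpha (-)", self.alpha, self.bse[2]),
        ]
        lines = ["Stretched-exponential adsorption capacity fit",
                 "N(t) = N_max (1 - exp(-(t/tau)^alpha))",
                 "-" * 52,
                 f"{'parameter':<20}{'estimate':>14}{'std err':>14}"]
        for name, val, se in rows:
            lines.append(f"{name:<20}{val:>14.4g}{se:>14.3g}")
        lines.append("-" * 52)
        lines.append(f"{'n points':<20}{self.n_points:>14d}")
        lines.append(f"{'RMS residual':<20}{self.resid_norm:>14.4g}")
        lines.append(f"{'converged':<20}{str(self.success):>14}")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        if self.curve is not None:
            ax.plot(self.curve.times, self.curve.total, ".", ms=3,
                    label="data", color="0.5")
            tt = np.linspace(self.curve.times[0], self.curve.times[-1], 400)
            ax.plot(tt, stretched_exponential(tt, *self.params),
                    label="fit", color="C3")
        ax.set_xlabel("time")
        ax.set_ylabel("proteins bound")
        ax.legend()
        return ax


class StretchedExponentialModel:
    """Nonlinear least-squares model for adsorption saturation curves.

    Parameters
    ----------
    curve
        The N_bound(t) series to fit.

    Examples
    --------
    >>> res = StretchedExponentialModel(curve).fit()   # doctest: +SKIP
    >>> print(res.summary())                           # doctest: +SKIP
    """

    def __init__(self, curve: AdsorptionCurve):
        if len(curve) < 10:
            raise ValueError("need at least 10 points to fit")
        self.curve = curve

    def _starts(self):
        t, n = self.curve.times, self.curve.total
        n_top = max(float(n.max()), 1.0)
        half = 0.5 * n_top
        above = np.flatnonzero(n >= half)
        t_half = float(t[above[0]]) if len(above) else float(t[-1]) / 2
        t_half = max(t_half, float(t[1] - t[0]))
        for nm in (n_top, 1.2 * n_top):
            for tau in (t_half, max(float(t[-1]) / 5.0, t_half / 5.0)):
                for alpha in (0.5, 0.8, 1.0):
                    yield (nm, tau, alpha)

    def fit(self) -> CapacityFitResults:
        t, n = self.curve.times, self.curve.total
        if float(n.max()) <= 0 or np.allclose(n, n[0]):
            return CapacityFitResults(
                n_max=np.nan, tau=np.nan, alpha=np.nan,
                bse=np.full(3, np.nan), resid_norm=float("nan"),
                success=False, n_points=len(t), curve=self.curve)
        best = None
        bounds = ([1e-9, 1e-9, 1e-3], [np.inf, np.inf, 2.0])
        for p0 in self._starts():
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    popt, pcov = curve_fit(
                        stretched_exponential, t, n, p0=p0, bounds=bounds,
                        maxfev=20000)
            except (RuntimeError, ValueError):
                continue
            ssr = float(((stretched_exponential(t, *popt) - n) ** 2).sum())
            if best is None or ssr < best[0]:
                best = (ssr, popt, pcov)
        if best is None:
            return CapacityFitResults(
                n_max=np.nan, tau=np.nan, alpha=np.nan,
                bse=np.full(3, np.nan), resid_norm=float("nan"),
                success=False, n_points=len(t), curve=self.curve)
        ssr, popt, pcov = best
        with np.errstate(invalid="ignore"):
            bse = np.sqrt(np.diag(pcov))
        return CapacityFitResults(
            n_max=float(popt[0]), tau=float(popt[1]), alpha=float(popt[2]),
            bse=bse, resid_norm=float(np.sqrt(ssr / len(t))),
            success=True, n_points=len(t), curve=self.curve)


def fit_capacity(curve: AdsorptionCurve,
                 raise_on_failure: bool = False) -> CapacityFitResults:
    """Fit the stretched-exponential saturation law to a bound-count series."""
    res = StretchedExponentialModel(curve).fit()
    if raise_on_failure and not res.success:
        raise FitFailureError("capacity fit did not converge", best=res)
    return res


# ---------------------------------------------------------------------------
# geometric capacity estimators
# ---------------------------------------------------------------------------

def nmax_wang(r_np: float, r_g: float) -> int:
    """N_max = 4 R_NP² / R_G² (proteins as gyration-sized patches)."""
    if r_np <= 0 or r_g <= 0:
        raise ValueError("radii must be positive")
    return int(round(4.0 * r_np ** 2 / r_g ** 2))


def nmax_calzolai(r_np: float, r_prot: float) -> int:
    """N_max = 0.65[(R_NP + 2R_prot)³ − R_NP³]/R_prot³ (close-packed shell).

    Diverges as R_prot → 0; callers should treat sub-Å protein radii as
    outside the formula's domain.
    """
    if r_np <= 0 or r_prot <= 0:
        raise ValueError("radii must be positive")
    return int(round(0.65 * ((r_np + 2.0 * r_prot) ** 3 - r_np ** 3)
                     / r_prot ** 3))


def nmax_dellorco(r_np: float, r_prot: float) -> int:
    """N_max = 4(R_NP − R_prot)²/R_prot² (flat-disc projection)."""
    if r_prot <= 0 or r_np <= 0:
        raise ValueError("radii must be positive")
    if r_prot >= r_np:
        raise ValueError("formula requires R_prot < R_NP")
    return int(round(4.0 * (r_np - r_prot) ** 2 / r_prot ** 2))


# ---------------------------------------------------------------------------
# secondary structure from Cα geometry
# ---------------------------------------------------------------------------

HELIX_D13 = (5.0, 6.0)        # Å, Cα(i)–Cα(i+3)
HELIX_DIHEDRAL = (50.0, 30.0)  # deg: centre ± half-width
STRAND_D12 = (6.4, 7.0)       # Å, Cα(i)–Cα(i+2)
STRAND_MIN_ANGLE = 115.0      # deg, pseudo bond angle
STRAND_MIN_DIHEDRAL = 120.0   # deg, |pseudo-dihedral| of an extended chain
TURN_MAX_ANGLE = 100.0        # deg, chain-reversal criterion
MIN_HELIX_RUN = 4
MIN_STRAND_RUN = 3


@dataclass
class SSAssignment:
    """Per-residue secondary-structure labels and content percentages."""

    labels: np.ndarray            # 'H' | 'E' | 'T' | 'U'
    percentages: dict             # helix/sheet/turn/unordered, sums to 100

    @property
    def n_residues(self) -> int:
        return len(self.labels)


def _zero_short_runs(mask: np.ndarray, min_run: int) -> np.ndarray:
    out = mask.copy()
    n = len(mask)
    i = 0
    while i < n:
        if out[i]:
            j = i
            while j < n and out[j]:
                j += 1
            if j - i < min_run:
                out[i:j] = False
            i = j
        else:
            i += 1
    return out


def assign_secondary_structure(p: CGProtein,
                               coords: np.ndarray | None = None
                               ) -> SSAssignment:
    """Assign H/E/T/U labels from Cα geometry (P-SEA-style rules)."""
    coords = p.coords if coords is None else np.asarray(coords, dtype=float)
    n = len(coords)
    if n < 5:
        raise ValueError("need at least 5 residues for assignment")

    helix = np.zeros(n, dtype=bool)
    strand = np.zeros(n, dtype=bool)

    quads = np.column_stack([np.arange(n - 3), np.arange(1, n - 2),
                             np.arange(2, n - 1), np.arange(3, n)])
    d13 = np.linalg.norm(coords[quads[:, 3]] - coords[quads[:, 0]], axis=1)
    dih = np.rad2deg(geom.dihedrals(coords, quads))
    centre, half = HELIX_DIHEDRAL
    hwin = (d13 >= HELIX_D13[0]) & (d13 <= HELIX_D13[1]) \
        & (np.abs(np.rad2deg(geom.wrapped_angle(
            np.deg2rad(dih - centre)))) <= half)
    # a window asserts only its two central residues; isolated hits are
    # then removed by the run-length smoothing
    for i in np.flatnonzero(hwin):
        helix[i + 1:i + 3] = True

    triples = np.column_stack([np.arange(n - 2), np.arange(1, n - 1),
                               np.arange(2, n)])
    d12 = np.linalg.norm(coords[triples[:, 2]] - coords[triples[:, 0]],
                         axis=1)
    ang = np.rad2deg(geom.angles(coords, triples))
    # extended pseudo-dihedral at the window (nearest defined quad)
    qidx = np.minimum(np.arange(n - 2), n - 4)
    extended = np.abs(dih[qidx]) >= STRAND_MIN_DIHEDRAL
    ewin = (d12 >= STRAND_D12[0]) & (d12 <= STRAND_D12[1]) \
        & (ang >= STRAND_MIN_ANGLE) & extended
    for i in np.flatnonzero(ewin):
        strand[i + 1] = True

    strand &= ~helix
    helix = _zero_short_runs(helix, MIN_HELIX_RUN)
    strand = _zero_short_runs(strand, MIN_STRAND_RUN)

    labels = np.full(n, "U", dtype="<U1")
    labels[strand] = "E"
    labels[helix] = "H"
    # turns: unlabeled residues where the chain direction reverses
    for k, i in enumerate(triples[:, 1]):
        if labels[i] == "U" and (ang[k] < TURN_MAX_ANGLE
                                 or d12[k] < HELIX_D13[0]):
            labels[i] = "T"

    counts = {lab: int((labels == lab).sum()) for lab in "HETU"}
    pct = {
        "helix": 100.0 * counts["H"] / n,
        "sheet": 100.0 * counts["E"] / n,
        "turn": 100.0 * counts["T"] / n,
        "unordered": 100.0 * counts["U"] / n,
    }
    return SSAssignment(labels=labels, percentages=pct)


def ss_change(before: SSAssignment, after: SSAssignment) -> dict:
    """Per-category percentage-point changes (after − before)."""
    if before.n_residues != after.n_residues:
        raise ValueError("assignments are for different protein lengths")
    return {k: after.percentages[k] - before.percentages[k]
            for k in before.percentages}
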