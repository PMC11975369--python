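"""Inter-domain orientation triads and the bead-on-chain (BOC) reduction.

A *triad* is an orthonormal, right-handed body frame {e1, e2, e3}
attached to the folded β-sheet core of a variable domain.  At a
reference frame e3 is the long axis of the core (first principal axis,
oriented toward the C-module), e1 the β-sheet normal (third principal
axis) and e2 = e3 × e1; at every other frame the triad is the reference
triad carried along by the rigid-body (Kabsch) rotation of the core, so
arm identity is stable over the trajectory.

The BOC model reduces the chassis to one bead per domain core plus
hinge beads; the V–C bending angles ∠TCRα and ∠TCRβ are the three-bead
angles at the hinges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .system import MolecularSystem, SelectionSpec, kabsch_rotation

__all__ = [
    "Triad",
    "TriadAngles",
    "BocModel",
    "HingeAngles",
    "reference_triad",
    "assign_triad",
    "triad_series",
    "triad_angles",
    "triad_angle_series",
    "cdr3_distance",
    "build_boc",
    "hinge_angles",
    "angle_at",
]

_ORTHO_TOL = 1e-8


@dataclass
class Triad:
    """Origin (Å) plus rows e1, e2, e3 of an orthonormal right-handed frame."""

    origin: np.ndarray
    arms: np.ndarray  # (3, 3), rows e1, e2, e3

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.arms = np.asarray(self.arms, dtype=float)
        if self.arms.shape != (3, 3):
            raise ValueError("arms must be a 3x3 array (rows e1, e2, e3)")
        G = self.arms @ self.arms.T
        if not np.allclose(G, np.eye(3), atol=1e-6):
            raise ValueError("triad arms are not orthonormal")
        if np.linalg.det(self.arms) < 0:
            raise ValueError("triad is left-handed (det < 0)")

    @property
    def e1(self) -> np.ndarray:
        return self.arms[0]

    @property
    def e2(self) -> np.ndarray:
        return self.arms[1]

    @property
    def e3(self) -> np.ndarray:
        return self.arms[2]

    def rotated(self, R: np.ndarray, origin: np.ndarray | None = None) -> "Triad":
        return Triad(self.origin if origin is None else origin, self.arms @ R.T)

    def anchor_points(self, arm_length: float = 10.0) -> np.ndarray:
        """Origin plus the three arm tips; a 4x3 array used for PCA input."""
        return np.vstack([self.origin, self.origin + arm_length * self.arms])


@dataclass(frozen=True)
class TriadAngles:
    """Angles (deg) between matching arms of two triads, each in [0, 180]."""

    e1: float
    e2: float
    e3: float

    def as_array(self) -> np.ndarray:
        return np.array([self.e1, self.e2, self.e3])


def _orient(v: np.ndarray, hint: np.ndarray | None) -> np.ndarray:
    """Fix the sign of a principal axis: along `hint` if given, else make
    the largest-magnitude component positive (deterministic)."""
    if hint is not None:
        return v if float(np.dot(v, hint)) >= 0 else -v
    k = int(np.argmax(np.abs(v)))
    return v if v[k] > 0 else -v


def reference_triad(
    core_coords: np.ndarray,
    long_axis_hint: np.ndarray | None = None,
    normal_hint: np.ndarray | None = None,
) -> Triad:
    """Define the reference triad from core Cα coordinates.

    e3 = first principal axis (long axis; oriented along
    ``long_axis_hint``, conventionally the V→C direction), e1 = third
    principal axis (β-sheet normal), e2 = e3 × e1.
    """
    X = np.asarray(core_coords, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3 or X.shape[0] < 3:
        raise ValueError("core_coords must be (n>=3, 3)")
    origin = X.mean(axis=0)
    Xc = X - origin
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise ValueError("core is collinear; cannot define a triad")
    e3 = _orient(Vt[0], long_axis_hint)
    e1 = _orient(Vt[2], normal_hint)
    e2 = np.cross(e3, e1)
    return Triad(origin, np.vstack([e1, e2, e3]))


def assign_triad(
    core_current: np.ndarray,
    core_reference: np.ndarray,
    ref_triad: Triad,
    rmsd_warn: float = 3.0,
) -> Triad:
    """Carry the reference triad to the current frame by the rigid-fit
    rotation of the core; origin = current core centroid.

    Warns if the core fits the reference worse than ``rmsd_warn`` Å
    (the core may be unfolding)."""
    cur = np.asarray(core_current, dtype=float)
    ref = np.asarray(core_reference, dtype=float)
    if cur.shape != ref.shape:
        raise ValueError("current and reference cores differ in atom count")
    cur_c = cur - cur.mean(axis=0)
    ref_c = ref - ref.mean(axis=0)
    R = kabsch_rotation(ref_c, cur_c)  # rotates reference orientation into current
    fitted = ref_c @ R.T
    rmsd = float(np.sqrt(((fitted - cur_c) ** 2).sum() / len(cur)))
    if rmsd > rmsd_warn:
        warnings.warn(
            f"core RMSD to reference is {rmsd:.2f} Å (> {rmsd_warn} Å); core may be unfolding",
            stacklevel=2,
        )
    return ref_triad.rotated(R, origin=cur.mean(axis=0))


def triad_series(
    system: MolecularSystem,
    core: SelectionSpec | np.ndarray,
    reference_frame: int = 0,
    long_axis_hint: np.ndarray | None = None,
    normal_hint: np.ndarray | None = None,
) -> list[Triad]:
    """Per-frame triads for one domain core (Cα selection)."""
    idx = core.resolve(system) if isinstance(core, SelectionSpec) else np.asarray(core, dtype=int)
    ref_coords = system.frames[reference_frame][idx]
    ref = reference_triad(ref_coords, long_axis_hint, normal_hint)
    out = []
    for f in range(system.n_frames):
        out.append(assign_triad(system.frames[f][idx], ref_coords, ref))
    return out


def triad_angles(triad_a: Triad, triad_b: Triad) -> TriadAngles:
    """∠ei = arccos of the dot product of matching arms, in degrees."""
    vals = []
    for i in range(3):
        a, b = triad_a.arms[i], triad_b.arms[i]
        for v in (a, b):
            if abs(np.linalg.norm(v) - 1.0) > 1e-6:
                raise ValueError("triad arm is not unit length")
        vals.append(float(np.degrees(np.arccos(np.clip(np.dot(a, b), -1.0, 1.0)))))
    return TriadAngles(*vals)


def triad_angle_series(triads_a: Sequence[Triad], triads_b: Sequence[Triad]) -> np.ndarray:
    """(n_frames, 3) array of ∠e1, ∠e2, ∠e3 in degrees."""
    if len(triads_a) != len(triads_b):
        raise ValueError("triad series have different lengths")
    return np.array([triad_angles(a, b).as_array() for a, b in zip(triads_a, triads_b)])


def cdr3_distance(
    system: MolecularSystem,
    alpha_base: SelectionSpec,
    beta_base: SelectionSpec,
) -> np.ndarray:
    """Distance (Å) between the CDR3α and CDR3β base midpoints, per frame.

    Each selection must resolve to exactly two Cα atoms (the residues at
    the base of the loop); the distance is between the two midpoints.
    """
    idx_a = alpha_base.resolve(system)
    idx_b = beta_base.resolve(system)
    for name, idx in ((alpha_base.name, idx_a), (beta_base.name, idx_b)):
        if idx.size != 2:
            raise ValueError(f"CDR3 base selection {name!r} must resolve to 2 Cα atoms, got {idx.size}")
    mid_a = system.frames[:, idx_a, :].mean(axis=1)
    mid_b = system.frames[:, idx_b, :].mean(axis=1)
    return np.linalg.norm(mid_b - mid_a, axis=1)


# ----------------------------------------------------------------------
# Bead-on-chain
# ----------------------------------------------------------------------

BOC_BEADS = ("Valpha", "Halpha", "Calpha", "Vbeta", "Hbeta", "Cbeta", "Cmodule")


@dataclass
class BocModel:
    """Bead positions over frames: dict label -> (n_frames, 3) array."""

    beads: dict
    frame_times: np.ndarray

    def __post_init__(self) -> None:
        for label, pos in self.beads.items():
            pos = np.asarray(pos, dtype=float)
            if not np.all(np.isfinite(pos)):
                raise ValueError(f"bead {label!r} has non-finite positions")
            self.beads[label] = pos

    @property
    def n_frames(self) -> int:
        return next(iter(self.beads.values())).shape[0]

    def coordinates(self, labels: Sequence[str]) -> np.ndarray:
        """(n_frames, 3 * len(labels)) flattened bead coordinates."""
        return np.concatenate([self.beads[lab] for lab in labels], axis=1)


@dataclass(frozen=True)
class HingeAngles:
    """V–hinge–C bending angles per chain, degrees, each in (0, 180]."""

    tcr_alpha: np.ndarray
    tcr_beta: np.ndarray


def build_boc(system: MolecularSystem, selections: Mapping[str, SelectionSpec]) -> BocModel:
    """Build the BOC from Cα selections.

    ``selections`` must provide ``Valpha, Vbeta, Calpha, Cbeta`` (domain
    cores) and ``Halpha, Hbeta`` (hinge residues).  Each bead is the
    unweighted Cα centroid of its selection; the C-module bead is the
    midpoint of the Cα and Cβ beads.
    """
    required = ("Valpha", "Halpha", "Calpha", "Vbeta", "Hbeta", "Cbeta")
    missing = [k for k in required if k not in selections]
    if missing:
        raise ValueError(f"missing BOC selections: {missing}")
    beads = {}
    for label in required:
        idx = selections[label].resolve(system)
        beads[label] = system.frames[:, idx, :].mean(axis=1)
    beads["Cmodule"] = 0.5 * (beads["Calpha"] + beads["Cbeta"])
    return BocModel(beads, system.frame_times.copy())


def angle_at(vertex: np.ndarray, p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Angle (deg) at ``vertex`` between directions to p and q; vectorised
    over leading axes."""
    u = p - vertex
    v = q - vertex
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    if np.any(nu < 1e-12) or np.any(nv < 1e-12):
        raise ValueError("zero-length limb vector at hinge")
    c = np.clip(np.einsum("...i,...i->...", u, v) / (nu * nv), -1.0, 1.0)
    return np.degrees(np.arccos(c))


def hinge_angles(boc: BocModel) -> HingeAngles:
    """∠TCRα = angle at Hα between Vα and Cα beads; ∠TCRβ analogous."""
    a = angle_at(boc.beads["Halpha"], boc.beads["Valpha"], boc.beads["Calpha"])
    b = angle_at(boc.beads["Hbeta"], boc.beads["Vbeta"], boc.beads["Cbeta"])
    return HingeAngles(tcr_alpha=a, tcr_beta=b)
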