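"""Applied-load and extension bookkeeping for restrained terminal atoms.

Tensile load is applied in simulation by holding terminal Cα atoms in
harmonic (optionally flat-bottomed) potentials.  This module recovers
the per-frame restoring forces from atom displacements, reduces them to
a scalar applied load by projecting each end's net force onto the
instantaneous end-to-end axis, and reports rolling-window statistics
(default 40 ns windows, 20 ns stride).  Forces are converted with
1 kcal/(mol·Å) = 69.48 pN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import constants as _const

from .system import MolecularSystem

__all__ = [
    "KCAL_PER_MOL_ANGSTROM_IN_PN",
    "Restraint",
    "RestraintDef",
    "MechanicsTrace",
    "ExtensionTrace",
    "restraint_force_series",
    "extension_series",
    "make_windows",
    "windowed_stats",
]

# 1 kcal/(mol Å) expressed in pN (thermochemical calorie).
KCAL_PER_MOL_ANGSTROM_IN_PN = (
    1000.0 * _const.calorie / _const.Avogadro / 1e-10 / 1e-12
)  # ≈ 69.48


@dataclass
class Restraint:
    """One harmonically restrained atom.

    k in kcal/(mol·Å²); ``flat_bottom`` is the half-width (Å) of the
    zero-force region around the centre; ``end`` labels which molecular
    end the restraint belongs to (e.g. "mhc" or "tcr").
    """

    residue: tuple[str, int]
    center: np.ndarray
    atom_name: str = "CA"
    k: float = 1.0
    flat_bottom: float = 0.0
    end: str = ""

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("spring constant must be non-negative")
        self.center = np.asarray(self.center, dtype=float)
        if self.center.shape != (3,):
            raise ValueError("restraint centre must be a 3-vector")


@dataclass
class RestraintDef:
    restraints: list[Restraint] = field(default_factory=list)

    def ends(self) -> list[str]:
        return list(dict.fromkeys(r.end for r in self.restraints))


def _atom_index(system: MolecularSystem, residue: tuple[str, int], atom_name: str) -> int:
    a = system.atoms
    mask = (
        (a["chain_id"] == residue[0])
        & (a["resseq"] == residue[1])
        & (a["atom_name"] == atom_name)
    )
    hits = np.nonzero(mask.to_numpy())[0]
    if hits.size != 1:
        raise ValueError(
            f"restrained atom {residue[0]}:{residue[1]}:{atom_name} "
            f"matches {hits.size} atoms (need exactly 1)"
        )
    return int(hits[0])


def make_windows(t0: float, t_end: float, window_ns: float, stride_ns: float) -> list[tuple[float, float]]:
    """Rolling [start, start+window) windows at the given stride."""
    out = []
    s = t0
    while s + window_ns <= t_end + 1e-9:
        out.append((s, s + window_ns))
        s += stride_ns
    return out


def windowed_stats(values: np.ndarray, times: np.ndarray, windows) -> tuple[np.ndarray, np.ndarray]:
    """Mean and std of a per-frame series in each window."""
    means = np.full(len(windows), np.nan)
    stds = np.full(len(windows), np.nan)
    for w, (s, e) in enumerate(windows):
        m = (times >= s - 1e-9) & (times < e - 1e-9)
        if m.any():
            means[w] = values[m].mean()
            stds[w] = values[m].std()
    return means, stds


@dataclass
class MechanicsTrace:
    """Per-frame restraint forces and the reduced applied load (pN)."""

    frame_times: np.ndarray
    per_restraint_magnitude: np.ndarray   # (n_restraints, n_frames) pN
    per_end_load: dict                    # end -> signed per-frame load (pN)
    load: np.ndarray                      # mean of the per-end loads (pN)
    windows: list
    window_mean: np.ndarray
    window_std: np.ndarray

    def average(self, interval: tuple[float, float]) -> float:
        lo, hi = interval
        m = (self.frame_times >= lo) & (self.frame_times < hi)
        if not m.any():
            raise ValueError(f"no frames in interval {interval}")
        return float(self.load[m].mean())

    def window_std_over(self, interval: tuple[float, float]) -> float:
        """Std of the windowed mean load across windows inside the interval."""
        lo, hi = interval
        cols = [i for i, (s, e) in enumerate(self.windows) if s >= lo - 1e-9 and e <= hi + 1e-9]
        if not cols:
            raise ValueError(f"no windows inside {interval}")
        return float(np.std(self.window_mean[cols]))


def restraint_force_series(
    system: MolecularSystem,
    restraints: RestraintDef,
    window_ns: float = 40.0,
    stride_ns: float = 20.0,
) -> MechanicsTrace:
    """Restoring forces on restrained atoms and the scalar applied load.

    Per frame, each restraint exerts F = k · max(|x − c| − w, 0) toward
    its centre.  The net force vector of each end is projected onto the
    instantaneous end-to-end axis (outward positive, so pure tension is
    positive at both ends); the reported load is the mean of the
    per-end projections.
    """
    if not restraints.restraints:
        raise ValueError("no restraints defined")
    ends = restraints.ends()
    if len(ends) != 2:
        raise ValueError(f"load reduction needs exactly 2 ends, got {ends}")

    idx = [_atom_index(system, r.residue, r.atom_name) for r in restraints.restraints]
    X = system.frames[:, idx, :]                          # (F, R, 3)
    centers = np.array([r.center for r in restraints.restraints])
    ks = np.array([r.k for r in restraints.restraints])
    ws = np.array([r.flat_bottom for r in restraints.restraints])

    disp = X - centers[None, :, :]
    dist = np.linalg.norm(disp, axis=2)
    excess = np.clip(dist - ws[None, :], 0.0, None)
    mag_kcal = ks[None, :] * excess                       # kcal/(mol Å)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(dist[..., None] > 1e-12, disp / np.maximum(dist, 1e-12)[..., None], 0.0)
    fvec = -mag_kcal[..., None] * unit * KCAL_PER_MOL_ANGSTROM_IN_PN   # pN, restoring

    end_of = np.array([r.end for r in restraints.restraints])
    end_atoms = {e: np.nonzero(end_of == e)[0] for e in ends}
    cent = {e: X[:, end_atoms[e], :].mean(axis=1) for e in ends}
    axis = cent[ends[1]] - cent[ends[0]]
    norm = np.linalg.norm(axis, axis=1, keepdims=True)
    axis = axis / np.maximum(norm, 1e-12)

    per_end = {}
    # outward unit vector: -axis at ends[0], +axis at ends[1]
    for e, sign in ((ends[0], -1.0), (ends[1], 1.0)):
        net = fvec[:, end_atoms[e], :].sum(axis=1)
        per_end[e] = (net * (sign * axis)).sum(axis=1)
    load = 0.5 * (per_end[ends[0]] + per_end[ends[1]])

    t = system.frame_times
    dt = t[1] - t[0] if len(t) > 1 else 0.0
    windows = make_windows(float(t[0]), float(t[-1]) + dt, window_ns, stride_ns)
    wmean, wstd = windowed_stats(load, t, windows) if windows else (np.empty(0), np.empty(0))

    return MechanicsTrace(
        frame_times=t.copy(),
        per_restraint_magnitude=mag_kcal.T * KCAL_PER_MOL_ANGSTROM_IN_PN,
        per_end_load=per_end,
        load=load,
        windows=windows,
        window_mean=wmean,
        window_std=wstd,
    )


@dataclass
class ExtensionTrace:
    """Setting (centre-to-centre) and realized (atom-to-atom) extension, Å."""

    setting: float
    realized: np.ndarray
    frame_times: np.ndarray
    windows: list
    window_mean: np.ndarray
    window_std: np.ndarray


def extension_series(
    system: MolecularSystem,
    end_atoms: tuple[tuple[str, int], tuple[str, int]],
    centers: tuple[np.ndarray, np.ndarray],
    atom_name: str = "CA",
    window_ns: float = 40.0,
    stride_ns: float = 20.0,
) -> ExtensionTrace:
    """Extension between the two terminal restraints.

    The *setting* is the distance between the two potential centres (the
    quantity quoted as a simulation's extension); the *realized*
    extension is the per-frame distance between the restrained atoms.
    """
    c0 = np.asarray(centers[0], dtype=float)
    c1 = np.asarray(centers[1], dtype=float)
    setting = float(np.linalg.norm(c1 - c0))
    if setting < 1e-9:
        warnings.warn("terminal restraint centres coincide", stacklevel=2)
    i0 = _atom_index(system, end_atoms[0], atom_name)
    i1 = _atom_index(system, end_atoms[1], atom_name)
    realized = np.linalg.norm(system.frames[:, i1, :] - system.frames[:, i0, :], axis=1)
    t = system.frame_times
    dt = t[1] - t[0] if len(t) > 1 else 0.0
    windows = make_windows(float(t[0]), float(t[-1]) + dt, window_ns, stride_ns)
    wmean, wstd = windowed_stats(realized, t, windows) if windows else (np.empty(0), np.empty(0))
    return ExtensionTrace(setting, realized, t.copy(), windows, wmean, wstd)
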