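"""Buried surface area, RMSF and the V-module–pMHC floor distance.

SASA uses the Shrake–Rupley spherical point-sampling algorithm with a
deterministic golden-spiral point set (default 960 points/atom, probe
1.4 Å) and a standard heavy-atom radius set; hydrogens are excluded.
BSA is differenced SASA: per-residue BSA = SASA(residue in its isolated
part) − SASA(residue in the complex), averaged over trajectory frames.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .contacts import instantaneous_contacts
from .system import MolecularSystem, SelectionSpec, resolve_selections, superpose

__all__ = [
    "SasaResult",
    "BsaResult",
    "RmsfProfile",
    "DEFAULT_RADII",
    "sphere_points",
    "shrake_rupley_sasa",
    "buried_surface_area",
    "rmsf",
    "v_pmhc_distance",
]

# Heavy-atom van der Waals radii (Å), Chothia-style values.
DEFAULT_RADII: Mapping[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "Se": 1.90,
    "H": 1.20,
}


def sphere_points(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere points (golden spiral)."""
    if n < 1:
        raise ValueError("need at least one sphere point")
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


@dataclass
class SasaResult:
    """Per-atom solvent-accessible surface area (Å²)."""

    area: np.ndarray
    atom_indices: np.ndarray
    probe: float
    n_points: int

    @property
    def total(self) -> float:
        return float(self.area.sum())


def shrake_rupley_sasa(
    coords: np.ndarray,
    elements: Sequence[str],
    probe: float = 1.4,
    n_points: int = 960,
    radii: Mapping[str, float] | None = None,
) -> SasaResult:
    """Shrake–Rupley SASA of one atom set in one frame.

    Each atom's accessible area is 4π(r+probe)² times the fraction of
    its test points not occluded by any neighbour's expanded sphere.
    """
    X = np.asarray(coords, dtype=float)
    elements = list(elements)
    if X.shape[0] != len(elements):
        raise ValueError("coords and elements disagree in length")
    table = dict(DEFAULT_RADII)
    if radii:
        table.update(radii)
    try:
        r = np.array([table[e] for e in elements])
    except KeyError as exc:
        raise ValueError(f"no radius for element {exc.args[0]!r}; pass radii={{...}}") from None

    R = r + probe
    pts = sphere_points(n_points)
    area = np.empty(len(X))
    tree = cKDTree(X)
    rmax = R.max()
    for i in range(len(X)):
        nbrs = [j for j in tree.query_ball_point(X[i], R[i] + rmax) if j != i]
        test = X[i] + R[i] * pts
        if nbrs:
            acc = np.ones(n_points, dtype=bool)
            for j in nbrs:
                d2 = ((test - X[j]) ** 2).sum(axis=1)
                acc &= d2 >= R[j] * R[j]
            frac = acc.mean()
        else:
            frac = 1.0
        area[i] = 4.0 * np.pi * R[i] * R[i] * frac
    return SasaResult(area=area, atom_indices=np.arange(len(X)), probe=probe, n_points=n_points)


@dataclass
class BsaResult:
    """Per-residue and total buried surface area (Å²), frame-averaged."""

    per_residue: dict              # (chain, resseq) -> mean BSA
    interface_residues: list
    interval: tuple[float, float]
    n_frames_used: int
    probe: float
    n_points: int

    @property
    def total(self) -> float:
        return float(sum(self.per_residue[r] for r in self.interface_residues))

    def part_total(self, chain_ids: set[str]) -> float:
        return float(
            sum(v for (c, _), v in self.per_residue.items() if c in chain_ids)
        )


def _heavy_idx(system: MolecularSystem, part) -> np.ndarray:
    specs = [part] if isinstance(part, SelectionSpec) else list(part)
    idx = resolve_selections(system, specs)
    el = system.atoms["element"].to_numpy()
    return idx[el[idx] != "H"]


def buried_surface_area(
    system: MolecularSystem,
    part_a,
    part_b,
    probe: float = 1.4,
    n_points: int = 960,
    interval: tuple[float, float] | None = None,
    stride_ns: float | None = 1.0,
    contact_cutoff: float = 4.0,
    interface_residues: Sequence | None = None,
    radii: Mapping[str, float] | None = None,
) -> BsaResult:
    """Trajectory-averaged BSA across the interface of two parts.

    Interface residues default to every residue appearing in any
    instantaneous contact (heavy-atom cutoff ``contact_cutoff``) in the
    frames analysed.  Frames are subsampled at ``stride_ns`` (None uses
    every frame in the interval).
    """
    idx_a = _heavy_idx(system, part_a)
    idx_b = _heavy_idx(system, part_b)
    if np.intersect1d(idx_a, idx_b).size:
        raise ValueError("parts overlap; BSA requires disjoint atom sets")

    t = system.frame_times
    if interval is None:
        interval = (float(t[0]), float(t[-1]) + 1e-9)
    lo, hi = interval
    frame_ids = np.nonzero((t >= lo) & (t < hi))[0]
    if frame_ids.size == 0:
        raise ValueError(f"no frames in interval {interval}")
    if stride_ns is not None and len(frame_ids) > 1:
        dt = t[1] - t[0]
        step = max(1, int(round(stride_ns / dt)))
        frame_ids = frame_ids[::step]

    a = system.atoms
    chains = a["chain_id"].to_numpy()
    resseq = a["resseq"].to_numpy()
    el = a["element"].to_numpy()

    def residues_of(idx):
        return [(chains[i], int(resseq[i])) for i in idx]

    res_a = residues_of(idx_a)
    res_b = residues_of(idx_b)

    if interface_residues is None:
        found: set = set()
        for f in frame_ids:
            for pa, pb in instantaneous_contacts(system, int(f), part_a, part_b, contact_cutoff):
                found.add(pa)
                found.add(pb)
        interface_residues = sorted(found)
    interface_residues = list(interface_residues)

    both = np.concatenate([idx_a, idx_b])
    accum: dict = {}
    for f in frame_ids:
        X = system.frames[f]
        iso_a = shrake_rupley_sasa(X[idx_a], el[idx_a], probe, n_points, radii)
        iso_b = shrake_rupley_sasa(X[idx_b], el[idx_b], probe, n_points, radii)
        cpx = shrake_rupley_sasa(X[both], el[both], probe, n_points, radii)
        iso = np.concatenate([iso_a.area, iso_b.area])
        delta = iso - cpx.area
        refs = res_a + res_b
        per: dict = {}
        for ref, d in zip(refs, delta):
            per[ref] = per.get(ref, 0.0) + d
        for ref, v in per.items():
            accum[ref] = accum.get(ref, 0.0) + v

    n_used = len(frame_ids)
    per_residue = {ref: v / n_used for ref, v in accum.items()}
    return BsaResult(
        per_residue=per_residue,
        interface_residues=interface_residues,
        interval=(float(lo), float(hi)),
        n_frames_used=n_used,
        probe=probe,
        n_points=n_points,
    )


@dataclass
class RmsfProfile:
    """Per-atom RMSF (Å) after superposition on the fit selection."""

    values: np.ndarray
    atom_indices: np.ndarray
    t_start: float
    n_frames_used: int


def rmsf(
    system: MolecularSystem,
    target_set,
    fit_set,
    t_start: float = 500.0,
) -> RmsfProfile:
    """RMSF_i = sqrt(mean_t |r_i(t) − ⟨r_i⟩|²) over frames with
    t >= t_start, after rigid superposition on ``fit_set``."""
    t = system.frame_times
    frame_ids = np.nonzero(t >= t_start)[0]
    if frame_ids.size < 2:
        raise ValueError(
            f"need >=2 frames after t_start={t_start} ns; trajectory ends at {t[-1]:.3f} ns"
        )
    sub = system.with_frames(system.frames[frame_ids], t[frame_ids])
    fitted, _ = superpose(sub, 0, fit_set)
    target_idx = (
        target_set.resolve(system)
        if isinstance(target_set, SelectionSpec)
        else resolve_selections(system, list(target_set))
    )
    traj = fitted.frames[:, target_idx, :]
    mean = traj.mean(axis=0)
    dev = traj - mean
    vals = np.sqrt((dev ** 2).sum(axis=2).mean(axis=0))
    return RmsfProfile(values=vals, atom_indices=target_idx, t_start=t_start,
                       n_frames_used=int(frame_ids.size))


def v_pmhc_distance(
    system: MolecularSystem,
    v_core,
    mhc_floor: SelectionSpec,
    expected_floor_atoms: int = 20,
) -> np.ndarray:
    """Per-frame distance between the Cα centroid of the V-module triad
    cores and the Cα centroid of the MHC floor strands (20 atoms)."""
    floor_idx = mhc_floor.resolve(system)
    if expected_floor_atoms and floor_idx.size != expected_floor_atoms:
        raise ValueError(
            f"MHC floor selection resolves to {floor_idx.size} Cα atoms, expected {expected_floor_atoms}"
        )
    v_idx = (
        v_core.resolve(system)
        if isinstance(v_core, SelectionSpec)
        else resolve_selections(system, list(v_core))
    )
    cv = system.frames[:, v_idx, :].mean(axis=1)
    cf = system.frames[:, floor_idx, :].mean(axis=1)
    return np.linalg.norm(cv - cf, axis=1)
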