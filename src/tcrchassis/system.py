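"""Structures, trajectories, selections and rigid-body superposition.

The central container is :class:`MolecularSystem`: a flat atom table
(pandas DataFrame) plus a stack of coordinate frames in Å with frame
times in ns.  Structures are read from PDB files via Biopython and
trajectories from DCD/XTC via MDAnalysis; everything downstream operates
on plain numpy arrays.

Conventions: coordinates in Å, times in ns, the first production frame
is t = 0.  Residue selections address *renumbered* residue numbers
(1..N per chain, insertion codes collapsed), which is how the analysis
selections for real TCR structures are specified.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MolecularSystem",
    "SelectionSpec",
    "DomainMap",
    "load_structure",
    "renumber_sequential",
    "load_trajectory",
    "superpose",
    "kabsch_rotation",
    "write_pdb",
    "write_dcd",
    "frames_in_interval",
    "BACKBONE_ATOMS",
]

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

_WATER_RESNAMES = frozenset({"HOH", "WAT", "TIP3", "SOL", "DOD"})

ATOM_COLUMNS = ["atom_id", "atom_name", "element", "resname", "resseq", "icode", "chain_id"]


def _infer_element(atom_name: str) -> str:
    """Best-effort element from a PDB atom name (no element column)."""
    stripped = "".join(ch for ch in atom_name if ch.isalpha())
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    two = stripped[:2].capitalize()
    if two in {"Fe", "Zn", "Mg", "Mn", "Ca", "Na", "Cl", "Br", "Cu", "Ni", "Se"} and len(stripped) > 1:
        return two
    return stripped[0].upper()


@dataclass
class MolecularSystem:
    """Topology plus an ordered stack of coordinate frames.

    Parameters
    ----------
    atoms : pandas.DataFrame
        One row per atom with columns ``atom_id, atom_name, element,
        resname, resseq, icode, chain_id`` in file order.
    frames : ndarray, shape (n_frames, n_atoms, 3)
        Cartesian coordinates in Å.
    frame_times : ndarray, shape (n_frames,)
        Time stamps in ns, strictly increasing.
    box : ndarray or None
        Optional periodic box dimensions in Å.
    """

    atoms: pd.DataFrame
    frames: np.ndarray
    frame_times: np.ndarray
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError(f"frames must have shape (n_frames, n_atoms, 3), got {self.frames.shape}")
        if self.frames.shape[0] != self.frame_times.shape[0]:
            raise ValueError(
                f"{self.frames.shape[0]} frames but {self.frame_times.shape[0]} frame times"
            )
        if self.frames.shape[1] != len(self.atoms):
            raise ValueError(
                f"frames carry {self.frames.shape[1]} atoms but atom table has {len(self.atoms)}"
            )
        if len(self.frame_times) > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise ValueError("frame_times must be strictly increasing")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def copy(self) -> "MolecularSystem":
        return MolecularSystem(
            atoms=self.atoms.copy(),
            frames=self.frames.copy(),
            frame_times=self.frame_times.copy(),
            box=None if self.box is None else np.array(self.box),
        )

    def with_frames(self, frames: np.ndarray, frame_times: np.ndarray) -> "MolecularSystem":
        return MolecularSystem(self.atoms, frames, frame_times, self.box)

    # -- time helpers -------------------------------------------------
    def frame_indices_between(self, t_start: float, t_end: float) -> np.ndarray:
        """Indices of frames with t_start <= t < t_end (ns)."""
        t = self.frame_times
        return np.nonzero((t >= t_start) & (t < t_end))[0]

    def chains(self) -> list[str]:
        return list(dict.fromkeys(self.atoms["chain_id"]))

    # -- residue helpers ----------------------------------------------
    def residue_index(self) -> pd.DataFrame:
        """One row per residue (chain_id, resseq, resname) in atom order."""
        a = self.atoms
        keys = a[["chain_id", "resseq", "resname"]]
        return keys.loc[~keys.duplicated(subset=["chain_id", "resseq"])].reset_index(drop=True)


@dataclass(frozen=True)
class SelectionSpec:
    """Named residue selection within one chain.

    ``residues`` mixes inclusive (first, last) pairs and single residue
    numbers, interpreted against renumbered ``resseq`` values.
    ``atom_filter`` is one of ``CA``, ``backbone``, ``heavy``, ``all``.
    """

    name: str
    chain_id: str
    residues: tuple = ()
    atom_filter: str = "CA"

    _FILTERS = ("CA", "backbone", "heavy", "all")

    def __post_init__(self) -> None:
        if self.atom_filter not in self._FILTERS:
            raise ValueError(f"atom_filter must be one of {self._FILTERS}, got {self.atom_filter!r}")

    def residue_numbers(self) -> list[int]:
        out: list[int] = []
        for item in self.residues:
            if isinstance(item, (tuple, list)):
                lo, hi = item
                if hi < lo:
                    raise ValueError(f"selection {self.name!r}: inverted range ({lo}, {hi})")
                out.extend(range(int(lo), int(hi) + 1))
            else:
                out.append(int(item))
        return out

    def resolve(self, system: MolecularSystem) -> np.ndarray:
        """Atom indices (row positions) matched by this selection."""
        a = system.atoms
        in_chain = a["chain_id"] == self.chain_id
        if not in_chain.any():
            raise ValueError(f"selection {self.name!r}: chain {self.chain_id!r} not in system")
        wanted = self.residue_numbers()
        if wanted:
            chain_res = set(a.loc[in_chain, "resseq"])
            missing = [r for r in wanted if r not in chain_res]
            if missing:
                raise ValueError(
                    f"selection {self.name!r}: residues {missing} not in chain {self.chain_id!r}"
                )
            mask = in_chain & a["resseq"].isin(wanted)
        else:
            mask = in_chain
        if self.atom_filter == "CA":
            mask &= a["atom_name"] == "CA"
        elif self.atom_filter == "backbone":
            mask &= a["atom_name"].isin(BACKBONE_ATOMS)
        elif self.atom_filter == "heavy":
            mask &= a["element"] != "H"
        idx = np.nonzero(mask.to_numpy())[0]
        if idx.size == 0:
            raise ValueError(f"selection {self.name!r} resolves to no atoms")
        return idx


def resolve_selections(system: MolecularSystem, specs: Sequence[SelectionSpec]) -> np.ndarray:
    """Union of atom indices over several selections (order preserved)."""
    idx = np.concatenate([s.resolve(system) for s in specs])
    return np.unique(idx)


@dataclass
class DomainMap:
    """Maps (chain_id, resseq) to a domain label such as Valpha or MHC."""

    mapping: dict = field(default_factory=dict)

    @classmethod
    def from_ranges(cls, ranges: Mapping[str, Iterable[tuple[str, tuple[int, int]]]]) -> "DomainMap":
        """Build from {label: [(chain_id, (first, last)), ...]}."""
        m: dict = {}
        for label, chunks in ranges.items():
            for chain_id, (lo, hi) in chunks:
                for r in range(int(lo), int(hi) + 1):
                    m[(chain_id, r)] = label
        return cls(m)

    def domain_of(self, chain_id: str, resseq: int) -> str:
        try:
            return self.mapping[(chain_id, int(resseq))]
        except KeyError:
            raise KeyError(f"residue {chain_id}:{resseq} has no domain label") from None

    def labels(self) -> list[str]:
        return sorted(set(self.mapping.values()))


# ----------------------------------------------------------------------
# Reading structures
# ----------------------------------------------------------------------

def load_structure(path: str | os.PathLike, include_hetero: bool = False) -> MolecularSystem:
    """Read a PDB file into a one-frame :class:`MolecularSystem`.

    Altloc handling keeps the highest-occupancy conformer (ties: first in
    file).  Waters are always dropped; other hetero residues only with
    ``include_hetero=True``.  A missing element column is tolerated (the
    element is inferred from the atom name).
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("s", os.fspath(path))
    except (PDBConstructionException, ValueError) as exc:
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc

    try:
        model = next(structure.get_models())
    except StopIteration:
        raise ValueError(f"PDB file {path} contains no model") from None

    rows = []
    coords = []
    atom_id = 0
    for chain in model:
        for residue in chain:
            hetflag, resseq, icode = residue.id
            resname = residue.get_resname().strip()
            if resname in _WATER_RESNAMES or hetflag == "W":
                continue
            if hetflag.strip() and not include_hetero:
                continue
            for atom in residue.get_list():
                if atom.is_disordered():
                    children = atom.disordered_get_list()
                    occs = [c.get_occupancy() or 0.0 for c in children]
                    atom = children[int(np.argmax(occs))]
                xyz = atom.get_coord()
                if xyz is None:
                    raise ValueError(f"atom {atom.get_fullname()} in {resname}{resseq} has no coordinates")
                element = (atom.element or "").strip().capitalize()
                if not element:
                    element = _infer_element(atom.get_name())
                rows.append(
                    (atom_id, atom.get_name().strip(), element, resname, int(resseq),
                     icode.strip(), chain.id.strip() or chain.id)
                )
                coords.append(np.asarray(xyz, dtype=float))
                atom_id += 1

    if not rows:
        raise ValueError(f"PDB file {path} contains no usable atoms")

    atoms = pd.DataFrame(rows, columns=ATOM_COLUMNS)
    frames = np.asarray(coords, dtype=float)[None, :, :]
    return MolecularSystem(atoms=atoms, frames=frames, frame_times=np.array([0.0]))


def renumber_sequential(system: MolecularSystem) -> tuple[MolecularSystem, dict]:
    """Renumber residues 1..N per chain in file order, collapsing icodes.

    Returns the renumbered system and, for the audit trail, a mapping
    ``{chain_id: {(old_resseq, icode): new_resseq}}``.
    """
    a = system.atoms
    mapping: dict[str, dict[tuple[int, str], int]] = {}
    new_resseq = np.empty(len(a), dtype=int)
    last_key: dict[str, tuple[int, str]] = {}
    for i, (chain, resseq, icode) in enumerate(zip(a["chain_id"], a["resseq"], a["icode"])):
        chain_map = mapping.setdefault(chain, {})
        key = (int(resseq), str(icode))
        if key not in chain_map:
            chain_map[key] = len(chain_map) + 1
        else:
            # residues must be contiguous blocks; a re-appearance is a duplicate
            if last_key.get(chain) != key:
                raise ValueError(
                    f"duplicate residue {key} in chain {chain!r}: appears in two separate blocks"
                )
        last_key[chain] = key
        new_resseq[i] = chain_map[key]
    atoms = a.copy()
    atoms["resseq"] = new_resseq
    atoms["icode"] = ""
    out = MolecularSystem(atoms, system.frames.copy(), system.frame_times.copy(), system.box)
    return out, mapping


def load_trajectory(
    system: MolecularSystem, path: str | os.PathLike, frame_interval_ns: float
) -> MolecularSystem:
    """Attach a DCD/XTC trajectory to a topology.

    The structure frame is treated as topology only: the returned system
    carries the trajectory frames with ``frame_times = i * frame_interval_ns``
    (first production frame at t = 0).
    """
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext == ".dcd":
        from MDAnalysis.coordinates.DCD import DCDReader as Reader
    elif ext == ".xtc":
        from MDAnalysis.coordinates.XTC import XTCReader as Reader
    else:
        raise ValueError(f"unsupported trajectory format {ext!r} (expected .dcd or .xtc)")
    if frame_interval_ns <= 0:
        raise ValueError("frame_interval_ns must be positive")

    with Reader(path) as reader:
        if reader.n_atoms != system.n_atoms:
            raise ValueError(
                f"trajectory {path} has {reader.n_atoms} atoms but topology has {system.n_atoms}"
            )
        frames = np.array([ts.positions.copy() for ts in reader], dtype=float)
    times = np.arange(frames.shape[0]) * float(frame_interval_ns)
    return system.with_frames(frames, times)


def frames_in_interval(duration_ns: float, saving_interval_ns: float) -> int:
    """Number of saved frames covering a production interval.

    A 500 ns interval saved every 20 ps yields 25,000 frames.
    """
    if saving_interval_ns <= 0:
        raise ValueError("saving_interval_ns must be positive")
    return int(round(duration_ns / saving_interval_ns))


# ----------------------------------------------------------------------
# Superposition
# ----------------------------------------------------------------------

def kabsch_rotation(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares rotation matrix taking centered ``mobile`` onto
    centered ``target`` (Kabsch, via SVD; proper rotation enforced)."""
    H = mobile.T @ target
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def superpose(
    system: MolecularSystem,
    reference: int | np.ndarray,
    fit_selection: SelectionSpec | Sequence[SelectionSpec] | np.ndarray,
) -> tuple[MolecularSystem, np.ndarray]:
    """Rigid-body fit every frame onto a reference using a selection.

    ``reference`` is a frame index or an (n_atoms, 3) coordinate array;
    ``fit_selection`` a SelectionSpec (or list of them) or explicit atom
    indices.  No mass weighting.  Returns the transformed system and the
    per-frame RMSD (Å) of the fit atoms.
    """
    if isinstance(fit_selection, SelectionSpec):
        fit_idx = fit_selection.resolve(system)
    elif isinstance(fit_selection, (list, tuple)) and fit_selection and isinstance(fit_selection[0], SelectionSpec):
        fit_idx = resolve_selections(system, fit_selection)
    else:
        fit_idx = np.asarray(fit_selection, dtype=int)
    if fit_idx.size < 3:
        raise ValueError(f"superposition needs >=3 fit atoms, got {fit_idx.size}")

    if isinstance(reference, (int, np.integer)):
        ref_coords = system.frames[int(reference)]
    else:
        ref_coords = np.asarray(reference, dtype=float)
        if ref_coords.shape != (system.n_atoms, 3):
            raise ValueError("reference coordinates must have shape (n_atoms, 3)")

    ref_fit = ref_coords[fit_idx]
    ref_center = ref_fit.mean(axis=0)
    ref_centered = ref_fit - ref_center
    # collinearity check: effectively rank < 2 in the plane
    sv = np.linalg.svd(ref_centered, compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise ValueError("fit selection is collinear; cannot define a rigid fit")

    out = np.empty_like(system.frames)
    rmsd = np.empty(system.n_frames)
    for f in range(system.n_frames):
        mob_fit = system.frames[f][fit_idx]
        mob_center = mob_fit.mean(axis=0)
        R = kabsch_rotation(mob_fit - mob_center, ref_centered)
        out[f] = (system.frames[f] - mob_center) @ R.T + ref_center
        d = out[f][fit_idx] - ref_fit
        rmsd[f] = np.sqrt((d * d).sum() / fit_idx.size)
    return system.with_frames(out, system.frame_times.copy()), rmsd


# ----------------------------------------------------------------------
# Writing
# ----------------------------------------------------------------------

def _to_mda_universe(system: MolecularSystem):
    import MDAnalysis as mda

    a = system.atoms
    res_key = list(zip(a["chain_id"], a["resseq"]))
    seen: dict = {}
    resindex = np.empty(len(a), dtype=int)
    for i, key in enumerate(res_key):
        if key not in seen:
            seen[key] = len(seen)
        resindex[i] = seen[key]
    n_res = len(seen)
    res_chain = [None] * n_res
    res_id = [0] * n_res
    res_name = [""] * n_res
    for i, key in enumerate(res_key):
        j = seen[key]
        res_chain[j] = key[0]
        res_id[j] = int(key[1])
        res_name[j] = a["resname"].iloc[i]
    seg_seen: dict = {}
    segindex = np.empty(n_res, dtype=int)
    for j, ch in enumerate(res_chain):
        if ch not in seg_seen:
            seg_seen[ch] = len(seg_seen)
        segindex[j] = seg_seen[ch]

    u = mda.Universe.empty(
        n_atoms=len(a),
        n_residues=n_res,
        n_segments=len(seg_seen),
        atom_resindex=resindex,
        residue_segindex=segindex,
        trajectory=True,
    )
    u.add_TopologyAttr("names", list(a["atom_name"]))
    u.add_TopologyAttr("elements", list(a["element"]))
    u.add_TopologyAttr("resnames", res_name)
    u.add_TopologyAttr("resids", res_id)
    u.add_TopologyAttr("segids", list(seg_seen))
    u.add_TopologyAttr("chainIDs", [str(c)[:1] for c in a["chain_id"]])
    u.add_TopologyAttr("occupancies", np.ones(len(a)))
    u.add_TopologyAttr("tempfactors", np.zeros(len(a)))
    u.atoms.positions = system.frames[0]
    return u


def write_pdb(system: MolecularSystem, path: str | os.PathLike, frame: int = 0) -> None:
    """Write one frame as a PDB file (10^-3 Å precision)."""
    import MDAnalysis as mda

    u = _to_mda_universe(system)
    u.atoms.positions = system.frames[frame]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(os.fspath(path), n_atoms=system.n_atoms) as w:
            w.write(u.atoms)


def write_dcd(system: MolecularSystem, path: str | os.PathLike) -> None:
    """Write all frames as a DCD trajectory."""
    import MDAnalysis as mda

    u = _to_mda_universe(system)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(os.fspath(path), n_atoms=system.n_atoms) as w:
            for f in range(system.n_frames):
                u.atoms.positions = system.frames[f]
                w.write(u.atoms)
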