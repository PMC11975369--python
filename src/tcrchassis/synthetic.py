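"""Synthetic chassis trajectories with known ground truth.

The toy system emulates the architecture of an αβ TCR bound to a pMHC:
two chains (A = α, B = β) each carrying a variable-domain core, two
CDR3-base residues, hinge residues and a constant-domain core, plus a
partner slab (chain M, 20 residues, doubling as the "MHC floor") with a
peptide ridge (chain P) and harmonically restrained terminal atoms at
the two ends of the complex.

Motions are prescribed, not simulated:

* hinge bending rotates the whole V-module rigidly about the
  inter-hinge axis, so the measured three-bead hinge angles equal the
  prescribed angle series exactly at zero noise;
* Vα–Vβ motion rotates the Vβ domain about its reference-triad arms as
  ``Rot(e3, b) · Rot(e2, a)``, which makes the matching-arm angles
  ∠e2 = |b| and ∠e3 = |a| exactly; "scissoring" drives a = a0 + s(t),
  b = b0 − s(t) so ∠e2 and ∠e3 move in opposite directions;
* residue-pair contacts follow an explicit boolean schedule and are
  realised geometrically: a probe side-chain atom on one residue is
  placed 1 Å inside (on) or left well outside (off) the contact cutoff;
* isotropic Gaussian noise (default σ = 0.1 Å) is added to every atom.

Everything is reproducible from seeds.  The generator deliberately
omits correlated thermal motion, solvent and force-field physics: it
provides statistical structure with known answers, not realism.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .geometry import reference_triad
from .system import ATOM_COLUMNS, DomainMap, MolecularSystem, SelectionSpec, write_dcd, write_pdb

__all__ = [
    "ChassisSpec",
    "MotionProcess",
    "ContactSchedule",
    "build_toy_complex",
    "simulate_trajectory",
    "write_fixture",
]


# ----------------------------------------------------------------------
# Motion processes
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class MotionProcess:
    """A prescribed scalar angle process, degrees vs time.

    kind:
      constant  -> value
      sinusoid  -> mean + amplitude * sin(2π t / period_ns + phase)
      ou        -> Ornstein-Uhlenbeck around mean (stationary std sigma,
                   relaxation time tau_ns), exact discretisation
      two_state -> telegraph between state_means with exponential dwell
                   times (dwell_ns)
    """

    kind: str = "constant"
    value: float = 0.0
    mean: float = 0.0
    amplitude: float = 0.0
    period_ns: float = 100.0
    phase: float = 0.0
    sigma: float = 0.0
    tau_ns: float = 1.0
    state_means: tuple[float, float] = (0.0, 0.0)
    dwell_ns: tuple[float, float] = (10.0, 10.0)
    seed: int | None = None

    def series(self, n_frames: int, dt_ns: float, rng: np.random.Generator | None = None) -> np.ndarray:
        """Angle series (deg) over ``n_frames`` at spacing ``dt_ns``."""
        if n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if rng is None:
            rng = np.random.default_rng(self.seed)
        t = np.arange(n_frames) * dt_ns
        if self.kind == "constant":
            return np.full(n_frames, float(self.value))
        if self.kind == "sinusoid":
            return self.mean + self.amplitude * np.sin(2.0 * np.pi * t / self.period_ns + self.phase)
        if self.kind == "ou":
            e = np.exp(-dt_ns / self.tau_ns)
            x = np.empty(n_frames)
            x[0] = rng.normal(0.0, self.sigma) if self.sigma > 0 else 0.0
            scale = self.sigma * np.sqrt(1.0 - e * e)
            steps = rng.normal(0.0, 1.0, n_frames - 1) if n_frames > 1 else np.empty(0)
            for i in range(1, n_frames):
                x[i] = x[i - 1] * e + scale * steps[i - 1]
            return self.mean + x
        if self.kind == "two_state":
            lo, hi = self.state_means
            p_leave = [1.0 - np.exp(-dt_ns / d) for d in self.dwell_ns]
            state = int(rng.integers(0, 2))
            out = np.empty(n_frames)
            u = rng.random(n_frames)
            for i in range(n_frames):
                out[i] = (lo, hi)[state]
                if u[i] < p_leave[state]:
                    state = 1 - state
            return out
        raise ValueError(f"unknown motion kind {self.kind!r}")


# ----------------------------------------------------------------------
# Contact schedules
# ----------------------------------------------------------------------

ResidueRef = tuple[str, int]  # (chain_id, resseq)


@dataclass
class ContactSchedule:
    """Boolean on/off series per residue pair over frames."""

    pairs: list[tuple[ResidueRef, ResidueRef]]
    states: np.ndarray  # (n_pairs, n_frames) bool

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=bool)
        if self.states.shape[0] != len(self.pairs):
            raise ValueError("states row count must equal number of pairs")

    @property
    def n_frames(self) -> int:
        return self.states.shape[1]

    def on_fraction(self) -> np.ndarray:
        return self.states.mean(axis=1)

    @classmethod
    def constant(cls, pairs: Sequence, n_frames: int, on: bool = True) -> "ContactSchedule":
        return cls(list(pairs), np.full((len(pairs), n_frames), bool(on)))

    @classmethod
    def from_arrays(cls, pairs: Sequence, states: np.ndarray) -> "ContactSchedule":
        return cls(list(pairs), np.asarray(states, dtype=bool))

    @classmethod
    def telegraph(
        cls,
        pairs: Sequence,
        n_frames: int,
        dt_ns: float,
        on_rate_per_ns: float,
        off_rate_per_ns: float,
        seed: int | None = None,
    ) -> "ContactSchedule":
        """Stationary two-state Markov (telegraph) schedules.

        Stationary on-fraction = on_rate / (on_rate + off_rate).  The
        exact discrete-time propagator is used, so fast rates give
        nearly independent frames.
        """
        if on_rate_per_ns < 0 or off_rate_per_ns < 0 or on_rate_per_ns + off_rate_per_ns == 0:
            raise ValueError("rates must be non-negative with a positive sum")
        rng = np.random.default_rng(seed)
        ktot = on_rate_per_ns + off_rate_per_ns
        p_on = on_rate_per_ns / ktot
        e = np.exp(-ktot * dt_ns)
        p_on_given_on = p_on + (1.0 - p_on) * e
        p_on_given_off = p_on * (1.0 - e)
        states = np.empty((len(pairs), n_frames), dtype=bool)
        for j in range(len(pairs)):
            u = rng.random(n_frames)
            s = u[0] < p_on
            states[j, 0] = s
            for i in range(1, n_frames):
                p = p_on_given_on if s else p_on_given_off
                s = u[i] < p
                states[j, i] = s
        return cls(list(pairs), states)

    def switched_off_at(self, pair_indices: Sequence[int], t_off_ns: float, frame_times: np.ndarray) -> "ContactSchedule":
        """Copy with the given pairs permanently off from ``t_off_ns``."""
        states = self.states.copy()
        mask = np.asarray(frame_times) >= t_off_ns
        for j in pair_indices:
            states[j, mask] = False
        return ContactSchedule(list(self.pairs), states)


# ----------------------------------------------------------------------
# Chassis geometry
# ----------------------------------------------------------------------

@dataclass
class ChassisSpec:
    """Geometry of the toy chassis.

    Distances in Å.  The defaults give four 24-residue domain cores on a
    2x3x4 grid, a 20-residue partner slab with a 4-residue peptide
    ridge, 13 scheduled contact pairs (8 chassis-partner, 5 internal)
    and terminal restraint atoms 62 Å apart along z.
    """

    core_grid: tuple[int, int, int] = (2, 3, 4)
    core_spacing: float = 4.0
    v_center_z: float = 30.0
    c_center_z: float = 10.0
    hinge_z: float = 20.0
    chain_offset_x: float = 10.0
    slab_z: float = 46.0
    slab_nx: int = 5
    slab_ny: int = 4
    slab_spacing: float = 5.0
    peptide_z: float = 42.0
    peptide_n: int = 4
    peptide_spacing: float = 4.0
    cdr3_inner_x: float = 5.0
    cdr3_z: float = 24.0
    probe_offset: float = 1.5
    contact_cutoff: float = 4.0
    contact_margin: float = 1.0
    mhc_terminal: tuple[float, float, float] = (0.0, 0.0, 60.0)
    alpha_terminal: tuple[float, float, float] = (-2.0, 0.0, -2.0)
    beta_terminal: tuple[float, float, float] = (2.0, 0.0, -2.0)
    spring_constant: float = 1.0  # kcal/(mol Å^2)

    def __post_init__(self) -> None:
        if min(self.core_grid) < 1:
            raise ValueError("domain core grid must have at least one atom per axis")
        if self.v_center_z - self.core_half_height() <= self.c_center_z + self.core_half_height():
            raise ValueError("V and C domains overlap at rest")
        if self.slab_z - self.core_half_height() <= self.v_center_z:
            raise ValueError("partner slab overlaps the V-module at rest")
        if self.mhc_terminal[2] <= self.alpha_terminal[2]:
            raise ValueError("terminal atoms must sit at opposite ends of the complex")

    def core_half_height(self) -> float:
        return (self.core_grid[2] - 1) * self.core_spacing / 2.0

    def rest_extension(self) -> float:
        """Distance between the partner-side terminal restraint and the
        midpoint of the two chassis-side terminal restraints."""
        top = np.array(self.mhc_terminal)
        bottom = 0.5 * (np.array(self.alpha_terminal) + np.array(self.beta_terminal))
        return float(np.linalg.norm(top - bottom))

    # -- residue layout ------------------------------------------------
    def _core_offsets(self) -> np.ndarray:
        nx, ny, nz = self.core_grid
        s = self.core_spacing
        xs = (np.arange(nx) - (nx - 1) / 2.0) * s
        ys = (np.arange(ny) - (ny - 1) / 2.0) * s
        zs = (np.arange(nz) - (nz - 1) / 2.0) * s
        pts = [(x, y, z) for z in zs for y in ys for x in xs]
        return np.array(pts)

    def layout(self) -> dict:
        """Residue CA positions and bookkeeping for every chain.

        Returns a dict with per-chain lists of (resseq, position) plus
        index ranges for the structural groups.
        """
        off = self._core_offsets()
        n_core = len(off)
        ax = self.chain_offset_x

        def shifted(center):
            return off + np.asarray(center)

        chains: dict[str, list[tuple[int, np.ndarray]]] = {"A": [], "B": [], "M": [], "P": []}
        groups: dict[str, list[ResidueRef]] = {}

        # chain A: Vα core, CDR3α base, hinge, Cα core, terminal
        r = 1
        for p in shifted((-ax, 0.0, self.v_center_z)):
            chains["A"].append((r, p)); r += 1
        groups["Valpha_core"] = [("A", i) for i in range(1, n_core + 1)]
        cdr3a = [(-self.cdr3_inner_x, -2.0, self.cdr3_z), (-self.cdr3_inner_x, 2.0, self.cdr3_z)]
        groups["cdr3_alpha"] = []
        for p in cdr3a:
            chains["A"].append((r, np.array(p))); groups["cdr3_alpha"].append(("A", r)); r += 1
        chains["A"].append((r, np.array([-ax, 0.0, self.hinge_z])))
        groups["Halpha"] = [("A", r)]; r += 1
        groups["Calpha_core"] = []
        for p in shifted((-ax, 0.0, self.c_center_z)):
            chains["A"].append((r, p)); groups["Calpha_core"].append(("A", r)); r += 1
        chains["A"].append((r, np.array(self.alpha_terminal)))
        groups["alpha_terminal"] = [("A", r)]

        # chain B: Vβ core, CDR3β base, two hinge residues, Cβ core, terminal
        r = 1
        for p in shifted((ax, 0.0, self.v_center_z)):
            chains["B"].append((r, p)); r += 1
        groups["Vbeta_core"] = [("B", i) for i in range(1, n_core + 1)]
        cdr3b = [(self.cdr3_inner_x, -2.0, self.cdr3_z), (self.cdr3_inner_x, 2.0, self.cdr3_z)]
        groups["cdr3_beta"] = []
        for p in cdr3b:
            chains["B"].append((r, np.array(p))); groups["cdr3_beta"].append(("B", r)); r += 1
        groups["Hbeta"] = []
        for p in [(ax, -2.0, self.hinge_z), (ax, 2.0, self.hinge_z)]:
            chains["B"].append((r, np.array(p))); groups["Hbeta"].append(("B", r)); r += 1
        groups["Cbeta_core"] = []
        for p in shifted((ax, 0.0, self.c_center_z)):
            chains["B"].append((r, p)); groups["Cbeta_core"].append(("B", r)); r += 1
        chains["B"].append((r, np.array(self.beta_terminal)))
        groups["beta_terminal"] = [("B", r)]

        # chain M: partner slab (the 20-residue "MHC floor") + terminal
        r = 1
        xs = (np.arange(self.slab_nx) - (self.slab_nx - 1) / 2.0) * self.slab_spacing
        ys = (np.arange(self.slab_ny) - (self.slab_ny - 1) / 2.0) * self.slab_spacing
        groups["mhc_floor"] = []
        for x in xs:
            for y in ys:
                chains["M"].append((r, np.array([x, y, self.slab_z])))
                groups["mhc_floor"].append(("M", r)); r += 1
        chains["M"].append((r, np.array(self.mhc_terminal)))
        groups["mhc_terminal"] = [("M", r)]

        # chain P: peptide ridge
        xs = (np.arange(self.peptide_n) - (self.peptide_n - 1) / 2.0) * self.peptide_spacing
        groups["peptide"] = []
        for i, x in enumerate(xs, start=1):
            chains["P"].append((i, np.array([x, 0.0, self.peptide_z])))
            groups["peptide"].append(("P", i))

        return {"chains": chains, "groups": groups, "n_core": n_core}

    # -- default contact pairs ----------------------------------------
    def default_contact_pairs(self) -> list[tuple[ResidueRef, ResidueRef]]:
        """13 scheduled pairs: 4 peptide–V, 4 partner–V, 2 Vα–Vβ, one
        V–C per chain and one Cα–Cβ.  The second residue of each pair
        carries the probe atom; no residue is the probe side of two
        pairs."""
        lay = self.layout()
        g = lay["groups"]
        pos = {(c, r): p for c, items in lay["chains"].items() for r, p in items}

        def core_res(chain: str, group: str, target) -> ResidueRef:
            # nearest core residue of the group to a target point
            best = min(g[group], key=lambda ref: float(np.linalg.norm(pos[ref] - np.asarray(target))))
            return best

        ax, hh = self.chain_offset_x, self.core_half_height()
        v_top = self.v_center_z + hh
        v_bot = self.v_center_z - hh
        c_top = self.c_center_z + hh
        c_mid = self.c_center_z
        half = self.core_spacing / 2.0

        pairs: list[tuple[ResidueRef, ResidueRef]] = [
            (g["peptide"][0], g["cdr3_alpha"][0]),
            (g["peptide"][1], g["cdr3_alpha"][1]),
            (g["peptide"][2], g["cdr3_beta"][0]),
            (g["peptide"][3], g["cdr3_beta"][1]),
            # slab contacts use the outermost slab columns so the pinned
            # probes stay clear of the peptide ridge
            (core_res("M", "mhc_floor", (-10.0, -2.5, self.slab_z)), core_res("A", "Valpha_core", (-ax - half, 0.0, v_top))),
            (core_res("M", "mhc_floor", (-10.0, 2.5, self.slab_z)), core_res("A", "Valpha_core", (-ax - half, 4.0, v_top))),
            (core_res("M", "mhc_floor", (10.0, -2.5, self.slab_z)), core_res("B", "Vbeta_core", (ax + half, 0.0, v_top))),
            (core_res("M", "mhc_floor", (10.0, 2.5, self.slab_z)), core_res("B", "Vbeta_core", (ax + half, 4.0, v_top))),
            (g["cdr3_alpha"][0], core_res("B", "Vbeta_core", (ax - half, -4.0, v_bot))),
            (g["cdr3_alpha"][1], core_res("B", "Vbeta_core", (ax - half, 4.0, v_bot))),
            (core_res("A", "Valpha_core", (-ax + half, 0.0, v_bot)), core_res("A", "Calpha_core", (-ax + half, 0.0, c_top))),
            (core_res("B", "Vbeta_core", (ax - half, 0.0, v_bot)), core_res("B", "Cbeta_core", (ax - half, 0.0, c_top))),
            (core_res("A", "Calpha_core", (-ax + half, 0.0, c_mid)), core_res("B", "Cbeta_core", (ax - half, 0.0, c_mid))),
        ]
        probe_side = [b for _, b in pairs]
        if len(set(probe_side)) != len(probe_side):
            raise ValueError("default contact pairs assign two probes to one residue")
        return pairs

    # -- analysis presets ----------------------------------------------
    def selections(self) -> dict[str, object]:
        """SelectionSpecs matching the toy layout (Cα unless noted)."""
        lay = self.layout()
        g = lay["groups"]

        def span(refs) -> SelectionSpec:
            chain = refs[0][0]
            nums = tuple(r for _, r in refs)
            return SelectionSpec(name="", chain_id=chain, residues=nums, atom_filter="CA")

        n_core = lay["n_core"]
        sel: dict[str, object] = {
            "Valpha": SelectionSpec("Valpha", "A", ((1, n_core),), "CA"),
            "Vbeta": SelectionSpec("Vbeta", "B", ((1, n_core),), "CA"),
            "Calpha": replace(span(g["Calpha_core"]), name="Calpha"),
            "Cbeta": replace(span(g["Cbeta_core"]), name="Cbeta"),
            "Halpha": replace(span(g["Halpha"]), name="Halpha"),
            "Hbeta": replace(span(g["Hbeta"]), name="Hbeta"),
            "cdr3_alpha": replace(span(g["cdr3_alpha"]), name="cdr3_alpha"),
            "cdr3_beta": replace(span(g["cdr3_beta"]), name="cdr3_beta"),
            "mhc_floor": replace(span(g["mhc_floor"]), name="mhc_floor"),
        }
        # contact groups span chains, hence lists of specs (heavy atoms)
        na = max(r for r, _ in lay["chains"]["A"])
        nb = max(r for r, _ in lay["chains"]["B"])
        nm = max(r for r, _ in lay["chains"]["M"])
        sel["tcr_group"] = [
            SelectionSpec("tcr_A", "A", ((1, na - 1),), "heavy"),   # exclude terminal
            SelectionSpec("tcr_B", "B", ((1, nb - 1),), "heavy"),
        ]
        sel["pmhc_group"] = [
            SelectionSpec("pmhc_M", "M", ((1, nm - 1),), "heavy"),
            SelectionSpec("pmhc_P", "P", ((1, self.peptide_n),), "heavy"),
        ]
        sel["valpha_group"] = [SelectionSpec("valpha_g", "A", ((1, n_core + 2),), "heavy")]
        sel["vbeta_group"] = [SelectionSpec("vbeta_g", "B", ((1, n_core + 2),), "heavy")]
        ca0 = g["Calpha_core"][0][1]
        ca1 = g["Calpha_core"][-1][1]
        cb0 = g["Cbeta_core"][0][1]
        cb1 = g["Cbeta_core"][-1][1]
        sel["calpha_group"] = [SelectionSpec("calpha_g", "A", ((ca0, ca1),), "heavy")]
        sel["cbeta_group"] = [SelectionSpec("cbeta_g", "B", ((cb0, cb1),), "heavy")]
        sel["peptide_ca"] = SelectionSpec("peptide_ca", "P", ((1, self.peptide_n),), "CA")
        # triad orientation hints: long axis points from V toward C (−z),
        # sheet normal along +x
        sel["long_axis_hint"] = np.array([0.0, 0.0, -1.0])
        sel["normal_hint"] = np.array([1.0, 0.0, 0.0])
        sel["domain_map"] = self.domain_map()
        return sel

    def domain_map(self) -> DomainMap:
        lay = self.layout()
        g = lay["groups"]
        m: dict = {}
        for ref in g["Valpha_core"] + g["cdr3_alpha"]:
            m[ref] = "Valpha"
        for ref in g["Vbeta_core"] + g["cdr3_beta"]:
            m[ref] = "Vbeta"
        for ref in g["Calpha_core"]:
            m[ref] = "Calpha"
        for ref in g["Cbeta_core"]:
            m[ref] = "Cbeta"
        for ref in g["Halpha"] + g["Hbeta"] + g["alpha_terminal"] + g["beta_terminal"]:
            m[ref] = "linker"
        for ref in g["mhc_floor"] + g["mhc_terminal"]:
            m[ref] = "MHC"
        for ref in g["peptide"]:
            m[ref] = "peptide"
        return DomainMap(m)

    def restraints(self):
        """RestraintDef on the three terminal atoms at their rest positions."""
        from .mechanics import Restraint, RestraintDef

        lay = self.layout()
        g = lay["groups"]
        k = self.spring_constant
        return RestraintDef(
            restraints=[
                Restraint(residue=g["mhc_terminal"][0], atom_name="CA",
                          center=np.array(self.mhc_terminal), k=k, end="mhc"),
                Restraint(residue=g["alpha_terminal"][0], atom_name="CA",
                          center=np.array(self.alpha_terminal), k=k, end="tcr"),
                Restraint(residue=g["beta_terminal"][0], atom_name="CA",
                          center=np.array(self.beta_terminal), k=k, end="tcr"),
            ]
        )


# ----------------------------------------------------------------------
# Building the one-frame structure
# ----------------------------------------------------------------------

def build_toy_complex(spec: ChassisSpec | None = None) -> MolecularSystem:
    """Build the rest-state toy complex (one frame).

    Chains: A (α), B (β), M (partner slab), P (peptide).  Probe-bearing
    residues (the second member of each scheduled contact pair) get a CB
    atom 1.5 Å from their CA; all other residues are CA-only.
    """
    spec = spec or ChassisSpec()
    lay = spec.layout()
    pairs = spec.default_contact_pairs()
    pos = {(c, r): p for c, items in lay["chains"].items() for r, p in items}
    probe_dir = {}
    for a_ref, b_ref in pairs:
        u = pos[a_ref] - pos[b_ref]
        probe_dir[b_ref] = u / np.linalg.norm(u)

    rows, coords = [], []
    atom_id = 0
    for chain_id in ("A", "B", "M", "P"):
        for resseq, p in lay["chains"][chain_id]:
            ref = (chain_id, resseq)
            resname = "ALA" if ref in probe_dir else "GLY"
            rows.append((atom_id, "CA", "C", resname, resseq, "", chain_id))
            coords.append(p)
            atom_id += 1
            if ref in probe_dir:
                rows.append((atom_id, "CB", "C", resname, resseq, "", chain_id))
                coords.append(p + spec.probe_offset * probe_dir[ref])
                atom_id += 1

    atoms = pd.DataFrame(rows, columns=ATOM_COLUMNS)
    frames = np.asarray(coords, dtype=float)[None, :, :]
    return MolecularSystem(atoms=atoms, frames=frames, frame_times=np.array([0.0]))


# ----------------------------------------------------------------------
# Trajectory synthesis
# ----------------------------------------------------------------------

def _rot(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    return Rotation.from_rotvec(np.radians(angle_deg) * np.asarray(axis)).as_matrix()


def simulate_trajectory(
    spec: ChassisSpec | None = None,
    hinge: MotionProcess | None = None,
    interdomain_twist: MotionProcess | None = None,
    contacts: ContactSchedule | None = None,
    noise_sigma: float = 0.1,
    n_frames: int = 100,
    frame_interval_ns: float = 0.02,
    seed: int = 0,
    twist_axis: str = "e3",
    scissor_baseline: tuple[float, float] = (10.0, 10.0),
    cdr3_hinge_coupling: float = 0.0,
    sway: Mapping[str, tuple[Sequence[float], MotionProcess]] | None = None,
) -> tuple[MolecularSystem, dict]:
    """Generate a trajectory with prescribed dynamics and ground truth.

    Parameters
    ----------
    hinge : MotionProcess or None
        Prescribed V–H–C bending angle (deg); None keeps the straight
        180° rest chain.  Applied to both chains (whole-module rotation
        about the inter-hinge axis).
    interdomain_twist : MotionProcess or None
        Vβ rotation angle series s(t).  With ``twist_axis`` "e1", "e2"
        or "e3" the rotation is about that reference arm; "scissor"
        drives a = a0 + s(t) about e2 and b = b0 − s(t) about e3, with
        (a0, b0) = ``scissor_baseline``.
    contacts : ContactSchedule or None
        On/off schedule for the spec's contact pairs (pairs must be a
        subset of ``spec.default_contact_pairs()``).
    cdr3_hinge_coupling : float
        Å per degree: displaces the CDR3 bases along the inter-domain
        axis by coupling × (hinge − 180°), prescribing a linear CDR3
        distance vs hinge angle relation.
    sway : mapping domain -> (direction, MotionProcess)
        Optional rigid translation of "Valpha"/"Vbeta" (Å along the
        given direction) for motion-asymmetry fixtures.

    Returns
    -------
    (system, truth)
        ``truth`` carries the prescribed per-frame hinge angle, triad
        arm angles, CDR3 distance, schedule states and sway series.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    spec = spec or ChassisSpec()
    rest = build_toy_complex(spec)
    lay = spec.layout()
    g = lay["groups"]
    pairs = spec.default_contact_pairs()
    if contacts is not None:
        known = set(pairs)
        bad = [p for p in contacts.pairs if p not in known]
        if bad:
            raise ValueError(f"scheduled pairs not in the chassis layout: {bad}")
        if contacts.n_frames != n_frames:
            raise ValueError("contact schedule length must equal n_frames")

    rng = np.random.default_rng(seed)
    dt = frame_interval_ns
    hinge_series = (hinge.series(n_frames, dt, None if hinge.seed is not None else rng)
                    if hinge else np.full(n_frames, 180.0))
    twist_series = (interdomain_twist.series(n_frames, dt, None if interdomain_twist.seed is not None else rng)
                    if interdomain_twist else np.zeros(n_frames))
    sway = dict(sway or {})
    sway_series = {}
    for dom, (direction, proc) in sway.items():
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        sway_series[dom] = (d, proc.series(n_frames, dt, None if proc.seed is not None else rng))

    atoms = rest.atoms
    # atom index sets
    def atom_idx(refs, names=None) -> np.ndarray:
        refset = set(refs)
        mask = [
            (c, r) in refset and (names is None or n in names)
            for c, r, n in zip(atoms["chain_id"], atoms["resseq"], atoms["atom_name"])
        ]
        return np.nonzero(mask)[0]

    valpha_atoms = atom_idx(g["Valpha_core"] + g["cdr3_alpha"])
    vbeta_atoms = atom_idx(g["Vbeta_core"] + g["cdr3_beta"])
    cdr3a_atoms = atom_idx(g["cdr3_alpha"])
    cdr3b_atoms = atom_idx(g["cdr3_beta"])
    vb_core_ca = atom_idx(g["Vbeta_core"], names={"CA"})
    va_core_ca = atom_idx(g["Valpha_core"], names={"CA"})
    domain_atoms = {"Valpha": valpha_atoms, "Vbeta": vbeta_atoms}

    ca_index = {}
    cb_index = {}
    for i, (c, r, n) in enumerate(zip(atoms["chain_id"], atoms["resseq"], atoms["atom_name"])):
        if n == "CA":
            ca_index[(c, r)] = i
        elif n == "CB":
            cb_index[(c, r)] = i

    base = rest.frames[0]
    sel = spec.selections()
    ref_triad = reference_triad(base[vb_core_ca], sel["long_axis_hint"], sel["normal_hint"])
    arms = ref_triad.arms  # identical for Vα by construction (congruent cores)
    vb_centroid = base[vb_core_ca].mean(axis=0)
    hinge_pivot = np.array([0.0, 0.0, spec.hinge_z])
    hinge_axis = np.array([1.0, 0.0, 0.0])
    x_axis = np.array([1.0, 0.0, 0.0])

    d_on = spec.contact_cutoff - spec.contact_margin
    frames = np.empty((n_frames, rest.n_atoms, 3))
    truth_angles = np.empty((n_frames, 3))
    cdr3_truth = np.empty(n_frames)

    for f in range(n_frames):
        X = base.copy()

        # 1. CDR3–hinge coupling (shift along the inter-domain axis)
        if cdr3_hinge_coupling != 0.0:
            delta = cdr3_hinge_coupling * (hinge_series[f] - 180.0)
            X[cdr3a_atoms] -= 0.5 * delta * x_axis
            X[cdr3b_atoms] += 0.5 * delta * x_axis

        # 2. Vβ rotation about its reference arms (about the core centroid)
        s = twist_series[f]
        if twist_axis == "scissor":
            a0, b0 = scissor_baseline
            R_rel = _rot(arms[2], b0 - s) @ _rot(arms[1], a0 + s)
        elif twist_axis == "e1":
            R_rel = _rot(arms[0], s)
        elif twist_axis == "e2":
            R_rel = _rot(arms[1], s)
        elif twist_axis == "e3":
            R_rel = _rot(arms[2], s)
        else:
            raise ValueError(f"unknown twist_axis {twist_axis!r}")
        X[vbeta_atoms] = (X[vbeta_atoms] - vb_centroid) @ R_rel.T + vb_centroid
        truth_angles[f] = [
            np.degrees(np.arccos(np.clip(np.dot(arms[i], R_rel @ arms[i]), -1.0, 1.0)))
            for i in range(3)
        ]

        # 3. Hinge: rotate the whole V-module about the inter-hinge axis
        delta_h = 180.0 - hinge_series[f]
        if delta_h != 0.0:
            Rh = _rot(hinge_axis, delta_h)
            vmod = np.concatenate([valpha_atoms, vbeta_atoms])
            X[vmod] = (X[vmod] - hinge_pivot) @ Rh.T + hinge_pivot

        # 4. Sway translations
        for dom, (d, series) in sway_series.items():
            X[domain_atoms[dom]] += d * series[f]

        # CDR3 ground truth from the noise-free placement
        cdr3_truth[f] = float(np.linalg.norm(X[cdr3a_atoms].mean(axis=0) - X[cdr3b_atoms].mean(axis=0)))

        # 5. Contacts: pin or park the probe atoms
        if contacts is not None:
            for j, (a_ref, b_ref) in enumerate(contacts.pairs):
                ia = ca_index[a_ref]
                ib = cb_index[b_ref]
                u = X[ca_index[b_ref]] - X[ia]
                u = u / np.linalg.norm(u)
                if contacts.states[j, f]:
                    X[ib] = X[ia] + d_on * u
                else:
                    X[ib] = X[ca_index[b_ref]] - spec.probe_offset * u

        # 6. Thermal noise
        if noise_sigma > 0:
            X = X + rng.normal(0.0, noise_sigma, X.shape)

        frames[f] = X

    times = np.arange(n_frames) * dt
    system = rest.with_frames(frames, times)
    truth = {
        "frame_times": times,
        "hinge_angle_deg": hinge_series,
        "twist_signal_deg": twist_series,
        "triad_angles_deg": truth_angles,  # columns ∠e1, ∠e2, ∠e3
        "cdr3_distance_A": cdr3_truth,
        "contact_pairs": list(contacts.pairs) if contacts is not None else [],
        "contact_states": contacts.states.copy() if contacts is not None else np.zeros((0, n_frames), bool),
        "sway": {dom: series for dom, (_, series) in sway_series.items()},
        "seed": seed,
        "noise_sigma": noise_sigma,
    }
    return system, truth


def write_fixture(system: MolecularSystem, out_dir: str | os.PathLike,
                  truth: dict | None = None, prefix: str = "fixture") -> dict:
    """Write PDB + DCD + ground-truth TSV; returns the paths."""
    if system.n_frames < 1:
        raise ValueError("system has no frames")
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "pdb": os.path.join(out_dir, f"{prefix}.pdb"),
        "dcd": os.path.join(out_dir, f"{prefix}.dcd"),
    }
    write_pdb(system, paths["pdb"])
    write_dcd(system, paths["dcd"])
    if truth is not None:
        cols = {
            "time_ns": truth["frame_times"],
            "hinge_angle_deg": truth["hinge_angle_deg"],
            "twist_signal_deg": truth["twist_signal_deg"],
            "angle_e1_deg": truth["triad_angles_deg"][:, 0],
            "angle_e2_deg": truth["triad_angles_deg"][:, 1],
            "angle_e3_deg": truth["triad_angles_deg"][:, 2],
            "cdr3_distance_A": truth["cdr3_distance_A"],
        }
        for j, pair in enumerate(truth["contact_pairs"]):
            (ca_, ra), (cb_, rb) = pair
            cols[f"contact_{ca_}{ra}_{cb_}{rb}"] = truth["contact_states"][j].astype(int)
        df = pd.DataFrame(cols)
        paths["truth"] = os.path.join(out_dir, f"{prefix}_truth.tsv")
        df.to_csv(paths["truth"], sep="\t", index=False, float_format="%.6f")
    return paths
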