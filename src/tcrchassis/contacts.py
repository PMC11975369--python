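"""Residue-contact detection, occupancy statistics and contact-loss traces.

A residue pair is in contact in a frame when any heavy-atom pair across
the two residues is within the cutoff (default 4.0 Å).  Occupancy is the
fraction of frames with the contact present, reported as an interval
average and in rolling windows (default 40 ns, 20 ns stride; the
"instantaneous occupancy" of the dual high-occupancy criterion is the
windowed occupancy).  The Hamming distance H counts how many of the
initially high-occupancy contacts are absent in a given window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .system import DomainMap, MolecularSystem, SelectionSpec

__all__ = [
    "OccupancyTable",
    "ContactLossTrace",
    "InterfaceCounts",
    "instantaneous_contacts",
    "occupancy_series",
    "high_occupancy_contacts",
    "contact_count_by_interface",
    "hamming_distance_series",
]

ResidueRef = tuple[str, int]

_DOMAIN_ORDER = ["MHC", "peptide", "beta2m", "Valpha", "Vbeta", "Calpha", "Cbeta", "linker"]
_TCR_DOMAINS = {"Valpha", "Vbeta", "Calpha", "Cbeta"}


def _as_spec_list(group) -> list[SelectionSpec]:
    if isinstance(group, SelectionSpec):
        return [group]
    return list(group)


def _heavy_atom_indices(system: MolecularSystem, group) -> np.ndarray:
    """Heavy-atom indices of a selection (hydrogens always excluded)."""
    idx = np.unique(np.concatenate([s.resolve(system) for s in _as_spec_list(group)]))
    elements = system.atoms["element"].to_numpy()
    return idx[elements[idx] != "H"]


def _residue_refs(system: MolecularSystem, idx: np.ndarray) -> np.ndarray:
    a = system.atoms
    chains = a["chain_id"].to_numpy()
    resseq = a["resseq"].to_numpy()
    return np.array([(chains[i], int(resseq[i])) for i in idx], dtype=object)


def instantaneous_contacts(
    system: MolecularSystem,
    frame: int,
    group_a,
    group_b,
    cutoff: float = 4.0,
    mode: str = "residue",
):
    """Contacts between two groups in one frame.

    ``mode="residue"`` returns a set of ((chain, resseq), (chain, resseq))
    pairs (first element from group A); ``mode="atom"`` returns the set
    of contacting atom-index pairs.
    """
    idx_a = _heavy_atom_indices(system, group_a)
    idx_b = _heavy_atom_indices(system, group_b)
    if idx_a.size == 0 or idx_b.size == 0:
        raise ValueError("contact groups must be non-empty")
    refs_a = _residue_refs(system, idx_a)
    refs_b = _residue_refs(system, idx_b)
    if set(map(tuple, refs_a)) & set(map(tuple, refs_b)):
        raise ValueError("contact groups share residues; they must be disjoint")
    X = system.frames[frame]
    tree = cKDTree(X[idx_b])
    hits = tree.query_ball_point(X[idx_a], r=cutoff)
    if mode == "atom":
        out = set()
        for i, lst in enumerate(hits):
            for j in lst:
                out.add((int(idx_a[i]), int(idx_b[j])))
        return out
    if mode != "residue":
        raise ValueError(f"mode must be 'residue' or 'atom', got {mode!r}")
    out = set()
    for i, lst in enumerate(hits):
        for j in lst:
            out.add((tuple(refs_a[i]), tuple(refs_b[j])))
    return out


@dataclass
class OccupancyTable:
    """Per residue-pair contact presence, interval and windowed occupancy."""

    pairs: list[tuple[ResidueRef, ResidueRef]]
    presence: np.ndarray            # (n_pairs, n_frames) bool
    frame_times: np.ndarray         # ns
    windows: list[tuple[float, float]]
    window_occupancy: np.ndarray    # (n_pairs, n_windows)
    interval: tuple[float, float]
    avg_occupancy: np.ndarray       # (n_pairs,) over `interval`
    cutoff: float = 4.0
    mode: str = "residue"

    def __post_init__(self) -> None:
        if np.any(self.window_occupancy < 0) or np.any(self.window_occupancy > 1):
            raise ValueError("occupancies must lie in [0, 1]")
        seen = set()
        for a, b in self.pairs:
            key = frozenset((a, b))
            if key in seen:
                raise ValueError(f"duplicate (unordered) pair {a}–{b}")
            seen.add(key)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def total_occupancy_per_window(self) -> np.ndarray:
        """Sum of per-pair windowed occupancies (the rolling 'total
        contact occupancy' trace)."""
        return self.window_occupancy.sum(axis=0)

    def max_window_occupancy(self, interval: tuple[float, float] | None = None) -> np.ndarray:
        cols = self._window_cols(interval)
        if not cols:
            raise ValueError("no windows inside the requested interval")
        return self.window_occupancy[:, cols].max(axis=1)

    def _window_cols(self, interval: tuple[float, float] | None) -> list[int]:
        if interval is None:
            return list(range(len(self.windows)))
        lo, hi = interval
        return [i for i, (s, e) in enumerate(self.windows) if s >= lo - 1e-9 and e <= hi + 1e-9]

    def occupancy_over(self, interval: tuple[float, float]) -> np.ndarray:
        lo, hi = interval
        cols = (self.frame_times >= lo) & (self.frame_times < hi)
        if not cols.any():
            raise ValueError(f"no frames in interval {interval}")
        return self.presence[:, cols].mean(axis=1)

    def to_dataframe(self, domain_map: DomainMap | None = None) -> pd.DataFrame:
        rows = []
        for k, (a, b) in enumerate(self.pairs):
            row = {
                "chainA": a[0], "resseqA": a[1], "chainB": b[0], "resseqB": b[1],
                "avg_occupancy": self.avg_occupancy[k],
                "max_window_occupancy": float(self.window_occupancy[k].max()),
            }
            if domain_map is not None:
                row["domainA"] = domain_map.domain_of(*a)
                row["domainB"] = domain_map.domain_of(*b)
            rows.append(row)
        return pd.DataFrame(rows)


def _make_windows(t0: float, t_end: float, window_ns: float, stride_ns: float) -> list[tuple[float, float]]:
    out = []
    s = t0
    while s + window_ns <= t_end + 1e-9:
        out.append((s, s + window_ns))
        s += stride_ns
    return out


def occupancy_series(
    system: MolecularSystem,
    group_a,
    group_b,
    cutoff: float = 4.0,
    window_ns: float = 40.0,
    stride_ns: float = 20.0,
    interval: tuple[float, float] | None = None,
    mode: str = "residue",
) -> OccupancyTable:
    """Detect contacts in every frame and tabulate occupancies.

    ``interval`` (ns, default the whole trajectory) sets the range for
    the reported average occupancy; overlapping windows of ``window_ns``
    at ``stride_ns`` span the full trajectory.
    """
    t = system.frame_times
    dt = t[1] - t[0] if len(t) > 1 else 0.0
    span = (t[-1] - t[0]) + dt
    if window_ns > span + 1e-9:
        raise ValueError(f"window ({window_ns} ns) exceeds trajectory length ({span:.3f} ns)")
    if interval is None:
        interval = (float(t[0]), float(t[-1]) + dt)

    pair_index: dict = {}
    per_frame: list[list[int]] = []
    for f in range(system.n_frames):
        hits = instantaneous_contacts(system, f, group_a, group_b, cutoff, mode="residue")
        row = []
        for pair in hits:
            if pair not in pair_index:
                pair_index[pair] = len(pair_index)
            row.append(pair_index[pair])
        per_frame.append(row)

    pairs = list(pair_index.keys())
    presence = np.zeros((len(pairs), system.n_frames), dtype=bool)
    for f, row in enumerate(per_frame):
        presence[row, f] = True

    windows = _make_windows(float(t[0]), float(t[-1]) + dt, window_ns, stride_ns)
    window_occ = np.zeros((len(pairs), len(windows)))
    for w, (s, e) in enumerate(windows):
        cols = (t >= s - 1e-9) & (t < e - 1e-9)
        if cols.any():
            window_occ[:, w] = presence[:, cols].mean(axis=1)

    lo, hi = interval
    in_int = (t >= lo) & (t < hi)
    if not in_int.any():
        raise ValueError(f"no frames in interval {interval}")
    avg = presence[:, in_int].mean(axis=1) if pairs else np.zeros(0)

    return OccupancyTable(
        pairs=pairs, presence=presence, frame_times=t.copy(), windows=windows,
        window_occupancy=window_occ, interval=(float(lo), float(hi)),
        avg_occupancy=avg, cutoff=cutoff, mode=mode,
    )


def high_occupancy_contacts(
    table: OccupancyTable,
    avg_threshold: float = 0.50,
    max_instantaneous_threshold: float = 0.80,
    interval: tuple[float, float] | None = None,
) -> list[tuple[ResidueRef, ResidueRef]]:
    """Pairs exceeding both the interval-average and the maximum windowed
    occupancy thresholds (strict inequalities)."""
    for thr in (avg_threshold, max_instantaneous_threshold):
        if not 0.0 <= thr <= 1.0:
            raise ValueError(f"thresholds must lie in [0, 1], got {thr}")
    if table.n_pairs == 0:
        return []
    avg = table.avg_occupancy if interval is None else table.occupancy_over(interval)
    mx = table.max_window_occupancy(interval)
    keep = (avg > avg_threshold) & (mx > max_instantaneous_threshold)
    return [p for p, k in zip(table.pairs, keep) if k]


@dataclass
class InterfaceCounts:
    """Contact counts split by the domain pair they bridge."""

    counts: dict
    intra_tcr_total: int
    intra_tcr_excluding_c_module: int
    tcr_pmhc_total: int

    def __getitem__(self, key: str) -> int:
        return self.counts.get(key, 0)


def _category(la: str, lb: str) -> str:
    def rank(x: str) -> int:
        return _DOMAIN_ORDER.index(x) if x in _DOMAIN_ORDER else len(_DOMAIN_ORDER)

    first, second = sorted((la, lb), key=rank)
    return f"{first}-{second}"


def contact_count_by_interface(
    pairs: Sequence[tuple[ResidueRef, ResidueRef]],
    domain_map: DomainMap,
) -> InterfaceCounts:
    """Tally contacts per interface category (e.g. MHC-Valpha).

    The intra-TCR total is reported both with and without the Cα-Cβ
    interface, which is conventionally excluded from the intramolecular
    trace."""
    counts: dict = {}
    intra = 0
    intra_excl = 0
    inter = 0
    pmhc = {"MHC", "peptide"}
    for a, b in pairs:
        la = domain_map.domain_of(*a)
        lb = domain_map.domain_of(*b)
        cat = _category(la, lb)
        counts[cat] = counts.get(cat, 0) + 1
        if la in _TCR_DOMAINS and lb in _TCR_DOMAINS:
            intra += 1
            if {la, lb} != {"Calpha", "Cbeta"}:
                intra_excl += 1
        if (la in pmhc) != (lb in pmhc):
            inter += 1
    return InterfaceCounts(
        counts=counts,
        intra_tcr_total=intra,
        intra_tcr_excluding_c_module=intra_excl,
        tcr_pmhc_total=inter,
    )


@dataclass
class ContactLossTrace:
    """Hamming contact-loss trace H(w) over windows."""

    initial_set: list
    H: np.ndarray
    windows: list
    reference_window: int
    presence_threshold: float

    def __post_init__(self) -> None:
        if len(self.initial_set) and (self.H.min() < 0 or self.H.max() > len(self.initial_set)):
            raise ValueError("H must lie in [0, |initial_set|]")


def hamming_distance_series(
    table: OccupancyTable,
    reference_window: int = 0,
    presence_threshold: float = 0.5,
) -> ContactLossTrace:
    """Count initially persistent contacts lost per window.

    The initial set holds the pairs whose occupancy in the reference
    window exceeds ``presence_threshold``; H(w) is the number of those
    pairs whose occupancy in window w falls below the threshold.  H may
    decrease again when contacts re-form."""
    if not 0 <= reference_window < len(table.windows):
        raise ValueError(
            f"reference window {reference_window} outside 0..{len(table.windows) - 1}"
        )
    ref_occ = table.window_occupancy[:, reference_window]
    members = ref_occ > presence_threshold
    initial = [p for p, m in zip(table.pairs, members) if m]
    if not initial:
        warnings.warn("empty initial contact set; H is identically zero", stacklevel=2)
        H = np.zeros(len(table.windows), dtype=int)
        return ContactLossTrace(initial, H, list(table.windows), reference_window, presence_threshold)
    occ = table.window_occupancy[members]
    H = (occ < presence_threshold).sum(axis=0).astype(int)
    return ContactLossTrace(initial, H, list(table.windows), reference_window, presence_threshold)
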