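"""PCA of reduced coordinates (triad anchor points or BOC beads).

The reduced representation is a small set of labelled points per frame
— the two V-module triad origins plus their arm tips, or the BOC beads
— flattened to a 3N-vector.  PCA diagonalises the covariance (n−1
normalisation) of the mean-centred vectors; mode amplitudes are the
standard deviations of the projections (sqrt of the eigenvalues), with
an uncertainty estimated by repeating the analysis in three overlapping
sub-intervals.  Mode signs are fixed by making the largest-magnitude
component positive so overlaps are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import BocModel, Triad

__all__ = [
    "PcaResult",
    "ModeOverlap",
    "triad_anchor_coordinates",
    "boc_coordinates",
    "slice_interval",
    "pca",
    "mode_overlap",
    "per_bead_amplitude_difference",
]

DEFAULT_RESAMPLE_FRACTIONS = ((0.0, 0.6), (0.2, 0.8), (0.4, 1.0))


def triad_anchor_coordinates(
    triads_a: Sequence[Triad], triads_b: Sequence[Triad], arm_length: float = 10.0
) -> tuple[np.ndarray, list[str]]:
    """Flatten two triad series to anchor points (origin + 3 arm tips
    each).  Returns the (n_frames, 24) matrix and per-point labels."""
    if len(triads_a) != len(triads_b):
        raise ValueError("triad series differ in length")
    rows = [
        np.concatenate([ta.anchor_points(arm_length).ravel(), tb.anchor_points(arm_length).ravel()])
        for ta, tb in zip(triads_a, triads_b)
    ]
    labels = [f"{dom}_{pt}" for dom in ("A", "B") for pt in ("origin", "e1", "e2", "e3")]
    return np.asarray(rows), labels


def boc_coordinates(
    boc: BocModel,
    labels: Sequence[str] = ("Valpha", "Halpha", "Calpha", "Vbeta", "Hbeta", "Cbeta"),
) -> tuple[np.ndarray, list[str]]:
    """Flatten BOC bead positions; returns (n_frames, 3*len(labels))
    matrix and the bead labels."""
    return boc.coordinates(list(labels)), list(labels)


def slice_interval(matrix: np.ndarray, times: np.ndarray, interval: tuple[float, float]) -> np.ndarray:
    lo, hi = interval
    m = (times >= lo) & (times < hi)
    if not m.any():
        raise ValueError(f"no frames in interval {interval}")
    return matrix[m]


@dataclass
class PcaResult:
    """Ordered modes, amplitudes (Å) and interval-resampled uncertainty."""

    mean: np.ndarray
    modes: np.ndarray           # (n_modes, n_coords), orthonormal rows
    amplitudes: np.ndarray      # (n_modes,), non-increasing
    total_variance: float
    n_samples: int
    resample_std: np.ndarray | None = None
    labels: list | None = None

    def __post_init__(self) -> None:
        G = self.modes @ self.modes.T
        if not np.allclose(G, np.eye(len(self.modes)), atol=1e-8):
            raise ValueError("mode vectors are not orthonormal")
        if np.any(np.diff(self.amplitudes) > 1e-10):
            raise ValueError("amplitudes must be non-increasing")

    @property
    def n_modes(self) -> int:
        return len(self.amplitudes)


def _fix_signs(modes: np.ndarray) -> np.ndarray:
    out = modes.copy()
    for i in range(out.shape[0]):
        k = int(np.argmax(np.abs(out[i])))
        if out[i, k] < 0:
            out[i] = -out[i]
    return out


def _eig_pca(matrix: np.ndarray, n_modes: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    X = np.asarray(matrix, dtype=float)
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    modes = _fix_signs(evecs[:, order].T[:n_modes])
    amps = np.sqrt(evals[:n_modes])
    return mean, modes, amps, float(evals.sum())


def pca(
    matrix: np.ndarray,
    n_modes: int = 6,
    times: np.ndarray | None = None,
    resample_intervals: Sequence[tuple[float, float]] | None = None,
    labels: Sequence | None = None,
) -> PcaResult:
    """PCA of a frames × coordinates matrix.

    ``times`` (ns per row) enables the resampling uncertainty: the
    amplitudes are recomputed in three overlapping sub-intervals
    (default the 0–60%, 20–80% and 40–100% spans, mirroring a 500–800 /
    600–900 / 700–1000 ns split of a 500–1000 ns interval) and their
    std is reported per mode.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("matrix must be 2-D with at least 2 frames")
    rank_bound = min(X.shape[0] - 1, X.shape[1])
    if n_modes > rank_bound:
        raise ValueError(f"n_modes={n_modes} exceeds the rank bound {rank_bound}")
    mean, modes, amps, total_var = _eig_pca(X, n_modes)

    resample_std = None
    if times is not None:
        times = np.asarray(times, dtype=float)
        if times.shape[0] != X.shape[0]:
            raise ValueError("times must match the number of rows")
        if resample_intervals is None:
            t0, t1 = float(times[0]), float(times[-1])
            span = t1 - t0
            resample_intervals = [
                (t0 + a * span, t0 + b * span + (1e-9 if b == 1.0 else 0.0))
                for a, b in DEFAULT_RESAMPLE_FRACTIONS
            ]
        sub_amps = []
        for lo, hi in resample_intervals:
            sub = X[(times >= lo) & (times < hi)]
            if sub.shape[0] < 2:
                raise ValueError(f"resample interval ({lo}, {hi}) holds <2 frames")
            _, _, a, _ = _eig_pca(sub, n_modes)
            sub_amps.append(a)
        resample_std = np.std(np.asarray(sub_amps), axis=0)

    return PcaResult(
        mean=mean, modes=modes, amplitudes=amps, total_variance=total_var,
        n_samples=X.shape[0], resample_std=resample_std,
        labels=list(labels) if labels is not None else None,
    )


@dataclass
class ModeOverlap:
    """|dot| between corresponding PC vectors of two systems."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.matrix < -1e-12) or np.any(self.matrix > 1.0 + 1e-9):
            raise ValueError("overlap entries must lie in [0, 1]")


def mode_overlap(pca_a: PcaResult, pca_b: PcaResult, n: int = 3) -> ModeOverlap:
    """Absolute dot products |u_i^A · u_j^B| for i, j <= n."""
    if pca_a.modes.shape[1] != pca_b.modes.shape[1]:
        raise ValueError(
            f"mode dimensionality differs: {pca_a.modes.shape[1]} vs {pca_b.modes.shape[1]}"
        )
    n = min(n, pca_a.n_modes, pca_b.n_modes)
    M = np.abs(pca_a.modes[:n] @ pca_b.modes[:n].T)
    return ModeOverlap(np.clip(M, 0.0, 1.0))


def per_bead_amplitude_difference(
    pca_result: PcaResult,
    bead_labels: Sequence[str],
    pairs: Sequence[tuple[str, str]] = (("Valpha", "Vbeta"), ("Halpha", "Hbeta")),
    n_modes: int = 3,
) -> dict:
    """α−β asymmetry of per-bead RMS displacement, per mode.

    Each bead occupies a 3-coordinate block; a bead's contribution to a
    mode is amplitude × ‖mode sub-vector on the bead‖.  Returns
    {(label_a, label_b): array over modes of (α − β)}; positive means
    the α-chain bead is the more mobile."""
    if 3 * len(bead_labels) != pca_result.modes.shape[1]:
        raise ValueError("bead_labels do not tile the coordinate vector")
    block = {lab: slice(3 * i, 3 * i + 3) for i, lab in enumerate(bead_labels)}
    n_modes = min(n_modes, pca_result.n_modes)
    out = {}
    for la, lb in pairs:
        if la not in block or lb not in block:
            raise ValueError(f"bead pair ({la}, {lb}) not found in labels {list(bead_labels)}")
        diffs = np.empty(n_modes)
        for m in range(n_modes):
            v = pca_result.modes[m]
            amp = pca_result.amplitudes[m]
            diffs[m] = amp * (np.linalg.norm(v[block[la]]) - np.linalg.norm(v[block[lb]]))
        out[(la, lb)] = diffs
    return out
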