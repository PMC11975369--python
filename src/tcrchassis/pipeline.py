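"""Config-driven orchestration of the full analysis battery.

``run_analysis`` executes every stage the available selections support
— contact occupancy and interface counts, Hamming trace, BSA, RMSF,
V–pMHC distance, triads and triad angles, CDR3 distance, BOC and hinge
angles, reduced-coordinate PCA, restraint mechanics — and returns a
report whose summary table carries the interval mean ± std of each
quantity.  ``compare_systems`` places several reports side by side
(refusing to compare runs with differing analysis settings) and
computes PC-mode overlaps between systems.

Every output TSV embeds the configuration hash and package version as
comment headers, so numbers can always be traced to their settings.
"""

from __future__ import annotations

import hashlib
import json
import os
import sys
import time
from dataclasses import asdict, dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .contacts import (
    contact_count_by_interface,
    hamming_distance_series,
    high_occupancy_contacts,
    occupancy_series,
)
from .geometry import build_boc, cdr3_distance, hinge_angles, triad_angle_series, triad_series
from .interface import buried_surface_area, rmsf, v_pmhc_distance
from .mechanics import extension_series, restraint_force_series
from .pca import boc_coordinates, mode_overlap, pca, per_bead_amplitude_difference, slice_interval, triad_anchor_coordinates
from .synthetic import ChassisSpec
from .system import MolecularSystem, load_structure, load_trajectory, renumber_sequential

__all__ = ["AnalysisConfig", "AnalysisReport", "run_analysis", "compare_systems"]

_HASHED_KEYS = (
    "interval", "window_ns", "stride_ns", "avg_threshold",
    "max_instantaneous_threshold", "cutoff", "probe", "sasa_points",
    "bsa_stride_ns", "preset",
)


@dataclass
class AnalysisConfig:
    """Settings of one analysis run (defaults follow the study
    conventions: 500–1000 ns interval, 40/20 ns windows, 0.50/0.80
    occupancy thresholds, 4.0 Å cutoff)."""

    label: str = "system"
    structure: str | None = None
    trajectory: str | None = None
    frame_interval_ns: float = 0.02
    renumber: bool = True
    preset: str = "toy"
    interval: tuple[float, float] = (500.0, 1000.0)
    window_ns: float = 40.0
    stride_ns: float = 20.0
    avg_threshold: float = 0.50
    max_instantaneous_threshold: float = 0.80
    cutoff: float = 4.0
    probe: float = 1.4
    sasa_points: int = 240
    bsa_stride_ns: float = 1.0
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        self.interval = (float(self.interval[0]), float(self.interval[1]))
        for thr in (self.avg_threshold, self.max_instantaneous_threshold):
            if not 0.0 <= thr <= 1.0:
                raise ValueError(f"occupancy thresholds must lie in [0, 1], got {thr}")

    @classmethod
    def from_yaml(cls, path: str) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def settings_hash(self) -> str:
        payload = {k: getattr(self, k) for k in _HASHED_KEYS}
        blob = json.dumps(payload, sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class AnalysisReport:
    label: str
    config: AnalysisConfig
    summary: dict
    results: dict = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"quantity": list(self.summary), self.label: list(self.summary.values())}
        ).set_index("quantity")


def _log(stage: str, t0: float) -> None:
    print(f"[tcrchassis] {stage}: {time.perf_counter() - t0:.2f} s", file=sys.stderr)


def _write_tsv(df: pd.DataFrame, path: str, config: AnalysisConfig) -> None:
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# tcrchassis {__version__} config_hash={config.settings_hash()}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _load_system(config: AnalysisConfig) -> MolecularSystem:
    if config.structure is None:
        raise ValueError("config.structure is required when no system is passed in")
    system = load_structure(config.structure)
    if config.renumber:
        system, _ = renumber_sequential(system)
    if config.trajectory:
        system = load_trajectory(system, config.trajectory, config.frame_interval_ns)
    return system


def _mean_std(values: np.ndarray, times: np.ndarray, interval) -> tuple[float, float]:
    lo, hi = interval
    m = (times >= lo) & (times < hi)
    if not m.any():
        raise ValueError(f"no frames in interval {interval}")
    return float(values[m].mean()), float(values[m].std())


def run_analysis(
    config: AnalysisConfig,
    system: MolecularSystem | None = None,
    selections: Mapping | None = None,
    restraints=None,
) -> AnalysisReport:
    """Run every supported stage and collect a summary report.

    ``selections`` defaults to the toy-chassis preset; pass a custom
    mapping (same keys as ``ChassisSpec.selections()``) for other
    systems.  Stages whose selections are missing are skipped with a
    log line rather than failing the whole run.
    """
    t_all = time.perf_counter()
    if system is None:
        system = _load_system(config)
    if selections is None:
        if config.preset != "toy":
            raise ValueError(f"no selections supplied and preset {config.preset!r} has no defaults")
        spec = ChassisSpec()
        selections = spec.selections()
        if restraints is None:
            restraints = spec.restraints()

    lo, hi = config.interval
    t = system.frame_times
    dt = t[1] - t[0] if len(t) > 1 else 0.0
    if lo < t[0] - 1e-9 or hi > t[-1] + dt + 1e-9:
        raise ValueError(
            f"analysis interval {config.interval} ns outside trajectory span "
            f"({t[0]:.3f}–{t[-1]:.3f} ns)"
        )

    summary: dict = {}
    results: dict = {}

    # ---- contacts ----------------------------------------------------
    t0 = time.perf_counter()
    group_pairs = {
        "tcr_pmhc": ("tcr_group", "pmhc_group"),
        "valpha_vbeta": ("valpha_group", "vbeta_group"),
        "valpha_calpha": ("valpha_group", "calpha_group"),
        "vbeta_cbeta": ("vbeta_group", "cbeta_group"),
        "calpha_cbeta": ("calpha_group", "cbeta_group"),
    }
    domain_map = selections.get("domain_map")
    for name, (ga, gb) in group_pairs.items():
        if ga not in selections or gb not in selections:
            continue
        table = occupancy_series(
            system, selections[ga], selections[gb], cutoff=config.cutoff,
            window_ns=config.window_ns, stride_ns=config.stride_ns,
            interval=config.interval,
        )
        results[f"occupancy_{name}"] = table
        ho = high_occupancy_contacts(
            table, config.avg_threshold, config.max_instantaneous_threshold,
            interval=config.interval,
        )
        results[f"high_occupancy_{name}"] = ho
        summary[f"n_high_occupancy_{name}"] = len(ho)
        total = table.total_occupancy_per_window()
        cols = table._window_cols(config.interval)
        if cols:
            summary[f"total_occupancy_{name}_mean"] = float(total[cols].mean())
            summary[f"total_occupancy_{name}_std"] = float(total[cols].std())
        trace = hamming_distance_series(table) if table.n_pairs else None
        results[f"hamming_{name}"] = trace
        if domain_map is not None and ho:
            counts = contact_count_by_interface(ho, domain_map)
            results[f"interface_counts_{name}"] = counts
            for cat, n in sorted(counts.counts.items()):
                summary[f"n_high_occupancy_{name}_{cat}"] = n
    _log("contacts", t0)

    # ---- interface metrics -------------------------------------------
    t0 = time.perf_counter()
    if "tcr_group" in selections and "pmhc_group" in selections:
        bsa = buried_surface_area(
            system, selections["tcr_group"], selections["pmhc_group"],
            probe=config.probe, n_points=config.sasa_points,
            interval=config.interval, stride_ns=config.bsa_stride_ns,
            contact_cutoff=config.cutoff,
        )
        results["bsa"] = bsa
        summary["bsa_total_A2"] = bsa.total
    if "peptide_ca" in selections and "mhc_floor" in selections:
        prof = rmsf(system, selections["peptide_ca"], selections["mhc_floor"], t_start=lo)
        results["rmsf_peptide"] = prof
        summary["peptide_rmsf_mean_A"] = float(prof.values.mean())
    if all(k in selections for k in ("Valpha", "Vbeta", "mhc_floor")):
        dist = v_pmhc_distance(system, [selections["Valpha"], selections["Vbeta"]], selections["mhc_floor"])
        results["v_pmhc_distance"] = dist
        m, s = _mean_std(dist, t, config.interval)
        summary["v_pmhc_distance_mean_A"] = m
        summary["v_pmhc_distance_std_A"] = s
    _log("interface", t0)

    # ---- chassis geometry --------------------------------------------
    t0 = time.perf_counter()
    hint = selections.get("long_axis_hint")
    nhint = selections.get("normal_hint")
    triads = {}
    if "Valpha" in selections and "Vbeta" in selections:
        triads["A"] = triad_series(system, selections["Valpha"], 0, hint, nhint)
        triads["B"] = triad_series(system, selections["Vbeta"], 0, hint, nhint)
        ang = triad_angle_series(triads["A"], triads["B"])
        results["triad_angles"] = ang
        for i, name in enumerate(("e1", "e2", "e3")):
            m, s = _mean_std(ang[:, i], t, config.interval)
            summary[f"angle_{name}_mean_deg"] = m
            summary[f"angle_{name}_std_deg"] = s
    if "cdr3_alpha" in selections and "cdr3_beta" in selections:
        d = cdr3_distance(system, selections["cdr3_alpha"], selections["cdr3_beta"])
        results["cdr3_distance"] = d
        m, s = _mean_std(d, t, config.interval)
        summary["cdr3_distance_mean_A"] = m
        summary["cdr3_distance_std_A"] = s
    boc = None
    if all(k in selections for k in ("Valpha", "Vbeta", "Calpha", "Cbeta", "Halpha", "Hbeta")):
        boc = build_boc(system, selections)
        results["boc"] = boc
        ha = hinge_angles(boc)
        results["hinge_angles"] = ha
        for name, series in (("tcr_alpha", ha.tcr_alpha), ("tcr_beta", ha.tcr_beta)):
            m, s = _mean_std(series, t, config.interval)
            summary[f"hinge_{name}_mean_deg"] = m
            summary[f"hinge_{name}_std_deg"] = s
    _log("geometry", t0)

    # ---- PCA ---------------------------------------------------------
    t0 = time.perf_counter()
    in_int = (t >= lo) & (t < hi)
    if triads:
        mat, labels = triad_anchor_coordinates(triads["A"], triads["B"])
        res = pca(slice_interval(mat, t, config.interval), n_modes=6, times=t[in_int])
        results["pca_triad"] = res
        for i in range(res.n_modes):
            summary[f"triad_pc{i + 1}_amplitude_A"] = float(res.amplitudes[i])
    if boc is not None:
        mat, labels = boc_coordinates(boc)
        res = pca(slice_interval(mat, t, config.interval), n_modes=6, times=t[in_int], labels=labels)
        results["pca_boc"] = res
        for i in range(res.n_modes):
            summary[f"boc_pc{i + 1}_amplitude_A"] = float(res.amplitudes[i])
        diffs = per_bead_amplitude_difference(res, labels)
        results["per_bead_amplitude_difference"] = diffs
        for (la, lb), arr in diffs.items():
            for m_i, v in enumerate(arr):
                summary[f"amp_diff_{la[0]}{la[-1]}_pc{m_i + 1}_A"] = float(v)
    _log("pca", t0)

    # ---- mechanics ---------------------------------------------------
    t0 = time.perf_counter()
    if restraints is not None and restraints.restraints:
        trace = restraint_force_series(system, restraints, config.window_ns, config.stride_ns)
        results["mechanics"] = trace
        summary["load_mean_pN"] = trace.average(config.interval)
        summary["load_window_std_pN"] = trace.window_std_over(config.interval)
        by_end: dict = {}
        for r in restraints.restraints:
            by_end.setdefault(r.end, []).append(r)
        ends = list(by_end)
        if len(ends) == 2:
            e0 = by_end[ends[0]][0]
            e1 = by_end[ends[1]][0]
            ext = extension_series(
                system, (e0.residue, e1.residue), (e0.center, e1.center),
                atom_name=e0.atom_name, window_ns=config.window_ns, stride_ns=config.stride_ns,
            )
            results["extension"] = ext
            summary["extension_setting_A"] = ext.setting
            m, s = _mean_std(ext.realized, t, config.interval)
            summary["extension_realized_mean_A"] = m
    _log("mechanics", t0)

    report = AnalysisReport(label=config.label, config=config, summary=summary, results=results)
    if config.out_dir:
        _write_outputs(report, system)
    _log("total", t_all)
    return report


def _write_outputs(report: AnalysisReport, system: MolecularSystem) -> None:
    cfg = report.config
    out = cfg.out_dir
    _write_tsv(report.summary_frame().reset_index(), os.path.join(out, "summary.tsv"), cfg)
    for key, val in report.results.items():
        if key.startswith("occupancy_"):
            _write_tsv(val.to_dataframe(), os.path.join(out, f"{key}.tsv"), cfg)
        elif key == "triad_angles":
            df = pd.DataFrame(val, columns=["angle_e1_deg", "angle_e2_deg", "angle_e3_deg"])
            df.insert(0, "time_ns", system.frame_times)
            _write_tsv(df, os.path.join(out, "triad_angles.tsv"), cfg)
        elif key == "cdr3_distance":
            df = pd.DataFrame({"time_ns": system.frame_times, "cdr3_distance_A": val})
            _write_tsv(df, os.path.join(out, "cdr3_distance.tsv"), cfg)
        elif key == "hinge_angles":
            df = pd.DataFrame({
                "time_ns": system.frame_times,
                "hinge_tcr_alpha_deg": val.tcr_alpha,
                "hinge_tcr_beta_deg": val.tcr_beta,
            })
            _write_tsv(df, os.path.join(out, "hinge_angles.tsv"), cfg)
        elif key == "mechanics":
            df = pd.DataFrame({"time_ns": val.frame_times, "load_pN": val.load})
            _write_tsv(df, os.path.join(out, "load.tsv"), cfg)
        elif key == "bsa":
            rows = [
                {"chain": c, "resseq": r, "bsa_A2": v}
                for (c, r), v in sorted(val.per_residue.items())
            ]
            _write_tsv(pd.DataFrame(rows), os.path.join(out, "bsa_per_residue.tsv"), cfg)
        elif key.startswith("hamming_") and val is not None:
            df = pd.DataFrame({
                "window_start_ns": [w[0] for w in val.windows],
                "window_end_ns": [w[1] for w in val.windows],
                "H": val.H,
            })
            _write_tsv(df, os.path.join(out, f"{key}.tsv"), cfg)


def compare_systems(reports: list[AnalysisReport], labels: list[str] | None = None) -> dict:
    """Side-by-side comparison of >=2 reports with identical settings.

    Returns a dict with a ``table`` DataFrame of all summary statistics
    and, when PCA results are present, pairwise mode-overlap matrices.
    """
    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    ref = reports[0].config
    for rep in reports[1:]:
        diffs = [
            k for k in _HASHED_KEYS
            if getattr(rep.config, k) != getattr(ref, k)
        ]
        if diffs:
            raise ValueError(
                f"reports {reports[0].label!r} and {rep.label!r} were produced "
                f"with differing settings: {diffs}"
            )
    labels = labels or [r.label for r in reports]
    frames = []
    for rep, lab in zip(reports, labels):
        df = rep.summary_frame()
        df.columns = [lab]
        frames.append(df)
    table = pd.concat(frames, axis=1)

    overlaps = {}
    for key in ("pca_triad", "pca_boc"):
        present = [(lab, r.results[key]) for lab, r in zip(labels, reports) if key in r.results]
        for i in range(len(present)):
            for j in range(i + 1, len(present)):
                (la, pa), (lb, pb) = present[i], present[j]
                overlaps[(key, la, lb)] = mode_overlap(pa, pb, n=3).matrix
    return {"table": table, "mode_overlaps": overlaps, "settings_hash": ref.settings_hash()}
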