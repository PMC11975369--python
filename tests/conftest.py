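"""Shared fixtures: the toy chassis and a few simulated trajectories.

Everything is generated programmatically with fixed seeds; expensive
trajectories are session-scoped so several test modules can share them.
"""

from __future__ import annotations

import numpy as np
import pytest

import tcrchassis as tc


@pytest.fixture(scope="session")
def spec() -> tc.ChassisSpec:
    return tc.ChassisSpec()


@pytest.fixture(scope="session")
def selections(spec):
    return spec.selections()


@pytest.fixture(scope="session")
def toy(spec):
    return tc.build_toy_complex(spec)


@pytest.fixture(scope="session")
def sim_static_contacts(spec):
    """Constant 160° hinge, all contacts on, σ = 0.1 Å."""
    sched = tc.ContactSchedule.constant(spec.default_contact_pairs(), 300, on=True)
    hinge = tc.MotionProcess(kind="constant", value=160.0)
    return tc.simulate_trajectory(
        spec, hinge=hinge, contacts=sched, noise_sigma=0.1, n_frames=300, seed=101
    )


@pytest.fixture(scope="session")
def sim_two_state_hinge(spec):
    """Two-state hinge 140°/165° (the bimodal bending fixture)."""
    hinge = tc.MotionProcess(kind="two_state", state_means=(140.0, 165.0),
                             dwell_ns=(1.5, 1.5), seed=7)
    return tc.simulate_trajectory(
        spec, hinge=hinge, noise_sigma=0.1, n_frames=2500, seed=102
    )


@pytest.fixture(scope="session")
def sim_twist30(spec):
    """Sinusoidal 30° Vβ rotation about the shared e3 arm."""
    tw = tc.MotionProcess(kind="sinusoid", amplitude=30.0, period_ns=2.0)
    return tc.simulate_trajectory(
        spec, interdomain_twist=tw, twist_axis="e3", noise_sigma=0.1,
        n_frames=1000, seed=103
    )


@pytest.fixture(scope="session")
def sim_scissor(spec):
    """Scissoring fixture: a = 10°+s(t), b = 10°−s(t), s sinusoidal ±8°."""
    sc = tc.MotionProcess(kind="sinusoid", amplitude=8.0, period_ns=2.0)
    return tc.simulate_trajectory(
        spec, interdomain_twist=sc, twist_axis="scissor", noise_sigma=0.1,
        n_frames=800, seed=104
    )


@pytest.fixture(scope="session")
def sim_telegraph06(spec):
    """Fast telegraph contact schedules with stationary on-fraction 0.6
    (rates 150/100 per ns give near-independent frames at 20 ps)."""
    n = 10_000
    pairs = spec.default_contact_pairs()
    sched = tc.ContactSchedule.telegraph(
        pairs, n, 0.02, on_rate_per_ns=150.0, off_rate_per_ns=100.0, seed=21
    )
    system, truth = tc.simulate_trajectory(
        spec, contacts=sched, noise_sigma=0.05, n_frames=n, seed=22
    )
    return system, truth, sched


@pytest.fixture(scope="session")
def triad_pair(selections):
    def _build(system, reference_frame=0):
        ta = tc.triad_series(system, selections["Valpha"], reference_frame,
                             selections["long_axis_hint"], selections["normal_hint"])
        tb = tc.triad_series(system, selections["Vbeta"], reference_frame,
                             selections["long_axis_hint"], selections["normal_hint"])
        return ta, tb

    return _build


def quaternion_superposition_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Independent superposition oracle (Horn's quaternion method).

    Returns the least-squares RMSD of P onto Q without using the
    package's Kabsch implementation."""
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)
    M = P.T @ Q
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam = np.linalg.eigvalsh(K).max()
    e2 = (P ** 2).sum() + (Q ** 2).sum() - 2.0 * lam
    return float(np.sqrt(max(e2, 0.0) / len(P)))
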