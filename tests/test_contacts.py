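"""Contact detection, occupancy bookkeeping and Hamming traces."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

import tcrchassis as tc
from tcrchassis.contacts import OccupancyTable
from tcrchassis.system import ATOM_COLUMNS, MolecularSystem, SelectionSpec


def _system_from_atoms(rows, coords):
    atoms = pd.DataFrame(rows, columns=ATOM_COLUMNS)
    return MolecularSystem(atoms, np.asarray(coords, float)[None], np.array([0.0]))


def _two_residue_system(gap):
    rows = [
        (0, "CA", "C", "ALA", 1, "", "A"),
        (1, "CA", "C", "ALA", 1, "", "B"),
    ]
    return _system_from_atoms(rows, [[0.0, 0.0, 0.0], [gap, 0.0, 0.0]])


GROUP_A = SelectionSpec("a", "A", (), "heavy")
GROUP_B = SelectionSpec("b", "B", (), "heavy")


class TestInstantaneousContacts:
    @pytest.mark.parametrize("gap,expected", [(3.5, 1), (4.5, 0)])
    def test_cutoff_rule(self, gap, expected):
        s = _two_residue_system(gap)
        hits = tc.instantaneous_contacts(s, 0, GROUP_A, GROUP_B, cutoff=4.0)
        assert len(hits) == expected

    def test_overlapping_groups_rejected(self):
        s = _two_residue_system(3.0)
        both = SelectionSpec("both", "A", (), "heavy")
        with pytest.raises(ValueError, match="disjoint"):
            tc.instantaneous_contacts(s, 0, both, both, 4.0)

    def test_matches_brute_force_all_pairs(self):
        """KD-tree detection equals an O(N²) distance-matrix scan on a
        random 20-residue interface, for both residue and atom modes."""
        rng = np.random.default_rng(8)
        rows, coords = [], []
        aid = 0
        for chain in ("A", "B"):
            shift = np.array([0.0, 0.0, 0.0]) if chain == "A" else np.array([6.0, 0.0, 0.0])
            for r in range(1, 21):
                center = rng.normal(0, 4, 3) + shift
                for name in ("CA", "CB", "CG"):
                    rows.append((aid, name, "C", "ALA", r, "", chain))
                    coords.append(center + rng.normal(0, 1.2, 3))
                    aid += 1
        s = _system_from_atoms(rows, coords)
        hits = tc.instantaneous_contacts(s, 0, GROUP_A, GROUP_B, 4.0)
        # oracle: full distance matrix
        X = np.asarray(coords)
        ia = np.nonzero((s.atoms["chain_id"] == "A").to_numpy())[0]
        ib = np.nonzero((s.atoms["chain_id"] == "B").to_numpy())[0]
        D = cdist(X[ia], X[ib])
        expect = set()
        for i, j in zip(*np.nonzero(D <= 4.0)):
            expect.add((("A", int(s.atoms["resseq"].iloc[ia[i]])),
                        ("B", int(s.atoms["resseq"].iloc[ib[j]]))))
        assert hits == expect
        atom_hits = tc.instantaneous_contacts(s, 0, GROUP_A, GROUP_B, 4.0, mode="atom")
        expect_atoms = {(int(ia[i]), int(ib[j])) for i, j in zip(*np.nonzero(D <= 4.0))}
        assert atom_hits == expect_atoms


def _schedule_system(states, dt=0.02):
    """One pair whose contact follows a given boolean series."""
    rows = [
        (0, "CA", "C", "ALA", 1, "", "A"),
        (1, "CA", "C", "ALA", 1, "", "B"),
    ]
    n = len(states)
    frames = np.zeros((n, 2, 3))
    frames[:, 1, 0] = np.where(states, 3.0, 6.0)
    atoms = pd.DataFrame(rows, columns=ATOM_COLUMNS)
    return MolecularSystem(atoms, frames, np.arange(n) * dt)


class TestOccupancy:
    def test_counting_oracle_600_of_1000(self):
        states = np.zeros(1000, bool)
        states[:600] = True
        s = _schedule_system(states)
        table = tc.occupancy_series(s, GROUP_A, GROUP_B, 4.0, window_ns=4.0, stride_ns=2.0)
        assert table.n_pairs == 1
        assert table.avg_occupancy[0] == pytest.approx(0.600, abs=1e-12)

    def test_always_on_pair_full_occupancy_every_window(self):
        s = _schedule_system(np.ones(400, bool))
        table = tc.occupancy_series(s, GROUP_A, GROUP_B, 4.0, window_ns=2.0, stride_ns=1.0)
        np.testing.assert_allclose(table.window_occupancy, 1.0)

    def test_total_occupancy_additivity(self, spec, selections, sim_static_contacts):
        system, _ = sim_static_contacts
        table = tc.occupancy_series(
            system, selections["pmhc_group"], selections["tcr_group"], 4.0,
            window_ns=2.0, stride_ns=1.0,
        )
        total = table.total_occupancy_per_window()
        np.testing.assert_allclose(total, table.window_occupancy.sum(axis=0), atol=0)
        # two always-on pairs sum to 2.0: all eight scheduled pairs stay on
        np.testing.assert_allclose(total, 8.0)

    def test_window_longer_than_trajectory_rejected(self):
        s = _schedule_system(np.ones(10, bool))
        with pytest.raises(ValueError, match="window"):
            tc.occupancy_series(s, GROUP_A, GROUP_B, 4.0, window_ns=5.0, stride_ns=1.0)

    def test_symmetry_under_group_order(self, selections, sim_static_contacts):
        system, _ = sim_static_contacts
        ab = tc.instantaneous_contacts(system, 0, selections["pmhc_group"], selections["tcr_group"], 4.0)
        ba = tc.instantaneous_contacts(system, 0, selections["tcr_group"], selections["pmhc_group"], 4.0)
        assert {frozenset(p) for p in ab} == {frozenset(p) for p in ba}


def _table_from_profiles(profiles, dt=0.02, window_ns=2.0, stride_ns=1.0):
    """OccupancyTable for pairs with given per-frame boolean profiles."""
    n = len(profiles[0])
    presence = np.asarray(profiles, bool)
    t = np.arange(n) * dt
    windows = []
    s0 = 0.0
    while s0 + window_ns <= t[-1] + dt + 1e-9:
        windows.append((s0, s0 + window_ns))
        s0 += stride_ns
    wocc = np.array([
        [presence[k][(t >= a) & (t < b)].mean() for (a, b) in windows]
        for k in range(len(profiles))
    ])
    pairs = [(("A", k + 1), ("B", k + 1)) for k in range(len(profiles))]
    return OccupancyTable(
        pairs=pairs, presence=presence, frame_times=t, windows=windows,
        window_occupancy=wocc, interval=(0.0, n * dt), avg_occupancy=presence.mean(axis=1),
    )


class TestHighOccupancy:
    def test_dual_threshold_rule(self):
        n = 1000
        rng = np.random.default_rng(3)

        def bern(p):
            return rng.random(n) < p

        hi_hi = np.zeros(n, bool)
        hi_hi[:600] = True                      # avg 0.6, one window at 1.0
        steady = bern(0.6)                      # avg 0.6, windows near 0.6 < 0.8
        low = np.zeros(n, bool)
        low[:400] = True                        # avg 0.4, max window 1.0
        table = _table_from_profiles([hi_hi, steady, low])
        kept = tc.high_occupancy_contacts(table, 0.50, 0.80)
        assert kept == [table.pairs[0]]

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(9)
        profiles = [rng.random(600) < p for p in (0.3, 0.5, 0.7, 0.9)]
        table = _table_from_profiles(profiles)
        sizes = [
            len(tc.high_occupancy_contacts(table, thr, 0.0))
            for thr in (0.2, 0.4, 0.6, 0.8)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_invalid_threshold_rejected(self):
        table = _table_from_profiles([np.ones(200, bool)])
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            tc.high_occupancy_contacts(table, 1.5, 0.8)


class TestInterfaceCounts:
    def _map(self):
        return tc.DomainMap({
            ("M", 1): "MHC", ("P", 1): "peptide",
            ("A", 1): "Valpha", ("A", 2): "Calpha",
            ("B", 1): "Vbeta", ("B", 2): "Cbeta",
        })

    def test_bookkeeping(self):
        pairs = [
            (("M", 1), ("A", 1)),
            (("P", 1), ("B", 1)),
            (("A", 2), ("B", 2)),
        ]
        counts = tc.contact_count_by_interface(pairs, self._map())
        assert counts["MHC-Valpha"] == 1
        assert counts["MHC-Vbeta"] == 0
        assert counts["peptide-Vbeta"] == 1
        assert counts["Calpha-Cbeta"] == 1
        assert counts.intra_tcr_total == 1
        assert counts.intra_tcr_excluding_c_module == 0
        assert counts.tcr_pmhc_total == 2

    def test_empty_pair_list(self):
        counts = tc.contact_count_by_interface([], self._map())
        assert counts.counts == {}
        assert counts.intra_tcr_total == 0

    def test_random_pairs_match_hand_tally(self):
        rng = np.random.default_rng(17)
        dm = self._map()
        refs = list(dm.mapping)
        pairs = []
        for _ in range(50):
            a, b = rng.choice(len(refs), 2, replace=False)
            pairs.append((refs[a], refs[b]))
        counts = tc.contact_count_by_interface(pairs, dm)
        tally = {}
        for a, b in pairs:
            la, lb = dm.domain_of(*a), dm.domain_of(*b)
            order = ["MHC", "peptide", "beta2m", "Valpha", "Vbeta", "Calpha", "Cbeta"]
            key = "-".join(sorted((la, lb), key=order.index))
            tally[key] = tally.get(key, 0) + 1
        assert counts.counts == tally
        assert sum(counts.counts.values()) == 50

    def test_unmapped_residue_raises_with_name(self):
        with pytest.raises(KeyError, match="Z:9"):
            tc.contact_count_by_interface([(("Z", 9), ("A", 1))], self._map())


class TestHamming:
    def test_persistent_contacts_give_zero(self):
        table = _table_from_profiles([np.ones(500, bool)] * 4)
        trace = tc.hamming_distance_series(table)
        assert len(trace.initial_set) == 4
        np.testing.assert_array_equal(trace.H, 0)

    def test_step_when_contacts_switch_off(self):
        """3 of 10 initially persistent contacts switched off at 4 ns
        raise H from 0 to 3 in the windows after the switch."""
        n, dt = 500, 0.02
        t_off = 4.0
        profiles = []
        for k in range(10):
            p = np.ones(n, bool)
            if k < 3:
                p[np.arange(n) * dt >= t_off] = False
            profiles.append(p)
        table = _table_from_profiles(profiles, dt=dt, window_ns=2.0, stride_ns=1.0)
        trace = tc.hamming_distance_series(table)
        assert trace.H[0] == 0
        for w, (a, b) in enumerate(trace.windows):
            if a >= t_off:
                assert trace.H[w] == 3
            if b <= t_off:
                assert trace.H[w] == 0

    def test_recovered_contact_lowers_h(self):
        n = 600
        p = np.ones(n, bool)
        p[150:300] = False      # off then back on
        table = _table_from_profiles([p, np.ones(n, bool)])
        trace = tc.hamming_distance_series(table)
        assert trace.H.max() == 1
        assert trace.H[-1] == 0

    def test_empty_initial_set_warns(self):
        table = _table_from_profiles([np.zeros(300, bool)])
        with pytest.warns(UserWarning, match="empty initial"):
            trace = tc.hamming_distance_series(table)
        np.testing.assert_array_equal(trace.H, 0)

    def test_schedule_bookkeeping_oracle_on_telegraph_fixture(self, spec, selections):
        """H computed from detected contacts equals H computed directly
        from the generator's schedule."""
        n, dt = 1500, 0.02
        pairs = spec.default_contact_pairs()
        sched = tc.ContactSchedule.constant(pairs, n, on=True)
        inter_idx = [i for i, pr in enumerate(pairs) if pr[0][0] in "MP"]
        sched = sched.switched_off_at(inter_idx[:3], 15.0, np.arange(n) * dt)
        system, _ = tc.simulate_trajectory(spec, contacts=sched, noise_sigma=0.05,
                                           n_frames=n, seed=33)
        table = tc.occupancy_series(system, selections["pmhc_group"], selections["tcr_group"],
                                    4.0, window_ns=4.0, stride_ns=2.0)
        trace = tc.hamming_distance_series(table)
        # oracle straight from the schedule
        idx = {frozenset(p): i for i, p in enumerate(sched.pairs)}
        t = np.arange(n) * dt
        expect = []
        for (a, b) in trace.windows:
            m = (t >= a) & (t < b)
            lost = 0
            for pr in trace.initial_set:
                occ = sched.states[idx[frozenset(pr)]][m].mean()
                if occ < 0.5:
                    lost += 1
            expect.append(lost)
        np.testing.assert_array_equal(trace.H, expect)
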