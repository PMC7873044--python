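"""Contact detection, probabilities, events, lifetimes, classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cgcontact.contacts import (ContactCriterion, candidate_pairs,
                                classify_interaction, compute_pair_stats,
                                contact_events, contact_map,
                                contact_probability, detect_contacts,
                                events_from_bool_series, lifetime_stats,
                                log_percentage, top_pairs)
from cgcontact.errors import InputError, UndefinedStatisticError
from cgcontact.topology import build_topology
from cgcontact.trajectory import Frame, Trajectory, TrajectoryEnsemble

from conftest import make_chain_topology, trajectory_from_distances

CRIT = ContactCriterion()


def linear_frame(n, spacing=3.8):
    return Frame(np.column_stack([np.arange(n) * spacing,
                                  np.zeros(n), np.zeros(n)]))


class TestDetectContacts:
    def test_sequence_separation_rule(self):
        topo = make_chain_topology({"A": 10})
        # residues 1 and 6 close, residues 1 and 4 close
        coords = np.zeros((10, 3))
        coords[:, 0] = np.arange(10) * 100.0
        coords[5] = [7.9, 0, 0]   # residue 6 at 7.9 A from residue 1
        coords[3] = [3.8, 0, 0]   # residue 4 at 3.8 A from residue 1
        hits = detect_contacts(Frame(coords), topo, CRIT)
        assert (1, 6) in hits
        assert (1, 4) not in hits  # separation 3 < 5

    def test_cutoff_boundary_inclusive(self):
        topo = make_chain_topology({"A": 1, "B": 1})
        at = lambda d: Frame(np.array([[0, 0, 0], [d, 0, 0]]))
        assert (1, 2) in detect_contacts(at(8.000), topo, CRIT)
        assert detect_contacts(at(8.001), topo, CRIT) == set()

    def test_interchain_pairs_bypass_separation(self):
        topo = make_chain_topology({"A": 3, "B": 3})
        coords = np.zeros((6, 3))
        coords[:, 1] = [0, 100, 200, 1, 300, 400]  # A1 and B1 at 1 A
        hits = detect_contacts(Frame(coords), topo, CRIT)
        assert (1, 4) in hits  # concatenated gap 3 but different chains

    def test_matches_bruteforce_on_random_frames(self, rng):
        topo = make_chain_topology({"A": 30, "B": 30})
        for _ in range(20):
            frame = Frame(rng.uniform(0, 30, size=(60, 3)))
            fast = detect_contacts(frame, topo, CRIT)
            slow = set()
            for i in range(60):
                for j in range(i + 1, 60):
                    ri, rj = topo.residue(i + 1), topo.residue(j + 1)
                    eligible = (ri.chain_id != rj.chain_id
                                or abs(ri.local_index - rj.local_index) >= 5)
                    d = np.linalg.norm(frame.coords[i] - frame.coords[j])
                    if eligible and d <= 8.0:
                        slow.add((i + 1, j + 1))
            assert fast == slow

    def test_rigid_motion_invariance(self, rng):
        topo = make_chain_topology({"A": 20})
        frame = Frame(rng.uniform(0, 25, size=(20, 3)))
        base = detect_contacts(frame, topo, CRIT)
        # random proper rotation + translation
        q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        moved = Frame(frame.coords @ q.T + rng.uniform(-40, 40, 3))
        assert detect_contacts(moved, topo, CRIT) == base

    def test_monotone_in_cutoff_and_separation(self, rng):
        topo = make_chain_topology({"A": 25})
        frame = Frame(rng.uniform(0, 20, size=(25, 3)))
        small = detect_contacts(frame, topo, ContactCriterion(6.0, 5))
        large = detect_contacts(frame, topo, ContactCriterion(9.0, 5))
        assert small <= large
        strict = detect_contacts(frame, topo, ContactCriterion(8.0, 8))
        assert strict <= detect_contacts(frame, topo, ContactCriterion(8.0, 3))

    def test_size_mismatch_raises(self):
        topo = make_chain_topology({"A": 3})
        with pytest.raises(InputError):
            detect_contacts(Frame(np.zeros((4, 3))), topo, CRIT)


class TestProbabilityAndMap:
    def test_probability_fraction_of_frames(self):
        d = np.array([5.0] * 21 + [20.0] * 79)
        traj, topo = trajectory_from_distances(d)
        assert contact_probability(traj, topo, (1, 2)) == pytest.approx(21.0)

    def test_probability_zero_when_never_in_contact(self):
        traj, topo = trajectory_from_distances(np.full(50, 30.0))
        assert contact_probability(traj, topo, (1, 2)) == 0.0

    def test_map_entry_100_for_permanent_contact(self):
        traj, topo = trajectory_from_distances(np.full(10, 5.0))
        cmap = contact_map(traj, topo, [1], [2])
        assert cmap.probability[0, 0] == pytest.approx(100.0)

    def test_map_transpose_symmetry(self, rng):
        topo = make_chain_topology({"A": 6, "B": 6})
        frames = [Frame(rng.uniform(0, 15, size=(12, 3))) for _ in range(30)]
        traj = Trajectory(frames, 10_000, label="x")
        a, b = list(range(1, 7)), list(range(7, 13))
        ab = contact_map(traj, topo, a, b)
        ba = contact_map(traj, topo, b, a)
        assert np.allclose(ab.probability, ba.probability.T)

    def test_map_respects_separation_exclusions(self, rng):
        topo = make_chain_topology({"A": 12})
        frames = [Frame(np.zeros((12, 3)))]  # everything coincident
        traj = Trajectory(frames, 10_000)
        group = list(range(1, 13))
        cmap = contact_map(traj, topo, group, group)
        # brute-force count of eligible pairs (|i-j| >= 5)
        n_elig = sum(1 for i in group for j in group if abs(i - j) >= 5)
        assert int((cmap.probability > 0).sum()) == n_elig

    def test_empty_group_rejected(self):
        traj, topo = trajectory_from_distances([5.0])
        with pytest.raises(InputError):
            contact_map(traj, topo, [], [1])

    def test_log_percentage_values(self):
        traj, topo = trajectory_from_distances(np.full(4, 5.0))
        cmap = contact_map(traj, topo, [1], [2])
        assert log_percentage(cmap)[0, 0] == pytest.approx(2.0)
        cmap.probability[0, 0] = 10.0
        assert log_percentage(cmap)[0, 0] == pytest.approx(1.0)
        cmap.probability[0, 0] = 0.0
        assert log_percentage(cmap, floor_pct=0.01)[0, 0] == pytest.approx(-2.0)


class TestEventsAndLifetimes:
    def test_simple_run_detection(self):
        traj, topo = trajectory_from_distances(
            [20, 5, 5, 5, 20])  # series 0,1,1,1,0
        evs = contact_events(traj, topo, (1, 2))
        assert len(evs) == 1
        assert evs[0].length_frames == 3
        assert evs[0].start_frame == 1
        assert not evs[0].censored

    def test_boundary_touching_events_censored(self):
        traj, topo = trajectory_from_distances([5, 5, 20, 5])  # 1,1,0,1
        evs = contact_events(traj, topo, (1, 2))
        assert [(e.length_frames, e.censored) for e in evs] == \
            [(2, True), (1, True)]

    def test_events_do_not_span_trajectories(self):
        t1, topo = trajectory_from_distances([5, 5], label="t1")
        t2, _ = trajectory_from_distances([5, 5], label="t2")
        evs = contact_events(TrajectoryEnsemble([t1, t2]), topo, (1, 2))
        assert [e.trajectory_label for e in evs] == ["t1", "t2"]
        assert all(e.length_frames == 2 and e.censored for e in evs)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.booleans(), min_size=1, max_size=60))
    def test_events_match_rle_oracle(self, series):
        import itertools
        evs = events_from_bool_series(np.array(series), (1, 2), "t")
        # independent run-length-encoding oracle
        expected, pos = [], 0
        for val, grp in itertools.groupby(series):
            ln = len(list(grp))
            if val:
                expected.append((pos, ln))
            pos += ln
        assert [(e.start_frame, e.length_frames) for e in evs] == expected
        assert sum(e.length_frames for e in evs) == sum(series)

    def test_lifetime_unit_conversion(self):
        evs = events_from_bool_series(np.array([0, 1, 1, 1, 0], bool), (1, 2), "t")
        mean, sd = lifetime_stats(evs, snapshot_interval_steps=10_000)
        assert mean == pytest.approx(0.3)
        assert sd == pytest.approx(0.0)

    def test_lifetime_mean_sd_two_events(self):
        evs = events_from_bool_series(np.array([1, 1, 0, 1], bool), (1, 2), "t")
        mean, sd = lifetime_stats(evs, snapshot_interval_steps=10_000)
        assert mean == pytest.approx(0.15)
        assert sd == pytest.approx(0.05)

    def test_lifetime_of_nothing_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            lifetime_stats([], 10_000)

    def test_geometric_run_lengths_match_expectation(self, rng):
        # persistence q: stay-in-contact probability; run lengths ~ Geom(1-q)
        q = 0.8
        n = 60_000
        series = np.empty(n, dtype=bool)
        series[0] = rng.random() < 0.5
        stay = rng.random(n)
        for i in range(1, n):
            series[i] = stay[i] < q if series[i - 1] else stay[i] < 0.2
        evs = [e for e in events_from_bool_series(series, (1, 2), "t")
               if not e.censored]
        mean, _ = lifetime_stats(evs, snapshot_interval_steps=100_000)
        expected = 1.0 / (1.0 - q)  # frames; unit = 1 frame here
        se = expected / np.sqrt(len(evs))  # ~ sd/sqrt(n) for geometric
        assert abs(mean - expected) < 3 * se


class TestStatsRankingClassification:
    def test_probability_equals_event_length_sum(self, rng):
        d = np.where(rng.random(200) < 0.3, 5.0, 20.0)
        traj, topo = trajectory_from_distances(d)
        p = contact_probability(traj, topo, (1, 2))
        evs = contact_events(traj, topo, (1, 2))
        assert p == pytest.approx(100.0 * sum(e.length_frames for e in evs) / 200)

    def test_top_pairs_ordering_and_ties(self):
        topo = build_topology({
            "chains": [{"id": "A", "sequence": "G" * 40}],
            "regions": [{"label": "PDZ", "chain": "A", "start": 1, "end": 20},
                        {"label": "BAR", "chain": "A", "start": 21, "end": 40}]})
        rngl = np.random.default_rng(3)
        # craft distances: pairs (1,30), (2,31), (3,32) with probs 90, 50, 50
        n = 10
        coords = np.full((n, 40, 3), 1e4)
        for k in range(40):
            coords[:, k, 1] = k * 1e3
        def set_pair(i, j, n_contact):
            coords[:n_contact, j - 1] = coords[:n_contact, i - 1] + [5.0, 0, 0]
        set_pair(1, 30, 9)
        set_pair(2, 31, 5)          # one event of 5 -> lifetime 5 frames
        for f in (0, 2, 4, 6, 8):   # five events of 1 -> lifetime 1 frame
            coords[f, 32 - 1] = coords[f, 3 - 1] + [5.0, 0, 0]
        traj = Trajectory([Frame(c) for c in coords], 10_000)
        pairs = [(1, 30), (2, 31), (3, 32)]
        stats = compute_pair_stats(traj, topo, pairs)
        table = top_pairs(stats, topo, "PDZ", "BAR", n=2)
        assert list(table["residue_1"]) == [1, 2]
        # tie on probability broken by longer lifetime
        table3 = top_pairs(stats, topo, "PDZ", "BAR", n=3)
        assert list(zip(table3["residue_1"], table3["residue_2"])) == \
            [(1, 30), (2, 31), (3, 32)]
        # N larger than universe returns everything
        assert len(top_pairs(stats, topo, "PDZ", "BAR", n=99)) == 3

    def test_classification_rules(self):
        topo = build_topology({"chains": [{"id": "A",
                                           "sequence": "KDVLSSX"}]})
        assert classify_interaction((1, 2), topo) == "ELECTROSTATIC"
        assert classify_interaction((3, 4), topo) == "HYDROPHOBIC"
        assert classify_interaction((5, 6), topo) == "POLAR"
        assert classify_interaction((1, 5), topo) == "MIXED"
        with pytest.warns(UserWarning, match="UNKNOWN"):
            assert classify_interaction((1, 7), topo) == "UNKNOWN"

    def test_candidate_pairs_respect_eligibility(self):
        topo = make_chain_topology({"A": 8})
        pairs = candidate_pairs(topo, [1, 2], [3, 6, 7])
        assert pairs == [(1, 6), (1, 7), (2, 7)]
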