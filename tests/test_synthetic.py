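"""Generator invariants: construction, move set, determinism, physics."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from cgcontact.contacts import contact_probability
from cgcontact.errors import ConfigurationError, ConstructionError
from cgcontact.synthetic import (BodyParams, RodParams, SyntheticModelParams,
                                 TailParams, build_system, calibrate_ground_truth,
                                 load_preset, planted_blobs, run_ensemble,
                                 run_mc, two_state_occupancy_theory)

PRESETS = ("system1-like", "system2-like", "two-state-toy")


def short(params, n_steps=4000, record=50, equil=500):
    params.n_steps, params.record_interval, params.equil_steps = \
        n_steps, record, equil
    return params


def min_nonbonded(coords, bonds):
    d = cdist(coords, coords)
    np.fill_diagonal(d, np.inf)
    for i, j in bonds:
        d[i, j] = d[j, i] = np.inf
    return d.min()


class TestBuildSystem:
    def test_bead_bookkeeping(self):
        params = SyntheticModelParams(
            ref_body=RodParams(n_beads=20),
            mobile_bodies=[BodyParams(n_beads=8, linker_length=10)])
        system = build_system(params)
        assert system.n_beads == 38
        assert system.topology.n_residues == 38
        regions = [r.region for r in system.topology.residues]
        assert regions[:20] == ["BAR"] * 20
        assert regions[20:30] == ["LINKER"] * 10
        assert regions[30:] == ["PDZ"] * 8

    def test_rod_alone_bond_lengths(self):
        params = SyntheticModelParams(ref_body=RodParams(n_beads=12))
        system = build_system(params)
        x = system.initial_frame.coords
        for i, j in system.bonds:
            assert np.linalg.norm(x[i] - x[j]) == pytest.approx(3.8, abs=1e-9)

    @pytest.mark.parametrize("preset", PRESETS)
    def test_no_hard_sphere_overlap_at_build(self, preset):
        params = load_preset(preset)
        system = build_system(params)
        assert min_nonbonded(system.initial_frame.coords, system.bonds) >= \
            2 * params.bead_radius

    def test_invalid_params_rejected(self):
        with pytest.raises(ConfigurationError):
            SyntheticModelParams(
                sticky_pairs=[], record_interval=0).validate()
        with pytest.raises(ConfigurationError):
            p = SyntheticModelParams(
                ref_body=RodParams(n_beads=5),
                tails=[TailParams(length=3, attach=9)])
            p.validate()

    def test_params_yaml_roundtrip(self, tmp_path):
        params = load_preset("system2-like")
        path = tmp_path / "p.yaml"
        params.to_yaml(path)
        back = SyntheticModelParams.from_yaml(path)
        assert back.to_dict() == params.to_dict()


class TestRunMc:
    def test_same_seed_bitwise_identical(self):
        params = short(load_preset("two-state-toy"))
        system = build_system(params)
        t1 = run_mc(system, params)
        t2 = run_mc(system, params)
        assert all(np.array_equal(a.coords, b.coords)
                   for a, b in zip(t1.frames, t2.frames))

    def test_different_seeds_differ(self):
        params = short(load_preset("two-state-toy"))
        system = build_system(params)
        t1 = run_mc(system, params, seed=1)
        t2 = run_mc(system, params, seed=2)
        assert not np.array_equal(t1.frames[-1].coords, t2.frames[-1].coords)

    @pytest.mark.parametrize("preset", PRESETS)
    def test_bonds_preserved_and_no_overlap(self, preset):
        params = short(load_preset(preset))
        system = build_system(params)
        traj = run_mc(system, params)
        x0 = system.initial_frame.coords
        ref_lengths = {b: np.linalg.norm(x0[b[0]] - x0[b[1]])
                       for b in system.bonds}
        for frame in traj.frames[::4]:
            x = frame.coords
            for (i, j), l0 in ref_lengths.items():
                assert np.linalg.norm(x[i] - x[j]) == pytest.approx(l0, abs=1e-8)
            assert min_nonbonded(x, system.bonds) >= 2 * params.bead_radius

    @pytest.mark.parametrize("preset", PRESETS)
    def test_acceptance_fraction_strictly_inside_unit_interval(self, preset):
        params = short(load_preset(preset))
        system = build_system(params)
        _, stats = run_mc(system, params, return_stats=True)
        assert 0.0 < stats["acceptance_fraction"] < 1.0

    def test_rod_beads_never_move(self):
        params = short(load_preset("system1-like"))
        system = build_system(params)
        traj = run_mc(system, params)
        n_rod = params.ref_body.n_beads
        x0 = system.initial_frame.coords[:n_rod]
        assert np.array_equal(traj.frames[-1].coords[:n_rod], x0)

    def test_ensemble_members_are_independent_streams(self):
        params = short(load_preset("two-state-toy"))
        ens = run_ensemble(params, 3)
        assert len(ens.trajectories) == 3
        assert len({t.label for t in ens.trajectories}) == 3
        a, b = ens.trajectories[0], ens.trajectories[1]
        assert not np.array_equal(a.frames[-1].coords, b.frames[-1].coords)


class TestPlantedPropensities:
    def test_unreachable_pair_probability_zero(self):
        # sticky pair between the rod's far end and a short tail that cannot
        # physically reach it: probability must be ~0 regardless of eps
        params = SyntheticModelParams(
            ref_body=RodParams(n_beads=30),
            tails=[TailParams(length=3, attach=1)],
            sticky_pairs=[],
            n_steps=3000, record_interval=30, equil_steps=300)
        system = build_system(params)
        traj = run_mc(system, params)
        assert contact_probability(traj, system.topology, (30, 33)) == 0.0

    def test_symmetric_sticky_pairs_equal_within_noise(self):
        # two tails attached at the two rod ends with mirror-image wells
        from cgcontact.synthetic import StickyPair
        params = SyntheticModelParams(
            ref_body=RodParams(n_beads=20),
            tails=[TailParams(length=6, attach=1),
                   TailParams(length=6, attach=20)],
            sticky_pairs=[StickyPair(3, 26, eps=2.0),
                          StickyPair(18, 32, eps=2.0)],
            n_steps=60_000, record_interval=60, equil_steps=3_000, seed=11)
        system = build_system(params)
        traj = run_mc(system, params)
        p1 = contact_probability(traj, system.topology, (3, 26))
        p2 = contact_probability(traj, system.topology, (18, 32))
        n = traj.n_frames
        pbar = (p1 + p2) / 200
        se = 100 * np.sqrt(2 * pbar * (1 - pbar) / n)
        assert abs(p1 - p2) < 4 * se

    def test_calibration_reports_all_pairs(self):
        params = short(load_preset("system1-like"), n_steps=3000)
        gt = calibrate_ground_truth(params, length_factor=1)
        assert len(gt.pair_probability_pct) == len(params.sticky_pairs)
        assert all(0 <= v <= 100 for v in gt.pair_probability_pct.values())


class TestClosedForms:
    def test_two_state_theory_limits(self):
        assert two_state_occupancy_theory(0, 4, 8, 12) == pytest.approx(
            (8 ** 3 - 4 ** 3) / (12 ** 3 - 4 ** 3))
        # deep well -> occupancy 1
        assert two_state_occupancy_theory(30, 4, 8, 12) == pytest.approx(1.0, abs=1e-6)

    def test_planted_blobs_weights(self, rng):
        pos, labels = planted_blobs([[0, 0, 0], [30, 0, 0]], [0.7, 0.3],
                                    sigma=1.0, n=20_000, seed=4)
        frac = np.bincount(labels) / 20_000
        assert frac[0] == pytest.approx(0.7, abs=0.02)
        assert pos.shape == (20_000, 3)
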