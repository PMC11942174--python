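"""Pocket-aligned superposition, fragment mobility, and contact analysis."""

import math

import numpy as np
import pytest

from katpscreenlab.pocket import (
    Topology,
    TrajectoryEnsemble,
    aggregate_contacts,
    align_ensemble,
    contact_fractions,
    frequency_report,
    group_com_trace,
    kabsch_superpose,
)
from katpscreenlab.synthetic import TrajectorySpec, gen_trajectory

from oracles import brute_force_contact_fractions, horn_superpose


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


class TestKabsch:
    def test_identity_on_equal_sets(self):
        pts = np.random.default_rng(0).normal(size=(6, 3))
        R, t, rmsd = kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-12)

    def test_recovers_rigid_transform(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(size=(10, 3))
        R0 = random_rotation(rng)
        mobile = ref @ R0.T + np.array([3.0, -2.0, 7.0])
        _, _, rmsd = kabsch_superpose(mobile, ref)
        assert rmsd < 1e-8

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_quaternion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mobile = rng.normal(size=(5, 3))
        ref = rng.normal(size=(5, 3))
        _, _, rmsd = kabsch_superpose(mobile, ref)
        _, _, rmsd_q = horn_superpose(mobile, ref)
        assert rmsd == pytest.approx(rmsd_q, abs=1e-9)

    def test_proper_rotation_even_for_reflected_input(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(size=(8, 3))
        mobile = ref * np.array([1.0, 1.0, -1.0])  # mirror image
        R, _, _ = kabsch_superpose(mobile, ref)
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_collinear_selection_rejected(self):
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="collinear|degenerate"):
            kabsch_superpose(line, line + 1.0)


@pytest.fixture(scope="module")
def drift_fixture():
    spec = TrajectorySpec(
        n_runs=3, n_frames=15,
        fragment_sigmas={k: 0.0 for k in "abcde"},
        global_drift=2.0, seed=10,
    )
    return gen_trajectory(spec)


class TestAlignEnsemble:
    def test_pure_drift_realigns_to_frame_zero(self, drift_fixture):
        topo, ens, _, _ = drift_fixture
        aligned = align_ensemble(ens, topo, "pocket_ca")
        for run in aligned.runs:
            assert np.abs(run - run[0]).max() < 1e-6

    def test_already_aligned_unchanged(self, drift_fixture):
        topo, ens, _, _ = drift_fixture
        aligned = align_ensemble(ens, topo, "pocket_ca")
        again = align_ensemble(aligned, topo, "pocket_ca")
        for a, b in zip(aligned.runs, again.runs):
            np.testing.assert_allclose(a, b, atol=1e-9)

    def test_jitter_fixture_pocket_rmsd_tracks_sigma(self):
        # pocket CAs never jitter, so post-alignment ligand spread ~ sigma
        spec = TrajectorySpec(
            n_runs=1, n_frames=400,
            fragment_sigmas={"a": 0.5, "b": 0, "c": 0, "d": 0, "e": 0},
            seed=11,
        )
        topo, ens, frags, _ = gen_trajectory(spec)
        aligned = align_ensemble(ens, topo, "pocket_ca")
        mob = group_com_trace(aligned, topo, frags)
        assert mob.sd_pooled["a"] == pytest.approx(math.sqrt(3) * 0.5, rel=0.15)


class TestMobility:
    def test_rigid_fixture_all_sds_zero(self, drift_fixture):
        topo, ens, frags, _ = drift_fixture
        aligned = align_ensemble(ens, topo, "pocket_ca")
        mob = group_com_trace(aligned, topo, frags)
        assert float(mob.sd_per_run.to_numpy().max()) < 1e-6

    def test_single_frame_run_sd_zero(self):
        spec = TrajectorySpec(n_runs=1, n_frames=1, seed=0)
        topo, ens, frags, _ = gen_trajectory(spec)
        mob = group_com_trace(ens, topo, frags)
        assert (mob.sd_per_run == 0).all().all()

    def test_planted_sigma_ordering_every_run(self):
        spec = TrajectorySpec(
            n_runs=5, n_frames=300,
            fragment_sigmas={"a": 0.2, "b": 0, "c": 0, "d": 0, "e": 2.0},
            seed=12,
        )
        topo, ens, frags, _ = gen_trajectory(spec)
        aligned = align_ensemble(ens, topo, "pocket_ca")
        mob = group_com_trace(aligned, topo, frags)
        assert (mob.sd_per_run.loc["e"] > mob.sd_per_run.loc["a"]).all()
        assert mob.sd_pooled["e"] == pytest.approx(math.sqrt(3) * 2.0, rel=0.15)
        assert mob.sd_pooled["a"] == pytest.approx(math.sqrt(3) * 0.2, rel=0.15)

    def test_hydrogen_only_group_rejected(self):
        spec = TrajectorySpec(n_runs=1, n_frames=2, seed=0)
        topo, ens, frags, _ = gen_trajectory(spec)
        h_ids = [int(a) for a, e in zip(topo.atom_ids, topo.elements) if e == "H"]
        with pytest.raises(ValueError, match="hydrogens"):
            group_com_trace(ens, topo, {"h_only": h_ids})

    def test_mobility_invariant_under_global_rigid_motion(self):
        spec = TrajectorySpec(
            n_runs=2, n_frames=60,
            fragment_sigmas={"a": 0.3, "b": 0, "c": 0, "d": 0, "e": 1.0},
            seed=13,
        )
        topo, ens, frags, _ = gen_trajectory(spec)
        rng = np.random.default_rng(99)
        moved_runs = []
        for run in ens.runs:
            out = run.copy()
            for f in range(run.shape[0]):
                R = random_rotation(rng)
                out[f] = run[f] @ R.T + rng.uniform(-20, 20, size=3)
            moved_runs.append(out)
        moved = TrajectoryEnsemble(moved_runs)
        sd0 = group_com_trace(align_ensemble(ens, topo, "pocket_ca"), topo, frags)
        sd1 = group_com_trace(align_ensemble(moved, topo, "pocket_ca"), topo, frags)
        np.testing.assert_allclose(
            sd0.sd_per_run.to_numpy(), sd1.sd_per_run.to_numpy(), atol=1e-8
        )


def tiny_topology(positions, elements, residue_ids, ligand_ids):
    n = len(positions)
    return Topology(
        atom_ids=np.arange(1, n + 1),
        elements=np.array(elements, dtype=object),
        residue_ids=np.array(residue_ids),
        residue_names=np.array(["X"] * n, dtype=object),
        chain_ids=np.array(["A"] * n, dtype=object),
        selections={"ligand": ligand_ids},
    )


class TestContactFractions:
    def test_fixed_distance_inside_and_outside_cutoff(self):
        # residue 1 atom at 3.0 Å from the ligand atom, residue 2 at 3.6 Å
        pos = np.array([[0.0, 0, 0], [3.0, 0, 0], [3.6, 0, 0]])
        topo = tiny_topology(pos, ["C", "C", "C"], [9, 1, 2], [1])
        ens = TrajectoryEnsemble([np.repeat(pos[None], 4, axis=0)])
        rep = contact_fractions(ens, topo, "ligand", cutoff=3.5)
        assert rep.fractions.loc[1, 0] == 1.0
        assert rep.fractions.loc[2, 0] == 0.0

    def test_hydrogens_excluded(self):
        # only a hydrogen is within the cutoff -> no contact
        pos = np.array([[0.0, 0, 0], [2.0, 0, 0], [6.0, 0, 0]])
        topo = tiny_topology(pos, ["C", "H", "C"], [9, 1, 1], [1])
        ens = TrajectoryEnsemble([pos[None]])
        rep = contact_fractions(ens, topo, "ligand", cutoff=3.5)
        assert rep.fractions.loc[1, 0] == 0.0

    def test_planted_occupancy_exact(self):
        spec = TrajectorySpec(
            n_runs=2, n_frames=100,
            contact_plan={(1, 0): 0.30, (4, 1): 0.75},
            seed=14,
        )
        topo, ens, frags, truth = gen_trajectory(spec)
        rep = contact_fractions(ens, topo, "ligand", frags)
        assert rep.fractions.loc[1, 0] == pytest.approx(0.30, abs=1e-12)
        assert rep.fractions.loc[4, 1] == pytest.approx(0.75, abs=1e-12)
        assert rep.fractions.loc[1, 1] == 0.0  # unplanted run stays out

    def test_occupancy_one_every_frame(self):
        spec = TrajectorySpec(n_runs=1, n_frames=25, contact_plan={(2, 0): 1.0}, seed=1)
        topo, ens, _, _ = gen_trajectory(spec)
        rep = contact_fractions(ens, topo, "ligand")
        assert rep.fractions.loc[2, 0] == 1.0

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_all_pairs_oracle_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        n_atoms = int(rng.integers(10, 51))
        n_lig = int(rng.integers(2, 6))
        n_frames = int(rng.integers(2, 8))
        residue_ids = np.concatenate(
            [[999] * n_lig, rng.integers(1, 8, size=n_atoms - n_lig)]
        )
        elements = rng.choice(["C", "N", "O", "H"], size=n_atoms).tolist()
        elements[:n_lig] = ["C"] * n_lig
        topo = tiny_topology(
            rng.normal(scale=4.0, size=(n_atoms, 3)),
            elements,
            residue_ids,
            list(range(1, n_lig + 1)),
        )
        run = rng.normal(scale=4.0, size=(n_frames, n_atoms, 3))
        ens = TrajectoryEnsemble([run])
        rep = contact_fractions(ens, topo, "ligand", cutoff=3.5)
        heavy = [e != "H" for e in elements]
        want = brute_force_contact_fractions(
            run, residue_ids, heavy, list(range(n_lig)), 3.5
        )
        got = {int(r): rep.fractions.loc[r, 0] for r in rep.fractions.index}
        assert got == want

    def test_monotone_in_cutoff(self):
        spec = TrajectorySpec(
            n_runs=1, n_frames=40,
            fragment_sigmas={"a": 1.0, "b": 0, "c": 0, "d": 0, "e": 3.0},
            contact_plan={(3, 0): 0.5},
            seed=15,
        )
        topo, ens, _, _ = gen_trajectory(spec)
        f1 = contact_fractions(ens, topo, "ligand", cutoff=3.5).fractions
        f2 = contact_fractions(ens, topo, "ligand", cutoff=5.0).fractions
        assert (f2.to_numpy() >= f1.to_numpy()).all()

    def test_empty_ligand_selection_rejected(self):
        pos = np.array([[0.0, 0, 0], [3.0, 0, 0], [4.0, 0, 0]])
        topo = tiny_topology(pos, ["H", "C", "C"], [9, 1, 2], [1])
        ens = TrajectoryEnsemble([pos[None]])
        with pytest.raises(ValueError, match="ligand"):
            contact_fractions(ens, topo, "ligand")


def report_from_fractions(per_run: dict[int, list[float]]):
    import pandas as pd

    from katpscreenlab.pocket import ContactReport

    df = pd.DataFrame(per_run).T
    return ContactReport(df, {}, [100] * df.shape[1], 3.5)


class TestAggregateContacts:
    def test_three_of_five_at_threshold_retained(self):
        rep = report_from_fractions({42: [0.35, 0.31, 0.30, 0.10, 0.00]})
        assert aggregate_contacts(rep) == {42}

    def test_below_threshold_everywhere_not_retained(self):
        rep = report_from_fractions({42: [0.29] * 5})
        assert aggregate_contacts(rep) == set()

    def test_inclusive_boundary(self):
        rep = report_from_fractions({7: [0.30, 0.30, 0.30, 0.0, 0.0]})
        assert aggregate_contacts(rep) == {7}

    def test_quorum_exceeding_runs_rejected(self):
        rep = report_from_fractions({7: [0.5, 0.5]})
        with pytest.raises(ValueError, match="quorum"):
            aggregate_contacts(rep, run_quorum=3)

    def test_quorum_generalizes_to_other_run_counts(self):
        # ceil(3/5 * 3) = 2 of 3 runs
        rep = report_from_fractions({7: [0.4, 0.4, 0.0], 8: [0.4, 0.0, 0.0]})
        assert aggregate_contacts(rep) == {7}

    def test_planted_retained_set_recovered(self):
        plan = {(1, 0): 0.5, (1, 1): 0.4, (1, 2): 0.35,   # 3 runs >= 0.3 -> in
                (2, 0): 0.5, (2, 1): 0.5,                 # only 2 runs -> out
                (3, 0): 0.2, (3, 1): 0.2, (3, 2): 0.2}    # below threshold -> out
        spec = TrajectorySpec(n_runs=5, n_frames=40, contact_plan=plan, seed=16)
        topo, ens, _, _ = gen_trajectory(spec)
        rep = contact_fractions(ens, topo, "ligand")
        assert aggregate_contacts(rep) == {1}


class TestFrequencyReport:
    def test_strictly_over_threshold(self):
        rep = report_from_fractions({1: [0.41] * 5, 2: [0.40] * 5})
        table = frequency_report(rep, 0.40)
        assert list(table.index) == [1]

    def test_empty_report_gives_empty_table(self):
        rep = report_from_fractions({1: [0.1] * 5})
        assert frequency_report(rep).empty

    def test_group_columns_reported_for_kept_rows(self):
        spec = TrajectorySpec(
            n_runs=2, n_frames=50, contact_plan={(5, 0): 0.9, (5, 1): 0.8}, seed=17
        )
        topo, ens, frags, _ = gen_trajectory(spec)
        rep = contact_fractions(ens, topo, "ligand", frags)
        table = frequency_report(rep, 0.40)
        assert 5 in table.index
        assert set("abcde") <= set(table.columns)
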