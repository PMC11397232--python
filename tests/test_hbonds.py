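import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mipscreen.hbonds import (
    brute_force_reference_events,
    detect_frame_hbonds,
    detect_trajectory_hbonds,
    minimum_image_distance,
)
from mipscreen.selection import AngleConvention, HBondCriteria, MoleculeRole
from mipscreen.trajectory import Frame, Trajectory

from conftest import make_bipartite_system, place_simple_frame, random_bipartite_frame


class TestMinimumImage:
    def test_wraps_across_the_boundary(self):
        d = minimum_image_distance(
            np.array([0.1, 0.0, 0.0]), np.array([2.95, 0.0, 0.0]), np.full(3, 3.0)
        )
        assert d == pytest.approx(0.15)

    def test_identical_points_give_zero(self):
        a = np.array([1.2, 0.7, 2.9])
        assert minimum_image_distance(a, a, np.full(3, 3.0)) == 0.0

    def test_matches_27_image_enumeration(self):
        rng = np.random.default_rng(7)
        box = np.array([3.0, 2.0, 4.0])
        shifts = [
            np.array(s) * box for s in itertools.product((-1, 0, 1), repeat=3)
        ]
        for _ in range(1000):
            a = rng.random(3) * box
            b = rng.random(3) * box
            expected = min(float(np.linalg.norm(a - (b + s))) for s in shifts)
            assert float(minimum_image_distance(a, b, box)) == pytest.approx(
                expected, abs=1e-12
            )


class TestFrameDetection:
    def test_collinear_geometry_is_one_event(self, simple_selection):
        frame = place_simple_frame(acceptor_xyz=(0.29, 0.0, 0.0))
        events = detect_frame_hbonds(frame, simple_selection)
        assert len(events) == 1
        ev = events[0]
        assert ev.d_DA == pytest.approx(0.29)
        assert ev.angle == pytest.approx(0.0, abs=1e-6)
        assert (ev.donor.atom_index, ev.hydrogen, ev.acceptor.atom_index) == (0, 1, 3)

    def test_beyond_distance_cutoff_is_no_event(self, simple_selection):
        frame = place_simple_frame(acceptor_xyz=(0.36, 0.0, 0.0))
        assert detect_frame_hbonds(frame, simple_selection) == []

    def test_exactly_at_cutoff_is_included(self, simple_selection):
        frame = place_simple_frame(acceptor_xyz=(0.35, 0.0, 0.0))
        events = detect_frame_hbonds(frame, simple_selection)
        assert len(events) == 1
        assert events[0].d_DA == pytest.approx(0.35)

    def test_beyond_angle_cutoff_is_no_event(self, simple_selection):
        # acceptor at 40 deg off the D->H axis, d_DA = 0.30 nm
        ang = np.radians(40.0)
        frame = place_simple_frame(
            acceptor_xyz=(0.30 * np.cos(ang), 0.30 * np.sin(ang), 0.0)
        )
        assert detect_frame_hbonds(frame, simple_selection) == []

    def test_angle_conventions_can_disagree(self, simple_selection):
        # HDA angle 21.8 deg (pass) but DHA deviation 31 deg (fail)
        frame = place_simple_frame(acceptor_xyz=(0.30, 0.12, 0.0))
        assert len(detect_frame_hbonds(frame, simple_selection)) == 1
        dha_sel = simple_selection.with_criteria(
            HBondCriteria(angle_convention=AngleConvention.DHA_DEVIATION)
        )
        assert detect_frame_hbonds(frame, dha_sel) == []

    def test_two_hydrogens_give_two_events_to_one_acceptor(self):
        from mipscreen.selection import (
            AtomSite,
            MoleculeGroup,
            SiteRole,
            SystemSelection,
        )

        mols = [
            MoleculeGroup(0, MoleculeRole.TEMPLATE, "T", (0, 1, 2)),
            MoleculeGroup(1, MoleculeRole.MONOMER, "M", (3,)),
        ]
        sites = [
            AtomSite(0, "N", SiteRole.DONOR, 0, (1, 2)),
            AtomSite(3, "O", SiteRole.ACCEPTOR, 1),
        ]
        sel = SystemSelection(mols, sites, n_atoms=4)
        coords = np.array(
            [
                [0.0, 0.0, 0.0],
                [0.10, 0.02, 0.0],
                [0.10, -0.02, 0.0],
                [0.30, 0.0, 0.0],
            ]
        )
        events = detect_frame_hbonds(Frame(coords, np.full(3, 3.0)), sel)
        assert len(events) == 2
        assert {e.hydrogen for e in events} == {1, 2}

    def test_intramolecular_pairs_excluded_by_default(self, simple_selection):
        # move the template's own acceptor next to its donor
        frame = place_simple_frame(acceptor_xyz=(2.0, 2.0, 2.0))
        frame.coords[2] = (0.29, 0.0, 0.0)
        assert detect_frame_hbonds(frame, simple_selection) == []
        events = detect_frame_hbonds(
            frame, simple_selection, exclude_intramolecular=False
        )
        assert len(events) == 1
        assert events[0].donor_molecule == events[0].acceptor_molecule == 0


class TestSearchEquivalence:
    def test_cell_list_equals_brute_force_and_oracle(self):
        system = make_bipartite_system(30, 30)
        rng = np.random.default_rng(11)
        for f in range(25):
            frame = random_bipartite_frame(system, rng)
            cell = detect_frame_hbonds(frame, system["selection"], f, method="cell")
            brute = detect_frame_hbonds(frame, system["selection"], f, method="brute")
            oracle = brute_force_reference_events(frame, system["selection"], f)
            assert [e.key for e in cell] == [e.key for e in brute]
            assert {e.key for e in brute} == {e.key for e in oracle}

    def test_small_box_falls_back_to_brute_force(self):
        system = make_bipartite_system(5, 5)
        rng = np.random.default_rng(2)
        frame = random_bipartite_frame(system, rng, box_edge=0.9)  # < 3 * d_max
        cell = detect_frame_hbonds(frame, system["selection"], method="cell")
        brute = detect_frame_hbonds(frame, system["selection"], method="brute")
        assert [e.key for e in cell] == [e.key for e in brute]

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(
        shift=st.tuples(
            *(st.floats(-10, 10, allow_nan=False) for _ in range(3))
        ),
        seed=st.integers(0, 100),
    )
    def test_translation_invariance_mod_box(self, shift, seed):
        system = make_bipartite_system(10, 10)
        rng = np.random.default_rng(seed)
        frame = random_bipartite_frame(system, rng)
        base = detect_frame_hbonds(frame, system["selection"])
        moved = Frame(frame.coords + np.array(shift), frame.box)
        shifted = detect_frame_hbonds(moved, system["selection"])
        assert [e.key for e in base] == [e.key for e in shifted]

    def test_event_count_monotone_in_cutoffs(self):
        system = make_bipartite_system(40, 40)
        rng = np.random.default_rng(5)
        frame = random_bipartite_frame(system, rng)
        counts_d = []
        for d_max in (0.2, 0.3, 0.4, 0.6):
            sel = system["selection"].with_criteria(HBondCriteria(d_max=d_max))
            counts_d.append(len(detect_frame_hbonds(frame, sel)))
        assert counts_d == sorted(counts_d)
        counts_a = []
        for angle_max in (10.0, 30.0, 60.0, 180.0):
            sel = system["selection"].with_criteria(
                HBondCriteria(angle_max=angle_max)
            )
            counts_a.append(len(detect_frame_hbonds(frame, sel)))
        assert counts_a == sorted(counts_a)


class TestTrajectoryDetection:
    def scripted_trajectory(self, simple_selection, bonded_frames):
        frames = []
        for f in range(30):
            if f in bonded_frames:
                frame = place_simple_frame(acceptor_xyz=(0.29, 0.0, 0.0))
            else:
                frame = place_simple_frame(acceptor_xyz=(1.5, 1.5, 1.5))
            frame.time = float(f)
            frames.append(frame)
        return Trajectory.from_frames(frames)

    def test_scripted_bond_appears_in_exactly_those_frames(self, simple_selection):
        traj = self.scripted_trajectory(simple_selection, set(range(10, 20)))
        per_frame = list(
            detect_trajectory_hbonds(
                traj,
                simple_selection,
                pair_filter=(MoleculeRole.TEMPLATE, MoleculeRole.MONOMER),
            )
        )
        assert sum(len(f) for f in per_frame) == 10
        assert [f for f, evs in enumerate(per_frame) if evs] == list(range(10, 20))

    def test_all_monomers_far_from_template_gives_empty_stream(
        self, simple_selection
    ):
        traj = self.scripted_trajectory(simple_selection, set())
        per_frame = list(detect_trajectory_hbonds(traj, simple_selection))
        assert all(evs == [] for evs in per_frame)

    def test_chunked_path_matches_per_frame_detection(self):
        system = make_bipartite_system(15, 15)
        rng = np.random.default_rng(9)
        frames = []
        for f in range(23):
            frame = random_bipartite_frame(system, rng)
            frame.time = float(f)
            frames.append(frame)
        traj = Trajectory.from_frames(frames)
        chunked = list(
            detect_trajectory_hbonds(traj, system["selection"], chunk_frames=7)
        )
        for f, frame in enumerate(frames):
            direct = detect_frame_hbonds(frame, system["selection"], f)
            assert [e.key for e in chunked[f]] == [e.key for e in direct]
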