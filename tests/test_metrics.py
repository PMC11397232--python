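import numpy as np
import pytest

from mipscreen.hbonds import HBondEvent
from mipscreen.metrics import (
    MonomerScorecard,
    binding_series,
    effective_binding_number,
    lifetimes,
    lifetimes_from_events,
    max_hbond_number,
    occupancy,
    rank_monomers,
    scorecard,
)
from mipscreen.selection import (
    AtomSite,
    HBondCriteria,
    MoleculeGroup,
    MoleculeRole,
    SiteRole,
    SystemSelection,
)
from mipscreen.synthetic import telegraph_series
from mipscreen.trajectory import Frame, Trajectory


@pytest.fixture
def two_monomer_selection():
    """Template (donor N-H + 2 acceptor O) with two acid monomers."""
    mols = [
        MoleculeGroup(0, MoleculeRole.TEMPLATE, "SDM", (0, 1, 2, 3)),
        MoleculeGroup(1, MoleculeRole.MONOMER, "AA", (4, 5, 6)),
        MoleculeGroup(2, MoleculeRole.MONOMER, "AA", (7, 8, 9)),
    ]
    sites = [
        AtomSite(0, "N", SiteRole.DONOR, 0, (1,), site_label="N-H"),
        AtomSite(2, "O", SiteRole.ACCEPTOR, 0, site_label="S=O"),
        AtomSite(3, "N", SiteRole.ACCEPTOR, 0, site_label="pyrimidine para-N"),
        AtomSite(4, "O", SiteRole.ACCEPTOR, 1, site_label="C=O"),
        AtomSite(5, "O", SiteRole.DONOR, 1, (6,), site_label="O-H"),
        AtomSite(7, "O", SiteRole.ACCEPTOR, 2, site_label="C=O"),
        AtomSite(8, "O", SiteRole.DONOR, 2, (9,), site_label="O-H"),
    ]
    return SystemSelection(mols, sites, HBondCriteria(), n_atoms=10)


def event(sel, frame, donor_atom, hydrogen, acceptor_atom):
    donor = next(
        s for s in sel.sites
        if s.atom_index == donor_atom and s.role is SiteRole.DONOR
    )
    acceptor = next(
        s for s in sel.sites
        if s.atom_index == acceptor_atom and s.role is SiteRole.ACCEPTOR
    )
    return HBondEvent(frame, donor, hydrogen, acceptor, 0.29, 5.0)


class TestBindingSeries:
    def test_no_events_gives_all_empty_series(self, two_monomer_selection):
        series = binding_series([], 5, two_monomer_selection)
        assert all(s == set() for s in series.bound_sets)
        assert effective_binding_number(series) == (0, 1.0)
        assert max_hbond_number(series) == 0

    def test_double_hydrogen_bond_has_multiplicity_two(self, two_monomer_selection):
        sel = two_monomer_selection
        # monomer 1 bound via template N-H...C=O and its O-H...pyrimidine N
        events = [event(sel, 0, 0, 1, 4), event(sel, 0, 5, 6, 3)]
        series = binding_series(events, 1, sel)
        assert series.multiplicities[0] == {1: 2}
        assert series.bound_sets[0] == {1}

    def test_double_plus_single_is_three_bonds_two_monomers(
        self, two_monomer_selection
    ):
        sel = two_monomer_selection
        events = [
            event(sel, 7, 0, 1, 4),  # template donor -> monomer 1 carbonyl
            event(sel, 7, 5, 6, 3),  # monomer 1 hydroxyl -> template N
            event(sel, 7, 8, 9, 2),  # monomer 2 hydroxyl -> template S=O
        ]
        series = binding_series(events, 10, sel)
        assert series.bound_sets[7] == {1, 2}
        assert series.multiplicities[7] == {1: 2, 2: 1}
        assert effective_binding_number(series) == (2, pytest.approx(0.1))
        assert max_hbond_number(series) == 3

    def test_monomer_monomer_events_are_ignored(self, two_monomer_selection):
        sel = two_monomer_selection
        series = binding_series([event(sel, 0, 5, 6, 7)], 3, sel)
        assert all(s == set() for s in series.bound_sets)

    def test_frame_index_beyond_series_is_an_error(self, two_monomer_selection):
        sel = two_monomer_selection
        with pytest.raises(ValueError, match="n_frames"):
            binding_series([event(sel, 9, 0, 1, 4)], 5, sel)


class TestOccupancy:
    def test_bond_every_frame_has_occupancy_one(self, two_monomer_selection):
        sel = two_monomer_selection
        events = [event(sel, f, 0, 1, 4) for f in range(50)]
        table = occupancy(events, 50, sel)
        assert table.loc[0, "group"] == "monomer-template"
        assert table.loc[0, "avg_bonds_per_frame"] == pytest.approx(1.0)
        assert table.loc[0, "frac_frames_bonded"] == pytest.approx(1.0)

    def test_partial_presence_counts_fraction(self, two_monomer_selection):
        sel = two_monomer_selection
        events = [event(sel, f, 0, 1, 4) for f in range(8000)]
        table = occupancy(events, 20000, sel)
        assert table.loc[0, "avg_bonds_per_frame"] == pytest.approx(0.4)

    def test_site_pair_occupancies_sum_to_role_pair_total(
        self, two_monomer_selection
    ):
        sel = two_monomer_selection
        rng = np.random.default_rng(4)
        events = []
        for f in range(200):
            if rng.random() < 0.5:
                events.append(event(sel, f, 0, 1, 4))
            if rng.random() < 0.3:
                events.append(event(sel, f, 5, 6, 3))
        by_site = occupancy(events, 200, sel, grouping="site-pair")
        by_role = occupancy(events, 200, sel, grouping="role-pair")
        assert by_site["avg_bonds_per_frame"].sum() == pytest.approx(
            by_role["avg_bonds_per_frame"].sum()
        )


class TestLifetimes:
    def test_single_uninterrupted_run(self):
        x = np.zeros(500, dtype=bool)
        x[0:100] = True
        res = lifetimes(x, dt=1.0, mode="continuous")
        assert res.mean_lifetime_ps == pytest.approx(100.0)
        assert res.n_episodes == 1

    def test_never_bonded_is_missing_not_zero(self):
        res = lifetimes(np.zeros(100, dtype=bool), dt=1.0)
        assert res.mean_lifetime_ps is None
        assert res.n_episodes == 0

    def test_gap_tolerance_merges_short_gaps(self):
        x = np.zeros(50, dtype=bool)
        x[0:10] = True
        x[11:20] = True  # 1-frame gap
        assert lifetimes(x, 1.0).n_episodes == 2
        merged = lifetimes(x, 1.0, gap_tolerance=1)
        assert merged.n_episodes == 1
        assert merged.mean_lifetime_ps == pytest.approx(20.0)

    def test_telegraph_mean_dwell_matches_inverse_off_rate(self):
        mats = [
            telegraph_series(0.01, 0.02, 20_000, dt=1.0, seed=s).states
            for s in range(10)
        ]
        res = lifetimes(np.stack(mats), dt=1.0, mode="continuous")
        assert res.mean_lifetime_ps == pytest.approx(50.0, rel=0.10)

    def test_intermittent_integral_on_block_signal(self):
        # single block of length L in a long series: C(t) ~ (L-t)/L,
        # so the integral is ~L/2
        n, L = 10_000, 100
        x = np.zeros(n, dtype=bool)
        x[200 : 200 + L] = True
        res = lifetimes(x, dt=1.0, mode="intermittent")
        assert res.mean_lifetime_ps == pytest.approx(L / 2, rel=0.05)

    def test_events_route_matches_indicator_route(self, two_monomer_selection):
        sel = two_monomer_selection
        events = [event(sel, f, 0, 1, 4) for f in (0, 1, 2, 7, 8)]
        res = lifetimes_from_events(events, 20, dt=2.0)
        assert res.mean_lifetime_ps == pytest.approx(2.0 * 2.5)
        assert res.n_episodes == 2


class TestScorecardAndRanking:
    def card(self, name, ebn, hbn, occ=0.0):
        return MonomerScorecard(
            monomer_name=name,
            ebn=ebn,
            hbn_max=hbn,
            frames_at_ebn=0.1,
            occupancy_site_pairs={},
            occupancy_role_pairs={"monomer-template": occ},
            mean_lifetime_ps={},
        )

    def test_hbn_breaks_equal_ebn(self):
        ranked = rank_monomers([self.card("EHMA", 2, 2), self.card("TFMAA", 2, 3)])
        assert [c.monomer_name for c in ranked] == ["TFMAA", "EHMA"]

    def test_higher_ebn_wins(self):
        ranked = rank_monomers([self.card("A", 1, 1), self.card("B", 2, 2)])
        assert ranked[0].monomer_name == "B"

    def test_occupancy_breaks_full_score_tie(self):
        ranked = rank_monomers(
            [self.card("X", 2, 3, occ=0.1), self.card("Y", 2, 3, occ=0.4)]
        )
        assert ranked[0].monomer_name == "Y"

    def test_identical_scorecards_keep_input_order(self):
        a, b = self.card("first", 2, 3, 0.2), self.card("second", 2, 3, 0.2)
        assert [c.monomer_name for c in rank_monomers([a, b])] == ["first", "second"]

    def test_ebn_cannot_exceed_hbn_max(self):
        with pytest.raises(ValueError):
            self.card("bad", 3, 2)

    def test_monomer_free_system_has_empty_scorecard(self):
        mols = [MoleculeGroup(0, MoleculeRole.TEMPLATE, "SDM", (0, 1))]
        sites = [AtomSite(0, "N", SiteRole.DONOR, 0, (1,))]
        sel = SystemSelection(mols, sites, n_atoms=2)
        frames = [
            Frame(np.full((2, 3), 1.0) + 0.01 * f, np.full(3, 3.0), time=float(f))
            for f in range(3)
        ]
        card = scorecard(Trajectory.from_frames(frames), sel)
        assert (card.ebn, card.hbn_max) == (0, 0)
        assert card.occupancy_site_pairs == {}
        assert card.mean_lifetime_ps == {}

    def test_scorecard_round_trips_through_json(self):
        card = MonomerScorecard(
            monomer_name="AA",
            ebn=2,
            hbn_max=3,
            frames_at_ebn=0.25,
            occupancy_site_pairs={("N-H", "C=O"): 0.5},
            occupancy_role_pairs={"monomer-template": 0.9},
            mean_lifetime_ps={"monomer-template": 12.5},
            ratio="10:1",
            n_frames=100,
        )
        import json

        again = MonomerScorecard.from_dict(json.loads(card.to_json()))
        assert again == card
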