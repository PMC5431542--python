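import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kinpocket import (
    InteractionCriteria,
    ScalarSeries,
    contact_count,
    find_halogen_bonds,
    find_hbonds,
    mean_contacts,
    saltbridge_occupancy,
)
from kinpocket.io import FrameSeries
from conftest import make_topology, selection
from oracles import (
    brute_contact_count,
    brute_hbond_pairs,
    brute_xbond_pairs,
    random_molecular_frame,
)


def test_criteria_validation():
    with pytest.raises(ValueError):
        InteractionCriteria(hbond_da_cut=-1.0)
    with pytest.raises(ValueError):
        InteractionCriteria(hbond_angle_cut=200.0)


def _dha_frame(da_dist, dha_angle_deg):
    """Donor O at origin with one H; acceptor placed at the given geometry."""
    d = np.array([0.0, 0.0, 0.0])
    h = np.array([0.96, 0.0, 0.0])
    theta = np.deg2rad(180.0 - dha_angle_deg)  # angle at H between D and A
    direction = np.array([np.cos(theta), np.sin(theta), 0.0])
    ha = None
    # place A so that |D-A| = da_dist along the chosen H-ray
    # solve |h + t*direction| = da_dist for t > 0
    b = 2 * np.dot(h, direction)
    c = np.dot(h, h) - da_dist ** 2
    t = (-b + np.sqrt(b * b - 4 * c)) / 2
    a = h + t * direction
    coords = np.vstack([d, h, a])
    top = make_topology(["O", "H", "O"], res_ids=[1, 1, 2])
    return coords, top


@pytest.mark.parametrize("dist,angle,expected", [
    (2.8, 160.0, 1),   # inside both cutoffs
    (3.2, 170.0, 0),   # distance fails
    (2.5, 100.0, 0),   # angle fails
])
def test_hbond_criteria(dist, angle, expected):
    coords, top = _dha_frame(dist, angle)
    records = find_hbonds(coords, top, selection([0]), selection([2]))
    assert len(records) == expected
    if expected:
        rec = records[0]
        assert rec.distance == pytest.approx(dist, abs=1e-9)
        assert rec.angle == pytest.approx(angle, abs=1e-6)
        assert rec.hydrogen_index == 1


def test_hbond_distance_boundary_is_strict():
    # D-A exactly at the cutoff: "less than 3.0 A" excludes it.
    coords = np.array([[0.0, 0, 0], [0.96, 0, 0], [3.0, 0, 0]])
    top = make_topology(["O", "H", "O"], res_ids=[1, 1, 2])
    assert find_hbonds(coords, top, selection([0]), selection([2])) == []


def test_hbond_distance_only_mode_without_hydrogens():
    coords = np.array([[0.0, 0, 0], [2.8, 0, 0]])
    top = make_topology(["O", "O"], res_ids=[1, 2])
    records = find_hbonds(coords, top, selection([0]), selection([1]))
    assert len(records) == 1
    assert records[0].angle is None and records[0].hydrogen_index is None


def test_hbond_donor_without_hydrogen_is_skipped(caplog):
    # Topology has hydrogens, but this donor has none bonded.
    coords = np.array([[0.0, 0, 0], [2.8, 0, 0], [9.0, 9, 9]])
    top = make_topology(["O", "O", "H"], res_ids=[1, 2, 3])
    with caplog.at_level("WARNING"):
        records = find_hbonds(coords, top, selection([0]), selection([1]))
    assert records == []
    assert any("no bonded" in r.message for r in caplog.records)


def test_hbond_multiple_hydrogens_deduplicated_best_angle():
    d = np.array([0.0, 0.0, 0.0])
    h1 = np.array([0.96, 0.0, 0.0])       # nearly linear toward A
    h2 = np.array([0.0, 0.96, 0.0])       # ~90 degrees, still > 120 fails
    a = np.array([2.8, 0.0, 0.0])
    coords = np.vstack([d, h1, h2, a])
    top = make_topology(["N", "H", "H", "O"], res_ids=[1, 1, 1, 2])
    records = find_hbonds(coords, top, selection([0]), selection([3]))
    assert len(records) == 1
    assert records[0].hydrogen_index == 1
    assert records[0].angle == pytest.approx(180.0, abs=1e-6)


@settings(max_examples=40, deadline=None)
@given(st.integers(0, 2 ** 31 - 1))
def test_hbonds_match_brute_force(seed):
    rng = np.random.default_rng(seed)
    coords, elements = random_molecular_frame(rng, n_atoms=30)
    top = make_topology(elements)
    all_sel = selection(range(30))
    records = find_hbonds(coords, top, all_sel, all_sel, warn_missing_h=False)
    got = {(r.donor_index, r.acceptor_index) for r in records}
    expected = brute_hbond_pairs(coords, elements, range(30), range(30))
    assert got == expected


@pytest.mark.parametrize("fo_dist,cfo_angle,expected", [
    (3.0, 180.0, 1),   # ideal sigma-hole geometry
    (3.0, 90.0, 0),    # angle fails
    (4.0, 180.0, 0),   # distance fails
])
def test_halogen_bond_criteria(fo_dist, cfo_angle, expected):
    c = np.array([0.0, 0.0, 0.0])
    f = np.array([1.35, 0.0, 0.0])
    theta = np.deg2rad(180.0 - cfo_angle)
    a = f + fo_dist * np.array([np.cos(theta), np.sin(theta), 0.0])
    coords = np.vstack([c, f, a])
    top = make_topology(["C", "F", "O"], res_ids=[1, 1, 2])
    records = find_halogen_bonds(coords, top, selection([1]), selection([2]))
    assert len(records) == expected
    if expected:
        assert records[0].distance == pytest.approx(fo_dist, abs=1e-9)


@settings(max_examples=40, deadline=None)
@given(st.integers(0, 2 ** 31 - 1))
def test_halogen_bonds_match_brute_force(seed):
    rng = np.random.default_rng(seed)
    coords, elements = random_molecular_frame(rng, n_atoms=30)
    top = make_topology(elements)
    all_sel = selection(range(30))
    records = find_halogen_bonds(coords, top, all_sel, all_sel)
    got = {(r.donor_index, r.acceptor_index) for r in records}
    expected = brute_xbond_pairs(coords, elements, range(30), range(30))
    assert got == expected


class TestContacts:
    def test_within_cutoff_counts(self):
        coords = np.array([[0.0, 0, 0], [6.0, 0, 0], [7.0, 0, 0]])
        top = make_topology(["C", "C", "C"])
        n = contact_count(coords, top, selection([0]), selection([1, 2]))
        assert n == 1

    def test_all_beyond_cutoff(self):
        coords = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        top = make_topology(["C", "C"])
        assert contact_count(coords, top, selection([0]), selection([1])) == 0

    def test_hydrogens_are_filtered(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        top = make_topology(["C", "H", "C"])
        n = contact_count(coords, top, selection([0, 1]), selection([2]))
        assert n == 1

    def test_symmetry_and_cutoff_monotonicity(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 12, size=(30, 3))
        top = make_topology(["C"] * 30)
        a, b = selection(range(15)), selection(range(15, 30))
        assert contact_count(coords, top, a, b) == contact_count(coords, top, b, a)
        counts = [
            contact_count(coords, top, a, b, InteractionCriteria(contact_cut=c))
            for c in (2.0, 4.0, 6.5, 9.0)
        ]
        assert counts == sorted(counts)

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        coords, elements = random_molecular_frame(rng, n_atoms=30, box=10.0)
        top = make_topology(elements)
        a, b = selection(range(15)), selection(range(15, 30))
        got = contact_count(coords, top, a, b)
        assert got == brute_contact_count(coords, elements, range(15),
                                          range(15, 30), 6.5)

    def test_mean_contacts(self):
        top = make_topology(["C", "C"])
        frames = np.zeros((2, 2, 3))
        frames[0, 1, 0] = 6.0   # 1 contact
        frames[1, 1, 0] = 7.0   # 0 contacts
        traj = FrameSeries(frames, dt=1.0)
        m = mean_contacts(traj, top, selection([0]), selection([1]))
        assert m == pytest.approx(0.5)


class TestSaltbridgeOccupancy:
    def test_always_bound(self):
        series = ScalarSeries(np.full(100, 2.9), dt=10.0)
        assert saltbridge_occupancy(series) == 1.0

    def test_never_bound_separated_state(self):
        series = ScalarSeries(np.full(100, 12.0), dt=10.0)
        assert saltbridge_occupancy(series) == 0.0

    def test_strict_inequality_at_cutoff(self):
        series = ScalarSeries(np.array([3.5, 3.499999, 3.6]), dt=1.0)
        assert saltbridge_occupancy(series) == pytest.approx(1 / 3)

    def test_empty_series_raises(self):
        with pytest.raises(ValueError):
            saltbridge_occupancy(ScalarSeries(np.array([]), dt=1.0))


def test_shrinking_cutoffs_never_add_records():
    rng = np.random.default_rng(42)
    for _ in range(20):
        coords, elements = random_molecular_frame(rng, n_atoms=25)
        top = make_topology(elements)
        sel = selection(range(25))
        loose = InteractionCriteria()
        tight = InteractionCriteria(hbond_da_cut=2.5, hbond_angle_cut=150.0,
                                    contact_cut=4.0, xbond_dist_cut=3.0,
                                    xbond_angle_cut=160.0)
        hb_loose = {(r.donor_index, r.acceptor_index)
                    for r in find_hbonds(coords, top, sel, sel, loose,
                                         warn_missing_h=False)}
        hb_tight = {(r.donor_index, r.acceptor_index)
                    for r in find_hbonds(coords, top, sel, sel, tight,
                                         warn_missing_h=False)}
        assert hb_tight <= hb_loose
        xb_loose = {(r.donor_index, r.acceptor_index)
                    for r in find_halogen_bonds(coords, top, sel, sel, loose)}
        xb_tight = {(r.donor_index, r.acceptor_index)
                    for r in find_halogen_bonds(coords, top, sel, sel, tight)}
        assert xb_tight <= xb_loose
        a, b = selection(range(12)), selection(range(12, 25))
        assert (contact_count(coords, top, a, b, tight)
                <= contact_count(coords, top, a, b, loose))
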