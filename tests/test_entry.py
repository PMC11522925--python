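"""Entry reaction coordinate, productive poses, si/re faces, segmentation."""
from __future__ import annotations

import importlib.resources

import numpy as np
import pytest

from entryscope import entry as en
from entryscope import synthcase as sc
from entryscope.model_io import AnalysisConfig, Trajectory, read_topology

REF_ANNOTATIONS = {
    "polymer_chains": ["P"],
    "serine": {"residue": 1, "atom": "OG"},
    "oxyanion_donors": [{"residue": 2, "atom": "HN1"},
                        {"residue": 3, "atom": "HN2"}],
    "ester_bonds": [[6, 7, 8]],
}


@pytest.fixture(scope="module")
def reference_ester():
    """The shipped geometry that anchors the si-face sign convention."""
    path = importlib.resources.files("entryscope.data") / "reference_ester.pdb"
    system = read_topology(str(path), REF_ANNOTATIONS)
    return system, system.reference_coordinates


def test_reference_geometry_is_si(reference_ester):
    system, coords = reference_ester
    assert en.face_label(coords, system, 0) == "si"


def test_mirrored_reference_is_re(reference_ester):
    """Reflection through any plane flips the prochiral label."""
    system, coords = reference_ester
    for axis in range(3):
        flip = np.ones(3)
        flip[axis] = -1.0
        assert en.face_label(coords * flip, system, 0) == "re"


def test_in_plane_serine_is_undefined(reference_ester):
    system, coords = reference_ester
    moved = coords.copy()
    og = system.index_of(system.serine_ogamma)
    c = coords[system.index_of(6)]
    # place OG inside the ester plane (the plane contains C1 and O1)
    o = coords[system.index_of(7)]
    moved[og] = c + 1.5 * (o - c)
    assert en.face_label(moved, system, 0) == "undefined"


def test_collinear_triplet_warns_undefined(reference_ester):
    system, coords = reference_ester
    degenerate = coords.copy()
    c = coords[system.index_of(6)]
    o = coords[system.index_of(7)]
    degenerate[system.index_of(8)] = c + 2.0 * (o - c)
    with pytest.warns(UserWarning, match="collinear"):
        assert en.face_label(degenerate, system, 0) == "undefined"


def test_rigid_motion_invariance(toy, config):
    """Rotation + translation of every frame leaves distances, flags and
    faces unchanged."""
    spec, system, ref = toy
    traj, _, _ = sc.simulate_entry(system, ref, spec, corridor=1, seed=21)
    base = en.entry_series(traj, system, config)
    theta = 0.7
    R = np.array([[np.cos(theta), -np.sin(theta), 0],
                  [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
    moved = Trajectory(coordinates=traj.coordinates @ R.T + np.array([5., -3., 8.]),
                       time=traj.time)
    got = en.entry_series(moved, system, config)
    assert np.allclose(got.ser_c, base.ser_c, atol=1e-9)
    assert np.allclose(got.oxyanion, base.oxyanion, atol=1e-9)
    assert np.array_equal(got.productive, base.productive)
    assert np.array_equal(got.face, base.face)


def test_mirror_flips_every_face(toy, config):
    spec, system, ref = toy
    traj, _, _ = sc.simulate_entry(system, ref, spec, corridor=2, seed=22)
    base = en.entry_series(traj, system, config)
    mirrored = Trajectory(coordinates=traj.coordinates * np.array([1, 1, -1.0]),
                          time=traj.time)
    got = en.entry_series(mirrored, system, config)
    swap = {"si": "re", "re": "si", "undefined": "undefined"}
    assert [swap[f] for f in base.face] == list(got.face)
    assert np.array_equal(got.productive, base.productive)


def test_productive_requires_all_three_distances(toy, config):
    """SER-C <= 4 alone is not productive; both oxyanion distances must
    also satisfy the cutoff."""
    spec, system, ref = toy
    coords = ref.copy()
    og = system.index_of(system.serine_ogamma)
    c_i = system.index_of(system.ester_bonds[0][0])
    poly = np.where(system.polymer_mask)[0]
    # bound pose: all three distances within 4 A
    coords[poly] += (ref[og] + np.array([3.0, 0, 0])) - ref[c_i]
    s1 = en.entry_series(Trajectory(coordinates=coords[None], time=[0.0]),
                         system, config)
    assert s1.productive[0]
    # pull one oxyanion donor away: same SER-C, no longer productive
    far = coords.copy()
    h = system.index_of(system.oxyanion_donors[1])
    far[h] += np.array([0.0, 6.0, 0.0])
    s2 = en.entry_series(Trajectory(coordinates=far[None], time=[0.0]),
                         system, config)
    assert s2.ser_c[0] == pytest.approx(s1.ser_c[0])
    assert not s2.productive[0]


def test_nearest_ester_selection(toy, config):
    """With two esters at 7 A and 3 A the nearer one is tracked."""
    spec, system, ref = toy
    coords = ref.copy()
    og = system.index_of(system.serine_ogamma)
    c0 = system.index_of(system.ester_bonds[0][0])
    c1 = system.index_of(system.ester_bonds[1][0])
    coords[c0] = coords[og] + np.array([7.0, 0, 0])
    coords[c1] = coords[og] + np.array([0, 3.0, 0])
    s = en.entry_series(Trajectory(coordinates=coords[None], time=[0.0]),
                        system, config)
    assert s.nearest_ester[0] == 1
    assert s.ser_c[0] == pytest.approx(3.0)


def test_noiseless_segmentation_is_exact(noiseless_entry, config):
    system, traj, truth, _ = noiseless_entry
    series = en.entry_series(traj, system, config)
    events = en.segment_entries(series, config)
    assert len(events) == 1
    ev = events[0]
    assert ev.outside == truth.outside
    assert ev.entry == truth.entry
    assert ev.inside == truth.inside
    assert ev.productive
    assert ev.face == "si"


def test_monotone_series_single_event(config):
    d = np.linspace(8.0, 2.0, 13)
    series = en.EntrySeries(ser_c=d, nearest_ester=np.zeros(13, int),
                            oxyanion=np.full((13, 2), 3.0),
                            productive=d <= 4.0,
                            face=np.array(["si"] * 13),
                            time=np.arange(13, dtype=float),
                            weights=np.ones(13))
    events = en.segment_entries(series, config)
    assert len(events) == 1
    ev = events[0]
    # 6 A crossed between indices 4 (7.0... ) and 5; 4 A between 8 and 9
    assert d[ev.outside[1] - 1] > 6.0 and d[ev.entry[0]] <= 6.0
    assert d[ev.inside[0]] < 4.0 and d[ev.inside[0] - 1] >= 4.0


def test_series_never_below_outer_gives_no_events(config):
    d = np.full(10, 7.5)
    series = en.EntrySeries(ser_c=d, nearest_ester=np.zeros(10, int),
                            oxyanion=np.full((10, 2), 5.0),
                            productive=np.zeros(10, bool),
                            face=np.array(["undefined"] * 10),
                            time=np.arange(10, dtype=float),
                            weights=np.ones(10))
    assert en.segment_entries(series, config) == []


def test_reversed_series_directionality(noiseless_entry, config):
    """Exit (reversed entry) never shares an inside-phase start with the
    forward pass."""
    system, traj, _, _ = noiseless_entry
    series = en.entry_series(traj, system, config)
    fwd = en.segment_entries(series, config)
    rev = en.EntrySeries(ser_c=series.ser_c[::-1].copy(),
                         nearest_ester=series.nearest_ester[::-1].copy(),
                         oxyanion=series.oxyanion[::-1].copy(),
                         productive=series.productive[::-1].copy(),
                         face=series.face[::-1].copy(),
                         time=series.time.copy(), weights=series.weights.copy())
    back = en.segment_entries(rev, config)
    starts_fwd = {e.inside[0] for e in fwd}
    starts_rev = {e.inside[0] for e in back}
    assert not (starts_fwd & starts_rev)


def test_noisy_recovery_rate(toy, config):
    """100 noisy entries (0.3 A): at least 95 recovered with phase
    boundaries within 2 frames of the planted truth."""
    spec, system, ref = toy
    ok = 0
    for i in range(100):
        traj, truth, _ = sc.simulate_entry(system, ref, spec,
                                           corridor=(i % 3) + 1, seed=5000 + i)
        events = en.segment_entries(en.entry_series(traj, system, config),
                                    config)
        if len(events) != 1:
            continue
        ev = events[0]
        if (abs(ev.entry[0] - truth.entry[0]) <= 2
                and abs(ev.inside[0] - truth.inside[0]) <= 2):
            ok += 1
    assert ok >= 95


def test_tally_counts():
    mk = lambda face, prod: en.EntryEvent((0, 1), (1, 2), (2, 3), face, prod, 0)
    tally = en.tally_entries([[mk("si", True), mk("re", True)],
                              [mk("si", True), mk("si", False)]])
    assert tally.n_events == 4
    assert tally.n_productive == 3
    assert (tally.n_si, tally.n_re) == (2, 1)
    empty = en.tally_entries([])
    assert empty.n_events == 0 and empty.n_productive == 0
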