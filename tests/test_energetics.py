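"""Nonbonded energy kernel vs closed forms and a double-loop oracle;
class profiles and site comparisons by direct arithmetic."""
from __future__ import annotations

import numpy as np
import pytest

from entryscope import energetics as eg
from entryscope import synthcase as sc
from entryscope._geom import minimum_image
from entryscope.model_io import AnalysisConfig, MolecularSystem, Trajectory


def brute_force_energy(coords, ga, gb, system, config, box=None):
    """Plain double loop; the independent oracle for the vectorized kernel."""
    coul = lj = 0.0
    for i in ga:
        for j in gb:
            r = np.linalg.norm(minimum_image(coords[j] - coords[i], box))
            if r > config.nonbonded_cutoff:
                continue
            coul += config.coulomb_constant * system.charge[i] * system.charge[j] / r
            sig = 0.5 * (system.lj_sigma[i] + system.lj_sigma[j])
            eps = np.sqrt(system.lj_epsilon[i] * system.lj_epsilon[j])
            if sig > 0:
                sr6 = (sig / r) ** 6
                lj += 4 * eps * (sr6 ** 2 - sr6)
    return coul, lj


@pytest.fixture(scope="module")
def charged_pair(small_toy):
    """Two single-atom groups at controlled separation in the toy system."""
    spec, system, ref = small_toy
    return system, ref


def test_unit_charges_at_one_angstrom(charged_pair, config):
    """Two +1 e point charges 1 A apart: Coulomb equals the configured
    constant, 332.0636 kcal/mol."""
    system, ref = charged_pair
    coords = ref.copy()
    i = system.index_of(2)                       # serine OG
    j = system.index_of(int(system.polymer_units[0][0]))
    coords[j] = coords[i] + np.array([1.0, 0.0, 0.0])
    saved = (system.charge.copy(), system.lj_sigma.copy())
    system.charge[:] = 0.0
    system.charge[[i, j]] = 1.0
    system.lj_sigma[:] = 0.0
    try:
        coul, lj = eg.pair_energy(coords, [i], [j], system, config)
    finally:
        system.charge[:], system.lj_sigma[:] = saved
    assert coul == pytest.approx(332.0636, abs=1e-10)
    assert lj == 0.0


def test_lj_minimum_identity(charged_pair, config):
    """Two neutral atoms at r = 2^(1/6) sigma sit at the LJ minimum -eps."""
    system, ref = charged_pair
    coords = ref.copy()
    i = system.index_of(2)
    j = system.index_of(int(system.polymer_units[0][0]))
    sigma = 0.5 * (system.lj_sigma[i] + system.lj_sigma[j])
    eps = np.sqrt(system.lj_epsilon[i] * system.lj_epsilon[j])
    coords[j] = coords[i] + np.array([2 ** (1 / 6) * sigma, 0.0, 0.0])
    saved = system.charge.copy()
    system.charge[:] = 0.0
    try:
        coul, lj = eg.pair_energy(coords, [i], [j], system, config)
    finally:
        system.charge[:] = saved
    assert coul == 0.0
    assert lj == pytest.approx(-eps, rel=1e-12)


def test_pair_energy_matches_double_loop(small_toy, config):
    spec, system, ref = small_toy
    traj, _, _ = sc.simulate_entry(system, ref, spec, corridor=2, seed=9)
    enz = np.where(system.enzyme_mask)[0]
    poly = np.where(system.polymer_mask)[0]
    for f in (0, traj.n_frames // 2, traj.n_frames - 1):
        got = eg.pair_energy(traj.coordinates[f], enz, poly, system, config)
        want = brute_force_energy(traj.coordinates[f], enz, poly, system, config)
        assert got[0] == pytest.approx(want[0], abs=1e-9)
        assert got[1] == pytest.approx(want[1], abs=1e-9)


def test_pair_energy_symmetry_and_charge_linearity(small_toy, config):
    spec, system, ref = small_toy
    enz = np.where(system.enzyme_mask)[0]
    poly = np.where(system.polymer_mask)[0]
    ab = eg.pair_energy(ref, enz, poly, system, config)
    ba = eg.pair_energy(ref, poly, enz, system, config)
    assert ab == pytest.approx(ba)
    saved = system.charge.copy()
    system.charge[enz] *= 2.0
    try:
        doubled = eg.pair_energy(ref, enz, poly, system, config)
    finally:
        system.charge[:] = saved
    assert doubled[0] == pytest.approx(2.0 * ab[0])
    assert doubled[1] == pytest.approx(ab[1])


def test_overlapping_groups_and_clash_errors(small_toy, config):
    spec, system, ref = small_toy
    with pytest.raises(ValueError, match="overlap"):
        eg.pair_energy(ref, [0, 1], [1, 2], system, config)
    clash = ref.copy()
    clash[5] = clash[0]
    with pytest.raises(ValueError, match="clash"):
        eg.pair_energy(clash, [0], [5], system, config)


def test_atoms_beyond_cutoff_are_irrelevant(small_toy, config):
    """Dropping atoms farther than the cutoff leaves the energy unchanged."""
    spec, system, ref = small_toy
    enz = np.where(system.enzyme_mask)[0]
    poly = np.where(system.polymer_mask)[0]
    i = system.index_of(system.serine_ogamma)
    d = np.linalg.norm(ref[poly] - ref[i], axis=1)
    near = poly[d <= config.nonbonded_cutoff]
    full = eg.pair_energy(ref, [i], poly, system, config)
    trimmed = eg.pair_energy(ref, [i], near, system, config) if len(near) \
        else (0.0, 0.0)
    assert full == pytest.approx(trimmed, abs=1e-12)


def test_residue_series_consistency(small_toy, config):
    """Per-residue series equals pair_energy called directly; residues far
    beyond the cutoff give all-zero series."""
    spec, system, ref = small_toy
    traj = Trajectory(coordinates=ref[None], time=[0.0])
    series = eg.residue_energy_series(traj, system, config)
    poly = np.where(system.polymer_mask)[0]
    for r, es in series.items():
        idx = system.residue_atom_indices(r)
        want = eg.pair_energy(ref, idx, poly, system, config)
        assert es.coulomb[0] == pytest.approx(want[0], abs=1e-9)
        assert es.lj[0] == pytest.approx(want[1], abs=1e-9)
        mind = min(np.linalg.norm(ref[j] - ref[i]) for i in idx for j in poly)
        if mind > config.nonbonded_cutoff:
            assert es.total[0] == 0.0


def test_class_profile_arithmetic(toy, config):
    """Hand-computed scaled means: two polar residues at -2 and -4 average
    to -3; one apolar residue passes through unchanged."""
    _, system, _ = toy
    by_name = {}
    for r in system.enzyme_residues():
        by_name.setdefault(system.residue_name_of(int(r)), []).append(int(r))
    thr1, thr2 = by_name["THR"][0], by_name["ASN"][0]   # both polar
    ala = by_name["ALA"][0]                             # apolar
    mk = lambda v: eg.EnergySeries(coulomb=np.array([v]), lj=np.array([0.0]),
                                   weights=np.array([1.0]))
    series = {thr1: mk(-2.0), thr2: mk(-4.0), ala: mk(-7.0)}
    prof = eg.class_profile(series, [thr1, thr2, ala], system)
    assert prof.class_energy["polar"] == pytest.approx(-3.0)
    assert prof.class_energy["apolar"] == pytest.approx(-7.0)
    assert prof.class_counts == {"polar": 2, "apolar": 1}
    with pytest.raises(ValueError, match="empty"):
        eg.class_profile(series, [], system)


def test_pet_internal_energy_rules(small_toy, config):
    spec, system, ref = small_toy
    traj = Trajectory(coordinates=ref[None], time=[0.0])
    with pytest.raises(ValueError, match="non-adjacent"):
        eg.pet_internal_energy(traj, system, config, (0, 1))
    with pytest.raises(ValueError, match="non-adjacent"):
        eg.pet_internal_energy(traj, system, config, (1, 1))
    es = eg.pet_internal_energy(traj, system, config, (0, 2))
    want = eg.pair_energy(ref, system.indices_of(system.polymer_units[0]),
                          system.indices_of(system.polymer_units[2]),
                          system, config)
    assert es.total[0] == pytest.approx(sum(want), abs=1e-9)
    # units far beyond the cutoff contribute nothing
    spread = ref.copy()
    spread[system.indices_of(system.polymer_units[2])] += 100.0
    far = eg.pet_internal_energy(Trajectory(coordinates=spread[None],
                                            time=[0.0]), system, config, (0, 2))
    assert far.total[0] == 0.0


def test_binding_onset_detection():
    t = np.arange(5, dtype=float)
    es = eg.EnergySeries(coulomb=np.array([-3.0, -8, -12, -15, -11]),
                         lj=np.zeros(5), weights=np.ones(5))
    assert eg.binding_onset(es, t, -10.0) == 2.0
    weak = eg.EnergySeries(coulomb=np.full(5, -5.0), lj=np.zeros(5),
                           weights=np.ones(5))
    assert eg.binding_onset(weak, t, -10.0) is None
    strong = eg.EnergySeries(coulomb=np.full(5, -12.0), lj=np.zeros(5),
                             weights=np.ones(5))
    assert eg.binding_onset(strong, t, -10.0) == 0.0


def test_site_delta_eint_recovers_planted_shift():
    mk = lambda v: eg.EnergySeries(coulomb=np.array([v, v]), lj=np.zeros(2),
                                   weights=np.ones(2))
    parent = {10: mk(-5.0), 20: mk(-8.0)}
    same = eg.site_delta_eint(parent, parent, [10, 20])
    assert all(v["delta"] == 0.0 for v in same.values())
    shifted = {10: mk(-3.0), 20: mk(-6.5)}
    out = eg.site_delta_eint(parent, shifted, [10, 20])
    assert out[10]["delta"] == pytest.approx(2.0)
    assert out[20]["delta"] == pytest.approx(1.5)
    with pytest.raises(KeyError, match="site 30"):
        eg.site_delta_eint(parent, shifted, [30])
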