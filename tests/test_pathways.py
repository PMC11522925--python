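"""Pathway PCA: feature extraction, dense-eigen oracle, corridor recovery."""
from __future__ import annotations

import numpy as np
import pytest
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score

from entryscope import entry as en
from entryscope import pathways as pw
from entryscope import synthcase as sc


@pytest.fixture(scope="module")
def corridor_batch(toy, config):
    """30 noisy entry trajectories, 10 per planted corridor."""
    spec, system, ref = toy
    trajs, events, labels = [], [], []
    for i in range(30):
        corridor = (i % 3) + 1
        traj, _, lab = sc.simulate_entry(system, ref, spec, corridor,
                                         seed=3000 + i)
        series = en.entry_series(traj, system, config)
        evs = en.segment_entries(series, config)
        trajs.append(traj)
        events.append(evs)
        labels.append(lab)
    return system, trajs, events, labels


def test_feature_matrix_values_and_caps(toy):
    """Distances appear verbatim within the radius; far residues are
    excluded from the set; drifting residues are capped at 2x radius."""
    spec, system, ref = toy
    og = system.index_of(system.serine_ogamma)
    c_i = system.index_of(system.ester_bonds[0][0])
    coords = ref.copy()
    poly = np.where(system.polymer_mask)[0]
    coords[poly] += (ref[og] + np.array([3.0, 0, 0])) - ref[c_i]
    from entryscope.model_io import Trajectory
    traj = Trajectory(coordinates=coords[None].repeat(4, axis=0),
                      time=np.arange(4, dtype=float))
    ev = en.EntryEvent((0, 1), (1, 2), (2, 4), "si", True, 0)
    M, residues, eid, w = pw.entry_feature_matrix([[ev]], [traj], system,
                                                  radius=10.0)
    assert M.shape[0] == 3          # entry + inside frames
    ca = (system.name == "CA") & system.enzyme_mask
    for k, r in enumerate(residues):
        i = np.where(ca & (system.residue_index == r))[0][0]
        d = np.linalg.norm(coords[i] - coords[c_i])
        assert d <= 10.0
        assert M[0, k] == pytest.approx(min(d, 20.0))
    # all excluded Calphas really are outside the radius
    excl = [i for i in np.where(ca)[0]
            if system.residue_index[i] not in set(residues)]
    for i in excl:
        assert np.linalg.norm(coords[i] - coords[c_i]) > 10.0
    assert M.max() <= 20.0


def test_pca_matches_dense_eigendecomposition(corridor_batch, config):
    """Unit-weight fit equals an independent covariance + eigh solve and
    sklearn's PCA up to sign."""
    system, trajs, events, _ = corridor_batch
    M, res, eid, w = pw.entry_feature_matrix(events, trajs, system, 10.0)
    model = pw.pca_fit(M, None, res)
    Xc = M - M.mean(axis=0)
    cov = Xc.T @ Xc / len(M)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    assert np.allclose(model.explained_variance, evals[order], atol=1e-8)
    for k in range(M.shape[1]):
        v = evecs[:, order[k]]
        assert np.allclose(np.abs(model.loadings[:, k]), np.abs(v), atol=1e-6)
    sk = PCA(n_components=M.shape[1]).fit(M)
    assert np.allclose(model.explained_fraction,
                       sk.explained_variance_ratio_, atol=1e-3)


def test_pca_identities(corridor_batch):
    """Reconstruction with all components is exact; projected variance
    along PC1 equals the first eigenvalue; projections are centered."""
    system, trajs, events, _ = corridor_batch
    M, res, eid, w = pw.entry_feature_matrix(events, trajs, system, 10.0)
    model = pw.pca_fit(M, w, res)
    Xc = M - model.mean
    recon = (Xc @ model.loadings) @ model.loadings.T
    assert np.allclose(recon, Xc, atol=1e-8)
    proj = pw.project(model, M, n_components=M.shape[1])
    wn = w / w.sum()
    assert np.allclose(wn @ proj, 0.0, atol=1e-8)
    var1 = float(wn @ proj[:, 0] ** 2)
    assert var1 == pytest.approx(model.explained_variance[0], rel=1e-8)


def test_line_and_isotropic_cases():
    t = np.linspace(0, 1, 50)
    line = np.column_stack([t, 2 * t])
    m = pw.pca_fit(line)
    assert m.explained_fraction[0] == pytest.approx(1.0, abs=1e-12)
    rng = np.random.default_rng(7)
    iso = rng.normal(size=(10_000, 2))
    m2 = pw.pca_fit(iso)
    assert m2.explained_fraction[0] == pytest.approx(0.5, abs=0.02)
    with pytest.raises(ValueError, match="zero-variance"):
        pw.pca_fit(np.ones((5, 3)))


def test_column_permutation_equivariance():
    rng = np.random.default_rng(8)
    X = rng.normal(size=(200, 5)) * np.array([3.0, 1.0, 0.5, 0.2, 0.1])
    m = pw.pca_fit(X)
    perm = np.array([4, 2, 0, 1, 3])
    mp = pw.pca_fit(X[:, perm])
    assert np.allclose(mp.loadings[:, 0], m.loadings[perm, 0], atol=1e-8)
    assert np.allclose(mp.explained_variance, m.explained_variance, atol=1e-10)


def test_contribution_ranking():
    rng = np.random.default_rng(9)
    X = rng.normal(size=(500, 2)) @ np.array([[0.8, -0.6], [0.6, 0.8]]) \
        * np.array([4.0, 0.5])
    m = pw.pca_fit(X)
    ranked = pw.pc_contributions(m, 0, count=2)
    assert abs(ranked[0][1]) >= abs(ranked[1][1])
    with pytest.raises(IndexError):
        pw.pc_contributions(m, 5)


def test_equal_loadings_below_strict_threshold():
    """A perfectly isotropic direction leaves no residue above 1/sqrt(d)."""
    t = np.linspace(0, 1, 40)
    m = pw.pca_fit(np.column_stack([t, t]))
    sig = pw.pc_contributions(m, 0)
    assert sig == []   # both loadings equal 1/sqrt(2), not above it


def test_three_corridors_separate_in_pc_plane(corridor_batch):
    """Planted corridors form separated clusters; assignment agrees with
    the generator labels (ARI >= 0.9) and planted discriminating residues
    rank at the top of PC1 contributions."""
    system, trajs, events, labels = corridor_batch
    M, res, eid, w = pw.entry_feature_matrix(events, trajs, system, 10.0)
    model = pw.pca_fit(M, w, res)
    proj = pw.project(model, M)
    assign = pw.assign_pathways(proj, eid, k=3, seed=0)
    pred = [assign[e] for e in sorted(assign)]
    assert adjusted_rand_score(labels, pred) >= 0.9
    # silhouette of corridor labels in the PC plane
    from sklearn.metrics import silhouette_score
    means = np.vstack([proj[eid == e].mean(axis=0) for e in sorted(set(eid))])
    assert silhouette_score(means, labels) > 0.5


def test_planted_discriminators_rank_high(toy, corridor_batch):
    spec, system, ref = toy
    _, trajs, events, labels = corridor_batch
    M, res, eid, w = pw.entry_feature_matrix(events, trajs, system, 10.0)
    model = pw.pca_fit(M, w, res)
    planted = sc.planted_corridor_residues(system, ref, radius=10.0)
    lateral = (set(planted[1]) | set(planted[3])) - set(planted[2])
    top5 = {r for r, *_ in pw.pc_contributions(model, 0, count=5)}
    assert top5 & lateral


def test_assignment_determinism_and_k1(corridor_batch):
    system, trajs, events, _ = corridor_batch
    M, res, eid, w = pw.entry_feature_matrix(events, trajs, system, 10.0)
    model = pw.pca_fit(M, w, res)
    proj = pw.project(model, M)
    a = pw.assign_pathways(proj, eid, k=3, seed=5)
    b = pw.assign_pathways(proj, eid, k=3, seed=5)
    assert a == b
    one = pw.assign_pathways(proj, eid, k=1, seed=5)
    assert set(one.values()) == {1}
    with pytest.raises(ValueError, match="at least"):
        pw.assign_pathways(proj[:3], eid[:3], k=5, seed=0)
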