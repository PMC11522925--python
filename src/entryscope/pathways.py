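"""Entry-pathway decomposition by PCA of ester-carbon-to-Calpha distances.

During each entry event the distance from the tracked ester carbon to
every enzyme Calpha that ever comes within a feature radius (10 A default)
forms one feature vector per frame.  A weighted PCA of these vectors maps
entries into the PC1/PC2 plane, where k-means (k = 3 by default) separates
the preferred entry routes; per-residue loadings rank the positions that
steer the entry.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.cluster import KMeans

from ._geom import minimum_image
from .entry import EntryEvent
from .model_io import MolecularSystem, Trajectory

__all__ = ["PCModel", "entry_feature_matrix", "pca_fit", "project",
           "pc_contributions", "assign_pathways"]


@dataclass
class PCModel:
    """Weighted-PCA model over a fixed, ordered residue feature list."""

    residues: np.ndarray          # (d,) residue indices, fixed order
    mean: np.ndarray              # (d,)
    loadings: np.ndarray          # (d, d) columns = components
    explained_variance: np.ndarray          # (d,) eigenvalues, descending
    explained_fraction: np.ndarray          # (d,)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "residues": self.residues.tolist(),
                "mean": self.mean.tolist(),
                "loadings": self.loadings.tolist(),
                "explained_variance": self.explained_variance.tolist(),
                "explained_fraction": self.explained_fraction.tolist(),
            }, fh)


def entry_feature_matrix(events: Sequence[Sequence[EntryEvent]],
                         trajs: Sequence[Trajectory], system: MolecularSystem,
                         radius: float = 10.0,
                         ca_name: str = "CA",
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Ester-C-to-Calpha distance features over entry + inside frames.

    ``events[t]`` are the events of ``trajs[t]``.  The residue feature set
    is the union, over all entry and inside frames of all events, of the
    enzyme residues whose Calpha lies within ``radius`` of the tracked
    ester carbon.  Feature values are capped at ``2 * radius`` when a
    selected residue drifts out of range, so every row is complete.

    Returns ``(matrix, residues, event_id, weights)`` with one row per
    frame.
    """
    if not any(len(e) for e in events):
        raise ValueError("no entry events supplied")
    ca_mask = (system.name == ca_name) & system.enzyme_mask
    ca_idx = np.where(ca_mask)[0]
    ca_res = system.residue_index[ca_idx]

    rows_d: list[np.ndarray] = []      # per-frame distances to every Calpha
    event_id: list[int] = []
    weights: list[float] = []
    in_radius = np.zeros(len(ca_idx), dtype=bool)
    eid = 0
    for t, (traj, ev_list) in enumerate(zip(trajs, events)):
        for ev in ev_list:
            c_id = system.ester_bonds[ev.ester_index][0]
            c_i = system.index_of(c_id)
            for f in range(ev.entry[0], ev.inside[1]):
                box = traj.frame_box(f)
                diff = minimum_image(
                    traj.coordinates[f, ca_idx] - traj.coordinates[f, c_i], box)
                d = np.linalg.norm(diff, axis=1)
                in_radius |= d <= radius
                rows_d.append(d)
                event_id.append(eid)
                weights.append(float(traj.frame_weight[f]))
            eid += 1
    if not in_radius.any():
        raise ValueError(f"no Calpha within {radius} A of the ester carbon "
                         "in any entry frame")
    sel = np.where(in_radius)[0]
    matrix = np.minimum(np.asarray(rows_d)[:, sel], 2.0 * radius)
    return (matrix, ca_res[sel].astype(int), np.asarray(event_id, int),
            np.asarray(weights, float))


def pca_fit(matrix: np.ndarray, weights: np.ndarray | None = None,
            residues: np.ndarray | None = None) -> PCModel:
    """Eigendecomposition of the weighted covariance of centered features.

    Components are sorted by eigenvalue (descending) with a deterministic
    sign convention: the largest-magnitude entry of each loading vector is
    positive.
    """
    X = np.asarray(matrix, float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("matrix must be 2D with at least 2 rows and 2 columns")
    if np.isnan(X).any():
        raise ValueError("matrix contains missing values")
    n, d = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    w = w / w.sum()
    mean = w @ X
    Xc = X - mean
    cov = (Xc * w[:, None]).T @ Xc
    if np.allclose(cov, 0):
        raise ValueError("zero-variance feature matrix")
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # sign convention
    for k in range(d):
        j = np.argmax(np.abs(evecs[:, k]))
        if evecs[j, k] < 0:
            evecs[:, k] = -evecs[:, k]
    total = evals.sum()
    res = np.arange(d) if residues is None else np.asarray(residues, int)
    return PCModel(residues=res, mean=mean, loadings=evecs,
                   explained_variance=evals,
                   explained_fraction=evals / total if total > 0 else evals)


def project(model: PCModel, matrix: np.ndarray,
            residues: np.ndarray | None = None, n_components: int = 2) -> np.ndarray:
    """Project feature rows onto the leading components."""
    X = np.asarray(matrix, float)
    if X.shape[1] != len(model.mean):
        raise ValueError("feature matrix does not match the fitted residue list")
    if residues is not None and not np.array_equal(np.asarray(residues, int),
                                                   model.residues):
        raise ValueError("residue list does not match the fitted model")
    return (X - model.mean) @ model.loadings[:, :n_components]


def project_and_fes(model: PCModel, matrix: np.ndarray,
                    weights: np.ndarray | None = None,
                    temperature: float = 303.0, bins: int = 50):
    """Projections in the (PC1, PC2) plane plus their free-energy surface."""
    from . import fes as _fes
    proj = project(model, matrix, n_components=2)
    grid = _fes.fes2d(proj[:, 0], proj[:, 1], weights, bins=bins,
                      temperature=temperature, axis_names=("PC1", "PC2"))
    return proj, grid


def pc_contributions(model: PCModel, component: int = 0,
                     threshold: float | None = None,
                     count: int | None = None) -> list[tuple[int, float, float]]:
    """Residues ranked by |loading| on one component.

    Returns ``(residue, signed_loading, |loading|)`` tuples, truncated to
    ``count`` if given.  ``threshold`` defaults to the uniform-loading
    baseline ``1/sqrt(d)``; residues at or below it are dropped unless
    ``count`` is given.
    """
    d = len(model.residues)
    if not (0 <= component < d):
        raise IndexError(f"component {component} out of range (d={d})")
    v = model.loadings[:, component]
    order = np.argsort(-np.abs(v))
    ranked = [(int(model.residues[i]), float(v[i]), float(abs(v[i]))) for i in order]
    if count is not None:
        return ranked[:count]
    if threshold is None:
        threshold = 1.0 / np.sqrt(d)
    # strictly above, with a float guard so exactly-uniform loadings
    # (the baseline itself) never qualify
    return [t for t in ranked if t[2] > threshold + 1e-9]


def assign_pathways(projections: np.ndarray, event_id: np.ndarray,
                    k: int = 3, seed: int = 0) -> dict[int, int]:
    """Cluster per-event mean projections into k pathways.

    Labels are re-ordered by cluster mean PC1, so pathway 1 sits at the
    most negative PC1 values and pathway k at the most positive.  Returns
    event id -> pathway label (1-based).
    """
    proj = np.asarray(projections, float)
    event_id = np.asarray(event_id, int)
    ids = np.unique(event_id)
    if len(ids) < k:
        raise ValueError(f"need at least k={k} events, have {len(ids)}")
    means = np.vstack([proj[event_id == e].mean(axis=0) for e in ids])
    km = KMeans(n_clusters=k, n_init=50, random_state=seed)
    raw = km.fit_predict(means)
    order = np.argsort(km.cluster_centers_[:, 0])   # by mean PC1
    relabel = {int(c): rank + 1 for rank, c in enumerate(order)}
    return {int(e): relabel[int(c)] for e, c in zip(ids, raw)}
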