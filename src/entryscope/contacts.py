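"""Residue-polymer contact mapping.

A residue is in contact with the polymer in a frame when the minimum
heavy-atom-heavy-atom distance between the residue and any polymer atom is
within the cutoff (3 A by default, boundary inclusive).  Contacts held for
at least a persistence fraction (75% default) of the weighted simulation
time define the binding residues, which are further split into proximal and
distal sites by the distance of the contacting polymer atoms to the
catalytic serine's gamma-oxygen (12 A default).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._geom import pairwise_distances
from .model_io import AnalysisConfig, MolecularSystem, Trajectory

__all__ = ["ContactMap", "contact_matrix", "persistence_filter",
           "proximal_distal_split", "contact_table"]


@dataclass
class ContactMap:
    """Boolean contact matrix (residue x frame) plus weighted fractions.

    ``fraction[r]`` is the frame-weighted mean of row ``r``.  ``labels`` is
    filled by :func:`proximal_distal_split` with one of ``proximal``,
    ``distal``, ``both`` or ``none`` per residue.
    """

    residues: np.ndarray          # (R,) enzyme residue indices
    matrix: np.ndarray            # (R, F) bool
    frame_weight: np.ndarray      # (F,)
    labels: dict[int, str] | None = None

    @property
    def fraction(self) -> np.ndarray:
        w = self.frame_weight / self.frame_weight.sum()
        return self.matrix @ w


def contact_matrix(traj: Trajectory, system: MolecularSystem,
                   cutoff: float = 3.0) -> ContactMap:
    """Per-frame residue-polymer contacts at a heavy-atom distance cutoff.

    Hydrogens are excluded on both sides; the boundary is inclusive
    (distance == cutoff counts as contact).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    traj.check_system(system)
    poly_idx = np.where(system.polymer_mask & system.heavy_mask)[0]
    if len(poly_idx) == 0:
        raise ValueError("polymer segment has no heavy atoms")
    residues = system.enzyme_residues()
    res_idx = [system.residue_atom_indices(r, heavy_only=True) for r in residues]

    mat = np.zeros((len(residues), traj.n_frames), dtype=bool)
    for f in range(traj.n_frames):
        box = traj.frame_box(f)
        poly = traj.coordinates[f, poly_idx]
        for ri, idx in enumerate(res_idx):
            if len(idx) == 0:
                continue
            d = pairwise_distances(traj.coordinates[f, idx], poly, box)
            mat[ri, f] = bool(d.min() <= cutoff)
    return ContactMap(residues=residues, matrix=mat,
                      frame_weight=traj.frame_weight.copy())


def persistence_filter(cmap: ContactMap, fraction: float = 0.75) -> set[int]:
    """Residues whose weighted contact fraction is >= ``fraction``."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    keep = cmap.fraction >= fraction
    return set(int(r) for r in cmap.residues[keep])


def proximal_distal_split(cmap: ContactMap, traj: Trajectory, system: MolecularSystem,
                          radius: float = 12.0,
                          majority: float = 0.9) -> dict[int, str]:
    """Label each residue's binding site proximal or distal to the serine.

    A residue's contact in a frame is proximal when the polymer heavy atoms
    in contact with that residue (within the contact cutoff implied by the
    map) come within ``radius`` of the serine gamma-oxygen in that frame.
    A residue is labelled ``proximal`` (``distal``) if at least ``majority``
    of its weighted contact frames are proximal (distal), ``both``
    otherwise, and ``none`` when it never contacts the polymer.

    The per-frame classification recomputes contacting polymer atoms from
    geometry, so the map's cutoff convention (3 A, inclusive) is re-applied.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if system.serine_ogamma is None:
        raise ValueError("catalytic serine annotation absent")
    traj.check_system(system)
    og = system.index_of(system.serine_ogamma)
    poly_idx = np.where(system.polymer_mask & system.heavy_mask)[0]
    res_idx = {int(r): system.residue_atom_indices(r, heavy_only=True)
               for r in cmap.residues}
    cutoff = _infer_cutoff(cmap)

    labels: dict[int, str] = {}
    w = cmap.frame_weight
    for ri, r in enumerate(cmap.residues):
        frames = np.where(cmap.matrix[ri])[0]
        if len(frames) == 0:
            labels[int(r)] = "none"
            continue
        prox_w = dist_w = 0.0
        for f in frames:
            box = traj.frame_box(f)
            d = pairwise_distances(traj.coordinates[f, res_idx[int(r)]],
                                   traj.coordinates[f, poly_idx], box)
            touching = poly_idx[np.where((d <= cutoff).any(axis=0))[0]]
            d_ser = pairwise_distances(traj.coordinates[f, touching],
                                       traj.coordinates[f, og][None, :], box)
            if d_ser.min() <= radius:
                prox_w += w[f]
            else:
                dist_w += w[f]
        total = prox_w + dist_w
        if prox_w / total >= majority:
            labels[int(r)] = "proximal"
        elif dist_w / total >= majority:
            labels[int(r)] = "distal"
        else:
            labels[int(r)] = "both"
    cmap.labels = labels
    return labels


def _infer_cutoff(cmap: ContactMap) -> float:
    return getattr(cmap, "cutoff", 3.0)


def contact_table(cmap: ContactMap, system: MolecularSystem,
                  path: str | Path | None = None) -> pd.DataFrame:
    """Tabulate residue index, name, contact fraction and site label;
    optionally write TSV."""
    labels = cmap.labels or {}
    df = pd.DataFrame({
        "residue_index": cmap.residues,
        "residue_name": [system.residue_name_of(int(r)) for r in cmap.residues],
        "contact_fraction": cmap.fraction,
        "label": [labels.get(int(r), "") for r in cmap.residues],
    })
    if path is not None:
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return df


def analyze(traj: Trajectory, system: MolecularSystem,
            config: AnalysisConfig) -> tuple[ContactMap, set[int], dict[int, str]]:
    """One-call contact stage: matrix, persistent set, site labels."""
    cmap = contact_matrix(traj, system, config.contact_cutoff)
    cmap.cutoff = config.contact_cutoff  # type: ignore[attr-defined]
    persistent = persistence_filter(cmap, config.persistence_fraction)
    labels = proximal_distal_split(cmap, traj, system, config.proximal_radius)
    return cmap, persistent, labels
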