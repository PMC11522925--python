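"""Substrate-entry analysis: reaction coordinate, productive poses, phases.

The entry reaction coordinate is the SER-C distance: catalytic serine
gamma-oxygen to the carbonyl carbon of the nearest polymer ester bond.  A
frame holds a *productive pose* when the SER-C distance and both distances
from that ester's carbonyl oxygen to the two oxyanion-hole amide hydrogens
are all within the productive cutoff (4 A default) -- the geometry
competent for nucleophilic attack.

Entry events segment a trajectory into outside (> 6 A), entry, and inside
(< 4 A) phases; the serine's approach face relative to the planar ester
carbonyl is labelled si or re.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._geom import distance, minimum_image
from .model_io import AnalysisConfig, MolecularSystem, Trajectory

__all__ = ["EntrySeries", "EntryEvent", "entry_series", "face_label",
           "segment_entries", "tally_entries", "EntryTally"]

# half-width of the in-plane dead band for face labels, A
FACE_DELTA = 0.1


@dataclass
class EntrySeries:
    """Per-frame entry descriptors along one trajectory."""

    ser_c: np.ndarray            # (F,) SER-C distance, A
    nearest_ester: np.ndarray    # (F,) index into system.ester_bonds
    oxyanion: np.ndarray         # (F, 2) carbonyl-O to donor-H distances, A
    productive: np.ndarray       # (F,) bool
    face: np.ndarray             # (F,) str: si | re | undefined
    time: np.ndarray             # (F,) ns
    weights: np.ndarray          # (F,)


@dataclass
class EntryEvent:
    """One outside -> entry -> inside passage.

    Frame ranges are half-open ``(start, stop)`` index pairs; phases are
    contiguous and ordered.  ``face`` is the label at the first productive
    frame (first inside frame when the event is nonproductive).
    """

    outside: tuple[int, int]
    entry: tuple[int, int]
    inside: tuple[int, int]
    face: str
    productive: bool
    ester_index: int


def _face_from_geometry(c: np.ndarray, o: np.ndarray, oe: np.ndarray,
                        og: np.ndarray, delta: float = FACE_DELTA) -> str:
    """Label the serine's side of the ester plane.

    The plane normal is n = (O - C) x (Oester - C); the label is *si* for
    n . (Ogamma - C) > delta, *re* below -delta, undefined inside the dead
    band or for a degenerate (collinear) triplet.  The sign-to-label
    assignment is anchored by the reference geometry shipped in
    ``data/reference_ester.pdb``, whose pose is labelled si.
    """
    n = np.cross(o - c, oe - c)
    norm = np.linalg.norm(n)
    if norm < 1e-8:
        warnings.warn("collinear ester triplet; face undefined")
        return "undefined"
    s = float(np.dot(n / norm, og - c))
    if s > delta:
        return "si"
    if s < -delta:
        return "re"
    return "undefined"


def face_label(frame_coords: np.ndarray, system: MolecularSystem,
               ester_index: int, box: np.ndarray | None = None) -> str:
    """si/re face of the serine for one frame and one ester bond."""
    c_id, o_id, oe_id = system.ester_bonds[ester_index]
    c = frame_coords[system.index_of(c_id)]
    og = frame_coords[system.index_of(system.serine_ogamma)]
    # displacements relative to the carbonyl carbon, minimum-image
    o = c + minimum_image(frame_coords[system.index_of(o_id)] - c, box)
    oe = c + minimum_image(frame_coords[system.index_of(oe_id)] - c, box)
    og = c + minimum_image(og - c, box)
    return _face_from_geometry(c, o, oe, og)


def entry_series(traj: Trajectory, system: MolecularSystem,
                 config: AnalysisConfig) -> EntrySeries:
    """Compute the per-frame SER-C coordinate, oxyanion distances,
    productive flags and face labels.

    The nearest ester is chosen per frame by minimal SER-C distance; the
    oxyanion distances refer to that same ester's carbonyl oxygen.
    """
    if not system.ester_bonds:
        raise ValueError("system has no ester bonds")
    traj.check_system(system)
    og_i = system.index_of(system.serine_ogamma)
    c_is = np.array([system.index_of(t[0]) for t in system.ester_bonds])
    o_is = np.array([system.index_of(t[1]) for t in system.ester_bonds])
    h_is = system.indices_of(system.oxyanion_donors)

    F = traj.n_frames
    ser_c = np.empty(F)
    nearest = np.empty(F, dtype=int)
    oxy = np.empty((F, 2))
    faces = np.empty(F, dtype=object)
    for f in range(F):
        box = traj.frame_box(f)
        xyz = traj.coordinates[f]
        d = minimum_image(xyz[c_is] - xyz[og_i], box)
        dists = np.linalg.norm(d, axis=1)
        k = int(np.argmin(dists))
        nearest[f] = k
        ser_c[f] = dists[k]
        o_xyz = xyz[o_is[k]]
        for j, h in enumerate(h_is):
            oxy[f, j] = distance(o_xyz, xyz[h], box)
        faces[f] = face_label(xyz, system, k, box)
    productive = (ser_c <= config.productive_cutoff) & \
        np.all(oxy <= config.productive_cutoff, axis=1)
    return EntrySeries(ser_c=ser_c, nearest_ester=nearest, oxyanion=oxy,
                       productive=productive, face=faces.astype(str),
                       time=traj.time.copy(), weights=traj.frame_weight.copy())


def segment_entries(series: EntrySeries, config: AnalysisConfig,
                    smooth: bool = False) -> list[EntryEvent]:
    """Detect outside -> entry -> inside passages of the SER-C coordinate.

    An event is emitted for each maximal run where the distance passes
    from above the outer boundary (6 A) to below the inner boundary (the
    productive cutoff, 4 A).  The entry phase spans the frames strictly
    between the last frame above the outer boundary and the first frame
    below the inner boundary.  The inside phase extends until the distance
    climbs back above the outer boundary.  A single frame below the inner
    boundary closes an event (no debouncing); ``smooth=True`` applies a
    width-5 median filter to the distance before segmentation.
    """
    d = series.ser_c
    if smooth and len(d) >= 5:
        from scipy.ndimage import median_filter
        d = median_filter(d, size=5, mode="nearest")
    outer, inner = config.outer_boundary, config.productive_cutoff
    events: list[EntryEvent] = []
    F = len(d)
    f = 0
    while f < F:
        # find the next frame above the outer boundary (start of an outside phase)
        while f < F and not (d[f] > outer):
            f += 1
        if f >= F:
            break
        out_start = f
        # advance to the first frame below the inner boundary, tracking the
        # last frame that was above the outer boundary
        last_above = f
        g = f
        while g < F and not (d[g] < inner):
            if d[g] > outer:
                last_above = g
            g += 1
        if g >= F:
            break  # never reaches the inside region
        in_start = g
        # inside phase persists until the coordinate exceeds the outer boundary
        h = g
        while h < F and not (d[h] > outer):
            h += 1
        in_stop = h
        prod_frames = np.where(series.productive[in_start:in_stop])[0]
        productive = len(prod_frames) > 0
        label_frame = in_start + (prod_frames[0] if productive else 0)
        events.append(EntryEvent(
            outside=(out_start, last_above + 1),
            entry=(last_above + 1, in_start),
            inside=(in_start, in_stop),
            face=str(series.face[label_frame]),
            productive=productive,
            ester_index=int(series.nearest_ester[label_frame]),
        ))
        f = in_stop
    return events


@dataclass
class EntryTally:
    """Aggregate entry statistics over a batch of trajectories."""

    n_events: int
    n_productive: int
    n_si: int
    n_re: int
    n_undefined: int
    productive_frame_fraction: float


def tally_entries(events_per_traj: Sequence[Sequence[EntryEvent]],
                  series_per_traj: Sequence[EntrySeries] | None = None) -> EntryTally:
    """Count productive entries and the si/re split; optionally also the
    weighted fraction of frames in productive poses."""
    n = n_prod = n_si = n_re = n_und = 0
    for events in events_per_traj:
        for ev in events:
            n += 1
            if ev.productive:
                n_prod += 1
                if ev.face == "si":
                    n_si += 1
                elif ev.face == "re":
                    n_re += 1
                else:
                    n_und += 1
    frac = 0.0
    if series_per_traj:
        w_tot = w_prod = 0.0
        for s in series_per_traj:
            w_tot += float(s.weights.sum())
            w_prod += float(s.weights[s.productive].sum())
        frac = w_prod / w_tot if w_tot > 0 else 0.0
    return EntryTally(n_events=n, n_productive=n_prod, n_si=n_si, n_re=n_re,
                      n_undefined=n_und, productive_frame_fraction=frac)
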