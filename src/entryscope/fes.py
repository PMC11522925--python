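"""Weighted 2D free-energy surfaces and their feature comparison.

A surface is built from weighted samples of two collective coordinates
(e.g. SER-C distance vs interaction energy, or the first two principal
components) as

    dG(bin) = -k_B T ln( P(bin) / P_max ),    k_B = 0.0083145 kJ/(mol K)

so the global minimum is at 0 and unsampled bins carry no value (masked;
they are never padded with pseudo-counts).  Free energies are reported in
kJ/mol.  Feature extraction locates local minima split at a productive
boundary on the distance axis, and the barrier between the deepest
productive and nonproductive minima as the bottleneck (minimax) value over
8-connected paths through sampled bins.
"""
from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = ["KB_KJ", "KCAL_TO_KJ", "FESGrid", "pool_replicas", "fes2d",
           "fes_features", "FESFeatures", "compare_fes"]

KB_KJ = 0.0083145          # kJ/(mol K)
KCAL_TO_KJ = 4.184


@dataclass
class FESGrid:
    """Binned 2D free-energy surface.

    ``dG`` is (nx, ny) in kJ/mol with NaN outside the sampled mask; the
    minimum over sampled bins is 0.  ``axis_names[0]`` labels the x axis;
    the distance axis (for productive/nonproductive splits) is declared by
    ``distance_axis`` (0 = x, 1 = y).
    """

    edges_x: np.ndarray
    edges_y: np.ndarray
    dG: np.ndarray
    mask: np.ndarray            # True where sampled
    temperature: float
    counts: np.ndarray | None = None   # effective weight per bin
    axis_names: tuple[str, str] = ("x", "y")
    distance_axis: int = 0

    @property
    def centers_x(self) -> np.ndarray:
        return 0.5 * (self.edges_x[:-1] + self.edges_x[1:])

    @property
    def centers_y(self) -> np.ndarray:
        return 0.5 * (self.edges_y[:-1] + self.edges_y[1:])

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# edges_x " + " ".join(f"{e:.6g}" for e in self.edges_x) + "\n")
            fh.write("# edges_y " + " ".join(f"{e:.6g}" for e in self.edges_y) + "\n")
            fh.write(f"# temperature {self.temperature:.6g}\n")
            np.savetxt(fh, np.where(self.mask, self.dG, np.nan), fmt="%.6g",
                       delimiter="\t")


def pool_replicas(x: np.ndarray, y: np.ndarray, replica_index: np.ndarray,
                  frame_weight: np.ndarray | None = None,
                  scheme: str | Mapping[int, float] = "uniform",
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pool replica-exchange samples into one weighted sample set.

    Each frame's pooled weight is ``frame_weight * replica_weight`` where
    the per-replica weight comes from ``scheme``: the string ``"uniform"``
    (weight 1 for every replica) or a mapping replica index -> weight.
    The mapping must cover every replica present; the study's down-weighting
    of higher replicas is data supplied here, not a built-in rule.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    replica_index = np.asarray(replica_index, int)
    if not (len(x) == len(y) == len(replica_index)):
        raise ValueError("x, y and replica_index must have equal length")
    if frame_weight is None:
        frame_weight = np.ones(len(x))
    if isinstance(scheme, str):
        if scheme != "uniform":
            raise ValueError(f"unknown pooling scheme {scheme!r}")
        rep_w = np.ones(len(x))
    else:
        missing = set(np.unique(replica_index).tolist()) - set(scheme)
        if missing:
            raise ValueError(f"missing replica weight for replicas {sorted(missing)}")
        rep_w = np.array([scheme[int(r)] for r in replica_index], float)
    return x, y, np.asarray(frame_weight, float) * rep_w


def fes2d(x: np.ndarray, y: np.ndarray, w: np.ndarray | None = None,
          bins: int | tuple = 50, temperature: float = 303.0,
          ranges: tuple | None = None, axis_names: tuple[str, str] = ("x", "y"),
          distance_axis: int = 0) -> FESGrid:
    """Weighted 2D histogram -> free-energy surface.

    The probability in each bin is the normalized weighted count;
    ``dG = -k_B T ln(P / P_max)`` over sampled bins.  With ``ranges`` unset
    the sampled range of each coordinate is expanded by 5% on both sides.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if w is None:
        w = np.ones(len(x))
    w = np.asarray(w, float)
    if not (len(x) == len(y) == len(w)):
        raise ValueError("x, y, w must have equal length")
    if not np.any(w > 0):
        raise ValueError("all sample weights are zero")
    if ranges is None:
        ranges = tuple(_expanded_range(v) for v in (x, y))
    H, ex, ey = np.histogram2d(x, y, bins=bins, range=ranges, weights=w)
    mask = H > 0
    P = H / H.sum()
    dG = np.full_like(H, np.nan)
    dG[mask] = -KB_KJ * temperature * np.log(P[mask] / P[mask].max())
    return FESGrid(edges_x=ex, edges_y=ey, dG=dG, mask=mask,
                   temperature=temperature, counts=H,
                   axis_names=axis_names, distance_axis=distance_axis)


def _expanded_range(v: np.ndarray, pad: float = 0.05) -> tuple[float, float]:
    lo, hi = float(v.min()), float(v.max())
    span = hi - lo
    if span == 0:
        span = max(abs(lo), 1.0)
    return lo - pad * span, hi + pad * span


# --------------------------------------------------------------------------
# feature extraction
# --------------------------------------------------------------------------

_NBRS = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]


@dataclass
class FESFeatures:
    """Local minima and the productive/nonproductive barrier of one surface.

    Minima are (i, j, dG) tuples; depths are dG values (global minimum is
    0, so a *deeper* minimum has a smaller value).  ``barrier`` is the
    bottleneck maximum along the minimum-energy path joining the deepest
    productive and nonproductive minima, NaN when either side is absent or
    disconnected.
    """

    productive_minima: list[tuple[int, int, float]]
    nonproductive_minima: list[tuple[int, int, float]]
    productive_depth: float     # NaN when no productive samples
    nonproductive_depth: float
    barrier: float

    def to_json(self, path: str | Path) -> None:
        def clean(v):
            return None if (isinstance(v, float) and np.isnan(v)) else v
        with open(path, "w") as fh:
            json.dump({
                "productive_minima": [[int(i), int(j), float(g)]
                                      for i, j, g in self.productive_minima],
                "nonproductive_minima": [[int(i), int(j), float(g)]
                                         for i, j, g in self.nonproductive_minima],
                "productive_depth": clean(float(self.productive_depth)),
                "nonproductive_depth": clean(float(self.nonproductive_depth)),
                "barrier": clean(float(self.barrier)),
            }, fh, indent=2)


def _local_minima(grid: FESGrid) -> list[tuple[int, int, float]]:
    """Sampled bins not exceeded by any sampled 8-neighbor; equal-valued
    plateaus are collapsed to their lowest (i, j) index."""
    dG, mask = grid.dG, grid.mask
    nx, ny = dG.shape
    cand = []
    for i in range(nx):
        for j in range(ny):
            if not mask[i, j]:
                continue
            ok = True
            for di, dj in _NBRS:
                a, b = i + di, j + dj
                if 0 <= a < nx and 0 <= b < ny and mask[a, b] and dG[a, b] < dG[i, j]:
                    ok = False
                    break
            if ok:
                cand.append((i, j))
    # collapse connected equal-value plateaus to the lowest index
    cand_set = set(cand)
    keep = []
    seen: set[tuple[int, int]] = set()
    for ij in sorted(cand):
        if ij in seen:
            continue
        stack, comp = [ij], []
        while stack:
            p = stack.pop()
            if p in seen:
                continue
            seen.add(p)
            comp.append(p)
            for di, dj in _NBRS:
                q = (p[0] + di, p[1] + dj)
                if q in cand_set and q not in seen and \
                        np.isclose(dG[q], dG[p], atol=1e-12):
                    stack.append(q)
        keep.append(min(comp))
    return [(i, j, float(dG[i, j])) for i, j in sorted(keep)]


def _bottleneck_barrier(grid: FESGrid, start: tuple[int, int],
                        goal: tuple[int, int]) -> float:
    """Minimax dG over 8-connected paths through sampled bins (Dijkstra on
    the bottleneck objective); masked bins are impassable (+inf)."""
    dG, mask = grid.dG, grid.mask
    nx, ny = dG.shape
    best = np.full((nx, ny), np.inf)
    best[start] = dG[start]
    pq = [(dG[start], start)]
    while pq:
        b, (i, j) = heapq.heappop(pq)
        if (i, j) == goal:
            return float(b)
        if b > best[i, j]:
            continue
        for di, dj in _NBRS:
            a, c = i + di, j + dj
            if 0 <= a < nx and 0 <= c < ny and mask[a, c]:
                nb = max(b, dG[a, c])
                if nb < best[a, c]:
                    best[a, c] = nb
                    heapq.heappush(pq, (nb, (a, c)))
    return float("nan")


def fes_features(grid: FESGrid, boundary: float = 4.0) -> FESFeatures:
    """Extract minima (split at ``boundary`` on the distance axis) and the
    productive/nonproductive barrier."""
    centers = grid.centers_x if grid.distance_axis == 0 else grid.centers_y
    minima = _local_minima(grid)
    prod, nonprod = [], []
    for i, j, g in minima:
        c = centers[i] if grid.distance_axis == 0 else centers[j]
        (prod if c < boundary else nonprod).append((i, j, g))
    p_depth = min((g for *_, g in prod), default=float("nan"))
    n_depth = min((g for *_, g in nonprod), default=float("nan"))
    barrier = float("nan")
    if prod and nonprod:
        p_best = min(prod, key=lambda t: t[2])[:2]
        n_best = min(nonprod, key=lambda t: t[2])[:2]
        barrier = _bottleneck_barrier(grid, p_best, n_best)
    return FESFeatures(productive_minima=prod, nonproductive_minima=nonprod,
                       productive_depth=p_depth, nonproductive_depth=n_depth,
                       barrier=barrier)


def compare_fes(parent: FESGrid, variant: FESGrid,
                boundary: float = 4.0) -> set[str]:
    """Classify how a variant's surface differs from its parent's.

    Returns a subset of {stabilized-productive, reduced-nonproductive,
    smoother-path}, each triggered when the corresponding feature shifts by
    more than 1 k_B T (thermal energy at the parent grid's temperature):

    - *stabilized-productive*: the variant's deepest productive minimum is
      deeper relative to its nonproductive minimum than the parent's;
    - *reduced-nonproductive*: the variant's deepest nonproductive minimum
      is shallower (higher dG);
    - *smoother-path*: the variant's productive/nonproductive barrier is
      lower.
    """
    if parent.dG.shape != variant.dG.shape or \
            not np.allclose(parent.edges_x, variant.edges_x) or \
            not np.allclose(parent.edges_y, variant.edges_y):
        raise ValueError("parent and variant grids must share identical binning")
    kbt = KB_KJ * parent.temperature
    fp = fes_features(parent, boundary)
    fv = fes_features(variant, boundary)
    out: set[str] = set()
    rel_p = fp.productive_depth - fp.nonproductive_depth
    rel_v = fv.productive_depth - fv.nonproductive_depth
    if np.isfinite(rel_p) and np.isfinite(rel_v) and rel_v < rel_p - kbt:
        out.add("stabilized-productive")
    if np.isfinite(fp.nonproductive_depth) and np.isfinite(fv.nonproductive_depth) \
            and fv.nonproductive_depth > fp.nonproductive_depth + kbt:
        out.add("reduced-nonproductive")
    if np.isfinite(fp.barrier) and np.isfinite(fv.barrier) \
            and fv.barrier < fp.barrier - kbt:
        out.add("smoother-path")
    return out
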