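"""Low-level distance kernels shared by the analysis modules.

All coordinates are in Angstrom.  Periodic systems use the orthorhombic
minimum-image convention; when no box is given, free space is assumed.
"""
from __future__ import annotations

import numpy as np


def minimum_image(diff: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Apply the orthorhombic minimum-image convention to displacement vectors.

    Parameters
    ----------
    diff : array, shape (..., 3)
        Raw displacement vectors.
    box : array of 3 floats, or None
        Orthorhombic box edge lengths; ``None`` means free space.
    """
    if box is None:
        return diff
    box = np.asarray(box, dtype=float)
    return diff - box * np.round(diff / box)


def pairwise_distances(a: np.ndarray, b: np.ndarray, box: np.ndarray | None = None) -> np.ndarray:
    """All-pairs Euclidean distances between two coordinate sets.

    Returns an (len(a), len(b)) matrix.  Minimum-image applied when a box
    is supplied.
    """
    diff = a[:, None, :] - b[None, :, :]
    diff = minimum_image(diff, box)
    return np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))


def distance(a: np.ndarray, b: np.ndarray, box: np.ndarray | None = None) -> float:
    """Distance between two points under the minimum-image convention."""
    d = minimum_image(np.asarray(b, float) - np.asarray(a, float), box)
    return float(np.linalg.norm(d))
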