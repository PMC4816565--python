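"""Periodic-box distance helpers (orthorhombic, minimum-image)."""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .errors import PBCError, SelectionError

__all__ = ["minimum_image", "pair_distances", "min_distance_to_set"]


def minimum_image(delta: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors."""
    if box is None:
        return delta
    box = np.asarray(box, dtype=float)
    return delta - box * np.round(delta / box)


def pair_distances(points: np.ndarray, origin: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Minimum-image distances from each point to a single origin."""
    delta = minimum_image(np.asarray(points) - np.asarray(origin), box)
    return np.linalg.norm(delta, axis=1)


def min_distance_to_set(
    targets: np.ndarray,
    reference: np.ndarray,
    box: np.ndarray | None,
) -> np.ndarray:
    """Per-target minimum distance to any reference point (minimum image).

    Uses a periodic k-d tree when a box is present.  Raises
    :class:`~solvshell.errors.SelectionError` on empty inputs.
    """
    targets = np.asarray(targets, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if reference.size == 0:
        raise SelectionError("reference point set is empty")
    if targets.size == 0:
        raise SelectionError("target point set is empty")
    if box is None:
        tree = cKDTree(reference)
        d, _ = tree.query(targets, k=1)
        return np.asarray(d, dtype=float)
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise PBCError("box edges must be positive")
    ref_w = np.mod(reference, box)
    tgt_w = np.mod(targets, box)
    # cKDTree's toroidal topology requires coordinates strictly inside [0, box)
    ref_w[ref_w == box] = 0.0
    tgt_w[tgt_w == box] = 0.0
    tree = cKDTree(ref_w, boxsize=box)
    d, _ = tree.query(tgt_w, k=1)
    return np.asarray(d, dtype=float)
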