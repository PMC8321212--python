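"""Exact Euclidean distance fields and the automatic scale quantities Δ and D.

For a pixel p and an edge map S, d_S(p) is the minimum Euclidean distance from
p to any marked pixel of S.  The similarity measures consume two such fields:
d_Gt (distances to the ground truth, penalizing false positives) and d_Dc
(distances to the candidate, penalizing false negatives).

Two image-level scales parameterize the normalized measure M automatically:

* Δ (``delta_max``): the maximum over all image pixels of d_Gt, typically
  attained at an image corner;
* D (``diagonal_length``): the image diagonal, sqrt(height² + width²).

With a nonempty ground truth, Δ < D always holds under these definitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .edgemap import EdgeMap
from .errors import EmptyGroundTruthError, ValidationError

__all__ = ["DistanceStats", "distance_field", "delta_max", "diagonal_length"]


def distance_field(edge_map: EdgeMap) -> np.ndarray:
    """Exact Euclidean distance from every pixel to the nearest marked pixel.

    Returns a float array of the map's shape; zero exactly at marked pixels.
    Distances are true Euclidean (no chamfer approximation).
    """
    if edge_map.is_empty:
        raise EmptyGroundTruthError("distance field of an empty point set is undefined")
    return ndimage.distance_transform_edt(~edge_map.mask)


def delta_max(gt: EdgeMap, over: EdgeMap | None = None) -> float:
    """Δ: the largest distance-to-ground-truth in the image.

    By default the maximum runs over every pixel of the grid, so Δ depends only
    on the ground truth and stays constant across the frames of a sequence.
    Passing ``over`` restricts the maximum to that map's marked pixels (e.g. a
    candidate map), for the frame-dependent variant.
    """
    field = distance_field(gt)
    if over is None:
        return float(field.max())
    if over.shape != gt.shape:
        raise ValidationError("restriction map must match the ground-truth dimensions")
    if over.is_empty:
        raise ValidationError("restriction map has no marked pixels")
    return float(field[over.mask].max())


def diagonal_length(height: int, width: int) -> float:
    """D: the image diagonal sqrt(height² + width²) in pixels."""
    if height < 1 or width < 1:
        raise ValidationError(f"dimensions must be positive, got {height}x{width}")
    return float(np.hypot(height, width))


@dataclass(frozen=True)
class DistanceStats:
    """Automatic scales of an image/ground-truth pair: Δ and D (pixels)."""

    delta: float
    diagonal: float

    @classmethod
    def from_ground_truth(cls, gt: EdgeMap) -> "DistanceStats":
        return cls(delta=delta_max(gt), diagonal=diagonal_length(gt.height, gt.width))

    def __post_init__(self):
        if not (0 <= self.delta <= self.diagonal):
            raise ValidationError(
                f"invalid scales: delta={self.delta}, diagonal={self.diagonal}"
            )
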