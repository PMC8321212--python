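"""Binary edge maps: the container every measure operates on, plus raster I/O.

An edge map is a binary 2-D pixel grid whose marked pixels form the contour of
an object.  The conventions fixed here are relied on everywhere else in the
package: 0-based ``(row, col)`` coordinates, row increasing downward, distances
in pixel units.
"""

from __future__ import annotations

import os
from typing import Iterable

import imageio.v3 as iio
import numpy as np

from .errors import DimensionMismatchError, EmptyGroundTruthError, ValidationError

__all__ = [
    "EdgeMap",
    "read_edge_map",
    "write_edge_map",
    "downscale",
    "validate_pair",
]

# Rec. 709 luma weights, used when a colour image must be reduced to grayscale.
_LUMA = np.array([0.2126, 0.7152, 0.0722])


class EdgeMap:
    """A binary 2-D grid marking contour points.

    Parameters
    ----------
    mask : array-like of bool, shape (height, width)
        True where a pixel belongs to the contour.

    Attributes
    ----------
    mask : ndarray of bool
        The underlying binary grid (never modified in place by the package).
    """

    __slots__ = ("mask",)

    def __init__(self, mask) -> None:
        arr = np.asarray(mask)
        if arr.ndim != 2:
            raise ValidationError(f"edge map must be 2-D, got shape {arr.shape}")
        self.mask = arr.astype(bool, copy=False)

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_points(cls, shape: tuple[int, int], points: Iterable[tuple[int, int]]) -> "EdgeMap":
        """Build a map of the given ``(height, width)`` from (row, col) pairs."""
        h, w = shape
        mask = np.zeros((h, w), dtype=bool)
        for r, c in points:
            if not (0 <= r < h and 0 <= c < w):
                raise ValidationError(f"point ({r}, {c}) outside {h}x{w} grid")
            mask[r, c] = True
        return cls(mask)

    @classmethod
    def empty(cls, shape: tuple[int, int]) -> "EdgeMap":
        return cls(np.zeros(shape, dtype=bool))

    # -- basic geometry -----------------------------------------------------

    @property
    def height(self) -> int:
        return self.mask.shape[0]

    @property
    def width(self) -> int:
        return self.mask.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def size(self) -> int:
        """|I|: total number of pixels in the image grid."""
        return self.mask.size

    @property
    def n_points(self) -> int:
        """|·|: number of marked contour pixels."""
        return int(self.mask.sum())

    @property
    def is_empty(self) -> bool:
        return not self.mask.any()

    def coords(self) -> np.ndarray:
        """Marked pixels as an (n, 2) int array of (row, col), row-major order."""
        return np.argwhere(self.mask)

    def point_set(self) -> frozenset[tuple[int, int]]:
        return frozenset(map(tuple, self.coords()))

    # -- dunder -------------------------------------------------------------

    def __eq__(self, other) -> bool:
        if not isinstance(other, EdgeMap):
            return NotImplemented
        return self.shape == other.shape and bool(np.array_equal(self.mask, other.mask))

    def __hash__(self):  # mutable ndarray inside; maps are compared, not hashed
        raise TypeError("EdgeMap is unhashable")

    def __repr__(self) -> str:
        return f"EdgeMap({self.height}x{self.width}, {self.n_points} points)"


def read_edge_map(path: str | os.PathLike, threshold: float | None = None,
                  invert: bool = False) -> EdgeMap:
    """Read a raster image (PNG/TIFF/BMP) as a binary edge map.

    Multi-channel images are reduced to luminance first.  A pixel is marked iff
    its gray value is >= ``threshold`` (after optional inversion, for files
    that store contours as dark-on-light).  With no threshold given the image
    must already be binary (at most two distinct gray levels); the default cut
    is half of the dtype's dynamic range.
    """
    try:
        img = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - backend specific
        raise IOError(f"cannot read image {path!r}: {exc}") from exc
    img = np.asarray(img)
    if img.ndim == 3:
        img = img[..., :3] @ _LUMA
    if img.ndim != 2:
        raise ValidationError(f"{path!r}: unsupported image layout {img.shape}")

    if threshold is None:
        levels = np.unique(img)
        if levels.size > 2:
            raise ValidationError(
                f"{path!r} has {levels.size} gray levels and no threshold was "
                "given; binarization is ambiguous"
            )
        if np.issubdtype(img.dtype, np.integer):
            threshold = (np.iinfo(img.dtype).max + 1) / 2
        else:
            threshold = (float(img.max()) + float(img.min())) / 2 if levels.size == 2 else 0.5
    if invert:
        mask = img < threshold
    else:
        mask = img >= threshold
    return EdgeMap(mask)


def write_edge_map(edge_map: EdgeMap, path: str | os.PathLike) -> None:
    """Write a map as an 8-bit image: contour pixels 255, background 0.

    Round-trips exactly through :func:`read_edge_map` with default options.
    """
    out = np.where(edge_map.mask, 255, 0).astype(np.uint8)
    try:
        iio.imwrite(path, out)
    except Exception as exc:
        raise IOError(f"cannot write image {path!r}: {exc}") from exc


def downscale(edge_map: EdgeMap, factor: int) -> EdgeMap:
    """Reduce a map by an integer factor with a block-maximum rule.

    An output pixel is marked iff its ``factor x factor`` source block contains
    at least one marked pixel.  This preserves thin 1-px contours, which plain
    subsampling would destroy.  Trailing rows/columns that do not fill a whole
    block are dropped (output dimensions are ``floor(dim / factor)``).
    """
    if factor < 1 or int(factor) != factor:
        raise ValidationError(f"factor must be a positive integer, got {factor!r}")
    factor = int(factor)
    if factor == 1:
        return EdgeMap(edge_map.mask.copy())
    h, w = edge_map.shape
    if factor > h or factor > w:
        raise ValidationError(f"factor {factor} exceeds map dimensions {h}x{w}")
    hh, ww = h // factor, w // factor
    trimmed = edge_map.mask[: hh * factor, : ww * factor]
    blocks = trimmed.reshape(hh, factor, ww, factor)
    return EdgeMap(blocks.any(axis=(1, 3)))


def validate_pair(gt: EdgeMap, dc: EdgeMap) -> None:
    """Check that (ground truth, candidate) can be scored together.

    Dimensions must match and the ground truth must carry at least one contour
    point (every measure divides by |Gt|).  An empty candidate is allowed; each
    measure defines its own degenerate value for it.
    """
    if gt.shape != dc.shape:
        raise DimensionMismatchError(
            f"ground truth is {gt.shape[0]}x{gt.shape[1]} but candidate is "
            f"{dc.shape[0]}x{dc.shape[1]}"
        )
    if gt.is_empty:
        raise EmptyGroundTruthError("ground truth has no contour points")
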