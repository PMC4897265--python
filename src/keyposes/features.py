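"""Radial silhouette-contour pose descriptor.

A binary silhouette mask is reduced to a low-dimensional pose
representation in four steps:

1. the ordered outer boundary of the (largest) foreground component is
   traced with Moore-neighbour border following;
2. the centroid of the contour points and the pointwise Euclidean
   distances from each contour point to it are computed;
3. each contour point is assigned to one of ``S`` radial bins of equal
   angle, sweeping clockwise around the centroid;
4. a scalar summary (variance-sum, max, or range of the centroid
   distances) is taken per bin and the ``S`` summaries are normalised to
   unit sum, which makes the descriptor scale invariant.

The descriptor is translation invariant by construction (everything is
centroid-relative) and rotating the contour by a multiple of the bin
angle cyclically shifts the descriptor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from skimage import measure

logger = logging.getLogger(__name__)

SUMMARY_FUNCTIONS = ("variance", "max", "range")

#: pre-normalisation totals below this are treated as a degenerate
#: (information-free) contour, e.g. a perfect circle under the range summary
DEGENERATE_SUM_TOL = 1e-9


class EmptyMaskError(ValueError):
    """Raised when a silhouette mask contains no foreground pixel."""


class DegenerateContourError(ValueError):
    """Raised when a contour is too short (< 3 points) to describe a pose."""


@dataclass(frozen=True)
class RadialFeatureConfig:
    """Parameters of the radial descriptor.

    Parameters
    ----------
    S:
        Number of radial bins (feature dimensionality). Typical values
        are 8-46; 12 is a good default.
    summary:
        Per-bin summary function: ``"variance"`` (sum of squared
        deviations from the bin mean), ``"max"`` or ``"range"``.
    """

    S: int = 12
    summary: str = "range"

    def __post_init__(self) -> None:
        if self.S < 1:
            raise ValueError(f"S must be >= 1, got {self.S}")
        if self.summary not in SUMMARY_FUNCTIONS:
            raise ValueError(
                f"summary must be one of {SUMMARY_FUNCTIONS}, got {self.summary!r}"
            )


@dataclass(frozen=True)
class PoseFeature:
    """The S-dimensional normalised radial summary vector of one frame."""

    values: np.ndarray
    degenerate: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return len(self.values)

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)


# ---------------------------------------------------------------------------
# mask I/O and contour extraction
# ---------------------------------------------------------------------------

def load_mask(path) -> np.ndarray:
    """Read a PNG/PGM image as a boolean silhouette; any nonzero pixel is
    foreground."""
    arr = np.asarray(Image.open(path))
    if arr.ndim == 3:
        arr = arr.any(axis=2)
    return arr != 0


# clockwise Moore neighbourhood in (row, col) offsets, starting north
_MOORE = ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1))
_MOORE_INDEX = {off: k for k, off in enumerate(_MOORE)}


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = measure.label(mask, connectivity=2, return_num=True)
    if n <= 1:
        return mask
    logger.warning("mask has %d foreground components; using the largest", n)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    return labels == sizes.argmax()


def extract_contour(mask: np.ndarray) -> np.ndarray:
    """Trace the ordered outer boundary of the largest foreground component.

    Returns an ``(n, 2)`` float array of ``(x, y)`` pixel coordinates in a
    fixed (clockwise, for y growing downward) traversal order, starting at
    the topmost-then-leftmost foreground pixel.  Every returned point is a
    foreground pixel with a background 8-neighbour.

    Raises
    ------
    EmptyMaskError
        If the mask has no foreground pixel.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("mask contains no foreground pixels")
    fg = _largest_component(mask)
    h, w = fg.shape

    rows, cols = np.nonzero(fg)
    start = (int(rows[0]), int(cols[0]))  # topmost, then leftmost

    def is_fg(p):
        return 0 <= p[0] < h and 0 <= p[1] < w and fg[p]

    def next_boundary(cur, backtrack):
        # search Moore neighbours clockwise, starting just after the
        # backtrack direction; return (next pixel, its new backtrack)
        i = _MOORE_INDEX[(backtrack[0] - cur[0], backtrack[1] - cur[1])]
        for k in range(1, 9):
            dr, dc = _MOORE[(i + k) % 8]
            cand = (cur[0] + dr, cur[1] + dc)
            if is_fg(cand):
                pr, pc = _MOORE[(i + k - 1) % 8]
                return cand, (cur[0] + pr, cur[1] + pc)
        return None, None  # isolated pixel

    # the west neighbour of the scan-order start pixel is always background
    state = (start, (start[0], start[1] - 1))
    seen = set()
    points = []
    while state not in seen:
        seen.add(state)
        cur, backtrack = state
        points.append(cur)
        nxt, nb = next_boundary(cur, backtrack)
        if nxt is None:
            break
        state = (nxt, nb)

    # (row, col) -> (x, y)
    return np.array([(c, r) for r, c in points], dtype=float)


# ---------------------------------------------------------------------------
# radial binning
# ---------------------------------------------------------------------------

def centroid(contour: np.ndarray) -> tuple[float, float]:
    """Arithmetic mean (x_c, y_c) of the contour points (not rounded)."""
    contour = np.asarray(contour, dtype=float)
    if contour.size == 0:
        raise ValueError("cannot take the centroid of an empty contour")
    xc, yc = contour.mean(axis=0)
    return float(xc), float(yc)


def centroid_distances(contour: np.ndarray, c: tuple[float, float]) -> np.ndarray:
    """Euclidean distance d_i from each contour point to the centroid."""
    contour = np.asarray(contour, dtype=float)
    if contour.size == 0:
        raise ValueError("empty contour")
    return np.hypot(contour[:, 0] - c[0], contour[:, 1] - c[1])


def bin_assignment(contour: np.ndarray, c: tuple[float, float], S: int) -> np.ndarray:
    """Assign each contour point to a radial bin in {1..S}.

    The angle of each point about the centroid is measured in image
    coordinates (y grows downward) as ``alpha = arccos(dy/d)`` degrees for
    ``dx >= 0`` and ``360 - arccos(dy/d)`` otherwise, so that alpha sweeps
    (0, 360] consistently around the centroid; ``alpha = 0`` is mapped to
    360.  The bin is ``ceil(S * alpha / 360)``; an angle exactly on a bin
    boundary belongs to the lower-index bin.  A point coinciding with the
    centroid (d = 0, where the angle is undefined) goes to bin 1.
    """
    if S < 1:
        raise ValueError(f"S must be >= 1, got {S}")
    contour = np.asarray(contour, dtype=float)
    dx = contour[:, 0] - c[0]
    dy = contour[:, 1] - c[1]
    d = np.hypot(dx, dy)
    ratio = np.divide(dy, d, out=np.ones_like(d), where=d > 0)
    # clamp: rounding can push dy/d marginally outside [-1, 1]
    base = np.degrees(np.arccos(np.clip(ratio, -1.0, 1.0)))
    alpha = np.where(dx >= 0, base, 360.0 - base)
    alpha = np.where(alpha == 0.0, 360.0, alpha)
    bins = np.ceil(S * alpha / 360.0).astype(int)
    bins = np.where(d > 0, bins, 1)
    return bins


def summarize_bin(bin_distances, fn: str) -> float:
    """Scalar summary of the centroid distances of one radial bin.

    ``variance`` is the sum of squared deviations from the bin mean (no
    division by the count), ``max`` the largest distance and ``range`` the
    spread max - min.  An empty bin summarises to 0.
    """
    dists = np.asarray(bin_distances, dtype=float)
    if dists.size == 0:
        return 0.0
    if fn == "variance":
        return float(np.sum((dists - dists.mean()) ** 2))
    if fn == "max":
        return float(dists.max())
    if fn == "range":
        return float(dists.max() - dists.min())
    raise ValueError(f"unknown summary function {fn!r}")


def pose_feature_from_contour(
    contour: np.ndarray, cfg: RadialFeatureConfig
) -> PoseFeature:
    """Radial descriptor of an already-extracted (or synthetic) contour.

    Operates on arbitrary real-valued ``(x, y)`` point lists, which makes
    exact geometric transformations (rotation, scaling about the centroid)
    testable without rasterisation.
    """
    contour = np.asarray(contour, dtype=float)
    if len(contour) < 3:
        raise DegenerateContourError(
            f"contour has {len(contour)} points; at least 3 are required"
        )
    # work relative to the contour minimum so integer translations of the
    # input change nothing, bit for bit (the centroid's float division
    # otherwise rounds differently under large coordinate offsets)
    rel = contour - contour.min(axis=0)
    c = centroid(rel)
    d = centroid_distances(rel, c)
    bins = bin_assignment(rel, c, cfg.S)
    v = np.array(
        [summarize_bin(d[bins == j], cfg.summary) for j in range(1, cfg.S + 1)]
    )
    total = v.sum()
    if total < DEGENERATE_SUM_TOL:
        return PoseFeature(np.zeros(cfg.S), degenerate=True)
    return PoseFeature(v / total, degenerate=False)


def pose_feature(mask: np.ndarray, cfg: RadialFeatureConfig) -> PoseFeature:
    """Extract the S-dimensional radial pose descriptor of one silhouette."""
    contour = extract_contour(mask)
    if len(contour) < 3:
        raise DegenerateContourError(
            f"silhouette yields only {len(contour)} contour points (need >= 3)"
        )
    return pose_feature_from_contour(contour, cfg)
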