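"""Chest-wall boundary tracing and nipple-anchored view bisection.

Orientation convention (see :mod:`mammoquad.image`): chest wall at the left
image edge, superior at the top, both lateralities (right-breast images are
pre-flipped). Coordinates are ``(row, col)``.

* On the CC view the chest wall coincides with the left image edge; the view
  is split by a horizontal line through the nipple into the lateral (CC-L)
  and medial (CC-M) halves. Which half is lateral follows from laterality:
  with a left breast in this convention the superior half of the CC image is
  the lateral side.
* On the MLO view the pectoral muscle occupies an oblique band along the
  chest edge. Starting from an operator seed point P on the breast-muscle
  interface, the boundary is traced row by row along the locus of maximum
  intensity-gradient magnitude, smoothed with a cubic B-spline, and the
  tangent at the curve's arc-length midpoint defines the chest-wall "edge
  line". The view is split by the line through the nipple perpendicular to
  that edge line into superior (MLO-S) and inferior (MLO-I) halves, and the
  muscle side of the traced curve is excluded from the breast mask.

Tie rule: pixels exactly on a bisecting line go to the lateral (CC) or
superior (MLO) partition, so the two partitions always tile the breast mask
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import interpolate
from skimage import filters

from .errors import ChestWallTraceError, InputError, LandmarkError
from .image import MammogramImage

__all__ = [
    "ChestWallBoundary",
    "ViewPartition",
    "trace_chest_wall",
    "bisect_cc",
    "bisect_mlo",
    "exclude_muscle",
]

#: gradient-trace column search window (+- columns per row step)
TRACE_WINDOW = 5
#: maximum spline residual against the traced points, pixels
SPLINE_MAX_RESIDUAL = 3.0
#: minimum number of traced rows for a valid boundary
MIN_TRACE_POINTS = 8

#: which CC half-view (by image side) carries the lateral label, per
#: laterality, under the chest-left/superior-top convention
CC_LATERAL_SIDE = {"L": "top", "R": "bottom"}


@dataclass
class ChestWallBoundary:
    """Traced and spline-smoothed breast-muscle interface on an MLO view.

    ``edge_line`` is the tangential line at the arc-length midpoint of the
    fitted curve, as ``(point, unit_direction)`` with the direction oriented
    from superior (small row) to inferior.
    """

    seed_point: tuple[int, int]
    traced_points: np.ndarray          # (n, 2) rows ascending
    spline_control_points: np.ndarray  # (n_c, 2)
    edge_line: tuple[np.ndarray, np.ndarray]
    _tck: tuple | None = None

    def col_at(self, rows: np.ndarray) -> np.ndarray:
        """Interface column at the given rows; outside the traced range the
        curve is extended linearly along the global edge-line tangent (the
        local end tangents are noise-sensitive and can fold the cut back
        into the breast)."""
        rows = np.asarray(rows, dtype=float)
        r0, r1 = self.traced_points[0, 0], self.traced_points[-1, 0]
        cols = interpolate.splev(np.clip(rows, r0, r1), self._tck)
        d = self.edge_line[1]
        slope = d[1] / d[0]  # d[0] > 0 by construction
        c0 = float(interpolate.splev(r0, self._tck))
        c1 = float(interpolate.splev(r1, self._tck))
        cols = np.where(rows < r0, c0 + slope * (rows - r0), cols)
        cols = np.where(rows > r1, c1 + slope * (rows - r1), cols)
        return cols


@dataclass
class ViewPartition:
    """A view split into two half-view partitions by a nipple bisector.

    ``masks`` maps each label (CC-L/CC-M or MLO-S/MLO-I) to a boolean mask;
    the two masks are disjoint and union to the breast mask.
    ``bisecting_line`` is ``(point, unit_direction)`` through the nipple.
    """

    view: str
    bisecting_line: tuple[np.ndarray, np.ndarray]
    masks: dict[str, np.ndarray]

    @property
    def labels(self) -> tuple[str, str]:
        return tuple(self.masks)


def _fit_spline(rows: np.ndarray, cols: np.ndarray):
    """Cubic smoothing spline col(row), with the smoothing factor relaxed
    until the worst residual is within SPLINE_MAX_RESIDUAL pixels."""
    n = rows.size
    for s in (9.0 * n, 4.0 * n, float(n), n / 4.0, 0.0):
        tck = interpolate.splrep(rows, cols, k=min(3, n - 1), s=s)
        resid = np.max(np.abs(interpolate.splev(rows, tck) - cols))
        if resid <= SPLINE_MAX_RESIDUAL:
            return tck
    return tck  # s = 0 interpolates: residual is zero


def trace_chest_wall(
    image: MammogramImage,
    P: tuple[int, int],
    window: int = TRACE_WINDOW,
) -> ChestWallBoundary:
    """Trace the breast-muscle interface from seed point ``P``.

    From P the trace follows the maximum gradient-magnitude column upward and
    downward one row at a time, searching ``+-window`` columns around the
    previous point. A direction stops when the local gradient falls below
    30% of the seed gradient (the muscle wedge has ended) or the image edge
    is reached. The traced points are fitted with a cubic B-spline.

    Raises
    ------
    InputError
        P outside the image.
    ChestWallTraceError
        Seed gradient indistinguishable from background (P not on an
        interface), or fewer than ``MIN_TRACE_POINTS`` rows traced; the
        message names the failing row.
    """
    nrows, ncols = image.shape
    r0, c0 = int(P[0]), int(P[1])
    if not (0 <= r0 < nrows and 0 <= c0 < ncols):
        raise InputError(f"seed point {P} outside image {image.shape}")

    grad = filters.sobel(image.pixels)
    # snap the seed onto the local gradient ridge
    lo, hi = max(0, c0 - window), min(ncols, c0 + window + 1)
    c0 = lo + int(np.argmax(grad[r0, lo:hi]))
    g0 = grad[r0, c0]
    floor = max(4.0 * float(np.median(grad)), 1e-3 * float(grad.max()), 1e-12)
    if g0 < floor:
        raise ChestWallTraceError(
            f"no gradient ridge at seed row {r0}: gradient {g0:.3g} below "
            f"floor {floor:.3g} (seed not on an interface?)"
        )
    keep = 0.3 * g0

    def _walk(step: int) -> list[tuple[int, int]]:
        pts = []
        r, c = r0, c0
        while True:
            r += step
            if not (0 <= r < nrows):
                break
            lo = max(0, c - window)
            hi = min(ncols, c + window + 1)
            c_new = lo + int(np.argmax(grad[r, lo:hi]))
            if grad[r, c_new] < keep:
                break
            c = c_new
            pts.append((r, c))
        return pts

    up = _walk(-1)
    down = _walk(+1)
    pts = list(reversed(up)) + [(r0, c0)] + down
    if len(pts) < MIN_TRACE_POINTS:
        fail_row = (up[-1][0] - 1) if up else (down[-1][0] + 1 if down else r0)
        raise ChestWallTraceError(
            f"gradient ridge lost at row {fail_row}: only {len(pts)} "
            f"interface rows traced (need {MIN_TRACE_POINTS})"
        )

    traced = np.asarray(pts, dtype=float)
    rows, cols = traced[:, 0], traced[:, 1]
    tck = _fit_spline(rows, cols)

    # tangent at the arc-length midpoint
    rr = np.linspace(rows[0], rows[-1], 256)
    cc = interpolate.splev(rr, tck)
    seglen = np.hypot(np.diff(rr), np.diff(cc))
    arclen = np.concatenate(([0.0], np.cumsum(seglen)))
    i_mid = int(np.searchsorted(arclen, arclen[-1] / 2.0))
    i_mid = min(max(i_mid, 0), rr.size - 1)
    r_mid = rr[i_mid]
    dcol = float(interpolate.splev(r_mid, tck, der=1))
    direction = np.array([1.0, dcol])
    direction /= np.linalg.norm(direction)
    point = np.array([r_mid, float(interpolate.splev(r_mid, tck))])

    knots, coeffs, _k = tck
    ctrl = np.column_stack([knots[: len(coeffs)], coeffs])
    return ChestWallBoundary(
        seed_point=(r0, c0),
        traced_points=traced,
        spline_control_points=ctrl,
        edge_line=(point, direction),
        _tck=tck,
    )


def exclude_muscle(breast_mask: np.ndarray, boundary: ChestWallBoundary
                   ) -> np.ndarray:
    """Remove the pectoral muscle from an MLO foreground mask: pixels on the
    chest side (smaller column) of the traced curve are dropped."""
    breast_mask = np.asarray(breast_mask, bool)
    rows = np.arange(breast_mask.shape[0], dtype=float)
    cut = boundary.col_at(rows)
    cols = np.arange(breast_mask.shape[1], dtype=float)
    muscle_side = cols[None, :] < cut[:, None]
    return breast_mask & ~muscle_side


def _check_nipple(breast_mask: np.ndarray, nipple: tuple[float, float]) -> None:
    rows, cols = np.nonzero(breast_mask)
    if rows.size == 0:
        raise InputError("breast_mask is empty")
    r, c = nipple
    if not (rows.min() <= r <= rows.max() and cols.min() <= c <= cols.max()):
        raise LandmarkError(
            f"nipple {nipple} outside breast bounding box "
            f"[{rows.min()}..{rows.max()}, {cols.min()}..{cols.max()}]"
        )


def bisect_cc(
    breast_mask: np.ndarray,
    nipple: tuple[float, float],
    laterality: str,
) -> ViewPartition:
    """Split a CC view into medial (CC-M) and lateral (CC-L) halves.

    The chest wall is the (vertical) left image edge, so the bisecting line
    through the nipple perpendicular to it is horizontal. Pixels exactly on
    the line go to the lateral half.
    """
    if laterality not in CC_LATERAL_SIDE:
        raise InputError(f"laterality must be L or R, got {laterality!r}")
    breast_mask = np.asarray(breast_mask, bool)
    _check_nipple(breast_mask, nipple)
    nr = float(nipple[0])
    rows = np.arange(breast_mask.shape[0], dtype=float)[:, None]
    if CC_LATERAL_SIDE[laterality] == "top":
        lateral = (rows <= nr) & breast_mask
    else:
        lateral = (rows >= nr) & breast_mask
    medial = breast_mask & ~lateral
    point = np.asarray(nipple, dtype=float)
    direction = np.array([0.0, 1.0])
    return ViewPartition(
        view="CC",
        bisecting_line=(point, direction),
        masks={"CC-L": lateral, "CC-M": medial},
    )


def bisect_mlo(
    breast_mask: np.ndarray,
    nipple: tuple[float, float],
    boundary: ChestWallBoundary,
) -> ViewPartition:
    """Split an MLO view into superior (MLO-S) and inferior (MLO-I) halves.

    The bisecting line runs through the nipple perpendicular to the chest
    edge line; pixels are classified by their signed offset along the edge
    direction. The superior half is the side containing the superior end of
    the traced chest boundary. Pixels exactly on the line go to MLO-S.

    ``breast_mask`` should already have the muscle excluded
    (:func:`exclude_muscle`).
    """
    breast_mask = np.asarray(breast_mask, bool)
    _check_nipple(breast_mask, nipple)
    point, d = boundary.edge_line
    nr, nc = float(nipple[0]), float(nipple[1])
    rows = np.arange(breast_mask.shape[0], dtype=float)[:, None]
    cols = np.arange(breast_mask.shape[1], dtype=float)[None, :]
    s = (rows - nr) * d[0] + (cols - nc) * d[1]

    top_end = boundary.traced_points[0]  # rows ascending: first is superior
    s_top = (top_end[0] - nr) * d[0] + (top_end[1] - nc) * d[1]
    sign_sup = 1.0 if s_top >= 0 else -1.0

    superior = (sign_sup * s >= 0) & breast_mask
    inferior = breast_mask & ~superior
    perp = np.array([-d[1], d[0]])
    return ViewPartition(
        view="MLO",
        bisecting_line=(np.array([nr, nc]), perp),
        masks={"MLO-S": superior, "MLO-I": inferior},
    )
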