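"""Extraction of biophysical parameters from cell-stretching image sequences.

A deformability-cytometry event is a short grayscale movie of one cell
passing through an extensional-flow junction.  This module turns such a
frame stack into a 15-parameter biophysical profile:

========  ==========================================================
A         initial equivalent diameter (um), median over pre-junction frames
C1        initial circularity 4*pi*area/perimeter^2
D1-D4     deformability (major/minor axis of the moment-equivalent
          ellipse) at junction arrival / junction mean / junction max /
          final frame
T1        time from junction arrival to maximum deformability (us)
T2        maximum strain rate between consecutive junction frames (1/us)
S1, S2    maximum strain and residual (final-frame) strain, with strain
          defined as (major axis - A)/A
M1, M2    pre-stretch boundary roughness and trace/moving-average
          intersection count
M3, M4    the same morphology metrics on the maximally deformed frame
AR1       area at maximum deformation / initial area
========  ==========================================================

Segmentation assumes a dark cell on a bright background (brightfield
contrast).  Contours are extracted at sub-pixel resolution with a
marching-squares iso-contour at the segmentation threshold, and shape
moments are computed from the contour polygon so that deformability is
rotation invariant and robust to +-1 px boundary error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu

#: Canonical column order of the 15-parameter profile.
PARAMETER_NAMES = (
    "A", "C1", "D1", "D2", "D3", "D4",
    "T1", "T2", "S1", "S2",
    "M1", "M2", "M3", "M4", "AR1",
)

DEFAULT_WINDOW = 31


class NoCellError(ValueError):
    """Raised when a frame contains no segmentable cell."""


class DegenerateShapeError(ValueError):
    """Raised for shapes on which a radial trace or axis ratio is undefined."""


class EventRejected(ValueError):
    """Raised when an event cannot yield a profile; carries a reason code."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass
class BoundaryTrace:
    """Radial boundary function r(theta) sampled at uniform angles.

    The polar transform of the cell boundary: ``radii[k]`` is the distance
    from the area centroid to the boundary along angle
    ``theta_k = 2*pi*k/n_angles``.  The trace is periodic in theta.
    """

    frame_index: int
    centroid: tuple[float, float]
    radii: np.ndarray
    n_angles: int = 360

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        if self.radii.shape != (self.n_angles,):
            raise ValueError("radii length must equal n_angles")
        if not np.all(np.isfinite(self.radii)) or np.any(self.radii <= 0):
            raise DegenerateShapeError("trace radii must be positive and finite")


@dataclass
class BiophysicalProfile:
    """The 15-parameter biophysical fingerprint of one cell event."""

    A: float
    C1: float
    D1: float
    D2: float
    D3: float
    D4: float
    T1: float
    T2: float
    S1: float
    S2: float
    M1: float
    M2: int
    M3: float
    M4: int
    AR1: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, p) for p in PARAMETER_NAMES], dtype=float)

    def as_dict(self) -> dict[str, float]:
        return {p: getattr(self, p) for p in PARAMETER_NAMES}


# ---------------------------------------------------------------------------
# segmentation


def segment_frame(
    image: np.ndarray,
    method: str = "otsu",
    threshold: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Segment the (single, dark) cell in a frame.

    Returns ``(mask, contour)`` where ``mask`` is the filled largest
    connected foreground component and ``contour`` an ordered closed
    boundary polygon in (row, col) sub-pixel coordinates.

    Raises
    ------
    NoCellError
        if no foreground pixels exist (blank frame).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    if not np.all(np.isfinite(image)):
        raise ValueError("image intensities must be finite")

    if method == "otsu":
        if np.ptp(image) == 0:
            raise NoCellError("constant image")
        thr = float(threshold_otsu(image))
    elif method == "fixed":
        if threshold is None:
            raise ValueError("fixed method requires a threshold")
        thr = float(threshold)
    else:
        raise ValueError(f"unknown segmentation method {method!r}")

    fg = image < thr  # dark object on bright background
    if not fg.any():
        raise NoCellError("no foreground pixels below threshold")

    labels, n = ndimage.label(fg)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    mask = ndimage.binary_fill_holes(labels == keep)

    # refine the contour level to the half-maximum between the cell and
    # background plateaus: under a symmetric PSF that iso-line sits on the
    # true object boundary, while the raw threshold can be biased inward
    interior = ndimage.binary_erosion(mask, iterations=3)
    exterior = ~ndimage.binary_dilation(mask, iterations=3)
    if interior.any() and exterior.any():
        level = 0.5 * (np.median(image[interior]) + np.median(image[exterior]))
    else:
        level = thr
    contour = _iso_contour(image, level, mask)
    return mask, contour


def _iso_contour(image: np.ndarray, level: float, mask: np.ndarray) -> np.ndarray:
    """Closed sub-pixel iso-contour at the segmentation level around `mask`."""
    com = ndimage.center_of_mass(mask)
    best, best_area = None, 0.0
    for c in measure.find_contours(image, level):
        if not np.allclose(c[0], c[-1]):
            continue
        area = abs(_shoelace(c))
        # keep the largest closed contour containing the mask centroid
        if area > best_area and measure.points_in_poly([com], c)[0]:
            best, best_area = c, area
    if best is None:
        # fall back to the binary mask boundary (e.g. heavy noise broke the
        # grayscale iso-contour)
        cs = measure.find_contours(mask.astype(float), 0.5)
        if not cs:
            raise NoCellError("no closed contour found")
        best = max(cs, key=lambda c: abs(_shoelace(c)))
    return best


def _shoelace(poly: np.ndarray) -> float:
    x, y = poly[:, 1], poly[:, 0]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


# ---------------------------------------------------------------------------
# polygon moments and deformability


def polygon_area_centroid(poly: np.ndarray) -> tuple[float, tuple[float, float]]:
    """Signed-area magnitude and area centroid of a closed (row, col) polygon."""
    r, c = poly[:, 0], poly[:, 1]
    r1, c1 = np.roll(r, -1), np.roll(c, -1)
    cross = c * r1 - c1 * r
    a = 0.5 * np.sum(cross)
    if a == 0:
        raise DegenerateShapeError("zero-area polygon")
    cr = np.sum((r + r1) * cross) / (6.0 * a)
    cc = np.sum((c + c1) * cross) / (6.0 * a)
    return abs(float(a)), (float(cr), float(cc))


def polygon_perimeter(poly: np.ndarray) -> float:
    return float(np.sum(np.hypot(*np.diff(poly, axis=0).T)))


def _polygon_second_moments(poly: np.ndarray) -> np.ndarray:
    """Per-unit-area central second-moment (covariance) matrix of a polygon."""
    r, c = poly[:, 0], poly[:, 1]
    r1, c1 = np.roll(r, -1), np.roll(c, -1)
    cross = c * r1 - c1 * r
    a = 0.5 * np.sum(cross)
    if a == 0:
        raise DegenerateShapeError("zero-area polygon")
    cr = np.sum((r + r1) * cross) / (6.0 * a)
    cc = np.sum((c + c1) * cross) / (6.0 * a)
    irr = np.sum((r * r + r * r1 + r1 * r1) * cross) / 12.0
    icc = np.sum((c * c + c * c1 + c1 * c1) * cross) / 12.0
    irc = np.sum((c * r1 + 2 * c * r + 2 * c1 * r1 + c1 * r) * cross) / 24.0
    cov = np.array([
        [irr / a - cr * cr, irc / a - cr * cc],
        [irc / a - cr * cc, icc / a - cc * cc],
    ])
    return cov


def deformability(shape: np.ndarray) -> float:
    """Major/minor axis ratio of the moment-equivalent ellipse (>= 1).

    Accepts either a binary mask (2-D bool/int array) or a closed contour
    polygon (N x 2 float array of (row, col) points).  Rotation invariant.
    """
    shape = np.asarray(shape)
    if shape.ndim == 2 and shape.shape[1] == 2 and shape.dtype.kind == "f":
        cov = _polygon_second_moments(shape)
    elif shape.ndim == 2:
        rows, cols = np.nonzero(shape)
        if rows.size == 0:
            raise DegenerateShapeError("empty mask")
        pts = np.column_stack([rows, cols]).astype(float)
        cov = np.cov(pts.T, bias=True)
    else:
        raise ValueError("expected a mask or an N x 2 contour")
    ev = np.linalg.eigvalsh(np.atleast_2d(cov))
    if ev[0] <= 0:
        raise DegenerateShapeError("degenerate (zero-variance) shape")
    return float(np.sqrt(ev[1] / ev[0]))


def major_axis_length(contour: np.ndarray) -> float:
    """Full major-axis length (px) of the moment-equivalent ellipse."""
    ev = np.linalg.eigvalsh(_polygon_second_moments(contour))
    return float(4.0 * np.sqrt(max(ev[1], 0.0)))


# ---------------------------------------------------------------------------
# radial trace


def contour_to_trace(
    contour: np.ndarray, n_angles: int = 360, frame_index: int = 0
) -> BoundaryTrace:
    """Polar transform of a closed contour: r(theta) by ray casting.

    Rays are cast from the area centroid at ``n_angles`` uniformly spaced
    angles; each ray's intersection with the contour polygon is found by
    linear interpolation along the crossed edge.  Requires the shape to be
    star convex about its centroid (one intersection per ray).
    """
    contour = np.asarray(contour, dtype=float)
    if len(contour) < 8:
        raise ValueError("contour needs at least 8 points")
    if not np.allclose(contour[0], contour[-1]):
        contour = np.vstack([contour, contour[0]])
    _, (cr, cc) = polygon_area_centroid(contour)
    if not measure.points_in_poly([(cr, cc)], contour)[0]:
        raise DegenerateShapeError("centroid outside contour (non-star-convex)")

    p = contour[:-1] - (cr, cc)          # edge start points, centroid origin
    q = contour[1:] - (cr, cc)           # edge end points
    theta = 2 * np.pi * np.arange(n_angles) / n_angles
    u = np.column_stack([np.sin(theta), np.cos(theta)])  # (row, col) direction

    radii = np.empty(n_angles)
    # per-angle vectorized ray/edge intersection
    d = q - p
    for k in range(n_angles):
        uk = u[k]
        denom = d[:, 0] * uk[1] - d[:, 1] * uk[0]
        with np.errstate(divide="ignore", invalid="ignore"):
            s = (p[:, 1] * uk[0] - p[:, 0] * uk[1]) / denom
            t = (p[:, 1] * d[:, 0] - p[:, 0] * d[:, 1]) / denom
        hit = (denom != 0) & (s >= 0) & (s <= 1) & (t > 0)
        if not hit.any():
            raise DegenerateShapeError(f"no boundary intersection at angle {k}")
        radii[k] = t[hit].max()
    return BoundaryTrace(frame_index=frame_index, centroid=(cr, cc),
                         radii=radii, n_angles=n_angles)


def trace_area(trace: BoundaryTrace | np.ndarray) -> float:
    """Enclosed area from a radial trace, (1/2) * integral of r^2 dtheta."""
    r = trace.radii if isinstance(trace, BoundaryTrace) else np.asarray(trace)
    return float(0.5 * np.sum(r**2) * (2 * np.pi / r.size))


# ---------------------------------------------------------------------------
# morphology metrics


def morphology_metrics(
    trace: BoundaryTrace | np.ndarray, window: int = DEFAULT_WINDOW
) -> tuple[float, int]:
    """Boundary roughness and trace/moving-average intersection count.

    The moving average is the circular (wrap-around) mean of r over
    ``window`` samples.  Roughness is SD(r - moving average)/mean(r); the
    intersection count is the number of sign changes of the residual over
    the closed trace, a run of exact zeros between opposite signs counting
    as a single crossing.  Both are invariant to the starting angle.
    """
    r = trace.radii if isinstance(trace, BoundaryTrace) else np.asarray(trace, float)
    n = r.size
    if window % 2 == 0 or window < 3 or window > n // 2:
        raise ValueError("window must be odd and within [3, n_angles/2]")
    idx = (np.arange(n)[:, None] + np.arange(-(window // 2), window // 2 + 1)) % n
    avg = r[idx].mean(axis=1)
    resid = r - avg
    roughness = float(np.std(resid) / np.mean(r))

    signs = np.sign(resid)
    nz = signs[signs != 0]
    if nz.size == 0:
        return 0.0, 0
    crossings = int(np.sum(nz != np.roll(nz, 1)))
    return roughness, crossings


# ---------------------------------------------------------------------------
# per-event profile extraction


def extract_profile(event, window: int = DEFAULT_WINDOW) -> BiophysicalProfile:
    """Extract the 15-parameter profile from one cell event.

    Junction residence is taken as the frames from ``junction_arrival_index``
    up to the frame of maximum deformability; frames before arrival are the
    undeformed reference used for A, C1, M1 and M2.

    Raises
    ------
    EventRejected
        if more than 20% of frames fail segmentation, or no pre-junction /
        junction frames are available.
    """
    frames = event.frames
    arrival = event.junction_arrival_index
    if arrival < 1 or arrival >= len(frames):
        raise EventRejected("no-pre-junction-frames")

    n = len(frames)
    contours: list[np.ndarray | None] = []
    n_fail = 0
    for img in frames:
        try:
            _, contour = segment_frame(img)
            contours.append(contour)
        except (NoCellError, DegenerateShapeError):
            contours.append(None)
            n_fail += 1
    if n_fail > 0.2 * n:
        raise EventRejected("segmentation-failed")
    if all(c is None for c in contours[:arrival]):
        raise EventRejected("no-pre-junction-segmentation")
    if all(c is None for c in contours[arrival:]):
        raise EventRejected("no-junction-segmentation")

    px = event.pixel_size
    dt = event.frame_interval

    areas = np.array([polygon_area_centroid(c)[0] if c is not None else np.nan
                      for c in contours])
    defos = np.array([deformability(c) if c is not None else np.nan
                      for c in contours])
    majors = np.array([major_axis_length(c) if c is not None else np.nan
                       for c in contours])

    pre = slice(0, arrival)
    A = float(np.nanmedian(2 * np.sqrt(areas[pre] / np.pi))) * px
    perims = np.array([polygon_perimeter(c) if c is not None else np.nan
                       for c in contours[:arrival]])
    C1 = float(np.nanmedian(4 * np.pi * areas[pre] / perims**2))

    d3_index = arrival + int(np.nanargmax(defos[arrival:]))
    junction = slice(arrival, d3_index + 1)

    strain = (majors * px - A) / A
    D1 = float(defos[arrival]) if np.isfinite(defos[arrival]) else float(
        np.nanmean(defos[junction]))
    D2 = float(np.nanmean(defos[junction]))
    D3 = float(defos[d3_index])
    D4 = float(defos[-1]) if np.isfinite(defos[-1]) else float(defos[d3_index])
    T1 = (d3_index - arrival) * dt
    js = strain[junction]
    if js.size >= 2:
        T2 = float(np.nanmax(np.diff(js))) / dt
    else:
        T2 = 0.0
    S1 = float(np.nanmax(js))
    S2 = float(strain[-1]) if np.isfinite(strain[-1]) else float(js[-1])

    pre_contour = next(c for c in contours[:arrival] if c is not None)
    m_pre = morphology_metrics(contour_to_trace(pre_contour), window)
    m_junc = morphology_metrics(
        contour_to_trace(contours[d3_index], frame_index=d3_index), window)
    AR1 = float(areas[d3_index] / np.nanmedian(areas[pre]))

    return BiophysicalProfile(
        A=A, C1=C1, D1=D1, D2=D2, D3=D3, D4=D4,
        T1=T1, T2=max(T2, 0.0), S1=S1, S2=S2,
        M1=m_pre[0], M2=m_pre[1], M3=m_junc[0], M4=m_junc[1], AR1=AR1,
    )


def batch_extract(
    events: Sequence, window: int = DEFAULT_WINDOW
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Extract profiles for many events.

    Returns a feature table (one row per accepted event, canonical column
    order, indexed by ``event_id``) and a rejection log of
    ``(event_id, reason)`` pairs.  Order is deterministic (input order).
    """
    if len(events) == 0:
        raise ValueError("events must be nonempty")
    rows, index, rejected = [], [], []
    for ev in events:
        try:
            prof = extract_profile(ev, window=window)
        except EventRejected as e:
            rejected.append((ev.event_id, e.reason))
            continue
        rows.append(prof.as_dict())
        index.append(ev.event_id)
    table = pd.DataFrame(rows, index=pd.Index(index, name="event_id"),
                         columns=list(PARAMETER_NAMES))
    if table.empty:
        import warnings

        warnings.warn("all events rejected", stacklevel=2)
    return table, rejected
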