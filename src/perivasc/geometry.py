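"""Capillary localisation and vessel straightening.

The vessel channel (SR101) shows the capillary as a single bright tube.
This module extracts a sub-pixel centerline from that image, estimates the
vessel radius, and resamples any image of the same field into a
"straightened" frame whose rows run along the vessel axis and whose columns
are signed perpendicular offsets from the centerline.  All vessel-centric
profile statistics downstream operate on straightened frames.

Coordinate conventions: 0-based (row, col) indices, pixel-center sampling.
The signed offset of straightened column ``j`` is ``(j - W//2) * spacing``;
column 0 is the most negative offset.  Excluded samples (outside the image,
or masked upstream) are NaN, and NaN propagates through interpolation: a
sample is excluded whenever any of its four bilinear corners is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import skeletonize


class SegmentationError(ValueError):
    """Raised when the vessel channel does not contain exactly one tube."""

    def __init__(self, n_components: int):
        self.n_components = n_components
        super().__init__(
            f"expected exactly 1 vessel component, found {n_components} "
            "vessel components"
        )


@dataclass
class VesselSegment:
    """A single in-focus capillary segment.

    centerline : (N, 2) array of sub-pixel (row, col) points, spaced
        <= 1 px apart after resampling.
    radius_um : mean half-width of the vessel measured perpendicular to the
        centerline.
    """

    centerline: np.ndarray
    radius_um: float
    pixel_size_um: float
    in_focus: bool = True

    @property
    def diameter_um(self) -> float:
        return 2.0 * self.radius_um

    @property
    def length_um(self) -> float:
        d = np.diff(self.centerline, axis=0)
        return float(np.sum(np.hypot(d[:, 0], d[:, 1]))) * self.pixel_size_um

    def __post_init__(self):
        self.centerline = np.asarray(self.centerline, dtype=float)
        if self.centerline.ndim != 2 or self.centerline.shape[1] != 2:
            raise ValueError("centerline must be an (N, 2) point array")
        if len(self.centerline) < 2:
            raise ValueError("centerline needs at least 2 points")
        if self.radius_um <= 0:
            raise ValueError("radius_um must be positive")


@dataclass
class StraightenedImage:
    """Image resampled into vessel-centric coordinates.

    values[i, j] is the input sampled at centerline point i, offset
    offsets_um[j] along the local unit normal.  NaN marks excluded samples.
    """

    values: np.ndarray
    sample_spacing_um: float

    @property
    def offsets_um(self) -> np.ndarray:
        w = self.values.shape[1]
        return (np.arange(w) - w // 2) * self.sample_spacing_um


def resample_polyline(points: np.ndarray, spacing_px: float = 1.0) -> np.ndarray:
    """Resample an ordered polyline to uniform arc-length spacing.

    Points are placed at arc positions 0, spacing, 2*spacing, ... up to the
    total length (a trailing remainder shorter than one spacing is dropped).
    """
    pts = np.asarray(points, dtype=float)
    seg = np.hypot(*np.diff(pts, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValueError("degenerate (zero-length) centerline")
    n = int(np.floor(total / spacing_px)) + 1
    target = np.arange(n) * spacing_px
    out = np.column_stack(
        [np.interp(target, s, pts[:, 0]), np.interp(target, s, pts[:, 1])]
    )
    return out


def _order_skeleton(skel: np.ndarray) -> np.ndarray:
    """Order skeleton pixels of a simple curve into a path (longest path
    between endpoints, 8-connectivity)."""
    coords = np.column_stack(np.nonzero(skel))
    if len(coords) < 2:
        raise SegmentationError(0)
    index = {tuple(c): i for i, c in enumerate(coords)}
    nbrs: list[list[int]] = [[] for _ in coords]
    for i, (r, c) in enumerate(coords):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                j = index.get((r + dr, c + dc))
                if j is not None:
                    nbrs[i].append(j)

    def bfs(start: int):
        prev = {start: -1}
        order = [start]
        queue = [start]
        while queue:
            cur = queue.pop(0)
            for j in nbrs[cur]:
                if j not in prev:
                    prev[j] = cur
                    order.append(j)
                    queue.append(j)
        return order[-1], prev

    # farthest point from an arbitrary endpoint, then farthest from that:
    # classic double-BFS longest path for tree-like skeletons
    a, _ = bfs(0)
    b, prev = bfs(a)
    path = []
    cur = b
    while cur != -1:
        path.append(cur)
        cur = prev[cur]
    return coords[path[::-1]]


def segment_vessel(
    vessel_image: np.ndarray, pixel_size_um: float, smooth_sigma_px: float = 2.0
) -> VesselSegment:
    """Locate the single capillary in a vessel-channel image.

    The image is thresholded with Otsu's method; exactly one connected
    bright component must remain (fields containing several vessels must be
    cropped upstream).  The centerline is the skeleton of the mask, smoothed
    and resampled to <= 1 px spacing; the radius is the mean distance from
    the centerline to the mask boundary.
    """
    img = np.asarray(vessel_image, dtype=float)
    thr = threshold_otsu(img)
    mask = img > thr
    labels = cc_label(mask, connectivity=2)
    n = labels.max()
    if n != 1:
        raise SegmentationError(int(n))

    skel = skeletonize(mask)
    path = _order_skeleton(skel).astype(float)
    if smooth_sigma_px > 0 and len(path) > 4:
        path = np.column_stack(
            [
                ndimage.gaussian_filter1d(path[:, 0], smooth_sigma_px, mode="nearest"),
                ndimage.gaussian_filter1d(path[:, 1], smooth_sigma_px, mode="nearest"),
            ]
        )
    centerline = resample_polyline(path, 1.0)

    # rough half-width from the distance transform, then sub-pixel
    # refinement as half the full width at half maximum of the collapsed
    # perpendicular intensity profile
    edt = ndimage.distance_transform_edt(mask)
    ri = np.clip(np.round(centerline[:, 0]).astype(int), 0, mask.shape[0] - 1)
    ci = np.clip(np.round(centerline[:, 1]).astype(int), 0, mask.shape[1] - 1)
    radius_px = float(np.mean(edt[ri, ci]))
    seg = VesselSegment(
        centerline=centerline,
        radius_um=radius_px * pixel_size_um,
        pixel_size_um=pixel_size_um,
    )
    refined = _fwhm_radius_um(img, seg)
    if refined is not None:
        seg.radius_um = refined
    return seg


def _fwhm_radius_um(image: np.ndarray, segment: VesselSegment) -> float | None:
    """Half the full-width-at-half-maximum of the vessel's perpendicular
    intensity profile (sub-pixel, via linear interpolation); None if the
    profile has no clean half-max crossings."""
    st = straighten(image, segment, half_width_um=20.0)
    with np.errstate(invalid="ignore"):
        prof = np.nanmean(st.values, axis=0)
    if np.all(np.isnan(prof)):
        return None
    center = int(np.nanargmax(prof))
    peak = prof[center]
    floor = np.nanmin(prof)
    half = floor + 0.5 * (peak - floor)

    def crossing(direction: int) -> float | None:
        j = center
        while 0 <= j + direction < len(prof):
            nxt = prof[j + direction]
            if np.isnan(nxt):
                return None
            if nxt < half:
                frac = (prof[j] - half) / (prof[j] - nxt)
                return abs(j + direction * frac - len(prof) // 2)
            j += direction
        return None

    left = crossing(-1)
    right = crossing(+1)
    if left is None or right is None:
        return None
    return 0.5 * (left + right) * st.sample_spacing_um


def _normals(centerline: np.ndarray) -> np.ndarray:
    """Unit normals from central differences on the centerline (one-sided at
    the endpoints)."""
    t = np.gradient(centerline, axis=0)
    norm = np.hypot(t[:, 0], t[:, 1])
    norm[norm == 0] = 1.0
    t = t / norm[:, None]
    # rotate tangent by +90 degrees in (row, col)
    return np.column_stack([-t[:, 1], t[:, 0]])


def _bilinear_nan(image: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Bilinear interpolation with strict exclusion semantics: any NaN or
    out-of-image corner makes the sample NaN."""
    h, w = image.shape
    r0 = np.floor(rows).astype(int)
    c0 = np.floor(cols).astype(int)
    fr = rows - r0
    fc = cols - c0
    inside = (r0 >= 0) & (r0 + 1 <= h - 1 + (fr == 0)) & (c0 >= 0) & (
        c0 + 1 <= w - 1 + (fc == 0)
    )
    # clip for safe gather; invalid samples overwritten below
    r0c = np.clip(r0, 0, h - 1)
    c0c = np.clip(c0, 0, w - 1)
    r1c = np.clip(r0 + 1, 0, h - 1)
    c1c = np.clip(c0 + 1, 0, w - 1)
    v00 = image[r0c, c0c]
    v01 = image[r0c, c1c]
    v10 = image[r1c, c0c]
    v11 = image[r1c, c1c]
    out = (
        v00 * (1 - fr) * (1 - fc)
        + v01 * (1 - fr) * fc
        + v10 * fr * (1 - fc)
        + v11 * fr * fc
    )
    # exact grid hits must not be polluted by a NaN neighbour with zero weight
    exact_r = fr == 0
    exact_c = fc == 0
    both = exact_r & exact_c
    out[both] = v00[both]
    row_only = exact_r & ~exact_c
    out[row_only] = v00[row_only] * (1 - fc[row_only]) + v01[row_only] * fc[row_only]
    col_only = exact_c & ~exact_r
    out[col_only] = v00[col_only] * (1 - fr[col_only]) + v10[col_only] * fr[col_only]
    out[~inside] = np.nan
    return out


def straighten(
    image: np.ndarray,
    segment: VesselSegment,
    half_width_um: float,
    sample_spacing_um: float | None = None,
) -> StraightenedImage:
    """Resample an image perpendicular to the vessel centerline.

    Each centerline point becomes a row; columns are signed offsets from
    -half_width_um to +half_width_um along the local unit normal.  The
    half-width must be at least 20 um so that profiles always extend a
    minimum of 20 um on either side of the vessel.
    """
    if half_width_um < 20:
        raise ValueError(
            f"half_width_um must be >= 20 um (got {half_width_um}); profiles "
            "must extend at least 20 um on either side of the vessel"
        )
    if sample_spacing_um is None:
        sample_spacing_um = segment.pixel_size_um
    img = np.asarray(image, dtype=float)
    cl = segment.centerline
    nrm = _normals(cl)
    half_w = int(round(half_width_um / sample_spacing_um))
    offsets_px = (np.arange(2 * half_w + 1) - half_w) * (
        sample_spacing_um / segment.pixel_size_um
    )
    rows = cl[:, 0][:, None] + nrm[:, 0][:, None] * offsets_px[None, :]
    cols = cl[:, 1][:, None] + nrm[:, 1][:, None] * offsets_px[None, :]
    values = _bilinear_nan(img, rows, cols)
    return StraightenedImage(values=values, sample_spacing_um=sample_spacing_um)


def polyline_distance_map(
    shape: tuple[int, int], polyline: np.ndarray, resolution_px: float = 0.25
) -> np.ndarray:
    """Distance (in px) from each pixel center to a polyline, via a KD-tree
    over a densely resampled copy of the polyline."""
    pts = np.asarray(polyline, dtype=float)
    if len(pts) > 1:
        pts = resample_polyline(pts, resolution_px)
    tree = cKDTree(pts)
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    query = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    d, _ = tree.query(query, workers=-1)
    return d.reshape(shape)
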