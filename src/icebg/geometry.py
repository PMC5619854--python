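"""Detector geometry, resolution mapping and the polar-regridding primitive.

A flat detector is described by its pixel grid, pixel size, sample-to-detector
distance, beam centre and wavelength.  Every pixel maps to a scattering angle
``2θ = atan(r / distance)`` and hence, through Bragg's law, to a resolution
``d = λ / (2 sin θ)``: pixels at equal radius from the beam centre lie on a
line of constant resolution.

The background pipeline regrids detector images onto a polar
(radius × azimuth) grid in a count-conserving way.  Each pixel's square
footprint is mapped to a quadrilateral in polar coordinates and intersected
with the rectangular polar cells using Sutherland–Hodgman convex polygon
clipping; the fractional overlap areas redistribute the pixel's counts.

Coordinate conventions
----------------------
Pixel ``(i, j)`` (slow, fast) occupies the half-open square
``[i, i+1) × [j, j+1)`` with its centre at ``(i + 0.5, j + 0.5)``; the polar
radius is measured in pixel units from the beam centre and the azimuth is
``atan2(fast - fast_centre, slow - slow_centre)`` in radians in ``(-π, π]``.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import sparse

__all__ = [
    "DetectorGeometry",
    "PolarGrid",
    "InvalidGeometryError",
    "polygon_area",
    "clip_polygon",
    "resolution_map",
    "radius_map",
    "azimuth_map",
    "pixel_overlap_fractions",
    "BEAM_CENTRE_MASK_RADIUS",
]

#: pixels whose centre lies within this many pixels of the beam centre are
#: excluded from the polar regridding (the straight-edge approximation of the
#: pixel footprint breaks down as r -> 0 and the azimuth is undefined at r = 0)
BEAM_CENTRE_MASK_RADIUS = 2.0


class InvalidGeometryError(ValueError):
    """Raised when a detector geometry has non-physical parameters."""


@dataclass(frozen=True)
class DetectorGeometry:
    """Flat single-panel detector geometry.

    Parameters
    ----------
    n_slow, n_fast : int
        Number of pixels along the slow and fast axes.
    pixel_size : float
        Pixel edge length in mm (square pixels).
    distance : float
        Sample-to-detector distance along the beam, in mm.
    beam_centre : tuple of float
        Beam centre ``(slow, fast)`` in pixel units; may lie off the panel.
    wavelength : float
        X-ray wavelength in Å.
    """

    n_slow: int
    n_fast: int
    pixel_size: float
    distance: float
    beam_centre: tuple[float, float]
    wavelength: float

    def __post_init__(self) -> None:
        if self.n_slow <= 0 or self.n_fast <= 0:
            raise InvalidGeometryError("detector must have positive pixel counts")
        if self.pixel_size <= 0:
            raise InvalidGeometryError("pixel_size must be positive")
        if self.distance <= 0:
            raise InvalidGeometryError("distance must be positive")
        if self.wavelength <= 0:
            raise InvalidGeometryError("wavelength must be positive")

    # -- conversions ------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_slow, self.n_fast)

    def resolution_at(self, radius_px: np.ndarray | float) -> np.ndarray | float:
        """Resolution d (Å) at a given radius from the beam centre (pixels).

        ``d = λ / (2 sin θ)`` with ``2θ = atan(r_mm / distance)``.  Returns
        ``inf`` at zero radius.
        """
        r_mm = np.asarray(radius_px, dtype=float) * self.pixel_size
        two_theta = np.arctan2(r_mm, self.distance)
        with np.errstate(divide="ignore"):
            d = self.wavelength / (2.0 * np.sin(0.5 * two_theta))
        if np.isscalar(radius_px):
            return float(d)
        return d

    def radius_at_resolution(self, d: float) -> float:
        """Radius in pixels of the ring at resolution ``d`` (Å)."""
        sin_theta = self.wavelength / (2.0 * d)
        if not 0.0 < sin_theta < 1.0:
            raise ValueError(f"resolution {d} Å is not reachable at λ={self.wavelength} Å")
        two_theta = 2.0 * math.asin(sin_theta)
        return self.distance * math.tan(two_theta) / self.pixel_size

    def max_corner_radius(self) -> float:
        """Largest radius (pixels) of any pixel corner on the panel."""
        sc, fc = self.beam_centre
        corners_s = np.array([0.0, 0.0, self.n_slow, self.n_slow])
        corners_f = np.array([0.0, self.n_fast, 0.0, self.n_fast])
        return float(np.max(np.hypot(corners_s - sc, corners_f - fc)))

    # -- (de)serialisation ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_slow": self.n_slow,
            "n_fast": self.n_fast,
            "pixel_size_mm": self.pixel_size,
            "distance_mm": self.distance,
            "beam_centre_px": list(self.beam_centre),
            "wavelength_A": self.wavelength,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DetectorGeometry":
        try:
            return cls(
                n_slow=int(d["n_slow"]),
                n_fast=int(d["n_fast"]),
                pixel_size=float(d["pixel_size_mm"]),
                distance=float(d["distance_mm"]),
                beam_centre=tuple(float(x) for x in d["beam_centre_px"]),
                wavelength=float(d["wavelength_A"]),
            )
        except KeyError as exc:
            raise InvalidGeometryError(f"geometry config missing key: {exc.args[0]!r}") from exc

    def fingerprint(self) -> str:
        """Stable hash of the geometry, stored in every derived artefact."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class PolarGrid:
    """Regular (radius × azimuth) grid used for the polar regridding.

    ``res_edges`` are radial bin edges in pixel units (increasing radius means
    decreasing resolution d); ``az_edges`` span exactly ``[-π, π]``.  An
    optional ``az_offset`` rotates the grid, which is useful for testing seam
    handling; cell azimuths are interpreted modulo 2π.
    """

    res_edges: np.ndarray
    az_edges: np.ndarray
    az_offset: float = 0.0

    def __post_init__(self) -> None:
        res = np.asarray(self.res_edges, float)
        az = np.asarray(self.az_edges, float)
        if res.ndim != 1 or res.size < 2 or np.any(np.diff(res) <= 0):
            raise ValueError("res_edges must be strictly increasing, length >= 2")
        if az.ndim != 1 or az.size < 2 or np.any(np.diff(az) <= 0):
            raise ValueError("az_edges must be strictly increasing, length >= 2")
        if not (math.isclose(az[0], -math.pi) and math.isclose(az[-1], math.pi)):
            raise ValueError("az_edges must span [-π, π] exactly once")
        object.__setattr__(self, "res_edges", res)
        object.__setattr__(self, "az_edges", az)

    @property
    def n_res(self) -> int:
        return self.res_edges.size - 1

    @property
    def n_az(self) -> int:
        return self.az_edges.size - 1

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_res, self.n_az)

    @property
    def cell_area(self) -> float:
        """Area of one polar cell in (pixel-radius × radian) units."""
        dr = float(self.res_edges[1] - self.res_edges[0])
        daz = float(self.az_edges[1] - self.az_edges[0])
        return dr * daz

    def res_centres(self) -> np.ndarray:
        return 0.5 * (self.res_edges[:-1] + self.res_edges[1:])

    def resolution_centres(self, geom: DetectorGeometry) -> np.ndarray:
        """d-spacing (Å) at the centre of each radial bin."""
        return np.asarray(geom.resolution_at(self.res_centres()))

    @classmethod
    def for_geometry(
        cls,
        geom: DetectorGeometry,
        n_az: int = 360,
        radial_oversample: int = 1,
        az_offset: float = 0.0,
    ) -> "PolarGrid":
        """Default grid: 1/``radial_oversample`` px radial bins, ``n_az`` azimuth bins.

        Radius-linear binning samples constant-resolution lines more coarsely
        at high resolution, where an azimuth bin subtends a longer arc.
        ``radial_oversample`` > 1 narrows the radial bins; it should be chosen
        so a bin is no wider than the sharpest radial feature to be preserved.
        """
        n_res = int(math.ceil(geom.max_corner_radius())) * int(radial_oversample)
        dr = math.ceil(geom.max_corner_radius()) / n_res
        res_edges = np.arange(n_res + 1) * dr
        az_edges = np.linspace(-math.pi, math.pi, n_az + 1)
        return cls(res_edges=res_edges, az_edges=az_edges, az_offset=float(az_offset))


# ---------------------------------------------------------------------------
# convex polygon clipping (Sutherland & Hodgman)
# ---------------------------------------------------------------------------

def polygon_area(vertices: np.ndarray) -> float:
    """Signed shoelace area of a polygon given as an (n, 2) vertex array.

    Counter-clockwise polygons have positive area.
    """
    v = np.asarray(vertices, float)
    if v.ndim != 2 or v.shape[0] < 3:
        return 0.0
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def clip_polygon(subject: np.ndarray, clip: np.ndarray) -> np.ndarray:
    """Intersect a polygon with a convex clip polygon (Sutherland–Hodgman).

    Parameters
    ----------
    subject : (n, 2) array
        Vertices of the subject polygon in order (either winding).
    clip : (m, 2) array
        Vertices of a convex clip polygon.

    Returns
    -------
    (k, 2) array
        Vertices of the intersection polygon, counter-clockwise; an empty
        (0, 2) array when the polygons are disjoint or either is degenerate.
    """
    subject = np.asarray(subject, float)
    clip = np.asarray(clip, float)
    empty = np.empty((0, 2))
    if subject.shape[0] < 3 or clip.shape[0] < 3:
        return empty
    if abs(polygon_area(clip)) < 1e-300 or abs(polygon_area(subject)) < 1e-300:
        return empty
    # normalise windings to counter-clockwise
    if polygon_area(subject) < 0:
        subject = subject[::-1]
    if polygon_area(clip) < 0:
        clip = clip[::-1]

    output = [tuple(p) for p in subject]
    for k in range(len(clip)):
        if not output:
            return empty
        ax, ay = clip[k]
        bx, by = clip[(k + 1) % len(clip)]
        ex, ey = bx - ax, by - ay  # clip edge direction; inside is to the left

        def inside(p):
            return ex * (p[1] - ay) - ey * (p[0] - ax) >= 0.0

        def intersect(p, q):
            # p-q crosses the infinite line through a-b
            dx, dy = q[0] - p[0], q[1] - p[1]
            denom = ex * dy - ey * dx
            t = (ex * (ay - p[1]) - ey * (ax - p[0])) / denom
            return (p[0] + t * dx, p[1] + t * dy)

        new_output = []
        prev = output[-1]
        prev_in = inside(prev)
        for curr in output:
            curr_in = inside(curr)
            if curr_in:
                if not prev_in:
                    new_output.append(intersect(prev, curr))
                new_output.append(curr)
            elif prev_in:
                new_output.append(intersect(prev, curr))
            prev, prev_in = curr, curr_in
        output = new_output
    if len(output) < 3:
        return empty
    return np.asarray(output)


# ---------------------------------------------------------------------------
# per-pixel maps
# ---------------------------------------------------------------------------

def radius_map(geom: DetectorGeometry) -> np.ndarray:
    """Radius (pixels) of every pixel centre from the beam centre."""
    sc, fc = geom.beam_centre
    ss = np.arange(geom.n_slow) + 0.5
    ff = np.arange(geom.n_fast) + 0.5
    return np.hypot(ss[:, None] - sc, ff[None, :] - fc)


def azimuth_map(geom: DetectorGeometry) -> np.ndarray:
    """Azimuth (radians, (-π, π]) of every pixel centre."""
    sc, fc = geom.beam_centre
    ss = np.arange(geom.n_slow) + 0.5
    ff = np.arange(geom.n_fast) + 0.5
    return np.arctan2(ff[None, :] - fc, ss[:, None] - sc)


def resolution_map(geom: DetectorGeometry) -> np.ndarray:
    """Per-pixel resolution d (Å) at pixel centres.

    The pixel containing the beam centre (radius 0) gets ``inf``; callers
    should mask non-finite values rather than use them.
    """
    return np.asarray(geom.resolution_at(radius_map(geom)))


# ---------------------------------------------------------------------------
# pixel <-> polar cell overlap fractions
# ---------------------------------------------------------------------------

_TWO_PI = 2.0 * math.pi


@njit(cache=False)
def _clip_area_rect(xs, ys, n, xlo, xhi, ylo, yhi, bx, by, cx, cy):  # pragma: no cover
    """Area of a polygon clipped to an axis-aligned rectangle.

    ``bx/by`` and ``cx/cy`` are scratch vertex buffers.  Specialised
    Sutherland–Hodgman: the four clip edges are the rectangle sides.
    """
    m = n
    for i in range(n):
        bx[i] = xs[i]
        by[i] = ys[i]
    # clip successively against x>=xlo, x<=xhi, y>=ylo, y<=yhi
    for edge in range(4):
        if m == 0:
            return 0.0
        k = 0
        px = bx[m - 1]
        py = by[m - 1]
        if edge == 0:
            pin = px >= xlo
        elif edge == 1:
            pin = px <= xhi
        elif edge == 2:
            pin = py >= ylo
        else:
            pin = py <= yhi
        for i in range(m):
            qx = bx[i]
            qy = by[i]
            if edge == 0:
                qin = qx >= xlo
                bound = xlo
            elif edge == 1:
                qin = qx <= xhi
                bound = xhi
            elif edge == 2:
                qin = qy >= ylo
                bound = ylo
            else:
                qin = qy <= yhi
                bound = yhi
            if qin != pin:
                if edge < 2:  # vertical boundary: solve for y at x = bound
                    t = (bound - px) / (qx - px)
                    cx[k] = bound
                    cy[k] = py + t * (qy - py)
                else:
                    t = (bound - py) / (qy - py)
                    cx[k] = px + t * (qx - px)
                    cy[k] = bound
                k += 1
            if qin:
                cx[k] = qx
                cy[k] = qy
                k += 1
            px = qx
            py = qy
            pin = qin
        m = k
        for i in range(m):
            bx[i] = cx[i]
            by[i] = cy[i]
    if m < 3:
        return 0.0
    area = 0.0
    for i in range(m):
        j = (i + 1) % m
        area += bx[i] * by[j] - bx[j] * by[i]
    return 0.5 * area


@njit(cache=False)
def _overlap_kernel(
    n_slow, n_fast, sc, fc, dr, n_res, daz, n_az, az0, min_radius
):  # pragma: no cover
    """Compute sparse (pixel, polar cell, area) triplets for all pixels.

    Pixel corners are mapped to (radius px, azimuth rad); the straight-edged
    corner quadrilateral is clipped against every candidate cell rectangle.
    Quadrilaterals straddling the azimuth seam are unwrapped by +2π and cells
    are indexed modulo n_az, which splits the pixel across the seam exactly.
    Returns (pixel_index, cell_index, clipped_area, pixel_polar_area).
    """
    cap = n_slow * n_fast * 8
    out_pix = np.empty(cap, np.int64)
    out_cell = np.empty(cap, np.int64)
    out_area = np.empty(cap, np.float64)
    pix_area = np.zeros(n_slow * n_fast, np.float64)
    n_out = 0

    xs = np.empty(8, np.float64)
    ys = np.empty(8, np.float64)
    bx = np.empty(16, np.float64)
    by = np.empty(16, np.float64)
    cx = np.empty(16, np.float64)
    cy = np.empty(16, np.float64)

    for i in range(n_slow):
        for j in range(n_fast):
            # pixel-centre mask near the beam centre
            rc = math.hypot(i + 0.5 - sc, j + 0.5 - fc)
            if rc < min_radius:
                continue
            # corner coordinates in polar space
            amin = 1e30
            amax = -1e30
            rmin = 1e30
            rmax = -1e30
            for k in range(4):
                # corners in order (i,j),(i,j+1),(i+1,j+1),(i+1,j)
                if k == 0:
                    ds, df = i - sc, j - fc
                elif k == 1:
                    ds, df = i - sc, j + 1.0 - fc
                elif k == 2:
                    ds, df = i + 1.0 - sc, j + 1.0 - fc
                else:
                    ds, df = i + 1.0 - sc, j - fc
                r = math.hypot(ds, df)
                a = math.atan2(df, ds) - az0
                # renormalise to (-pi, pi]
                while a <= -math.pi:
                    a += _TWO_PI
                while a > math.pi:
                    a -= _TWO_PI
                xs[k] = r
                ys[k] = a
            # seam unwrap: if azimuth extent is > π the pixel straddles ±π
            amin = min(ys[0], min(ys[1], min(ys[2], ys[3])))
            amax = max(ys[0], max(ys[1], max(ys[2], ys[3])))
            if amax - amin > math.pi:
                for k in range(4):
                    if ys[k] < 0.0:
                        ys[k] += _TWO_PI
                amin = min(ys[0], min(ys[1], min(ys[2], ys[3])))
                amax = max(ys[0], max(ys[1], max(ys[2], ys[3])))
            rmin = min(xs[0], min(xs[1], min(xs[2], xs[3])))
            rmax = max(xs[0], max(xs[1], max(xs[2], xs[3])))

            # ensure counter-clockwise orientation
            area_q = 0.0
            for k in range(4):
                kk = (k + 1) % 4
                area_q += xs[k] * ys[kk] - xs[kk] * ys[k]
            area_q *= 0.5
            if area_q < 0.0:
                # reverse
                xs[0], xs[1], xs[2], xs[3] = xs[3], xs[2], xs[1], xs[0]
                ys[0], ys[1], ys[2], ys[3] = ys[3], ys[2], ys[1], ys[0]
                area_q = -area_q
            if area_q <= 0.0:
                continue
            p = i * n_fast + j
            pix_area[p] = area_q

            i0 = int(math.floor(rmin / dr))
            i1 = int(math.floor(rmax / dr))
            if i0 < 0:
                i0 = 0
            if i1 > n_res - 1:
                i1 = n_res - 1
            j0 = int(math.floor((amin + math.pi) / daz))
            j1 = int(math.floor((amax + math.pi) / daz))
            for ri in range(i0, i1 + 1):
                rlo = ri * dr
                rhi = rlo + dr
                for aj in range(j0, j1 + 1):
                    alo = -math.pi + aj * daz
                    ahi = alo + daz
                    area = _clip_area_rect(xs, ys, 4, rlo, rhi, alo, ahi, bx, by, cx, cy)
                    if area > 0.0:
                        if n_out == cap:
                            cap2 = cap * 2
                            np_pix = np.empty(cap2, np.int64)
                            np_cell = np.empty(cap2, np.int64)
                            np_area = np.empty(cap2, np.float64)
                            np_pix[:cap] = out_pix
                            np_cell[:cap] = out_cell
                            np_area[:cap] = out_area
                            out_pix = np_pix
                            out_cell = np_cell
                            out_area = np_area
                            cap = cap2
                        out_pix[n_out] = p
                        out_cell[n_out] = ri * n_az + (aj % n_az)
                        out_area[n_out] = area
                        n_out += 1
    return out_pix[:n_out], out_cell[:n_out], out_area[:n_out], pix_area


class OverlapFractions:
    """Sparse pixel ↔ polar-cell overlap map.

    Attributes
    ----------
    fractions : scipy.sparse.csr_matrix, shape (n_pixels, n_cells)
        Entry (p, c) is the fraction of pixel p's polar footprint falling in
        cell c; rows of on-grid pixels sum to 1.
    areas : scipy.sparse.csr_matrix, shape (n_pixels, n_cells)
        The same map in absolute polar-area units (pixel-radius × radian).
    pixel_area : ndarray, shape (n_pixels,)
        Polar-space area of each pixel footprint (0 for masked pixels).
    on_grid : ndarray of bool, shape (n_slow, n_fast)
        True for pixels that participate in the regridding.
    """

    def __init__(self, geom: DetectorGeometry, grid: PolarGrid, fractions, areas, pixel_area):
        self.geom = geom
        self.grid = grid
        self.fractions = fractions
        self.areas = areas
        self.pixel_area = pixel_area
        self.on_grid = (pixel_area > 0).reshape(geom.shape)


def pixel_overlap_fractions(
    geom: DetectorGeometry,
    grid: PolarGrid | None = None,
    min_radius: float = BEAM_CENTRE_MASK_RADIUS,
) -> OverlapFractions:
    """Compute the count-conserving pixel → polar-cell overlap fractions.

    For every pixel further than ``min_radius`` pixels from the beam centre,
    the four corners are mapped to polar coordinates and the resulting
    quadrilateral is clipped against each overlapping cell rectangle.  The
    clipped areas, normalised by the quadrilateral area, give the fraction of
    the pixel's counts assigned to each cell; per pixel they sum to 1.
    """
    if grid is None:
        grid = PolarGrid.for_geometry(geom)
    dr = float(grid.res_edges[1] - grid.res_edges[0])
    daz = float(grid.az_edges[1] - grid.az_edges[0])
    if not np.allclose(np.diff(grid.res_edges), dr) or not np.allclose(
        np.diff(grid.az_edges), daz
    ):
        raise ValueError("pixel_overlap_fractions requires a uniform PolarGrid")
    sc, fc = geom.beam_centre
    pix, cell, area, pix_area = _overlap_kernel(
        geom.n_slow,
        geom.n_fast,
        float(sc),
        float(fc),
        dr,
        grid.n_res,
        daz,
        grid.n_az,
        float(grid.az_offset),
        float(min_radius),
    )
    n_pix = geom.n_slow * geom.n_fast
    n_cells = grid.n_res * grid.n_az
    areas = sparse.coo_matrix((area, (pix, cell)), shape=(n_pix, n_cells)).tocsr()
    with np.errstate(invalid="ignore", divide="ignore"):
        inv = np.where(pix_area > 0, 1.0 / np.where(pix_area > 0, pix_area, 1.0), 0.0)
    fractions = sparse.diags(inv) @ areas
    return OverlapFractions(geom, grid, fractions.tocsr(), areas, pix_area)
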