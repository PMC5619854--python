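"""Static global background model built from an image stack.

The model is the per-pixel mean of the background pixels over all images,
cleaned of outliers and gaps by filtering in polar coordinates where ice
rings are (nearly) constant along lines of equal resolution:

1. masked per-pixel mean over the stack, keeping only pixels to which more
   than ``min_images`` images contributed;
2. count-conserving regrid of the mean image onto a (radius × azimuth) grid;
3. median filter along each constant-resolution column, wrapped at the
   azimuth seam, to reject high-valued outliers;
4. diffusion fill of masked-out cells (discrete Laplace equation with the
   valid cells as Dirichlet data);
5. inverse regrid back to detector pixels.

The result is a smooth non-negative background *shape* ``b`` which is scaled
per reflection by :mod:`icebg.reflection_fit`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import cg
from sklearn.base import BaseEstimator

from icebg.geometry import (
    BEAM_CENTRE_MASK_RADIUS,
    DetectorGeometry,
    OverlapFractions,
    PolarGrid,
    pixel_overlap_fractions,
)

__all__ = [
    "ImageStack",
    "PixelStatistics",
    "PolarImage",
    "BackgroundModel",
    "GlobalBackgroundModel",
    "accumulate_mean",
    "polar_transform",
    "median_filter_columns",
    "fill_missing_diffusion",
    "inverse_polar_transform",
    "build_global_model",
]


@dataclass
class ImageStack:
    """A stack of detector images with per-image background-usability masks.

    ``masks[k]`` is True where pixel counts of image ``k`` contain only
    background (no predicted reflection foreground); those pixels feed the
    global model.  When ``masks`` is None every pixel is usable.
    """

    images: np.ndarray
    masks: np.ndarray | None = None

    def __post_init__(self) -> None:
        images = np.asarray(self.images)
        if images.ndim != 3 or images.shape[0] < 1:
            raise ValueError("images must be a non-empty (n_images, n_slow, n_fast) array")
        if np.any(images < 0):
            raise ValueError("counts must be non-negative")
        if self.masks is None:
            masks = np.ones(images.shape, dtype=bool)
        else:
            masks = np.asarray(self.masks, dtype=bool)
            if masks.shape != images.shape:
                raise ValueError("masks must match images in shape")
        self.images = images
        self.masks = masks

    @property
    def n_images(self) -> int:
        return self.images.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.images.shape[1:]


@dataclass
class PixelStatistics:
    """Per-pixel mean/variance/dispersion across the usable images.

    ``dispersion`` (index of dispersion, variance/mean) is NaN where the mean
    is zero or fewer than two images contributed; for purely Poisson counts
    it concentrates around 1, and systematically exceeds 1 for pixels whose
    underlying rate varies through the scan (e.g. drifting ice rings).
    """

    mean: np.ndarray
    variance: np.ndarray
    dispersion: np.ndarray
    n_contrib: np.ndarray


def accumulate_mean(
    stack: ImageStack, min_images: int = 10
) -> tuple[PixelStatistics, np.ndarray]:
    """Masked per-pixel statistics over the stack and the usable-pixel mask.

    A pixel is usable when strictly more than ``min_images`` images
    contributed to it; for stacks shorter than 10 images the threshold is
    reduced to ``max(1, n_images - 1)``.

    Returns
    -------
    stats : PixelStatistics
    usable : ndarray of bool
        True where the pixel's mean enters the global background model.
    """
    images = stack.images.astype(np.float64, copy=False)
    masks = stack.masks
    n = stack.n_images
    if n < 10:
        min_images = max(1, n - 1)

    n_contrib = masks.sum(axis=0)
    s1 = np.einsum("kij,kij->ij", images, masks)
    s2 = np.einsum("kij,kij,kij->ij", images, images, masks)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n_contrib > 0, s1 / np.maximum(n_contrib, 1), np.nan)
        # unbiased sample variance
        variance = np.where(
            n_contrib > 1,
            np.maximum(s2 - np.maximum(n_contrib, 1) * mean**2, 0.0)
            / np.maximum(n_contrib - 1, 1),
            np.nan,
        )
        dispersion = np.where(
            (n_contrib > 1) & (mean > 0), variance / np.where(mean > 0, mean, 1.0), np.nan
        )
    usable = n_contrib > min_images
    stats = PixelStatistics(
        mean=mean, variance=variance, dispersion=dispersion, n_contrib=n_contrib
    )
    return stats, usable


@dataclass
class PolarImage:
    """Detector data regridded onto a (radius × azimuth) grid.

    ``values`` holds redistributed counts, ``weight`` the summed overlap
    fractions of contributing (unmasked, on-grid) pixels — so
    ``values / weight`` is the mean count per pixel in each cell — and
    ``coverage`` the absolute polar area those pixels cover.  ``valid`` marks
    cells whose coverage reaches the configured fraction of the full cell
    area.  Counts are conserved: the total over cells equals the total of
    the unmasked on-grid input pixels.
    """

    values: np.ndarray
    weight: np.ndarray
    valid: np.ndarray
    grid: PolarGrid
    coverage: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def ratio(self) -> np.ndarray:
        """Per-cell mean count per pixel (NaN on invalid cells with no weight)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(self.weight > 0, self.values / np.where(self.weight > 0, self.weight, 1), np.nan)
        return r

    def total(self) -> float:
        """Total regridded counts (all cells; conservation is exact cell-wise)."""
        return float(self.values.sum())


def polar_transform(
    image: np.ndarray,
    mask: np.ndarray | None,
    overlap: OverlapFractions,
    weight_threshold: float = 0.5,
) -> PolarImage:
    """Regrid an image (and mask) to polar coordinates, conserving counts.

    Each unmasked on-grid pixel's value is split over the polar cells it
    overlaps in proportion to the clipped areas.  ``weight_threshold`` is the
    minimum covered fraction of a cell's area for the cell to count as valid.
    """
    geom, grid = overlap.geom, overlap.grid
    image = np.asarray(image, dtype=np.float64)
    if image.shape != geom.shape:
        raise ValueError(f"image shape {image.shape} does not match geometry {geom.shape}")
    if mask is None:
        mask = np.ones(image.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != image.shape:
            raise ValueError("mask shape does not match image shape")
    use = (mask & overlap.on_grid).ravel()
    x = np.where(use, image.ravel(), 0.0)
    # NaNs can occur in mean images at all-masked pixels; they carry no weight
    x = np.nan_to_num(x, nan=0.0)
    values = overlap.fractions.T @ x
    weight = overlap.fractions.T @ use.astype(np.float64)
    coverage = overlap.areas.T @ use.astype(np.float64)
    valid = coverage >= weight_threshold * grid.cell_area
    shape = grid.shape
    return PolarImage(
        values=values.reshape(shape),
        weight=weight.reshape(shape),
        valid=valid.reshape(shape),
        grid=grid,
        coverage=coverage.reshape(shape),
    )


def median_filter_columns(p: PolarImage, window: int = 10) -> PolarImage:
    """Wrapped median filter along each constant-resolution column.

    For every valid cell the median is taken over the cell itself and its
    ``window`` nearest *valid* neighbours along the azimuth direction,
    wrapping at the seam; invalid cells are skipped and stay invalid.
    Columns with no more than ``window`` valid cells are left unchanged.
    The filter acts on the per-pixel ratio (``values / weight``) so cells
    only partially covered by unmasked pixels are not biased low.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    ratio = p.ratio
    new_values = p.values.copy()
    half_lo = window // 2
    half_hi = window - half_lo
    offsets = np.arange(-half_lo, half_hi + 1)
    for i in range(p.grid.n_res):
        cols = np.nonzero(p.valid[i])[0]
        m = cols.size
        if m <= window:
            continue
        vals = ratio[i, cols]
        idx = (np.arange(m)[:, None] + offsets[None, :]) % m
        med = np.median(vals[idx], axis=1)
        new_values[i, cols] = med * p.weight[i, cols]
    return PolarImage(
        values=new_values,
        weight=p.weight,
        valid=p.valid,
        grid=p.grid,
        coverage=p.coverage,
        meta=dict(p.meta),
    )


def _neighbour_structure(shape: tuple[int, int]):
    """Indices of the 4-neighbours on the polar grid (azimuth wraps)."""
    n_res, n_az = shape
    idx = np.arange(n_res * n_az).reshape(shape)
    nbrs = []
    nbrs.append((idx[:-1, :].ravel(), idx[1:, :].ravel()))  # radial
    nbrs.append((idx[:, :].ravel(), np.roll(idx, -1, axis=1).ravel()))  # azimuth, wrapped
    rows = np.concatenate([a for a, _ in nbrs])
    cols = np.concatenate([b for _, b in nbrs])
    return rows, cols


def fill_missing_diffusion(
    p: PolarImage,
    tol: float = 1e-6,
    max_iter: int = 10000,
    method: str = "direct",
) -> PolarImage:
    """Fill invalid cells by solving the discrete Laplace equation.

    Valid cells are Dirichlet data and keep their values; each invalid cell
    converges to the mean of its 4-neighbours (azimuth wraps, radius does
    not).  ``method="direct"`` solves the fixed point of the diffusion with a
    conjugate-gradient solve on the graph Laplacian; ``method="jacobi"``
    performs the literal iteration, stopping when the largest update falls
    below ``tol`` times the range of the valid-cell values.  By the discrete
    maximum principle, filled values lie within [min, max] of the valid data.
    """
    if not p.valid.any():
        raise ValueError("cannot fill a polar image with no valid cells")
    shape = p.grid.shape
    ratio = p.ratio.copy()
    valid = p.valid
    vvals = ratio[valid]
    lo, hi = float(np.min(vvals)), float(np.max(vvals))
    scale = hi - lo if hi > lo else max(abs(hi), 1.0)
    ratio[~valid] = float(np.mean(vvals))
    converged = True

    if valid.all():
        filled = ratio
    elif method == "jacobi":
        filled, converged = _jacobi_fill(ratio, valid, tol * scale, max_iter)
    elif method == "direct":
        filled = _laplace_fill(ratio, valid, rtol=min(tol, 1e-8))
    else:
        raise ValueError(f"unknown fill method: {method!r}")
    if not converged:
        warnings.warn("diffusion fill did not converge within max_iter", RuntimeWarning)

    weight = np.where(p.weight > 0, p.weight, 1.0)
    return PolarImage(
        values=np.where(valid, p.values, filled * weight),
        weight=weight,
        valid=np.ones(shape, dtype=bool),
        grid=p.grid,
        coverage=p.coverage,
        meta={**p.meta, "fill_converged": bool(converged), "fill_method": method},
    )


def _jacobi_fill(ratio, valid, atol, max_iter):
    n_res, n_az = ratio.shape
    x = ratio.copy()
    free = ~valid
    for _ in range(max_iter):
        up = np.vstack([x[:1], x[:-1]])
        down = np.vstack([x[1:], x[-1:]])
        left = np.roll(x, 1, axis=1)
        right = np.roll(x, -1, axis=1)
        cnt = np.full(x.shape, 4.0)
        cnt[0] -= 1.0
        cnt[-1] -= 1.0
        s = left + right + down + up
        s[0] -= up[0]
        s[-1] -= down[-1]
        new = s / cnt
        delta = np.abs(new[free] - x[free]).max() if free.any() else 0.0
        x[free] = new[free]
        if delta < atol:
            return x, True
    return x, False


def _laplace_fill(ratio, valid, rtol=1e-10):
    """Solve the Dirichlet problem on the invalid cells with sparse CG."""
    shape = ratio.shape
    n = ratio.size
    free = (~valid).ravel()
    free_idx = np.nonzero(free)[0]
    pos = -np.ones(n, dtype=np.int64)
    pos[free_idx] = np.arange(free_idx.size)

    rows, cols = _neighbour_structure(shape)
    # symmetrise edges
    a = np.concatenate([rows, cols])
    b = np.concatenate([cols, rows])
    sel = free[a]
    a, b = a[sel], b[sel]

    deg = np.bincount(pos[a], minlength=free_idx.size).astype(np.float64)
    rhs = np.zeros(free_idx.size)
    flat = ratio.ravel()
    nb_free = free[b]
    # free-free couplings
    ff = sparse.coo_matrix(
        (-np.ones(np.count_nonzero(nb_free)), (pos[a[nb_free]], pos[b[nb_free]])),
        shape=(free_idx.size, free_idx.size),
    )
    A = (sparse.diags(deg) + ff).tocsr()
    np.add.at(rhs, pos[a[~nb_free]], flat[b[~nb_free]])
    x0 = np.full(free_idx.size, float(np.mean(flat[~free])))
    sol, info = cg(A, rhs, x0=x0, rtol=rtol, maxiter=20 * int(np.sqrt(free_idx.size) + 100))
    if info != 0:  # pragma: no cover - CG on an SPD Laplacian converges
        warnings.warn("CG diffusion solve stopped early", RuntimeWarning)
    out = flat.copy()
    out[free_idx] = sol
    return out.reshape(shape)


@dataclass
class BackgroundModel:
    """Per-pixel background shape on the detector grid.

    ``b`` is non-negative and finite everywhere; ``off_grid`` flags pixels
    (beam-centre neighbourhood) that took no part in the regridding and whose
    model value is 0 by convention.
    """

    b: np.ndarray
    off_grid: np.ndarray
    provenance: dict = field(default_factory=dict)

    def shoebox_values(self, bbox: tuple[int, int, int, int]) -> np.ndarray:
        """Model values for a half-open bounding box (s0, s1, f0, f1)."""
        s0, s1, f0, f1 = bbox
        return self.b[s0:s1, f0:f1]


def inverse_polar_transform(p: PolarImage, overlap: OverlapFractions) -> BackgroundModel:
    """Map a fully valid polar image back to the detector grid.

    Each pixel receives the overlap-fraction weighted average of the per-cell
    ratios, i.e. the polar cell contents are redistributed in proportion to
    overlap area and normalised by the pixel's total overlap weight, so a
    constant polar field maps back to the same constant.
    """
    if not p.valid.all():
        raise ValueError("inverse transform requires a fully valid polar image")
    ratio = np.nan_to_num(p.ratio.ravel(), nan=0.0)
    b = overlap.fractions @ ratio
    b = np.maximum(b, 0.0).reshape(overlap.geom.shape)
    off_grid = ~overlap.on_grid
    b[off_grid] = 0.0
    return BackgroundModel(b=b, off_grid=off_grid, provenance=dict(p.meta))


class GlobalBackgroundModel(BaseEstimator):
    """Estimator building the static global background model from a stack.

    Parameters
    ----------
    geometry : DetectorGeometry
        Detector geometry used for the polar regridding.
    min_images : int, default 10
        A pixel enters the model only if strictly more than this many images
        contributed to its mean (auto-reduced for stacks of < 10 images).
    median_window : int, default 10
        Number of wrapped nearest neighbours pooled with each cell in the
        azimuthal median filter.
    n_az : int, default 360
        Azimuth bins of the polar grid.
    radial_oversample : int, default 1
        Radial bins per pixel of radius; raise for data with radial features
        sharper than ~1 px (e.g. narrow ice rings).
    weight_threshold : float, default 0.5
        Minimum covered fraction of a polar cell for it to count as valid.
    diffusion_tol, diffusion_max_iter, diffusion_method
        Convergence controls for the gap fill (see
        :func:`fill_missing_diffusion`).

    Attributes
    ----------
    background_ : ndarray
        The fitted per-pixel background shape.
    model_ : BackgroundModel
    statistics_ : PixelStatistics
    usable_mask_ : ndarray of bool
    polar_mean_, polar_filtered_, polar_filled_ : PolarImage
        Intermediate stages, kept for diagnostics.
    conservation_ : dict
        Count totals through the pipeline (input / polar / output).
    """

    def __init__(
        self,
        geometry: DetectorGeometry | None = None,
        min_images: int = 10,
        median_window: int = 10,
        n_az: int = 360,
        radial_oversample: int = 1,
        weight_threshold: float = 0.5,
        diffusion_tol: float = 1e-6,
        diffusion_max_iter: int = 10000,
        diffusion_method: str = "direct",
        min_radius: float = BEAM_CENTRE_MASK_RADIUS,
    ) -> None:
        self.geometry = geometry
        self.min_images = min_images
        self.median_window = median_window
        self.n_az = n_az
        self.radial_oversample = radial_oversample
        self.weight_threshold = weight_threshold
        self.diffusion_tol = diffusion_tol
        self.diffusion_max_iter = diffusion_max_iter
        self.diffusion_method = diffusion_method
        self.min_radius = min_radius

    def fit(self, X, y=None, masks=None, overlap: OverlapFractions | None = None):
        """Build the background model from an image stack.

        Parameters
        ----------
        X : ImageStack or (n_images, n_slow, n_fast) array
        masks : optional bool array matching ``X``
            Ignored when ``X`` is already an :class:`ImageStack`.
        overlap : optional precomputed OverlapFractions
            Reused when several stacks share one geometry.
        """
        if self.geometry is None:
            raise ValueError("GlobalBackgroundModel requires a geometry")
        stack = X if isinstance(X, ImageStack) else ImageStack(np.asarray(X), masks)
        if stack.frame_shape != self.geometry.shape:
            raise ValueError("stack frame shape does not match geometry")

        stats, usable = accumulate_mean(stack, self.min_images)
        if overlap is None:
            grid = PolarGrid.for_geometry(
                self.geometry, n_az=self.n_az, radial_oversample=self.radial_oversample
            )
            overlap = pixel_overlap_fractions(self.geometry, grid, self.min_radius)
        self.overlap_ = overlap

        mean_for_model = np.where(usable, stats.mean, 0.0)
        polar = polar_transform(mean_for_model, usable, overlap, self.weight_threshold)
        filtered = median_filter_columns(polar, self.median_window)
        filled = fill_missing_diffusion(
            filtered,
            tol=self.diffusion_tol,
            max_iter=self.diffusion_max_iter,
            method=self.diffusion_method,
        )
        model = inverse_polar_transform(filled, overlap)
        model.provenance.update(self.get_params(deep=False) | {"geometry": self.geometry.to_dict()})

        self.statistics_ = stats
        self.usable_mask_ = usable
        self.polar_mean_ = polar
        self.polar_filtered_ = filtered
        self.polar_filled_ = filled
        self.model_ = model
        self.background_ = model.b
        self.mean_ = stats.mean
        self.variance_ = stats.variance
        self.dispersion_ = stats.dispersion
        masked_total = float(
            np.nan_to_num(mean_for_model[usable & overlap.on_grid]).sum()
        )
        self.conservation_ = {
            "input_total": masked_total,
            "polar_total": polar.total(),
            "output_total": float(model.b.sum()),
        }
        return self

    def predict(self, bboxes) -> list[np.ndarray]:
        """Model values for a sequence of (s0, s1, f0, f1) bounding boxes."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "model_")
        return [self.model_.shoebox_values(tuple(b)) for b in bboxes]


def build_global_model(
    stack: ImageStack,
    geom: DetectorGeometry,
    overlap: OverlapFractions | None = None,
    **params,
) -> BackgroundModel:
    """One-call pipeline: masked mean → polar → median → fill → inverse.

    Deterministic given its inputs; ``params`` are forwarded to
    :class:`GlobalBackgroundModel`.
    """
    est = GlobalBackgroundModel(geometry=geom, **params)
    est.fit(stack, overlap=overlap)
    return est.model_
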