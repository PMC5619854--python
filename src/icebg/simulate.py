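"""Synthetic rotation-series generator with known ground truth.

Emulates the phenomenology the background pipeline must cope with: a smooth
radial background, powder rings from crystalline ice at fixed d-spacings
(sharp or diffuse, optionally azimuthally modulated and drifting in
amplitude through the scan), Gaussian Bragg spots, detector gaps, and
Poisson counting noise.  Everything is seeded and bit-reproducible.

The per-pixel rate of image ``j`` is

    λ_j(p) = base(p) + drift_j · Σ_k A_k exp(−(d(p) − d_k)² / 2 w_k²)
                                  · (1 + m_k cos(az(p) − φ_k))
             + spots on image j,

with counts drawn as Poisson(λ_j).  Shoeboxes are generated around each
spot: foreground = pixels within 3σ of the centre, background = the
surrounding frame.

The ring d-spacings ship as literature constants for hexagonal and cubic
ice; the Gaussian radial ring profile is deliberately *not* the shape the
background model assumes, making recovery a fair test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from icebg.geometry import DetectorGeometry, azimuth_map, radius_map, resolution_map
from icebg.global_model import ImageStack
from icebg.reflection_fit import Shoebox

__all__ = [
    "HEXAGONAL_ICE_D",
    "CUBIC_ICE_D",
    "IceRing",
    "Spot",
    "SimulationConfig",
    "GroundTruth",
    "SimulatedData",
    "simulate_stack",
    "default_presets",
    "scaled_preset",
    "sample_empty_shoeboxes",
    "build_spot_shoeboxes",
]

#: d-spacings (Å) of the three strong inner hexagonal-ice powder rings
HEXAGONAL_ICE_D = (3.90, 3.67, 3.44)
#: d-spacings (Å) of the strongest cubic-ice rings
CUBIC_ICE_D = (3.67, 2.25, 1.92)


@dataclass(frozen=True)
class IceRing:
    """A powder ring: Gaussian in d-spacing, optionally azimuthally modulated."""

    d: float  # ring position, Å
    amplitude: float  # peak counts/pixel at drift scale 1
    width: float  # Gaussian sigma in d, Å
    modulation: float = 0.0  # azimuthal amplitude modulation in [0, 1)
    phase: float = 0.0  # modulation phase, radians

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.width <= 0:
            raise ValueError("ring amplitude must be >= 0 and width > 0")
        if not 0 <= self.modulation < 1:
            raise ValueError("modulation must lie in [0, 1)")


@dataclass(frozen=True)
class Spot:
    """A Gaussian Bragg spot on a single image."""

    image: int
    centre: tuple[float, float]  # (slow, fast) px
    intensity: float  # integrated counts
    sigma: float  # isotropic Gaussian sigma, px


@dataclass
class SimulationConfig:
    """Everything needed to generate a stack; fixed seed ⇒ identical output."""

    geometry: DetectorGeometry
    n_images: int = 10
    seed: int = 0
    base_background: float | tuple = 20.0  # counts/px, or radial polynomial coefficients
    rings: tuple = ()
    ring_drift: np.ndarray | None = None  # per-image amplitude scale, default all 1
    spots: tuple = ()
    gaps: tuple = ()  # masked rectangles (s0, s1, f0, f1)
    fg_radius_sigma: float = 3.0  # foreground = pixels within this many spot sigmas
    shoebox_margin: int = 4  # background frame width around the foreground, px

    def drift(self) -> np.ndarray:
        if self.ring_drift is None:
            return np.ones(self.n_images)
        d = np.asarray(self.ring_drift, dtype=float)
        if d.shape != (self.n_images,):
            raise ValueError("ring_drift must have one scale per image")
        if np.any(d < 0):
            raise ValueError("ring_drift scales must be non-negative")
        return d


@dataclass
class GroundTruth:
    """Noiseless rates and true quantities behind a simulated stack."""

    base_map: np.ndarray  # static background component, counts/px
    ring_map: np.ndarray  # summed ring component at drift scale 1
    drift: np.ndarray  # per-image ring amplitude scale
    spot_table: pd.DataFrame  # per-spot truth (position, intensity, kept flag)
    bg_sums: np.ndarray  # per-shoebox true background under the foreground
    mean_map: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.mean_map = self.base_map + float(np.mean(self.drift)) * self.ring_map

    def background_lambda(self, image: int) -> np.ndarray:
        """Noiseless background rate map of one image (spots excluded)."""
        return self.base_map + self.drift[image] * self.ring_map


@dataclass
class SimulatedData:
    stack: ImageStack
    truth: GroundTruth
    shoeboxes: list
    table: pd.DataFrame


def _base_map(cfg: SimulationConfig) -> np.ndarray:
    geom = cfg.geometry
    if np.isscalar(cfg.base_background):
        return np.full(geom.shape, float(cfg.base_background))
    # polynomial in normalised radius u = r / r_max
    coeffs = np.asarray(cfg.base_background, dtype=float)
    u = radius_map(geom) / geom.max_corner_radius()
    lam = np.zeros(geom.shape)
    for k, a in enumerate(coeffs):
        lam += a * u**k
    if np.any(lam < 0):
        raise ValueError("base background polynomial must be non-negative on the detector")
    return lam


def _ring_map(cfg: SimulationConfig) -> np.ndarray:
    geom = cfg.geometry
    out = np.zeros(geom.shape)
    if not cfg.rings:
        return out
    d = resolution_map(geom)
    az = azimuth_map(geom)
    finite = np.isfinite(d)
    for ring in cfg.rings:
        prof = np.zeros(geom.shape)
        prof[finite] = ring.amplitude * np.exp(
            -((d[finite] - ring.d) ** 2) / (2.0 * ring.width**2)
        )
        if ring.modulation:
            prof *= 1.0 + ring.modulation * np.cos(az - ring.phase)
        out += prof
    return out


def build_spot_shoeboxes(
    images: np.ndarray,
    gap_mask: np.ndarray,
    geom: DetectorGeometry,
    spot_table: pd.DataFrame,
    fg_radius_sigma: float = 3.0,
    margin: int = 4,
) -> list:
    """Cut a shoebox around every kept spot in a spot table.

    Foreground pixels are those within ``fg_radius_sigma`` spot sigmas of the
    centre; the bounding box extends ``margin`` further pixels of background
    frame and is clipped to the panel.  Used both when simulating and when
    rebuilding shoeboxes from a persisted stack.
    """
    n_s, n_f = geom.shape
    out = []
    for row in spot_table.itertuples():
        if not bool(row.kept):
            continue
        s0, f0 = float(row.slow), float(row.fast)
        fg_r = fg_radius_sigma * float(row.sigma)
        half = int(math.ceil(fg_r)) + margin
        lo_s, hi_s = int(math.floor(s0)) - half, int(math.floor(s0)) + half + 1
        lo_f, hi_f = int(math.floor(f0)) - half, int(math.floor(f0)) + half + 1
        lo_s, hi_s = max(lo_s, 0), min(hi_s, n_s)
        lo_f, hi_f = max(lo_f, 0), min(hi_f, n_f)
        sub_s = np.arange(lo_s, hi_s) + 0.5
        sub_f = np.arange(lo_f, hi_f) + 0.5
        dist2 = (sub_s[:, None] - s0) ** 2 + (sub_f[None, :] - f0) ** 2
        fg = dist2 <= fg_r**2
        rc = math.hypot(s0 - geom.beam_centre[0], f0 - geom.beam_centre[1])
        out.append(
            Shoebox(
                bbox=(lo_s, hi_s, lo_f, hi_f),
                counts=images[int(row.image), lo_s:hi_s, lo_f:hi_f],
                fg_mask=fg,
                valid_mask=gap_mask[lo_s:hi_s, lo_f:hi_f],
                id=int(row.spot),
                image=int(row.image),
                d=float(geom.resolution_at(rc)),
            )
        )
    return out


def simulate_stack(cfg: SimulationConfig) -> SimulatedData:
    """Generate images, masks, ground truth and the shoebox table.

    Per-image Poisson streams are spawned deterministically from the master
    seed, so the same config always yields bit-identical output.  Spots whose
    centre lies off the detector are skipped with a warning.
    """
    geom = cfg.geometry
    n_s, n_f = geom.shape
    drift = cfg.drift()
    base = _base_map(cfg)
    ring = _ring_map(cfg)

    # spot bookkeeping
    spot_rows = []
    kept_spots = []
    for k, sp in enumerate(cfg.spots):
        s0, f0 = sp.centre
        on = (0 <= s0 < n_s) and (0 <= f0 < n_f) and (0 <= sp.image < cfg.n_images)
        if not on:
            warnings.warn(f"spot {k} at {sp.centre} (image {sp.image}) is off the detector; skipped")
        spot_rows.append(
            {"spot": k, "image": sp.image, "slow": s0, "fast": f0,
             "intensity": sp.intensity, "sigma": sp.sigma, "kept": on}
        )
        if on:
            kept_spots.append((k, sp))

    gap_mask = np.ones((n_s, n_f), dtype=bool)
    for s0, s1, f0, f1 in cfg.gaps:
        gap_mask[s0:s1, f0:f1] = False

    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.n_images)

    images = np.empty((cfg.n_images, n_s, n_f), dtype=np.int32)
    masks = np.repeat(gap_mask[None], cfg.n_images, axis=0)

    spots_by_image: dict[int, list] = {}
    for k, sp in kept_spots:
        spots_by_image.setdefault(sp.image, []).append((k, sp))

    ss_grid, ff_grid = np.meshgrid(np.arange(n_s) + 0.5, np.arange(n_f) + 0.5, indexing="ij")
    for j in range(cfg.n_images):
        lam = base + drift[j] * ring
        for _, sp in spots_by_image.get(j, ()):
            s0, f0 = sp.centre
            amp = sp.intensity / (2.0 * math.pi * sp.sigma**2)
            lam = lam + amp * np.exp(
                -((ss_grid - s0) ** 2 + (ff_grid - f0) ** 2) / (2.0 * sp.sigma**2)
            )
        rng = np.random.default_rng(children[j])
        images[j] = rng.poisson(lam)

    # shoeboxes around each kept spot; foreground excluded from that image's mask
    spot_df = pd.DataFrame(spot_rows)
    shoeboxes = build_spot_shoeboxes(
        images, gap_mask, geom, spot_df, cfg.fg_radius_sigma, cfg.shoebox_margin
    )
    bg_sums = []
    for sb in shoeboxes:
        lo_s, hi_s, lo_f, hi_f = sb.bbox
        lam_bg = base[lo_s:hi_s, lo_f:hi_f] + drift[sb.image] * ring[lo_s:hi_s, lo_f:hi_f]
        bg_sums.append(float(lam_bg[sb.fg_mask & sb.valid_mask].sum()))
        masks[sb.image, lo_s:hi_s, lo_f:hi_f] &= ~sb.fg_mask

    truth = GroundTruth(
        base_map=base,
        ring_map=ring,
        drift=drift,
        spot_table=spot_df,
        bg_sums=np.asarray(bg_sums),
    )
    table = pd.DataFrame(
        [
            {"id": sb.id, "image": sb.image, "s0": sb.bbox[0], "s1": sb.bbox[1],
             "f0": sb.bbox[2], "f1": sb.bbox[3], "d": sb.d,
             "true_intensity": truth.spot_table.loc[sb.id, "intensity"],
             "true_bg_sum": truth.bg_sums[i]}
            for i, sb in enumerate(shoeboxes)
        ]
    )
    return SimulatedData(
        stack=ImageStack(images=images, masks=masks),
        truth=truth,
        shoeboxes=shoeboxes,
        table=table,
    )


def sample_empty_shoeboxes(
    data: SimulatedData,
    geom: DetectorGeometry,
    n: int,
    d_min: float,
    d_max: float,
    fg_radius: float = 2.5,
    margin: int = 4,
    seed: int = 0,
) -> list:
    """Cut shoeboxes with no underlying spot, uniform in radius over a d range.

    These "zero-intensity reflections" probe background-estimation bias: an
    unbiased background model integrates them to zero on average.  Shoeboxes
    are spread uniformly over azimuth and images.
    """
    rng = np.random.default_rng(seed)
    n_s, n_f = geom.shape
    r_lo = geom.radius_at_resolution(d_max)
    r_hi = geom.radius_at_resolution(d_min)
    half = int(math.ceil(fg_radius)) + margin
    out = []
    n_images = data.stack.n_images
    attempts = 0
    while len(out) < n and attempts < 50 * n:
        attempts += 1
        r = rng.uniform(r_lo, r_hi)
        az = rng.uniform(-math.pi, math.pi)
        s0 = geom.beam_centre[0] + r * math.cos(az)
        f0 = geom.beam_centre[1] + r * math.sin(az)
        lo_s, hi_s = int(math.floor(s0)) - half, int(math.floor(s0)) + half + 1
        lo_f, hi_f = int(math.floor(f0)) - half, int(math.floor(f0)) + half + 1
        if lo_s < 0 or lo_f < 0 or hi_s > n_s or hi_f > n_f:
            continue
        sub_s = np.arange(lo_s, hi_s) + 0.5
        sub_f = np.arange(lo_f, hi_f) + 0.5
        dist2 = (sub_s[:, None] - s0) ** 2 + (sub_f[None, :] - f0) ** 2
        fg = dist2 <= fg_radius**2
        j = int(rng.integers(n_images))
        sb = Shoebox(
            bbox=(lo_s, hi_s, lo_f, hi_f),
            counts=data.stack.images[j, lo_s:hi_s, lo_f:hi_f],
            fg_mask=fg,
            valid_mask=data.stack.masks[j, lo_s:hi_s, lo_f:hi_f] | fg,
            id=len(out),
            image=j,
            d=float(geom.resolution_at(r)),
        )
        out.append(sb)
    return out


def _preset_geometry() -> DetectorGeometry:
    """1024² PILATUS-like panel (0.172 mm px, 264 mm) with the hexagonal-ice
    rings at r ≈ 404–461 px, reproducing the radial sampling of the real
    instruments: an 0.018 Å ring is ~2 px wide, narrow but resolvable."""
    return DetectorGeometry(
        n_slow=1024, n_fast=1024, pixel_size=0.172, distance=264.0,
        beam_centre=(512.0, 512.0), wavelength=1.0,
    )


def default_presets(n_images: int = 100, seed: int = 0) -> dict[str, SimulationConfig]:
    """Named configurations mirroring the main ice-ring regimes.

    - ``sharp``: strong, narrow (σ_d ≤ 0.02 Å) hexagonal-ice rings with
      azimuthal irregularity and per-image amplitude drift — the hardest
      case for a static model.
    - ``diffuse``: broad (σ_d ≥ 0.08 Å) nanocrystalline cubic-ice rings.
    - ``faint``: barely visible rings on a weak background.
    - ``none``: no rings at all (control).
    """
    geom = _preset_geometry()
    j = np.arange(n_images)
    drift = 1.0 + 0.2 * np.sin(2.0 * math.pi * j / max(n_images, 1))
    rng = np.random.default_rng(seed + 977)
    spots = tuple(
        Spot(
            image=int(rng.integers(n_images)),
            centre=(float(rng.uniform(20, geom.n_slow - 20)), float(rng.uniform(20, geom.n_fast - 20))),
            intensity=float(rng.uniform(500, 5000)),
            sigma=1.5,
        )
        for _ in range(60)
    )
    sharp_rings = tuple(
        IceRing(d=d, amplitude=a, width=0.018, modulation=0.3, phase=ph)
        for d, a, ph in zip(HEXAGONAL_ICE_D, (60.0, 100.0, 45.0), (0.3, 1.4, 2.6))
    )
    diffuse_rings = (IceRing(d=CUBIC_ICE_D[0], amplitude=25.0, width=0.10),)
    faint_rings = tuple(
        IceRing(d=d, amplitude=4.0, width=0.05) for d in HEXAGONAL_ICE_D
    )
    common = dict(geometry=geom, n_images=n_images, seed=seed, spots=spots)
    return {
        "sharp": SimulationConfig(
            base_background=15.0, rings=sharp_rings, ring_drift=drift, **common
        ),
        "diffuse": SimulationConfig(base_background=20.0, rings=diffuse_rings, **common),
        "faint": SimulationConfig(base_background=10.0, rings=faint_rings, **common),
        # smooth radial solvent-scatter falloff, no rings: the control case
        "none": SimulationConfig(base_background=(25.0, 0.0, -10.0), rings=(), **common),
    }


def scaled_preset(name: str, size: int = 128, n_images: int = 20, seed: int = 0) -> SimulationConfig:
    """A preset scaled down to ``size``² pixels with geometry rescaled so the
    ice rings stay on the panel (useful for quick runs and unit tests)."""
    cfg = default_presets(n_images=n_images, seed=seed)[name]
    geom = cfg.geometry
    factor = size / geom.n_slow
    small = DetectorGeometry(
        n_slow=size, n_fast=size, pixel_size=geom.pixel_size,
        distance=geom.distance * factor,
        beam_centre=(size / 2.0, size / 2.0), wavelength=geom.wavelength,
    )
    rng = np.random.default_rng(seed + 977)
    spots = tuple(
        Spot(
            image=int(rng.integers(n_images)),
            centre=(float(rng.uniform(10, size - 10)), float(rng.uniform(10, size - 10))),
            intensity=float(rng.uniform(500, 5000)),
            sigma=1.5,
        )
        for _ in range(20)
    )
    return replace(cfg, geometry=small, spots=spots)
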