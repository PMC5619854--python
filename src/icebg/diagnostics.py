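"""Evidence plots and statistics for background-model quality.

Three views reveal ice-ring damage and whether a background model removed
it:

- intensity versus resolution: a biased background shows up as a spike in
  the binned mean intensity at the ring d-spacing with dips either side;
- per-pixel index of dispersion (variance/mean over the stack): Poisson
  pixels sit near 1, drifting ice-ring pixels well above it;
- fourth acentric moments of the normalised structure factors E: 2 for
  untwinned and 1.5 for perfectly twinned error-free intensities, inflated
  by σ(I)²/⟨I⟩² when measurement errors are folded in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from icebg.geometry import DetectorGeometry, radius_map
from icebg.global_model import PixelStatistics

__all__ = [
    "ResolutionSeries",
    "MomentSeries",
    "intensity_vs_resolution",
    "fourth_moment_E",
    "dispersion_report",
    "DispersionReport",
]


@dataclass
class ResolutionSeries:
    """Per-reflection intensities plus binned means with standard errors."""

    d: np.ndarray
    intensity: np.ndarray
    variance: np.ndarray
    bin_edges: np.ndarray
    bins: pd.DataFrame  # columns: d_centre, n, mean, se, ice_ring

    def spike_bins(self) -> pd.DataFrame:
        return self.bins[self.bins["ice_ring"]]


def intensity_vs_resolution(
    d,
    intensity,
    variance=None,
    n_bins: int = 30,
    d_range: tuple[float, float] | None = None,
    ring_d=(),
    ring_halfwidth: float = 0.05,
) -> ResolutionSeries:
    """Bin reflection intensities by resolution and flag ice-ring bins.

    Bins are linear in d over ``d_range`` (data range by default).  The
    standard error of each bin mean is estimated from the within-bin scatter;
    bins whose range overlaps ``ring_d ± ring_halfwidth`` are flagged.
    """
    d = np.asarray(d, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if d.size == 0:
        raise ValueError("no reflections to bin")
    variance = (
        np.full_like(intensity, np.nan) if variance is None else np.asarray(variance, float)
    )
    keep = np.isfinite(d) & np.isfinite(intensity)
    d, intensity, variance = d[keep], intensity[keep], variance[keep]
    if d.size == 0:
        raise ValueError("no finite reflections to bin")
    lo, hi = d_range if d_range is not None else (d.min(), d.max())
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    rows = []
    for k in range(n_bins):
        sel = idx == k
        n = int(sel.sum())
        centre = 0.5 * (edges[k] + edges[k + 1])
        ice = any(
            (edges[k] <= rd + ring_halfwidth) and (edges[k + 1] >= rd - ring_halfwidth)
            for rd in ring_d
        )
        if n == 0:
            rows.append({"d_centre": centre, "n": 0, "mean": np.nan, "se": np.nan, "ice_ring": ice})
            continue
        vals = intensity[sel]
        mean = float(vals.mean())
        se = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        rows.append({"d_centre": centre, "n": n, "mean": mean, "se": se, "ice_ring": ice})
    return ResolutionSeries(
        d=d, intensity=intensity, variance=variance, bin_edges=edges, bins=pd.DataFrame(rows)
    )


@dataclass
class MomentSeries:
    """Fourth moments of |E| per resolution bin with the inflated expectation."""

    d_centre: np.ndarray
    m4: np.ndarray
    expected_untwinned: np.ndarray  # 2 + σ(I)²/⟨I⟩² per bin
    n: np.ndarray
    flagged: np.ndarray  # True where ⟨I⟩ <= 0 (no moment)


def fourth_moment_E(
    intensities,
    variances=None,
    d=None,
    n_bins: int = 20,
) -> MomentSeries:
    """Fourth acentric moment ⟨E⁴⟩ of normalised structure factors per bin.

    Normalisation is per resolution bin: ``E² = I / ⟨I⟩`` with ⟨I⟩ the bin
    mean (all intensities, negatives included); negative ``E²`` values are
    clipped to 0 in the fourth-moment estimator.  Error-free Wilson acentric
    intensities give ⟨E⁴⟩ = 2 (untwinned) and 1.5 (perfect twin); with
    measurement variances the untwinned expectation inflates to
    ``2 + σ(I)²/⟨I⟩²``, which is reported per bin alongside the estimate.
    When ``d`` is omitted a single bin is used.
    """
    I = np.asarray(intensities, dtype=float).ravel()
    if I.size == 0:
        raise ValueError("no intensities")
    var = None if variances is None else np.asarray(variances, dtype=float).ravel()
    if d is None:
        groups = [np.arange(I.size)]
        centres = np.array([np.nan])
    else:
        d = np.asarray(d, dtype=float).ravel()
        edges = np.linspace(d.min(), d.max(), n_bins + 1)
        idx = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
        groups = [np.nonzero(idx == k)[0] for k in range(n_bins)]
        centres = 0.5 * (edges[:-1] + edges[1:])

    m4 = np.full(len(groups), np.nan)
    exp4 = np.full(len(groups), np.nan)
    n = np.zeros(len(groups), dtype=int)
    flagged = np.zeros(len(groups), dtype=bool)
    for k, g in enumerate(groups):
        n[k] = g.size
        if g.size == 0:
            flagged[k] = True
            continue
        mean_I = I[g].mean()
        if mean_I <= 0:
            flagged[k] = True
            continue
        e2 = np.maximum(I[g] / mean_I, 0.0)
        m4[k] = float(np.mean(e2**2))
        if var is not None:
            exp4[k] = 2.0 + float(np.mean(var[g])) / mean_I**2
        else:
            exp4[k] = 2.0
    return MomentSeries(d_centre=centres, m4=m4, expected_untwinned=exp4, n=n, flagged=flagged)


@dataclass
class DispersionReport:
    """Summary of the per-pixel index of dispersion across the detector."""

    median: float
    by_bin: pd.DataFrame  # d_centre, n, median_dispersion, ice_ring
    ring_median: float
    off_ring_median: float

    @property
    def ring_contrast(self) -> float:
        """Ratio of ring-bin to off-ring median dispersion (1 ⇒ no excess)."""
        return self.ring_median / self.off_ring_median


def dispersion_report(
    stats: PixelStatistics,
    geom: DetectorGeometry,
    ring_d=(),
    ring_halfwidth: float = 0.05,
    n_bins: int = 40,
) -> DispersionReport:
    """Median index of dispersion overall and per resolution bin.

    Static Poisson pixels give a median near 1.0; resolution bins containing
    drifting ice rings stand out with elevated medians.
    """
    disp = stats.dispersion
    finite = np.isfinite(disp)
    r = radius_map(geom)
    d_map = np.asarray(geom.resolution_at(r))
    overall = float(np.median(disp[finite])) if finite.any() else np.nan

    dd = d_map[finite]
    vv = disp[finite]
    ok = np.isfinite(dd)
    dd, vv = dd[ok], vv[ok]
    # bin linearly in 1/d^2 (d diverges at the beam centre; reciprocal-space
    # binning is the crystallographic convention and keeps shells comparable)
    s2 = 1.0 / dd**2
    edges = np.linspace(0.0, s2.max(), n_bins + 1)
    idx = np.clip(np.digitize(s2, edges) - 1, 0, n_bins - 1)
    rows = []
    ring_vals, off_vals = [], []
    for k in range(n_bins):
        sel = idx == k
        centre = float(1.0 / math.sqrt(0.5 * (edges[k] + edges[k + 1]))) if edges[k + 1] > 0 else np.inf
        d_hi = 1.0 / math.sqrt(edges[k]) if edges[k] > 0 else np.inf  # low-angle side
        d_lo = 1.0 / math.sqrt(edges[k + 1])
        ice = any(d_lo - ring_halfwidth <= rd <= d_hi + ring_halfwidth for rd in ring_d)
        med = float(np.median(vv[sel])) if sel.any() else np.nan
        rows.append({"d_centre": centre, "n": int(sel.sum()), "median_dispersion": med, "ice_ring": ice})
        if sel.any():
            (ring_vals if ice else off_vals).append(med)
    return DispersionReport(
        median=overall,
        by_bin=pd.DataFrame(rows),
        ring_median=float(np.median(ring_vals)) if ring_vals else np.nan,
        off_ring_median=float(np.median(off_vals)) if off_vals else np.nan,
    )
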