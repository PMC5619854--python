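# Methods

## The model

A rotation-series data set is a stack of detector images with Poisson-
distributed photon counts. `icebg` assumes the *shape* of the X-ray
background is stable across the scan and models it as a static per-pixel
map `b`, built once from the whole stack, then scaled per reflection by a
single factor `B` fitted to that reflection's background pixels. This is a
deliberate middle ground: a flat or planar local background cannot follow
an ice ring through a shoebox, while a fully local curved model would be
both noisy and expensive at millions of reflections.

### Building the background shape

1. **Masked mean.** Per-pixel mean over images, using only pixels whose
   per-image mask marks them as background (no predicted reflection
   foreground). Pixels with more than `min_images` (default 10)
   contributing images are kept; for stacks shorter than 10 images the
   threshold drops to `max(1, n_images − 1)`. Mean, unbiased sample
   variance (n−1 denominator; the convention, nothing in the procedure
   depends on it) and the index of dispersion (variance/mean) are recorded
   per pixel.
2. **Polar regrid.** The mean image is mapped to a (radius × azimuth) grid
   so that ice rings become columns of constant resolution. Each pixel's
   square footprint is transformed corner-wise to polar coordinates and the
   straight-edged quadrilateral is intersected with the cell rectangles by
   Sutherland–Hodgman clipping; overlap areas, normalised per pixel, split
   the pixel's counts among cells. Totals are conserved exactly (the
   fractions per pixel sum to 1). Quadrilaterals straddling the azimuth
   seam at ±π are unwrapped and indexed modulo the azimuth bin count, which
   splits them across the seam without loss; rotating the grid by an
   arbitrary azimuth offset leaves radial totals unchanged (tested).
3. **Wrapped median filter** along each constant-resolution column: every
   valid cell is replaced by the median over itself and its `median_window`
   (default 10) nearest valid neighbours in azimuth, wrapping circularly.
   This kills high-valued outliers (zingers, unmasked reflection tails)
   without disturbing the radial ring profile. Filtering operates on the
   area-normalised per-pixel ratio, so partially covered cells are not
   biased low; columns with no more valid cells than the window are left
   unchanged.
4. **Diffusion fill.** Cells that received too little unmasked area
   (below `weight_threshold` = 50% of the cell) are filled by solving the
   discrete Laplace equation with the valid cells as Dirichlet data —
   each missing cell converges to the mean of its four neighbours (azimuth
   wraps, radius does not). The default solver computes this fixed point
   directly with a conjugate-gradient solve on the graph Laplacian of the
   missing cells, which is exact and fast even when large off-detector
   regions of the grid are empty; `method="jacobi"` performs the literal
   relaxation (stopping when the largest update falls below `tol` × the
   valid-value range, default 1e−6) and agrees with the direct solve to
   numerical precision on test grids. Filled values obey the discrete
   maximum principle.
5. **Inverse regrid** through the same overlap fractions: each pixel
   receives the fraction-weighted average of the per-cell ratios, so a
   constant polar field maps back to the same constant and, when every
   covered cell is kept, the round trip is an exact count redistribution
   identity. The two pixel-footprint convolutions (forward and inverse)
   smooth the model radially by about one pixel in total — a property of
   the regridding, so radial features much narrower than ~2 px emerge
   slightly attenuated (see "Limitations").

### Geometry and the polar grid

Resolution follows Bragg's law, `d = λ / (2 sin θ)` with
`2θ = atan(r_mm/distance)`; `d` diverges at the beam centre, and pixels
within 2 px of it are excluded from the regridding (the straight-edge
footprint approximation, whose error is O(px/radius), breaks down there;
elsewhere it is accurate to ~1e−3 of a pixel's area at r ≈ 20 px and
better further out). The radial grid coordinate is pixel radius with
1/`radial_oversample` px bins (default 1 px, `n_az` = 360): radius-linear
binning automatically samples high resolution more coarsely along the
ring direction. `radial_oversample` should be raised (2–4) when the data
contain radial features comparable to 1 px — a Nyquist-style argument:
the bin must not be wider than the narrowest ring to be preserved.

### Fitting each reflection

With Poisson counts `c_i` and model values `b_i` over the N background
pixels of a shoebox, the log-likelihood is maximised in closed form by
`B = Σc_i / Σb_i` with inverse-Fisher variance `var(B) = B / Σb_i`. The
flat baseline used for comparison is the special case `b ≡ 1` (B = mean
background count).

The robust variant transforms counts with the Anscombe transform
`y = 2√(x + 3/8)`, approximately N(μ, 1), predicts `μ_i(B) = 2√(B b_i + 3/8)`,
and solves the Huber-weighted least-squares problem
(`w = min(1, c_tune/|r|)`, `c_tune = 3`, residuals `r_i = y_i − μ_i` at
unit stabilised variance) by iteratively reweighted least squares; each
iteration is a Gauss–Newton step in the single parameter, initialised at
the plain ML estimate, converged when `|ΔB|/B < 1e−6` (default, at most
100 iterations; non-convergence returns the last iterate flagged). The
reported `var(B)` is the inverse of the weighted Gauss–Newton information
`Σ w_i (dμ_i/dB)²`, which reduces to `B/Σb` in the unweighted large-count
limit. A single contaminated pixel's influence is bounded by the tuning
constant — roughly `c_tune/(N·dμ/dB)` — whereas the plain ML estimate
shifts by the outlier's full count share (both tested).

Two documented small-sample properties of the transform matter for
interpretation. It is noticeably biased where the mean count is below ~4;
such fits carry a `low_counts` flag but still run. And at moderate rates
the transform-space fit underestimates the background by ≈ 0.25 counts per
pixel (because E[2√(X+3/8)] falls short of 2√(λ+3/8) by ≈ 1/(4√λ)); a unit
test pins this offset. For bias *experiments* that compare background
shapes, the package therefore contrasts flat-ML against global-ML — the
same unbiased estimator with only the model shape changed — keeping the
robust fit for what it is for: outlier resistance.

Summation integration: `I = Σ_fg c − B Σ_fg b`, with
`var(I) = Σ_fg c + var(B)·(Σ_fg b)²` — Poisson variance of the foreground
sum plus the propagated scale uncertainty. This error formula is this
package's own declaration (the estimator upstream does not fix one).
Negative intensities are legitimate and retained. Degenerate cases are
flagged, not raised: `Σb = 0` (zero model), no foreground, no background,
all-zero counts (B = 0).

## The simulator

The generator emulates exactly the phenomenology the pipeline must handle:
a smooth radial background (flat or polynomial in normalised radius);
powder rings Gaussian in d-spacing at literature ice d-spacings
(hexagonal 3.90/3.67/3.44 Å, cubic 3.67/2.25/1.92 Å) with optional
azimuthal cosine modulation and per-image amplitude drift; Gaussian Bragg
spots with shoeboxes (foreground = within 3σ, background = surrounding
frame); rectangular detector gaps; Poisson counts from per-image streams
spawned deterministically from one master seed. The Gaussian radial ring
profile is intentionally *not* the shape the background model assumes, so
model recovery is a fair test.

Presets mirror the main regimes: `sharp` (strong, narrow σ_d = 0.018 Å
hexagonal rings, 30% azimuthal modulation, ±20% sinusoidal drift — the
hard case), `diffuse` (broad σ_d = 0.10 Å cubic ring), `faint` (weak
rings), `none` (ring-free control with a gentle radial falloff). The
preset detector is a 1024² PILATUS-like panel (0.172 mm pixels, 264 mm,
λ = 1.0 Å), chosen so the rings sit at r ≈ 404–461 px and a sharp ring is
~2.2 px wide — the radial sampling of real MX instruments. On a much
smaller panel the same ring narrows below one pixel and *no* method that
regrids at the pixel scale can represent it; `scaled_preset` provides such
reduced versions for quick tests, with that caveat.

What the simulator does **not** emulate — and hence what passing tests do
not demonstrate: physically rigorous powder profiles (no Lorentzian tails
or preferred-orientation arcs), crystal-orientation-driven spot prediction,
detector point spread, module gap correlations ("virtual pixels"), or
per-image backgrounds that change shape (only ring *amplitude* drifts).
Real sharp, irregular, strongly time-varying rings remain harder than any
static model, as the hard preset is designed to show.

## Acceptance experiments and problem sizes

The statistical targets use 1e6 draws (moments of E: 2 and 1.5 within
±0.02; Anscombe variance 1 within ±0.03) and a 200-image 128² static stack
(median dispersion 1 within ±0.05). The bias-removal experiment uses the
sharp preset at 24 images with no spots, 600 zero-intensity shoeboxes in
d ∈ [3.2, 4.2] Å, 25 resolution bins, and a model built with
`radial_oversample=2`; these sizes give per-bin standard errors a few
counts wide, small enough to expose the flat model's spike (z ≈ +14) and
dips (z ≈ −11) unambiguously. "Bias" is the binned mean intensity of
reflections whose true intensity is zero; the global model is required to
sit within 2 SE of zero in every bin where the flat model fails at |z| ≥ 3.
The ring-free control (512² scaled preset, 16 images, 400 boxes) requires
flat and global intensities to agree within 2 combined SE in every bin.

## Numerical choices

- Pixel (i, j) owns the half-open square [i, i+1) × [j, j+1); centres at
  +0.5. All bookkeeping (masks, bounding boxes, overlap areas) follows
  from this single convention.
- Median window semantics: "the N neighbouring cells" is read as the N
  nearest valid wrapped neighbours *plus* the centre cell (N/2 each side
  for even N); the window is a parameter, so either reading is available.
- Cell validity threshold: 50% of the full cell area, exposed as
  `weight_threshold`.
- Convergence tolerances: diffusion 1e−6 of the valid value range; IRLS
  1e−6 relative in B. Conservation checks are logged per stage and hold
  to ~1e−9 relative (floating-point accumulation only).
- Determinism: no stage uses randomness; the same stack yields the same
  model bit for bit, and image order is irrelevant (the mean commutes).

## Limitations

- The model is static: ring-amplitude drift through the scan widens the
  per-reflection scatter and genuinely time-varying ring *shapes* are out
  of scope (a scan-varying model would be the natural extension).
- Radial features narrower than ~2 px are attenuated by a few per cent by
  the two regridding convolutions; raise `radial_oversample` and/or use a
  geometry that resolves them.
- The robust fit inherits the Anscombe transform's small-count bias
  (flagged below mean counts of 4) and its ≈ −0.25 counts/px offset at
  moderate rates.
- Single flat panel only; no parallax, thickness or multi-panel geometry.
- 2-D shoeboxes: each reflection is fitted on one image slice; no 3-D
  profile fitting.
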