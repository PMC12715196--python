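# Models and methods

## The gated decay model

A gated SPAD-array acquisition records `k` images, the detector gate
(width `w`, ns) opening at delays `t_m = t_start + m·ΔT` relative to the
laser trigger.  The excitation pulse is modelled as a Gaussian of width
σ; the fluorescence impulse response as a sum of up to four exponential
components `A_i e^{−t/τ_i}`.  The expected counts in the gate at delay
`t` are the Gaussian-convolved decay integrated over `(t, t+w)`:

    μ(t) = Σ_i A_i [F_i(t − t0 + w) − F_i(t − t0)] + baseline
    F_i(x) = (τ_i/2) [ erf(x/√2σ) − exp(σ²/2τ_i²) erfc(σ/√2τ_i − x/√2σ) e^{−x/τ_i} ]

The product `exp(σ²/2τ²)·erfc(·)·e^{−x/τ}` overflows in the naive form
for σ/τ ≳ 2; it is evaluated as `erfcx(z)·e^{−x²/2σ²}` where `z > 0`
and as `erfc(z)·e^{σ²/2τ² − x/τ}` where `z ≤ 0`, both bounded.  Unit
tests pin the analytic form against adaptive-quadrature integration of
the convolved decay to 10⁻⁶ relative over the practical parameter range
(τ ∈ 0.3–8 ns, σ ∈ 0.05–0.6 ns, w ∈ 1–10 ns).

The instrument response itself (laser reflection measured with the
gate) is the Gaussian integrated over the gate window — an erf
difference with free σ, w, t0 and an overall amplitude.  The amplitude
is not part of the shape and exists so the model can be fitted to
measured IRF counts.

**Assumptions and validity.**  Wrap-around from previous laser pulses
is not modelled; the model is valid when the laser period exceeds
roughly five times the longest lifetime (T = 50 ns, τ_max ≈ 5.4 ns
here).  The gate is treated as sharp-edged; σ absorbs the combined
laser and gate edge width.

## Maximum-likelihood fitting

Fits minimize the Poisson negative log-likelihood `Σ_m (μ_m − n_m ln μ_m)`
with bounded L-BFGS-B (weighted least squares with weights
`max(n, 0.05·mean(n))` is selectable for corrected counts that are no
longer Poisson; the weight floor is proportional to the mean so that
least-squares estimates are invariant under rescaling of the counts).
Two numerical choices matter:

- **Amplitude profiling.**  The counts-scale amplitude is 4–5 orders of
  magnitude larger than the ns-scale lifetimes; left in the optimizer it
  flattens the quasi-Newton steps and the fit stalls short of the
  optimum.  Whenever the baseline is fixed at 0 the optimal amplitude
  has a closed form (`Σn/Σshape` for Poisson) and is profiled out, so
  the optimizer only sees shape parameters.  The same is done for the
  IRF fit.
- **Deterministic multi-start.**  Two-exponential likelihoods have
  local optima; fits start from a fixed grid of lifetime pairs and
  fractions derived from the tail log-slope estimate (last 60% of
  post-peak gates), and the IRF fit from a ±1-gate-step grid around the
  half-maximum edge estimates.  The best NLL wins.  Convergence
  tolerance is 10⁻⁸ on the relative NLL change.

σ and w are always held fixed at the values extracted from the IRF
measurement — gated data cannot constrain them together with the
lifetimes.  `FitResult.converged` is false when the optimizer fails,
when a free lifetime lands on its bounds, or when the decay has fewer
than `min_photons` (default 100) counts; in the last case the estimates
are the deterministic initial values.  Standard errors come from the
numerically inverted observed information at the optimum.

Per-pixel fits (`pixelwise_fit`) run the same machinery independently
per pixel with NaN for sub-threshold or non-converged pixels.  Masked
("sum") fits sum the decay over the mask first — the photon-weighted
behaviour the two-round workflow and pattern derivation rely on.

## Corrections, and one clipping subtlety

Dark counts are subtracted per gate and pixel, then the pile-up
inversion `N_corr = −ln(1 − N·F/255)·255/F` is applied (in that order;
F = 1 static, 3.5 scanned illumination).  Counts at ≥ 99.9% of the
invertible range `255/F` are clamped and flagged per pixel rather than
erroring, since bright-pixel saturation is routinely excluded
downstream (e.g. by the 95th-percentile cap).

Subtraction clips at 0 by default, which the phasor transform requires.
The clip, however, adds `rate·P(N=0)` per pixel to near-empty gates;
summed over a mask this floor mimics a long-lifetime tail and can bias
two-component sum fits by whole nanoseconds at low dark rates.
Summed-decay pipelines therefore subtract with `clip=False`: individual
pixels may go slightly negative, but per-gate sums stay unbiased and
the correction formula extends smoothly through zero.

## Phasor analysis

The discretized transform uses gate centers `(m+½)ΔT` and
`ω = 2π/(k·ΔT)` — the total detection time spanned by the gates, not
the laser period, following the transform's definition.  Gate width
does not enter; the complex division by the IRF phasor absorbs the
common gate-shape bias along with the pulse delay and width (verified
to 5·10⁻³ against a sharp-IRF reference at fine gate sampling; at
k = 25 the residual discretization difference is ~10⁻²).  Automatic
cursor placement runs count-weighted k-means on pixels above a count
threshold (default 100) and draws 2-Mahalanobis-σ ellipses from the
weighted cluster covariances.  k-means splits even a unimodal cloud
into halves separated by ~2.7× the within-half spread, so clusters
closer than 3× the spread along the center axis are labelled degenerate
and a warning is raised.

## Unmixing

Patterns (τ₁, τ₂, short-amplitude fraction a₁) come from free
two-component fits to each mask's summed decay; patterns from several
planes/organoids average photon-weighted.  The pixel-wise superposition
fit holds the pattern curves fixed (normalized to unit gate-sum, so
each amplitude is the photon count attributed to that species) and
solves the two non-negative amplitudes per pixel by multiplicative
EM-type updates, vectorized over all pixels — the same Poisson MLE a
bounded optimizer would find, orders of magnitude faster per frame.
Amplitude maps are Gaussian-smoothed (σ = 1 px) before weighting the
total intensity into species images; the unsmoothed path is kept and
sums exactly to the total intensity.

## Fusion and quality metrics

Registration is a single global 3D translation by phase correlation
(the transform class the dual-view geometry requires); confidence is
the Pearson correlation of the aligned overlap, and shifts with
confidence < 0.2 are zeroed with a warning.  The specimen is segmented
in a maximum-intensity projection (Gaussian σ = 10 px, mean threshold,
disk-10 dilation); sigmoid weights `1/(e^{±(x−l/2)/(l/8)}+1)` over the
bounding-box width l blend the two views per x.  Note the sigmoid's
scale is l/8, so at the box edges the opposite view still carries
weight `1/(e⁴+1) ≈ 0.018` — the blend never becomes strictly one-sided
inside the box.

DCTS is the Shannon entropy of the L2-normalized 2D DCT magnitudes
within a low-frequency support, divided by the coefficient count;
higher = sharper.  No absolute reference values exist for it here; it
is pinned by monotonicity under Gaussian blur and invariance to
intensity scaling.  The depth-intensity profile segments each plane
(Gaussian blur + Otsu), bins mask pixels by distance to the mask edge
(2 µm default) and reports the 99th-percentile intensity per bin,
flagging bins with fewer than 10 pixels.

## The two-round Flipper-TR workflow

Round 1: per z-plane, pixels between the 50th and 95th intensity
percentile (in-focus membrane, excluding pile-up-prone bright pixels)
are summed and fitted with both lifetimes and the amplitude ratio free;
the short lifetime and ratio average unweighted over planes and
organoids into `FlipperGlobals`.  The amplitude ratio is defined as the
short-component amplitude fraction a₁/(a₁+a₂): a value of 0.45 means
45% of the pre-exponential amplitude is in the short component.
Round 2 re-fits each plane, timepoint or cell with those two values
fixed, leaving only τ₂ and the amplitude free — tests show this roughly
halves the τ₂ spread at 10⁴ photons.  Cell masks are external label
images, dilated by a disk of radius 1 to cover the junction width.

## What the simulator emulates — and what it does not

Scenes place up to four species on a 2D frame: membrane networks are
dilated Voronoi-cell boundaries, nuclei are compact super-Gaussian
blobs placed at the interiors of the *same* Voronoi cells (so the two
structures are spatially complementary, as in tissue), plus uniform
fields.  Brightness is expected photons per structure pixel summed over
gates; exponential attenuation along z and the propagation axis is
optional.  The acquisition realizes expected counts through the
saturation map `N = (255/F)(1 − e^{−λF/255})` — exactly the map the
pile-up correction inverts — with binomial statistics over
`round(255/F)` effective binary frames (rescaled so the mean equals the
map), and dark counts at 0.1 counts/gate/pixel by default.

Benchmark scenes fix the study conditions:

- `two_species_organoid` (64×64): nuclei pattern τ = 2.1/5.4 ns with
  a₁ = 0.85, membrane pattern τ = 1.0/4.8 ns with a₁ = 0.45, 400
  photons/pixel, ≥10⁵ photons per species mask.  The nuclei fraction is
  chosen so the photon-weighted mean lifetimes of the species differ by
  ~1.2 ns, the separation reported for GFP vs Flipper-TR.
- `flipper_timelapse` (64×64): membrane pattern τ = 1.0/5.0 ns,
  a₁ = 0.45, 700 photons/membrane-pixel plus a uniform floor at 10% of
  that — a membrane stain leaves no pixel of an organoid truly empty,
  and without the floor the percentile mask would admit empty
  background pixels whose selected upward noise adds a spurious flat
  tail.
- `uniform_calibration` (32×32): ~1000 counts/pixel mono-exponential
  field, the bright-pixel benchmark regime.
- `dual_view_pair`: a 4-plane nuclei volume with x-attenuation for
  registration/fusion tests.

Not modelled: optical blur and scattering, light-sheet waist geometry,
fixed-pattern detector noise, afterpulsing, and the mechanistic
beam-passage origin of the scanning pile-up factor (F is a single
configurable parameter, and the scanning saturation is the same
one-parameter map the correction inverts — so correction validation is
a well-posed round trip, not an independent hardware model).  Passing
recovery tests therefore demonstrate the *analysis chain* is unbiased
under the stated photon statistics; they do not certify performance
under optical aberrations or detector artifacts absent from the model.

Default timing (25 gates, 2 ns step, 5 ns width, 50 ns period,
σ = 0.25 ns, t0 = 5 ns) is a simulator convention consistent with a
25-gate acquisition; problem sizes in the test suite (frame sizes
32–64 px, 9 unmixing replicates, 3×18 flipper planes, 100 seeds for
per-cell tracking) are chosen so the full validation runs on one CPU in
about a minute per suite file.

## Known limitations

- Two free lifetimes maximum per fit; more components are only
  supported with fixed patterns.
- The pile-up inversion amplifies noise near saturation; above ~80% of
  the 8-bit range the corrected counts acquire a convexity (Jensen)
  bias that no longer cancels, which is why bright pixels are capped or
  flagged rather than trusted.
- Per-pixel IRF maps are supported at the API level via per-fit
  `IRFParams`, but the batch helpers use a single global IRF.
- The phasor transform requires non-negative counts, so it runs on the
  clipped correction path and inherits its (small, ratio-level) floor
  bias; masks are unaffected in practice.
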