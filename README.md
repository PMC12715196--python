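# gatedflim

Analysis of time-gated fluorescence lifetime imaging (FLIM) data from
SPAD-array detectors, as produced by light-sheet FLIM microscopes: the
detector records one image per nanosecond gate position, and the per-gate
photon counts sample the fluorescence decay in every pixel.

The package is for microscopists and image analysts working with gated
FLIM hyperstacks who need calibrated lifetimes rather than raw contrast.
It covers the complete chain:

- **Gated decay model** — analytic expected counts for a Gaussian
  excitation pulse (width σ) convolved with exponential decays and
  integrated over a sharp-edged gate of width *w*:
  the gate at delay *t* sees `A [F(t−t0+w) − F(t−t0)]`, with `F` the
  closed-form antiderivative of the Gaussian⊗exponential (erf/erfcx
  form, stable for σ/τ ≫ 1).  The IRF itself is the erf difference
  `√(π/2) σ [erf((t−t0+w)/√2σ) − erf((t−t0)/√2σ)]`.
- **Poisson maximum-likelihood fitting** — model objects
  (`IRFModel`, `GatedDecayModel`) whose `fit()` returns a `FitResult`
  with estimates, standard errors from the observed information,
  convergence diagnostics and a `summary()` table.  One or two
  exponential components; any of {amplitude, short-amplitude fraction
  f₁, τ₁, τ₂, t₀, baseline} can be held fixed.
- **Corrections** — dark-count background subtraction and the pile-up
  inversion for 8-bit gated images, `N_corr = −ln(1 − N·F/255)·255/F`
  (F = 1 static, F = 3.5 scanned illumination).
- **Phasor analysis** — discretized phasor transform
  `G = Σ N_m cos(ω(m+½)ΔT)/ΣN_m` (likewise S with sin, ω = 2π/T),
  complex division by the IRF phasor, elliptic cursors (manual or
  count-weighted k-means) and back-mapping to pixel masks.
- **Two-species unmixing** — per-mask summed-decay fits define fixed
  two-component lifetime patterns; a superposition with only the
  species amplitudes free is fitted per pixel and weights the total
  intensity into unmixed species images.
- **Dual-illumination fusion & quality** — phase-correlation 3D
  translation registration, sigmoid weights
  `w₁,₂(x) = 1/(e^{±(x−l/2)/(l/8)}+1)` over the specimen bounding box,
  weighted-sum fusion of intensity and lifetime stacks, DCTS (DCT
  Shannon entropy) sharpness scoring and 99th-percentile
  depth-intensity profiles.
- **Flipper-TR two-round tension workflow** — 50th–95th percentile
  masking, free two-component sum fits per z-plane (round 1), global
  fixing of the short lifetime and amplitude ratio, and fixed-globals
  τ₂ tracking per plane, timepoint or segmented cell (round 2).
- **Forward simulator** — organoid-like scenes (Voronoi membrane
  networks, nuclei blobs), Poisson/binomial photon statistics, the
  8-bit gate saturation whose exact inverse is the pile-up correction,
  and dark counts — so every stage is testable without microscope data.

## Worked example

Simulate a two-species organoid plane (nuclear GFP-like label plus a
Flipper-TR-like membrane probe), correct it, and recover both lifetime
patterns from the phasor plot:

```python
from gatedflim import (GatedStack, correct_stack, phasor_transform,
                       irf_correct, irf_phasor, auto_cursors,
                       select_and_backmap, derive_patterns)
from gatedflim.simulate import make_benchmark_scene, simulate
import numpy as np

scene, acq = make_benchmark_scene("two_species_organoid", seed=1)
stack, truth = simulate(scene, acq, seed=1)
plane = GatedStack(stack.data[:, 0], stack.timeline)
dark = GatedStack(np.full_like(plane.data, acq.dark_rate, dtype=float),
                  plane.timeline)
corrected, _ = correct_stack(plane, dark, acq.pileup, clip=False)
masks_src, _ = correct_stack(plane, dark, acq.pileup)   # clipped, for phasor

ph = irf_correct(phasor_transform(masks_src), irf_phasor(acq.irf, plane.timeline))
cursors = auto_cursors(ph, n=2, min_counts=100, seed=0)
masks = select_and_backmap(ph, cursors)
patterns, fits = derive_patterns(corrected, masks, acq.irf)
for p in sorted(patterns, key=lambda p: p.mean_lifetime):
    print(f"{p.label}: tau1={p.tau1:.2f} ns  tau2={p.tau2:.2f} ns  a1={p.a1:.2f}")
```

Output:

```
species_0: tau1=2.07 ns  tau2=5.12 ns  a1=0.83
species_1: tau1=1.01 ns  tau2=4.79 ns  a1=0.45
```

The first line is the nuclear species (generated with τ = 2.1/5.4 ns,
short-amplitude fraction 0.85), the second the membrane probe
(generated with τ = 1.0/4.8 ns, fraction 0.45): the phasor-selected
masks and summed-decay fits recover the generating patterns.

A `gatedflim` console script exposes the same stages as subcommands
(`simulate`, `correct`, `fit`, `phasor`, `unmix`, `fuse`, `flipper`,
`quality`), each writing a JSON provenance record alongside its output.

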