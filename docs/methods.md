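# Methods

This note documents the models implemented in `limbusflow`, the defaults and
why they were chosen, the numerical details, and what the synthetic-data
tests do and do not establish.

## Imaging model (phantom generator)

A frame is `background + Σ tubes`, convolved with the PSF, plus additive
Gaussian noise, clamped at zero:

- **Geometry.** Square field of view, default 423 μm over a 512 px grid
  (pitch ≈ 0.826 μm — fine enough to resolve 3.5 μm optical features).
  Pixel centers, 0-based, row-major; all physical outputs in μm.
- **Vessels.** A vessel is a polyline centerline with a Gaussian
  cross-section: intensity A·exp(−d²/2σ₀²) of the distance d to the
  centerline. The operational **diameter is the profile FWHM**
  2√(2 ln 2)·σ₀ ≈ 2.3548·σ₀. The imaging literature never defines vessel
  "diameter" operationally for this instrument; FWHM is the standard
  profile-based convention and makes the radius-from-scale calibration below
  exact. Tubes are truncated at 4σ₀ (relative error < 4·10⁻⁴).
- **PSF.** Isotropic Gaussian with FWHM equal to the 3.5 μm lateral
  resolution (σ_psf ≈ 1.486 μm). Because Gaussians are closed under
  convolution, a rendered vessel has observed profile SD
  σ′ = √(σ₀² + σ_psf²) — this identity is both a generator test and the
  basis of the PSF deconvolution in the diameter estimator. The fiber-bundle
  honeycomb artifact is not simulated: the instrument's own viewer already
  interpolates it away, and the analysis operates on such post-processed
  frames.
- **Noise.** Additive Gaussian only. Intensities are arbitrary units (au)
  with no photon calibration available, so Poisson shot noise would be an
  invented parameter; "SNR 10" in the tests means peak amplitude / noise SD
  = 10.
- **Wash-in.** Single saturating exponential
  I(t) = I∞·(1 − e^−(t−t0)/τ) for t ≥ t0, else 0 — the simplest monotone
  saturating form consistent with an empirical rise to plateau. Presets:
  τ = 300/ln 20 ≈ 100.1 s (porcine, 95% of plateau at 5 min) and
  τ = 420/ln 20 ≈ 140.2 s (human, 7 min).
- **Limbal dataset.** 24 angles at 15° spacing per eye. Per-angle total
  vessel fluorescence is drawn from N(1742, 271²) au on the inferior arc
  and N(1300, 316²) au elsewhere. These group summaries come from ex-vivo
  human-eye imaging and are reported as mean ± SEM; the per-angle spread behind them is not
  recoverable, and treating the printed dispersions as per-angle SEMs
  (SD ≈ 1014/1843 au) would contradict the direction-reproducibility
  requirement the generator must meet (the probability of the inferior
  sample mean exceeding the other mean would be only ≈ 0.86). The printed
  dispersions are therefore used as the **between-angle SDs** of the
  generator's stated world. Group sizes (eyes, angles) are parameters, not
  constants. Large-caliber vessels (top 30% of the 10–50 μm range) are
  confined to contiguous angular runs of ≈ 45° (configurable), mirroring the
  observed clustering of large episcleral vessels.

## Ridge detection and scale-derived diameters

At each scale σ from a 12-point geometric grid spanning 1.5–25 μm (covering
FWHM 10–50 μm with margin on both sides):

    R(σ) = (σ²)^γ · max(0, −λ_min(H_σ)),

where H_σ is the Hessian of the σ-smoothed image (Gaussian derivatives,
reflective boundaries, expressed per μm² so responses are
pitch-independent) and λ_min its most-negative eigenvalue. Only bright
ridges are kept — fluorescein is a positive contrast agent.

- **Scale calibration.** On a Gaussian ridge of SD σ₀ the response in the
  scale variable t = σ² is ∝ t^γ·σ₀·(σ₀² + t)^−3/2, maximized at
  t* = γσ₀²/(3/2 − γ). **γ = 0.75 gives σ* = σ₀ exactly**, a parameter-free
  width estimate; γ = 1 would give σ* = σ₀√2. The estimator then reports
  the PSF-deconvolved FWHM 2√(2 ln 2)·√(max(σ*² − σ_psf², ε)) with
  ε = 10⁻⁴ μm² guarding point-like detections.
- **Sub-grid scale refinement.** The geometric grid has a step of ≈ 29% in
  σ; nearest-grid selection alone would quantize widths by up to ±13%,
  which would dominate the ≤ 10% recovery requirement. A quadratic fit of
  log R against log t over the argmax and its two neighbours refines σ*
  (verified error < 0.1% in σ on the analytic response); grid-edge maxima
  cannot be refined and are flagged `scale_clipped`.
- **Across-scale combination.** The default keeps the per-pixel **maximum
  over scales** (ties to the smallest scale — the sharper interpretation),
  the standard automatic-scale-selection rule. The instrument vendor's
  description mentions a "medium response" whose exact combination rule is
  unpublished (possibly a median); a median-over-scales switch
  (`combine="median"`) is provided, affecting thresholding/suppression while
  σ* always comes from the argmax.
- **Detection.** Pixels above `response_threshold` that are local maxima of
  the combined response along the across-ridge normal (eigenvector of
  λ_min) survive; sub-pixel position comes from a quadratic fit along the
  normal (offset clipped to ±0.5 px). Detections within 3σ* of the frame
  edge are flagged `near_edge`.
- **Linking.** Greedy: from the strongest unclaimed point, extend in both
  tangent directions to the nearest unclaimed point within
  `link_max_gap_px` (default 5) whose orientation differs ≤ 45° and which
  lies ahead of the travel direction (±75° cone). A KD-tree-accelerated
  merge pass then joins chain ends within twice the gap with consistent
  tangents — this repairs crossings, where the shared point is claimed by
  whichever chain passes first; only chains of ≥ 4 points participate
  (shorter fragments are noise, and merging them is quadratic in their
  number). Segments shorter than `min_segment_len_px` points are dropped.
- **Threshold choice.** Responses scale linearly with image amplitude, so
  no universal default exists. At SNR 10 the finest scales (1.5–2 μm,
  below the PSF width) respond to pixel noise with magnitudes comparable to
  true vessel responses, which is why the recovery tests run at
  `response_threshold = 4.0` (phantom amplitude 100 au) and match detected
  segments to ground-truth centerlines — the standard evaluation protocol —
  rather than assuming the frame contains nothing but the vessel.

## ROI kinetics

`roi_total_intensity` sums pixel centers with Euclidean distance ≤ radius
(boundary inclusive; verified against an explicit double-loop oracle,
exactly). The wash-in fit is bounded trust-region least squares of
B + I∞(1 − e^−(t−t0)/τ)·1[t ≥ t0] with initialization I∞₀ = range,
τ₀ = span/3, t₀₀ = first time above 5% of range. When no sample precedes
the onset, t0 and (B, I∞) trade off exactly (only B + I∞, I∞·e^{t0/τ} and τ
are identified), so t0 is bounded below at one median sampling interval
before the first sample; the bound moves with the time axis, preserving
shift equivariance. The **optimal imaging time** is operationalized as the
time of 95% of fitted plateau, t0 + τ·ln 20 — plateau times are otherwise
only described qualitatively; the 95% criterion is recorded in the fit result.
Constant series are flagged degenerate (I∞ = 0, optimal time = t0);
non-convergence returns a flagged, unfitted course rather than raising.
Intensities are never renormalized.

## Quadrant statistics

The inferior quadrant is the **closed** arc 225–315°: the arc is conventionally
given as "from 225° to 315°" without stated endpoint handling, so both endpoints
count as inferior (7 of 24 grid angles; the convention is recorded in the
comparison output). Angles are normalized modulo 360 before
classification, with 270° at the inferior pole. The headline test pools
eyes — inferior (n = 7 per eye) vs all others (n = 17 per eye) — using a
two-tailed two-sample t-test; **Welch** (unequal variance) is the default
since the reporting convention specifies only a two-tailed t-test, and the pooled-variance
variant is available for exact reproduction of either convention. A per-eye
stratified report is also provided. No multiple-testing correction is
applied: the design is a single pre-specified comparison. Cluster analysis
reports maximal circular runs of consecutive angles whose per-angle maximum
diameter meets a threshold (span = 15° × run length, wrapping 345° → 0°).

A note on the permutation cross-check: the analytic t p-value agrees with a
20,000-draw permutation p within 0.01 on continuous small groups, but *not*
on the tied 3-vs-3 integer example {3,4,5} vs {1,2,3}, whose permutation
distribution has only C(6,3) = 20 atoms (exact permutation p = 4/20 = 0.2
vs analytic 0.0705). The tests check the continuous-group agreement and,
separately, the 3v3 sampled permutation against its exact enumeration.

## What the synthetic world does and does not establish

Green tests establish that the algorithms are internally correct: scale
selection matches its closed form, diameters are recovered to < 10% at
SNR 10 across 10–50 μm, midlines are localized to ≤ 1 px on curved
phantoms, ROI sums are exact, wash-in timing is recovered to one frame
interval, the t-test holds its type-I error, and the default effect spec
reproduces the inferior-excess direction in ≥ 95% of runs.

They do **not** establish performance on real CLE frames: the phantoms have
no honeycomb artifact, no motion, no depth-dependent attenuation, no
out-of-focus background vessels, Gaussian rather than physical noise, and
vessel profiles that are exactly Gaussian. The printed group summaries
(1742 ± 271 vs 1300 ± 316 au) parameterize the generator; they are inputs,
not reproduced measurements — the original cadaveric-eye images are not
publicly deposited, so no criterion can compare against them directly.

## Scaled-down defaults in tests

To keep the suite within a small CPU budget, recovery tests use 256 px
grids (pitch ≈ 1.65 μm, still ≥ 2 px per PSF FWHM and ≥ 6 px per minimum
vessel) and the wash-in/pipeline tests 64–128 px grids; the generator's
default remains 512 px. No acceptance threshold was altered to accommodate
the scaling.
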