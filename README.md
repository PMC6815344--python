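# limbusflow

Quantification of episcleral blood-vessel morphology and regional
aqueous-outflow variation from fluorescence confocal laser endomicroscopy
(CLE) frames.

## The problem

Aqueous humor drains through Schlemm's canal into collector channels and
episcleral veins, and the capacity of this outflow system varies around the
corneoscleral limbus. Minimally invasive glaucoma surgery (MIGS) ablates or
bypasses a segment of the trabecular meshwork, so knowing *which* clock hours
carry the most outflow could make the surgery more effective. Fiber-optic CLE
(423 × 423 μm field of view, 3.5 μm lateral resolution) can image episcleral
vessels after intracameral fluorescein injection; this package provides the
computational chain that turns those frames into quantitative morphology:

1. **Synthetic phantoms** (`limbusflow.phantom`) — CLE-like frames with known
   ground truth: Gaussian-profile tubular vessels (diameter ≡ profile FWHM
   = 2√(2 ln 2)·σ₀), isotropic Gaussian PSF matched to the 3.5 μm lateral
   resolution, additive noise, saturating-exponential dye wash-in, and a
   24-position limbal dataset with an inferior-quadrant fluorescence excess.
2. **Multiscale ridge segmentation** (`limbusflow.ridge`) — vessels are
   bright ridges; at each scale σ the detector computes the γ-normalized
   magnitude of the most-negative Hessian eigenvalue of the σ-smoothed image,
   R(σ) = (σ²)^γ·|λ_min|, takes the per-pixel maximum over scales,
   suppresses non-maxima across the ridge (sub-pixel), and links the
   surviving points into midline segments. With γ = 0.75 the scale of
   maximal response satisfies σ* = σ₀ on Gaussian profiles, so the selected
   scale is a calibration-free width estimate; the reported diameter is the
   PSF-deconvolved FWHM 2√(2 ln 2)·√(σ*² − σ_psf²).
3. **Wash-in kinetics** (`limbusflow.flow`) — total ROI fluorescence per
   frame vs time, fitted with total(t) = B + I∞(1 − e^−(t−t0)/τ); the
   optimal imaging time is when the curve reaches 95% of plateau,
   t0 + τ·ln 20 (≈5 min porcine, ≈7 min human presets).
4. **Limbal mapping** (`limbusflow.limbal`) — per-angle summaries on the 15°
   grid, inferior quadrant = closed arc 225–315° (7 of 24 positions),
   two-tailed two-sample t-test (Welch default) of inferior vs all other
   positions, and circular run-length analysis of large-diameter clusters.
5. **Pipeline & I/O** (`limbusflow.pipeline`, `limbusflow.io`) —
   simulate → segment → quantify → compare with a reproducible artifact
   bundle; TIFF/PNG frames and CSV/JSON tables.

## Worked example

```sh
python examples/limbal_quadrants.py
```

```
inferior: 1701 +/- 77 au (n=14)
other:    1319 +/- 60 au (n=34)
Welch t = 3.92, df = 29.1, p = 0.000489 (significant at alpha = 0.05)
large-vessel cluster: 120-150 deg (span 45 deg)
large-vessel cluster: 240-270 deg (span 45 deg)
large-vessel cluster: 300-0 deg (span 75 deg)
```

Two simulated eyes, 24 limbal angles each: the inferior arc carries more
total fluorescence (mean ± SEM, arbitrary units) and the difference is
significant under a Welch t-test pooling both eyes. Large-caliber vessels
(≥ 38 μm here) group in contiguous angular runs of roughly 45–75°.

Segmentation recovery on a noisy phantom (`examples/segment_vessels.py`):

```
largest segment: 338 midline points, median diameter 30.0 um (truth: 30.0 um)
```

Wash-in timing (`examples/washin_timecourse.py`):

```
time constant tau = 140.4 s (truth 140.2 s)
optimal imaging time (95% of plateau): 421 s - about 7 minutes, the human-eye preset
```

The other examples (`simulate_frame.py`, `full_pipeline.py`) render a
ground-truth phantom frame and run the end-to-end pipeline with its artifact
bundle (sample CSVs, comparison JSON, overlay PNG, run manifest).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's main results from scratch at the given seed: it
simulates a two-eye circumferential dataset, segments all 48 frames, runs
the quadrant comparison, fits the wash-in model on a simulated human-preset
series, and recovers a phantom diameter, printing each result. See
`docs/methods.md` for the model details, parameter defaults, and the limits
of what the synthetic world can establish.
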