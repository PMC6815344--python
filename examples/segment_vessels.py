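"""Segment vessels in a noisy phantom and recover their diameters.

A 30 um vessel is rendered at signal-to-noise 10, the multiscale ridge
detector is run, and the per-segment diameter table is printed.  The
largest segment should recover the true caliber to within a few percent.
"""

import limbusflow as lf

spec = lf.FrameSpec(grid_px=256, background_au=20.0, noise_sd_au=10.0, seed=2)
vessel = lf.VesselTruth.from_fwhm(
    lf.straight_centerline(spec, angle_deg=30.0), 30.0, 100.0)
frame, _ = lf.generate_vessel_frame(spec, [vessel])

params = lf.ScaleSpaceParams(response_threshold=4.0)
segments = lf.segment_frame(frame, params)
table = lf.frame_vessel_summary(frame, segments)

main = table.loc[table["n_points"].idxmax()]
print(f"{len(segments)} segments detected "
      f"(short noise fragments included at this threshold)")
print(f"largest segment: {int(main['n_points'])} midline points, "
      f"median diameter {main['median_diameter_um']:.1f} um "
      f"(truth: {vessel.truth_diameter_um:.1f} um)")
print(f"total intraluminal fluorescence: {main['total_intraluminal_au']:.0f} au")

overlay = lf.render_overlay(frame, segments)
print(f"overlay image: {overlay.shape} uint8 RGB "
      "(midline red, border blue) - save with imageio if desired")
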