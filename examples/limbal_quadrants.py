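"""Circumferential quadrant statistics on a simulated two-eye dataset.

Generates per-angle total fluorescence for 24 limbal positions (15 degree
grid) in two eyes with the default inferior-quadrant excess, runs the
two-tailed Welch t-test of inferior (225-315 deg) vs all other positions,
and locates the angular clusters of large-caliber vessels.
"""

import limbusflow as lf

spec = lf.FrameSpec()
effect = lf.LimbalEffectSpec(n_eyes=2)           # defaults: 1742 vs 1300 au
samples, _ = lf.generate_limbal_dataset(spec, effect, seed=4)

c = lf.compare_inferior_vs_rest(samples)
print(f"inferior: {c.group_means_au['inferior']:.0f} +/- "
      f"{c.group_sems_au['inferior']:.0f} au (n={c.n_per_group['inferior']})")
print(f"other:    {c.group_means_au['other']:.0f} +/- "
      f"{c.group_sems_au['other']:.0f} au (n={c.n_per_group['other']})")
print(f"Welch t = {c.t_stat:.2f}, df = {c.df:.1f}, p = {c.p_value:.4g} "
      f"({'significant' if c.significant else 'not significant'} at "
      f"alpha = {c.alpha})")

table = lf.diameter_by_angle(samples)
runs = lf.cluster_span(table, high_threshold_um=38.0)
for start, end, span in runs:
    print(f"large-vessel cluster: {start:.0f}-{end:.0f} deg (span {span:.0f} deg)")
# Clusters of ~45 deg match the spatial grouping of large episcleral vessels
# the generator emulates.
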