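"""Volumetric group analysis: detect a lateralized caudate volume deficit.

Generates a two-group cohort (39 controls vs 39 cases) in which the cases'
right-caudate volumes are reduced by 10% and the left by 5% — the
right-lateralized pattern reported in pediatric ADHD morphometry. Runs the
independent-samples Student t-test per side on the ground-truth volumes and
prints the table: the right side should reject H0 at alpha = 0.05 and the
left (sub-threshold effect) should not.
"""

from caudatecut.pipeline import gt_volume_analysis

results = gt_volume_analysis(n_control=39, n_case=39, deficit=0.10, seed=0)

print(f"{'side':>6} {'M ctrl':>8} {'M case':>8} {'d':>7} {'t':>6} {'p':>8}  decision")
for side in ("right", "left"):
    r = results[side]
    decision = "reject H0" if r.reject else "accept H0"
    print(
        f"{side:>6} {r.mean_a:8.1f} {r.mean_b:8.1f} {r.diff:7.1f} "
        f"{r.t:6.2f} {r.p:8.4f}  {decision}"
    )
print("Volumes in mm^3. d is the control-minus-case mean difference; only "
      "the right caudate's reduction is statistically detectable.")
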