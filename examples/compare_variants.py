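"""Which learning mechanism converges fastest?

Runs the three cue-bearing variants on 60 shared seeds and compares their
convergence speed: constant attention (cue only) learns fastest, cue-enhanced
attention is intermediate, and attention independent of cues is slowest —
even though all three converge to (nearly) the same gaze-following value.
"""

from gazerl import ModelSpec, Variant, compare_models

specs = [
    ModelSpec(variant=v)
    for v in (Variant.CUE, Variant.ENHANCEMENT, Variant.INDEPENDENT_STATE)
]
out = compare_models(specs, seeds=range(60))

print(f"{'variant':<22}{'median conv. trial':>20}{'IQR':>16}{'asymptote':>11}")
for v, med, iqr, fp in zip(
    out["variants"], out["median_convergence"], out["iqr"],
    out["weighted_fixed_points"],
):
    print(f"{v:<22}{med:>20.0f}{f'[{iqr[0]:.0f}, {iqr[1]:.0f}]':>16}{fp:>11.4f}")

print()
for (a, b), p in out["pairwise_p_faster"].items():
    print(f"P[median({a}) < median({b})] = {p:.3f}")

print(
    "\nMedian convergence trials order cue < enhancement < independent_state "
    "\n(bootstrap confidence near 1 for each pair): communicative cues speed "
    "\nup learning most when they also raise the infant's attentional state."
)
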