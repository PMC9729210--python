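"""Segment a speckled multi-object phantom with the power-mean model.

Generates the standard three-object scene (disk + rectangle + ring on a
dark background) corrupted by multiplicative speckle noise of variance
0.2, segments it at the default settings (p=0.5, mu=0.7, sigma=3), and
reports overlap accuracy against the known ground truth.
"""

from powerseg import ModelParams, dice, jaccard, realize, segment, three_object_spec

image, truth = realize(three_object_spec(seed=0))
result = segment(image, ModelParams(), ground_truth=truth)

print(f"iterations           : {result.iterations} (converged={result.converged})")
print(f"region centers       : c1={result.centers.c1:.3f}, c2={result.centers.c2:.3f}")
print(f"final energy         : {result.energy_trace[-1]:.1f}")
print(f"Jaccard vs truth     : {jaccard(result.mask, truth):.4f}")
print(f"Dice vs truth        : {dice(result.mask, truth):.4f}")
print()
print("c1/c2 are the recovered foreground/background intensities. The")
print("background (0.2) is recovered closely; the foreground estimate sits")
print("near 1.0 because variance-0.2 speckle saturates a large fraction of")
print("the bright objects' pixels at the intensity ceiling, and the robust")
print("location locks onto that mode. Jaccard and Dice measure overlap of")
print("the thresholded membership with the uncorrupted object mask.")
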