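"""Compare the power-mean model with the CV and FEBM baselines.

Runs all three models on five seeded speckle-0.2 phantoms and prints the
per-seed and median Jaccard accuracies.  FEBM is the least-squares (p=1)
limit of the power-mean model; CV is the classical piecewise-constant
model in relaxed membership form.
"""

import warnings

import numpy as np

from powerseg import (
    cv_segment,
    febm_segment,
    jaccard,
    realize,
    segment,
    three_object_spec,
)

warnings.simplefilter("ignore", RuntimeWarning)

rows = {"power-mean (p=0.5)": [], "FEBM (p=1)": [], "CV": []}
for seed in range(5):
    image, truth = realize(three_object_spec(seed=seed))
    rows["power-mean (p=0.5)"].append(jaccard(segment(image).mask, truth))
    rows["FEBM (p=1)"].append(jaccard(febm_segment(image).mask, truth))
    rows["CV"].append(jaccard(cv_segment(image).mask, truth))

print("Jaccard vs ground truth on 5 speckled phantoms (variance 0.2):")
for name, js in rows.items():
    per_seed = " ".join(f"{j:.3f}" for j in js)
    print(f"  {name:<20} {per_seed}   median {np.median(js):.3f}")
print()
print("Under this heavy multiplicative noise all three memberships-plus-")
print("smoothing pipelines land in the same accuracy band; the robust data")
print("term shows its advantage in the center estimates (see example 01)")
print("and under impulse outliers rather than in symmetric speckle.")
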