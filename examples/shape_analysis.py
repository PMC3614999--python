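"""Landmark shape analysis: GPA, partial warps, CVA and cross-validation.

Simulates a four-species landmark sample at the study's group sizes,
superimposes it, derives the W' shape variables and asks how reliably
species can be told apart by shape alone.
"""

import numpy as np

from leucidelim import (
    default_templates,
    fit_cva,
    gpa_align,
    loo_crossvalidate_cva,
    partial_warp_scores,
    procrustes_distance,
    simulate_landmarks,
)
from leucidelim.pipeline import group_mean_shapes

configs = simulate_landmarks(default_templates(), [65, 26, 27, 27], seed=42)
aligned = gpa_align(configs)
warps = partial_warp_scores(aligned)
print(f"{aligned.n} specimens, {aligned.k} landmarks, "
      f"GPA converged in {aligned.n_iterations} iterations")
print(f"W' matrix: {warps.scores.shape[0]} x {warps.scores.shape[1]} "
      "(36 partial-warp + 2 uniform scores)")

cva = fit_cva(warps.scores, warps.taxa)
print("\nMahalanobis distances between group means (shape space):")
print("      " + "  ".join(f"{l:>7s}" for l in cva.labels))
for i, row in enumerate(cva.mahalanobis):
    print(f"{cva.labels[i]:>4s}  " + "  ".join(f"{v:7.2f}" for v in row))

means = group_mean_shapes(aligned, warps.taxa)
d = procrustes_distance(means["Sl"], means["Ss"])
print(f"\nProcrustes distance between the two congeners' mean shapes: {d:.4f}")

cm = loo_crossvalidate_cva(warps.scores, warps.taxa)
print(f"\nLeave-one-out cross-validation: {cm.overall_correct_pct:.1f}% correct")
for label, pct in zip(cm.labels, cm.per_group_misclassified_pct):
    print(f"  {label}: {pct:.1f}% misclassified")
print("\nHigh accuracy means shape separates the four species; the worst "
      "pairs show where lateral-profile variation overlaps.")
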