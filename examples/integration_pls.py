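"""Shape-genetics integration by two-block partial least squares.

Simulates an integrated dataset in which species mean shapes track
genetic divergence (planted first-pair correlation 0.9) and one specimen
carries another species' sequences, then shows that PLS recovers the
planted correlation and flags the mismatched specimen.
"""

from leucidelim import (
    gpa_align,
    integration_report,
    partial_warp_scores,
    pcoa,
    pls_permutation_test,
    p_distance_matrix,
    simulate_integrated,
    two_block_pls,
)

ds = simulate_integrated(n_per_species=[65, 26, 27, 27], target_r=0.9, seed=7,
                         planted_outlier=True)
print(f"planted analytic first-pair R: {ds.truth['analytic_r']:.3f}")
print(f"planted outlier (morphology of one species, sequences of another): "
      f"{ds.truth['planted_outlier']}")

warps = partial_warp_scores(gpa_align(ds.configs))
dm = p_distance_matrix([ds.alignments["cytb"], ds.alignments["rag1"]])
genetic = pcoa(dm, n_axes=2).coordinates

res = two_block_pls(warps.scores, genetic)
res.permutation_p = pls_permutation_test(warps.scores, genetic, n_perm=999, seed=7)
print(f"\nfitted first-pair R  = {res.pair_correlations[0]:.3f}")
print(f"linear fit R^2       = {res.linear_r2:.3f}")
print(f"Spearman rho         = {res.spearman_rho:.3f}")
print(f"permutation p (999)  = {res.permutation_p[0]:.4f}")

report = integration_report(res, ds.labels(), ds.specimen_ids())
print(f"\nflagged specimens (genetic latent-1 half-plane disagrees with "
      f"their group): {report.flagged}")
print("\nA fitted R near the planted 0.9 with p < 0.05 shows shape and "
      "genetic divergence covary; the flagged specimen is exactly the "
      "planted sequence swap.")
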