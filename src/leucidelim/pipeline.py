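"""End-to-end orchestration: every analysis stage over one specimen roster.

``run_pipeline`` takes landmark configurations, meristic records and
per-marker alignments (any subset), runs the stages that its inputs
support and returns a single nested report dictionary:

1. shape: GPA -> partial warps -> CVA (+ pairwise permutation test) ->
   leave-one-out cross-validation;
2. meristics: classification-tree key + stratified cross-validation;
3. sequences: per-marker variable sites and haplotypes, diagnostic
   differences for a chosen species pair, similarity summaries;
4. distances: averaged p-distance matrix over the phylogenetic markers ->
   2-axis principal coordinate embedding;
5. integration: two-block PLS of the shape block against the genetic
   axes, permutation p-values and the group/outlier report.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .classify import cva_permutation_test, fit_crt, fit_cva, key_text, loo_crossvalidate_cva
from .morphometry import gpa_align, partial_warp_scores, procrustes_distance
from .pls import integration_report, pls_permutation_test, two_block_pls
from .popgen import (
    collapse_haplotypes,
    count_variable_sites,
    diagnostic_differences,
    p_distance_matrix,
    pcoa,
    similarity_summary,
)


def group_mean_shapes(aligned, labels):
    names = sorted(set(labels))
    means = {}
    for name in names:
        rows = [i for i, l in enumerate(labels) if l == name]
        m = aligned.coords[rows].mean(axis=0)
        means[name] = m
    return means


def run_pipeline(
    configs=None,
    meristics=None,
    alignments: Optional[dict] = None,
    distance_markers: Sequence[str] = ("cytb", "rag1"),
    diagnostic_pair: Optional[tuple] = None,
    n_perm: int = 999,
    seed: int = 0,
) -> dict:
    """Run all supported stages and return one nested report dict."""
    report: dict = {}
    warps = None
    labels = None
    specimen_ids = None

    if configs is not None:
        aligned = gpa_align(configs)
        warps = partial_warp_scores(aligned)
        labels = warps.taxa
        specimen_ids = warps.specimen_ids
        cva = fit_cva(warps.scores, labels)
        cva.permutation_p = cva_permutation_test(warps.scores, labels, n_perm=min(n_perm, 199), seed=seed)
        means = group_mean_shapes(aligned, labels)
        names = cva.labels
        pd = np.zeros((len(names), len(names)))
        for i, a in enumerate(names):
            for j in range(i + 1, len(names)):
                pd[i, j] = pd[j, i] = procrustes_distance(means[a], means[names[j]])
        cva.procrustes_group_distance = pd
        loo = loo_crossvalidate_cva(warps.scores, labels)
        report["shape"] = {
            "n_specimens": aligned.n,
            "n_landmarks": aligned.k,
            "gpa_iterations": aligned.n_iterations,
            "cva": cva.to_dict(),
            "loo_crossvalidation": loo.to_dict(),
        }

    if meristics is not None:
        tree = fit_crt(meristics, seed=seed)
        report["meristics"] = {
            "tree": tree.to_dict(),
            "key_text": key_text(tree),
            "cv": tree.cv.to_dict() if tree.cv else None,
        }

    if alignments:
        seq_report = {}
        for marker, aln in alignments.items():
            entry = {
                "n_sequences": len(aln),
                "variable_sites": count_variable_sites(aln) if aln.aligned else None,
                "n_haplotypes": collapse_haplotypes(aln).n_haplotypes if aln.aligned else None,
                "similarity": similarity_summary(aln) if aln.aligned else None,
            }
            if diagnostic_pair is not None and aln.aligned:
                taxa = set(aln.taxa())
                if set(diagnostic_pair) <= taxa:
                    entry["diagnostic_differences"] = diagnostic_differences(
                        aln, *diagnostic_pair
                    ).to_dict()
            seq_report[marker] = entry
        report["sequences"] = seq_report

        available = [m for m in distance_markers if m in alignments]
        if available:
            dm = p_distance_matrix([alignments[m] for m in available])
            ordination = pcoa(dm, n_axes=2)
            report["distances"] = {
                "markers": available,
                "metric_tag": dm.metric_tag,
                "matrix": dm.to_dict(),
                "pcoa": ordination.to_dict(),
            }
            if warps is not None:
                roster = {sid: i for i, sid in enumerate(dm.ids)}
                if set(specimen_ids) == set(dm.ids):
                    order = [roster[sid] for sid in specimen_ids]
                    gscores = ordination.coordinates[order]
                    pls = two_block_pls(warps.scores, gscores)
                    pls.permutation_p = pls_permutation_test(
                        warps.scores, gscores, n_perm=n_perm, seed=seed
                    )
                    rep = integration_report(pls, labels, specimen_ids)
                    report["integration"] = {
                        "pls": pls.to_dict(),
                        "report": rep.to_dict(),
                    }
    return report
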