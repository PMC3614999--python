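"""One call through every stage: simulate, analyse, report.

Generates a complete synthetic four-species dataset and runs the whole
pipeline (shape CVA, meristic key, sequence summaries, distances/PCOA and
the PLS integration), printing the headline numbers of each stage.
"""

from leucidelim import simulate_dataset
from leucidelim.pipeline import run_pipeline

ds = simulate_dataset(n_per_species=[65, 26, 27, 27], seed=11)
report = run_pipeline(
    configs=ds.configs,
    meristics=ds.meristics,
    alignments=ds.alignments,
    diagnostic_pair=("Sl", "Ss"),
    n_perm=199,
    seed=11,
)

shape = report["shape"]
print(f"shape: {shape['n_specimens']} specimens aligned; LOO accuracy "
      f"{shape['loo_crossvalidation']['overall_correct_pct']:.1f}%")
print(f"meristics: CRT cross-validated accuracy "
      f"{report['meristics']['cv']['overall_correct_pct']:.1f}%")
for marker, entry in report["sequences"].items():
    v = entry["variable_sites"]
    print(f"{marker}: {v['variable']}/{v['length']} variable sites, "
          f"{entry['n_haplotypes']} haplotypes")
dd = report["sequences"]["cyfunp"].get("diagnostic_differences")
if dd:
    print(f"cyfunp Sl/Ss diagnostics: {len(dd['substitutions'])} substitutions, "
          f"{len(dd['indels'])} indel block(s)")
pls = report["integration"]["pls"]
print(f"integration: first-pair R = {pls['pair_correlations'][0]:.3f}, "
      f"p = {pls['permutation_p'][0]:.4f}")
print("\nEach stage supports the same conclusion from a different data "
      "source: the four groups are distinct, and shape tracks genetic "
      "divergence.")
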