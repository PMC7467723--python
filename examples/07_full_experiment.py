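"""End-to-end simulated labeling study: two genotypes, every estimator.

A reference genotype and a slow mutant (longer G2, slower entry, slower
larval growth) are pushed through the whole chain — continuous-labeling G2
time course, 3/6/10-h entry accumulation, larval growth, snapshot indices —
and the report compares estimates to generating truths and to the reference.
"""

import json

from spckinetics import ExperimentConfig, run_experiment, popsim

wt = popsim.CellCycleParams(
    t_g1=0.5, t_s=4.0, t_g2=2.25, t_m=0.5,
    entry_rate=6.0, growth_doubling_time=6.1, n_cells=200,
)
mutant = wt.replace(t_g2=2.875, entry_rate=6.0 * 0.82, growth_doubling_time=8.1)

config = ExperimentConfig(
    genotypes={"reference": wt, "slow_mutant": mutant},
    reference="reference",
    master_seed=42,
    n_germlines_g2=30,
    n_germlines_entry=30,
)
report = run_experiment(config)

for name, geno in report["genotypes"].items():
    est, truth = geno["estimates"], geno["truth"]
    print(f"{name}:")
    print(f"  median G2    : {est['median_g2_h']:.3f} h  (truth {truth['analytic_t50_h']:.3f})")
    print(f"  entry rate   : {est['entry_rate_cells_per_h']:.2f} cells/h  "
          f"(truth {truth['entry_rate_cells_per_h']:.2f})")
    print(f"  doubling time: {est['doubling_time_h']:.2f} h  "
          f"(truth {truth['doubling_time_h']:.2f})")
    print(f"  mitotic index: {est['mitotic_index']:.4f}  (truth {truth['m_occupancy']:.4f})")

print("\npercent differences vs reference:")
print(json.dumps(report["percent_difference_vs_reference"], indent=2))
print(
    "\nA longer G2 and slower entry reproduce the signature of a slow,\n"
    "hyper-repressive genotype: +~28% median G2, -~18% entry rate, +~33%\n"
    "doubling time."
)
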