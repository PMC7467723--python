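"""Median G2 length from a continuous EdU labeling time course.

Worms are fed EdU continuously and dissected every 30 min; the percentage of
pH3-positive (M-phase) nuclei that are also EdU-positive rises from 0 to 100
as cells that were in S at labeling onset reach M. A variable-slope sigmoid
constrained to run from 0 to 100 is fit to the series; its t50 is the median
G2 duration. Comparing a reference genotype to a mutant whose G2 is 25%
longer recovers that contrast.
"""

import numpy as np

from spckinetics import kinetics, popsim

SAMPLE_TIMES = tuple(np.arange(0.0, 3.51, 0.5))

wt = popsim.CellCycleParams(t_g1=0.5, t_s=4.0, t_g2=2.25, t_m=0.5, entry_rate=0.0)
mut = wt.replace(t_g2=wt.analytic_t50 * 1.25 - wt.t_m / 2)  # t50 longer by 25%

for name, params, seed in (("reference", wt, 11), ("slow-G2 mutant", mut, 12)):
    protocol = popsim.LabelingProtocol(mode="continuous", sample_times=SAMPLE_TIMES)
    obs = popsim.records_to_dataframe(
        popsim.run_labeling_experiment(params, protocol, n_germlines=40, seed=seed)
    )
    series = kinetics.g2_fraction_series(obs)
    fit = kinetics.fit_g2_t50(series)
    print(f"{name:15s}: t50 = {fit.t50:.3f} h (analytic {params.analytic_t50:.3f} h), "
          f"hill slope {fit.hill_slope:.1f}")
    if name == "reference":
        t50_ref = fit.t50
    else:
        diff = kinetics.percent_difference(t50_ref, fit.t50)
        print(f"\npercent difference in median G2: {diff:+.1f}% "
              "(generating truth +25%)")

print(
    "\nt50 estimates the median G2 because a pH3+ cell becomes EdU+ once the\n"
    "time since labeling onset exceeds its G2 transit plus its position in M."
)
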