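"""Meiotic entry rate from REC-8-/EdU+ accumulation.

Under continuous EdU labeling, cells that enter meiosis lose the SPC marker
REC-8 but keep their EdU label; counting REC-8-negative/EdU-positive nuclei
at 3, 6 and 10 h and fitting a line gives the entry flux in cells per hour.
"""

from spckinetics import kinetics, popsim

TRUE_RATE = 6.0  # cells entering meiosis per hour per germline

params = popsim.CellCycleParams(entry_rate=TRUE_RATE, n_cells=250)
protocol = popsim.LabelingProtocol(mode="continuous", sample_times=(3.0, 6.0, 10.0))
obs = popsim.records_to_dataframe(
    popsim.run_labeling_experiment(params, protocol, n_germlines=30, seed=3)
)

pooled = obs.groupby("time_h")["n_rec8neg_edu"].mean()
print("mean REC-8-/EdU+ cells per germline:")
for t, n in pooled.items():
    print(f"  {t:5.1f} h : {n:6.1f}")

fit = kinetics.fit_entry_rate(pooled.index.to_numpy(), pooled.to_numpy())
print(f"\nfitted entry rate : {fit.slope:.2f} cells/h "
      f"(truth {TRUE_RATE}), r^2 = {fit.r_squared:.4f}")
print(
    "\nThe slope is the differentiation rate of the progenitor pool; the\n"
    "intercept absorbs the early lag while already-labeled cells accumulate."
)
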