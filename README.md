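# spckinetics

Quantitative kinetics of germline **stem and progenitor cell (SPC)**
populations, modeled on the *C. elegans* distal germline: a stochastic
simulator of maintained cycling pools under EdU/pH3/REC-8 labeling, and the
estimators that turn such observations into cell-cycle and differentiation
rates. Everything the estimators consume can be generated by the simulator at
known ground truth, so the whole analysis chain is validated by parameter
recovery.

## Who this is for

Researchers quantifying stem-cell population dynamics from labeling
experiments: cell-cycle phase indices from marker counts, median G2 length
from pulse-labeling time courses, meiotic-entry (differentiation) rates from
label accumulation, doubling times from larval growth — plus the accompanying
molecular (ΔΔCt, poly(A) gel densitometry, immunoblot ratios) and imaging
(Costes-threshold colocalization, PLA focus density) quantifications.

## The model and the estimators

The simulator (`spckinetics.popsim`) is a **conveyor-renewal** population:
`n` cells cycle through G1→S→G2→M with durations `t_G1 … t_M` (fixed, or
gamma-dispersed with CV `duration_cv`); at each division exactly one daughter
re-enters the pool in place. The pool size and the uniform distribution of
cycle ages are therefore stationary, and every snapshot index has a closed
form: the expected fraction of cells in phase *p* is `t_p / t_cycle`. Meiotic
entry is a Poisson flux of `entry_rate` cells/h that converts random cycling
cells to a REC-8-negative state, freezing their EdU label.

The estimators (`spckinetics.kinetics`) mirror the standard assays:

* **Mitotic index** `= n_pH3+ / n_REC-8+`; **S-phase index**
  `= n_EdU+ / n_REC-8+` after a short pulse.
* **Median G2** — under continuous EdU labeling, the percent of pH3+ nuclei
  that are EdU+ at time *t* follows `100 · clamp((t − t_G2)/t_M, 0, 1)`; a
  variable-slope sigmoid `y(t) = 100 / (1 + 10^((t50 − t)·h))` (top/bottom
  fixed at 100/0) is fit, and its `t50 = t_G2 + t_M/2` is the median G2
  length.
* **Meiotic entry rate** — OLS slope of REC-8−/EdU+ counts versus labeling
  duration (cells/h).
* **Doubling time** — log2-linear fit `log2 N(t) = log2 n0 + t/T_d`.
* **SPC-zone length** — distal prefix of cell rows fully occupied by REC-8+
  cells.

`spckinetics.molecular` implements comparative ΔΔCt (fold
`= 2^(−ΔΔCt)`, control group scaled to exactly 1), background-subtracted
max-normalized lane densitometry with primary/secondary poly(A) peak calls,
and loading-normalized immunoblot band ratios. `spckinetics.imaging`
implements Pearson correlation with the Costes automatic threshold (scan the
coupled thresholds downward until the *sub*-threshold correlation reaches
zero) and PLA focus counting as thresholded connected components per µm².

## Worked example

`examples/02_median_g2_sigmoid.py` simulates two genotypes whose analytic
median G2 differs by 25% (reference `t50 = 2.5 h`), runs a continuous
labeling time course sampled every 30 min for 3.5 h on 40 germlines each,
and fits the constrained sigmoid:

```
reference      : t50 = 2.499 h (analytic 2.500 h), hill slope 19.9
slow-G2 mutant : t50 = 3.152 h (analytic 3.125 h), hill slope 1.0

percent difference in median G2: +26.1% (generating truth +25%)
```

The fitted t50s recover the generating medians to within sampling error, and
the genotype contrast recovers the generating +25% difference. The other
scripts in `examples/` walk through phase indices, entry-rate regression,
doubling-time fits, the molecular quantifications, colocalization/PLA, and
the end-to-end two-genotype experiment driver (`spc run config.yaml` from the
shell, or `spckinetics.run_experiment` from Python).

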