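# Methods

## Population model

The simulator represents a maintained pool of cycling stem/progenitor cells
(SPCs) as a *conveyor-renewal* process. Each of `n_cells` cells progresses
through G1 → S → G2 → M according to a per-cell schedule of phase durations;
when a cell completes M, exactly one daughter re-enters the pool in place
(the other is treated as displaced out of the observed zone). This keeps the
pool size constant and the distribution of cell-cycle ages uniform for all
time, which is what gives every snapshot quantity a closed-form expectation:

* fraction of cells in phase *p* = `t_p / t_cycle`;
* fraction EdU+ after a pulse of length *p* = `(t_S + p) / t_cycle`;
* fraction of pH3+ (M-phase) cells that are EdU+ at time *t* of continuous
  labeling = `clamp((t − t_G2)/t_M, 0, 1)`, hence an analytic median
  `t50 = t_G2 + t_M/2`.

The conveyor assumption reflects the biology of a steady-state progenitor
zone that neither grows nor shrinks in the adult; it is also what makes the
estimators testable by parameter recovery rather than by comparison to
another simulator.

**Phase durations.** Defaults are `t_G1 = 0.5 h`, `t_S = 4 h`,
`t_G2 = 2.25 h`, `t_M = 0.5 h` (a 7.25-h cycle with the abbreviated G1
characteristic of germline progenitors, giving an analytic median G2 of
2.5 h). The default reference t50 of 2.5 h was chosen to sit comfortably
inside the standard 0–3.5 h sampling window of a 30-min-interval continuous
labeling design — a 25% longer mutant t50 (3.125 h) must still be crossed by
the sampled series or the sigmoid is unidentifiable. With
`duration_cv > 0`, each cell's schedule is drawn per cycle from gamma
distributions with the nominal means and the requested CV; the default is 0
(fixed durations) so the closed forms above are exact.

**Meiotic entry.** Entry is a Poisson flux over the pool: in a step of
length `dt`, `Poisson(entry_rate · dt)` randomly chosen cycling cells become
MEIOTIC (REC-8−), freezing their label. Because entrants are drawn uniformly
from the pool, an entrant is EdU+ with exactly the current labeled fraction,
and the accumulation of REC-8−/EdU+ cells grows at asymptotic slope
`entry_rate` once all cycling cells are labeled (at `t ≥ t_cycle − t_S`
under continuous labeling). Entry is *not* position-triggered: there is no
spatial axis in the model. The default `entry_rate = 6 cells/h` is a
realistic adult-germline flux; the genotype contrasts only depend on rate
ratios.

**Time stepping.** `advance` moves each cell boundary-to-boundary within a
step (event-exact), so multiple phase transitions per step are handled and
the exact interval a cell spends in S is known. EdU marking is therefore
exact: a cell is labeled iff its S-phase occupancy interval overlaps the
labeling window, with no discretization bias at the window edges. Steps
larger than the shortest nominal phase duration are rejected so that entry
events act on a current phase distribution; the labeling driver uses
`dt = 0.05 h`.

**Seeds.** One master seed per experiment; each germline gets a derived
31-bit stream (`seed · 1000003 + index mod 2^31`) recorded in its
observation rows, so any single germline can be regenerated bit-identically.

## Estimators

**Indices.** Mitotic index = `n_pH3 / n_REC-8`, S-phase index
= `n_EdU / n_REC-8`; zero denominators raise rather than return NaN.

**Median G2.** Per time point, counts are pooled (summed) across germlines
before the percentage is taken — pooling weights germlines by their cell
counts and matches scoring several germlines per time point; per-germline
weighting was considered and rejected for simplicity. The series is fit with
`y(t) = 100 / (1 + 10^((t50 − t) · h))`, top and bottom fixed at 100 and 0,
over `t50 > 0, h > 0` (scipy `curve_fit`, bounded trust-region). Time is
linear, not log-transformed, because sampling starts at `t = 0`.
Initialization: t50 from linear interpolation of the 50% crossing, `h = 1`.
A series that never crosses 50% raises as unidentifiable; time points with
no pH3+ nuclei are dropped with a warning. With fixed durations the
underlying curve is a linear ramp, not a logistic; fitting the logistic to a
30-min grid therefore carries a small model-mismatch bias in t50 (of order
0.05 h) when the 50% crossing falls between samples. This is a property of
the assay design, shared by any analysis of such data, and is well inside
the tolerances used in the tests.

**Entry rate and doubling time.** Plain OLS (no weighting): entered-cell
counts versus labeling duration for the entry rate; `log2 N` versus time for
the doubling time (`T_d = 1/slope`, `n0 = 2^intercept`). Non-positive
counts, constant counts, or non-increasing series raise. The doubling-time
fit is exactly scale-invariant in the counts.

**Percent difference** is reported *signed* as `100 · (test − ref)/ref`
(positive = test larger). The conventional wet-lab phrasing computes
`(ref − test)/ref`, whose sign is opposite; magnitudes agree, and this
package standardizes on the signed test-relative-to-reference convention.

**SPC-zone length** uses the strict prefix rule: the zone is the count of
leading rows fully occupied by REC-8+ cells; the first partial row
terminates it (an interior partial row ends the zone even if later rows are
full).

## Molecular quantifications

**ΔΔCt.** Default mode pairs target and reference Cts per replicate,
computes per-replicate relative abundances `2^(−(Ct_target − Ct_ref))`,
averages them per group, and rescales so the control group is exactly 1.
The classic mean-Ct mode (`mode="mean_ct"`) is also provided; the two agree
whenever replicate scatter is symmetric, and exactly with one replicate.
Fold changes are invariant to adding a constant to every Ct of a run.

**Lane densitometry.** Profiles are background-subtracted (scalar), clipped
at zero, and max-normalized. Replicates must share the tail-length axis
(size calibration is the caller's responsibility; ladder fitting is out of
scope). The primary peak is the global maximum of the mean profile (ties
resolve to the smallest tail length and are flagged); secondary peaks are
local maxima at least 0.5× the primary height (configurable) and at least
3 axis steps away (configurable) — the literature leaves both free, so they
are declared defaults, not inferred ones.

## Imaging

**Costes automatic threshold.** Channel roles are symmetric, so the
threshold coupling line `ch2 = a·ch1 + b` is fit by reduced-major-axis
(orthogonal) regression rather than OLS. T1 is scanned downward from the
channel-1 maximum in steps of one intensity quantization level (1 for
integer data, range/256 for float), with `T2 = a·T1 + b`; the scan stops at
the first (largest) T1 where the Pearson correlation of pixels below *both*
thresholds is ≤ 0. If that never happens (e.g. perfectly correlated
channels) the thresholds land at the minimum intensity and the result is
flagged. `pearson_above` is computed over pixels above threshold in
*either* channel by default (`above="both"` selectable). Block-permutation
significance testing is not implemented.

**PLA foci.** Otsu (default) or fixed-value threshold, 8-connected
components, area filter, density = count / (mask pixels · pixel_size²).

**Granule generator.** Gaussian spots of equal amplitude at uniform random
positions; a `coloc_fraction` share of channel-2 spots reuse channel-1
positions. Additive Gaussian noise, clipped at zero. It emulates the
*statistical* structure of two-channel granule images (spot density, spot
size, known colocalized fraction, read noise) and deliberately not the
confounds of real confocal data: no bleed-through, no uneven illumination,
no nuclear autofluorescence, no z-blur. Passing tests therefore demonstrate
correctness of the measurement chain, not robustness to those confounds.

## Reference scenarios and problem sizes

`spckinetics.benchmarks` fixes the published kinetic truths as generator
settings (doubling times 6.1 vs 8.1 h; median-G2 ratio 1.25; entry-rate
ratios 1.31 and 0.82; transgene fold 4.5; M-occupancy ratio 1.54) and
recovers each quantity end to end. Stochastic scenarios use 150 germlines ×
200 cells per time point for the G2 pipeline and 30 germlines × 200 cells
for the mitotic-index contrast, each averaged over 5 independent replicate
experiments — sizes chosen to match realistic per-experiment germline counts
while keeping Monte-Carlo error a fraction of the assay tolerances. At these
sizes the G2 percent difference has residual bias ≈ +1.7 points from the
sigmoid/ramp mismatch described above, and the mitotic-index contrast has a
standard error ≈ 4 points.

## Known limitations

* No spatial niche geometry, signaling gradients, or distal-tip modeling;
  meiotic entry is a well-mixed Poisson flux.
* pH3 marks M phase only, although the antibody also marks late-G2/prophase
  chromatin in real germlines.
* EdU uptake is instantaneous at the window start (no feeding/uptake lag).
* No label dilution across divisions, no apoptosis, and no separate
  meiotic-S compartment — the non-cycling meiotic-S fraction of real
  progenitor zones (which inflates real mitotic-index denominators) is not
  represented.
* The entry flux depletes the cycling pool over long horizons (entered cells
  are not replaced); time courses beyond ~10 h at high entry rates leave the
  maintained-pool regime.
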