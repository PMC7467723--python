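"""Reference kinetic scenarios computed end to end through the package.

Each function simulates a study condition from the germline SPC literature
— wild-type versus *fbf-1* / *fbf-2* loss-of-function kinetics — at its
published ground truth and recovers the quantity with the package's own
estimators.  :func:`run_all` returns the full set under descriptive names.

Published truths used as generator settings:

* larval doubling time 6.1 h (wild type) and 8.1 h (*fbf-2(lf)*);
* median G2 length longer by 25% in *fbf-2(lf)*;
* meiotic entry rate +31% in *fbf-1(lf)* and −18% in *fbf-2(lf)*;
* transgene mRNA fold change ~4.5 for FBE-mutant versus wild-type 3'UTR;
* mitotic index +54% in *fbf-1(lf)*.
"""

from __future__ import annotations

import numpy as np

from . import kinetics, molecular, popsim

__all__ = [
    "WT_DOUBLING_TIME_H",
    "FBF2_DOUBLING_TIME_H",
    "recover_doubling_time",
    "g2_length_percent_difference",
    "entry_rate_percent_difference",
    "transgene_fold_change",
    "mitotic_index_percent_difference",
    "run_all",
]

WT_DOUBLING_TIME_H = 6.1
FBF2_DOUBLING_TIME_H = 8.1
FBF2_G2_FACTOR = 1.25       # median G2 longer by 25%
FBF1_ENTRY_FACTOR = 1.31    # entry rate up 31%
FBF2_ENTRY_FACTOR = 0.82    # entry rate down 18%
TRANSGENE_FOLD = 4.5
FBF1_M_INDEX_FACTOR = 1.54  # mitotic index up 54%

GROWTH_TIMES_H = (0.0, 17.0, 21.0)
ENTRY_TIMES_H = (3.0, 6.0, 10.0)
G2_SAMPLE_TIMES_H = tuple(np.arange(0.0, 3.51, 0.5))


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % 2**31 for s in ss.generate_state(n)]


def recover_doubling_time(doubling_time: float) -> float:
    """Round-trip a doubling time through noise-free larval growth + fit."""
    counts = popsim.simulate_larval_growth(2, doubling_time, GROWTH_TIMES_H, noise="none")
    fit = kinetics.fit_doubling_time(GROWTH_TIMES_H, counts)
    return fit.doubling_time


def _g2_t50_from_simulation(params: popsim.CellCycleParams, n_germlines: int,
                            seed: int) -> float:
    protocol = popsim.LabelingProtocol(mode="continuous", sample_times=G2_SAMPLE_TIMES_H)
    obs = popsim.records_to_dataframe(
        popsim.run_labeling_experiment(params, protocol, n_germlines, seed)
    )
    series = kinetics.g2_fraction_series(obs)
    return kinetics.fit_g2_t50(series).t50


def g2_length_percent_difference(
    seed: int,
    n_germlines: int = 150,
    n_seeds: int = 5,
    factor: float = FBF2_G2_FACTOR,
) -> float:
    """Percent difference in sigmoid-fit median G2 between two genotypes whose
    analytic t50s (t_g2 + t_m/2) differ by ``factor``; averaged over
    ``n_seeds`` independent replicate experiments.
    """
    wt = popsim.CellCycleParams(t_g1=0.5, t_s=4.0, t_g2=2.25, t_m=0.5, entry_rate=0.0)
    mut_t50 = wt.analytic_t50 * factor
    mut = wt.replace(t_g2=mut_t50 - wt.t_m / 2.0)
    diffs = []
    for s in _spawn_seeds(seed, n_seeds):
        t50_wt = _g2_t50_from_simulation(wt, n_germlines, s)
        t50_mut = _g2_t50_from_simulation(mut, n_germlines, s + 1)
        diffs.append(kinetics.percent_difference(t50_wt, t50_mut))
    return float(np.mean(diffs))


def entry_rate_percent_difference(factor: float, base_rate: float = 6.0) -> float:
    """Percent difference in fitted entry rates for noise-free accumulation
    y = r*t at 3/6/10 h, with the mutant rate = ``factor`` * wild type."""
    t = np.asarray(ENTRY_TIMES_H)
    fit_wt = kinetics.fit_entry_rate(t, base_rate * t)
    fit_mut = kinetics.fit_entry_rate(t, factor * base_rate * t)
    return kinetics.percent_difference(fit_wt.slope, fit_mut.slope)


def transgene_fold_change(fold: float = TRANSGENE_FOLD) -> float:
    """ΔΔCt round trip: shift the target gene's Ct by −log2(fold) in the test
    group (reference gene constant) and recover the fold change."""
    rows = []
    for group, target_ct in (("wt_3utr", 20.0), ("fbm_3utr", 20.0 - np.log2(fold))):
        for rep in (1, 2):
            rows.append({"sample_group": group, "gene": "act-1",
                         "replicate": rep, "ct": 15.0})
            rows.append({"sample_group": group, "gene": "3xflag-cyb-2.1",
                         "replicate": rep, "ct": target_ct})
    table = molecular.CtTable(rows)
    folds = molecular.delta_delta_ct(
        table, target="3xflag-cyb-2.1", reference="act-1", control_group="wt_3utr"
    )
    return float(folds["fbm_3utr"])


def _pooled_mitotic_index(params: popsim.CellCycleParams, n_germlines: int,
                          seed: int) -> float:
    n_ph3 = n_rec8 = 0
    for g in range(n_germlines):
        pop = popsim.init_population(params, popsim.germline_seed(seed, g))
        c = pop.counts()
        n_ph3 += c["n_ph3"]
        n_rec8 += c["n_rec8"]
    return kinetics.mitotic_index({"n_rec8": n_rec8, "n_ph3": n_ph3,
                                   "n_edu": 0, "n_ph3_edu": 0})


def mitotic_index_percent_difference(
    seed: int,
    n_germlines: int = 30,
    n_cells: int = 200,
    n_seeds: int = 5,
    factor: float = FBF1_M_INDEX_FACTOR,
) -> float:
    """Percent difference in snapshot mitotic indices between two genotypes
    with identical cycle length whose M-phase occupancies differ by
    ``factor``; averaged over ``n_seeds`` replicate experiments."""
    wt = popsim.CellCycleParams(
        t_g1=0.5, t_s=4.0, t_g2=2.25, t_m=0.5, entry_rate=0.0, n_cells=n_cells
    )
    t_m_mut = wt.t_m * factor
    # keep the total cycle identical so only the occupancy ratio changes
    mut = wt.replace(t_m=t_m_mut, t_g2=wt.t_g2 - (t_m_mut - wt.t_m))
    diffs = []
    for s in _spawn_seeds(seed, n_seeds):
        mi_wt = _pooled_mitotic_index(wt, n_germlines, s)
        mi_mut = _pooled_mitotic_index(mut, n_germlines, s + 1)
        diffs.append(kinetics.percent_difference(mi_wt, mi_mut))
    return float(np.mean(diffs))


def run_all(seed: int) -> dict[str, dict]:
    """Compute every reference scenario; keys are descriptive quantity names."""
    return {
        "doubling_time_wild_type_h": {
            "value": recover_doubling_time(WT_DOUBLING_TIME_H),
            "n": len(GROWTH_TIMES_H),
        },
        "doubling_time_fbf2_h": {
            "value": recover_doubling_time(FBF2_DOUBLING_TIME_H),
            "n": len(GROWTH_TIMES_H),
        },
        "g2_length_percent_difference_fbf2": {
            "value": g2_length_percent_difference(seed),
            "n": 150,
        },
        "entry_rate_percent_difference_fbf1": {
            "value": entry_rate_percent_difference(FBF1_ENTRY_FACTOR),
            "n": len(ENTRY_TIMES_H),
        },
        "entry_rate_percent_difference_fbf2_magnitude": {
            "value": abs(entry_rate_percent_difference(FBF2_ENTRY_FACTOR)),
            "n": len(ENTRY_TIMES_H),
        },
        "transgene_fold_change_fbm_vs_wt": {
            "value": transgene_fold_change(),
            "n": 8,
        },
        "mitotic_index_percent_difference_fbf1": {
            "value": mitotic_index_percent_difference(seed),
            "n": 30,
        },
    }
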