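"""Simulator correctness: stationary occupancies, labeling closed forms,
entry flux statistics, growth closed forms, determinism."""

import numpy as np
import pytest

from spckinetics import popsim
from spckinetics.popsim import G1, S, G2, M, MEIOTIC

from conftest import single_cell_population


class TestParamsAndProtocol:
    def test_invalid_durations_rejected(self):
        with pytest.raises(ValueError):
            popsim.CellCycleParams(t_g1=0.0)
        with pytest.raises(ValueError):
            popsim.CellCycleParams(duration_cv=1.0)
        with pytest.raises(ValueError):
            popsim.CellCycleParams(n_cells=0)
        with pytest.raises(ValueError):
            popsim.CellCycleParams(entry_rate=-1.0)

    def test_cycle_time_is_sum_of_phases(self, fixed_cycle_params):
        assert fixed_cycle_params.t_cycle == pytest.approx(8.0)
        assert fixed_cycle_params.analytic_t50 == pytest.approx(3.25)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(mode="pulse", sample_times=(1.0,)),  # missing pulse_duration
            dict(mode="continuous", sample_times=()),
            dict(mode="continuous", sample_times=(2.0, 1.0)),
            dict(mode="continuous", sample_times=(1.0,), start_time=2.0),
            dict(mode="banana", sample_times=(1.0,)),
        ],
    )
    def test_bad_protocols_rejected(self, kwargs):
        with pytest.raises(ValueError):
            popsim.LabelingProtocol(**kwargs)

    def test_observation_record_invariants(self):
        with pytest.raises(ValueError):
            popsim.ObservationRecord(
                time=0, n_rec8=10, n_ph3=12, n_edu=0, n_ph3_edu=0,
                n_rec8neg_edu=0, germline_id="g", seed=0,
            )
        with pytest.raises(ValueError):
            popsim.ObservationRecord(
                time=0, n_rec8=10, n_ph3=2, n_edu=1, n_ph3_edu=2,
                n_rec8neg_edu=0, germline_id="g", seed=0,
            )


class TestStationaryInitialization:
    def test_occupancy_equals_duration_over_cycle(self, big_population):
        # uniform-age initialization: P(phase) = duration / cycle
        params, pop = big_population
        n = params.n_cells
        for phase, expected in [(G1, 0.5 / 8), (S, 4 / 8), (G2, 3 / 8), (M, 0.5 / 8)]:
            frac = (pop.phase == phase).mean()
            tol = 4 * np.sqrt(expected * (1 - expected) / n)
            assert frac == pytest.approx(expected, abs=tol)

    def test_phase_age_within_schedule(self, big_population):
        _, pop = big_population
        sched = pop.schedule[np.arange(pop.n_cells), pop.phase]
        assert (pop.phase_age >= 0).all()
        assert (pop.phase_age < sched).all()

    def test_seed_determinism_single_cell(self, fixed_cycle_params):
        p = fixed_cycle_params.replace(n_cells=1)
        a = popsim.init_population(p, seed=42).cell(0)
        b = popsim.init_population(p, seed=42).cell(0)
        assert a == b

    def test_dispersed_schedules_have_requested_cv(self):
        params = popsim.CellCycleParams(duration_cv=0.3, n_cells=50_000)
        pop = popsim.init_population(params, seed=5)
        g2 = pop.schedule[:, G2]
        assert g2.mean() == pytest.approx(params.t_g2, rel=0.02)
        assert g2.std() / g2.mean() == pytest.approx(0.3, rel=0.05)


class TestAdvance:
    def test_boundary_crossing(self, fixed_cycle_params):
        pop = single_cell_population(fixed_cycle_params, G2, 2.9)
        popsim.advance(pop, 0.2, fixed_cycle_params)
        cell = pop.cell(0)
        assert cell.phase == "M"
        assert cell.phase_age == pytest.approx(0.1)

    def test_m_to_g1_wrap_keeps_label(self, fixed_cycle_params):
        pop = single_cell_population(fixed_cycle_params, M, 0.45)
        pop.edu[0] = True
        popsim.advance(pop, 0.1, fixed_cycle_params)
        cell = pop.cell(0)
        assert cell.phase == "G1"
        assert cell.edu

    def test_oversized_dt_rejected(self, fixed_cycle_params):
        pop = popsim.init_population(fixed_cycle_params, 0)
        with pytest.raises(ValueError):
            popsim.advance(pop, 1.0, fixed_cycle_params)  # > t_g1 = t_m = 0.5

    def test_entry_rate_zero_conserves_pool(self, fixed_cycle_params):
        pop = popsim.init_population(fixed_cycle_params, 3)
        for _ in range(80):
            popsim.advance(pop, 0.25, fixed_cycle_params)
        assert pop.counts()["n_rec8"] == fixed_cycle_params.n_cells

    def test_occupancy_stationary_after_advancing(self, fixed_cycle_params):
        # conveyor renewal keeps the age distribution uniform for all time
        params = fixed_cycle_params.replace(n_cells=50_000)
        pop = popsim.init_population(params, 9)
        for _ in range(26):  # 13 h, > one full cycle
            popsim.advance(pop, 0.5, params)
        frac_m = (pop.phase == M).mean()
        tol = 4 * np.sqrt(0.0625 * 0.9375 / params.n_cells)
        assert frac_m == pytest.approx(0.0625, abs=tol)

    def test_entry_flux_matches_poisson_oracle(self, fixed_cycle_params):
        params = fixed_cycle_params.replace(entry_rate=8.0, n_cells=400)
        total = []
        for rep in range(200):
            pop = popsim.init_population(params, 1000 + rep)
            for _ in range(40):
                popsim.advance(pop, 0.25, params)
            total.append(pop.n_entered)
        total = np.array(total)
        # oracle: direct Poisson sampling at the same mean
        oracle = np.random.default_rng(7).poisson(80.0, 200)
        assert total.mean() == pytest.approx(80.0, abs=4 * np.sqrt(80 / 200))
        assert total.mean() == pytest.approx(oracle.mean(), abs=4 * np.sqrt(2 * 80 / 200))
        # dispersion consistent with a Poisson flux
        assert 0.7 < total.var() / total.mean() < 1.3

    def test_entered_cells_lose_rec8(self, fixed_cycle_params):
        params = fixed_cycle_params.replace(entry_rate=10.0)
        pop = popsim.init_population(params, 2)
        for _ in range(40):
            popsim.advance(pop, 0.25, params)
        c = pop.counts()
        assert pop.n_entered > 0
        assert c["n_rec8"] == params.n_cells - pop.n_entered


class TestLabeling:
    def test_pulse_labeled_fraction_closed_form(self, fixed_cycle_params):
        # cells in S at any instant of a pulse of length p: (t_s + p) / t_cycle
        params = fixed_cycle_params.replace(n_cells=20_000)
        protocol = popsim.LabelingProtocol(
            mode="pulse", sample_times=(0.5,), pulse_duration=0.5
        )
        (rec,) = popsim.run_labeling_experiment(params, protocol, 1, seed=7)
        expected = (4.0 + 0.5) / 8.0
        tol = 4 * np.sqrt(expected * (1 - expected) / params.n_cells)
        assert rec.n_edu / rec.n_rec8 == pytest.approx(expected, abs=tol)

    def test_continuous_ph3_edu_fraction_closed_form(self, fixed_cycle_params):
        # P(pH3+ cell is EdU+ at t) = clamp((t - t_g2)/t_m, 0, 1)
        params = fixed_cycle_params.replace(n_cells=5000)
        times = (0.0, 1.0, 2.0, 3.0, 3.25, 3.5, 4.0)
        protocol = popsim.LabelingProtocol(mode="continuous", sample_times=times)
        records = popsim.run_labeling_experiment(params, protocol, 4, seed=21)
        df = popsim.records_to_dataframe(records)
        pooled = df.groupby("time_h")[["n_ph3", "n_ph3_edu"]].sum()
        for t, row in pooled.iterrows():
            expected = np.clip((t - params.t_g2) / params.t_m, 0.0, 1.0)
            frac = row["n_ph3_edu"] / row["n_ph3"]
            tol = 4 * np.sqrt(max(expected * (1 - expected), 0.01) / row["n_ph3"])
            assert frac == pytest.approx(expected, abs=tol), f"t={t}"

    def test_no_double_label_at_time_zero(self, fixed_cycle_params):
        protocol = popsim.LabelingProtocol(mode="continuous", sample_times=(0.0,))
        (rec,) = popsim.run_labeling_experiment(
            fixed_cycle_params.replace(n_cells=5000), protocol, 1, seed=3
        )
        assert rec.n_ph3_edu == 0  # S and M are disjoint phases

    def test_labeled_fraction_monotone_in_time(self, fixed_cycle_params):
        protocol = popsim.LabelingProtocol(
            mode="continuous", sample_times=tuple(np.arange(0.0, 6.1, 0.5))
        )
        records = popsim.run_labeling_experiment(
            fixed_cycle_params, protocol, 3, seed=13
        )
        df = popsim.records_to_dataframe(records)
        for _, g in df.groupby("germline_id"):
            edu = g.sort_values("time_h")["n_edu"].to_numpy()
            assert (np.diff(edu) >= 0).all()

    def test_bitwise_reproducible(self, fixed_cycle_params):
        protocol = popsim.LabelingProtocol(
            mode="continuous", sample_times=(1.0, 2.0)
        )
        a = popsim.run_labeling_experiment(fixed_cycle_params, protocol, 3, seed=5)
        b = popsim.run_labeling_experiment(fixed_cycle_params, protocol, 3, seed=5)
        assert a == b

    def test_records_roundtrip_csv(self, fixed_cycle_params, tmp_path):
        protocol = popsim.LabelingProtocol(mode="continuous", sample_times=(1.0,))
        records = popsim.run_labeling_experiment(fixed_cycle_params, protocol, 2, seed=1)
        path = tmp_path / "obs.csv"
        popsim.write_observations_csv(records, path)
        df = popsim.read_observations_csv(path)
        assert len(df) == 2
        assert df["n_rec8"].tolist() == [r.n_rec8 for r in records]


class TestLarvalGrowth:
    def test_time_zero_identity(self):
        assert popsim.simulate_larval_growth(2, 6.1, [0.0])[0] == 2.0

    def test_one_doubling(self):
        assert popsim.simulate_larval_growth(2, 6.1, [6.1])[0] == pytest.approx(4.0)

    def test_closed_form(self):
        (n,) = popsim.simulate_larval_growth(2, 8.1, [17.0])
        assert n == pytest.approx(2 * 2 ** (17 / 8.1))

    def test_poisson_noise_reproducible_and_near_mean(self):
        a = popsim.simulate_larval_growth(2, 6.1, [17, 21], noise="poisson", seed=3)
        b = popsim.simulate_larval_growth(2, 6.1, [17, 21], noise="poisson", seed=3)
        assert (a == b).all()
        mean = 2 * 2 ** (np.array([17, 21]) / 6.1)
        assert np.all(np.abs(a - mean) < 6 * np.sqrt(mean))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            popsim.simulate_larval_growth(0, 6.1, [1.0])
        with pytest.raises(ValueError):
            popsim.simulate_larval_growth(2, 6.1, [-1.0])
        with pytest.raises(ValueError):
            popsim.simulate_larval_growth(2, 6.1, [1.0], noise="gamma")
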