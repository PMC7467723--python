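"""Stochastic simulator of a maintained, asynchronously cycling stem/progenitor
cell (SPC) population.

The model is a "conveyor renewal" scheme: the pool holds a fixed number of
cycling cells, each progressing through G1 -> S -> G2 -> M with fixed (or
gamma-dispersed) phase durations.  At each division exactly one daughter
re-enters the pool in place, so the pool size and the uniform distribution of
cell-cycle ages are stationary.  This gives every snapshot index a closed-form
truth: the expected fraction of cells in a phase equals that phase's duration
divided by the total cycle time.

Marker semantics mirror the common germline immunostaining readouts:

* ``rec8``  -- cohesin REC-8 marks cycling (pre-meiotic) cells; it is lost on
  meiotic entry, so ``rec8`` is simply ``phase != MEIOTIC``.
* ``ph3``   -- phospho-histone H3 marks M phase; ``ph3`` is ``phase == M``.
* ``edu``   -- the thymidine analog EdU is incorporated during S phase while
  label is being fed; the flag is monotone (once labeled, always labeled, and
  inherited by the continuing daughter).

Meiotic entry is a Poisson flux over the pool: entry events at rate
``entry_rate`` per hour convert randomly chosen cycling cells to MEIOTIC,
freezing their label state.  Entered cells are retained so that accumulation
of REC-8-negative/EdU-positive nuclei can be scored exactly as in a
continuous-labeling time course.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PHASES",
    "G1",
    "S",
    "G2",
    "M",
    "MEIOTIC",
    "CellCycleParams",
    "CellState",
    "LabelingProtocol",
    "ObservationRecord",
    "Population",
    "init_population",
    "advance",
    "run_labeling_experiment",
    "simulate_larval_growth",
    "records_to_dataframe",
    "write_observations_csv",
    "read_observations_csv",
]

# Phase codes.  The four cycling phases are ordered; MEIOTIC is terminal.
G1, S, G2, M, MEIOTIC = 0, 1, 2, 3, 4
PHASES = ("G1", "S", "G2", "M", "MEIOTIC")

_OBS_COLUMNS = [
    "germline_id",
    "time_h",
    "n_rec8",
    "n_ph3",
    "n_edu",
    "n_ph3_edu",
    "n_rec8neg_edu",
    "seed",
]


@dataclass(frozen=True)
class CellCycleParams:
    """Ground-truth kinetic parameters of a simulated genotype.

    Parameters
    ----------
    t_g1, t_s, t_g2, t_m
        Nominal phase durations in hours.  Germline SPCs have an abbreviated
        G1 and a long G2; the defaults reflect an 8-hour cycle dominated by
        S and G2.
    duration_cv
        Coefficient of variation of per-cell phase durations.  0 (default)
        means fixed durations; positive values draw each cell's schedule from
        gamma distributions with the nominal means.
    entry_rate
        Meiotic entry flux, cells per hour per germline.
    growth_doubling_time
        Doubling time (h) used in larval exponential-growth mode.
    n_cells
        Size of the maintained cycling pool per germline.
    """

    t_g1: float = 0.5
    t_s: float = 4.0
    t_g2: float = 2.25
    t_m: float = 0.5
    duration_cv: float = 0.0
    entry_rate: float = 6.0
    growth_doubling_time: float = 6.1
    n_cells: int = 200

    def __post_init__(self) -> None:
        for name in ("t_g1", "t_s", "t_g2", "t_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 <= self.duration_cv < 1.0):
            raise ValueError("duration_cv must be in [0, 1)")
        if self.entry_rate < 0:
            raise ValueError("entry_rate must be >= 0")
        if self.growth_doubling_time <= 0:
            raise ValueError("growth_doubling_time must be > 0")
        if self.n_cells <= 0:
            raise ValueError("n_cells must be a positive count")

    @property
    def durations(self) -> np.ndarray:
        return np.array([self.t_g1, self.t_s, self.t_g2, self.t_m])

    @property
    def t_cycle(self) -> float:
        """Total cycle time in hours."""
        return self.t_g1 + self.t_s + self.t_g2 + self.t_m

    @property
    def analytic_t50(self) -> float:
        """Median time for a pH3+ cell to have completed G2 under continuous
        labeling: t_g2 + t_m/2 for fixed durations."""
        return self.t_g2 + self.t_m / 2.0

    def phase_occupancy(self, phase: int) -> float:
        """Stationary fraction of cycling cells in ``phase`` (duration/cycle)."""
        return float(self.durations[phase] / self.t_cycle)

    def replace(self, **kwargs) -> "CellCycleParams":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class CellState:
    """Read-only view of one cell (mainly for inspection and tests)."""

    phase: str
    phase_age: float
    edu: bool
    cycle_schedule: tuple[float, float, float, float]

    @property
    def ph3(self) -> bool:
        return self.phase == "M"

    @property
    def rec8(self) -> bool:
        return self.phase != "MEIOTIC"


@dataclass(frozen=True)
class LabelingProtocol:
    """EdU feeding protocol.

    ``pulse`` mode labels during ``[start_time, start_time + pulse_duration]``;
    ``continuous`` mode labels from ``start_time`` onward.  ``sample_times``
    are the dissection times (hours, absolute simulation time).
    """

    mode: str
    sample_times: tuple[float, ...]
    start_time: float = 0.0
    pulse_duration: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("pulse", "continuous"):
            raise ValueError("mode must be 'pulse' or 'continuous'")
        times = tuple(float(t) for t in self.sample_times)
        if len(times) == 0:
            raise ValueError("sample_times must not be empty")
        if any(t < self.start_time for t in times):
            raise ValueError("sample_times must all be >= start_time")
        if list(times) != sorted(times):
            raise ValueError("sample_times must be sorted")
        object.__setattr__(self, "sample_times", times)
        if self.mode == "pulse":
            if self.pulse_duration is None or self.pulse_duration <= 0:
                raise ValueError("pulse mode requires pulse_duration > 0")

    @property
    def window(self) -> tuple[float, float]:
        """Absolute labeling window ``(start, end)``; end is inf when continuous."""
        if self.mode == "continuous":
            return (self.start_time, np.inf)
        return (self.start_time, self.start_time + float(self.pulse_duration))


@dataclass(frozen=True)
class ObservationRecord:
    """Marker counts scored from one germline at one time point."""

    time: float
    n_rec8: int
    n_ph3: int
    n_edu: int
    n_ph3_edu: int
    n_rec8neg_edu: int
    germline_id: str
    seed: int

    def __post_init__(self) -> None:
        counts = (self.n_rec8, self.n_ph3, self.n_edu, self.n_ph3_edu, self.n_rec8neg_edu)
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if self.n_ph3_edu > min(self.n_ph3, self.n_edu):
            raise ValueError("n_ph3_edu cannot exceed n_ph3 or n_edu")
        if self.n_ph3 > self.n_rec8:
            raise ValueError("n_ph3 cannot exceed n_rec8")


class Population:
    """Array-backed population state.

    Cycling cells carry a per-cell schedule of realized phase durations (a
    row of 4 floats); MEIOTIC cells no longer advance.  The population owns
    its RNG stream and clock, so :func:`advance` is reproducible from the
    seed used at initialization.
    """

    def __init__(
        self,
        phase: np.ndarray,
        phase_age: np.ndarray,
        edu: np.ndarray,
        schedule: np.ndarray,
        rng: np.random.Generator,
        time: float = 0.0,
    ) -> None:
        self.phase = phase
        self.phase_age = phase_age
        self.edu = edu
        self.schedule = schedule
        self.rng = rng
        self.time = time
        self.n_entered = 0  # cumulative meiotic entries

    # -- scoring -----------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.phase.size

    @property
    def cycling(self) -> np.ndarray:
        return self.phase != MEIOTIC

    def counts(self) -> dict[str, int]:
        """Marker counts as scored in an immunostained germline."""
        cyc = self.cycling
        in_m = self.phase == M
        return {
            "n_rec8": int(cyc.sum()),
            "n_ph3": int(in_m.sum()),
            "n_edu": int((cyc & self.edu).sum()),
            "n_ph3_edu": int((in_m & self.edu).sum()),
            "n_rec8neg_edu": int((~cyc & self.edu).sum()),
        }

    def cell(self, i: int) -> CellState:
        return CellState(
            phase=PHASES[int(self.phase[i])],
            phase_age=float(self.phase_age[i]),
            edu=bool(self.edu[i]),
            cycle_schedule=tuple(float(x) for x in self.schedule[i]),
        )

    def cells(self) -> list[CellState]:
        return [self.cell(i) for i in range(self.n_cells)]


def _draw_schedules(params: CellCycleParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Realized per-cell phase durations: fixed, or gamma with CV = duration_cv."""
    base = np.broadcast_to(params.durations, (n, 4)).copy()
    if params.duration_cv > 0:
        shape = 1.0 / params.duration_cv**2  # gamma CV = 1/sqrt(shape)
        base = rng.gamma(shape, base / shape)
    return base


def init_population(params: CellCycleParams, seed: int) -> Population:
    """Initialize a stationary cycling population.

    Each cell's position in the cycle is drawn uniformly over its own total
    cycle time, which (with conveyor renewal) is the stationary age
    distribution; snapshot phase occupancies are then unbiased estimates of
    duration/cycle.
    """
    n = params.n_cells
    rng = np.random.default_rng(seed)
    schedule = _draw_schedules(params, n, rng)
    totals = schedule.sum(axis=1)
    u = rng.uniform(0.0, totals)
    bounds = np.cumsum(schedule, axis=1)  # (n, 4) upper phase boundaries
    phase = (u[:, None] >= bounds).sum(axis=1).astype(np.int64)
    lower = bounds - schedule
    phase_age = u - lower[np.arange(n), phase]
    edu = np.zeros(n, dtype=bool)
    return Population(phase, phase_age, edu, schedule, rng)


def _step(pop: Population, dt: float, params: CellCycleParams,
          label_window: tuple[float, float] | None) -> None:
    """Advance every cycling cell by ``dt`` with event-exact phase transitions.

    Within the step each cell is moved boundary-to-boundary, so the exact
    interval it spends in S is known and EdU marking via overlap with the
    labeling window is exact (no discretization bias at the window edges).
    """
    t0 = pop.time
    remaining = np.where(pop.cycling, dt, 0.0)
    elapsed = np.zeros(pop.n_cells)
    # Bounded loop: each pass either exhausts `remaining` or crosses one
    # boundary; realized durations are positive so it terminates.
    while True:
        active = remaining > 0
        if not active.any():
            break
        idx = np.flatnonzero(active)
        ph = pop.phase[idx]
        sched = pop.schedule[idx, ph]
        ttb = sched - pop.phase_age[idx]
        adv = np.minimum(remaining[idx], ttb)

        if label_window is not None:
            # exact S-occupancy interval for this sub-step, absolute time
            in_s = ph == S
            if in_s.any():
                s_idx = idx[in_s]
                a0 = t0 + elapsed[s_idx]
                a1 = a0 + adv[in_s]
                lo, hi = label_window
                overlap = np.minimum(a1, hi) - np.maximum(a0, lo)
                pop.edu[s_idx] |= overlap > 0

        crossing = adv >= ttb - 1e-12
        stay = ~crossing
        pop.phase_age[idx[stay]] += adv[stay]
        cross_idx = idx[crossing]
        if cross_idx.size:
            new_phase = pop.phase[cross_idx] + 1
            wrapped = new_phase > M
            # M -> G1: the continuing daughter keeps its label; with
            # dispersion a fresh schedule is drawn for the new cycle.
            if wrapped.any():
                w_idx = cross_idx[wrapped]
                new_phase[wrapped] = G1
                if params.duration_cv > 0:
                    pop.schedule[w_idx] = _draw_schedules(params, w_idx.size, pop.rng)
            pop.phase[cross_idx] = new_phase
            pop.phase_age[cross_idx] = 0.0
        elapsed[idx] += adv
        remaining[idx] -= adv
        remaining[remaining < 1e-12] = 0.0

    # Meiotic entry: Poisson number of events over the step; each converts a
    # randomly chosen cycling cell, freezing its markers.
    if params.entry_rate > 0:
        n_events = pop.rng.poisson(params.entry_rate * dt)
        if n_events:
            cyc_idx = np.flatnonzero(pop.cycling)
            n_events = min(n_events, cyc_idx.size)
            chosen = pop.rng.choice(cyc_idx, size=n_events, replace=False)
            pop.phase[chosen] = MEIOTIC
            pop.n_entered += n_events
    pop.time = t0 + dt


def advance(pop: Population, dt: float, params: CellCycleParams,
            label_window: tuple[float, float] | None = None) -> Population:
    """Advance the population by ``dt`` hours (in place; returns ``pop``).

    ``dt`` must not exceed the shortest nominal phase duration: larger steps
    would let the Poisson entry flux act on a stale phase distribution, so
    they are rejected rather than silently substepped.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if dt > params.durations.min() + 1e-12:
        raise ValueError(
            f"dt={dt} exceeds the shortest phase duration "
            f"({params.durations.min()}); use a smaller step"
        )
    _step(pop, dt, params, label_window)
    return pop


def germline_seed(master_seed: int, index: int) -> int:
    """Derived per-germline integer seed (deterministic counter offset)."""
    return int((master_seed * 1_000_003 + index) % 2**31)


def run_labeling_experiment(
    params: CellCycleParams,
    protocol: LabelingProtocol,
    n_germlines: int,
    seed: int,
    dt: float = 0.05,
) -> list[ObservationRecord]:
    """Simulate an EdU labeling time course and score marker counts.

    Each germline is an independent population with its own derived seed.
    A cell scores EdU-positive at a sample time iff some part of its S phase
    (this or any earlier cycle) fell inside the labeling window up to that
    time.  One record is produced per germline per sample time; the same
    simulated germline is observed at successive times, mirroring a
    continuous time course.
    """
    if n_germlines <= 0:
        raise ValueError("n_germlines must be positive")
    window = protocol.window
    records: list[ObservationRecord] = []
    dt = min(dt, float(params.durations.min()))
    for g in range(n_germlines):
        gseed = germline_seed(seed, g)
        pop = init_population(params, gseed)
        for t_sample in protocol.sample_times:
            # advance in equal sub-steps to the sample time
            span = t_sample - pop.time
            if span > 1e-12:
                n_sub = max(1, int(np.ceil(span / dt)))
                sub = span / n_sub
                for _ in range(n_sub):
                    _step(pop, sub, params, window)
            c = pop.counts()
            records.append(
                ObservationRecord(
                    time=float(t_sample),
                    germline_id=f"g{g:03d}",
                    seed=gseed,
                    **c,
                )
            )
    return records


def simulate_larval_growth(
    n0: int,
    doubling_time: float,
    times: Sequence[float],
    noise: str = "none",
    seed: int | None = None,
) -> np.ndarray:
    """Exponential larval germ-cell accumulation from ``n0`` founders.

    ``noise='none'`` returns the real-valued mean N(t) = n0 * 2**(t/Td);
    ``noise='poisson'`` returns Poisson draws with that mean.
    """
    if n0 < 1:
        raise ValueError("n0 must be >= 1")
    if doubling_time <= 0:
        raise ValueError("doubling_time must be > 0")
    t = np.asarray(times, dtype=float)
    if (t < 0).any():
        raise ValueError("times must be non-negative")
    mean = n0 * 2.0 ** (t / doubling_time)
    if noise == "none":
        return mean
    if noise == "poisson":
        rng = np.random.default_rng(seed)
        return rng.poisson(mean).astype(float)
    raise ValueError("noise must be 'none' or 'poisson'")


# -- tabular I/O ------------------------------------------------------------

def records_to_dataframe(records: Iterable[ObservationRecord]) -> pd.DataFrame:
    rows = [
        {
            "germline_id": r.germline_id,
            "time_h": r.time,
            "n_rec8": r.n_rec8,
            "n_ph3": r.n_ph3,
            "n_edu": r.n_edu,
            "n_ph3_edu": r.n_ph3_edu,
            "n_rec8neg_edu": r.n_rec8neg_edu,
            "seed": r.seed,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=_OBS_COLUMNS)


def write_observations_csv(records: Iterable[ObservationRecord], path) -> None:
    records_to_dataframe(records).to_csv(path, index=False)


def read_observations_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_OBS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"observation table missing columns: {sorted(missing)}")
    return df
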