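"""Synthetic study cohorts for the aversive PIT paradigm.

Generates complete multi-subject datasets with the statistical structure of
the two experiments: an instrumental training phase (gray background), a
Pavlovian threat-conditioning phase (CS+ paired with shock on half of its
trials), and a transfer phase crossing CS+/CS- with the four instrumental
conditions.  Behavioral event logs are produced by driving the task engine
with per-subject responder policies; psychophysiological CS-level amplitude
estimates (SCR, pupil size, heart period) are drawn so that the paired
CS+/CS- contrasts have configurable standardized effect sizes.

The one behavioral effect injected by default is conditioned facilitation
of avoidance: a CS+ increment of the press rate confined to Withdraw-Go
trials, scaled so the population paired effect size equals the configured
Cohen's d (0.40 by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .task import TaskParams, TrialSpec, default_params, simulate_trials_batch

__all__ = [
    "DesignSpec",
    "PsychophysSpec",
    "EffectConfig",
    "SubjectProfile",
    "CohortDataset",
    "make_design",
    "sample_cohort",
    "calibrate_us_intensity",
    "pit_delta_for_target_d",
]

FRAMES = ("approach", "withdraw")
GONOGO = ("go", "nogo")
CS_LEVELS = ("cs+", "cs-")

EVENT_COLUMNS = ["subject", "phase", "block", "trial_index", "frame", "go",
                 "cs", "event_type", "time_s", "value"]


@dataclass(frozen=True)
class DesignSpec:
    """Trial-count structure of one experiment.

    ``phase1_blocks`` / ``phase3_blocks`` are per-block mappings from
    condition tuples — ``(frame, go)`` for phase 1, ``(cs, frame, go)`` for
    phase 3 — to trial counts; trials are presented in random order within
    a block.  Phase 2 is Pavlovian overtraining: 32 CS+ (half reinforced)
    and 32 CS- in random order.
    """

    experiment: int
    n_subjects: int
    phase1_blocks: tuple[Mapping[tuple[str, str], int], ...]
    phase2_cs_plus: int = 32
    phase2_cs_plus_reinforced: int = 16
    phase2_cs_minus: int = 32
    phase3_blocks: tuple[Mapping[tuple[str, str, str], int], ...] = ()
    iti_s: float = 2.5

    def phase3_cell_trials(self, cs: str, frame: str, go: str) -> int:
        return sum(b.get((cs, frame, go), 0) for b in self.phase3_blocks)

    @property
    def phase1_total(self) -> int:
        return sum(sum(b.values()) for b in self.phase1_blocks)

    @property
    def phase3_total(self) -> int:
        return sum(sum(b.values()) for b in self.phase3_blocks)


def make_design(experiment: int, n_subjects: Optional[int] = None) -> DesignSpec:
    """Exact trial-count structure of Experiment 1 or 2.

    Experiment 1: phase 1 = 64 trials (16 per instrumental condition, two
    analysis blocks of 8); phase 3 = 64 trials (8 per CS x frame x go type,
    two analysis blocks of 4).  Experiment 2 shifts the Go:NoGo ratio to
    3:1 — phase 1 = 4 blocks of 16 (6+6 Go, 2+2 NoGo), phase 3 = 2 blocks
    of 32 (six trials per Go type, two per NoGo type).
    """
    if experiment == 1:
        p1 = tuple({(f, g): 8 for f in FRAMES for g in GONOGO} for _ in range(2))
        p3 = tuple({(c, f, g): 4 for c in CS_LEVELS for f in FRAMES for g in GONOGO}
                   for _ in range(2))
        return DesignSpec(experiment=1, n_subjects=n_subjects or 21,
                          phase1_blocks=p1, phase3_blocks=p3, iti_s=2.5)
    if experiment == 2:
        p1 = tuple({(f, g): (6 if g == "go" else 2) for f in FRAMES for g in GONOGO}
                   for _ in range(4))
        p3 = tuple({(c, f, g): (6 if g == "go" else 2)
                    for c in CS_LEVELS for f in FRAMES for g in GONOGO}
                   for _ in range(2))
        return DesignSpec(experiment=2, n_subjects=n_subjects or 35,
                          phase1_blocks=p1, phase3_blocks=p3, iti_s=1.5)
    raise ValueError("experiment must be 1 or 2")


@dataclass(frozen=True)
class PsychophysSpec:
    """CS-level amplitude distribution for one autonomic measure.

    ``diff_sd`` is the between-subject SD of the within-subject CS+ minus
    CS- difference, so the paired effect size is
    (mean_plus - mean_minus) / diff_sd.  ``between_sd`` scatters the CS-
    baseline across subjects.
    """

    mean_plus: float
    mean_minus: float
    diff_sd: float
    between_sd: float
    units: str = ""

    @classmethod
    def from_effect_size(cls, mean_plus: float, mean_minus: float, d: float,
                         between_sd: float, units: str = "") -> "PsychophysSpec":
        if d <= 0:
            raise ValueError("from_effect_size requires d > 0; set diff_sd directly for null configs")
        return cls(mean_plus, mean_minus, (mean_plus - mean_minus) / d,
                   between_sd, units)

    @property
    def d(self) -> float:
        return (self.mean_plus - self.mean_minus) / self.diff_sd


def _default_psychophys() -> dict[str, PsychophysSpec]:
    # CS-level means and paired effect sizes as observed in the confirmation
    # experiment; between-subject SDs back-computed from printed SEMs at n=35.
    rt35 = math.sqrt(35.0)
    return {
        "scr": PsychophysSpec.from_effect_size(0.39, 0.30, 0.673, 0.04 * rt35, "uS"),
        "pupil": PsychophysSpec.from_effect_size(3.16, 3.02, 0.52, 0.07 * rt35, "mm"),
        "heart_period": PsychophysSpec.from_effect_size(13.86, -15.52, 0.78, 3.94 * rt35, "ms"),
    }


@dataclass(frozen=True)
class EffectConfig:
    """Population-level effects and responder parameters for a cohort.

    ``pit_d`` is the target paired Cohen's d for the CS+ vs CS- response
    rate contrast on Withdraw-Go trials; the corresponding per-second rate
    increment is derived analytically from the rate variance components
    (see :func:`pit_delta_for_target_d`).  ``extra_deltas`` may inject CS+
    rate changes into other (frame, go) conditions; they default to zero.
    """

    pit_d: float = 0.40
    pit_delta_sd: float = 0.25
    go_rate_mean: float = 6.4
    go_rate_sd: float = 0.8
    nogo_rate_mean: float = 0.05
    nogo_rate_sd: float = 0.05
    latency_median_approach: float = 0.45
    latency_median_withdraw: float = 0.55
    latency_log_sd: float = 0.25
    extra_deltas: Mapping[tuple[str, str], float] = field(default_factory=dict)
    psychophys: Mapping[str, PsychophysSpec] = field(default_factory=_default_psychophys)

    @classmethod
    def null(cls) -> "EffectConfig":
        """All CS effects zero (behavioral and autonomic)."""
        phys = {name: replace(s, mean_plus=s.mean_minus)
                for name, s in _default_psychophys().items()}
        return cls(pit_d=0.0, psychophys=phys)


@dataclass(frozen=True)
class SubjectProfile:
    """Random-effects realization for one subject."""

    subject: int
    go_rate: float
    nogo_rate: float
    pit_delta: float
    latency_median: Mapping[str, float]


@dataclass
class CohortDataset:
    """Event logs (all phases), psychophysiological amplitude table, and
    the design they realize."""

    events: pd.DataFrame
    psychophys: pd.DataFrame
    design: DesignSpec
    seed: int
    params: TaskParams


def pit_delta_for_target_d(config: EffectConfig, design: DesignSpec,
                           params: TaskParams | None = None) -> float:
    """Rate increment (presses/s) realizing the target paired d.

    The observed per-subject CS difference on Withdraw-Go trials is the
    subject's increment plus trial-averaging noise; with Poisson press
    counts over ``m`` trials per cell of duration ``T`` the difference
    variance is ``pit_delta_sd^2 + 2 * rate / (T * m)``, so the increment
    that yields Cohen's d is ``d * sqrt(that variance)``.
    """
    params = params or default_params()
    m = design.phase3_cell_trials("cs+", "withdraw", "go")
    if m == 0:
        raise ValueError("design has no Withdraw-Go phase-3 trials")
    var = config.pit_delta_sd ** 2 + 2.0 * config.go_rate_mean / (params.response_duration * m)
    return config.pit_d * math.sqrt(var)


def _draw_profiles(design: DesignSpec, config: EffectConfig, delta_pop: float,
                   rng: np.random.Generator, params: TaskParams) -> list[SubjectProfile]:
    profiles = []
    for s in range(design.n_subjects):
        go_rate = float(np.clip(rng.normal(config.go_rate_mean, config.go_rate_sd),
                                0.5, params.max_press_rate - 0.5))
        nogo_rate = float(max(0.0, rng.normal(config.nogo_rate_mean, config.nogo_rate_sd)))
        pit_delta = float(rng.normal(delta_pop, config.pit_delta_sd))
        lat = {f: float(np.exp(rng.normal(math.log(m), config.latency_log_sd)))
               for f, m in (("approach", config.latency_median_approach),
                            ("withdraw", config.latency_median_withdraw))}
        profiles.append(SubjectProfile(s, go_rate, nogo_rate, pit_delta, lat))
    return profiles


def _shuffled_trials(block_maps: Sequence[Mapping],
                     rng: np.random.Generator) -> list[tuple[int, tuple]]:
    """Expand per-block count maps into a randomized (block, condition) list."""
    out = []
    for b, counts in enumerate(block_maps, start=1):
        trials = [cond for cond, k in counts.items() for _ in range(k)]
        rng.shuffle(trials)
        out.extend((b, cond) for cond in trials)
    return out


@dataclass
class _TrialBatch:
    """Column arrays describing every coin trial of one cohort."""

    subject: list[int] = field(default_factory=list)
    phase: list[int] = field(default_factory=list)
    block: list[int] = field(default_factory=list)
    trial_index: list[int] = field(default_factory=list)
    frame: list[str] = field(default_factory=list)
    go: list[str] = field(default_factory=list)
    cs: list[str] = field(default_factory=list)
    rate: list[float] = field(default_factory=list)
    latency: list[float] = field(default_factory=list)

    def add_phase(self, profile: SubjectProfile, config: EffectConfig,
                  params: TaskParams, phase: int,
                  trials: Sequence[tuple[int, tuple]]) -> None:
        for idx, (block, cond) in enumerate(trials):
            if len(cond) == 3:
                cs, frame, go = cond
            else:
                (frame, go), cs = cond, "none"
            rate = profile.go_rate if go == "go" else profile.nogo_rate
            if cs == "cs+":
                if frame == "withdraw" and go == "go":
                    rate += profile.pit_delta
                rate += config.extra_deltas.get((frame, go), 0.0)
            self.subject.append(profile.subject)
            self.phase.append(phase)
            self.block.append(block)
            self.trial_index.append(idx)
            self.frame.append(frame)
            self.go.append(go)
            self.cs.append(cs)
            self.rate.append(float(np.clip(rate, 0.0, params.max_press_rate)))
            self.latency.append(profile.latency_median[frame])


def sample_cohort(
    design: DesignSpec,
    config: EffectConfig | None = None,
    seed: int = 0,
    params: TaskParams | None = None,
    phases: Iterable[int] = (1, 2, 3),
) -> CohortDataset:
    """Generate one full synthetic cohort.

    Deterministic given ``seed``.  ``phases`` can be restricted (e.g. to
    ``(3,)``) when only the transfer phase is needed.
    """
    config = config or EffectConfig()
    params = params or default_params()
    phases = tuple(phases)
    delta_pop = pit_delta_for_target_d(config, design, params) if config.pit_d else 0.0
    if config.go_rate_mean + delta_pop > params.max_press_rate:
        raise ValueError("configured PIT effect infeasible under the press-rate cap")

    root = np.random.SeedSequence(seed)
    order_rng = np.random.default_rng(root.spawn(1)[0])
    press_rng = np.random.default_rng(root.spawn(1)[0])
    dynamics_rng = np.random.default_rng(root.spawn(1)[0])
    phys_rng = np.random.default_rng(root.spawn(1)[0])
    profiles = _draw_profiles(design, config, delta_pop,
                              np.random.default_rng(root.spawn(1)[0]), params)

    batch = _TrialBatch()
    phase2_rows: list[tuple] = []
    for profile in profiles:
        if 1 in phases:
            batch.add_phase(profile, config, params, 1,
                            _shuffled_trials(design.phase1_blocks, order_rng))
        if 2 in phases:
            # Pavlovian conditioning: no coin task; log each trial's US event
            cs_list = (["cs+r"] * design.phase2_cs_plus_reinforced
                       + ["cs+"] * (design.phase2_cs_plus - design.phase2_cs_plus_reinforced)
                       + ["cs-"] * design.phase2_cs_minus)
            order_rng.shuffle(cs_list)
            for idx, cs in enumerate(cs_list):
                reinforced = cs == "cs+r"
                phase2_rows.append((profile.subject, 2, 1, idx, "", "",
                                    "cs+" if reinforced else cs, "outcome", 3.5,
                                    "us" if reinforced else "no_us"))
        if 3 in phases:
            batch.add_phase(profile, config, params, 3,
                            _shuffled_trials(design.phase3_blocks, order_rng))

    events = _realize_events(batch, phase2_rows, design, params, press_rng,
                             dynamics_rng)
    psychophys = _sample_psychophys(design, config, phys_rng)
    return CohortDataset(events=events, psychophys=psychophys, design=design,
                         seed=seed, params=params)


def _realize_events(batch: _TrialBatch, phase2_rows: list[tuple],
                    design: DesignSpec, params: TaskParams,
                    press_rng: np.random.Generator,
                    dynamics_rng: np.random.Generator) -> pd.DataFrame:
    """Sample press schedules, run the coin dynamics, assemble the log."""
    n = len(batch.rate)
    T = params.response_duration
    frames = []
    if n:
        rate = np.asarray(batch.rate)
        counts = press_rng.poisson(rate * T)
        lat = np.clip(np.asarray(batch.latency)
                      * np.exp(press_rng.normal(0.0, 0.1, n)), 0.05, T - 0.05)
        total = int(counts.sum())
        trial_of_press = np.repeat(np.arange(n), counts)
        u = press_rng.uniform(0.0, 1.0, total)
        times = lat[trial_of_press] + u * (T - lat[trial_of_press])
        order = np.lexsort((times, trial_of_press))
        trial_of_press, times = trial_of_press[order], times[order]

        specs = [TrialSpec(frame=f, go=g, cs=c)
                 for f, g, c in zip(batch.frame, batch.go, batch.cs)]
        schedules = np.split(times, np.cumsum(counts)[:-1])
        outcomes = simulate_trials_batch(specs, schedules, params, dynamics_rng)

        cols = {name: np.asarray(getattr(batch, name))
                for name in ("subject", "phase", "block", "trial_index",
                             "frame", "go", "cs")}
        press_df = pd.DataFrame({
            **{k: v[trial_of_press] for k, v in cols.items()},
            "event_type": "press", "time_s": np.round(times, 4), "value": "1"})
        outcome_df = pd.DataFrame({
            **cols, "event_type": "outcome", "time_s": T,
            "value": outcomes.astype(str)})
        frames += [press_df, outcome_df]
    if phase2_rows:
        frames.append(pd.DataFrame(phase2_rows, columns=EVENT_COLUMNS))
    if not frames:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    events = pd.concat(frames, ignore_index=True)[EVENT_COLUMNS]
    return events.sort_values(
        ["subject", "phase", "block", "trial_index", "time_s", "event_type"],
        kind="mergesort").reset_index(drop=True)


def _sample_psychophys(design: DesignSpec, config: EffectConfig,
                       rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for s in range(design.n_subjects):
        for name in sorted(config.psychophys):
            spec = config.psychophys[name]
            base = rng.normal(spec.mean_minus, spec.between_sd)
            diff = rng.normal(spec.mean_plus - spec.mean_minus, spec.diff_sd)
            rows.append((s, name, "cs+", round(base + diff, 6), spec.units))
            rows.append((s, name, "cs-", round(base, 6), spec.units))
    return pd.DataFrame(rows, columns=["subject", "measure", "cs", "amplitude", "units"])


def calibrate_us_intensity(
    ratings: Sequence[tuple[float, float]],
    threshold_current: float,
    fraction: float = 0.85,
    mode: str = "rating",
) -> float:
    """Shock intensity from the rating procedure.

    Participants rate shocks of different currents on a 0-100 scale; the
    task intensity is the current at which the (piecewise-linearly
    interpolated) rating reaches ``100 * fraction``.  Non-monotone rating
    curves are resolved by taking the first upward crossing of the target
    (the conservative, lower-current choice); the result is clamped to the
    tested current range.  ``mode="current"`` instead returns
    ``fraction * threshold_current`` (the alternative reading of "85% of
    the threshold"), likewise clamped.
    """
    pts = sorted((float(c), float(r)) for c, r in ratings)
    if len(pts) < 2:
        raise ValueError("need at least two rating points")
    currents = [c for c, _ in pts]
    rvals = [r for _, r in pts]
    if any(not (0.0 <= r <= 100.0) for r in rvals):
        raise ValueError("ratings must lie in [0, 100]")
    if any(c <= 0 or c > threshold_current for c in currents):
        raise ValueError("currents must be positive and at most the threshold")
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")

    if mode == "current":
        return float(np.clip(fraction * threshold_current, currents[0], currents[-1]))
    if mode != "rating":
        raise ValueError("mode must be 'rating' or 'current'")

    target = 100.0 * fraction
    if rvals[0] >= target:
        return currents[0]
    for (c0, r0), (c1, r1) in zip(pts, pts[1:]):
        if r0 < target <= r1:  # first upward crossing
            if r1 == r0:
                return c1
            return c0 + (c1 - c0) * (target - r0) / (r1 - r0)
    return currents[-1]  # target never reached: top of tested range
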