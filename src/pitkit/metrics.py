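"""Behavioral dependent variables from long-format trial event logs.

Three measures per trial, aggregated to subject x condition cells:

* response rate — key presses per second, averaged over the whole 5-s
  response period (presses/s);
* response accuracy — fraction of trials whose coin reached the required
  target (wins over all trials);
* latency of first key press — seconds from response-period onset; for
  NoGo cells presses only occur on incorrect trials, so the latency is
  aggregated over incorrect trials only (and is undefined for a cell with
  no such trials).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .task import TrialLog

__all__ = ["response_rate", "accuracy", "first_press_latency", "summarize"]


def response_rate(trial: TrialLog, response_duration: float = 5.0) -> float:
    """Presses per second over the full response period."""
    return trial.n_presses / response_duration


def accuracy(trials: Sequence[TrialLog]) -> float:
    """Fraction of winning trials; lose and incomplete both count as errors."""
    if not trials:
        raise ValueError("accuracy undefined for an empty cell")
    return sum(t.outcome == "win" for t in trials) / len(trials)


def first_press_latency(trial: TrialLog) -> float | None:
    """Seconds from response-period onset to the first press; None if none."""
    return trial.first_press_latency


def _per_trial_table(events: pd.DataFrame, phase: int,
                     response_duration: float) -> pd.DataFrame:
    ev = events[events["phase"] == phase]
    if ev.empty:
        raise ValueError(f"no events for phase {phase}")
    keys = ["subject", "block", "trial_index", "frame", "go", "cs"]
    presses = ev[ev["event_type"] == "press"]
    outcomes = ev[ev["event_type"] == "outcome"]
    agg = presses.groupby(keys, observed=True)["time_s"].agg(["count", "min"])
    trials = outcomes.set_index(keys)[["value"]].rename(columns={"value": "outcome"})
    trials = trials.join(agg).reset_index()
    trials["count"] = trials["count"].fillna(0).astype(int)
    trials["rate"] = trials["count"] / response_duration
    trials["win"] = (trials["outcome"] == "win").astype(float)
    trials = trials.rename(columns={"min": "latency"})
    return trials


def summarize(
    events: pd.DataFrame,
    phase: int,
    by: Iterable[str] = ("cs", "frame", "go"),
    response_duration: float = 5.0,
) -> pd.DataFrame:
    """One row per subject x condition cell with the three measures.

    ``by`` selects the grouping factors (any of ``cs``, ``frame``, ``go``,
    ``block``).  Every subject must contribute at least one trial to every
    cell of the crossed design; missing cells raise rather than being
    silently dropped.
    """
    by = list(by)
    allowed = {"cs", "frame", "go", "block"}
    if not set(by) <= allowed:
        raise ValueError(f"grouping factors must be among {sorted(allowed)}")
    trials = _per_trial_table(events, phase, response_duration)

    # NoGo trials contribute a latency only when incorrect (a press on a
    # correct NoGo trial cannot exist; a correct cell yields no latency)
    nogo_correct = (trials["go"] == "nogo") & (trials["win"] == 1.0)
    trials["latency_eff"] = trials["latency"].where(~nogo_correct)

    keys = ["subject"] + by
    grouped = trials.groupby(keys, observed=True)
    out = grouped.agg(response_rate=("rate", "mean"),
                      accuracy=("win", "mean"),
                      latency=("latency_eff", "mean"),
                      n_trials=("rate", "size")).reset_index()

    # flag missing cells: full cross of observed levels x subjects
    levels = [trials[f].unique() for f in by]
    expected = len(trials["subject"].unique()) * int(np.prod([len(l) for l in levels]))
    if len(out) != expected:
        raise ValueError(
            f"incomplete design: {len(out)} cells present, {expected} expected")
    return out.sort_values(keys, kind="mergesort").reset_index(drop=True)
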