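"""Reading and writing the package's file formats.

Event logs are long-format CSV (one row per key press or trial outcome);
task parameters travel as YAML; a cohort is a directory with events.csv,
psychophys.csv and design.json.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import yaml

from .cohort import EVENT_COLUMNS, CohortDataset, DesignSpec, make_design
from .task import TaskParams, TrialLog

__all__ = [
    "trial_log_to_frame",
    "write_events",
    "read_events",
    "params_to_yaml",
    "params_from_yaml",
    "write_cohort",
    "read_cohort_events",
]


def trial_log_to_frame(log: TrialLog, subject: int = 0, phase: int = 1,
                       block: int = 1, trial_index: int = 0,
                       response_duration: float = 5.0) -> pd.DataFrame:
    """Serialize one trial to the long event-log format."""
    s = log.spec
    rows = [(subject, phase, block, trial_index, s.frame, s.go, s.cs,
             "press", round(t, 4), "1") for t in log.press_times]
    rows.append((subject, phase, block, trial_index, s.frame, s.go, s.cs,
                 "outcome", response_duration, log.outcome))
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=False,
                       dtype={"value": str, "cs": str, "frame": str, "go": str})


def params_to_yaml(params: TaskParams, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(params), sort_keys=True))


def params_from_yaml(path: str | Path) -> TaskParams:
    return TaskParams(**yaml.safe_load(Path(path).read_text()))


def _design_to_dict(design: DesignSpec) -> dict:
    d = dataclasses.asdict(design)
    d["phase1_blocks"] = [{"|".join(k): v for k, v in b.items()}
                          for b in design.phase1_blocks]
    d["phase3_blocks"] = [{"|".join(k): v for k, v in b.items()}
                          for b in design.phase3_blocks]
    return d


def write_cohort(dataset: CohortDataset, out_dir: str | Path) -> Path:
    """Write events.csv, psychophys.csv and design.json into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.events.to_csv(out / "events.csv", index=False)
    dataset.psychophys.to_csv(out / "psychophys.csv", index=False)
    meta = {"design": _design_to_dict(dataset.design), "seed": dataset.seed,
            "params": dataclasses.asdict(dataset.params)}
    (out / "design.json").write_text(json.dumps(meta, indent=2))
    return out


def read_cohort_events(cohort_dir: str | Path) -> pd.DataFrame:
    return read_events(Path(cohort_dir) / "events.csv")
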