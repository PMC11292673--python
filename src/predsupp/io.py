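"""Reading, writing and validating the pipeline's tabular formats.

Events go to BIDS-style per-run ``events.tsv`` (onset, duration, trial_type,
modulator, block_condition); ROI time series and nuisance regressors to
plain TSV; first-level estimates and behavior to CSV with fixed schemas.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .design import ExperimentDesign

EVENTS_COLUMNS = ["onset", "duration", "trial_type", "modulator", "block_condition"]
ESTIMATES_COLUMNS = ["subject", "run", "roi", "condition", "beta", "se"]
BEHAVIOR_COLUMNS = ["subject", "run", "trial", "position", "response", "correct"]


def write_events(design: ExperimentDesign, out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for run in design.runs:
        frame = run.events_frame()[EVENTS_COLUMNS]
        p = out_dir / f"run-{run.run:02d}_events.tsv"
        frame.to_csv(p, sep="\t", index=False, na_rep="n/a")
        paths.append(p)
    return paths


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    missing = set(EVENTS_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise ValueError(f"events file missing columns {sorted(missing)}")
    return df


def write_bold(bold: Mapping[int, pd.DataFrame], out_dir: str | Path,
               prefix: str = "bold") -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for run, frame in bold.items():
        f = frame.copy()
        f.insert(0, "volume", np.arange(len(f)))
        p = out_dir / f"run-{run:02d}_{prefix}.tsv"
        f.to_csv(p, sep="\t", index=False)
        paths.append(p)
    return paths


def read_bold(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.drop(columns=[c for c in ("volume",) if c in df.columns])


def validate_inputs(paths: dict[str, str | Path]) -> list[str]:
    """Schema diagnostics for events/bold/estimates/behavior files.

    Purely diagnostic — returns a list of human-readable issues, empty when
    everything checks out.
    """
    issues: list[str] = []
    for kind, path in paths.items():
        path = Path(path)
        if not path.exists():
            issues.append(f"{kind}: file {path} does not exist")
            continue
        if kind.startswith("events"):
            try:
                df = read_events(path)
            except ValueError as e:
                issues.append(f"{kind}: {e}")
                continue
            onsets = df["onset"].to_numpy(dtype=float)
            if (np.diff(onsets) < 0).any():
                issues.append(f"{kind}: onsets are not non-decreasing")
            if (df["duration"] < 0).any():
                issues.append(f"{kind}: negative durations")
        elif kind.startswith("bold") or kind.startswith("nuisance"):
            df = pd.read_csv(path, sep="\t")
            if not df.select_dtypes(exclude="number").drop(
                columns=[], errors="ignore"
            ).empty:
                issues.append(f"{kind}: non-numeric columns present")
            if df.isna().any().any():
                issues.append(f"{kind}: missing values")
        elif kind.startswith("estimates"):
            df = pd.read_csv(path)
            missing = set(ESTIMATES_COLUMNS) - set(df.columns)
            if missing:
                issues.append(f"{kind}: missing columns {sorted(missing)}")
            elif (df["se"] <= 0).any():
                n = int((df["se"] <= 0).sum())
                issues.append(f"{kind}: {n} rows with non-positive se")
        elif kind.startswith("behavior"):
            df = pd.read_csv(path)
            missing = set(BEHAVIOR_COLUMNS) - set(df.columns)
            if missing:
                issues.append(f"{kind}: missing columns {sorted(missing)}")
            elif not df["correct"].isin([0, 1]).all():
                issues.append(f"{kind}: correct column must be 0/1")
        else:
            issues.append(f"{kind}: unknown input kind")
    return issues
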