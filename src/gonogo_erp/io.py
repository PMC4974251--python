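"""On-disk formats and in-memory containers for continuous recordings.

A recording on disk is the triplet (EDF continuous data, TSV event file,
JSON montage).  Derived measurement tables are plain long-format CSV with
columns (subject, group, stimulation, cue, hand, measure, value); wide
per-measure summaries mirror the condition-mean (SEM) layout of published
result tables.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import edf
from .montage import Montage
from .task import EVENT_CODES

RAW = "raw"
AVG_MASTOID = "average-mastoid"

MEASURE_COLUMNS = ["subject", "group", "stimulation", "cue", "hand", "measure", "value"]


@dataclass
class ContinuousRecording:
    """Channels x samples in microvolts plus the event stream."""

    data: np.ndarray
    fs: float
    montage: Montage
    events: pd.DataFrame
    reference_state: str = RAW

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.data.shape[0] != len(self.montage.channels):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but montage lists "
                f"{len(self.montage.channels)} channels"
            )
        self.events = (
            self.events.sort_values("onset_ms", kind="stable").reset_index(drop=True)
        )
        validate_events(self.events, self.duration_ms)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.n_samples / self.fs * 1000.0

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.montage.index(label)]

    def sample_of(self, onset_ms: float) -> int:
        # 0-based; sample index = round(onset_ms * fs / 1000)
        return int(round(onset_ms * self.fs / 1000.0))

    def copy_with(self, **kw) -> "ContinuousRecording":
        return replace(self, **kw)


def validate_events(events: pd.DataFrame, duration_ms: float | None = None) -> None:
    if not {"onset_ms", "code"} <= set(events.columns):
        raise ValueError("event frame needs columns onset_ms, code")
    bad = set(events["code"]) - set(EVENT_CODES)
    if bad:
        raise ValueError(
            f"unknown event code(s) {sorted(bad)}; valid codes: {list(EVENT_CODES)}"
        )
    if not events["onset_ms"].is_monotonic_increasing:
        raise ValueError("event onsets must be non-decreasing")
    if duration_ms is not None and len(events):
        last = float(events["onset_ms"].iloc[-1])
        if last >= duration_ms:
            raise ValueError(
                f"event at {last:.1f} ms lies beyond the recording end "
                f"({duration_ms:.1f} ms)"
            )
        if float(events["onset_ms"].iloc[0]) < 0:
            raise ValueError("event onset before recording start")


def write_recording(rec: ContinuousRecording, out_dir: str | Path, stem: str) -> dict[str, Path]:
    """Write the (EDF, TSV events, JSON montage) bundle; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "edf": out / f"{stem}.edf",
        "events": out / f"{stem}_events.tsv",
        "montage": out / f"{stem}_montage.json",
    }
    edf.write_edf(paths["edf"], rec.data, rec.fs, rec.montage.channels)
    rec.events.to_csv(paths["events"], sep="\t", index=False)
    rec.montage.to_json(paths["montage"])
    return paths


def read_recording(
    continuous_file: str | Path,
    event_file: str | Path,
    montage_file: str | Path,
) -> ContinuousRecording:
    """Read a recording bundle; events are validated and attached sorted."""
    data, fs, labels = edf.read_edf(continuous_file)
    montage = Montage.from_json(montage_file)
    if labels != montage.channels:
        raise ValueError(
            "EDF channel labels do not match the montage: "
            f"{labels[:4]}... vs {montage.channels[:4]}..."
        )
    events = pd.read_csv(event_file, sep="\t")
    events = events.sort_values("onset_ms", kind="stable").reset_index(drop=True)
    duration_ms = data.shape[1] / fs * 1000.0
    validate_events(events, duration_ms)
    return ContinuousRecording(data=data, fs=fs, montage=montage, events=events)


# ---------------------------------------------------------------------------
# measure tables


def validate_measures(measures: pd.DataFrame) -> None:
    if measures.empty:
        raise ValueError("measure table is empty")
    missing = set(MEASURE_COLUMNS) - set(measures.columns)
    if missing:
        raise ValueError(f"measure table is missing columns {sorted(missing)}")
    keys = ["subject", "stimulation", "cue", "hand", "measure"]
    dup = measures.duplicated(subset=keys)
    if dup.any():
        rows = measures.loc[dup, keys].head(5)
        raise ValueError(f"duplicate measure rows for keys:\n{rows}")


def summarize_measure(measures: pd.DataFrame, measure: str) -> pd.DataFrame:
    """Cell means with SEM across subjects, one row per stimulation level.

    Columns are cue x hand cells labelled like ``directional_L``; SEM
    columns carry the suffix ``_sem``.  Mirrors the layout of published
    condition-mean tables.
    """
    sub = measures[measures["measure"] == measure]
    if sub.empty:
        raise ValueError(f"no rows for measure {measure!r}")
    out = {}
    for (stim,), grp in sub.groupby(["stimulation"]):
        row = {}
        for (cue, hand), cell in grp.groupby(["cue", "hand"]):
            name = f"{cue}_{hand}"
            vals = cell["value"].to_numpy(float)
            row[name] = vals.mean()
            row[f"{name}_sem"] = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan
        out[stim] = row
    wide = pd.DataFrame(out).T
    wide.index.name = "stimulation"
    return wide.sort_index(axis=1)


def write_tables(
    measures: pd.DataFrame,
    anova: pd.DataFrame | None,
    bf: pd.DataFrame | None,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the long measure CSV, wide per-measure summaries and stats CSVs."""
    validate_measures(measures)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["measures"] = out / "measures.csv"
    measures.to_csv(paths["measures"], index=False)
    for m in measures["measure"].unique():
        p = out / f"summary_{m}.csv"
        summarize_measure(measures, m).to_csv(p)
        paths[f"summary_{m}"] = p
    if anova is not None and len(anova):
        paths["anova"] = out / "anova.csv"
        anova.to_csv(paths["anova"], index=False)
    if bf is not None and len(bf):
        paths["bayes_factors"] = out / "bayes_factors.csv"
        bf.to_csv(paths["bayes_factors"], index=False)
    return paths


def read_measures(path: str | Path) -> pd.DataFrame:
    measures = pd.read_csv(path)
    validate_measures(measures)
    return measures
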