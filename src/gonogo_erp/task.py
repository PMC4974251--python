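"""Trial scheduling for the cued go/nogo task.

The task is an S1-S2 paradigm: a fixation cross, then a cue whose duration
equals the cue-target interval, then an imperative target.  Directional cues
validly predict the response hand but 30% of their targets are nogo stimuli;
non-directional cues predict only target timing and are always followed by a
go target.  Directional and non-directional cues run in separate blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Event codes shared across the package (TSV event files use these verbatim).
FIX = "FIX"
CUE_DIR_L = "CUE_DIR_L"
CUE_DIR_R = "CUE_DIR_R"
CUE_NONDIR = "CUE_NONDIR"
TGT_GO_L = "TGT_GO_L"
TGT_GO_R = "TGT_GO_R"
TGT_NOGO = "TGT_NOGO"
RESP_L = "RESP_L"
RESP_R = "RESP_R"

EVENT_CODES = (
    FIX, CUE_DIR_L, CUE_DIR_R, CUE_NONDIR,
    TGT_GO_L, TGT_GO_R, TGT_NOGO, RESP_L, RESP_R,
)


@dataclass(frozen=True)
class TaskConfig:
    """Timing and block structure of one session.

    Durations are milliseconds.  ``cue_dur`` is the cue-target interval:
    the target replaces the cue exactly ``cue_dur`` ms after cue onset.
    ``iti_*`` describe the jittered gap between target offset and the next
    trial's fixation onset (drawn uniform on [iti_min, iti_max]).
    ``nogo_proportion`` applies to directional blocks only.
    """

    fixation_dur: float = 500.0
    cue_dur: float = 1500.0
    target_dur: float = 1000.0
    iti_mean: float = 2000.0
    iti_min: float = 1500.0
    iti_max: float = 2500.0
    n_blocks_directional: int = 3
    n_blocks_nondirectional: int = 2
    trials_per_block: int = 80
    nogo_proportion: float = 0.30

    def __post_init__(self) -> None:
        if not (self.iti_min <= self.iti_mean <= self.iti_max):
            raise ValueError(
                f"require iti_min <= iti_mean <= iti_max, got "
                f"{self.iti_min}/{self.iti_mean}/{self.iti_max}"
            )
        if self.trials_per_block <= 0:
            raise ValueError("trials_per_block must be positive")
        if not 0.0 <= self.nogo_proportion <= 1.0:
            raise ValueError("nogo_proportion must lie in [0, 1]")
        if self.nogo_proportion > 0 and self.n_blocks_directional == 0:
            raise ValueError(
                "nogo_proportion > 0 requires directional blocks: the task "
                "defines nogo targets only under directional cues"
            )
        for name in ("fixation_dur", "cue_dur", "target_dur"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TrialSchedule:
    """Timed event sequence of one session.

    ``trials`` has one row per trial with columns:
    trial, block, block_type (directional | nondirectional), cue_code,
    cue_dir (L | R | none), target_code, target_dir (L | R | none),
    fix_onset_ms, cue_onset_ms, target_onset_ms.
    """

    trials: pd.DataFrame
    task: TaskConfig = field(repr=False, default_factory=TaskConfig)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def duration_ms(self) -> float:
        last = self.trials.iloc[-1]
        return float(last.target_onset_ms + self.task.target_dur)

    def events(self) -> pd.DataFrame:
        """Stimulus events as a long (onset_ms, code) frame, time-sorted."""
        rows = []
        for t in self.trials.itertuples():
            rows.append((t.fix_onset_ms, FIX))
            rows.append((t.cue_onset_ms, t.cue_code))
            rows.append((t.target_onset_ms, t.target_code))
        out = pd.DataFrame(rows, columns=["onset_ms", "code"])
        return out.sort_values("onset_ms", kind="stable").reset_index(drop=True)


def make_schedule(task: TaskConfig, seed: int) -> TrialSchedule:
    """Draw one session's trial schedule.

    Block order is randomized.  In directional blocks the nogo count is
    exact (floor of nogo_proportion x trials_per_block) with randomized
    positions, and go-target direction equals the cue direction (cues are
    valid).  Non-directional blocks contain no nogo targets and random
    target directions.
    """
    rng = np.random.default_rng(seed)
    block_types = ["directional"] * task.n_blocks_directional + [
        "nondirectional"
    ] * task.n_blocks_nondirectional
    order = rng.permutation(len(block_types))
    block_types = [block_types[i] for i in order]

    rows = []
    t_cursor = 0.0
    trial_idx = 0
    for block_i, btype in enumerate(block_types):
        n = task.trials_per_block
        if btype == "directional":
            n_nogo = int(np.floor(task.nogo_proportion * n))
            is_nogo = np.zeros(n, dtype=bool)
            is_nogo[rng.choice(n, size=n_nogo, replace=False)] = True
        else:
            is_nogo = np.zeros(n, dtype=bool)
        dirs = rng.choice(["L", "R"], size=n)
        for j in range(n):
            fix_onset = t_cursor
            cue_onset = fix_onset + task.fixation_dur
            target_onset = cue_onset + task.cue_dur
            if btype == "directional":
                cue_dir = dirs[j]
                cue_code = CUE_DIR_L if cue_dir == "L" else CUE_DIR_R
                if is_nogo[j]:
                    target_code, target_dir = TGT_NOGO, "none"
                else:
                    target_code = TGT_GO_L if cue_dir == "L" else TGT_GO_R
                    target_dir = cue_dir
            else:
                cue_dir, cue_code = "none", CUE_NONDIR
                target_dir = dirs[j]
                target_code = TGT_GO_L if target_dir == "L" else TGT_GO_R
            rows.append(
                (trial_idx, block_i, btype, cue_code, cue_dir, target_code,
                 target_dir, fix_onset, cue_onset, target_onset)
            )
            trial_idx += 1
            iti = rng.uniform(task.iti_min, task.iti_max)
            t_cursor = target_onset + task.target_dur + iti
    trials = pd.DataFrame(
        rows,
        columns=[
            "trial", "block", "block_type", "cue_code", "cue_dir",
            "target_code", "target_dir", "fix_onset_ms", "cue_onset_ms",
            "target_onset_ms",
        ],
    )
    return TrialSchedule(trials=trials, task=task)
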