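"""Signal chain from continuous EEG to condition-averaged ERP waveforms.

Order of operations mirrors standard ERP practice: re-reference to averaged
mastoids, band-pass (0.02-30 Hz) plus 50 Hz notch, epoch around a named
zero event, baseline-correct, reject amplitude artifacts, then average
within condition cells.  All windows are half-open [t_start, t_end) in ms
relative to the zero event, with sample 0 at the event's onset sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .io import AVG_MASTOID, RAW, ContinuousRecording
from .montage import Montage
from . import task as tk

log = logging.getLogger(__name__)

# epoch anchors -> event codes
_ANCHORS = {
    "fixation": {tk.FIX},
    "cue": {tk.CUE_DIR_L, tk.CUE_DIR_R, tk.CUE_NONDIR},
    "target": {tk.TGT_GO_L, tk.TGT_GO_R, tk.TGT_NOGO},
    "response": {tk.RESP_L, tk.RESP_R},
}


@dataclass
class EpochSet:
    """Trials x channels x time, with per-trial metadata and rejection mask."""

    data: np.ndarray
    fs: float
    time_ms: np.ndarray
    zero_event: str
    montage: Montage
    trial_meta: pd.DataFrame
    reject_mask: np.ndarray = field(default=None)  # True = rejected
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.reject_mask is None:
            self.reject_mask = np.zeros(len(self.trial_meta), dtype=bool)
        if len(self.reject_mask) != self.data.shape[0]:
            raise ValueError("reject_mask length must equal trial count")
        if len(self.trial_meta) != self.data.shape[0]:
            raise ValueError("trial_meta length must equal trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def retained(self) -> np.ndarray:
        return ~self.reject_mask

    def copy_with(self, **kw) -> "EpochSet":
        return replace(self, **kw)


@dataclass
class ErpWaveform:
    """Condition-averaged channels x time waveform."""

    values: np.ndarray
    time_ms: np.ndarray
    channels: list[str]
    zero_event: str
    n_trials: int
    baseline_interval: tuple[float, float] | None = None
    condition: dict = field(default_factory=dict)

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.values[self.channels.index(label)]
        except ValueError:
            raise ValueError(f"channel {label!r} not in waveform") from None


def rereference_mastoids(rec: ContinuousRecording) -> ContinuousRecording:
    """Subtract the mean of the two mastoid channels from every channel."""
    if rec.reference_state != RAW:
        raise ValueError(
            f"recording is already referenced ({rec.reference_state}); "
            "re-referencing twice is not meaningful"
        )
    mastoids = rec.montage.mastoids
    if len(mastoids) != 2:
        raise ValueError(
            f"average-mastoid reference requires exactly 2 mastoid channels, "
            f"montage tags {len(mastoids)}: {mastoids}"
        )
    ref = (rec.channel(mastoids[0]) + rec.channel(mastoids[1])) / 2.0
    return rec.copy_with(data=rec.data - ref[None, :], reference_state=AVG_MASTOID)


def filter_recording(
    rec: ContinuousRecording,
    band: tuple[float, float] = (0.02, 30.0),
    notch: float | None = 50.0,
    order: int = 4,
    notch_q: float = 30.0,
    detrend_fallback_s: float = 60.0,
) -> ContinuousRecording:
    """Zero-phase band-pass plus notch.

    The band-pass is a forward-backward Butterworth (SOS).  A 0.02 Hz
    high-pass corner is numerically fragile on recordings shorter than
    ``detrend_fallback_s``; such recordings are linearly detrended and
    low-pass filtered instead (logged).
    """
    nyq = rec.fs / 2.0
    lo, hi = band
    if not (0 < lo < hi < nyq):
        raise ValueError(f"band edges must satisfy 0 < {lo} < {hi} < Nyquist ({nyq})")
    if notch is not None and notch >= nyq:
        raise ValueError(f"notch frequency {notch} >= Nyquist ({nyq})")

    data = rec.data
    # a zero-phase IIR high-pass is only trustworthy when the recording
    # spans several corner periods; below that, fall back to a linear
    # detrend plus low-pass (logged), as edge transients would otherwise
    # contaminate the whole segment
    min_dur = max(detrend_fallback_s, 10.0 / lo)
    padlen = None
    if rec.n_samples / rec.fs < min_dur:
        log.warning(
            "recording shorter than %.0f s: using linear detrend + %.3g Hz "
            "low-pass instead of the %.3g Hz high-pass corner",
            min_dur, hi, lo,
        )
        data = signal.detrend(data, axis=1, type="linear")
        sos = signal.butter(order, hi, btype="lowpass", fs=rec.fs, output="sos")
    else:
        sos = signal.butter(order, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
        padlen = min(rec.n_samples - 1, int(3.0 * rec.fs / lo))
    if padlen is None:
        data = signal.sosfiltfilt(sos, data, axis=1)
    else:
        data = signal.sosfiltfilt(sos, data, axis=1, padlen=padlen)
    if notch is not None:
        b, a = signal.iirnotch(notch, notch_q, fs=rec.fs)
        data = signal.filtfilt(b, a, data, axis=1)
    return rec.copy_with(data=data)


def parse_trials(events: pd.DataFrame) -> pd.DataFrame:
    """Reconstruct per-trial metadata from a flat event stream.

    Returns one row per trial: onsets of fixation/cue/target, cue type and
    direction, target type and direction, response hand, RT (ms from target
    onset) and correctness.  A go trial is correct when the response hand
    matches the target direction; a nogo trial when no response occurred.
    """
    rows = []
    current: dict | None = None
    for ev in events.itertuples():
        if ev.code == tk.FIX:
            if current is not None:
                rows.append(current)
            current = {
                "fix_onset_ms": ev.onset_ms, "cue_onset_ms": np.nan,
                "target_onset_ms": np.nan, "cue": None, "cue_dir": "none",
                "target_type": None, "target_dir": "none",
                "hand": "none", "rt_ms": np.nan, "response_onset_ms": np.nan,
            }
        elif current is None:
            raise ValueError(f"event {ev.code} at {ev.onset_ms} ms precedes any trial")
        elif ev.code in _ANCHORS["cue"]:
            current["cue_onset_ms"] = ev.onset_ms
            if ev.code == tk.CUE_NONDIR:
                current["cue"] = "nondirectional"
            else:
                current["cue"] = "directional"
                current["cue_dir"] = "L" if ev.code == tk.CUE_DIR_L else "R"
        elif ev.code in _ANCHORS["target"]:
            current["target_onset_ms"] = ev.onset_ms
            if ev.code == tk.TGT_NOGO:
                current["target_type"] = "nogo"
            else:
                current["target_type"] = "go"
                current["target_dir"] = "L" if ev.code == tk.TGT_GO_L else "R"
        elif ev.code in _ANCHORS["response"]:
            hand = "L" if ev.code == tk.RESP_L else "R"
            if np.isnan(current["target_onset_ms"]):
                raise ValueError(
                    f"response at {ev.onset_ms} ms has no preceding target"
                )
            if current["hand"] == "none":  # keep first response only
                current["hand"] = hand
                current["response_onset_ms"] = ev.onset_ms
                current["rt_ms"] = ev.onset_ms - current["target_onset_ms"]
    if current is not None:
        rows.append(current)
    meta = pd.DataFrame(rows)
    if meta.empty:
        return meta
    responded = meta["hand"] != "none"
    go = meta["target_type"] == "go"
    meta["correct"] = np.where(
        go,
        responded & (meta["hand"] == meta["target_dir"]),
        ~responded,
    )
    meta["trial"] = np.arange(len(meta))
    return meta


def extract_epochs(
    rec: ContinuousRecording,
    zero_event: str,
    t_start: float,
    t_end: float,
) -> EpochSet:
    """Cut per-trial windows [t_start, t_end) ms around ``zero_event``.

    ``zero_event`` is one of fixation | cue | target | response.  Trials
    lacking the anchor (e.g. response-locked epochs of nogo or omitted
    trials) are excluded; trials whose window falls outside the recording
    are dropped and counted in ``n_dropped``.
    """
    if zero_event not in _ANCHORS:
        raise ValueError(f"zero_event must be one of {sorted(_ANCHORS)}")
    if t_start >= t_end:
        raise ValueError("t_start must precede t_end")
    meta = parse_trials(rec.events)
    if meta.empty:
        raise ValueError("recording contains no trials")
    anchor_col = {
        "fixation": "fix_onset_ms", "cue": "cue_onset_ms",
        "target": "target_onset_ms", "response": "response_onset_ms",
    }[zero_event]
    meta = meta[np.isfinite(meta[anchor_col])].reset_index(drop=True)
    if meta.empty:
        raise ValueError(f"no trial carries a {zero_event} anchor event")

    off_start = int(round(t_start * rec.fs / 1000.0))
    n_samp = int(round((t_end - t_start) * rec.fs / 1000.0))
    time_ms = (np.arange(n_samp) + off_start) / rec.fs * 1000.0

    starts = np.array([rec.sample_of(t) for t in meta[anchor_col]]) + off_start
    ok = (starts >= 0) & (starts + n_samp <= rec.n_samples)
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.info("dropped %d trial(s) whose epoch window exceeds the recording",
                 n_dropped)
    meta = meta[ok].reset_index(drop=True)
    starts = starts[ok]
    data = np.stack([rec.data[:, s : s + n_samp] for s in starts]) if len(starts) \
        else np.empty((0, rec.data.shape[0], n_samp))
    return EpochSet(
        data=data, fs=rec.fs, time_ms=time_ms, zero_event=zero_event,
        montage=rec.montage, trial_meta=meta, n_dropped=n_dropped,
    )


def _interval_mask(time_ms: np.ndarray, interval: tuple[float, float]) -> np.ndarray:
    lo, hi = interval
    if lo >= hi:
        raise ValueError("baseline interval must satisfy start < end")
    mask = (time_ms >= lo) & (time_ms < hi)
    if not mask.any():
        raise ValueError(
            f"interval [{lo}, {hi}) ms contains no samples of the epoch "
            f"time base [{time_ms[0]:.1f}, {time_ms[-1]:.1f}] ms"
        )
    return mask


def baseline(epochs: EpochSet, interval: tuple[float, float]) -> EpochSet:
    """Subtract the per-trial, per-channel mean over ``interval`` (ms)."""
    mask = _interval_mask(epochs.time_ms, interval)
    means = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return epochs.copy_with(data=epochs.data - means)


def baseline_waveform(erp: ErpWaveform, interval: tuple[float, float]) -> ErpWaveform:
    """Baseline an averaged waveform (equivalent to baselining per trial)."""
    mask = _interval_mask(erp.time_ms, interval)
    means = erp.values[:, mask].mean(axis=1, keepdims=True)
    return replace(erp, values=erp.values - means, baseline_interval=tuple(interval))


def reject_artifacts(
    epochs: EpochSet,
    abs_threshold: float = 100.0,
    max_rejected_fraction: float = 0.4,
) -> tuple[EpochSet, bool]:
    """Mask trials where any scalp channel exceeds +-abs_threshold uV.

    Returns the epochs with an updated rejection mask plus a flag that is
    True when the rejected fraction exceeds ``max_rejected_fraction``
    (candidate for whole-subject exclusion).
    """
    if abs_threshold <= 0:
        raise ValueError("abs_threshold must be positive")
    scalp_idx = [epochs.montage.index(c) for c in epochs.montage.scalp]
    exceeded = (np.abs(epochs.data[:, scalp_idx, :]) > abs_threshold).any(axis=(1, 2))
    mask = epochs.reject_mask | exceeded
    frac = mask.mean() if len(mask) else 0.0
    flagged = bool(frac > max_rejected_fraction)
    if flagged:
        log.warning("%.0f%% of epochs rejected (threshold %.0f uV)",
                    100 * frac, abs_threshold)
    return epochs.copy_with(reject_mask=mask), flagged


def average_condition(
    epochs: EpochSet,
    by: list[str],
    go_only: bool = True,
    cells: list[tuple] | None = None,
) -> dict[tuple, ErpWaveform]:
    """Arithmetic mean over retained trials for each cell of ``by``.

    ``by`` lists trial_meta columns (e.g. ["cue", "hand"]).  With
    ``go_only`` (default) only correct go trials enter the averages, as in
    the ERP analyses this package reproduces.  If ``cells`` is given, every
    requested cell must be non-empty.
    """
    meta = epochs.trial_meta.copy()
    keep = epochs.retained()
    if go_only:
        keep = keep & (meta["target_type"] == "go").to_numpy() \
            & meta["correct"].to_numpy(bool)
    meta = meta[keep]
    if meta.empty:
        raise ValueError("no retained trials to average")
    out: dict[tuple, ErpWaveform] = {}
    for key, grp in meta.groupby(by, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        idx = grp.index.to_numpy()
        out[key] = ErpWaveform(
            values=epochs.data[idx].mean(axis=0),
            time_ms=epochs.time_ms,
            channels=list(epochs.montage.channels),
            zero_event=epochs.zero_event,
            n_trials=len(idx),
            condition=dict(zip(by, key)),
        )
    if cells is not None:
        missing = [c for c in cells if tuple(np.atleast_1d(c)) not in out]
        if missing:
            raise ValueError(f"empty condition cell(s): {missing} for keys {by}")
    return out


def behavioral_measures(
    epochs_or_meta: EpochSet | pd.DataFrame,
    subject: str,
    stimulation: str,
    group: str = "none",
) -> pd.DataFrame:
    """Per cue x hand mean RT (correct go trials), omission and false-alarm rates.

    Rates are keyed with hand = "collapsed": go-error (omission/wrong-hand)
    rate per cue over go trials, false-alarm rate over nogo trials.
    """
    meta = epochs_or_meta.trial_meta if isinstance(epochs_or_meta, EpochSet) \
        else epochs_or_meta
    rows = []

    def add(cue, hand, measure, value):
        rows.append({
            "subject": subject, "group": group, "stimulation": stimulation,
            "cue": cue, "hand": hand, "measure": measure, "value": value,
        })

    go = meta[meta["target_type"] == "go"]
    for (cue, hand), cell in go[go["correct"]].groupby(["cue", "target_dir"]):
        add(cue, hand, "rt", float(cell["rt_ms"].mean()))
    for cue, cell in go.groupby("cue"):
        add(cue, "collapsed", "go_error_rate", float(1.0 - cell["correct"].mean()))
    nogo = meta[meta["target_type"] == "nogo"]
    if len(nogo):
        add("directional", "collapsed", "false_alarm_rate",
            float(1.0 - nogo["correct"].mean()))
    return pd.DataFrame(rows)
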