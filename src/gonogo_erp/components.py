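"""ERP component quantification.

Implements the study measurements this package reproduces: CNV mean
amplitude, P300 peak amplitude/latency, the lateralized readiness
potential via the double subtraction

    LRP = [ mean(C4 - C3) over left-hand trials
          + mean(C3 - C4) over right-hand trials ] / 2

(negative for correct-response activation), and onset latency by 25%
fractional area, where the mean amplitude across the measurement window
serves as the threshold: area accumulates only where the waveform exceeds
that threshold in the component's polarity direction, and the latency is
the (linearly interpolated) time at which the cumulative area first
reaches the requested fraction of the total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.integrate import cumulative_trapezoid

from .preprocess import ErpWaveform


class UndefinedLatencyError(ValueError):
    """No suprathreshold area in the window: the onset latency is undefined."""


@dataclass(frozen=True)
class ComponentSpec:
    """How one component is measured.

    ``statistic`` is mean_amplitude, peak, or fractional_area_latency;
    ``fraction`` applies to the latency statistic only.  ``window`` and
    ``baseline`` are ms relative to the component's zero event.
    """

    name: str  # CNV | P300 | tLRP | rLRP
    channel: str | None
    window: tuple[float, float]
    baseline: tuple[float, float]
    polarity: str = "negative"
    statistic: str = "mean_amplitude"
    fraction: float | None = None

    def __post_init__(self) -> None:
        if self.statistic not in ("mean_amplitude", "peak", "fractional_area_latency"):
            raise ValueError(f"unknown statistic {self.statistic!r}")
        if self.polarity not in ("positive", "negative"):
            raise ValueError("polarity must be positive or negative")
        if self.statistic == "fractional_area_latency":
            if self.fraction is None or not 0.0 < self.fraction < 1.0:
                raise ValueError("latency statistic requires fraction in (0, 1)")
        elif self.fraction is not None:
            raise ValueError("fraction is defined only for the latency statistic")


@dataclass
class LrpWaveform:
    """Double-subtraction LRP time series (one virtual channel)."""

    values: np.ndarray
    time_ms: np.ndarray
    zero_event: str
    n_trials: dict[str, int] = field(default_factory=dict)
    condition: dict = field(default_factory=dict)


def _window_slice(time_ms: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    if lo >= hi:
        raise ValueError("window start must precede window end")
    if lo < time_ms[0] - 1e-9 or hi > time_ms[-1] + 1e-9:
        raise ValueError(
            f"window [{lo}, {hi}] ms outside epoch time base "
            f"[{time_ms[0]:.1f}, {time_ms[-1]:.1f}] ms"
        )
    mask = (time_ms >= lo - 1e-9) & (time_ms <= hi + 1e-9)
    if mask.sum() < 2:
        raise ValueError("window contains fewer than 2 samples")
    return mask


def mean_amplitude(erp: ErpWaveform, channel: str, window: tuple[float, float]) -> float:
    """Arithmetic mean of the (baselined) waveform over ``window``."""
    mask = _window_slice(erp.time_ms, window)
    return float(erp.channel(channel)[mask].mean())


def peak_measure(
    erp: ErpWaveform,
    channel: str,
    window: tuple[float, float],
    polarity: str = "positive",
) -> tuple[float, float]:
    """Extremum of the stated polarity in ``window`` -> (amplitude uV, latency ms).

    The extremum is the absolute extremum within the window (endpoints are
    eligible); ties are broken by the earliest time.
    """
    mask = _window_slice(erp.time_ms, window)
    vals = erp.channel(channel)[mask]
    t = erp.time_ms[mask]
    idx = int(np.argmax(vals)) if polarity == "positive" else int(np.argmin(vals))
    return float(vals[idx]), float(t[idx])


def derive_lrp(erp_by_hand: dict[str, ErpWaveform]) -> LrpWaveform:
    """Double subtraction of the C3/C4 pair across response hands."""
    try:
        left, right = erp_by_hand["L"], erp_by_hand["R"]
    except KeyError as e:
        raise ValueError(f"need waveforms for both hands, missing {e}") from None
    if left.values.shape[1] != right.values.shape[1] or not np.allclose(
        left.time_ms, right.time_ms
    ):
        raise ValueError("left- and right-hand waveforms have mismatched time bases")
    values = 0.5 * (
        (left.channel("C4") - left.channel("C3"))
        + (right.channel("C3") - right.channel("C4"))
    )
    cond = {k: v for k, v in left.condition.items() if k != "hand"}
    return LrpWaveform(
        values=values,
        time_ms=left.time_ms.copy(),
        zero_event=left.zero_event,
        n_trials={"L": left.n_trials, "R": right.n_trials},
        condition=cond,
    )


def lowpass_lrp(lrp: LrpWaveform, cutoff: float = 30.0, fs: float | None = None,
                order: int = 4) -> LrpWaveform:
    """Zero-phase low-pass of the LRP waveform (no latency shift)."""
    if fs is None:
        dt = np.median(np.diff(lrp.time_ms))
        fs = 1000.0 / dt
    if cutoff >= fs / 2.0:
        raise ValueError(f"cutoff {cutoff} Hz >= Nyquist ({fs / 2.0} Hz)")
    sos = signal.butter(order, cutoff, btype="lowpass", fs=fs, output="sos")
    out = signal.sosfiltfilt(sos, lrp.values)
    return LrpWaveform(values=out, time_ms=lrp.time_ms, zero_event=lrp.zero_event,
                       n_trials=dict(lrp.n_trials), condition=dict(lrp.condition))


def fractional_area_latency(
    time_ms: np.ndarray,
    values: np.ndarray,
    window: tuple[float, float],
    fraction: float = 0.25,
    polarity: str = "negative",
    area_reference: str = "window_mean",
) -> float:
    """Fractional-area onset latency within ``window``.

    With ``area_reference='window_mean'`` (the default convention) the
    threshold is the mean amplitude across the window, and area accumulates
    only where the waveform lies beyond the threshold in the polarity
    direction.  With ``area_reference='zero'`` area is taken relative to
    zero instead (the alternative reading of the convention).  Raises
    :class:`UndefinedLatencyError` when no suprathreshold area exists.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    time_ms = np.asarray(time_ms, dtype=float)
    values = np.asarray(values, dtype=float)
    mask = _window_slice(time_ms, window)
    t = time_ms[mask]
    v = values[mask]
    if area_reference == "window_mean":
        threshold = v.mean()
    elif area_reference == "zero":
        threshold = 0.0
    else:
        raise ValueError("area_reference must be 'window_mean' or 'zero'")
    dev = np.maximum(threshold - v, 0.0) if polarity == "negative" \
        else np.maximum(v - threshold, 0.0)
    cum = cumulative_trapezoid(dev, t, initial=0.0)
    total = cum[-1]
    if total <= 0.0:
        raise UndefinedLatencyError(
            f"no suprathreshold area in window [{window[0]}, {window[1]}] ms"
        )
    target = fraction * total
    k = int(np.searchsorted(cum, target))
    if k == 0:
        return float(t[0])
    # linear interpolation of the cumulative-area curve between samples
    c0, c1 = cum[k - 1], cum[k]
    if c1 == c0:
        return float(t[k])
    return float(t[k - 1] + (target - c0) / (c1 - c0) * (t[k] - t[k - 1]))


def lrp_onset_latency(
    lrp: LrpWaveform,
    window: tuple[float, float],
    fraction: float = 0.25,
    area_reference: str = "window_mean",
) -> float:
    """25% fractional-area onset of an LRP (negative polarity convention)."""
    return fractional_area_latency(
        lrp.time_ms, lrp.values, window, fraction=fraction,
        polarity="negative", area_reference=area_reference,
    )


def measure_all(
    waveforms: dict[str, dict],
    specs: list[ComponentSpec],
    subject: str,
    stimulation: str,
    group: str = "none",
    area_reference: str = "window_mean",
) -> pd.DataFrame:
    """Apply every component spec to the available waveforms.

    ``waveforms`` maps component name to its per-cell averages:
    CNV/P300 -> {(cue, hand): ErpWaveform}; tLRP/rLRP -> {(cue,): LrpWaveform}
    (the double subtraction collapses hand, so LRP rows are keyed by cue
    only).  Returns long-format measure rows.
    """
    rows = []

    def add(cue, hand, measure, value):
        rows.append({
            "subject": subject, "group": group, "stimulation": stimulation,
            "cue": cue, "hand": hand, "measure": measure, "value": float(value),
        })

    for spec in specs:
        if spec.name not in waveforms:
            raise ValueError(
                f"component spec {spec.name!r} cannot be resolved: available "
                f"waveform sets are {sorted(waveforms)}"
            )
        cells = waveforms[spec.name]
        for key, wave in cells.items():
            key = key if isinstance(key, tuple) else (key,)
            if isinstance(wave, LrpWaveform):
                cue, hand = key[0], "collapsed"
                if spec.statistic != "fractional_area_latency":
                    raise ValueError(
                        f"{spec.name}: LRP components are measured by "
                        "fractional_area_latency"
                    )
                val = lrp_onset_latency(
                    wave, spec.window, fraction=spec.fraction,
                    area_reference=area_reference,
                )
                add(cue, hand, f"{spec.name.lower()}_onset", val)
            else:
                cue, hand = key
                if spec.statistic == "mean_amplitude":
                    add(cue, hand, f"{spec.name.lower()}_amp",
                        mean_amplitude(wave, spec.channel, spec.window))
                elif spec.statistic == "peak":
                    amp, lat = peak_measure(wave, spec.channel, spec.window,
                                            spec.polarity)
                    add(cue, hand, f"{spec.name.lower()}_amp", amp)
                    add(cue, hand, f"{spec.name.lower()}_lat", lat)
                else:
                    val = fractional_area_latency(
                        wave.time_ms, wave.channel(spec.channel), spec.window,
                        fraction=spec.fraction, polarity=spec.polarity,
                        area_reference=area_reference,
                    )
                    add(cue, hand, f"{spec.name.lower()}_onset", val)
    return pd.DataFrame(rows)
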