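"""Function-assessment signal processing.

Turns raw bite-force and surface-EMG recordings of a unilateral clenching
task (five static bites at 10-50 N targets, sampled at 2000 Hz) into the
two simulation inputs: a 0.25 s target bite-force curve and one
ipsilateral-to-contralateral (IC) activation ratio per muscle pair.

Processing chain for EMG: detrend -> rectify -> zero-phase 4th-order
Butterworth low-pass at 6 Hz -> normalize by the envelope's mean over an
explicitly supplied 20 N-bite baseline window. The bite-force channel is
low-pass filtered the same way; drift removal for force is anchored to
rest windows when supplied (a full-series linear detrend would corrupt
the absolute force scale of a staircase of bites).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .core import InvalidInputError, UniformSeries

EMG_CHANNELS = ("LT", "RT", "LM", "RM")  # left/right temporalis, left/right masseter
DEFAULT_TARGET_LEVELS = (10.0, 20.0, 30.0, 40.0, 50.0)


@dataclass(frozen=True)
class BiteRecording:
    """One unilateral bite task: force channel + four EMG channels.

    All series must share the sample rate and time span. ``task_side`` is
    the biting side ('left' or 'right'); ``target_levels`` are the guided
    force levels in N.
    """

    force: UniformSeries
    emg: dict[str, UniformSeries]
    task_side: str
    target_levels: tuple[float, ...] = DEFAULT_TARGET_LEVELS

    def __post_init__(self) -> None:
        if self.task_side not in ("left", "right"):
            raise InvalidInputError("task_side must be 'left' or 'right'")
        if set(self.emg) != set(EMG_CHANNELS):
            raise InvalidInputError(f"EMG channels must be exactly {EMG_CHANNELS}")
        for name, s in self.emg.items():
            if abs(s.sample_rate - self.force.sample_rate) > 1e-9:
                raise InvalidInputError(f"channel {name} sample rate differs from force")
            if s.n != self.force.n or abs(s.start_time - self.force.start_time) > 1e-9:
                raise InvalidInputError(f"channel {name} time span differs from force")


@dataclass(frozen=True)
class ProcessedTask:
    """Model inputs extracted from one task recording.

    ``force_curve`` spans exactly 0.25 s; ``final_bite_force`` equals its
    last sample and anchors the scaling-stress normalization.
    """

    force_curve: UniformSeries
    ic_temporalis: float
    ic_masseter: float
    final_bite_force: float

    def __post_init__(self) -> None:
        if self.ic_temporalis <= 0 or self.ic_masseter <= 0:
            raise InvalidInputError("IC ratios must be positive")
        if abs(self.force_curve.duration - 0.25) > self.force_curve.dt:
            raise InvalidInputError("force_curve must span 0.25 s")


def detrend(series: UniformSeries) -> UniformSeries:
    """Remove the least-squares straight line over the full series."""
    t = series.times - series.start_time
    coef = np.polynomial.polynomial.polyfit(t, series.values, 1)
    return series.with_values(series.values - np.polynomial.polynomial.polyval(t, coef))


def rectify(series: UniformSeries) -> UniformSeries:
    """Elementwise absolute value (full-wave rectification)."""
    return series.with_values(np.abs(series.values))


def lowpass(series: UniformSeries, order: int = 4, cutoff: float = 6.0) -> UniformSeries:
    """Zero-phase Butterworth low-pass (applied forward-backward).

    The forward-backward pass squares the magnitude response and cancels
    phase, so envelope timing stays aligned with the force channel.
    """
    nyq = series.sample_rate / 2.0
    if cutoff >= nyq:
        raise InvalidInputError(f"cutoff {cutoff} Hz >= Nyquist {nyq} Hz")
    b, a = butter(order, cutoff / nyq)
    return series.with_values(filtfilt(b, a, series.values))


def emg_envelope(raw: UniformSeries, baseline_window: tuple[float, float],
                 order: int = 4, cutoff: float = 6.0) -> UniformSeries:
    """Detrend, rectify, low-pass and normalize one EMG channel.

    The envelope is divided by its mean over ``baseline_window`` (the 20 N
    bite plateau), making it dimensionless with mean 1 over that window.
    """
    env = lowpass(rectify(detrend(raw)), order=order, cutoff=cutoff)
    sl = env.window_slice(baseline_window)
    base = float(env.values[sl].mean())
    if base <= 0:
        raise InvalidInputError("baseline envelope mean is non-positive")
    return env.with_values(env.values / base)


def clip_resample(series: UniformSeries, window: tuple[float, float],
                  duration: float = 0.25, n_out: int = 250) -> UniformSeries:
    """Clip ``window`` and linearly resample onto ``n_out`` samples over ``duration``.

    The ``n_out`` output samples span [``t_start``, ``t_end``] inclusively,
    preserving the window's endpoint values; the output is re-timed to
    start at 0 and span exactly ``duration`` seconds.
    """
    if n_out < 2:
        raise InvalidInputError("n_out must be >= 2")
    t0, t1 = float(window[0]), float(window[1])
    if t1 <= t0:
        raise InvalidInputError(f"empty or inverted window {window}")
    if t0 < series.start_time - 1e-12 or t1 > series.end_time + 1e-12:
        raise InvalidInputError(f"window {window} outside series span")
    t_src = np.linspace(t0, t1, n_out)
    vals = np.interp(t_src, series.times, series.values)
    rate = (n_out - 1) / duration
    return UniformSeries(sample_rate=rate, values=vals, start_time=0.0)


def ic_ratio(ipsi_env: UniformSeries, contra_env: UniformSeries,
             window: tuple[float, float]) -> float:
    """Mean ipsilateral envelope over ``window`` divided by mean contralateral."""
    if abs(ipsi_env.sample_rate - contra_env.sample_rate) > 1e-9:
        raise InvalidInputError("envelopes must share sampling")
    num = float(ipsi_env.values[ipsi_env.window_slice(window)].mean())
    den = float(contra_env.values[contra_env.window_slice(window)].mean())
    if den <= 0:
        raise InvalidInputError("contralateral mean is non-positive")
    return num / den


def _force_drift_removed(force: UniformSeries,
                         rest_windows: list[tuple[float, float]] | None) -> UniformSeries:
    """Remove sensor drift from the force channel.

    When rest (zero-force) windows are supplied, the least-squares line
    through those segments is subtracted; otherwise the signal is used
    as-is (a full-series detrend would shift the absolute force scale).
    """
    if not rest_windows:
        return force
    t_all, v_all = [], []
    for w in rest_windows:
        sl = force.window_slice(w)
        t_all.append(force.times[sl])
        v_all.append(force.values[sl])
    t = np.concatenate(t_all) - force.start_time
    v = np.concatenate(v_all)
    coef = np.polynomial.polynomial.polyfit(t, v, 1)
    trend = np.polynomial.polynomial.polyval(force.times - force.start_time, coef)
    return force.with_values(force.values - trend)


def process_recording(rec: BiteRecording, bite_window: tuple[float, float],
                      baseline_window: tuple[float, float],
                      rest_windows: list[tuple[float, float]] | None = None,
                      n_out: int = 250) -> ProcessedTask:
    """Full preparation chain for one task recording.

    ``bite_window`` brackets the highest-force bite plateau (the segment
    clipped and resampled to 0.25 s); ``baseline_window`` brackets the
    20 N bite plateau used for EMG normalization. Ipsilateral channels are
    selected by ``rec.task_side``.
    """
    force = lowpass(_force_drift_removed(rec.force, rest_windows))
    force_curve = clip_resample(force, bite_window, duration=0.25, n_out=n_out)

    envs = {name: emg_envelope(s, baseline_window) for name, s in rec.emg.items()}
    if rec.task_side == "left":
        ipsi_t, contra_t, ipsi_m, contra_m = "LT", "RT", "LM", "RM"
    else:
        ipsi_t, contra_t, ipsi_m, contra_m = "RT", "LT", "RM", "LM"
    r_t = ic_ratio(envs[ipsi_t], envs[contra_t], bite_window)
    r_m = ic_ratio(envs[ipsi_m], envs[contra_m], bite_window)

    return ProcessedTask(force_curve=force_curve, ic_temporalis=r_t,
                         ic_masseter=r_m,
                         final_bite_force=float(force_curve.values[-1]))
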