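"""ΔF/F calcium-response metrics with habituation across repeated trials.

ROI-mean fluorescence traces are normalized to a pre-stimulus baseline: the
average of the 20 frames preceding stimulus delivery is the baseline B and
ΔF/F = (F - B)/B per frame. Taste stimulation lasts 5 s; bitter responses
show a transient at stimulus onset (ON response) and often a second transient
at offset (OFF response). With repeated stimulation the ON response
habituates more strongly than the OFF response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidTraceError, WindowError

#: number of pre-stimulus frames that define the baseline
BASELINE_FRAMES = 20

#: OFF-response search window after stimulus offset (s)
OFF_WINDOW_S = 5.0

#: moving-average width (frames) applied before peak extraction
SMOOTH_FRAMES = 3


@dataclass
class CalciumTrace:
    """One ROI fluorescence trace for one stimulation trial."""

    frame_rate: float
    f: np.ndarray
    stim_onset_frame: int
    stim_duration: float = 5.0
    trial_index: int = 1

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.stim_onset_frame < BASELINE_FRAMES:
            raise InvalidTraceError(
                f"need >= {BASELINE_FRAMES} pre-stimulus frames, onset at {self.stim_onset_frame}"
            )

    @property
    def stim_offset_frame(self) -> int:
        return self.stim_onset_frame + int(round(self.stim_duration * self.frame_rate))


@dataclass
class ResponseMetrics:
    """Peak ΔF/F amplitudes of the ON and OFF transients."""

    on_amplitude: float
    off_amplitude: float
    windows: dict[str, float]


@dataclass
class HabituationProfile:
    """Trial-by-trial amplitudes normalized to the first trial."""

    on_normalized: np.ndarray
    off_normalized: np.ndarray
    on_final_over_first: float
    off_final_over_first: float


def dff(trace: CalciumTrace) -> np.ndarray:
    """ΔF/F per frame relative to the 20-frame pre-stimulus baseline.

    B = mean of frames [onset - 20, onset); dff = (f - B)/B. The baseline
    window's mean ΔF/F is zero by construction, and the series is invariant
    to a uniform gain applied to f.
    """
    lo = trace.stim_onset_frame - BASELINE_FRAMES
    baseline = float(np.mean(trace.f[lo : trace.stim_onset_frame]))
    if baseline <= 0:
        raise InvalidTraceError(f"non-positive baseline fluorescence ({baseline})")
    return (trace.f - baseline) / baseline


def _smooth(series: np.ndarray, width: int = SMOOTH_FRAMES) -> np.ndarray:
    """Centered moving average; window shrinks at the edges."""
    return (
        pd.Series(series).rolling(width, center=True, min_periods=1).mean().to_numpy()
    )


def on_off_amplitudes(
    dff_series: np.ndarray,
    frame_rate: float,
    stim_onset_frame: int,
    stim_duration: float = 5.0,
    off_window: float = OFF_WINDOW_S,
    smooth_frames: int = SMOOTH_FRAMES,
) -> ResponseMetrics:
    """Peak ON and OFF ΔF/F amplitudes for one trial.

    ON amplitude is the maximum of the smoothed ΔF/F over [onset, offset]
    (a 3-frame moving average suppresses single-frame noise). OFF amplitude
    is the maximum of the smoothed series over (offset, offset + off_window]
    minus the raw ΔF/F value at offset, floored at zero — referencing the
    offset value keeps a sustained ON plateau from registering as an OFF
    transient.
    """
    offset = stim_onset_frame + int(round(stim_duration * frame_rate))
    off_hi = offset + int(round(off_window * frame_rate))
    if off_hi >= len(dff_series):
        raise WindowError(
            f"trace must extend {off_window} s past stimulus offset "
            f"(needs {off_hi + 1} frames, has {len(dff_series)})"
        )
    s = _smooth(np.asarray(dff_series, dtype=float), smooth_frames)
    on_amp = float(np.max(s[stim_onset_frame : offset + 1]))
    off_peak = float(np.max(s[offset + 1 : off_hi + 1]))
    off_amp = max(off_peak - float(dff_series[offset]), 0.0)
    return ResponseMetrics(
        on_amplitude=on_amp,
        off_amplitude=off_amp,
        windows={"stim_s": stim_duration, "off_s": off_window},
    )


def trial_metrics(trace: CalciumTrace, **kwargs) -> ResponseMetrics:
    """Convenience: ΔF/F then ON/OFF amplitudes for one trace."""
    return on_off_amplitudes(
        dff(trace), trace.frame_rate, trace.stim_onset_frame, trace.stim_duration, **kwargs
    )


def habituation_profile(trials: Sequence[ResponseMetrics]) -> HabituationProfile:
    """Amplitudes across repeated trials, normalized to trial 1.

    Requires at least two trials in stimulation order. A component whose
    first-trial amplitude is zero has an undefined profile and is reported
    as NaN.
    """
    if len(trials) < 2:
        raise ValueError("habituation requires >= 2 trials in stimulation order")
    on = np.array([t.on_amplitude for t in trials])
    off = np.array([t.off_amplitude for t in trials])

    def norm(a: np.ndarray) -> np.ndarray:
        if a[0] == 0:
            return np.full_like(a, math.nan)
        return a / a[0]

    on_n, off_n = norm(on), norm(off)
    return HabituationProfile(
        on_normalized=on_n,
        off_normalized=off_n,
        on_final_over_first=float(on_n[-1]),
        off_final_over_first=float(off_n[-1]),
    )


# ---------------------------------------------------------------------------
# file I/O


def read_traces(
    roi_table_path,
    manifest_path,
    sep: str | None = None,
) -> list[CalciumTrace]:
    """Read per-frame ROI means plus a trial manifest.

    The ROI table has columns (trial, frame, mean_f); the manifest has one row
    per trial with columns (trial, frame_rate, stim_onset_frame,
    stim_duration). Traces are returned in trial order.
    """
    roi = pd.read_csv(roi_table_path, sep=sep, engine="python")
    man = pd.read_csv(manifest_path, sep=sep, engine="python").set_index("trial")
    traces = []
    for trial, g in roi.groupby("trial", sort=True):
        row = man.loc[trial]
        traces.append(
            CalciumTrace(
                frame_rate=float(row["frame_rate"]),
                f=g.sort_values("frame")["mean_f"].to_numpy(),
                stim_onset_frame=int(row["stim_onset_frame"]),
                stim_duration=float(row["stim_duration"]),
                trial_index=int(trial),
            )
        )
    return traces


def write_metrics(metrics: Sequence[ResponseMetrics], path) -> None:
    pd.DataFrame(
        {
            "trial": np.arange(1, len(metrics) + 1),
            "on_amplitude": [m.on_amplitude for m in metrics],
            "off_amplitude": [m.off_amplitude for m in metrics],
        }
    ).to_csv(path, index=False)
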