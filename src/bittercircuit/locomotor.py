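"""Kinematic stimulus responses and quadrant preference indices.

Flies walking in a circular four-quadrant arena are filmed at 30 frames/s and
tracked upstream (position, forward velocity, angular velocity per frame).
Optogenetic light is delivered either arena-wide (locomotor assay) or to two
opposing quadrants (innate preference assay); in the learning assay two odors
are delivered to opposing quadrant pairs and swapped between two test periods.

This module quantifies:

* onset responses — change in forward/angular velocity during the first 1 s of
  light relative to a 4 s pre-onset baseline;
* offset responses — change in forward velocity over the 5 s after light
  offset relative to the same baseline (freezing appears as a negative delta);
* preference index (PI) time series in 1 s bins,
  ``(# flies in light quadrants - # flies in non-light quadrants) / total``,
  with negative values indicating aversion of the lit quadrants;
* the final PI (mean over the last 5 s of light) and the learned (CS+ vs CS-)
  PI combined over the two counterbalanced odor tests.

Statistics downstream operate on trial-level values: flies are averaged within
a trial and each trial contributes one data point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    EmptyInputError,
    ProtocolError,
    QualityError,
    WindowError,
)

ALL_QUADRANTS = frozenset({1, 2, 3, 4})

#: default analysis windows (seconds)
BASELINE_WINDOW_S = 4.0
ONSET_WINDOW_S = 1.0
OFFSET_WINDOW_S = 5.0
FINAL_PI_WINDOW_S = 5.0


def quadrant_labels(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Assign quadrant labels 1..4 from arena-centered coordinates.

    Quadrants are the four sign sectors of the (x, y) plane: Q1 (+,+),
    Q2 (-,+), Q3 (-,-), Q4 (+,-). Points exactly on a boundary axis are
    assigned to the adjacent quadrant with the lower index (the boundary has
    measure zero, so the PI is insensitive to this rule).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    q = np.full(x.shape, 0, dtype=int)
    q[(x >= 0) & (y >= 0)] = 1
    q[(x < 0) & (y >= 0)] = 2
    q[(x <= 0) & (y < 0)] = 3
    q[(x > 0) & (y < 0)] = 4
    return q


@dataclass
class Trajectory:
    """Per-fly tracked kinematics at a fixed frame rate.

    Positions are in mm relative to the arena center; ``forward_velocity`` in
    mm/s; ``angular_velocity`` in deg/s. Lost-track frames are NaN.
    """

    fly_id: str
    frame_rate: float
    x: np.ndarray
    y: np.ndarray
    forward_velocity: np.ndarray
    angular_velocity: np.ndarray
    arena_radius: float = 30.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.forward_velocity = np.asarray(self.forward_velocity, dtype=float)
        self.angular_velocity = np.asarray(self.angular_velocity, dtype=float)
        n = len(self.x)
        if not (len(self.y) == len(self.forward_velocity) == len(self.angular_velocity) == n):
            raise ValueError("all per-frame series must have equal length")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.x)

    def quadrants(self) -> np.ndarray:
        """Quadrant label (1..4) per frame; 0 where position is lost."""
        q = quadrant_labels(np.nan_to_num(self.x), np.nan_to_num(self.y))
        q[np.isnan(self.x) | np.isnan(self.y)] = 0
        return q

    def quadrant_of(self, frame: int) -> int:
        return int(self.quadrants()[frame])


@dataclass(frozen=True)
class Epoch:
    """One timed stimulus epoch.

    ``kind`` is ``"light"`` or ``"odor"``; ``intensity`` is µW/mm² for light
    or an odor identifier; ``quadrant_mask`` is the set of stimulated
    quadrants (``ALL_QUADRANTS`` for arena-wide); ``pulse`` is ``"continuous"``
    or ``"pulsed:<freq Hz>"``.
    """

    start: float
    end: float
    kind: str = "light"
    intensity: float | str = 0.0
    quadrant_mask: frozenset[int] = ALL_QUADRANTS
    pulse: str = "continuous"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ProtocolError(f"epoch start {self.start} must precede end {self.end}")
        object.__setattr__(self, "quadrant_mask", frozenset(self.quadrant_mask))
        if not self.quadrant_mask <= ALL_QUADRANTS:
            raise ProtocolError(f"quadrant_mask {set(self.quadrant_mask)} outside Q1..Q4")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class StimulusProtocol:
    """Ordered list of stimulus epochs; same-kind epochs must not overlap."""

    epochs: list[Epoch] = field(default_factory=list)

    def __post_init__(self) -> None:
        by_kind: dict[str, list[Epoch]] = {}
        for ep in self.epochs:
            by_kind.setdefault(ep.kind, []).append(ep)
        for kind, eps in by_kind.items():
            eps = sorted(eps, key=lambda e: e.start)
            for a, b in zip(eps, eps[1:]):
                if b.start < a.end:
                    raise ProtocolError(f"overlapping {kind} epochs at t={b.start}")

    def of_kind(self, kind: str) -> list[Epoch]:
        return sorted((e for e in self.epochs if e.kind == kind), key=lambda e: e.start)

    @property
    def end(self) -> float:
        return max((e.end for e in self.epochs), default=0.0)


@dataclass
class PISeries:
    """Preference index in fixed-width time bins."""

    bin_edges: np.ndarray  # length n_bins + 1, seconds
    pi: np.ndarray  # NaN where no fly was tracked
    n_flies: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class KinematicResponse:
    """Per-trial kinematic deltas relative to the pre-onset baseline."""

    delta_forward: np.ndarray
    delta_angular: np.ndarray
    baseline_forward: np.ndarray
    baseline_angular: np.ndarray
    windows: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# window helpers


def _window_mean(series: np.ndarray, lo: int, hi: int, max_missing: float = 0.5) -> float:
    """Mean of series[lo:hi] excluding NaNs; QualityError if mostly missing."""
    if lo < 0 or hi > len(series):
        raise WindowError(f"window [{lo}, {hi}) outside series of length {len(series)}")
    w = series[lo:hi]
    n_missing = int(np.isnan(w).sum())
    if len(w) == 0:
        raise WindowError("empty analysis window")
    if n_missing / len(w) > max_missing:
        raise QualityError(f"{n_missing}/{len(w)} frames missing in window")
    return float(np.nanmean(w))


def bin_kinematics(traj: Trajectory, bin_frames: int = 10) -> pd.DataFrame:
    """Average velocities over fixed-size frame bins (default 10 frames = 0.33 s).

    The trailing partial bin is dropped; output length is
    ``floor(n_frames / bin_frames)``. NaN frames are excluded from each bin's
    mean (an all-NaN bin stays NaN).
    """
    if bin_frames < 1:
        raise ValueError("bin_frames must be >= 1")
    if traj.n_frames == 0:
        raise EmptyInputError("empty trajectory")
    n_bins = traj.n_frames // bin_frames
    out = {}
    with np.errstate(invalid="ignore"):
        for name, series in (
            ("forward_velocity", traj.forward_velocity),
            ("angular_velocity", traj.angular_velocity),
        ):
            trimmed = series[: n_bins * bin_frames].reshape(n_bins, bin_frames)
            out[name] = np.nanmean(trimmed, axis=1)
    t = (np.arange(n_bins) + 0.5) * bin_frames / traj.frame_rate
    return pd.DataFrame(out, index=pd.Index(t, name="time_s"))


def _trial_mean_series(trial: Sequence[Trajectory], attr: str) -> tuple[np.ndarray, float]:
    """Average one kinematic series over the flies of a trial."""
    if len(trial) == 0:
        raise EmptyInputError("trial contains no trajectories")
    rates = {t.frame_rate for t in trial}
    if len(rates) != 1:
        raise ValueError("all trajectories in a trial must share a frame rate")
    n = min(t.n_frames for t in trial)
    stack = np.vstack([getattr(t, attr)[:n] for t in trial])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN frames stay NaN
        mean = np.nanmean(stack, axis=0)
    return mean, rates.pop()


def onset_response(
    trials: Sequence[Sequence[Trajectory]],
    protocol: StimulusProtocol,
    epoch_index: int = 0,
    baseline_window: float = BASELINE_WINDOW_S,
    onset_window: float = ONSET_WINDOW_S,
) -> KinematicResponse:
    """Velocity change during the first second of light, per trial.

    delta = mean over [onset, onset + onset_window) minus mean over
    [onset - baseline_window, onset). Flies are averaged within each trial;
    one delta per trial is returned for downstream statistics.
    """
    epoch = protocol.of_kind("light")[epoch_index]
    df, da, bf, ba = [], [], [], []
    for trial in trials:
        fwd, rate = _trial_mean_series(trial, "forward_velocity")
        ang, _ = _trial_mean_series(trial, "angular_velocity")
        onset = int(round(epoch.start * rate))
        b_lo = onset - int(round(baseline_window * rate))
        o_hi = onset + int(round(onset_window * rate))
        if b_lo < 0:
            raise WindowError(
                f"need {baseline_window} s of pre-onset data, epoch starts at {epoch.start} s"
            )
        if epoch.duration < onset_window:
            raise WindowError("light epoch shorter than the onset window")
        base_f = _window_mean(fwd, b_lo, onset)
        base_a = _window_mean(ang, b_lo, onset)
        df.append(_window_mean(fwd, onset, o_hi) - base_f)
        da.append(_window_mean(ang, onset, o_hi) - base_a)
        bf.append(base_f)
        ba.append(base_a)
    return KinematicResponse(
        delta_forward=np.array(df),
        delta_angular=np.array(da),
        baseline_forward=np.array(bf),
        baseline_angular=np.array(ba),
        windows={"baseline_s": baseline_window, "onset_s": onset_window},
    )


def offset_response(
    trials: Sequence[Sequence[Trajectory]],
    protocol: StimulusProtocol,
    epoch_index: int = 0,
    baseline_window: float = BASELINE_WINDOW_S,
    offset_window: float = OFFSET_WINDOW_S,
) -> np.ndarray:
    """Forward-velocity change over the 5 s after light offset, per trial.

    Uses the same pre-onset baseline as :func:`onset_response`; post-offset
    freezing therefore appears as a negative delta.
    """
    epoch = protocol.of_kind("light")[epoch_index]
    out = []
    for trial in trials:
        fwd, rate = _trial_mean_series(trial, "forward_velocity")
        onset = int(round(epoch.start * rate))
        offset = int(round(epoch.end * rate))
        b_lo = onset - int(round(baseline_window * rate))
        o_hi = offset + int(round(offset_window * rate))
        if b_lo < 0:
            raise WindowError("insufficient pre-onset data for baseline")
        if o_hi > len(fwd):
            raise WindowError(
                f"need {offset_window} s of post-offset data, trace ends early"
            )
        out.append(_window_mean(fwd, offset, o_hi) - _window_mean(fwd, b_lo, onset))
    return np.array(out)


def preference_index_series(
    trajs: Sequence[Trajectory],
    quadrant_mask: Iterable[int],
    bin_s: float = 1.0,
    occupancy: str = "midpoint",
) -> PISeries:
    """PI per time bin: (# flies in mask quadrants - # outside) / total.

    ``occupancy`` selects how a fly's quadrant is determined within a bin:
    ``"midpoint"`` samples the bin-midpoint frame (default); ``"majority"``
    uses the quadrant occupied for the most frames of the bin. Lost-track
    flies are excluded from that bin's count.
    """
    mask = frozenset(quadrant_mask)
    if not mask or mask == ALL_QUADRANTS:
        raise ProtocolError("PI requires a strict, non-empty subset of quadrants")
    if not mask <= ALL_QUADRANTS:
        raise ProtocolError(f"unknown quadrants {set(mask) - ALL_QUADRANTS}")
    if occupancy not in ("midpoint", "majority"):
        raise ValueError(f"unknown occupancy rule {occupancy!r}")
    if len(trajs) == 0:
        raise EmptyInputError("no trajectories")
    rate = trajs[0].frame_rate
    n_frames = min(t.n_frames for t in trajs)
    bin_frames = max(int(round(bin_s * rate)), 1)
    n_bins = n_frames // bin_frames
    quads = np.vstack([t.quadrants()[: n_bins * bin_frames] for t in trajs])
    pi = np.full(n_bins, np.nan)
    n_flies = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        lo = b * bin_frames
        if occupancy == "midpoint":
            q = quads[:, lo + bin_frames // 2]
        else:
            block = quads[:, lo : lo + bin_frames]
            q = np.array(
                [np.bincount(row[row > 0], minlength=5).argmax() if (row > 0).any() else 0 for row in block]
            )
        tracked = q > 0
        n = int(tracked.sum())
        n_flies[b] = n
        if n > 0:
            in_mask = np.isin(q[tracked], sorted(mask))
            pi[b] = (in_mask.sum() - (~in_mask).sum()) / n
    edges = np.arange(n_bins + 1) * bin_frames / rate
    return PISeries(bin_edges=edges, pi=pi, n_flies=n_flies)


def final_pi(series: PISeries, epoch: Epoch, final_window: float = FINAL_PI_WINDOW_S) -> float:
    """Mean PI over the last ``final_window`` seconds of the epoch."""
    if epoch.duration < final_window:
        raise WindowError(f"epoch of {epoch.duration} s shorter than final window")
    lo, hi = epoch.end - final_window, epoch.end
    centers = series.bin_centers
    sel = (centers >= lo) & (centers < hi)
    if not sel.any():
        raise WindowError("final window contains no PI bins")
    return float(np.nanmean(series.pi[sel]))


def learned_pi(
    trajs: Sequence[Trajectory],
    tests: Sequence[tuple[Epoch, Iterable[int]]],
    bin_s: float = 1.0,
    final_window: float = FINAL_PI_WINDOW_S,
) -> float:
    """Learned odor preference combined over two counterbalanced tests.

    ``tests`` holds exactly two (epoch, CS+ quadrant set) pairs whose CS+
    quadrant sets are complements (the odor quadrants are switched between
    tests to cancel any spatial bias). For each test the PI is computed with
    the CS+ quadrants in the positive role and the final PI taken over the
    last 5 s; the returned value is the mean of the two test finals.
    """
    if len(tests) != 2:
        raise ProtocolError("learned PI requires exactly two counterbalanced tests")
    (ep1, m1), (ep2, m2) = tests
    m1, m2 = frozenset(m1), frozenset(m2)
    if m1 | m2 != ALL_QUADRANTS or m1 & m2:
        raise ProtocolError("CS+ quadrant sets of the two tests must be complementary")
    finals = []
    for ep, mask in ((ep1, m1), (ep2, m2)):
        series = preference_index_series(trajs, mask, bin_s=bin_s)
        finals.append(final_pi(series, ep, final_window))
    return float(np.mean(finals))


# ---------------------------------------------------------------------------
# file I/O


def read_trajectories(
    path,
    frame_rate: float = 30.0,
    arena_radius: float = 30.0,
    sep: str | None = None,
) -> list[Trajectory]:
    """Read a tracker table (frame, fly_id, x, y, forward_velocity, angular_velocity)."""
    df = pd.read_csv(path, sep=sep, engine="python")
    required = {"frame", "fly_id", "x", "y", "forward_velocity", "angular_velocity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"tracker table missing columns: {sorted(missing)}")
    out = []
    for fly_id, g in df.groupby("fly_id", sort=True):
        g = g.sort_values("frame")
        out.append(
            Trajectory(
                fly_id=str(fly_id),
                frame_rate=frame_rate,
                x=g["x"].to_numpy(),
                y=g["y"].to_numpy(),
                forward_velocity=g["forward_velocity"].to_numpy(),
                angular_velocity=g["angular_velocity"].to_numpy(),
                arena_radius=arena_radius,
            )
        )
    return out


def write_trajectories(trajs: Sequence[Trajectory], path, sep: str = ",") -> None:
    frames = []
    for t in trajs:
        frames.append(
            pd.DataFrame(
                {
                    "frame": np.arange(t.n_frames),
                    "fly_id": t.fly_id,
                    "x": t.x,
                    "y": t.y,
                    "forward_velocity": t.forward_velocity,
                    "angular_velocity": t.angular_velocity,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)
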