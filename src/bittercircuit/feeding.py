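"""Feeding microstructure and PER suppression indices.

A capacitance-based two-channel feeding assay records food-contact intervals
("interactions") per channel. Individual sips cluster into feeding bursts and
bursts into feeding bouts; the hierarchy is recovered by gap thresholding.
In the closed-loop configuration, light is triggered by each interaction with
the stimulated food source and stays on for 1.5 s.

The proboscis extension response (PER) suppression index quantifies how much
a manipulation reduces PER: ``1 - (PER with stimulus / PER without)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .exceptions import EmptyInputError, InvalidParameterError

#: closed-loop light pulse length (s): light stays on 1.5 s after each contact
LIGHT_EPOCH_S = 1.5

#: default segmentation gap thresholds (s). These are package defaults, not
#: measured values; tune to the sensor via configuration.
INTRA_BURST_GAP_S = 0.5
INTER_BOUT_GAP_S = 2.0

#: interactions shorter than this are discarded as sensor noise (s)
MIN_SIP_DURATION_S = 0.030


@dataclass
class EventStream:
    """Per-channel food-interaction intervals for one session."""

    channels: list[str]
    interactions: pd.DataFrame  # columns: channel, start, end (seconds)
    session_length: float
    light_epochs: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        required = {"channel", "start", "end"}
        if not required <= set(self.interactions.columns):
            raise ValueError(f"interactions table needs columns {sorted(required)}")
        bad = self.interactions["start"] >= self.interactions["end"]
        if bad.any():
            raise ValueError("interaction intervals must have start < end")
        if (self.interactions["end"] > self.session_length + 1e-9).any():
            raise ValueError("interactions extend past session end")

    def on_channel(self, channel: str) -> pd.DataFrame:
        sel = self.interactions[self.interactions["channel"] == channel]
        return sel.sort_values("start").reset_index(drop=True)


@dataclass
class ChannelSegmentation:
    """Sips with burst/bout membership for one channel."""

    sips: pd.DataFrame  # columns: start, end, burst_id, bout_id

    @property
    def n_sips(self) -> int:
        return len(self.sips)

    @property
    def n_bursts(self) -> int:
        return self.sips["burst_id"].nunique() if len(self.sips) else 0

    @property
    def n_bouts(self) -> int:
        return self.sips["bout_id"].nunique() if len(self.sips) else 0

    def bout_intervals(self) -> pd.DataFrame:
        if not len(self.sips):
            return pd.DataFrame(columns=["start", "end"])
        g = self.sips.groupby("bout_id")
        return pd.DataFrame({"start": g["start"].min(), "end": g["end"].max()})


@dataclass
class Segmentation:
    per_channel: dict[str, ChannelSegmentation]
    intra_burst_gap: float
    inter_bout_gap: float
    session_length: float


@dataclass
class FeedingSummary:
    """Per-channel feeding parameters and cumulative curves."""

    table: pd.DataFrame  # index channel; columns n_sips, n_bursts, n_bouts, ...
    cumulative: pd.DataFrame  # index time_s (1 s grid); one column per channel

    def difference(self, control: str, opto: str) -> pd.Series:
        """control - opto difference for each feeding parameter."""
        return self.table.loc[control] - self.table.loc[opto]


def segment_sips(
    events: EventStream,
    intra_burst_gap: float = INTRA_BURST_GAP_S,
    inter_bout_gap: float = INTER_BOUT_GAP_S,
    min_sip_duration: float = MIN_SIP_DURATION_S,
) -> Segmentation:
    """Cluster interaction intervals into sips, bursts, and bouts per channel.

    Each interaction is one sip (after discarding sub-``min_sip_duration``
    blips). Consecutive sips whose gap (next start minus previous end) is at
    most ``intra_burst_gap`` share a burst; bursts whose gap is at most
    ``inter_bout_gap`` share a bout. Interactions are sorted first, so the
    segmentation is independent of input order.
    """
    if not intra_burst_gap < inter_bout_gap:
        raise InvalidParameterError(
            f"intra_burst_gap ({intra_burst_gap}) must be < inter_bout_gap ({inter_bout_gap})"
        )
    per_channel = {}
    for channel in events.channels:
        sel = events.on_channel(channel)
        sel = sel[(sel["end"] - sel["start"]) >= min_sip_duration].reset_index(drop=True)
        starts = sel["start"].to_numpy()
        ends = sel["end"].to_numpy()
        n = len(starts)
        burst_id = np.zeros(n, dtype=int)
        bout_id = np.zeros(n, dtype=int)
        if n:
            gaps = starts[1:] - ends[:-1]
            burst_id[1:] = np.cumsum(gaps > intra_burst_gap)
            bout_id[1:] = np.cumsum(gaps > inter_bout_gap)
        per_channel[channel] = ChannelSegmentation(
            sips=pd.DataFrame(
                {"start": starts, "end": ends, "burst_id": burst_id, "bout_id": bout_id}
            )
        )
    return Segmentation(
        per_channel=per_channel,
        intra_burst_gap=intra_burst_gap,
        inter_bout_gap=inter_bout_gap,
        session_length=events.session_length,
    )


def closed_loop_annotation(
    events: EventStream,
    stim_channel: str,
    light_duration: float = LIGHT_EPOCH_S,
) -> list[tuple[float, float]]:
    """Light epochs implied by the closed-loop rule.

    Each interaction on the stimulated channel triggers one epoch
    ``(start, start + light_duration)``; overlapping epochs are merged and the
    last epoch is truncated at session end.
    """
    if stim_channel not in events.channels:
        raise InvalidParameterError(f"unknown stim channel {stim_channel!r}")
    starts = events.on_channel(stim_channel)["start"].to_numpy()
    epochs: list[tuple[float, float]] = []
    for s in starts:
        e = min(s + light_duration, events.session_length)
        if epochs and s <= epochs[-1][1]:
            epochs[-1] = (epochs[-1][0], max(epochs[-1][1], e))
        else:
            epochs.append((s, e))
    return epochs


def feeding_summary(segmentation: Segmentation, horizon: float = 3600.0) -> FeedingSummary:
    """Feeding parameters and cumulative feeding-duration curves per channel.

    Sips straddling the horizon are truncated at the horizon for duration
    sums. The cumulative curve is sampled on a 1 s grid and is non-decreasing;
    its value at the horizon equals the channel's total feeding duration.
    An empty channel yields an all-zero row, not an error.
    """
    if horizon > segmentation.session_length + 1e-9:
        raise InvalidParameterError("horizon exceeds session length")
    rows = {}
    grid = np.arange(0.0, math.floor(horizon) + 1.0)
    cumulative = {}
    for channel, seg in segmentation.per_channel.items():
        sips = seg.sips[seg.sips["start"] < horizon]
        starts = sips["start"].to_numpy()
        ends = np.minimum(sips["end"].to_numpy(), horizon)
        durations = ends - starts
        bouts = seg.sips[seg.sips["start"] < horizon]
        rows[channel] = {
            "n_sips": len(sips),
            "n_bursts": bouts["burst_id"].nunique() if len(bouts) else 0,
            "n_bouts": bouts["bout_id"].nunique() if len(bouts) else 0,
            "total_feeding_duration": float(durations.sum()),
            "mean_sip_duration": float(durations.mean()) if len(sips) else 0.0,
            "mean_bout_duration": _mean_bout_duration(sips, horizon),
        }
        # time eaten up to each grid point: sum of clip(t - start, 0, duration)
        cumulative[channel] = np.add.reduce(
            np.clip(grid[None, :] - starts[:, None], 0.0, durations[:, None]), axis=0
        ) if len(sips) else np.zeros_like(grid)
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "channel"
    cum = pd.DataFrame(cumulative, index=pd.Index(grid, name="time_s"))
    return FeedingSummary(table=table, cumulative=cum)


def _mean_bout_duration(sips: pd.DataFrame, horizon: float) -> float:
    if not len(sips):
        return 0.0
    g = sips.groupby("bout_id")
    dur = np.minimum(g["end"].max(), horizon) - g["start"].min()
    return float(dur.mean())


def per_suppression(per_with: float, per_without: float) -> float:
    """PER suppression index ``1 - (PER with / PER without)``.

    Both arguments are response proportions in [0, 1]. When the
    without-stimulus PER is zero the index is undefined and NaN is returned
    (some conditions produce zero PER); this is a marker, not an error.
    """
    for name, v in (("per_with", per_with), ("per_without", per_without)):
        if not 0.0 <= v <= 1.0:
            raise InvalidParameterError(f"{name}={v} outside [0, 1]")
    if per_without == 0:
        return math.nan
    return 1.0 - per_with / per_without


# ---------------------------------------------------------------------------
# file I/O


def read_event_stream(path, session_length: float, sep: str | None = None) -> EventStream:
    """Read an interaction table (channel, start, end) as CSV/TSV."""
    df = pd.read_csv(path, sep=sep, engine="python")
    if df.empty and not set(df.columns) >= {"channel", "start", "end"}:
        raise EmptyInputError("interaction table is empty and has no header")
    channels = sorted(df["channel"].astype(str).unique())
    df["channel"] = df["channel"].astype(str)
    return EventStream(channels=channels, interactions=df, session_length=session_length)


def write_summary(summary: FeedingSummary, table_path, cumulative_path) -> None:
    summary.table.to_csv(table_path)
    long = summary.cumulative.reset_index().melt(
        id_vars="time_s", var_name="channel", value_name="cumulative_duration_s"
    )
    long.to_csv(cumulative_path, index=False)
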