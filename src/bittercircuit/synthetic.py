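"""Synthetic data generators with planted ground truth.

Every pipeline stage has a matching generator here so that parameter recovery
can be tested without external data:

* arena trials — flies walking in a circular arena with stimulus-locked
  kinematic changes (speed/turn boost at light onset, probabilistic freezing
  after light offset) and a biased random walk producing quadrant preference;
* feeding sessions — two-channel interaction streams with hierarchical sip /
  burst / bout timing and closed-loop suppression on the stimulated channel;
* calcium trials — ON/OFF transients on a fluorescence baseline with
  per-trial multiplicative habituation;
* circuit graphs — planted seed / third-layer / fourth-layer structure with
  subtype connectivity motifs, region annotations, feedback edges, and
  sub-threshold decoy edges.

All generators take an integer seed and are bitwise deterministic; planted
values are recorded in a :class:`GroundTruth` record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .calcium import BASELINE_FRAMES, CalciumTrace
from .connectome import DEFAULT_REGION_CATALOG, CircuitGraph, Neuron
from .exceptions import InvalidParameterError, ProtocolError
from .feeding import EventStream, closed_loop_annotation
from .locomotor import StimulusProtocol, Trajectory


@dataclass
class GroundTruth:
    """Planted parameter values recorded by a generator."""

    seed: int
    planted: dict[str, Any] = field(default_factory=dict)

    def __getitem__(self, key: str):
        return self.planted[key]


# ---------------------------------------------------------------------------
# arena trials


@dataclass
class ArenaSimParams:
    """Arena-walk generator parameters.

    Speeds in mm/s, turning in deg/s, durations in s. ``light_attraction``
    is a signed drift speed (mm/s) toward (+) or away from (-) the nearest
    lit-quadrant centroid while light is on; the study's stimuli are
    aversive, so the default is negative.
    """

    n_flies: int = 24
    frame_rate: float = 30.0
    baseline_speed: float = 6.0
    onset_speed_boost: float = 4.0
    onset_turn_boost: float = 60.0
    offset_freeze_prob: float = 0.75
    freeze_duration: float = 30.0
    light_attraction: float = -0.5
    noise_sd: float = 1.0
    angular_noise_sd: float = 20.0
    arena_radius: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise InvalidParameterError("frame_rate must be positive")
        if self.n_flies < 1:
            raise InvalidParameterError("n_flies must be >= 1")
        if not 0.0 <= self.offset_freeze_prob <= 1.0:
            raise InvalidParameterError("offset_freeze_prob must lie in [0, 1]")


def _quadrant_centroids(radius: float) -> dict[int, np.ndarray]:
    h = radius / 2.0
    return {1: np.array([h, h]), 2: np.array([-h, h]), 3: np.array([-h, -h]), 4: np.array([h, -h])}


def generate_arena_trial(
    params: ArenaSimParams,
    protocol: StimulusProtocol,
    session_length: float | None = None,
) -> tuple[list[Trajectory], GroundTruth]:
    """Simulate one arena trial of ``n_flies`` tracked flies.

    During light epochs, flies inside stimulated quadrants walk at
    ``baseline_speed + onset_speed_boost`` and turn with an extra
    ``onset_turn_boost``; at each light offset a fraction
    ``offset_freeze_prob`` of flies freezes (speed drawn from
    \\|N(0, 0.1·baseline_speed)\\|) for ``freeze_duration``. Positions follow
    a heading random walk plus the signed quadrant drift.
    """
    if session_length is None:
        session_length = protocol.end + 10.0
    if protocol.end > session_length:
        raise ProtocolError("protocol epochs extend past the session length")
    rng = np.random.default_rng(params.seed)
    fr = params.frame_rate
    n_frames = int(round(session_length * fr))
    n = params.n_flies
    dt = 1.0 / fr

    light_epochs = protocol.of_kind("light")
    centroids = _quadrant_centroids(params.arena_radius)

    # initial state
    r0 = params.arena_radius * np.sqrt(rng.uniform(0, 1, n)) * 0.95
    a0 = rng.uniform(0, 2 * np.pi, n)
    pos = np.column_stack([r0 * np.cos(a0), r0 * np.sin(a0)])
    heading = rng.uniform(0, 2 * np.pi, n)
    freeze_until = np.full(n, -1.0)

    x = np.empty((n, n_frames))
    y = np.empty((n, n_frames))
    speed_out = np.empty((n, n_frames))
    ang_out = np.empty((n, n_frames))

    offset_frames = {int(round(ep.end * fr)): ep for ep in light_epochs}

    for i in range(n_frames):
        t = i * dt
        # freezing decision at each light offset
        if i in offset_frames:
            frozen = rng.uniform(0, 1, n) < params.offset_freeze_prob
            freeze_until[frozen] = t + params.freeze_duration

        active = next((ep for ep in light_epochs if ep.start <= t < ep.end), None)
        quad = _quadrants_of(pos)
        lit = (
            np.isin(quad, sorted(active.quadrant_mask)) if active is not None else np.zeros(n, bool)
        )

        speed = np.full(n, params.baseline_speed)
        ang = np.zeros(n)
        speed[lit] += params.onset_speed_boost
        ang[lit] += params.onset_turn_boost
        if params.noise_sd > 0:
            speed = speed + rng.normal(0, params.noise_sd, n)
        if params.angular_noise_sd > 0:
            ang = ang + rng.normal(0, params.angular_noise_sd, n)
        speed = np.clip(speed, 0, None)

        frozen_now = t < freeze_until
        if frozen_now.any():
            speed[frozen_now] = np.abs(
                rng.normal(0, 0.1 * params.baseline_speed, int(frozen_now.sum()))
            )
            ang[frozen_now] = 0.0

        x[:, i], y[:, i] = pos[:, 0], pos[:, 1]
        speed_out[:, i], ang_out[:, i] = speed, ang

        # advance state
        heading = heading + np.radians(ang) * dt
        step = speed[:, None] * dt * np.column_stack([np.cos(heading), np.sin(heading)])
        if active is not None and params.light_attraction != 0 and len(active.quadrant_mask) < 4:
            step = step + _quadrant_drift(
                pos, active.quadrant_mask, centroids, params.light_attraction * dt
            )
        pos = pos + step
        radius = np.hypot(pos[:, 0], pos[:, 1])
        over = radius > params.arena_radius
        if over.any():
            pos[over] *= (params.arena_radius / radius[over])[:, None]
            heading[over] = heading[over] + np.pi  # bounce back

    trajs = [
        Trajectory(
            fly_id=f"fly{j:03d}",
            frame_rate=fr,
            x=x[j],
            y=y[j],
            forward_velocity=speed_out[j],
            angular_velocity=ang_out[j],
            arena_radius=params.arena_radius,
        )
        for j in range(n)
    ]
    truth = GroundTruth(
        seed=params.seed,
        planted={
            "baseline_speed": params.baseline_speed,
            "onset_speed_boost": params.onset_speed_boost,
            "onset_turn_boost": params.onset_turn_boost,
            "offset_freeze_prob": params.offset_freeze_prob,
            "freeze_duration": params.freeze_duration,
            "light_attraction": params.light_attraction,
        },
    )
    return trajs, truth


def _quadrants_of(pos: np.ndarray) -> np.ndarray:
    from .locomotor import quadrant_labels

    return quadrant_labels(pos[:, 0], pos[:, 1])


def _quadrant_drift(
    pos: np.ndarray,
    mask: frozenset[int],
    centroids: dict[int, np.ndarray],
    magnitude: float,
) -> np.ndarray:
    """Signed drift toward (+) / away from (-) the nearest lit-quadrant centroid."""
    lit = sorted(mask)
    cents = np.stack([centroids[q] for q in lit])  # (m, 2)
    diffs = cents[None, :, :] - pos[:, None, :]  # (n, m, 2)
    dists = np.linalg.norm(diffs, axis=2)
    nearest = np.argmin(dists, axis=1)
    vec = diffs[np.arange(len(pos)), nearest]
    norm = np.linalg.norm(vec, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return magnitude * vec / norm


# ---------------------------------------------------------------------------
# feeding sessions


@dataclass
class FeedingSimParams:
    """Hierarchical sip-timing generator parameters (all times in s).

    Inter-event intervals are exponential at three nested scales, truncated
    so the generated gaps respect the segmentation thresholds
    (``burst_gap_threshold`` / ``bout_gap_threshold``): within-burst gaps fall
    below the burst threshold, between-burst gaps between the two thresholds,
    and between-bout gaps above the bout threshold. On the closed-loop
    channel, every sip after the first is retained with probability
    ``opto_suppression_factor`` (light-triggered suppression of the
    interaction rate).
    """

    session_length: float = 3600.0
    sip_duration_mean: float = 0.15
    intra_burst_interval_mean: float = 0.2
    inter_burst_interval_mean: float = 1.0
    inter_bout_interval_mean: float = 60.0
    opto_suppression_factor: float = 0.1
    burst_gap_threshold: float = 0.5
    bout_gap_threshold: float = 2.0
    mean_sips_per_burst: float = 5.0
    mean_bursts_per_bout: float = 3.0
    min_sip_duration: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (
            self.intra_burst_interval_mean
            < self.inter_burst_interval_mean
            < self.inter_bout_interval_mean
        ):
            raise InvalidParameterError(
                "interval means must satisfy intra_burst < inter_burst < inter_bout"
            )
        if not 0.0 <= self.opto_suppression_factor <= 1.0:
            raise InvalidParameterError("opto_suppression_factor must lie in [0, 1]")
        if not self.burst_gap_threshold < self.bout_gap_threshold:
            raise InvalidParameterError("gap thresholds must be ordered")


def _truncated_exp(rng: np.random.Generator, mean: float, lo: float, hi: float) -> float:
    """Exponential(mean) conditioned on (lo, hi) via inverse CDF."""
    if math.isinf(hi):
        return lo + rng.exponential(mean)
    a, b = math.exp(-lo / mean), math.exp(-hi / mean)
    u = rng.uniform(0, 1)
    return -mean * math.log(a - u * (a - b))


def _gen_channel_sips(params: FeedingSimParams, rng: np.random.Generator) -> pd.DataFrame:
    """One channel's sip intervals with planted burst/bout structure."""
    rows = []
    t = rng.exponential(params.inter_bout_interval_mean)
    bout_id = burst_id = -1
    while t < params.session_length:
        bout_id += 1
        n_bursts = 1 + rng.poisson(max(params.mean_bursts_per_bout - 1, 0))
        for b in range(n_bursts):
            burst_id += 1
            n_sips = 1 + rng.poisson(max(params.mean_sips_per_burst - 1, 0))
            for s in range(n_sips):
                dur = params.min_sip_duration + rng.exponential(
                    max(params.sip_duration_mean - params.min_sip_duration, 1e-3)
                )
                if t + dur > params.session_length:
                    return pd.DataFrame(rows, columns=["start", "end", "burst_id", "bout_id"])
                rows.append((t, t + dur, burst_id, bout_id))
                t += dur
                if s < n_sips - 1:
                    t += _truncated_exp(
                        rng, params.intra_burst_interval_mean, 0.0, params.burst_gap_threshold
                    )
            if b < n_bursts - 1:
                t += _truncated_exp(
                    rng,
                    params.inter_burst_interval_mean,
                    params.burst_gap_threshold,
                    params.bout_gap_threshold,
                )
        t += _truncated_exp(rng, params.inter_bout_interval_mean, params.bout_gap_threshold, math.inf)
    return pd.DataFrame(rows, columns=["start", "end", "burst_id", "bout_id"])


def generate_feeding_session(
    params: FeedingSimParams, closed_loop_channel: str = "opto"
) -> tuple[EventStream, GroundTruth]:
    """Simulate a two-channel feeding session ("control" + stimulated channel).

    Both channels draw from the same hierarchical sip process; on the
    stimulated channel every sip after the first is kept with probability
    ``opto_suppression_factor``. Light epochs follow the closed-loop rule
    (1.5 s per interaction, merged).
    """
    rng = np.random.default_rng(params.seed)
    channels = ["control", closed_loop_channel]
    control = _gen_channel_sips(params, rng)
    stim_full = _gen_channel_sips(params, rng)
    if len(stim_full) > 1 and params.opto_suppression_factor < 1.0:
        keep = rng.uniform(0, 1, len(stim_full)) < params.opto_suppression_factor
        keep[0] = True  # suppression begins with the first (light-triggering) contact
        stim = stim_full[keep].reset_index(drop=True)
    else:
        stim = stim_full

    frames = []
    for channel, sips in (("control", control), (closed_loop_channel, stim)):
        df = sips[["start", "end"]].copy()
        df.insert(0, "channel", channel)
        frames.append(df)
    interactions = pd.concat(frames, ignore_index=True).sort_values("start").reset_index(drop=True)
    events = EventStream(
        channels=channels, interactions=interactions, session_length=params.session_length
    )
    events.light_epochs = closed_loop_annotation(events, closed_loop_channel)

    def counts(df: pd.DataFrame) -> dict[str, int]:
        return {
            "n_sips": len(df),
            "n_bursts": df["burst_id"].nunique() if len(df) else 0,
            "n_bouts": df["bout_id"].nunique() if len(df) else 0,
        }

    truth = GroundTruth(
        seed=params.seed,
        planted={
            "opto_suppression_factor": params.opto_suppression_factor,
            "control_counts": counts(control),
            "stim_counts_prethinning": counts(stim_full),
            "stim_n_sips_kept": len(stim),
            "burst_gap_threshold": params.burst_gap_threshold,
            "bout_gap_threshold": params.bout_gap_threshold,
        },
    )
    return events, truth


# ---------------------------------------------------------------------------
# calcium trials


@dataclass
class CalciumSimParams:
    """ON/OFF transient generator parameters.

    Amplitudes are ΔF/F fractions; habituation factors are per-trial
    multiplicative decrements applied to the respective amplitude. The OFF
    transient starts ``off_latency_frames`` after stimulus offset and holds a
    short plateau before decaying with ``decay_tau`` so that the peak equals
    the planted amplitude even after light smoothing.
    """

    frame_rate: float = 6.5
    baseline_f: float = 100.0
    on_amplitude: float = 0.7
    off_amplitude: float = 0.4
    decay_tau: float = 2.0
    habituation_factor_on: float = 0.6
    habituation_factor_off: float = 0.9
    noise_sd: float = 0.02
    off_latency_frames: int = 2
    off_plateau_frames: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_f <= 0:
            raise InvalidParameterError("baseline_f must be positive")
        if self.on_amplitude < 0 or self.off_amplitude < 0:
            raise InvalidParameterError("amplitudes must be non-negative")
        for h in (self.habituation_factor_on, self.habituation_factor_off):
            if not 0.0 < h <= 1.0:
                raise InvalidParameterError("habituation factors must lie in (0, 1]")


def generate_calcium_trial(
    params: CalciumSimParams,
    n_trials: int = 3,
    stim_onset: float = 5.0,
    stim_duration: float = 5.0,
) -> tuple[list[CalciumTrace], GroundTruth]:
    """Simulate ``n_trials`` repeated-stimulation fluorescence traces.

    Trial k carries ON amplitude ``on_amplitude * habituation_factor_on**(k-1)``
    (and analogously for OFF). The ON response is sustained for the stimulus
    duration; the OFF transient begins just after offset.
    """
    fr = params.frame_rate
    onset = int(round(stim_onset * fr))
    if onset < BASELINE_FRAMES:
        raise InvalidParameterError(
            f"stimulus onset must allow >= {BASELINE_FRAMES} baseline frames"
        )
    rng = np.random.default_rng(params.seed)
    dur_frames = int(round(stim_duration * fr))
    offset = onset + dur_frames
    n_frames = offset + int(round(10.0 * fr))  # 5 s OFF window + decay tail

    traces = []
    on_amps, off_amps = [], []
    for k in range(1, n_trials + 1):
        on_k = params.on_amplitude * params.habituation_factor_on ** (k - 1)
        off_k = params.off_amplitude * params.habituation_factor_off ** (k - 1)
        on_amps.append(on_k)
        off_amps.append(off_k)
        dff_true = np.zeros(n_frames)
        dff_true[onset:offset] = on_k
        off_start = offset + params.off_latency_frames
        off_end = off_start + params.off_plateau_frames
        dff_true[off_start:off_end] = off_k
        tail = np.arange(off_end, n_frames)
        dff_true[tail] = off_k * np.exp(-(tail - off_end + 1) / (params.decay_tau * fr))
        f = params.baseline_f * (1.0 + dff_true)
        if params.noise_sd > 0:
            f = f + rng.normal(0, params.noise_sd * params.baseline_f, n_frames)
        traces.append(
            CalciumTrace(
                frame_rate=fr,
                f=f,
                stim_onset_frame=onset,
                stim_duration=stim_duration,
                trial_index=k,
            )
        )
    truth = GroundTruth(
        seed=params.seed,
        planted={
            "on_amplitudes": on_amps,
            "off_amplitudes": off_amps,
            "habituation_factor_on": params.habituation_factor_on,
            "habituation_factor_off": params.habituation_factor_off,
        },
    )
    return traces, truth


def write_calcium_tables(traces: Sequence[CalciumTrace], roi_path, manifest_path) -> None:
    """Write traces in the (trial, frame, mean_f) + manifest format."""
    roi = pd.concat(
        [
            pd.DataFrame(
                {"trial": t.trial_index, "frame": np.arange(len(t.f)), "mean_f": t.f}
            )
            for t in traces
        ],
        ignore_index=True,
    )
    roi.to_csv(roi_path, index=False)
    pd.DataFrame(
        {
            "trial": [t.trial_index for t in traces],
            "frame_rate": [t.frame_rate for t in traces],
            "stim_onset_frame": [t.stim_onset_frame for t in traces],
            "stim_duration": [t.stim_duration for t in traces],
        }
    ).to_csv(manifest_path, index=False)


# ---------------------------------------------------------------------------
# circuit graphs


@dataclass
class CircuitSimParams:
    """Planted layered-circuit generator parameters.

    The default seed population mirrors the three seed subtypes and their
    cell counts (6 + 5 + 10 = 21); planted inter-subtype motif edges carry
    >= 5 synapses, layer edges carry weights within ``edge_weight_range``
    (floored at the admission threshold of 3), and decoy edges stay below
    threshold.
    """

    seed_subtypes: tuple[tuple[str, int], ...] = (("mAL3A", 6), ("mAL3B", 5), ("mAL4", 10))
    n_seed: int = 21
    n_layer2: int = 32
    n_layer3: int = 30
    edge_weight_range: tuple[int, int] = (3, 40)
    planted_motif: dict[tuple[str, str], int] | None = None
    region_catalog: tuple[str, ...] = DEFAULT_REGION_CATALOG
    feedback_fraction: float = 0.1
    n_decoy: int = 15
    n_spurious_edges: int = 40
    contra_prob: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(c for _, c in self.seed_subtypes) != self.n_seed:
            raise InvalidParameterError("seed subtype counts must sum to n_seed")
        if self.n_layer2 < 0 or self.n_layer3 < 0:
            raise InvalidParameterError("layer counts must be >= 0")
        if self.edge_weight_range[0] < 1:
            raise InvalidParameterError("edge weights must be >= 1 synapse")
        if not 0.0 <= self.feedback_fraction <= 1.0:
            raise InvalidParameterError("feedback_fraction must lie in [0, 1]")

    def default_motif(self) -> dict[tuple[str, str], int]:
        """Hierarchical default: strong A→B, weak B→A and {A,B}→third, none back."""
        names = [n for n, _ in self.seed_subtypes]
        if len(names) < 2:
            return {}
        motif = {(names[0], names[1]): 8, (names[1], names[0]): 2}
        if len(names) > 2:
            motif[(names[0], names[2])] = 2
            motif[(names[1], names[2])] = 2
        return motif


def generate_circuit(params: CircuitSimParams) -> tuple[CircuitGraph, GroundTruth]:
    """Generate a planted layered circuit with known memberships and motif."""
    rng = np.random.default_rng(params.seed)
    lo, hi = params.edge_weight_range
    strong_lo = max(lo, 3)
    graph = CircuitGraph()
    catalog = list(params.region_catalog)

    seeds_by_subtype: dict[str, list[str]] = {}
    seed_ids: list[str] = []
    for name, count in params.seed_subtypes:
        ids = [f"{name}_{i + 1:02d}" for i in range(count)]
        seeds_by_subtype[name] = ids
        seed_ids.extend(ids)
        for cid in ids:
            graph.add_neuron(Neuron(cell_id=cid, cell_type=name, subtype_group=name))

    layer2 = [f"L3N_{i + 1:03d}" for i in range(params.n_layer2)]
    layer3 = [f"L4N_{i + 1:03d}" for i in range(params.n_layer3)]
    decoys = [f"DEC_{i + 1:03d}" for i in range(params.n_decoy)]
    for cid in layer2:
        graph.add_neuron(Neuron(cell_id=cid, cell_type="3N"))
    for cid in layer3:
        graph.add_neuron(Neuron(cell_id=cid, cell_type="4N"))
    for cid in decoys:
        graph.add_neuron(Neuron(cell_id=cid, cell_type="decoy"))

    def connect_layer(sources: list[str], targets: list[str]) -> None:
        for post in targets:
            n_in = 1 + int(rng.integers(0, min(6, len(sources))))
            pres = rng.choice(sources, size=n_in, replace=False)
            for pre in pres:
                graph.add_edge(str(pre), post, int(rng.integers(strong_lo, hi + 1)))

    connect_layer(seed_ids, layer2)
    connect_layer(layer2, layer3)

    # planted seed-subtype motif (edges of >= 5 synapses between seed cells)
    motif = params.planted_motif if params.planted_motif is not None else params.default_motif()
    subtype_names = sorted(seeds_by_subtype)
    truth_motif = pd.DataFrame(0, index=subtype_names, columns=subtype_names, dtype=int)
    for (a, b), n_edges in motif.items():
        pairs = [
            (u, v) for u in seeds_by_subtype[a] for v in seeds_by_subtype[b] if u != v
        ]
        chosen = rng.choice(len(pairs), size=min(n_edges, len(pairs)), replace=False)
        for idx in np.sort(chosen):
            u, v = pairs[int(idx)]
            graph.add_edge(u, v, int(rng.integers(5, 31)))
            truth_motif.loc[a, b] += 1

    # feedback: a fraction of layer-3 cells send a supra-threshold edge to a seed
    n_feedback = int(round(params.feedback_fraction * params.n_layer3))
    feedback_targets: set[str] = set()
    if n_feedback and layer3:
        fb_sources = rng.choice(layer3, size=min(n_feedback, len(layer3)), replace=False)
        for src in fb_sources:
            dst = str(rng.choice(seed_ids))
            graph.add_edge(str(src), dst, int(rng.integers(strong_lo, hi + 1)))
            feedback_targets.add(dst)

    # sub-threshold decoy edges: never admit anyone, never touch seed targets
    posts_pool = decoys + layer2 + layer3
    pres_pool = seed_ids + layer2
    attempts = 0
    added = 0
    while added < params.n_spurious_edges and attempts < params.n_spurious_edges * 20:
        attempts += 1
        pre = str(rng.choice(pres_pool))
        post = str(rng.choice(posts_pool))
        if pre == post or graph.edge_weight(pre, post) > 0:
            continue
        graph.add_edge(pre, post, int(rng.integers(1, 3)))
        added += 1

    # region annotations and plumbing totals
    for cid in sorted(graph.neurons):
        n_regions = 1 + int(rng.integers(0, 4))
        regions = rng.choice(catalog, size=min(n_regions, len(catalog)), replace=False)
        graph.neurons[cid].output_regions = [
            (str(r), "contra" if rng.uniform() < params.contra_prob else "ipsi")
            for r in regions
        ]
    for cid in layer2 + layer3:
        in_total = sum(w for _, _, w in graph.graph.in_edges(cid, data="weight"))
        if in_total:
            graph.neurons[cid].total_input_synapses = int(
                round(in_total / rng.uniform(0.02, 0.15))
            )

    truth = GroundTruth(
        seed=params.seed,
        planted={
            "seed_ids": set(seed_ids),
            "subtype_map": {cid: st for st, ids in seeds_by_subtype.items() for cid in ids},
            "layer2_members": set(layer2),
            "layer3_members": set(layer3),
            "motif_matrix": truth_motif,
            "feedback_targets": feedback_targets,
        },
    )
    return graph, truth
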