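"""Stage handlers binding the analysis modules to file inputs and outputs.

Each handler takes a :class:`~bittercircuit.config.RunConfig` plus an output
directory and returns a map of artifact name → written path. They are thin:
all science lives in the analysis modules.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import calcium as ca
from . import classification as cl
from . import connectome as cx
from . import feeding as fd
from . import locomotor as lm
from . import synthetic as syn
from .config import RunConfig, load_protocol, protocol_from_dict
from .exceptions import ConfigError


def _default_arena_protocol() -> lm.StimulusProtocol:
    return lm.StimulusProtocol([lm.Epoch(start=30.0, end=35.0, kind="light")])


def _get_protocol(config: RunConfig):
    if "protocol" in config.inputs:
        return load_protocol(config.inputs["protocol"])
    if "protocol" in config.params:
        return protocol_from_dict(config.params["protocol"])
    return _default_arena_protocol()


def _simulate(config: RunConfig, out_dir: Path) -> dict[str, Path]:
    kind = config.params.get("kind", "arena")
    gen = dict(config.params.get("generator", {}))
    gen["seed"] = config.seed
    artifacts: dict[str, Path] = {}
    if kind == "arena":
        protocol = _get_protocol(config)
        trajs, _ = syn.generate_arena_trial(syn.ArenaSimParams(**gen), protocol)
        path = out_dir / "trajectories.csv"
        lm.write_trajectories(trajs, path)
        artifacts["trajectories"] = path
    elif kind == "feeding":
        events, _ = syn.generate_feeding_session(syn.FeedingSimParams(**gen))
        path = out_dir / "interactions.csv"
        events.interactions.to_csv(path, index=False)
        artifacts["interactions"] = path
    elif kind == "calcium":
        traces, _ = syn.generate_calcium_trial(
            syn.CalciumSimParams(**gen),
            n_trials=int(config.params.get("n_trials", 3)),
        )
        roi, man = out_dir / "roi_traces.csv", out_dir / "trial_manifest.csv"
        syn.write_calcium_tables(traces, roi, man)
        artifacts.update(roi_traces=roi, trial_manifest=man)
    elif kind == "circuit":
        graph, _ = syn.generate_circuit(syn.CircuitSimParams(**gen))
        path = out_dir / "edges.tsv"
        cx.write_edge_list(graph, path)
        artifacts["edges"] = path
    else:
        raise ConfigError(f"unknown simulate kind {kind!r}")
    return artifacts


def _read_trajs(config: RunConfig) -> list[lm.Trajectory]:
    return lm.read_trajectories(
        config.inputs["trajectories"],
        frame_rate=float(config.params.get("frame_rate", 30.0)),
        arena_radius=float(config.params.get("arena_radius", 30.0)),
    )


def _locomotor(config: RunConfig, out_dir: Path) -> dict[str, Path]:
    trajs = _read_trajs(config)
    protocol = _get_protocol(config)
    p = config.params
    onset = lm.onset_response(
        [trajs],
        protocol,
        baseline_window=float(p.get("baseline_window", lm.BASELINE_WINDOW_S)),
        onset_window=float(p.get("onset_window", lm.ONSET_WINDOW_S)),
    )
    offset = lm.offset_response(
        [trajs],
        protocol,
        baseline_window=float(p.get("baseline_window", lm.BASELINE_WINDOW_S)),
        offset_window=float(p.get("offset_window", lm.OFFSET_WINDOW_S)),
    )
    path = out_dir / "kinematic_response.csv"
    pd.DataFrame(
        {
            "trial": np.arange(1, len(onset.delta_forward) + 1),
            "delta_forward": onset.delta_forward,
            "delta_angular": onset.delta_angular,
            "baseline_forward": onset.baseline_forward,
            "offset_delta_forward": offset,
        }
    ).to_csv(path, index=False)
    return {"kinematic_response": path}


def _preference(config: RunConfig, out_dir: Path) -> dict[str, Path]:
    trajs = _read_trajs(config)
    protocol = _get_protocol(config)
    rows, series_frames = [], []
    for i, epoch in enumerate(protocol.of_kind("light")):
        if not (0 < len(epoch.quadrant_mask) < 4):
            continue
        series = lm.preference_index_series(trajs, epoch.quadrant_mask)
        series_frames.append(
            pd.DataFrame(
                {"epoch": i, "time_s": series.bin_centers, "pi": series.pi, "n_flies": series.n_flies}
            )
        )
        rows.append({"epoch": i, "final_pi": lm.final_pi(series, epoch)})
    if not rows:
        raise ConfigError("protocol contains no quadrant-restricted light epoch")
    series_path, final_path = out_dir / "pi_series.csv", out_dir / "final_pi.csv"
    pd.concat(series_frames, ignore_index=True).to_csv(series_path, index=False)
    pd.DataFrame(rows).to_csv(final_path, index=False)
    return {"pi_series": series_path, "final_pi": final_path}


def _feeding(config: RunConfig, out_dir: Path) -> dict[str, Path]:
    p = config.params
    events = fd.read_event_stream(
        config.inputs["interactions"], session_length=float(p.get("session_length", 3600.0))
    )
    seg = fd.segment_sips(
        events,
        intra_burst_gap=float(p.get("intra_burst_gap", fd.INTRA_BURST_GAP_S)),
        inter_bout_gap=float(p.get("inter_bout_gap", fd.INTER_BOUT_GAP_S)),
    )
    summary = fd.feeding_summary(seg, horizon=float(p.get("horizon", events.session_length)))
    table_path, cum_path = out_dir / "feeding_summary.csv", out_dir / "cumulative.csv"
    fd.write_summary(summary, table_path, cum_path)
    artifacts = {"feeding_summary": table_path, "cumulative": cum_path}
    stim = p.get("stim_channel")
    if stim:
        epochs = fd.closed_loop_annotation(events, stim)
        light_path = out_dir / "light_epochs.csv"
        pd.DataFrame(epochs, columns=["start", "end"]).to_csv(light_path, index=False)
        artifacts["light_epochs"] = light_path
    return artifacts


def _calcium(config: RunConfig, out_dir: Path) -> dict[str, Path]:
    traces = ca.read_traces(config.inputs["roi_traces"], config.inputs["trial_manifest"])
    metrics = [ca.trial_metrics(t) for t in traces]
    metrics_path = out_dir / "response_metrics.csv"
    ca.write_metrics(metrics, metrics_path)
    artifacts = {"response_metrics": metrics_path}
    if len(metrics) >= 2:
        prof = ca.habituation_profile(metrics)
        hab_path = out_dir / "habituation.csv"
        pd.DataFrame(
            {
                "trial": np.arange(1, len(metrics) + 1),
                "on_normalized": prof.on_normalized,
                "off_normalized": prof.off_normalized,
            }
        ).to_csv(hab_path, index=False)
        artifacts["habituation"] = hab_path
    return artifacts


def _classify(config: RunConfig, out_dir: Path) -> dict[str, Path]:
    p = config.params
    df = pd.read_csv(config.inputs["measurements"])
    table = cl.classify_table(
        df,
        experimental=p["experimental"],
        controls=tuple(p["controls"]),
        reference=p["reference"],
        alpha=float(p.get("alpha", cl.ALPHA)),
    )
    path = out_dir / "effect_records.csv"
    table.to_csv(path, index=False)
    matrix = table.pivot_table(
        index="genotype", columns="behavior", values="effect_class", aggfunc="first"
    )
    matrix_path = out_dir / "effect_matrix.csv"
    matrix.to_csv(matrix_path)
    return {"effect_records": path, "effect_matrix": matrix_path}


def _load_graph(config: RunConfig) -> cx.CircuitGraph:
    graph = cx.load_circuit_table(config.inputs["edges"], dialect="edge_list")
    if "annotations" in config.inputs:
        cx.load_neuron_annotations(config.inputs["annotations"], graph=graph)
    return graph


def _sources(config: RunConfig, graph: cx.CircuitGraph) -> set[str]:
    p = config.params
    if "sources" in p:
        return set(p["sources"])
    if "source_types" in p:
        types = set(p["source_types"])
        return {cid for cid, n in graph.neurons.items() if n.cell_type in types}
    raise ConfigError("trace stages need params.sources or params.source_types")


def _layer_table(layer: cx.LayerResult) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": list(layer.members),
            "total_input": [m.total_input for m in layer.members.values()],
            "n_contributing": [m.n_contributing for m in layer.members.values()],
            "is_lateral": [m.is_lateral for m in layer.members.values()],
        }
    ).sort_values(["total_input", "cell_id"], ascending=[False, True])


def _trace(config: RunConfig, out_dir: Path) -> dict[str, Path]:
    p = config.params
    graph = _load_graph(config)
    sources = _sources(config, graph)
    layer = cx.downstream_layer(graph, sources, edge_min=int(p.get("edge_min", cx.EDGE_MIN_SYNAPSES)))
    artifacts = {}
    layer_path = out_dir / "layer_members.csv"
    _layer_table(layer).to_csv(layer_path, index=False)
    artifacts["layer_members"] = layer_path
    if "pop_min" in p or "top_n" in p:
        exclude = sources if p.get("exclude_seeds", True) else set()
        if "pop_min" in p:
            top = cx.top_targets(layer, "population_min", k=int(p["pop_min"]), exclude=exclude)
        else:
            top = cx.top_targets(layer, "top_n", n=int(p["top_n"]), exclude=exclude)
        top_path = out_dir / "top_targets.csv"
        _layer_table(top).to_csv(top_path, index=False)
        artifacts["top_targets"] = top_path
    return artifacts


def _motif(config: RunConfig, out_dir: Path) -> dict[str, Path]:
    p = config.params
    graph = _load_graph(config)
    matrix = cx.interconnection_matrix(
        graph,
        edge_min=int(p.get("edge_min", cx.MOTIF_EDGE_MIN)),
        mode=p.get("mode", "count"),
    )
    path = out_dir / "motif_matrix.csv"
    matrix.to_csv(path)
    return {"motif_matrix": path}


def _regions(config: RunConfig, out_dir: Path) -> dict[str, Path]:
    p = config.params
    table = cx.load_circuit_table(config.inputs["summary_table"], dialect="summary_table")
    fractions = cx.region_fractions(
        table.members_as_neurons(), side_rule=p.get("side_rule", "ipsi_only")
    )
    path = out_dir / "region_fractions.csv"
    fractions.to_csv(path, header=True)
    return {"region_fractions": path}


def _paths(config: RunConfig, out_dir: Path) -> dict[str, Path]:
    p = config.params
    graph = _load_graph(config)
    sources = _sources(config, graph)
    result = cx.find_paths(
        graph,
        sources,
        target=p["target"],
        max_intermediates=int(p.get("max_intermediates", 3)),
        edge_min=int(p.get("edge_min", 1)),
        by_type=bool(p.get("by_type", False)),
    )
    path = out_dir / "paths.csv"
    pd.DataFrame(
        [
            {
                "path": " -> ".join(row["nodes"]),
                "weights": ",".join(map(str, row["weights"])),
                "min_weight": row["min_weight"],
                "total_weight": row["total_weight"],
                "n_hops": row["n_hops"],
            }
            for row in result.paths
        ]
    ).to_csv(path, index=False)
    return {"paths": path}


HANDLERS = {
    "simulate": _simulate,
    "locomotor": _locomotor,
    "preference": _preference,
    "feeding": _feeding,
    "calcium": _calcium,
    "classify": _classify,
    "trace": _trace,
    "motif": _motif,
    "regions": _regions,
    "paths": _paths,
}
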