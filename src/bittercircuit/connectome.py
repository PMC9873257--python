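"""Layered tracing of synaptic circuitry downstream of a seed population.

Starting from a seed set of second-order bitter projection neurons (mlSEZt;
cell types mAL3A/mAL3B/mAL4 in the hemibrain nomenclature), downstream layers
are expanded with per-edge synapse thresholds:

* third-order neurons (3Ns): cells receiving >= 3 synapses from at least one
  seed cell; *top* 3Ns are non-seed cells receiving >= 20 total synapses from
  the seed population;
* fourth-order neurons (4Ns): cells receiving >= 3 synapses from at least one
  top 3N; the top 30 4Ns are ranked by total input from the top-3N
  population.

Additional summaries: seed-subtype interconnection motif matrices (edges of
>= 5 synapses), per-region projection fractions with ipsi/contra laterality
("(C)" marks the contralateral hemisphere), feedback detection (seed cells
reappearing downstream), and bounded weighted path search to descending
neurons.

The two packaged summary tables (``data/table1_3n.tsv``, ``data/table2_4n.tsv``)
hold the published top-3N and top-4N populations and serve as reference
inputs; :func:`load_table1` / :func:`load_table2` read them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import FormatError, InvalidParameterError, LabelingError

#: per-edge synapse threshold admitting a cell into the next layer
EDGE_MIN_SYNAPSES = 3
#: population threshold defining "top" targets
POPULATION_MIN_SYNAPSES = 20
#: threshold for motif-matrix edges
MOTIF_EDGE_MIN = 5

#: region abbreviations from the top-3N table legend (NeuPrint nomenclature)
TABLE1_REGIONS = (
    "AOTU", "AVLP", "GOR", "IB", "ICL", "LH", "MB", "PLP", "PVLP", "SCL",
    "SIP", "SLP", "SMP", "VES",
)
#: additional abbreviations introduced by the top-4N table legend
TABLE2_EXTRA_REGIONS = ("CAN", "CRE", "LAL", "POC", "SPS", "mALT")
#: regions appearing in the published rows without a legend entry
EXTRA_DATA_REGIONS = ("AL",)

DEFAULT_REGION_CATALOG = tuple(
    sorted(set(TABLE1_REGIONS) | set(TABLE2_EXTRA_REGIONS) | set(EXTRA_DATA_REGIONS))
)


def parse_region_token(token: str) -> tuple[str, str]:
    """Split one region token into (region, side); "(C)" marks contralateral."""
    token = token.strip()
    if token.endswith("(C)"):
        return token[: -len("(C)")].strip(), "contra"
    return token, "ipsi"


def parse_region_list(text: str, sep: str = ",") -> list[tuple[str, str]]:
    """Parse a delimited region list, tolerating stray delimiters and spaces."""
    out = []
    for token in str(text).split(sep):
        token = token.strip()
        if token:
            out.append(parse_region_token(token))
    return out


@dataclass
class Neuron:
    """One reconstructed cell with its output-region annotations."""

    cell_id: str
    cell_type: str = ""
    subtype_group: str | None = None
    output_regions: list[tuple[str, str]] = field(default_factory=list)
    total_input_synapses: int | None = None

    def projects_to(self, region: str, side_rule: str = "ipsi_only") -> bool:
        if side_rule == "ipsi_only":
            return any(r == region and s == "ipsi" for r, s in self.output_regions)
        if side_rule == "either":
            return any(r == region for r, s in self.output_regions)
        raise ValueError(f"unknown side_rule {side_rule!r}")


@dataclass
class CircuitGraph:
    """Directed weighted synaptic graph over annotated neurons.

    Edge weights are positive integer synapse counts, pre-aggregated to one
    edge per ordered cell pair.
    """

    neurons: dict[str, Neuron] = field(default_factory=dict)
    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    def add_neuron(self, neuron: Neuron) -> None:
        existing = self.neurons.get(neuron.cell_id)
        if existing is not None and existing != neuron:
            raise FormatError(f"conflicting annotations for cell {neuron.cell_id}")
        self.neurons[neuron.cell_id] = neuron
        self.graph.add_node(neuron.cell_id)

    def add_edge(self, pre: str, post: str, weight: int) -> None:
        if weight < 1:
            raise InvalidParameterError("edge weight must be a positive synapse count")
        for cid in (pre, post):
            if cid not in self.neurons:
                self.add_neuron(Neuron(cell_id=cid))
        prev = self.graph.edges.get((pre, post), {}).get("weight", 0)
        self.graph.add_edge(pre, post, weight=int(prev) + int(weight))

    def edge_weight(self, pre: str, post: str) -> int:
        return int(self.graph.edges.get((pre, post), {}).get("weight", 0))

    def edges(self) -> Iterable[tuple[str, str, int]]:
        for u, v, w in self.graph.edges.data("weight"):
            yield u, v, int(w)

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    def subtype_of(self, cell_id: str) -> str | None:
        n = self.neurons.get(cell_id)
        return n.subtype_group if n else None

    def __eq__(self, other) -> bool:
        if not isinstance(other, CircuitGraph):
            return NotImplemented
        return self.neurons == other.neurons and sorted(self.edges()) == sorted(other.edges())


@dataclass
class LayerMember:
    """One admitted cell with its qualifying input from the previous layer."""

    cell_id: str
    total_input: int
    contributing_edges: list[tuple[str, int]] = field(default_factory=list)
    contributing_types: set[str] = field(default_factory=set)
    n_contributing: int = 0
    percent_input: float | None = None
    is_lateral: bool = False  # member also belongs to the source set

    @property
    def contributing_cells(self) -> set[str]:
        return {pre for pre, _ in self.contributing_edges}


@dataclass
class LayerResult:
    """Cells admitted into one traversal layer."""

    layer_index: int
    members: dict[str, LayerMember] = field(default_factory=dict)

    @property
    def member_ids(self) -> set[str]:
        return set(self.members)

    def totals(self) -> pd.Series:
        s = pd.Series(
            {cid: m.total_input for cid, m in self.members.items()}, dtype=int
        )
        return s.sort_values(ascending=False)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class SummaryTable:
    """A published layer summary: admitted cells plus region annotations."""

    layer: LayerResult
    neurons: dict[str, Neuron]

    def members_as_neurons(self) -> list[Neuron]:
        return [self.neurons[cid] for cid in self.layer.members]


@dataclass
class PathResult:
    """Simple paths from a seed set to a target, ranked by bottleneck weight."""

    paths: list[dict]

    def __len__(self) -> int:
        return len(self.paths)


# ---------------------------------------------------------------------------
# loading


def load_circuit_table(
    path,
    dialect: str = "edge_list",
    layer_index: int = 3,
    region_catalog: Sequence[str] = DEFAULT_REGION_CATALOG,
    unknown_region: str = "extend",
):
    """Read a connectivity table.

    ``edge_list``: TSV with columns pre_id, post_id, weight → CircuitGraph
    (duplicate ordered pairs are summed).

    ``summary_table``: a published-layer-shaped TSV with columns (cell type,
    cell ID, # input cells, input types, # synapses, % input, target regions)
    → :class:`SummaryTable`. Region tokens outside ``region_catalog`` trigger
    a warning and extend the catalog (``unknown_region="extend"``) or raise a
    :class:`FormatError` (``"reject"``).
    """
    if dialect == "edge_list":
        df = pd.read_csv(path, sep="\t")
        required = {"pre_id", "post_id", "weight"}
        if not required <= set(df.columns):
            raise FormatError(f"edge list needs columns {sorted(required)}")
        graph = CircuitGraph()
        for row in df.itertuples(index=False):
            graph.add_edge(str(row.pre_id), str(row.post_id), int(row.weight))
        return graph
    if dialect == "summary_table":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.shape[1] != 7:
            raise FormatError(f"summary table must have 7 columns, got {df.shape[1]}")
        catalog = set(region_catalog)
        layer = LayerResult(layer_index=layer_index)
        neurons: dict[str, Neuron] = {}
        for row in df.itertuples(index=False):
            cell_type, cell_id = str(row[0]).strip(), str(row[1]).strip()
            regions = parse_region_list(row[6])
            for region, _ in regions:
                if region not in catalog:
                    if unknown_region == "reject":
                        raise FormatError(f"unknown region token {region!r}")
                    warnings.warn(f"extending region catalog with {region!r}", stacklevel=2)
                    catalog.add(region)
            neuron = Neuron(cell_id=cell_id, cell_type=cell_type, output_regions=regions)
            if cell_id in neurons and neurons[cell_id] != neuron:
                raise FormatError(f"duplicate cell ID {cell_id} with conflicting attributes")
            neurons[cell_id] = neuron
            layer.members[cell_id] = LayerMember(
                cell_id=cell_id,
                total_input=int(row[4]),
                contributing_types=set(t.strip() for t in str(row[3]).split(",") if t.strip()),
                n_contributing=int(row[2]),
                percent_input=float(row[5]),
            )
        return SummaryTable(layer=layer, neurons=neurons)
    raise ValueError(f"unknown dialect {dialect!r}")


def load_neuron_annotations(path, graph: CircuitGraph | None = None) -> dict[str, Neuron]:
    """Read a neuron annotation TSV (cell_id, cell_type, subtype_group,
    regions, total_input_synapses); regions are semicolon-separated with a
    "(C)" suffix for contralateral targets."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, Neuron] = {}
    for row in df.itertuples(index=False):
        total = row.total_input_synapses
        neuron = Neuron(
            cell_id=str(row.cell_id),
            cell_type=str(row.cell_type) if pd.notna(row.cell_type) else "",
            subtype_group=(str(row.subtype_group) if pd.notna(row.subtype_group) else None),
            output_regions=parse_region_list(row.regions, sep=";") if pd.notna(row.regions) else [],
            total_input_synapses=int(total) if pd.notna(total) else None,
        )
        if neuron.cell_id in out and out[neuron.cell_id] != neuron:
            raise FormatError(f"duplicate cell ID {neuron.cell_id} with conflicting attributes")
        out[neuron.cell_id] = neuron
        if graph is not None:
            graph.neurons[neuron.cell_id] = neuron
            graph.graph.add_node(neuron.cell_id)
    return out


def write_neuron_annotations(neurons: dict[str, Neuron] | Iterable[Neuron], path) -> None:
    """Write the annotation TSV read by :func:`load_neuron_annotations`."""
    if isinstance(neurons, dict):
        neurons = neurons.values()
    rows = []
    for n in sorted(neurons, key=lambda n: n.cell_id):
        regions = ";".join(
            r + ("(C)" if side == "contra" else "") for r, side in n.output_regions
        )
        rows.append(
            {
                "cell_id": n.cell_id,
                "cell_type": n.cell_type,
                "subtype_group": n.subtype_group or "",
                "regions": regions,
                "total_input_synapses": (
                    "" if n.total_input_synapses is None else n.total_input_synapses
                ),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_edge_list(graph: CircuitGraph, path) -> None:
    pd.DataFrame(
        sorted(graph.edges()), columns=["pre_id", "post_id", "weight"]
    ).to_csv(path, sep="\t", index=False)


def _fixture_path(name: str):
    return resources.files("bittercircuit.data").joinpath(name)


def load_table1() -> SummaryTable:
    """The packaged top-3N summary table (32 cells, >= 20 seed synapses)."""
    with resources.as_file(_fixture_path("table1_3n.tsv")) as p:
        return load_circuit_table(p, dialect="summary_table", layer_index=3)


def load_table2() -> SummaryTable:
    """The packaged top-4N summary table (30 cells ranked by top-3N input)."""
    with resources.as_file(_fixture_path("table2_4n.tsv")) as p:
        return load_circuit_table(p, dialect="summary_table", layer_index=4)


# ---------------------------------------------------------------------------
# layer expansion and ranking


def downstream_layer(
    graph: CircuitGraph,
    source_set: Iterable[str],
    edge_min: int = EDGE_MIN_SYNAPSES,
    layer_index: int = 3,
    include_subthreshold_in_total: bool = False,
) -> LayerResult:
    """Cells receiving at least one edge of >= ``edge_min`` synapses from the
    source set.

    A member's reported total sums its qualifying edges from the source set;
    set ``include_subthreshold_in_total`` to also count sub-threshold edges
    once the cell is admitted. Source-set members reached this way are
    retained and flagged ``is_lateral`` (lateral/feedback connectivity).
    """
    sources = set(source_set)
    unknown = sources - set(graph.neurons)
    if unknown:
        raise InvalidParameterError(f"source cells not in graph: {sorted(unknown)[:5]}")
    result = LayerResult(layer_index=layer_index)
    incoming: dict[str, list[tuple[str, int]]] = {}
    for pre in sources:
        for _, post, w in graph.graph.out_edges(pre, data="weight"):
            incoming.setdefault(post, []).append((pre, int(w)))
    for post, edges in incoming.items():
        qualifying = [(pre, w) for pre, w in edges if w >= edge_min]
        if not qualifying:
            continue
        counted = edges if include_subthreshold_in_total else qualifying
        neuron = graph.neurons[post]
        total = sum(w for _, w in counted)
        result.members[post] = LayerMember(
            cell_id=post,
            total_input=total,
            contributing_edges=sorted(counted),
            contributing_types={
                graph.neurons[pre].cell_type for pre, _ in counted if graph.neurons[pre].cell_type
            },
            n_contributing=len({pre for pre, _ in counted}),
            percent_input=(
                100.0 * total / neuron.total_input_synapses
                if neuron.total_input_synapses
                else None
            ),
            is_lateral=post in sources,
        )
    return result


def top_targets(
    layer: LayerResult,
    mode: str = "population_min",
    k: int = POPULATION_MIN_SYNAPSES,
    n: int = 30,
    exclude: Iterable[str] = (),
) -> LayerResult:
    """Restrict a layer to its strongest targets.

    ``population_min`` keeps members whose total input is >= ``k`` synapses
    after removing ``exclude`` (e.g. the seed cells themselves);
    ``top_n`` keeps the ``n`` largest totals, ties broken by ascending
    cell ID for determinism.
    """
    exclude = set(exclude)
    kept = {cid: m for cid, m in layer.members.items() if cid not in exclude}
    if mode == "population_min":
        members = {cid: m for cid, m in kept.items() if m.total_input >= k}
    elif mode == "top_n":
        if n <= 0:
            raise InvalidParameterError("top_n requires n >= 1")
        if not kept:
            raise InvalidParameterError("top_n on an empty layer")
        ranked = sorted(kept.values(), key=lambda m: (-m.total_input, m.cell_id))
        members = {m.cell_id: m for m in ranked[:n]}
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return LayerResult(layer_index=layer.layer_index, members=members)


def interconnection_matrix(
    graph: CircuitGraph,
    subtype_map: dict[str, str] | None = None,
    edge_min: int = MOTIF_EDGE_MIN,
    mode: str = "count",
    cells: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Subtype-by-subtype motif matrix over qualifying edges.

    Cell (i, j) aggregates edges of >= ``edge_min`` synapses from subtype i
    to subtype j: the number of such edges (``mode="count"``) or their summed
    weight (``mode="weight"``). ``subtype_map`` defaults to the graph's
    ``subtype_group`` annotations; every cell considered must be labeled.
    """
    if mode not in ("count", "weight"):
        raise ValueError(f"unknown mode {mode!r}")
    if subtype_map is None:
        subtype_map = {
            cid: n.subtype_group for cid, n in graph.neurons.items() if n.subtype_group
        }
    pool = set(cells) if cells is not None else set(subtype_map)
    unlabeled = pool - set(subtype_map)
    if unlabeled:
        raise LabelingError(f"cells without subtype label: {sorted(unlabeled)[:5]}")
    labels = sorted(set(subtype_map[c] for c in pool))
    mat = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for pre, post, w in graph.edges():
        if pre in pool and post in pool and w >= edge_min:
            value = 1 if mode == "count" else w
            mat.loc[subtype_map[pre], subtype_map[post]] += value
    mat.index.name = "from_subtype"
    mat.columns.name = "to_subtype"
    return mat


def region_fractions(
    members: Sequence[Neuron],
    side_rule: str = "ipsi_only",
    catalog: Sequence[str] | None = None,
) -> pd.Series:
    """Fraction of member cells whose output regions include each region.

    With ``side_rule="ipsi_only"`` only ipsilateral projections count; with
    ``"either"`` a contralateral "(C)" projection also counts. An empty
    member set is undefined and yields an all-NaN result.
    """
    if catalog is None:
        seen = sorted({r for m in members for r, _ in m.output_regions})
        catalog = seen or list(DEFAULT_REGION_CATALOG)
    if not members:
        return pd.Series(np.nan, index=pd.Index(catalog, name="region"))
    counts = {
        region: sum(m.projects_to(region, side_rule) for m in members)
        for region in catalog
    }
    return pd.Series(
        {r: c / len(members) for r, c in counts.items()},
        index=pd.Index(catalog, name="region"),
        name=f"fraction_{side_rule}",
    )


def feedback_detect(layer: LayerResult, seed_set: Iterable[str]) -> dict[str, list[tuple[str, int]]]:
    """Seed cells reappearing in a downstream layer, with their qualifying edges.

    Returns a map seed cell ID → list of (presynaptic cell, weight) edges
    through which the seed cell was re-admitted (feedback connections).
    """
    seeds = set(seed_set)
    return {
        cid: list(m.contributing_edges)
        for cid, m in layer.members.items()
        if cid in seeds
    }


def find_paths(
    graph: CircuitGraph,
    source_set: Iterable[str],
    target: str,
    max_intermediates: int = 3,
    edge_min: int = 1,
    by_type: bool = False,
) -> PathResult:
    """All simple paths from the seed set to a target cell (or cell type).

    Paths have at most ``max_intermediates`` intermediate nodes and use only
    edges of >= ``edge_min`` synapses; they are ranked by bottleneck
    (minimum-edge) weight descending, then total weight descending. With
    ``by_type`` the target names a cell type and every cell of that type is
    searched.
    """
    sources = sorted(set(source_set))
    if by_type:
        targets = sorted(
            cid for cid, n in graph.neurons.items() if n.cell_type == target
        )
    else:
        targets = [target] if target in graph.neurons else []
    if not targets and not by_type:
        raise InvalidParameterError(f"target cell {target!r} not in graph")
    sub = nx.DiGraph(
        (u, v, {"weight": w}) for u, v, w in graph.edges() if w >= edge_min
    )
    paths = []
    for t in targets:
        if t not in sub:
            continue
        for s in sources:
            if s not in sub or s == t:
                continue
            for nodes in nx.all_simple_paths(sub, s, t, cutoff=max_intermediates + 1):
                weights = [int(sub.edges[u, v]["weight"]) for u, v in zip(nodes, nodes[1:])]
                paths.append(
                    {
                        "nodes": tuple(nodes),
                        "weights": tuple(weights),
                        "min_weight": min(weights),
                        "total_weight": sum(weights),
                        "n_hops": len(weights),
                    }
                )
    paths.sort(key=lambda p: (-p["min_weight"], -p["total_weight"], p["nodes"]))
    return PathResult(paths=paths)
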