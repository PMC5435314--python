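"""End-to-end analysis report for an anatomical network.

Runs the full pipeline — census, betweenness centrality, modularity
optimization under the chosen null, and the force-directed layout — and
writes a reproducible bundle: centrality CSV, partition CSV with Q, a
module-composition table (module -> bones, knots, muscles by name), layout
coordinates, an optional figure, and a JSON summary.  Two runs with the
same configuration produce byte-identical JSON (floats at fixed precision,
keys sorted).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from .centrality import betweenness, count_above_threshold
from .datasets import frog_hindlimb_fixture
from .graph import (
    AnatomicalNetwork,
    NodeType,
    Partition,
    degree_census,
    find_within_type_edges,
    load_network,
)
from .layout import LayoutConfig, LayoutResult, fruchterman_reingold, layout_separation_score
from .modularity import build_null, compute_q
from .search import best_partition, compare_partitions

__all__ = ["RunConfig", "run_full_analysis"]

_TYPE_ORDER = (NodeType.BONE, NodeType.CONNECTIVE_KNOT, NodeType.MUSCLE)


@dataclass
class RunConfig:
    """Configuration of one full analysis run (all seeds logged)."""

    fixture: str | None = None  # "frog" loads the packaged network
    node_path: str | None = None
    edge_path: str | None = None
    null_kind: str = "configuration"
    forbidden_type: str | None = None
    restarts: int = 20
    seed: int = 1
    betweenness_threshold: float = 100.0
    layout_iterations: int = 500
    reference_partition: str | None = None  # "published" or a CSV path
    out_dir: str = "results"
    figure: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _load_input(config: RunConfig) -> AnatomicalNetwork:
    if config.fixture == "frog":
        return frog_hindlimb_fixture()
    if config.fixture:
        raise ValueError(f"unknown fixture {config.fixture!r}; only 'frog' is packaged")
    if not config.node_path:
        raise ValueError("no input: set fixture='frog' or node_path/edge_path")
    for p in (config.node_path, config.edge_path):
        if p and not Path(p).exists():
            raise FileNotFoundError(f"input file not found: {p}")
    return load_network(config.node_path, config.edge_path)


def _reference(config: RunConfig, net: AnatomicalNetwork) -> Partition | None:
    if config.reference_partition in (None, ""):
        return None
    if config.reference_partition in ("published", "table2"):
        return net.published_partition()
    df = pd.read_csv(config.reference_partition)
    return Partition({int(r["id"]): str(r["module"]) for _, r in df.iterrows()})


def _module_table(net: AnatomicalNetwork, partition: Partition) -> pd.DataFrame:
    """Module composition in the shape of a published module table:
    one row per module listing bones, fibrous knots and muscles by name."""
    rows = []
    for label in partition.labels:
        members = partition.members(label)
        by_type = {
            t: ", ".join(net.name_of(i) for i in members if net.type_of(i) is t)
            or "-"
            for t in _TYPE_ORDER
        }
        rows.append(
            {
                "module": label,
                "bones": by_type[NodeType.BONE],
                "fibrous_knots": by_type[NodeType.CONNECTIVE_KNOT],
                "muscles": by_type[NodeType.MUSCLE],
                "size": len(members),
            }
        )
    return pd.DataFrame(rows)


def run_full_analysis(config: RunConfig) -> dict:
    """Run the pipeline and write the report bundle into ``config.out_dir``.

    Returns the JSON summary as a dict (also written to ``summary.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net = _load_input(config)

    # centrality
    table = betweenness(net)
    cent_rows = [
        {
            "id": i,
            "name": net.name_of(i),
            "type": net.type_of(i).value,
            "degree": net.degree(i),
            "betweenness": round(table[i], 6),
            "rank": rank + 1,
        }
        for rank, i in enumerate(table.ranking)
    ]
    pd.DataFrame(cent_rows).to_csv(out / "centrality.csv", index=False)

    # modularity search
    null = build_null(net, config.null_kind, config.forbidden_type)
    result = best_partition(net, null, restarts=config.restarts, seed=config.seed)
    part = result.partition
    pd.DataFrame(
        [{"id": i, "module": part.assignment[i]} for i in net.node_ids]
    ).to_csv(out / "partition.csv", index=False)
    _module_table(net, part).to_csv(out / "modules_table.csv", index=False)

    # layout
    layout = fruchterman_reingold(
        net, LayoutConfig(iterations=config.layout_iterations, seed=config.seed)
    )
    pd.DataFrame(
        [
            {"id": i, "x": round(x, 6), "y": round(y, 6)}
            for i, (x, y) in sorted(layout.coordinates.items())
        ]
    ).to_csv(out / "layout.csv", index=False)
    if config.figure:
        _draw(net, layout, part, out / "layout.png")

    reference = _reference(config, net)
    census = net.type_census()
    muscle_deg = degree_census(net, NodeType.MUSCLE)
    summary = {
        "n": net.n,
        "m": net.m,
        "bones": census.get("bone", 0),
        "muscles": census.get("muscle", 0),
        "connective_knots": census.get("connective_knot", 0),
        "muscle_degree2": muscle_deg.get(2, 0),
        "within_muscle_edges": [list(e) for e in find_within_type_edges(net, NodeType.MUSCLE)],
        "betweenness_threshold": config.betweenness_threshold,
        "betweenness_above_threshold": count_above_threshold(
            table, config.betweenness_threshold
        ),
        "null_kind": config.null_kind,
        "q": round(result.q, 6),
        "q_rounded": _round_half_up(result.q, 2),
        "modules": part.n_modules,
        "module_sizes": {lab: len(part.members(lab)) for lab in part.labels},
        "restarts": config.restarts,
        "seed": config.seed,
    }
    if reference is not None:
        comp = compare_partitions(part, reference)
        summary["reference_ari"] = round(comp.ari, 6)
        summary["reference_vi"] = round(comp.vi, 6)
        summary["reference_q"] = round(compute_q(net, reference, null), 6)
    try:
        summary["layout_separation_score"] = round(
            layout_separation_score(net, layout, part), 6
        )
    except ValueError:
        summary["layout_separation_score"] = None

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
    return summary


def _round_half_up(x: float, ndigits: int) -> float:
    """Round-half-up (0.485 -> 0.49), matching printed-table conventions."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


_TYPE_MARKERS = {"bone": "s", "muscle": "o", "connective_knot": "^"}


def _draw(
    net: AnatomicalNetwork,
    layout: LayoutResult,
    partition: Partition,
    path: Path,
) -> None:
    """Layout figure: node colour = module, marker shape = node type."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 8))
    for u, v in net.edges():
        xu, yu = layout.coordinates[u]
        xv, yv = layout.coordinates[v]
        ax.plot([xu, xv], [yu, yv], color="0.8", lw=0.8, zorder=1)
    cmap = plt.get_cmap("tab10")
    colors = {lab: cmap(i % 10) for i, lab in enumerate(partition.labels)}
    for i in net.node_ids:
        x, y = layout.coordinates[i]
        ax.scatter(
            x, y,
            c=[colors[partition.assignment[i]]],
            marker=_TYPE_MARKERS[net.type_of(i).value],
            s=60, zorder=2, edgecolors="k", linewidths=0.4,
        )
        ax.annotate(str(i), (x, y), fontsize=6, ha="center", va="center", zorder=3)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
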