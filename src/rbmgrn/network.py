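"""Assembly and comparison of directed weighted gene regulatory networks.

Candidate pairs surviving RBM training are filtered by the acceptance
threshold theta on the absolute difference of their two strength values,
oriented with the Gaussian naive-Bayes rule on raw expression, and
assembled into a directed graph whose edge weight is the regulator-side
strength.  Networks from two conditions (e.g. normal vs diseased) are
compared by partitioning their unordered gene pairs into shared and
condition-specific classes.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .direction import decide_direction
from .expression import ExpressionMatrix
from .paired_rbm import PairResult

__all__ = [
    "InteractionCandidate",
    "Edge",
    "RegulatoryNetwork",
    "NetworkComparison",
    "filter_interactions",
    "build_network",
    "compare_networks",
    "edges_vs_threshold",
    "export_network",
    "read_edge_list",
    "candidates_from_results",
]

#: theta range exercised in practice; purely conventional, not enforced.
THETA_RANGE = (0.004, 0.016)
DEFAULT_THETA = 0.006


@dataclass(frozen=True)
class InteractionCandidate:
    """Unordered gene pair with its two RBM strength values."""

    gene_a: str
    gene_b: str
    strength_a: float
    strength_b: float
    converged: bool = True

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-pair not allowed: {self.gene_a}")

    @property
    def strength_gap(self) -> float:
        return abs(self.strength_a - self.strength_b)

    @property
    def key(self) -> tuple[str, str]:
        return tuple(sorted((self.gene_a, self.gene_b)))  # type: ignore[return-value]


@dataclass(frozen=True)
class Edge:
    """One oriented interaction regulator -> target with its strength."""

    regulator: str
    target: str
    strength: float
    tie: bool = False


@dataclass
class RegulatoryNetwork:
    """Directed weighted network of accepted, oriented interactions."""

    nodes: list[str]
    edges: list[Edge]
    condition_label: str = ""
    theta: float = DEFAULT_THETA

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for e in self.edges:
            if e.regulator == e.target:
                raise ValueError(f"self-loop on {e.regulator}")
            key = tuple(sorted((e.regulator, e.target)))
            if key in seen:
                raise ValueError(f"duplicate edge over pair {key}")
            seen.add(key)

    @property
    def edge_pairs(self) -> set[tuple[str, str]]:
        """Unordered gene pairs covered by an edge."""
        return {tuple(sorted((e.regulator, e.target))) for e in self.edges}

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph(condition=self.condition_label, theta=self.theta)
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.regulator, e.target, strength=e.strength, tie=e.tie)
        return g


@dataclass(frozen=True)
class NetworkComparison:
    """Partition of the union of unordered edge pairs of two networks."""

    only_in_x: frozenset[tuple[str, str]]
    only_in_y: frozenset[tuple[str, str]]
    shared_same_direction: frozenset[tuple[str, str]]
    shared_reversed_direction: frozenset[tuple[str, str]]
    label_x: str = "x"
    label_y: str = "y"

    @property
    def counts(self) -> dict[str, int]:
        return {
            "only_in_x": len(self.only_in_x),
            "only_in_y": len(self.only_in_y),
            "shared_same_direction": len(self.shared_same_direction),
            "shared_reversed_direction": len(self.shared_reversed_direction),
        }

    def to_json(self) -> str:
        payload = {
            "label_x": self.label_x,
            "label_y": self.label_y,
            "counts": self.counts,
            "only_in_x": sorted(map(list, self.only_in_x)),
            "only_in_y": sorted(map(list, self.only_in_y)),
            "shared_same_direction": sorted(map(list, self.shared_same_direction)),
            "shared_reversed_direction": sorted(map(list, self.shared_reversed_direction)),
        }
        return json.dumps(payload, indent=2)


def candidates_from_results(results: Iterable[PairResult]) -> list[InteractionCandidate]:
    """Turn trained pair results into filter candidates.

    Pairs whose strengths are undefined (no matched hidden unit) carry no
    usable strength values and are skipped.
    """
    out = []
    for r in results:
        if not r.strengths_defined:
            continue
        out.append(
            InteractionCandidate(
                gene_a=r.gene_a,
                gene_b=r.gene_b,
                strength_a=r.strength_a,
                strength_b=r.strength_b,
                converged=r.converged,
            )
        )
    return out


def filter_interactions(
    candidates: Iterable[InteractionCandidate], theta: float
) -> list[InteractionCandidate]:
    """Keep converged candidates whose strength gap is within theta (inclusive).

    A pair is a valid interaction when its two strength values agree to
    within theta; the comparison is <= so a pair sitting exactly at the
    threshold is retained.
    """
    if theta <= 0:
        raise ValueError("theta must be > 0")
    return [c for c in candidates if c.converged and c.strength_gap <= theta]


def build_network(
    candidates: Sequence[InteractionCandidate],
    expressions: ExpressionMatrix,
    condition_label: str = "",
    theta: float = DEFAULT_THETA,
) -> RegulatoryNetwork:
    """Orient filtered candidates and assemble the directed network.

    Direction is decided on the RAW (pre-normalization) expression rows;
    the edge carries the strength value belonging to the regulator's side
    of the pair.  Every candidate yields exactly one edge.
    """
    edges: list[Edge] = []
    for cand in candidates:
        for gene in (cand.gene_a, cand.gene_b):
            if gene not in expressions.data.index:
                raise ValueError(f"gene {gene!r} missing from expression matrix")
        decision = decide_direction(
            cand.gene_a,
            expressions.row(cand.gene_a),
            cand.gene_b,
            expressions.row(cand.gene_b),
        )
        strength = (
            cand.strength_a if decision.regulator == cand.gene_a else cand.strength_b
        )
        edges.append(
            Edge(
                regulator=decision.regulator,
                target=decision.target,
                strength=strength,
                tie=decision.tie,
            )
        )
    return RegulatoryNetwork(
        nodes=list(expressions.gene_ids),
        edges=edges,
        condition_label=condition_label,
        theta=theta,
    )


def compare_networks(
    net_x: RegulatoryNetwork, net_y: RegulatoryNetwork
) -> NetworkComparison:
    """Partition unordered pairs of both networks into four disjoint classes:
    present only in x, only in y, shared with the same orientation, shared
    with reversed orientation."""
    dir_x = {tuple(sorted((e.regulator, e.target))): (e.regulator, e.target) for e in net_x.edges}
    dir_y = {tuple(sorted((e.regulator, e.target))): (e.regulator, e.target) for e in net_y.edges}
    pairs_x, pairs_y = set(dir_x), set(dir_y)
    shared = pairs_x & pairs_y
    same = {p for p in shared if dir_x[p] == dir_y[p]}
    return NetworkComparison(
        only_in_x=frozenset(pairs_x - pairs_y),
        only_in_y=frozenset(pairs_y - pairs_x),
        shared_same_direction=frozenset(same),
        shared_reversed_direction=frozenset(shared - same),
        label_x=net_x.condition_label or "x",
        label_y=net_y.condition_label or "y",
    )


def edges_vs_threshold(
    candidates: Sequence[InteractionCandidate], thetas: Sequence[float]
) -> list[tuple[float, int]]:
    """Accepted-edge count at each theta; counts are non-decreasing in theta."""
    thetas = list(thetas)
    if any(b <= a for a, b in zip(thetas, thetas[1:])):
        raise ValueError("thetas must be strictly ascending")
    return [(t, len(filter_interactions(candidates, t))) for t in thetas]


_EDGE_COLUMNS = ["regulator", "target", "strength", "tie", "theta", "condition"]


def export_network(
    net: RegulatoryNetwork, path: str | Path, format: str = "tsv"
) -> Path:
    """Write the network as edge-list TSV, GraphML, or DOT."""
    path = Path(path)
    if format == "tsv":
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(_EDGE_COLUMNS)
            for e in net.edges:
                writer.writerow(
                    [e.regulator, e.target, repr(e.strength), e.tie, net.theta,
                     net.condition_label]
                )
    elif format == "graphml":
        nx.write_graphml(net.to_networkx(), path)
    elif format == "dot":
        lines = [f'digraph "{net.condition_label or "grn"}" {{']
        for node in net.nodes:
            lines.append(f'  "{node}";')
        for e in net.edges:
            lines.append(
                f'  "{e.regulator}" -> "{e.target}" [label="{e.strength:.4g}", '
                f'weight={e.strength:.6f}];'
            )
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}; use tsv, graphml or dot")
    return path


def read_edge_list(path: str | Path) -> RegulatoryNetwork:
    """Read back a TSV written by :func:`export_network`."""
    path = Path(path)
    edges: list[Edge] = []
    theta = DEFAULT_THETA
    condition = ""
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != _EDGE_COLUMNS:
            raise ValueError(f"{path}: unexpected columns {reader.fieldnames}")
        for row in reader:
            edges.append(
                Edge(
                    regulator=row["regulator"],
                    target=row["target"],
                    strength=float(row["strength"]),
                    tie=row["tie"] == "True",
                )
            )
            theta = float(row["theta"])
            condition = row["condition"]
    nodes = sorted({n for e in edges for n in (e.regulator, e.target)})
    return RegulatoryNetwork(
        nodes=nodes, edges=edges, condition_label=condition, theta=theta
    )
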