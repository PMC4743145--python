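"""Substitution-site subsets, complete/reduced SAR graphs, R-group trees.

A compound's *site combination* is the exact set of substitution sites at
which it carries a non-H substituent; combinations partition a series into
disjoint subsets. The complete graph is the layered directed acyclic graph
over all 2^n combinations (layer k = combinations of k sites, edges between
adjacent layers wherever one combination is a subset of the other); the
reduced graph is its induced subgraph on non-empty nodes. R-group trees
resolve one subset down to individual analogs, with stereoisomer groups
marked by incremental indices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import networkx as nx

from analogsar.mcs import RGroupAssignment
from analogsar.series import AnalogSeries

logger = logging.getLogger(__name__)

COMPLETE_GRAPH_CEILING = 12  # 4096 nodes; larger series get reduced graphs only


@dataclass(frozen=True)
class SiteCombination:
    """A sorted set of substitution sites with its text label.

    The label concatenates the site numbers ("0" for the empty combination,
    "1345" for {1,3,4,5}); sites are dot-separated as soon as any site
    number has two digits, keeping the encoding bijective.
    """

    sites: frozenset[int]

    @property
    def label(self) -> str:
        if not self.sites:
            return "0"
        parts = [str(s) for s in sorted(self.sites)]
        if max(self.sites) < 10:
            return "".join(parts)
        label = ".".join(parts)
        if "." not in label:  # single two-digit site: keep a dot so parsing stays unambiguous
            label += "."
        return label

    @property
    def layer(self) -> int:
        return len(self.sites)

    @classmethod
    def from_sites(cls, sites) -> "SiteCombination":
        return cls(frozenset(int(s) for s in sites))

    @classmethod
    def from_label(cls, label: str) -> "SiteCombination":
        if label == "0":
            return cls(frozenset())
        if "." in label:
            return cls(frozenset(int(p) for p in label.split(".") if p))
        return cls(frozenset(int(c) for c in label))

    def sort_key(self):
        return (self.layer, tuple(sorted(self.sites)))


@dataclass
class SubsetPartition:
    """Disjoint, covering split of a series by exact site combination."""

    series_id: str
    subsets: dict[SiteCombination, list[str]]

    @property
    def n_compounds(self) -> int:
        return sum(len(v) for v in self.subsets.values())

    def combination_of(self, compound_id: str) -> SiteCombination:
        for combo, cids in self.subsets.items():
            if compound_id in cids:
                return combo
        raise KeyError(compound_id)


@dataclass
class SarGraph:
    """Layered DAG over site combinations with per-node SAR statistics."""

    kind: str  # "complete" | "reduced"
    n_sites: int
    target: str
    g: nx.DiGraph

    def to_networkx(self) -> nx.DiGraph:
        return self.g

    @property
    def n_nodes(self) -> int:
        return self.g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.g.number_of_edges()

    def node(self, label: str) -> dict:
        return self.g.nodes[label]


@dataclass
class RGroupTree:
    """Per-subset tree splitting analogs substituent by substituent."""

    combination: SiteCombination
    layer_order: list[int]
    g: nx.DiGraph
    stereo_indices: dict[str, int] = field(default_factory=dict)

    def to_networkx(self) -> nx.DiGraph:
        return self.g

    def leaves(self) -> list[str]:
        """Leaf node ids in left-to-right (sibling-order) traversal."""
        out: list[str] = []

        def walk(n):
            kids = sorted(self.g.successors(n), key=lambda c: self.g.nodes[c]["order"])
            if not kids and self.g.nodes[n].get("kind") == "leaf":
                out.append(n)
            for c in kids:
                walk(c)

        walk("root")
        return out


# ---------------------------------------------------------------------------
# partition


def partition_series(series: AnalogSeries,
                     rgroup_assignments: Mapping[str, RGroupAssignment]) -> SubsetPartition:
    """Assign every member to the subset of its exact non-H site set.

    A compound identical to the core maps to the root combination "0".
    Raises if any member lacks an R-group assignment.
    """
    subsets: dict[SiteCombination, list[str]] = {}
    for cid in sorted(series.members):
        if cid not in rgroup_assignments:
            raise ValueError(f"series {series.series_id}: member {cid} has no R-group assignment")
        a = rgroup_assignments[cid]
        combo = SiteCombination.from_sites(s for s, g in a.groups.items() if g != "H")
        subsets.setdefault(combo, []).append(cid)
    return SubsetPartition(series_id=series.series_id, subsets=subsets)


# ---------------------------------------------------------------------------
# node statistics


def node_statistics(compound_ids: Sequence[str],
                    potencies: Mapping[str, Mapping[str, float]],
                    target: str) -> tuple[int, float | None, float | None]:
    """(count, mean potency, potency range) of a node's compounds.

    Potency range is max - min in log units (orders of magnitude); both
    statistics are undefined (None) for an empty node.
    """
    values = [potencies[cid][target] for cid in compound_ids]
    if not values:
        return 0, None, None
    return len(values), sum(values) / len(values), max(values) - min(values)


def _node_attrs(combo: SiteCombination, cids: Sequence[str],
                potencies, target) -> dict:
    count, mean, rng = node_statistics(cids, potencies, target)
    return dict(
        label=combo.label,
        sites=tuple(sorted(combo.sites)),
        layer=combo.layer,
        count=count,
        mean_potency=None if mean is None else round(mean, 6),
        potency_range=None if rng is None else round(rng, 6),
        empty=count == 0,
        compounds=tuple(cids),
    )


# ---------------------------------------------------------------------------
# complete / reduced graphs


def build_complete_graph(partition: SubsetPartition, n_sites: int,
                         potencies: Mapping[str, Mapping[str, float]],
                         target: str, *,
                         ceiling: int = COMPLETE_GRAPH_CEILING) -> SarGraph:
    """Build the complete graph over all 2^n_sites site combinations.

    Layer k holds C(n_sites, k) nodes; an edge joins every adjacent-layer
    subset pair. Above ``ceiling`` sites the complete graph is refused
    (build the reduced graph directly instead).
    """
    if n_sites > ceiling:
        raise ValueError(
            f"complete graph with {n_sites} sites exceeds the {ceiling}-site ceiling "
            f"(2^{n_sites} nodes); use build_reduced_graph on occupied combinations")
    occupied = {c.label: cids for c, cids in partition.subsets.items()}
    g = nx.DiGraph(kind="complete", n_sites=n_sites, target=target,
                   series_id=partition.series_id)
    all_combos = []
    for k in range(n_sites + 1):
        for sites in combinations(range(1, n_sites + 1), k):
            all_combos.append(SiteCombination.from_sites(sites))
    for combo in all_combos:
        cids = occupied.get(combo.label, [])
        g.add_node(combo.label, **_node_attrs(combo, cids, potencies, target))
    for combo in all_combos:
        for extra in range(1, n_sites + 1):
            if extra not in combo.sites:
                child = SiteCombination(combo.sites | {extra})
                g.add_edge(combo.label, child.label)
    return SarGraph(kind="complete", n_sites=n_sites, target=target, g=g)


def reduce_graph(complete: SarGraph) -> SarGraph:
    """Remove all empty nodes and their edges (plain induced subgraph).

    No transitive re-wiring happens across removed nodes, so a reduced
    graph may be disconnected. Reduction is idempotent.
    """
    keep = [n for n, d in complete.g.nodes(data=True) if not d.get("empty")]
    g = nx.DiGraph(**{**complete.g.graph, "kind": "reduced"})
    for n in keep:
        g.add_node(n, **complete.g.nodes[n])
    keep_set = set(keep)
    g.add_edges_from((u, v) for u, v in complete.g.edges if u in keep_set and v in keep_set)
    return SarGraph(kind="reduced", n_sites=complete.n_sites, target=complete.target, g=g)


def build_reduced_graph(partition: SubsetPartition, n_sites: int,
                        potencies: Mapping[str, Mapping[str, float]],
                        target: str) -> SarGraph:
    """Reduced graph built directly from the occupied combinations.

    Equivalent to ``reduce_graph(build_complete_graph(...))`` but never
    materializes the 2^n node set, so it also serves series above the
    complete-graph ceiling.
    """
    combos = sorted(partition.subsets, key=lambda c: c.sort_key())
    g = nx.DiGraph(kind="reduced", n_sites=n_sites, target=target,
                   series_id=partition.series_id)
    for combo in combos:
        g.add_node(combo.label, **_node_attrs(combo, partition.subsets[combo], potencies, target))
    for a in combos:
        for b in combos:
            if b.layer == a.layer + 1 and a.sites < b.sites:
                g.add_edge(a.label, b.label)
    return SarGraph(kind="reduced", n_sites=n_sites, target=target, g=g)


# ---------------------------------------------------------------------------
# R-group trees


def build_rgroup_tree(subset: SiteCombination, compound_ids: Sequence[str],
                      rgroup_assignments: Mapping[str, RGroupAssignment],
                      potencies: Mapping[str, Mapping[str, float]],
                      target: str) -> RGroupTree:
    """Build the R-group tree of one subset.

    Sites are arranged in layers ordered by ascending number of distinct
    R-groups (ties by site number), so the most conserved site sits nearest
    the root. Intermediate nodes hold analogs sharing the same substituents
    at the sites resolved so far; each analog is a single leaf, and
    stereoisomers of one constitution sit adjacently under their shared
    constitution node.
    """
    if not compound_ids:
        raise ValueError("cannot build an R-group tree for an empty subset")
    cids = sorted(compound_ids)
    sites = sorted(subset.sites)
    uniq = {s: len({rgroup_assignments[c].groups[s] for c in cids}) for s in sites}
    layer_order = sorted(sites, key=lambda s: (uniq[s], s))

    g = nx.DiGraph(kind="rgroup_tree", subset=subset.label,
                   layer_order=",".join(str(s) for s in layer_order))
    count, mean, rng = node_statistics(cids, potencies, target)
    g.add_node("root", kind="root", label=subset.label, layer=0, order=0,
               count=count, mean_potency=None if mean is None else round(mean, 6),
               compounds=tuple(cids))

    def grow(parent: str, members: list[str], depth: int) -> None:
        if depth == len(layer_order):
            # members share every R-group => one constitution class
            for i, cid in enumerate(sorted(members, key=lambda c: (
                    "".join(rgroup_assignments[c].stereo_signature), c))):
                a = rgroup_assignments[cid]
                g.add_node(f"leaf:{cid}", kind="leaf", label=cid, layer=depth + 1,
                           order=i, compound=cid, count=1,
                           mean_potency=round(potencies[cid][target], 6),
                           constitution=a.constitution,
                           stereo_signature="".join(a.stereo_signature))
                g.add_edge(parent, f"leaf:{cid}")
            return
        site = layer_order[depth]
        by_group: dict[str, list[str]] = {}
        for cid in members:
            by_group.setdefault(rgroup_assignments[cid].groups[site], []).append(cid)
        last = depth == len(layer_order) - 1
        for i, smi in enumerate(sorted(by_group)):
            sub = by_group[smi]
            if last and len(sub) == 1:
                # a unique analog: attach the leaf directly
                cid = sub[0]
                a = rgroup_assignments[cid]
                g.add_node(f"leaf:{cid}", kind="leaf", label=cid, layer=depth + 1,
                           order=i, compound=cid, count=1, site=site, rgroup=smi,
                           mean_potency=round(potencies[cid][target], 6),
                           constitution=a.constitution,
                           stereo_signature="".join(a.stereo_signature))
                g.add_edge(parent, f"leaf:{cid}")
                continue
            nid = f"{parent}/{site}={smi}"
            c, m, _ = node_statistics(sub, potencies, target)
            g.add_node(nid, kind="group", label=smi, site=site, rgroup=smi,
                       layer=depth + 1, order=i, count=c,
                       mean_potency=None if m is None else round(m, 6),
                       compounds=tuple(sorted(sub)))
            g.add_edge(parent, nid)
            grow(nid, sub, depth + 1)

    grow("root", cids, 0)
    return RGroupTree(combination=subset, layer_order=layer_order, g=g)


def assign_stereo_indices(tree: RGroupTree,
                          stereo_signatures: Mapping[str, Sequence[str]] | None = None) -> RGroupTree:
    """Index stereoisomer groups 1, 2, ... in left-to-right tree order.

    A constitution class with >= 2 leaves is a stereoisomer group; all its
    leaves carry the same index, and distinct groups within one tree get
    incremental indices. Singleton leaves carry no index.
    """
    leaves = tree.leaves()
    by_constitution: dict[str, list[str]] = {}
    for n in leaves:
        by_constitution.setdefault(tree.g.nodes[n]["constitution"], []).append(n)
    tree.stereo_indices.clear()
    assigned: dict[str, int] = {}
    for n in leaves:
        const = tree.g.nodes[n]["constitution"]
        if len(by_constitution[const]) < 2:
            continue
        if const not in assigned:
            assigned[const] = len(assigned) + 1
        tree.g.nodes[n]["stereo_index"] = assigned[const]
        tree.stereo_indices[tree.g.nodes[n]["compound"]] = assigned[const]
    return tree


# ---------------------------------------------------------------------------
# selectivity


def build_selectivity_views(series: AnalogSeries, partition: SubsetPartition,
                            potencies: Mapping[str, Mapping[str, float]],
                            target_a: str, target_b: str) -> tuple[SarGraph, SarGraph]:
    """Target-specific reduced graphs over one shared partition.

    Both graphs have identical topology; only node statistics differ. Each
    node additionally carries ``delta_mean`` = mean(target_a) - mean(target_b),
    the per-subset selectivity in log units.
    """
    if target_a == target_b:
        raise ValueError("selectivity analysis needs two distinct targets")
    for combo, cids in partition.subsets.items():
        for cid in cids:
            missing = {target_a, target_b} - set(potencies.get(cid, {}))
            if missing:
                raise ValueError(
                    f"compound {cid} lacks potency for {sorted(missing)}; filter "
                    "members to dual-target compounds before partitioning")
    n_sites = max((max(c.sites) for c in partition.subsets if c.sites), default=0)
    n_sites = max(n_sites, getattr(series.core, "n_sites", 0) or 0)
    ga = build_reduced_graph(partition, n_sites, potencies, target_a)
    gb = build_reduced_graph(partition, n_sites, potencies, target_b)
    for n in ga.g.nodes:
        ma, mb = ga.g.nodes[n]["mean_potency"], gb.g.nodes[n]["mean_potency"]
        delta = None if ma is None or mb is None else round(ma - mb, 6)
        ga.g.nodes[n]["delta_mean"] = delta
        gb.g.nodes[n]["delta_mean"] = delta
    return ga, gb
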