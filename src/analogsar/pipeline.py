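"""End-to-end per-series analysis: core, R-groups, partition, graphs, trees."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from analogsar.chem_io import CompoundRecord
from analogsar.graphs import (
    COMPLETE_GRAPH_CEILING,
    RGroupTree,
    SarGraph,
    SubsetPartition,
    assign_stereo_indices,
    build_complete_graph,
    build_reduced_graph,
    build_rgroup_tree,
    partition_series,
    reduce_graph,
)
from analogsar.mcs import (
    DEFAULT_MCS_TIMEOUT,
    DEFAULT_MIN_COVERAGE,
    AtomMapping,
    CoreStructure,
    RGroupAssignment,
    compute_mcs,
    decompose_rgroups,
    map_to_core,
    records_by_id,
)
from analogsar.series import AnalogSeries

logger = logging.getLogger(__name__)


@dataclass
class SeriesAnalysis:
    """Everything derived from one analog series."""

    series: AnalogSeries
    core: CoreStructure
    mappings: dict[str, AtomMapping]
    assignments: dict[str, RGroupAssignment]
    partition: SubsetPartition
    complete: SarGraph | None
    reduced: SarGraph
    trees: dict[str, RGroupTree]        # keyed by subset label
    stereo_indices: dict[str, int]      # compound -> per-tree stereo group index
    target: str
    potencies: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def n_stereo_groups(self) -> int:
        return sum(len(set(t.stereo_indices.values())) for t in self.trees.values())

    def summary(self) -> str:
        return (f"series {self.series.series_id}: {len(self.series.members)} members, "
                f"{self.core.n_sites} sites, {len(self.partition.subsets)} subsets, "
                f"{self.n_stereo_groups} stereo groups"
                + (" [low-coverage MCS]" if self.core.low_coverage else "")
                + (" [scaffold fallback]" if self.core.scaffold_fallback else ""))


def analyze_series(series: AnalogSeries, records: Sequence[CompoundRecord] | Mapping[str, CompoundRecord],
                   *, target: str | None = None,
                   min_coverage: float = DEFAULT_MIN_COVERAGE,
                   mcs_timeout: int = DEFAULT_MCS_TIMEOUT,
                   complete_ceiling: int = COMPLETE_GRAPH_CEILING) -> SeriesAnalysis:
    """Run the full analysis for one series.

    Computes the MCS core, maps and decomposes every member, partitions the
    series by site combination, and builds the complete graph (when the
    site count permits), the reduced graph, and one stereo-indexed R-group
    tree per non-empty subset.
    """
    recmap = records if isinstance(records, Mapping) else records_by_id(records)
    if target is None:
        targets = sorted({t for cid in series.members for t in recmap[cid].potencies})
        if not targets:
            raise ValueError(f"series {series.series_id}: no potency values available")
        target = targets[0]
    missing = [cid for cid in series.members if target not in recmap[cid].potencies]
    if missing:
        raise ValueError(f"series {series.series_id}: members lacking {target!r}: {missing}")

    core = compute_mcs(series, recmap, min_coverage=min_coverage, timeout=mcs_timeout)
    mappings = {cid: map_to_core(recmap[cid], core) for cid in sorted(series.members)}
    assignments = {cid: decompose_rgroups(recmap[cid], core, m) for cid, m in mappings.items()}
    partition = partition_series(series, assignments)
    potencies = {cid: recmap[cid].potencies for cid in series.members}

    complete = None
    if core.n_sites <= complete_ceiling:
        complete = build_complete_graph(partition, core.n_sites, potencies, target,
                                        ceiling=complete_ceiling)
        reduced = reduce_graph(complete)
    else:
        logger.warning("series %s: %d sites exceed the complete-graph ceiling (%d); "
                       "building the reduced graph directly",
                       series.series_id, core.n_sites, complete_ceiling)
        reduced = build_reduced_graph(partition, core.n_sites, potencies, target)

    trees: dict[str, RGroupTree] = {}
    stereo_indices: dict[str, int] = {}
    for combo in sorted(partition.subsets, key=lambda c: c.sort_key()):
        tree = build_rgroup_tree(combo, partition.subsets[combo], assignments, potencies, target)
        assign_stereo_indices(tree)
        trees[combo.label] = tree
        stereo_indices.update(tree.stereo_indices)

    analysis = SeriesAnalysis(
        series=series, core=core, mappings=mappings, assignments=assignments,
        partition=partition, complete=complete, reduced=reduced, trees=trees,
        stereo_indices=stereo_indices, target=target, potencies=potencies,
    )
    logger.info(analysis.summary())
    return analysis
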