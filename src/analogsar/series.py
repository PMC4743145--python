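"""Analog-series identification by hierarchical molecular scaffolds.

Compounds are grouped by their Bemis-Murcko framework (ring systems plus
linker atoms, side chains removed) or, one level up the hierarchy, by the
generic carbon skeleton in which every atom is carbon and every bond is a
single bond. Compounds sharing a scaffold at the chosen level form one
analog series; acyclic compounds have no scaffold and stay unassigned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from analogsar.chem_io import CompoundRecord

logger = logging.getLogger(__name__)

ScaffoldLevel = Literal["framework", "generic_skeleton"]


@dataclass(frozen=True)
class Scaffold:
    """A hierarchical molecular scaffold at a fixed level.

    ``framework`` is the Bemis-Murcko framework; ``generic_skeleton``
    additionally replaces every atom by carbon and every bond by a single
    bond, so it only retains ring/linker topology.
    """

    smiles: str
    level: ScaffoldLevel


@dataclass
class AnalogSeries:
    """A scaffold-defined group of compounds; the MCS core is filled later."""

    series_id: str
    scaffold: Scaffold | None
    members: list[str]
    core: object | None = None  # CoreStructure, set by mcs.compute_mcs


def extract_scaffold(compound: CompoundRecord | Chem.Mol, level: ScaffoldLevel = "framework") -> Scaffold | None:
    """Extract the scaffold of one compound, or None for acyclic molecules.

    The framework keeps all ring atoms, the linker atoms between rings, and
    atoms double-bonded to those; stereochemistry is discarded. Scaffold
    extraction is idempotent: the scaffold of a scaffold is itself.
    """
    mol = compound.mol if isinstance(compound, CompoundRecord) else compound
    if mol.GetRingInfo().NumRings() == 0:
        return None
    frame = MurckoScaffold.GetScaffoldForMol(mol)
    if frame.GetNumAtoms() == 0:
        return None
    if level == "generic_skeleton":
        frame = MurckoScaffold.MakeScaffoldGeneric(frame)
    elif level != "framework":
        raise ValueError(f"unknown scaffold level {level!r}")
    Chem.RemoveStereochemistry(frame)
    return Scaffold(smiles=Chem.MolToSmiles(frame), level=level)


def group_into_series(compounds: Sequence[CompoundRecord], level: ScaffoldLevel = "framework",
                      min_series_size: int = 2) -> list[AnalogSeries]:
    """Partition scaffold-bearing compounds into analog series.

    Groups smaller than ``min_series_size`` are left unassigned (logged, not
    returned). Series ids are assigned deterministically: sorted by member
    count descending, then by scaffold SMILES, so neither compound order in
    the input nor atom order within records affects the result.
    """
    by_scaffold: dict[Scaffold, list[str]] = {}
    for rec in compounds:
        sc = extract_scaffold(rec, level)
        if sc is None:
            logger.info("compound %s is acyclic (no scaffold), unassigned", rec.compound_id)
            continue
        by_scaffold.setdefault(sc, []).append(rec.compound_id)
    groups = [(sc, sorted(cids)) for sc, cids in by_scaffold.items()]
    kept = [g for g in groups if len(g[1]) >= min_series_size]
    for sc, cids in groups:
        if len(cids) < min_series_size:
            logger.info("scaffold %s group of %d below min_series_size=%d, unassigned: %s",
                        sc.smiles, len(cids), min_series_size, cids)
    kept.sort(key=lambda g: (-len(g[1]), g[0].smiles))
    return [
        AnalogSeries(series_id=f"S{i + 1}", scaffold=sc, members=cids)
        for i, (sc, cids) in enumerate(kept)
    ]


def unassigned_compounds(compounds: Sequence[CompoundRecord], series: Iterable[AnalogSeries]) -> list[str]:
    """Compound ids not covered by any series (acyclic or sub-threshold)."""
    assigned = {cid for s in series for cid in s.members}
    return [r.compound_id for r in compounds if r.compound_id not in assigned]
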