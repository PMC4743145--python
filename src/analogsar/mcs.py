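"""Series MCS, symmetry-consistent core mapping, R-group decomposition, stereo.

The maximum common substructure of a series is computed as a *connected*
substructure under strict matching: atoms match by element, bonds by exact
bond order, and ring bonds only match ring bonds. Every member is then
mapped onto the core by a canonical choice among all symmetry-equivalent
substructure embeddings, so that, e.g., all mono-substituted analogs of a
symmetric core land on the same substitution site. Substitution sites are
numbered 1..n by the canonical atom ranking of the core, which makes site
indices independent of input atom and record order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from rdkit import Chem
from rdkit.Chem import rdCIPLabeler, rdFMCS

from analogsar.chem_io import CompoundRecord
from analogsar.series import AnalogSeries, extract_scaffold

logger = logging.getLogger(__name__)

DEFAULT_MIN_COVERAGE = 2.0 / 3.0
DEFAULT_MCS_TIMEOUT = 60  # seconds per series


@dataclass
class CoreStructure:
    """The shared core of a series with indexed substitution sites.

    ``query`` is the substructure query whose atom indices define core atom
    numbering; ``site_index`` maps the core atoms that carry a non-H
    substituent in at least one member to site numbers 1..n_sites.
    """

    query: Chem.Mol
    smiles: str
    ranks: tuple[int, ...]              # canonical rank per core atom
    site_index: dict[int, int] = field(default_factory=dict)
    n_sites: int = 0
    low_coverage: bool = False
    scaffold_fallback: bool = False

    @property
    def n_atoms(self) -> int:
        return self.query.GetNumAtoms()

    @property
    def n_bonds(self) -> int:
        return self.query.GetNumBonds()

    def site_atoms(self) -> dict[int, int]:
        """site number -> core atom index."""
        return {s: a for a, s in self.site_index.items()}


@dataclass
class AtomMapping:
    """Canonical injective map core atom -> compound atom."""

    compound_id: str
    core_to_compound: dict[int, int]


@dataclass
class RGroupAssignment:
    """Per-compound R-groups: site number -> substituent SMILES or ``"H"``.

    Substituent SMILES carry a single ``*`` attachment marker; a fragment
    bridging two core atoms is reported at the lower-numbered site with two
    markers and flagged in ``multi_attachment``. ``constitution`` is the
    stereo-free canonical SMILES used to detect stereoisomer groups.
    """

    compound_id: str
    groups: dict[int, str]
    stereo_signature: tuple[str, ...]
    constitution: str
    multi_attachment: frozenset[int] = frozenset()


def records_by_id(records: Sequence[CompoundRecord]) -> dict[str, CompoundRecord]:
    return {r.compound_id: r for r in records}


# ---------------------------------------------------------------------------
# MCS


def _canonical_mol(mol: Chem.Mol) -> Chem.Mol:
    """Renumber atoms canonically so results never depend on input order."""
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=True, includeChirality=True))
    order = [i for i, _ in sorted(enumerate(ranks), key=lambda t: t[1])]
    return Chem.RenumberAtoms(mol, order)


def _mcs_params(timeout: int) -> dict:
    return dict(
        maximizeBonds=False,  # maximal in atoms first, bonds second
        atomCompare=rdFMCS.AtomCompare.CompareElements,
        bondCompare=rdFMCS.BondCompare.CompareOrderExact,
        ringMatchesRingOnly=True,
        completeRingsOnly=False,
        timeout=timeout,
    )


def _core_from_query(query: Chem.Mol, ref: Chem.Mol) -> tuple[str, tuple[int, ...]]:
    """Canonical SMILES and per-query-atom canonical ranks of the core.

    The core is realized in a canonically renumbered reference member, then
    ranked with RDKit's fragment canonical ranking, so ranks depend only on
    the core's structure, not on how any input file ordered its atoms.
    """
    match = ref.GetSubstructMatch(query)
    if not match:
        raise RuntimeError("MCS query does not match its own reference molecule")
    atom_set = set(match)
    bond_ids = []
    for qb in query.GetBonds():
        rb = ref.GetBondBetweenAtoms(match[qb.GetBeginAtomIdx()], match[qb.GetEndAtomIdx()])
        if rb is None:
            raise RuntimeError("MCS query bond missing in reference molecule")
        bond_ids.append(rb.GetIdx())
    if bond_ids:
        smiles = Chem.MolFragmentToSmiles(ref, atomsToUse=sorted(atom_set), bondsToUse=bond_ids, canonical=True)
        frag_ranks = list(Chem.CanonicalRankAtomsInFragment(
            ref, atomsToUse=sorted(atom_set), bondsToUse=bond_ids, breakTies=True))
    else:
        smiles = Chem.MolFragmentToSmiles(ref, atomsToUse=sorted(atom_set), bondsToUse=[], canonical=True)
        frag_ranks = list(Chem.CanonicalRankAtomsInFragment(
            ref, atomsToUse=sorted(atom_set), bondsToUse=[], breakTies=True))
    raw = [frag_ranks[match[q]] for q in range(query.GetNumAtoms())]
    # compress to 0..n-1 preserving order
    order = sorted(range(len(raw)), key=lambda q: raw[q])
    ranks = [0] * len(raw)
    for r, q in enumerate(order):
        ranks[q] = r
    return smiles, tuple(ranks)


def compute_mcs(series: AnalogSeries, records: Mapping[str, CompoundRecord], *,
                min_coverage: float = DEFAULT_MIN_COVERAGE,
                timeout: int = DEFAULT_MCS_TIMEOUT) -> CoreStructure:
    """Compute the connected MCS over all series members and index its sites.

    The result is maximal in atoms, then bonds. If the search hits the
    timeout, the series scaffold is used as the core instead and the result
    is flagged ``scaffold_fallback``. A core covering less than
    ``min_coverage`` of the mean heavy-atom count is flagged
    ``low_coverage`` (warning) but still processed.

    Also fills ``series.core`` and returns the core with substitution sites
    indexed from the canonical member mappings.
    """
    if len(series.members) < 2:
        raise ValueError(f"series {series.series_id} needs >= 2 members for an MCS")
    member_ids = sorted(series.members)
    mols = [_canonical_mol(records[cid].mol) for cid in member_ids]
    result = rdFMCS.FindMCS(mols, **_mcs_params(timeout))
    fallback = False
    if result.canceled or result.numAtoms == 0:
        logger.warning("series %s: MCS search timed out, falling back to scaffold core",
                       series.series_id)
        fallback = True
        sc = series.scaffold or extract_scaffold(records[member_ids[0]], "framework")
        query = Chem.MolFromSmiles(sc.smiles)
    else:
        query = result.queryMol if result.queryMol is not None else Chem.MolFromSmarts(result.smartsString)
    smiles, ranks = _core_from_query(query, mols[0])
    core = CoreStructure(query=query, smiles=smiles, ranks=ranks, scaffold_fallback=fallback)

    mean_heavy = sum(m.GetNumHeavyAtoms() for m in mols) / len(mols)
    if core.n_atoms < min_coverage * mean_heavy:
        core.low_coverage = True
        logger.warning("series %s: MCS of %d atoms covers < %.0f%% of mean size %.1f",
                       series.series_id, core.n_atoms, 100 * min_coverage, mean_heavy)

    # containment of the series scaffold is preferred but not forced
    if series.scaffold is not None and not fallback:
        sc_mol = Chem.MolFromSmiles(series.scaffold.smiles)
        core_mol = Chem.MolFromSmiles(smiles, sanitize=False)
        if sc_mol is not None and core_mol is not None and \
                not core_mol.HasSubstructMatch(sc_mol):
            logger.info("series %s: core does not contain the series scaffold",
                        series.series_id)

    mappings = [_canonical_match(records[cid], core) for cid in member_ids]
    index_substitution_sites(core, mappings, records)
    series.core = core
    return core


# ---------------------------------------------------------------------------
# canonical mapping


def _compound_ranks(mol: Chem.Mol) -> list[int]:
    # constitution-level ranks: stereoisomers get identical tie-break keys
    return list(Chem.CanonicalRankAtoms(mol, breakTies=True, includeChirality=False))


def _attachment_components(mol: Chem.Mol, match: Sequence[int]) -> list[tuple[list[int], list[int]]]:
    """Connected non-core components and the core *query* atoms they touch.

    Returns a list of (component atom indices, attached query atom indices);
    only heavy atoms count.
    """
    in_core = {a: q for q, a in enumerate(match)}
    outside = [a.GetIdx() for a in mol.GetAtoms() if a.GetIdx() not in in_core]
    seen: set[int] = set()
    comps: list[tuple[list[int], list[int]]] = []
    for start in outside:
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            a = stack.pop()
            comp.append(a)
            for nb in mol.GetAtomWithIdx(a).GetNeighbors():
                ni = nb.GetIdx()
                if ni not in in_core and ni not in seen:
                    seen.add(ni)
                    stack.append(ni)
        attach = sorted({
            in_core[nb.GetIdx()]
            for a in comp
            for nb in mol.GetAtomWithIdx(a).GetNeighbors()
            if nb.GetIdx() in in_core
        })
        comps.append((sorted(comp), attach))
    return comps


def _fragment_smiles(mol: Chem.Mol, comp: Sequence[int], attach_atoms: Sequence[int]) -> str:
    """Substituent fragment as canonical SMILES with ``*`` attachment marker(s)."""
    em = Chem.RWMol()
    idx_map: dict[int, int] = {}
    for a in comp:
        atom = mol.GetAtomWithIdx(a)
        na = Chem.Atom(atom.GetAtomicNum())
        na.SetFormalCharge(atom.GetFormalCharge())
        na.SetIsAromatic(atom.GetIsAromatic())
        na.SetNumExplicitHs(atom.GetTotalNumHs())
        na.SetNoImplicit(True)
        idx_map[a] = em.AddAtom(na)
    comp_set = set(comp)
    for a in comp:
        for b in mol.GetAtomWithIdx(a).GetBonds():
            o = b.GetOtherAtomIdx(a)
            if o in comp_set and o > a:
                em.AddBond(idx_map[a], idx_map[o], b.GetBondType())
    # one dummy per attachment bond into the core
    for a in comp:
        for b in mol.GetAtomWithIdx(a).GetBonds():
            o = b.GetOtherAtomIdx(a)
            if o in attach_atoms:
                d = em.AddAtom(Chem.Atom(0))
                em.AddBond(idx_map[a], d, b.GetBondType())
    frag = em.GetMol()
    try:
        Chem.SanitizeMol(frag, Chem.SanitizeFlags.SANITIZE_ALL ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE)
    except Exception:
        pass
    return Chem.MolToSmiles(frag)


def _match_key(mol: Chem.Mol, match: Sequence[int], core: CoreStructure,
               comp_ranks: Sequence[int]):
    """Tie-break key for one embedding: (occupied core ranks,
    substituent SMILES by rank, mapped canonical-rank sequence)."""
    comps = _attachment_components(mol, match)
    by_rank: dict[int, str] = {}
    occupied: list[int] = []
    atom_set = {match[q] for q in range(len(match))}
    for comp, attach_qs in comps:
        attach_atoms = [match[q] for q in attach_qs]
        smi = _fragment_smiles(mol, comp, set(attach_atoms))
        lead = min(core.ranks[q] for q in attach_qs)
        occupied.append(lead)
        by_rank[lead] = min(smi, by_rank.get(lead, smi))
    occupied_sorted = sorted(occupied)
    frag_list = [by_rank[r] for r in sorted(by_rank)]
    rank_seq = tuple(comp_ranks[a] for a in match)
    return (occupied_sorted, frag_list, rank_seq)


def _canonical_match(record: CompoundRecord, core: CoreStructure) -> AtomMapping:
    """Choose the canonical embedding among all symmetry-equivalent matches."""
    mol = record.mol
    matches = mol.GetSubstructMatches(core.query, uniquify=False, maxMatches=100000)
    if not matches:
        raise ValueError(f"core is not a substructure of compound {record.compound_id}")
    comp_ranks = _compound_ranks(mol)
    best = min(matches, key=lambda m: _match_key(mol, m, core, comp_ranks))
    return AtomMapping(compound_id=record.compound_id,
                       core_to_compound={q: a for q, a in enumerate(best)})


def map_to_core(compound: CompoundRecord, core: CoreStructure) -> AtomMapping:
    """Map a compound onto the core, resolving intramolecular symmetry.

    Among all substructure embeddings (core automorphisms x embedding
    choices) the canonical one minimizes, in order: the sorted occupied
    site ranks, the per-site substituent SMILES, and the mapped atoms'
    constitution-level canonical ranks. Stereoisomers therefore receive
    identical mappings at the constitution level.
    """
    return _canonical_match(compound, core)


def index_substitution_sites(core: CoreStructure, mappings: Sequence[AtomMapping],
                             records: Mapping[str, CompoundRecord]) -> CoreStructure:
    """Number the substitution sites of a core from all member mappings.

    A core atom is a site iff it has a non-H neighbor outside the mapped
    core in at least one member; sites are numbered 1..n following the
    canonical atom ranking of the core.
    """
    site_atoms: set[int] = set()
    for m in mappings:
        mol = records[m.compound_id].mol
        match = [m.core_to_compound[q] for q in range(core.n_atoms)]
        for comp, attach_qs in _attachment_components(mol, match):
            site_atoms.update(attach_qs)
    ordered = sorted(site_atoms, key=lambda q: core.ranks[q])
    core.site_index = {q: i + 1 for i, q in enumerate(ordered)}
    core.n_sites = len(ordered)
    return core


# ---------------------------------------------------------------------------
# R-group decomposition


def decompose_rgroups(compound: CompoundRecord, core: CoreStructure,
                      mapping: AtomMapping) -> RGroupAssignment:
    """Decompose one compound into per-site R-groups against the core.

    Every site gets an entry: the substituent fragment as canonical SMILES
    with an attachment marker, or ``"H"`` when unsubstituted. A fragment
    attached to two core atoms is reported at the lower-numbered site with
    two markers and flagged.
    """
    mol = compound.mol
    match = [mapping.core_to_compound[q] for q in range(core.n_atoms)]
    groups: dict[int, str] = {s: "H" for s in range(1, core.n_sites + 1)}
    multi: set[int] = set()
    for comp, attach_qs in _attachment_components(mol, match):
        sites = []
        for q in attach_qs:
            if q not in core.site_index:
                raise ValueError(
                    f"compound {compound.compound_id}: substituent attached to "
                    f"non-site core atom {q}; stale core for this series?")
            sites.append(core.site_index[q])
        if not sites:
            raise ValueError(f"compound {compound.compound_id}: dangling non-core atoms {comp}")
        attach_atoms = {match[q] for q in attach_qs}
        smi = _fragment_smiles(mol, comp, attach_atoms)
        site = min(sites)
        if len(sites) > 1:
            multi.add(site)
        if groups[site] != "H":  # two fragments on one site atom: join deterministically
            smi = ".".join(sorted([groups[site], smi]))
        groups[site] = smi
    return RGroupAssignment(
        compound_id=compound.compound_id,
        groups=groups,
        stereo_signature=stereo_signature(compound),
        constitution=constitution_key(compound),
        multi_attachment=frozenset(multi),
    )


# ---------------------------------------------------------------------------
# stereochemistry


def constitution_key(compound: CompoundRecord | Chem.Mol) -> str:
    """Stereo-free canonical SMILES; equal keys = identical constitution."""
    mol = compound.mol if isinstance(compound, CompoundRecord) else compound
    return Chem.MolToSmiles(mol, isomericSmiles=False)


_BOND_STEREO = {
    Chem.BondStereo.STEREOE: "E",
    Chem.BondStereo.STEREOZ: "Z",
    Chem.BondStereo.STEREOTRANS: "E",
    Chem.BondStereo.STEREOCIS: "Z",
}


def stereo_signature(compound: CompoundRecord | Chem.Mol) -> tuple[str, ...]:
    """CIP descriptors over all stereocenters in canonical atom order.

    R/S for tetrahedral centers, E/Z for double bonds, ``?`` where a center
    exists but is unspecified. Two compounds are stereoisomers iff their
    constitutions are equal and their signatures differ.
    """
    mol = Chem.Mol(compound.mol if isinstance(compound, CompoundRecord) else compound)
    Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
    try:
        rdCIPLabeler.AssignCIPLabels(mol)
    except Exception:  # pragma: no cover - CIP labeller limits
        logger.warning("CIP labelling failed; using raw stereo descriptors")
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=True, includeChirality=False))
    entries: list[tuple[tuple[int, ...], str]] = []
    for info in Chem.FindPotentialStereo(mol):
        if info.type == Chem.StereoType.Atom_Tetrahedral:
            atom = mol.GetAtomWithIdx(info.centeredOn)
            if info.specified == Chem.StereoSpecified.Specified and atom.HasProp("_CIPCode"):
                desc = atom.GetProp("_CIPCode")
            elif info.specified == Chem.StereoSpecified.Specified:
                desc = "*"  # specified but no CIP label (e.g. pseudo-asymmetric edge cases)
            else:
                desc = "?"
            entries.append(((ranks[info.centeredOn],), desc))
        elif info.type == Chem.StereoType.Bond_Double:
            bond = mol.GetBondWithIdx(info.centeredOn)
            key = tuple(sorted((ranks[bond.GetBeginAtomIdx()], ranks[bond.GetEndAtomIdx()])))
            if info.specified == Chem.StereoSpecified.Specified:
                if bond.HasProp("_CIPCode"):
                    desc = bond.GetProp("_CIPCode")
                else:
                    desc = _BOND_STEREO.get(bond.GetStereo(), "*")
            else:
                desc = "?"
            entries.append((key, desc))
    entries.sort(key=lambda e: e[0])
    return tuple(d for _, d in entries)


# ---------------------------------------------------------------------------
# series combination


def combine_series(series_a: AnalogSeries, series_b: AnalogSeries,
                   records: Mapping[str, CompoundRecord], *,
                   min_coverage: float = DEFAULT_MIN_COVERAGE,
                   timeout: int = DEFAULT_MCS_TIMEOUT) -> AnalogSeries:
    """Merge two series into one by recomputing the MCS over the union.

    All downstream structures (partition, graphs, trees) must be rebuilt
    from the new core. Combining a series with itself returns an equivalent
    series with an identical core.
    """
    if not series_a.members or not series_b.members:
        raise ValueError("cannot combine an empty series")
    members = sorted(set(series_a.members) | set(series_b.members))
    scaffold = series_a.scaffold if series_a.scaffold == series_b.scaffold else None
    sid = series_a.series_id if series_a.series_id == series_b.series_id \
        else f"{series_a.series_id}+{series_b.series_id}"
    merged = AnalogSeries(series_id=sid, scaffold=scaffold, members=members)
    compute_mcs(merged, records, min_coverage=min_coverage, timeout=timeout)
    return merged
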