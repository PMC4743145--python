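"""Synthetic analog-series generator and brute-force test oracles.

The generator assembles analog series from a core template with numbered
attachment points and per-site substituent pools, stamps each compound with
potencies from an additive substituent model plus seeded Gaussian noise,
and writes a standard SD file. Identical (spec, seed) pairs produce
byte-identical files, so every downstream stage is testable without any
external compound set.

The oracles recompute, by exhaustive enumeration, the two quantities the
pipeline's correctness hinges on: the size of the maximum common connected
subgraph of a small series, and the subset partition implied by a set of
R-group assignments.
"""

from __future__ import annotations

import random
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
from networkx.algorithms import isomorphism
from rdkit import Chem
from rdkit.Chem import rdDepictor
from rdkit.Chem.EnumerateStereoisomers import (
    EnumerateStereoisomers,
    StereoEnumerationOptions,
)

DEFAULT_NOISE_SD = 0.2  # log units


@dataclass
class PotencyModel:
    """Additive potency model: base + per-(site, substituent) increments.

    Increments not listed explicitly are derived deterministically from a
    hash of (site, substituent SMILES), mapped into [-1, 1] log units, so
    every substituent has a reproducible effect without enumerating all of
    them. Gaussian noise (default sd 0.2 log units) is added per compound
    from the spec seed.
    """

    base: float = 6.0
    increments: dict[tuple[int, str], float] = field(default_factory=dict)
    noise_sd: float = DEFAULT_NOISE_SD

    def increment(self, site: int, smiles: str) -> float:
        if (site, smiles) in self.increments:
            return self.increments[(site, smiles)]
        h = zlib.crc32(f"{site}:{smiles}".encode())
        return (h % 2001) / 1000.0 - 1.0

    def value(self, subs: Mapping[int, str]) -> float:
        return self.base + sum(self.increment(s, smi) for s, smi in subs.items())


@dataclass
class FixtureSpec:
    """Recipe for one synthetic analog series.

    ``core_template`` is a SMILES with numbered attachment dummies
    ``[*:k]``; unused attachment points become hydrogens. Each entry of
    ``occupancy_pattern`` yields one compound: either a set of sites
    (substituents drawn from the pools, duplicates avoided) or an explicit
    site -> substituent map. ``stereo_pattern`` maps a pattern index to the
    number of stereoisomers to emit for that compound.
    """

    core_template: str
    substituent_pools: dict[int, list[str]]
    occupancy_pattern: list[Sequence[int] | Mapping[int, str]]
    stereo_pattern: dict[int, int] = field(default_factory=dict)
    potency_models: dict[str, PotencyModel] = field(default_factory=lambda: {"pKi": PotencyModel()})
    seed: int = 0
    id_prefix: str = "CPD"

    def sites(self) -> list[int]:
        core = Chem.MolFromSmiles(self.core_template)
        return sorted(a.GetAtomMapNum() for a in core.GetAtoms() if a.GetAtomicNum() == 0)


def _attach(core_template: str, subs: Mapping[int, str]) -> Chem.Mol:
    """Realize one compound: substituents onto the core, open sites -> H."""
    core = Chem.MolFromSmiles(core_template)
    if core is None:
        raise ValueError(f"invalid core template: {core_template}")
    pieces = [core]
    for site, smi in subs.items():
        frag = Chem.MolFromSmiles(smi)
        if frag is None:
            raise ValueError(f"invalid substituent SMILES {smi!r} for site {site}")
        frag = Chem.RWMol(frag)
        dummies = [a for a in frag.GetAtoms() if a.GetAtomicNum() == 0]
        if len(dummies) != 1:
            raise ValueError(f"substituent {smi!r} for site {site} needs exactly one '*'")
        dummies[0].SetAtomMapNum(site)
        pieces.append(frag.GetMol())
    combo = pieces[0]
    for p in pieces[1:]:
        combo = Chem.CombineMols(combo, p)
    # drop unused attachment dummies before zipping
    rw = Chem.RWMol(combo)
    used = set(subs)
    for idx in sorted((a.GetIdx() for a in rw.GetAtoms()
                       if a.GetAtomicNum() == 0 and a.GetAtomMapNum() not in used), reverse=True):
        rw.RemoveAtom(idx)
    mol = Chem.molzip(rw.GetMol())
    Chem.SanitizeMol(mol)
    mol = Chem.MolFromSmiles(Chem.MolToSmiles(mol))
    return mol


def _realize(spec: FixtureSpec) -> list[tuple[str, Chem.Mol, dict[str, float]]]:
    """Deterministically expand a spec into (id, molecule, potencies) rows."""
    rng = random.Random(spec.seed)
    noise_rng = random.Random(spec.seed + 1)
    rows: list[tuple[str, Chem.Mol, dict[int, str]]] = []
    used_combos: set[tuple[tuple[int, str], ...]] = set()
    for idx, entry in enumerate(spec.occupancy_pattern):
        if isinstance(entry, Mapping):
            subs = dict(entry)
        else:
            subs = {}
            for _attempt in range(50):
                subs = {s: rng.choice(spec.substituent_pools[s]) for s in entry}
                key = tuple(sorted(subs.items()))
                if key not in used_combos:
                    break
            used_combos.add(tuple(sorted(subs.items())))
        mol = _attach(spec.core_template, subs)
        n_iso = spec.stereo_pattern.get(idx, 0)
        if n_iso > 1:
            opts = StereoEnumerationOptions(onlyUnassigned=True, unique=True)
            isomers = sorted(EnumerateStereoisomers(mol, options=opts), key=Chem.MolToSmiles)
            if len(isomers) < n_iso:
                raise ValueError(
                    f"pattern entry {idx} admits only {len(isomers)} stereoisomers, "
                    f"{n_iso} requested")
            for j, iso in enumerate(isomers[:n_iso]):
                rows.append((f"{spec.id_prefix}{idx:03d}{chr(97 + j)}", iso, subs))
        else:
            rows.append((f"{spec.id_prefix}{idx:03d}", mol, subs))
    out = []
    for cid, mol, subs in rows:
        pots = {}
        for tag in sorted(spec.potency_models):
            model = spec.potency_models[tag]
            pots[tag] = round(model.value(subs) + noise_rng.gauss(0.0, model.noise_sd), 4)
        out.append((cid, mol, pots))
    return out


def expected_potencies(spec: FixtureSpec) -> dict[str, dict[str, float]]:
    """Recompute every potency tag from the spec (the additive-model oracle)."""
    return {cid: pots for cid, _, pots in _realize(spec)}


def generate_series_sdf(spec: FixtureSpec, path: str | Path) -> int:
    """Write the realized series to an SD file; returns the compound count."""
    rows = _realize(spec)
    writer = Chem.SDWriter(str(path))
    try:
        for cid, mol, pots in rows:
            mol = Chem.Mol(mol)
            rdDepictor.Compute2DCoords(mol)
            mol.SetProp("_Name", cid)
            for tag, v in pots.items():
                mol.SetProp(tag, f"{v:.4f}")
            writer.write(mol)
    finally:
        writer.close()
    return len(rows)


def load_fixture_spec(path: str | Path) -> FixtureSpec:
    """Read a fixture spec from a YAML (or JSON) config file.

    Schema::

        core_template: SMILES with [*:k] attachment dummies
        substituent_pools: {site: [substituent SMILES with one *]}
        occupancy_pattern:         # one entry per compound
          - [1, 2]                 # sites drawn from the pools
          - {4: "[*]C(O)C"}        # or explicit site -> substituent
        stereo_pattern: {entry index: number of stereoisomers}
        potency_models:
          pKi: {base: 6.0, noise_sd: 0.2,
                increments: [{site: 1, smiles: "[*]C", delta: 0.5}]}
        seed: 0
        id_prefix: CPD
    """
    import yaml

    data = yaml.safe_load(Path(path).read_text())
    models = {}
    for tag, m in (data.get("potency_models") or {"pKi": {}}).items():
        increments = {(int(e["site"]), e["smiles"]): float(e["delta"])
                      for e in m.get("increments", [])}
        models[tag] = PotencyModel(base=float(m.get("base", 6.0)),
                                   increments=increments,
                                   noise_sd=float(m.get("noise_sd", DEFAULT_NOISE_SD)))
    pattern: list = []
    for entry in data["occupancy_pattern"]:
        if isinstance(entry, Mapping):
            pattern.append({int(k): str(v) for k, v in entry.items()})
        else:
            pattern.append(tuple(int(s) for s in entry))
    return FixtureSpec(
        core_template=data["core_template"],
        substituent_pools={int(k): list(v) for k, v in data["substituent_pools"].items()},
        occupancy_pattern=pattern,
        stereo_pattern={int(k): int(v) for k, v in (data.get("stereo_pattern") or {}).items()},
        potency_models=models,
        seed=int(data.get("seed", 0)),
        id_prefix=str(data.get("id_prefix", "CPD")),
    )


# ---------------------------------------------------------------------------
# ready-made specs


#: N-(pyridin-2-yl)thiophene-2-carboxamide with five aromatic substitution
#: sites. Every ring position is symmetry-unique, so each attachment point
#: corresponds to exactly one substitution site downstream.
DEFAULT_CORE = "O=C(Nc1ccc([*:4])c([*:5])n1)c1sc([*:1])c([*:2])c1[*:3]"

DEFAULT_POOLS = {
    1: ["[*]C", "[*]O", "[*]Cl", "[*]F"],
    2: ["[*]C", "[*]OC", "[*]Br"],
    3: ["[*]C", "[*]CC", "[*]C(C)C"],
    4: ["[*]C", "[*]O", "[*]OC"],
    5: ["[*]C", "[*]OC"],
}

#: substituents that create tetrahedral stereocenters on attachment
STEREO_SUB_1 = "[*]C(O)C"        # one center -> enantiomer pair
STEREO_SUB_2 = "[*]C(O)C(C)Cl"   # two centers -> up to four stereoisomers
STEREO_SUB_3 = "[*]C(O)CC"       # one center -> enantiomer pair


def default_fixture_spec(seed: int = 0) -> FixtureSpec:
    """A 25-compound, 5-site series with one 3-member stereoisomer set.

    Sixteen distinct site combinations are realized (including the bare
    core), and the four-site combination {1,3,4,5} holds seven analogs,
    three of which are stereoisomers of one constitution - the shape of a
    mid-size lead-optimization series.
    """
    pattern: list = [
        (),                   # the bare core itself
        (1,), (1,), (2,), (3,), (4,), (5,),
        (1, 2), (1, 2), (1, 3), (2, 4), (4, 5), (2, 3),
        (1, 2, 3), (1, 4, 5), (2, 4, 5),
        # four-site combination 1345, incl. a 3-member stereo set
        {1: "[*]C", 3: "[*]CC", 4: STEREO_SUB_2, 5: "[*]OC"},
        (1, 3, 4, 5), (1, 3, 4, 5), (1, 3, 4, 5), (1, 3, 4, 5),
        (1, 2, 3, 4, 5), (1, 2, 3, 4, 5),
    ]
    return FixtureSpec(
        core_template=DEFAULT_CORE,
        substituent_pools=DEFAULT_POOLS,
        occupancy_pattern=pattern,
        stereo_pattern={16: 3},
        seed=seed,
    )


def stereo_demo_fixture_spec(seed: int = 0) -> FixtureSpec:
    """A fixture with one 3-member stereo set and, in another subset, two
    stereo pairs - exercises incremental stereo-group indexing."""
    pattern: list = [
        (),
        (1,), (2,),
        {1: "[*]C", 3: "[*]CC", 4: STEREO_SUB_2, 5: "[*]OC"},   # 3 stereoisomers
        {4: STEREO_SUB_1, 5: "[*]C"},                            # pair 1 in subset 45
        {4: STEREO_SUB_3, 5: "[*]C"},                            # pair 2 in subset 45
        (4, 5),
    ]
    return FixtureSpec(
        core_template=DEFAULT_CORE,
        substituent_pools=DEFAULT_POOLS,
        occupancy_pattern=pattern,
        stereo_pattern={3: 3, 4: 2, 5: 2},
        seed=seed,
    )


def selectivity_fixture_spec(seed: int = 0) -> FixtureSpec:
    """Two-target fixture: every compound carries pIC50_A and pIC50_B."""
    base = default_fixture_spec(seed)
    return FixtureSpec(
        core_template=base.core_template,
        substituent_pools=base.substituent_pools,
        occupancy_pattern=base.occupancy_pattern,
        stereo_pattern=base.stereo_pattern,
        potency_models={
            "pIC50_A": PotencyModel(base=7.0),
            "pIC50_B": PotencyModel(base=5.5),
        },
        seed=seed,
    )


#: small cores (with site dummies) for oracle-scale series, <= 12 heavy atoms
TINY_CORES = [
    "c1cc([*:1])oc1[*:2]",      # furan
    "c1cc([*:1])cnc1[*:2]",     # pyridine
    "C1CC([*:1])CC1[*:2]",      # cyclopentane
    "c1cc([*:1])sc1[*:2]",      # thiophene
    "c1cc([*:1])cc([*:2])c1",   # benzene-1,3
]

TINY_POOLS = {
    1: ["[*]C", "[*]O", "[*]Cl", "[*]CC", "[*]N"],
    2: ["[*]C", "[*]O", "[*]C=C", "[*]CO"],
}


def tiny_series_specs(n_series: int, seed: int = 0) -> list[FixtureSpec]:
    """Seeded small-molecule series for brute-force MCS validation.

    Every generated molecule stays at or below 12 heavy atoms so the
    exhaustive subgraph oracle remains tractable.
    """
    rng = random.Random(seed)
    specs = []
    patterns = [
        [(), (1,), (2,), (1, 2)],
        [(1,), (2,), (1, 2)],
        [(), (1,), (1, 2)],
        [(1,), (1,), (2,)],
    ]
    for i in range(n_series):
        specs.append(FixtureSpec(
            core_template=TINY_CORES[i % len(TINY_CORES)],
            substituent_pools=TINY_POOLS,
            occupancy_pattern=list(patterns[rng.randrange(len(patterns))]),
            seed=rng.randrange(2**31),
            id_prefix=f"T{i:02d}_",
        ))
    return specs


# ---------------------------------------------------------------------------
# oracles


def _mol_to_graph(mol: Chem.Mol) -> nx.Graph:
    g = nx.Graph()
    for a in mol.GetAtoms():
        g.add_node(a.GetIdx(), z=a.GetAtomicNum(), ring=a.IsInRing())
    for b in mol.GetBonds():
        g.add_edge(b.GetBeginAtomIdx(), b.GetEndAtomIdx(),
                   order=b.GetBondTypeAsDouble(), ring=b.IsInRing())
    return g


_NODE_MATCH = isomorphism.categorical_node_match(["z", "ring"], [None, None])
_EDGE_MATCH = isomorphism.categorical_edge_match(["order", "ring"], [None, None])


def oracle_mcs(molecules: Sequence[Chem.Mol], max_atoms: int = 12) -> tuple[int, int]:
    """Exhaustive maximum common connected subgraph size: (atoms, bonds).

    Enumerates every connected edge-induced subgraph (plus single atoms) of
    the smallest molecule and tests monomorphism into all others under the
    production match rules: element identity, exact bond order, ring atoms/
    bonds only onto ring atoms/bonds. Maximal in atoms, then bonds.
    Refuses molecules above ``max_atoms`` heavy atoms.
    """
    if any(m.GetNumHeavyAtoms() > max_atoms for m in molecules):
        raise ValueError(f"oracle_mcs is limited to molecules of <= {max_atoms} heavy atoms")
    graphs = [_mol_to_graph(m) for m in molecules]
    smallest = min(range(len(graphs)), key=lambda i: graphs[i].number_of_nodes())
    pattern_src = graphs[smallest]
    others = [g for i, g in enumerate(graphs) if i != smallest]

    def common(sub: nx.Graph) -> bool:
        return all(
            isomorphism.GraphMatcher(g, sub, node_match=_NODE_MATCH,
                                     edge_match=_EDGE_MATCH).subgraph_is_monomorphic()
            for g in others)

    best = (0, 0)
    # single atoms
    for n, d in pattern_src.nodes(data=True):
        sub = nx.Graph()
        sub.add_node(n, **d)
        if common(sub):
            best = max(best, (1, 0))
            break
    edges = list(pattern_src.edges)
    # largest edge subsets first: a connected subgraph with e edges has at
    # most e+1 atoms, so smaller subsets cannot beat an established optimum
    masks = sorted(range(1, 1 << len(edges)), key=lambda m: -m.bit_count())
    for mask in masks:
        e = mask.bit_count()
        if (e + 1, e) <= best:
            break
        chosen = [edges[i] for i in range(len(edges)) if mask >> i & 1]
        sub = pattern_src.edge_subgraph(chosen)
        if (sub.number_of_nodes(), sub.number_of_edges()) <= best:
            continue
        if not nx.is_connected(sub):
            continue
        if common(sub):
            best = max(best, (sub.number_of_nodes(), sub.number_of_edges()))
    return best


def oracle_partition(assignments: Mapping[str, object]) -> dict[frozenset[int], list[str]]:
    """Naive subset recomputation: compound -> exact set of non-H sites."""
    out: dict[frozenset[int], list[str]] = {}
    for cid in sorted(assignments):
        a = assignments[cid]
        sites = frozenset(s for s, g in a.groups.items() if g != "H")
        out.setdefault(sites, []).append(cid)
    return out
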