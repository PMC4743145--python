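# Methods

## Series identification

Compounds are grouped by hierarchical molecular scaffold. The default level
is the Bemis–Murcko *framework*: all ring atoms, the linker atoms between
rings, and atoms double-bonded to ring or linker atoms; side chains are
removed and stereochemistry discarded. One level up, the *generic skeleton*
replaces every atom by carbon and every bond by a single bond, so series
that differ only in ring heteroatoms merge. Framework grouping is the
default because an analog series in the usual medicinal-chemistry sense
shares a specific core, not just a ring topology; the generic level is an
option for users who want heteroatom-tolerant grouping rather than an
automatic merge.

Acyclic compounds have no scaffold and are excluded from series formation
(logged); groups below `min_series_size` (default 2 — an MCS and an R-group
comparison are meaningless for one compound) are left unassigned. Series ids
are assigned by descending member count, then scaffold SMILES, so they are
independent of input order.

## MCS flavor and cost control

The series core is the *connected* maximum common substructure under strict
matching: element identity for atoms, exact bond order for bonds, and ring
atoms/bonds only onto ring atoms/bonds. This flavor keeps R-group
decomposition well-defined: every non-core fragment hangs off an
unambiguous core atom. The search (RDKit FMCS) maximizes atom count first,
bond count second. Degenerate inputs are handled explicitly: if no bond can
match (e.g. an aromatic against a saturated ring) the MCS collapses to a
single matched atom and the series is flagged *low-coverage*; the same flag
is raised whenever the core covers less than `min_coverage` (default 2/3)
of the mean heavy-atom count. A configurable timeout (default 60 s per
series) falls back to the series scaffold as core, flagged
`scaffold_fallback`. Scaffold containment in the MCS is preferred and
logged when violated, but not forced.

For series of molecules with at most 12 heavy atoms the implementation is
cross-checked against an independent exhaustive oracle that enumerates every
connected edge-induced subgraph of the smallest member and tests
monomorphism into all others under the same match rules.

## Canonical core mapping and site indexing

A compound may embed the core in many symmetry-equivalent ways (core
automorphisms × embedding choices); R-group assignment must not depend on
the choice. Among all substructure matches the canonical one minimizes, in
order:

1. the sorted list of occupied core positions (by canonical core atom rank),
2. the per-position substituent canonical SMILES,
3. the sequence of constitution-level canonical atom ranks of the mapped
   compound atoms.

Step 3 uses stereo-free ranks, so stereoisomers with equal constitution
receive identical mappings. Core atom ranks come from RDKit's fragment
canonical ranking of the core realized in a canonically renumbered
reference member; they are therefore a function of the core's structure
only, never of input atom order. Substitution sites are the core atoms that
carry a non-H neighbor outside the mapped core in at least one member,
numbered 1..n in canonical rank order. Consequence: on a symmetric core,
every mono-substituted analog occupies the same site index, and permuting
input atoms or records changes nothing downstream (tested byte-for-byte on
the exports).

A substituent fragment bonded to two core atoms (ring fusion onto the core)
is reported at the lower-numbered site with two attachment markers and
flagged `multi_attachment` — a documented extension for a case the layered
subset logic cannot otherwise express. Two separate fragments on one site
atom are joined into a single dot-separated SMILES deterministically.

## Stereochemistry

Stereo descriptors are CIP labels (R/S for tetrahedral centers, E/Z for
double bonds, `?` for a present-but-unspecified center), listed over the
molecule's potential stereocenters in stereo-free canonical atom order. Two
compounds are stereoisomers iff their stereo-free canonical SMILES
(constitution) are equal and their signatures differ. Stereocenters inside
the core and inside R-groups are treated alike — any signature difference
with equal constitution makes a stereoisomer pair. In an R-group tree,
every constitution class with ≥ 2 leaves is a stereo group; groups are
indexed 1, 2, … in left-to-right tree order, all leaves of a group carry
its index, and singletons carry none. Compounds with unspecified stereo
join a group only through constitution equality; their `?` signature keeps
them distinguishable from resolved mates.

## Graphs and trees

A compound's site combination is the exact set of its non-H sites; subsets
are therefore disjoint and covering by construction (checked against a
naive re-derivation in the tests). The complete graph holds all 2^n
combinations with edges between every adjacent-layer subset pair; above a
ceiling of 12 sites (4096 nodes) it is refused and the reduced graph is
built directly from the occupied combinations, which is equivalent to
reducing the complete graph but never materializes it. Reduction is a plain
induced subgraph on non-empty nodes — no transitive re-wiring across
removed nodes, so disconnected reduced graphs are legal. The empty root is
removed like any empty node; a non-empty root (the bare core compound
exists in the set) is kept.

Node statistics are the analog count, arithmetic mean potency, and potency
range (max − min) in log units. Exports carry them as numeric attributes
together with layer indices as layout hints; suggested visual bins (size by
count tertile, color over the series potency range, thick border at range
≥ 1 order of magnitude) are configurable conventions, not semantics.

R-group trees order a subset's sites by ascending count of distinct
R-groups (ties by site number), putting the most conserved site nearest the
root. Children split on the next site's R-group, sorted lexicographically;
at the last layer a unique analog becomes a leaf directly, while a
constitution shared by several compounds becomes an intermediate node whose
leaves are the individual stereoisomers, adjacent by construction.

Combination labels concatenate site digits ("0" for the root, "1345" for
{1,3,4,5}); with any two-digit site the label switches to dot-separated
form, with a trailing dot for a lone two-digit site so the encoding stays
bijective.

## Selectivity

Given two targets, compounds lacking either potency are dropped before
partitioning, so both target-specific reduced graphs share one partition
and one topology; only node statistics differ, and each node carries the
mean-potency difference (log units) as a selectivity attribute.

## Synthetic data

The fixture generator emulates a lead-optimization analog series: a fixed
core template with numbered attachment points, per-site substituent pools,
an occupancy pattern (one compound per entry), optional stereoisomer
expansion, and potencies from an additive model — base value plus
per-(site, substituent) increments plus seeded Gaussian noise (sd 0.2 log
units), the simplest model that produces readable SAR gradients in the
trees. Unlisted increments derive deterministically from a hash, so every
substituent has a reproducible effect. Identical (spec, seed) pairs yield
byte-identical SD files.

The default series (25 compounds, 5 sites, 16 occupied combinations, one
3-member stereo set, a 7-analog four-site subset) mirrors a mid-size
optimization campaign. Its core is an asymmetric heteroaromatic
(N-(pyridin-2-yl)thiophene-2-carboxamide) in which every ring position is
symmetry-unique, so each attachment point corresponds to exactly one
substitution site; symmetric-core behavior is exercised separately with
benzene-core series. Tiny-series specs keep every molecule at ≤ 12 heavy
atoms so the exhaustive MCS oracle stays tractable (problem sizes used
throughout: 20 oracle series, 200 random partition assignments, 25-compound
demo series).

What the generator does *not* emulate: realistic substituent frequency
distributions, activity cliffs beyond additive noise, measurement
censoring, multi-core series, or salts/mixtures beyond a largest-fragment
test case. Passing tests therefore demonstrate correctness of the
organization and graph machinery, not predictive realism of the potencies.

## Numerical and I/O choices

Potencies are assumed to be already on a negative-log scale (pKi/pIC50); no
unit conversion is attempted. Compounds missing every configured potency
tag are dropped at read time, since every graphical attribute requires
potency. Salt entries keep the largest fragment by heavy-atom count, ties
broken by smallest canonical SMILES. Duplicate structures under distinct
ids are kept and logged, not merged. Means and ranges are rounded to 1e-6
in exports; all writers are deterministic, so identical inputs produce
byte-identical reports and graph files.

## Known limitations

- The MCS is connected-only; series whose members share two disconnected
  moieties are represented by the larger common fragment.
- Canonical-mapping enumeration visits every substructure match; extremely
  symmetric cores with many embeddings are handled but at combinatorial
  cost.
- The scaffold-timeout fallback changes the core definition for affected
  series (flagged); downstream numbers are then scaffold-relative.
- Exports are static (with layer layout hints); there is no interactive
  graph editing.
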