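# analogsar

Extraction and graphical analysis of analog series from compound sets, with
explicit stereochemistry handling.

Medicinal-chemistry lead optimization produces series of analogs — compounds
sharing a common core and differing only in their substituents (R-groups).
Once a series outgrows a conventional R-group table, its structure–activity
relationships (SAR) are easier to read from graphs. `analogsar`:

1. groups compounds into **analog series** by hierarchical molecular
   scaffold (Bemis–Murcko framework, or the generic carbon skeleton one
   level up),
2. computes each series' **maximum common substructure (MCS)** — connected,
   atoms matched by element, bonds by exact order, ring bonds only onto
   ring bonds — and maps every member onto it with a canonical,
   symmetry-consistent atom assignment,
3. **decomposes** every member into indexed R-groups (sites R1..Rn), and
4. organizes the series into three graphical components:
   - the **complete graph**: the layered DAG over all 2^n substitution-site
     combinations (layer k = combinations of k sites; node *1* holds analogs
     substituted only at R1, node *12* those substituted at R1 and R2, the
     root *0* the bare core); nodes carry analog count, mean potency, and
     potency range (in log units / orders of magnitude), empty nodes mark
     unexplored chemistry;
   - the **reduced graph**: the induced subgraph on non-empty nodes;
   - per-subset **R-group trees** resolving analogs substituent by
     substituent down to single compounds, with stereoisomers of one
     constitution marked by incremental group indices (1, 2, ...).

Selectivity analysis builds target-specific reduced graphs over one shared
partition (identical topology, per-target statistics, per-node potency
difference), and two series can be merged by recomputing their joint MCS.

Input is standard SD files (V2000/V3000) with potencies in SD property tags
on a negative-log scale (pKi / pIC50). Outputs are a TSV subset report and
graph exports in JSON (round-trippable), GraphML, and DOT.

## Worked example

The package ships a deterministic fixture generator, so a complete analysis
can be reproduced from nothing:

```sh
analogsar make-fixture --kind default --seed 0 -o demo.sdf
analogsar multi -i demo.sdf -o demo_out --format json
```

which prints

```
wrote 25 compounds to demo.sdf
series S1: 25 members, 5 sites, 16 subsets, 1 stereo groups
wrote 19 files; manifest: demo_out/manifest.json
```

One series of 25 analogs over a five-site core was found; its 16 occupied
site combinations yield a 32-node complete graph, the reduced graph, and one
R-group tree per subset. The subset report starts

```
series_id  subset  compound_id  R1  R2   R3  R4  R5  pKi   stereo_group
S1         0       CPD000       H   H    H   H   H   6.26
S1         1       CPD005       *O  H    H   H   H   6.08
S1         2       CPD003       H   *OC  H   H   H   5.06
```

(`*` marks the attachment point; `H` an unsubstituted site; the last column
is the stereo-group index where stereoisomers share a constitution). The
four-site node *1345* of the reduced graph reads

```json
{"id": "1345", "layer": 4, "count": 7, "mean_potency": 6.31,
 "potency_range": 2.24, "empty": false,
 "compounds": "CPD016a,CPD016b,CPD016c,CPD017,CPD018,CPD019,CPD020"}
```

seven analogs spanning 2.2 orders of magnitude in potency, three of which
(`CPD016a–c`) are stereoisomers of one constitution and appear in the
subset's R-group tree as adjacent leaves sharing stereo-group index 1.

Other subcommands: `single` (one series by id), `selectivity` (two potency
fields, e.g. `-f pIC50_A -f pIC50_B`), `merge` (`--series-a S1 --series-b
S2`), and `make-fixture --spec spec.yaml` for custom fixture recipes (schema
documented in `analogsar.fixtures.load_fixture_spec`).

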