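# structint

A structural interactomics toolkit: post-prediction analysis of modelled
protein–protein complexes. Deep-learning structure predictors can now
produce atomic models for tens of thousands of candidate protein
interactions, but raw models are useless without machinery to score
their interfaces, confront them with orthogonal experiments, map
functional sites onto them, and combine them into larger assemblies.
`structint` provides that machinery for structural biologists and
systems biologists working with predicted dimer models:

- **Interface detection and pDockQ scoring** — a residue is interfacial
  when any heavy atom lies within 10 Å of the partner chain; model
  confidence is the sigmoid

  pDockQ = 0.707 / (1 + exp(−0.03148 · (x − 388.06))) + 0.03138,
  with x = ⟨interface plDDT⟩ · ln(N_if),

  where N_if is the number of interface residues over both chains and
  plDDT (0–100, read from the B-factor column) is the predictor's
  per-residue confidence. Conventional cut-offs: pDockQ > 0.23
  acceptable, > 0.5 high confidence. A stricter geometric rule
  (more than 20 Cα–Cα contacts under 8 Å) separates *direct* physical
  interactions from co-complex neighbours.
- **Crosslink validation** — a lysine–lysine crosslink supports a model
  when the NZ–NZ distance is within the linker span (32 Å default).
- **Site mapping and enrichment** — mutations and phosphosites mapped
  onto interface residues; pathogenic-vs-benign interface enrichment via
  Fisher's exact test; recurrence ranking of cancer-mutated interfaces.
- **Phosphosite co-regulation** — filter strongly regulated interface
  phosphosites (|log2FC| > 1 in ≥ 3 conditions), correlate across a
  condition panel, Ward-cluster the correlation profiles, then test each
  cluster's per-condition regulation (signed one-sided Z-test) and term
  over-representation (hypergeometric + Benjamini–Hochberg).
- **Geometry and assembly** — Kabsch superposition, TM-score
  (d0 = 1.24·(L−15)^⅓ − 1.8, floored at 0.5 Å), and a greedy iterative
  builder that grows multimers from scored dimers: seed with the
  top-ranked dimer, superpose each candidate dimer's shared chain onto
  its placed copy (gate: TM-score > 0.8), accept the carried-over chain
  unless > 25% of its residues clash (Cα–Cα < 5 Å), restart the sweep
  after every addition.
- **Synthetic fixtures** — idealized multi-chain complexes with exact
  ground-truth transforms, planted crosslinks, and planted co-regulation
  clusters, so every pipeline is testable without downloading a model
  archive.

## Worked example

Generate a synthetic 5-chain ring complex with its dimer decomposition,
score one dimer, and rebuild the complex from the dimers:

```bash
$ structint simulate complex --n-chains 5 --geometry ring --seed 7 --out-dir demo
wrote complex + 5 dimers to demo

$ structint pdockq demo/P001-P002.pdb --chain-a A --chain-b B --json
{
  "n_contacts": 60,
  "mean_if_plddt": 90.0,
  "x": 368.491,
  "pdockq": 0.27931,
  "bin": "acceptable"
}

$ structint assemble --dimers demo/manifest.tsv --out demo/built.pdb --log demo/assembly.json
placed 5 chains -> demo/built.pdb
```

The dimer buries 60 interface residues at uniform plDDT 90, giving
x = 90·ln 60 ≈ 368.5, just below the sigmoid midpoint (388.06), hence a
mid-range score of 0.279 — an "acceptable" model. The assembly log in
`demo/assembly.json` records one `seed` and four `added` decisions (the
fifth, redundant ring dimer is skipped because both its proteins are
already placed); the rebuilt complex matches the generator's ground
truth to numerical precision. The same steps are available from Python
via `structint.make_complex`, `structint.score_dimer` and
`structint.assemble`.

Other subcommands: `structint direct` (direct-interaction
classification), `structint xl-validate` (crosslink distances),
`structint coreg` (co-regulation pipeline), `structint simulate
crosslinks|fcmatrix`.

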