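# Methods

This note documents the models, rules and numerical conventions the
package implements, the choices made where more than one convention is
defensible, and what the synthetic fixtures do and do not demonstrate.

## Coordinate model and plDDT

Structures are read with gemmi (PDB and mmCIF) into a small hierarchy
(Structure → Chain → Residue → Atom) that keeps heavy atoms only;
hydrogens are dropped on read (retainable by flag), waters always, and
other heteroatoms unless explicitly included. Multi-model files
contribute their first model. Per-residue plDDT (0–100) is taken from
the B-factor column, following the convention of AlphaFold-family
predictors; when atoms of a residue carry different B-factors the Cα
value is used (predicted models write uniform values per residue, so
this fallback only matters for experimental files). For experimental
structures with alternate locations, the highest-occupancy altloc is
kept, ties broken by altloc label order. Residue identity is
(chain id, author seq id, insertion code) with 1-based author
numbering throughout, so UniProt-style site tables map by position
without translation unless the caller supplies an offset.

The disorder fraction of a chain is the fraction of residues with
plDDT strictly below a threshold. plDDT is on the 0–100 scale here, so
the conventional disorder cut is 50 (literature sometimes prints the
same threshold as 0.5 on a 0–1 scale); the threshold is a parameter.

## Interface definition and pDockQ

A residue is an interface residue iff any of its heavy atoms lies
within 10 Å (inclusive — "within") of any heavy atom of the partner
chain. The interface size N_if counts interface *residues* summed over
both chains, and the interface plDDT pools those residues with equal
weight (a per-chain mean-of-means variant is not the default). The
confidence score is

    pDockQ = 0.707 / (1 + exp(−0.03148 (x − 388.06))) + 0.03138,
    x = ⟨interface plDDT⟩ · ln(N_if).

The logarithm is natural: with log10 the quantity x could not plausibly
reach the midpoint 388.06 (plDDT ≤ 100 and log10 N_if ≈ 2–3 for real
interfaces), whereas with ln a confident model (plDDT ≈ 80, N_if ≈
100–200) lands near it. N_if = 0 returns score 0.0 rather than the
sigmoid baseline 0.03138, so non-interacting pairs are not awarded
residual confidence. The four sigmoid constants are treated as fixed
fitted parameters; refitting them is out of scope. Confidence bins use
strict thresholds: > 0.5 high, > 0.23 acceptable, else low.

Direct versus indirect interaction uses a separate rule: count Cα–Cα
pairs strictly closer than 8 Å; the pair is direct iff the count
strictly exceeds 20. Both geometric kernels are KD-tree accelerated
with an explicit strict/inclusive distance check, and the test suite
holds them bit-equivalent to brute-force all-pairs scans.

## Crosslink validation

A lysine–lysine crosslink is evaluated as the Euclidean distance
between the two NZ (ε-amino) atoms; satisfied iff ≤ 32 Å (inclusive —
the generic maximal span of common Lys–Lys linkers; linker-specific
values are a parameter). Solvent-accessible surface distance is not
computed. A link whose residue is missing, is not lysine, or lacks its
NZ atom is *unevaluable* — reported with a reason, never silently
dropped, and excluded from satisfaction denominators. There is no Cα
fallback by default, since the measurement is specifically between
side-chain amines. Support summaries group models by pDockQ bin and
report the fraction with at least one satisfied link.

## Site mapping and enrichment

Sites (mutations, phosphosites) are matched to interfaces by
(protein, position). The annotation keeps one row per site × interface;
for enrichment each (protein, position) counts once, interfacial if any
dimer marks it so. Enrichment of class 1 over class 2 at interfaces is
the ratio of interface proportions, fold = (a/(a+b)) / (c/(c+d)), on
the 2×2 table of interface/elsewhere counts, with a two-sided Fisher's
exact p-value (one-sided available). The "elsewhere" denominator is
modelled residues, not full protein length — sites outside the
modelled range are flagged NA rather than counted as non-interface.
Recurrence ranking scores each interface by mutations per interface
position and flags interfaces at or above the 75th percentile of
density (ties inclusive); an interface with zero mutations is never
flagged even when all densities are zero.

## Superposition and TM-score

Kabsch superposition is the closed-form SVD solution with the
reflection suppressed (det = +1), so mirror images keep a positive
residual; it requires ≥ 3 non-collinear points. TM-score uses

    TM = (1/L) Σ_i 1 / (1 + (d_i/d0)²),
    d0(L) = 1.24 (L − 15)^⅓ − 1.8, floored at 0.5 Å,

normalised by the reference length L. Maximisation follows the
classic fragment-seeded scheme: Kabsch on windows of length L, L/2,
…, 4 (stride half the window), each refined by iterating "superpose on
residues with d_i < d0" to a fixed point (cap 20 iterations), keeping
the best score. Correspondence is by residue number or an explicit
map; sequence-independent alignment is a non-goal. Assembly-vs-
reference comparison matches chains by protein accession, enumerates
copy permutations per protein (≤ 8 copies; greedy beyond), and reports
RMSD and TM from a single global superposition over all matched Cα,
with d0 computed from the reference's total Cα count.

## Greedy assembly from dimers

Dimers are ranked by descending pDockQ, ties broken lexicographically
by dimer id so the build is deterministic. The top-ranked dimer (or a
caller-chosen one) seeds the complex in its own frame. Sweeping the
ranking, a dimer may extend the complex only when exactly one of its
proteins is already placed; then its copy of the shared protein is
gated by TM-score > 0.8 against the placed copy (each placed copy tried
in placement order), the placement transform is the least-squares
Kabsch fit over all shared Cα with residue-number correspondence, and
the transformed second chain is accepted unless strictly more than 25%
of its residues fall strictly within 5 Å (Cα–Cα) of any placed chain.
After an acceptance the sweep restarts from the top of the ranking;
rejected dimers are retried on later sweeps; the build terminates when
a full sweep adds nothing. Every attempt is logged with its action and
metrics, and the log is byte-deterministic for identical inputs.
Trimer or larger inputs are supported by decomposing them into their
pairwise sub-dimers before building. Stoichiometry inference and the
scoring of alternative final conformations are out of scope; a
different seed dimer can be selected to explore alternatives.

## Phosphosite co-regulation

"Strongly regulated" means |log2FC| strictly greater than 1 (twofold)
in at least 3 conditions (raw-ratio input should be log2-transformed
upstream). Correlations are pairwise-complete Pearson; pairs observed
together in fewer than 5 conditions, or involving a constant profile,
are undefined and imputed as 0 (with a warning) so the matrix stays
usable. Clustering represents each site by its row of the correlation
matrix, takes Euclidean distances between rows, and applies Ward's
minimum-variance linkage in the ward.D2 convention (scipy's `ward` on
Euclidean distances); flat clusters come from a dendrogram cut height
or a requested cluster count — cut heights are data-dependent, so no
universal default is hard-coded.

Per-cluster condition regulation uses

    z = (mean_cluster − mean_background) / (sd_background / √n),

where the background is the condition's full fold-change distribution,
cluster members included (excluding them is a flag-level variant the
API can grow; including them matches testing "against the overall
distribution" and is conservative). The one-sided p is taken on the
side of the observed deviation, p = P(Z ≥ |z|), and reported as
−log10 p signed positive iff the cluster median exceeds the background
median — so the sign reflects a robust location difference even when
the mean drives the test. Under a global null this p is uniform on
(0, 0.5]; the calibration test folds it by doubling before the
Kolmogorov–Smirnov check. Clusters with fewer than 2 measured values
in a condition give NA.

Term over-representation is the one-sided upper-tail hypergeometric
test per term, skipping terms with no population members, with
Benjamini–Hochberg q-values across the tested terms (the correction
choice is this package's; some upstream analyses report raw p).

## Synthetic fixtures

The generator builds idealized poly-lysine α-helical chains (Cα, CB,
NZ per residue; 1.5 Å rise, 100° turn) with parallel axes on a line, a
ring, or a snake-ordered grid, spaced 9 Å apart by default. That
spacing makes adjacent chains genuine direct interactions (far more
than 20 Cα contacts under 8 Å) while non-adjacent chains share no Cα
contacts; generation asserts this contract and raises on violation.
Each adjacent pair is exported as a dimer in a private frame produced
by a recorded uniformly random rigid motion, so assembly output can be
compared against exact ground truth. Crosslink planting samples
inter-chain NZ pairs on both sides of the 32 Å boundary at a requested
satisfied fraction; fold-change planting draws one latent log2FC per
(cluster, condition) from N(0, signal_sd²) and adds independent
N(0, noise_sd²) noise per site, with defaults signal_sd = 2.0,
noise_sd = 0.2 — strong, clean co-regulation at a 10:1 signal-to-noise
ratio. All randomness flows through numpy's seeded PCG64 generator,
making fixtures reproducible across platforms.

What the fixtures do *not* emulate: real side-chain packing, partial
disorder, conformational change between a dimer model and the
assembled context, noisy or decoy crosslinks, missing values and
batch structure in phosphoproteomics panels, or homologous subunits
that confuse copy assignment. Passing tests therefore demonstrate the
correctness of the implemented rules and numerics, not the biological
accuracy of predicted models these rules would be applied to.

## Problem sizes and tolerances

Tests and the acceptance script run on small, seeded instances chosen
to finish quickly while still exercising every code path: 100 random
fixtures for oracle-equivalence and rigid-motion recovery, 5- and
8-chain complexes (30 residues per chain) for assembly round trips,
60 sites × 40 conditions × 20 seeds for co-regulation recovery, and a
300 × 30 pure-noise matrix for null calibration. Geometric recoveries
are asserted at 1e-6 Å (Kabsch) and 1 Å (assembly round trip, which
tolerates accumulated floating-point error along the build chain);
analytic sigmoid anchors at 1e-5; cluster recovery at adjusted Rand
index ≥ 0.9 per seed; null calibration by a KS test at α = 0.01.
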