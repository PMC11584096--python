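# Methods

This note documents the models, numerical choices and limitations of the
package. It states nothing the test suite or `scripts/acceptance.py` does
not itself compute.

## Alphabet and coordinates

All frequency algebra runs over the 20 canonical amino acids plus gap as a
first-class 21st symbol; nonstandard codes (B, Z, X, U, O, J) map to gap
with a logged count. Columns that are gaps in the reference (query-species)
row are removed before any scoring, and every output reports 1-based
reference coordinates through the retained-column map, matching clinical
mutation nomenclature (e.g. p.I857S).

Ties for "most frequent symbol" break alphabetically among residues, and a
gap loses any tie against a residue. This is a determinism choice; it only
matters for near-degenerate columns.

## Position typing and weighting

The six-category decision tree compares the representative residues of the
target, closest and rest groups. Conservation thresholds are inclusive
(`≥ thr1`, `≥ thr2`, `≤ thr_bls`); thr1 = 0.98 and thr2 = 0.8 for the CaSR
preset (reflecting its exceptional conservation), 0.8/0.8 for the others,
and thr_bls = 0.5 on BLOSUM62 rows normalized by their row maximum (so the
diagonal is always 1). When the target representative is a gap (category
2), the type is II if either other group's representative is also gap and I
only when both are residues.

For a multi-subfamily closest or rest group whose members' top residues
include the target representative, the group's score is the *largest*
matching member frequency (the pseudocode references a single such member;
taking the maximum makes the choice deterministic when several match).
A multi-subfamily *target* group is pooled by averaging frequency vectors.

Final weights chain the four types: type I anchors the scale at `c1` (1.0,
or 1.5 for TAS1R2), the type IV cap is the mean type-I weight, the type III
cap is the minimum type-IV weight (GPRC6A), half of it (CaSR) or 0.5
(TAS1Rs), and the type II cap is 0.2/0.25 or, for CaSR, half the minimum
type-III weight. GPRC6A type-I weights double at the end. Degenerate
inputs: no type I column is an error (the type IV cap is undefined); an
empty type IV with type III present falls back to a 0.5 cap, an empty type
III under the CaSR policy to 0.2, both logged. The ordering
`max w_I ≥ max w_IV ≥ max w_III ≥ max w_II` is structural for the CaSR
policy and holds for the constant-capped policies whenever initial scores
stay in the range attainable by sums of group conservation of reasonably
conserved columns (≥ 0.8), which is the regime the acceptance check samples.

## Profile scoring

Baseline emissions are observed column frequencies with gap mass removed,
floored at 1e-4 and renormalized (the floor keeps unseen residues finitely
penalized, ≈ −9 bits against the uniform background). The weighting
multiplies each column's match log-odds contribution by its weight during
scoring; the exported HMMER3 profile equivalently raises emissions to the
weight and renormalizes. Both leave a weight-1 column untouched.

`score_sequence` is a global affine-gap dynamic program over match, insert
and delete states: inserts emit at background (0 bits), gap open costs 15
bits and extension 3 bits. The stiff penalties are deliberate: with cheap
gaps the aligner can skip every target-specific column of a mismatching
sequence and collect only the shared conserved ones, exactly the failure
mode the weighting exists to prevent. A sequence is "hit" by a profile when
its score is positive (bits relative to the background model).

## Acceptability distributions and SDP scores

The per-subfamily acceptability of residue *a* at a position is

    raw(a) = P_root(a) + Σ_{internal n ≠ root} max(0, P_n(a) − P_parent(n)(a))

normalized over residues. Each independent gain counts once however many
descendants inherit it; duplicating a leaf adds no mass. Leaves are
excluded from the accumulation — ancestral reconstructions emit posteriors
for internal nodes, and leaf states already shaped those posteriors.
Input posterior vectors renormalize when within 1e-3 of the simplex and
error beyond that.

The SDP combination treats a subfamily as conserved when its own
representative's acceptability exceeds 0.5 (strict). The ω weight takes the
maximum of the target representative's acceptability over the *other*
subfamilies only. Distances D_i are branch-length path sums between clade
root (MRCA) nodes on the merged tree and must be positive. Positions score
"specific" strictly above 5.

## Contact scores and the activation network

Kernel constants d_min = 3.23 Å and d_max = 4.63 Å with a linear ramp in
between; heavy atoms only, highest-occupancy conformer per atom name. For
residues fewer than 5 apart in sequence (same chain), main-chain atoms
(N, CA, C, O, OXT) are excluded so bonded-backbone geometry does not
register as contact. Atom-level scoring treats every heavy atom as its own
unit; summing a residue pair's atom-level scores reproduces its
residue-level score when the neighbour rule is fixed.

The Welch screen tests every unit pair seen in any structure (absent pairs
score 0), keeps p < 0.01 and applies no multiple-testing adjustment. Pairs
whose pooled within-state variance is zero (to a 1e-12 relative tolerance,
absorbing float rounding of identical coordinates) get p = 1 and are never
reported — so detection requires genuine score variance, which in practice
comes from atoms sitting in the kernel's linear zone. Symmetric homodimer
observations (A→B and B→A) enter the test as separate data points and
collapse to a single network edge; atom-level multiplicity counts distinct
significant atom pairs per residue pair.

## Mutation classifier

Features per substitution: conservation (raw column frequency, gaps in the
denominator) of the reference and substituted residue in each subfamily
alignment; both residues' 20-entry BLOSUM62 rows; nine physico-chemical
scales (Zimmerman polarity, average flexibility, Dayhoff relative
mutability, mean buried area, Kyte-Doolittle hydropathicity, Grantham
atomic-weight ratio, molecular weight, Zimmerman bulkiness, transmembrane
tendency) for both residues; and a one-hot domain label. The packaged scale
table ships in `subspec/data/physchem.tsv`. Raw column frequency is used
for conservation because it is the only conservation measure defined on a
bare alignment; positions not covered by a subfamily alignment contribute
zeros plus a cleared coverage flag.

Protocol: stratified 80/20 train/test splits, five stratified 25%
validation subsamples of the training split, greedy one-parameter-at-a-time
tuning in the fixed order eta (linear grid 1e-5…1e-3, step 1e-5), gamma,
subsample, column subsample, minimum child weight, lambda, alpha — depth
fixed at 2, 200 boosting rounds — selecting by mean validation AUROC with
ties going to the smallest candidate, then a final fit on the full training
split. Continuous features are z-scored with training-split statistics only
(population SD); one-hot and flag columns pass through; zero-variance
columns zero out with a warning. Splits are made on indices before any
normalization, so test rows can never influence the scaling (asserted by a
dedicated leakage test). `TuningGrid.reduced()` subsamples the same ranges
coarsely for small studies.

Evaluation reports AUROC, AUPR, accuracy and F1. LoF is the positive class
for AUPR and the headline F1 — it is the majority clinical class, and
LoF-positive F1 is the definition that reproduces the packaged validation
table's printed 0.83 (GoF-positive does not). GoF/LoF calls threshold the
GoF probability at 0.5; substitutions to residues observed at that column
of the target alignment are overlaid as neutral regardless of the model.

On planted data the replication metrics are computed against the
*uncorrupted* planted labels while training uses the noisy ones: this
measures recovery of the planted rule. Against the noisy labels themselves
the achievable AUROC is capped near 0.87 by the label corruption (with a
28% minority class, 10% symmetric flips leave only ~78% of minority-labeled
items truly minority), a property of the noise, not the model.

## Synthetic study conditions

The planted-alignment generator simulates substitutions down a generated
tree (per-branch substitution probability `1 − exp(−rate·length)`), not
i.i.d. columns, so independent-event counting is genuinely exercised.
Defaults: 5 subfamilies × 20 sequences (+5 held out, scattered across the
clade so they are exchangeable with training leaves) × 200 columns; column
plan mix 20% target-specific, 30% globally conserved, 15% shared with the
closest clade, 25% variable, 10% gap blocks (cycling which group is
gapped, including a target-gap mode so every typing category occurs);
conserved-column rate 0.02, variable-column rate 0.6 substitutions per unit
branch length. The 0.6 rate yields variable columns with a dominant residue
plus minority variants, as real within-subfamily ortholog alignments show —
fully randomized columns are not a realistic condition. Ancestral tables
place 0.97 posterior mass on the simulated state. At target-specific
columns the other clades' root states exclude the planted residue;
convergent re-gains remain possible through within-clade substitution.

The SDP recovery study uses the zero-noise generator with no free-variable
columns, where "exactly k target-conserved/other-variable positions" holds
literally. With background noise a single confident internal substitution
halves a position's acceptability — correct independent-event behaviour
that makes exact top-k recovery the wrong invariant for noisy conditions.

Toy structures are poly-alanine-like: N/CA/C/O plus CB and CG pseudo
side-chain atoms, residues 10 Å apart on a line so no unplanted pair is
ever within the kernel. A planted pair lifts one residue above its partner
at the state distance (3.0 Å active / 6.0 Å inactive by default, 7 active /
5 inactive structures, 0.05 Å coordinate jitter); the CB/CG geometry places
cross atom pairs at ±1.5 Å of the planted distance, guaranteeing at least
one pair in the kernel's linear zone in each state so jitter produces
testable variance.

Mutation datasets label substitutions at target-specific columns GoF (the
substituted residue is the most tolerated non-target residue unseen in the
target column) and at globally conserved columns LoF (a residue unseen in
any subfamily), at the 94:243 clinical class ratio, with optional label
flips; positions are re-sampled with replacement when more rows are
requested than planted positions exist.

What passing these tests shows — and does not. The planted fixtures
demonstrate that each algorithm recovers exactly the signal its design
targets under controlled conditions; they do not demonstrate performance on
real proteomes, where alignment error, paralog leakage, heterogeneous
rates, correlated sites and structure-determination noise all exist and are
deliberately out of the generators' scope. The packaged 22-row literature
table is the one real-data surface, and it validates only the published
predictions' scoring, not retraining.

## Known limitations

- The profile aligner is a plain global affine-gap scorer, not a calibrated
  probabilistic HMM; its bit scores have no e-value semantics. Exported
  HMMER3 profiles carry fixed documented transition defaults (only
  emissions are reweighted).
- Domain boundaries shipped for the human CaSR are approximate segment
  annotations intended for worked examples.
- The approximate taxonomic condition in subfamily assignment expects a
  precomputed taxon-range mapping; no taxonomy database is consulted.
- Physico-chemical scale values follow the published scale tables, except
  where the package's validation surface fixes a specific printed value.
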