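# Methods

## The model

Solubility here is treated as a property of overall amino-acid composition.
Each standard residue carries a weight *W<sub>i</sub>*; the
Solubility-Weighted Index of a sequence is the mean weight, SWI = ⟨W⟩.  The
score is position- and length-independent by construction: permuting a
sequence or concatenating two sequences changes SWI only through
composition (the concatenation's SWI is exactly the length-weighted mean of
the parts).  A logistic link maps SWI to a probability of solubility,
p = 1/(1 + exp(−(a·SWI + b))).  The bundled calibration
(a = 81.05812, b = −62.7775) was fitted to 12 216 binary *E. coli*
expression outcomes and travels with the bundled final weights; weights
trained on other data are only identified up to a positive affine
transform (AUC is rank-based), so they must be paired with their own
calibration, which `fit_logistic` provides.

Structural flexibility enters in two forms.  The windowed form assigns
position *i* the convex combination

f<sub>i</sub> = [B<sub>i</sub> + 0.8125(B<sub>i−1</sub>+B<sub>i+1</sub>) +
0.625(B<sub>i−2</sub>+B<sub>i+2</sub>) + 0.4375(B<sub>i−3</sub>+B<sub>i+3</sub>) +
0.25(B<sub>i−4</sub>+B<sub>i+4</sub>)] / 5.25,

over normalized B-factors B; the nine coefficients sum to the divisor, so
each f<sub>i</sub> lies between min(B) and max(B) and a homopolymer's
profile equals its B value exactly.  Global flexibility is F = ⟨f⟩; the
simplified form F′ = ⟨B⟩ drops the window entirely.  Only fully covered
windows are scored (positions 5…L−4, 1-based); there are no mirrored or
truncated edge windows, so a profile has max(0, L−8) values and sequences
shorter than 9 residues have no windowed flexibility (reported as NaN).

## Bundled residue scales

`smith2003` (the training pipeline's default initial weights),
`vihinen1994` (the scale behind the standard sliding-window flexibility
implementation and the default for flexibility reporting),
`bhaskaran1988` (an older B-factor-derived flexibility propensity set),
`swi_final` (the published final SWI weights; cysteine is the minimum, as
expected where disulfide bonds cannot form), and `kyte_doolittle`
(hydropathy; GRAVY is its mean).  Each ships as a JSON data file with a
provenance string; floats serialize via `repr` so weight files round-trip
exactly.  The registry is read-only at runtime — user-derived weights
enter only through explicit weight files.

## Training pipeline

`train_swi` (wrapped by `SWISolubilityClassifier.fit`):

1. **Folds.**  Sequences arrive with similarity-cluster identifiers
   (externally computed, or from the bundled greedy clusterer run on
   His-tag-trimmed sequences; training and scoring always use the full,
   tagged sequences).  Whole clusters are assigned to folds by greedy bin
   packing — largest cluster first, into the currently smallest fold, ties
   among equal-size clusters broken by a seeded shuffle — so fold sizes are
   balanced and no cluster ever spans the train/test boundary.  The loop
   asserts this on every run.
2. **Bootstrap.**  Per fold, class-balanced resamples (with replacement;
   defaults 1000 resamples of 1000 + 1000) decouple the optimizer from
   class imbalance and redundant family structure.
3. **Optimization.**  AUC is non-differentiable, so each resample is
   optimized with Nelder–Mead over the 20 weights, objective
   −AUC(composition-scored SWI, labels).  The initial simplex is the
   initial vector plus one vertex per coordinate displaced by 5% of its
   value (floor 0.01); convergence when the simplex function spread falls
   below 1e−6, capped at 5000 iterations.  Because the initial vector is a
   simplex vertex and the method never discards its best vertex, the
   returned weights cannot score below the initial weights on that sample.
4. **Aggregation.**  The fold's optimized vectors average into V_k
   (bootstrap mean first), V_k is evaluated on the training folds and the
   held-out fold, and the final weights are W = ⟨V_k⟩ across folds.

AUC itself is the Mann–Whitney form computed from ranks (ties get half
credit), cross-checked in the tests against an O(n²) pairwise oracle and
an independent library implementation.

The logistic calibration is a capped maximum-likelihood fit; complete
separation of the scores is detected explicitly and flagged as
non-converged rather than returning silently diverged parameters.

## Region analysis

Regions are 1-based inclusive; a region's report scores the extracted
substring only, and regional flexibility uses only windows fully inside
the region.  The boundary optimizer does simulated annealing over
extensions of a seed region: start values in [1, seed start], end values in
[seed end, L] (an `allow_shrink` flag lifts the extension-only restriction),
moves displace either boundary by up to 3 residues, acceptance is
Metropolis on the probability difference (always if Δp ≥ 0, else with
probability exp(Δp/T)), cooling is geometric (T ← 0.95·T from 1.0 down to
1e−4) with 50 moves per temperature.  Ties in the best-region record break
toward shorter regions.  All proposals are cached and scored at most once;
the best-ever region is returned first, then the other distinct accepted
regions by descending probability.  On short sequences the search space is
tiny (≤ 465 regions for L ≤ 40 with a central seed), and the annealer is
checked against exhaustive enumeration.  The schedule values are package
choices; nothing forces them, and they live in `AnnealConfig`.

Tag fusion scoring concatenates tag and target (tag first for N-terminal
fusion).  SWI of the fusion is exactly the length-weighted mean of the
component SWIs, so the terminus affects flexibility profiles but never SWI
or probability.

## Enrichment and random controls

Bit scores are log2 ratios of residue frequencies, group over background,
with frequencies normalized by each group's total residue count.  Residues
with zero frequency on either side are flagged undefined — no pseudocounts,
since smoothing would silently change the statistic.  The random control
generator draws i.i.d. residues on a length grid (defaults 50…6000 step 50,
100 sequences per length = 12 000 sequences), resampling duplicates so the
set is unique; composition defaults to uniform over the 20 residues and can
be set to any table (e.g. background-matched).

## Synthetic data

The generator emulates a homology-clustered binary solubility screen:
each of 20 families descends from an i.i.d.-uniform ancestor (length
100–300) by 10% per-residue substitution; each member's label is Bernoulli
with p = expit(slope · (planted SWI − center)), slope 800, center at the
dataset's median planted SWI, planted weights defaulting to the bundled
final weights.  That slope makes labels strongly but not deterministically
composition-driven (AUC under the planted weights ≈ 0.95–0.98): sd of
planted SWI at these lengths is ≈ 0.009, so slope·sd ≈ 7 logistic units
across one standard deviation.  Labels are per-sequence, so families can be
label-mixed, as real similarity clusters are.  A hard-threshold link with a
margin is available when perfectly separable labels are wanted.

What the generator does *not* emulate: indels and domain structure,
realistic family size or composition skew, continuous solubility
percentages (the logistic probability is exposed as a continuous hook), or
any His-tag artifacts.  Passing recovery tests therefore demonstrate that
the pipeline recovers a planted composition signal under clustered
homology and label noise — not field performance on real screens.

## Problem sizes and determinism

The recovery experiment runs at 400 sequences, 3 folds × 20 bootstraps ×
100 per class — large enough that the recovered weights rank-correlate
with the planted ones at ρ ≈ 0.94–0.98 while the whole experiment stays in
the tens of seconds; the study-scale defaults (10 × 1000 × 1000) remain the
constructor defaults.  Every stochastic component (fold tie-breaks,
bootstrap draws, annealing, generators) takes a seed or Generator, and all
pipeline sub-streams derive from one root seed via `SeedSequence.spawn`, so
reruns are bitwise identical.  Long-sequence means accumulate through
`math.fsum` (exactly rounded) to keep scores platform-stable.

## Known limitations

- Composition scoring ignores residue order entirely; two permutations of
  one sequence score identically even though their folding need not.
- The greedy k-mer clusterer is a deterministic fixture-grade stand-in; it
  makes no claim of equivalence to production clustering tools, whose
  identity definitions differ.
- The bundled calibration assumes the protein expresses at all; it
  estimates solubility conditional on expression.
- Proteolytic removal of a solubility tag can leave an insoluble core;
  fusion scoring does not model post-cleavage behavior.
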