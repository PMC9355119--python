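# Methods

## Problem and modeling approach

Eye irritation and corrosion are contact-driven toxicological endpoints
classified under the UN GHS scheme (Cat 1 irreversible/corrosive, Cat 2A/2B
reversible irritation, NC not classified). oculotox treats hazard
prediction as supervised classification on molecular descriptors: binary
(irritant vs non-irritant, corrosive vs non-corrosive) or three-class
(corrosive / irritant = 2A+2B / NC). Two complementary learners are
provided. The random forest is a conventional global model fitted per
descriptor space. MuDRA (multi-descriptor read-across) fits nothing: it
stores the training instances in several descriptor spaces and, at query
time, reads the label across from nearest neighbors — the approach a
toxicologist's manual read-across automates — which handles
activity-cliff-rich datasets better than a single global decision surface.

## Curation

Structures are normalized with the toolkit's standardizer (canonical
charge-separated nitro form, consistent aromaticity), then counter ions are
stripped: in a multi-fragment structure the largest organic fragment is
kept only when every remaining fragment appears in an explicit,
configurable counter-ion/solvent dictionary (halides, alkali and
alkaline-earth cations, small inorganic acids, water/ethanol/methanol/
acetone/chloroform). Anything else stays multi-fragment and is removed as a
true mixture; fragments without carbon are removed as inorganic. Charges
are neutralized only where valence permits — quaternary ammonium keeps its
charge. Structural identity for deduplication is the canonical,
stereo-aware SMILES computed after standardization; equal-label duplicate
groups collapse to one record, while groups with conflicting labels are
removed entirely (a conflicting in vivo call cannot be adjudicated from
structure). "Similar biological response" is read strictly as label
equality, the only reading available for categorical labels. Curation is
idempotent and order-invariant, and the log reconciles exactly:
input = output + Σ removals.

## Descriptor spaces and feature filter

Three spaces: Morgan circular fingerprints (radius 2, folded to 2048 bits),
the 166 public structural keys (the toolkit emits 167 bits with bit 0
unused; the block drops it), and the toolkit's full whole-molecule
physicochemical set. The physicochemical count is toolkit-version dependent
(210 here) and is recorded in `feature_names` rather than enforced; the
vector is computed from the canonically re-parsed molecule so that
identical structures give bit-identical values regardless of input atom
order. Before modeling, continuous blocks pass a two-stage filter:
zero-variance columns first, then a scan over feature pairs in fixed
feature order dropping the later-indexed member of any pair with
|Pearson r| > 0.9 (raw, unscaled values). The later-drop rule is a
determinism choice; any tie rule satisfies the postcondition that no
surviving pair exceeds the threshold, and the filter is a projection
(re-applying it removes nothing). Bit fingerprints are exempt — the filter
targets the continuous descriptor collections.

## Balancing

Curated toxicity sets are heavily negative-skewed. With n positives, the
balancer selects ⌈n/2⌉ negatives by descending maximum Tanimoto similarity
to any positive (stable tie-break on record order) — deliberately the
hardest, most positive-like negatives, forcing the classifier to separate
close analogues — and ⌊n/2⌋ more uniformly at random (seeded) from the
remainder for chemical-space coverage. The similarity space defaults to the
Morgan fingerprints (the most discriminating bit space here; configurable).
Tanimoto of two all-zero vectors is defined as 0.

## Classifiers

**Random forest**: 500 trees, unlimited depth, square-root feature
subsampling, fixed seed — standard documented defaults, since nothing about
the endpoint argues for tuning. The positive class is called at
probability ≥ 0.5, ties positive: when the evidence is exactly balanced, a
toxicity pipeline should err toward flagging hazard.

**MuDRA**: per space, the k = 5 most similar training compounds cast votes
weighted by similarity — Tanimoto for bit spaces, 1/(1 + Euclidean
distance) on z-scaled features for continuous spaces (a bounded similarity
comparable across spaces). The consensus label is taken from the space
whose top neighbor similarity is highest, i.e. the space in which the query
is best anchored; the prediction's confidence is that space's winning vote
fraction. These mechanics (k, weighting, consensus rule) are this package's
fixed, documented choices for the read-across family — other published
variants differ in weighting details, so all per-space evidence (top
neighbor, similarity, votes) is returned with every prediction to keep the
consensus auditable. An optional similarity floor (default 0) excludes
neighbors below a similarity cut-off; if no neighbor clears it in any
space, the prediction is flagged low-evidence with confidence 0.

## Applicability domain

One global threshold `D_T = ȳ + Z·σ`, where each training compound
contributes its mean Euclidean distance to its k nearest training
neighbors (self excluded) and ȳ, σ are the mean and SD of those values
pooled over the training set — one scalar each, the reading most consistent
with a single-threshold formula. Defaults: Z = 0.5; k = 5 (k is a common
read-across neighborhood size; it is recorded in the fitted state and
exposed in the config since the formula does not fix it). Continuous
features are z-scaled with training statistics before distances; bit
vectors are used raw as 0/1 coordinates. Membership is boundary-inclusive
(distance = D_T is in-domain). Coverage is the in-domain fraction of
assessed predictions and is non-decreasing in Z. MuDRA predictions are
never AD-assessed: an instance-based method carries its own evidence
(neighbor similarities) instead.

## Validation

5-fold external cross-validation: a seeded stratified partition into five
near-equal parts, each part held out once (80/20 modeling/test). Test
compounds take no part in model construction — feature filtering and AD
fitting happen inside the training portion of each fold. Stratification is
a hygiene choice preventing degenerate folds; on balanced sets it is
practically indistinguishable from a purely random equal split. Headline
metrics are computed on the pooled out-of-fold predictions (per-fold
reports are retained; pooled confusion counts equal the per-fold sums).
Y-randomization permutes labels (seeded), reruns the full CV, and repeats
n_rounds = 10 times; mean CCR ≈ 0.5 and mean MCC ≈ 0 confirm the real
model's performance is not chance. Metrics with zero denominators are
reported as undefined (NaN) and skipped, with a warning, in multiclass
averaging — never coerced to 0, which would silently bias averages.
Values are rounded to two decimals only at the presentation layer. The
acceptability gate requires Se, Sp, CCR, PPV and NPV ≥ 0.6 (inclusive).

## Synthetic fixtures

The generator enumerates a small scaffold grammar — alkyl chains C1–C12
crossed with ~40 templates (ethers, esters, amides, ketones, amines,
substituted benzenes/pyridines, glycols, thioethers, piperazines) — into
~3,200 unique, valid structures per class pool. Positives carry a planted
toxophore appended to a grammar base (default sulfonic acid, a classic
corrosive chemotype; sulfonamide and nitro tiers serve the GHS multiclass
fixture); negatives are verified toxophore-free by substructure match.
Labels equal toxophore presence XOR seeded noise, so noise_rate sets the
attainable classification ceiling directly (10% noise caps CCR near 0.9).
Configured rates inject salt forms (recognized counter ions appended),
concordant/discordant duplicates (2:1), inorganics and mixtures, with a
manifest recording exactly what was injected.

What the fixture does *not* emulate: the size, skeletal diversity,
stereochemistry, and activity-cliff structure of real regulatory
inventories, or a mechanistic link between the planted group and biology.
Passing tests therefore demonstrate that the pipeline's machinery —
curation bookkeeping, balancing arithmetic, leakage-free validation, signal
recovery at a known noise ceiling — is correct; they say nothing about
predictive accuracy on real chemicals, which depends entirely on the
training data supplied.

## Problem sizes and numerical choices

The standard test/verification runs use n = 400 compounds (10% noise) for
signal-recovery and Y-randomization checks, and fixtures at 937 and 209
positives to exercise the balancer at the class sizes of interest —
comfortably desk-scale while leaving the arithmetic exact. Brute-force
oracles (all-pairs similarity/distance tables, formula transcriptions) back
the tests on instances of ≤ 50 compounds. Determinism throughout: every
stochastic step takes a seed (fold shuffling, random negative fill, label
permutation, forest construction); stable sorts break similarity ties by
record order; fingerprint spaces are bit-exact by construction.

## Known limitations

- The original regulatory training data is not distributed; models trained
  here are only as good as the data the user supplies.
- Counter-ion dictionary is finite; exotic salts will surface as mixtures
  (visible in the log) rather than being silently stripped.
- MuDRA's consensus is one fixed rule from the read-across design space;
  the per-space evidence is exposed so alternatives can be audited.
- The AD applies to global models only, and a single pooled threshold is
  deliberately coarse — it flags extrapolation, not local reliability.
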