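# Methods

## Problem setting

Given a miRNA expression matrix and an mRNA expression matrix over the same
two-class samples (features × samples, expression units as supplied), a
miRNA→predicted-target map, and optionally UTR/CDS sequences, the package
infers bipartite miRNA–mRNA regulatory modules. The organizing primitive is
the **100%-frequency rule**: a conjunction of closed intervals, one per
feature, covering every sample of one class and no sample of the other.
Such rules capture coordinated expression *changes* between classes rather
than co-expression, which lets the method recover positive as well as
inverse regulation.

## Rule discovery from the miRNA matrix

**Gain ratio.** For a continuous feature, every midpoint between
consecutive distinct sorted values is a candidate binary split. Information
gain is the drop in class entropy; split information is the entropy of the
partition sizes; the gain ratio is their quotient, maximized over
candidates. Entropies are in bits — any fixed base gives the same ranking.
No MDL-style penalty is applied. Constant features score 0. Features with
gain ratio above the cutoff (default 0.5) proceed; ties in the ranking are
broken lexicographically on feature id for determinism.

**t-test.** The per-feature p-value is the classical pooled-variance
two-sided Student's t-test; a `welch` flag switches to unequal variances,
since the variance assumption is a genuinely open choice. The ranking
itself is gain-ratio-driven; p-values are reported, not thresholded, and no
multiple-testing correction is applied at this stage.

**Committee trees.** Decision trees are grown by recursive gain-ratio
splitting (left branch = value ≤ threshold), stopping at pure nodes, at
zero-gain nodes, or at the depth cap (default 2, matching the 2-feature
rule focus; `max_k` is configurable). The committee repeats: fit, record,
remove the root feature, refit — until only two features remain or a tree
fails to split. This forces successive trees to explore different
discriminators.

**Rule extraction.** Every root-to-leaf path whose region contains all
samples of one class and none of the other becomes a rule; mining is done
for both classes. One-sided path tests are converted to two-sided closed
intervals by tightening each bound to the target class's observed
per-feature min/max — the form in which such rules are reported in
practice, and a transformation that preserves purity because the tightened
box is contained in the path region. A pure path shorter than *k* features
(a single miRNA separating the classes outright) is padded to *k* with the
highest-gain-ratio remaining features: adding a feature's class-range
interval keeps every target-class sample and can only exclude other-class
samples, so purity is again preserved. This padding is this package's
design choice for strongly separable data, where depth-1 trees would
otherwise yield no 2-feature rules at all; padded rules are still pure
class-range pair boxes, verifiable by exhaustive search. Duplicate rules
(same feature set and class) are collapsed.

## Rule discovery from the mRNA matrix

For each miRNA rule the mRNA matrix is first restricted to the union of the
rule miRNAs' predicted targets present on the array. Greedy compactness
mining then searches for one rule per class: each remaining attribute
proposes the closed interval spanned by the target class among currently
active samples; its compactness p = N_c/N is the class purity inside that
interval; the most compact attribute is accepted (ties lexicographic), the
active set is restricted, and the loop continues until p = 1 or p fails to
*strictly* increase (interpreting "cannot be improved" as no strict
increase, which rules out plateau loops). Class ranges are recomputed on
active samples each iteration so accepted conditions interact; because
every target-class sample survives every restriction, the class range of
any attribute is in fact invariant across iterations and accepted rules
always cover the full class — frequency is measured against the full class
size and equals 1 by construction. Mining runs in rounds: attributes
consumed by any accepted rule are removed and both classes are retried
(retrying a previously failing class is harmless and keeps termination
simple) until a round yields no rule.

A useful consequence, exercised by the tests: whenever some pure
≤2-condition class-range box exists, the greedy loop cannot stall —
at any plateau at least one member of the pure pair strictly improves
compactness — so rule *existence* always agrees with exhaustive search,
though the mined rule may use different or more attributes.

## Rule scoring

The **Max-Min distance** of a rule is the minimum Euclidean distance
between cross-class sample pairs, computed on raw expression values in the
rule's own feature subspace (the scale on which the rule's bounds are
printed). The **cross-validated AUC** trains a depth-≤2 gain-ratio tree on
the rule's features per stratified fold (seeded shuffling, default 10
folds), scores held-out samples by leaf class-probability, and averages the
per-fold ROC AUC; folds whose test split is single-class are excluded with
a warning, and fold counts exceeding the smaller class size are rejected.
Computing the AUC per rule (rather than per committee tree) is a deliberate
reading: it makes the score attributable to the rule being reported.

## Modules and the merged network

Per miRNA rule, up to two mRNA rules per class (default) are selected,
ordered by mining round, then rule length, then feature ids — earlier
rounds consume the most compact attributes, so round order is the natural
"top rule" ordering; this ordering is a package choice where several are
defensible. Edges run from each rule miRNA to each selected-rule mRNA it is
predicted to target, annotated with the Pearson correlation over the
samples present in both matrices (unpaired columns are dropped with a
logged count; constant profiles yield no correlation rather than 0). Edges
carry the signed correlation rather than a hard inverse/positive label so
the user chooses the sign threshold. Modules merge into one bipartite
network with per-edge module provenance; miRNAs co-occurring in a rule are
exported as a separate `corule` edge type in SIF output. The many-to-many
core keeps mRNAs with at least `min_regulators` (default 3) distinct miRNA
partners.

## Seed scanning and Markov significance

The miRNA seed is taken as positions 2–8 of the mature sequence (7 nt);
seed strings are user inputs — mature sequences are not bundled. A window
on the sense strand matches if it equals the reverse complement of the seed
at ≤ `max_mismatch` positions (default 1), counting Watson–Crick pairs
only; G–U wobble can be enabled by flag but is off by default since the
binding model is plain complementarity. Coordinates are 1-based inclusive.

Significance uses a first-order Markov chain estimated from the scanned
sequence itself: counts of adjacent base pairs (L−1 transitions for a
length-L sequence, so the terminal base starts no transition),
row-normalized to transition probabilities, with the initial distribution
equal to the global base composition. The reported

- `p_exact` is the chain probability of the *observed genomic window*
  (composition[c₁]/L × Π transition probabilities), and
- `p_window` = 1 − (1 − p_exact)^(L−k+1) approximates the probability of
  at least one occurrence of that window anywhere in the sequence.

When sites are matched with a mismatch there is no single canonical
"probability of the complementary site"; scoring the observed window is
the defensible choice, both quantities are labeled, and neither is claimed
to equal any externally printed P value. Zero-count transition rows are
flagged and give probability 0. All matrix output uses base order A, G, U,
C.

## Synthetic data

The generator emulates the structure of a paired two-class expression
study: signal miRNAs drawn from class-shifted Gaussians (defaults: 24/12
samples, 4 signal + 16 noise miRNAs, class gap 10 with within-class SD 0.1
— a gap-to-noise ratio of 100, i.e. cleanly separable classes), target
mRNAs equal to sign × 0.9 × their regulator plus Gaussian noise with
alternating inverse/positive signs (3 targets each), iid noise mRNAs, a
target map with 2 decoy targets per miRNA, random 7-nt seeds, and 120-nt
UTRs with one planted seed-complementary site per coupling (1 mismatch at a
uniform position; 5' UTR for positive couplings, 3' UTR for inverse ones).
A single integer seed fully determines the output, and the ground truth
(signal ids, coupling signs, seeds, site positions) is returned alongside
the five artifacts.

What it does **not** emulate: microarray technical artifacts, dye bias,
replicate structure, heavy-tailed or correlated noise, partially paired
samples, or realistic UTR length/composition. Passing the recovery tests
therefore demonstrates correctness of the algorithms under their stated
assumptions, not performance on real microarray data.

## Numerical choices and degenerate inputs

- Entropy base 2 everywhere; gain-ratio threshold ties resolved toward the
  smallest threshold; feature ties lexicographic.
- Interval bounds are closed on both ends; boundary samples are covered.
- Constant feature → gain ratio 0; zero-variance t-test → p = 1 (equal
  means) or 0; constant vector in Pearson → error, never silently 0.
- Missing labels, duplicate ids, non-numeric or non-finite cells are hard
  parse errors; no imputation anywhere (100%-frequency rules are
  meaningless on repaired data).
- Expression values are used exactly as supplied — any normalization or
  log transform belongs upstream. CSV round-trips are bit-identical
  (round-trip float parsing).
- One global pipeline seed fans out to per-stage seeds by fixed offsets, so
  adding a stage never changes earlier stages' randomness.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run entirely on generated data:
200 random matrices of ≤12 features × ≤40 samples for the miner-vs-oracle
comparison, 20 planted simulations (36 samples, 20 miRNAs, 32 mRNAs) for
end-to-end recovery, 100 null simulations (class gap 0, 20 features) for
the false-discovery check, and 20 random transition matrices for Markov
normalization — sizes chosen so the whole verification runs in seconds
while every combinatorial regime (pure/no-rule, single/pair separability,
tie-breaks) is exercised.

## Known limitations

- The committee-tree miner is heuristic: it emits a subset of all pure
  2-feature boxes (exhaustive enumeration is the oracle in tests, not the
  production path).
- Greedy mRNA mining guarantees rule existence matching exhaustive
  ≤2-condition search, but not minimal or unique rule composition; mined
  counts can depend on tie-breaking.
- 100%-frequency is a stringent criterion appropriate for strongly
  separated classes; for noisier designs the frequency threshold would need
  relaxing (not currently exposed).
- Pearson correlation only (no rank correlation), raw p-values only, and
  no multiple-testing correction, by design of the method being
  implemented.
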