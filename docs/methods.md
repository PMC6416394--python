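# Methods

## Model and assumptions

The interactome is an undirected, unweighted graph of physical
protein–protein interactions; all distances are shortest-path hop counts.
Two modelling assumptions drive everything downstream: (i) disease proteins
form a localized neighborhood (disease module) in this graph, and (ii) a
drug's mechanism is summarized by the network footprint of its binding
targets. Dosage, directionality of regulation and edge confidence are
outside the model.

A drug–disease relationship is measured by the closest distance
`d(X, Y) = (1/‖Y‖) Σ_{y∈Y} min_{x∈X} d(x, y)` — note the average runs over
the disease proteins only, so the measure is deliberately asymmetric — and
standardized as `z = (d − μ)/σ` against distances between random protein
sets degree-matched to both `X` and `Y`. A drug–drug relationship is
measured by the separation `s_AB = ⟨d_AB⟩ − (⟨d_AA⟩ + ⟨d_BB⟩)/2`, with
`⟨d_AB⟩` the *symmetric* closest distance (each target to the nearest
target of the other drug, averaged over |A| + |B| terms; shared targets
contribute zero). The drug–drug "closest" baseline (two-sided) and the
drug–disease distance (one-sided) are intentionally not harmonized; both
are implemented exactly as defined.

The classifier is a pure sign function: `(s_AB < 0?, z_A < 0?, z_B < 0?)`
maps to the six exposure classes, with the boundary values `s_AB = 0` and
`z = 0` assigned to the "separated"/"not exposed" branches. Predictions
are the Complementary-Exposure (P2) pairs sorted by increasing `s_AB`,
with ties broken by the canonical (lexicographic) pair id; a secondary
score combining the z-scores is deliberately not used in ranking.

## Degree-preserving randomization

Random reference sets are drawn from degree bins: nodes are grouped by
exact degree, then groups are merged from the highest degree downward until
every bin holds at least `min_bin_size` nodes (default 100 on real-scale
networks; 30 on the 180-node test fixtures). Sampling is without
replacement within a bin, falling back to with-replacement (logged) only
when a template demands more nodes than a bin holds. Both the target set
and the disease set are re-drawn every iteration; `randomize="drug"`
restricts randomization to the drug side. `n_random` defaults to 1000;
`μ` and `σ` are the plain mean and (population) standard deviation of the
reference distances. `σ = 0` yields `z = NaN` — an explicit undefined
sentinel, never ±∞ — and such records are excluded from classification and
reported, never silently classified.

Per-drug z-scores are computed once per (drug, disease) and shared across
all pairs, both for speed and consistency; each drug draws its own RNG
stream from `SeedSequence([seed, crc32(drug_id)])`, so results are
independent of evaluation order and reproducible bit-for-bit.

## Unreachable pairs and degenerate inputs

The graph need not be connected. Every average skips infinite distances
and counts the skips (`n_skipped` in output tables); a quantity with no
finite contribution becomes NaN and propagates to "unclassifiable". The
within-set distance `⟨d_AA⟩` of a singleton target set is defined as 0, so
two distinct single-target drugs get `s_AB = d(a, b)`. In the kernel
measure, unreachable pairs contribute zero weight (`e^{−∞}`); in the
centre measure, candidate centres are ranked by (number of reachable set
members, total distance), so a node that reaches more of its set wins over
one with a smaller sum across fewer members; tied centres are all kept and
centre–centre distances averaged. Restriction to the largest connected
component is available (`--lcc`) but off by default.

## Data filters

Drug–target tables are filtered to binding affinities (Ki, Kd, IC50, EC50)
≤ 10 µM; rows without a numeric affinity (curated interactions) are kept
unless `require_affinity` is set, and a (drug, target) pair survives if
*any* of its records passes. Drugs need at least `min_targets = 2` targets
after affinity filtering (applied before network mapping); drugs left
without in-network targets are excluded and reported. Identifiers are
trimmed, case-preserving strings; cross-vocabulary mapping is the data
preparer's job.

## Similarity metrics

Tanimoto similarity of equal-length fingerprints is `c/(a + b − c)`, with
two all-zero fingerprints defined as 0 (the formula is 0/0; zero encodes
"no evidence of similarity"). Sequence, co-expression and GO similarities
average over cross pairs `a ∈ A, b ∈ B, a ≠ b`, so a target shared by both
drugs is never compared with itself; a pair with no admissible comparison
returns NaN. Sequence similarity uses Smith–Waterman local alignment
(BLOSUM62, gap open 10, extend 0.5, all configurable). The default
per-pair score is the self-score-normalized alignment score
`SW(a,b)/√(SW(a,a)·SW(b,b))`: unrelated random sequences score ≈ 0.06 and
identical ones 1.0. Percent identity over the optimal local alignment is
available (`method="identity"`) but not the default, because the optimal
*local* alignment of two unrelated sequences is a short high-scoring
segment whose identity averages ≈ 0.3 — it does not approach zero for
unrelated inputs and therefore makes a poor dissimilarity baseline.
Co-expression similarity is the mean |Pearson r| across tissues, optionally
restricted to gene pairs that are interactome edges (the noise-reduction
mapping; on whenever a network is supplied). GO similarity is Wang's
semantic-contribution measure (edge weights 0.8 for `is_a`, 0.6 for
`part_of`) combined by best-match averaging; the test suite pins it to a
hand-worked toy-DAG table. ATC similarity averages level-wise prefix
agreement over the five code levels, and over all code pairs for
multi-code drugs. Overlap statistics use the exact hypergeometric tails
for enrichment (`P[X ≥ c_obs]`) and depletion (`P[X ≤ c_obs]`).

## Evaluation statistics

Because negatives are unreported, the balanced AUC samples `|positives|`
unknown pairs per repeat (without replacement), computes the ROC AUC of the
score ranking (midrank tie handling; `lower_is_better=True` for `s_AB`) and
averages over 100 repeats. Class enrichment of a labelled pair set uses a
permutation test: the null redraws equally many pairs uniformly from the
classified universe; `p = (1 + #{null ≥ obs})/(1 + n_perm)` (add-one
estimator, so the smallest reportable p at 10,000 permutations is
≈ 1.0 × 10⁻⁴). Bootstrap controls draw equal-sized adverse-DDI sets,
without replacement within a draw by default.

## The synthetic fixture generator

Fixtures are stochastic block models of six equal 30-node communities,
each split into two 15-node sub-clusters (edge probabilities: 0.55 within
a sub-cluster, 0.10 between sub-clusters of one community, 0.006 between
communities), with one community acting as the disease module and drugs
planted as 4-target sets — sizes chosen to mimic the few-targets-per-drug,
dense-module regime of real drug–target data. The two-sub-cluster
structure is what makes the planted classes recoverable: a drug in either
disease sub-cluster is closer to the disease proteins than degree-matched
random sets (all communities share one degree profile, so random sets mix
communities), giving z ≈ −5, while drugs in a distant community give
z ≈ +4; two drugs in different sub-clusters are separated (s ≈ +0.5 to
+1) while a drug copying ≥ 50% of another's targets overlaps it (s < 0).
Same-module disjoint pairs hover at the s = 0 boundary and are therefore
excluded from the ground-truth table. Expected z signs, s signs and
exposure classes are emitted alongside the data, and generation is a pure
function of the spec: sub-seeds derive from (seed, component name), and a
draw whose largest component covers < 90% of the nodes is regenerated
under an incremented sub-seed (logged).

What the fixtures do *not* emulate: scale-free degree heterogeneity, the
size of the real interactome (16k proteins), hub-mediated short paths,
noisy disease-gene annotations, and correlated multi-database target
evidence. Passing the recovery tests therefore demonstrates correctness of
the statistics and classifier under a controlled geometry, not predictive
performance on real pharmacology.

## Problem sizes used in tests and the acceptance script

Oracle-equivalence checks run all five set measures against independent
brute-force implementations (dense Floyd–Warshall plus literal-definition
loops) on 1,000 seeded random graphs of ≤ 12 nodes at 1 × 10⁻¹² tolerance.
Recovery runs 20 fixture seeds with `n_random = 100` and
`min_bin_size = 30`. Calibration uses 8 independent null-score draws for
the balanced AUC and 200 null permutation runs at `n_perm = 199`. The
acceptance script's planted benchmark uses 15 drugs (five per disease
sub-cluster, five distant) → 105 pairs, 25 planted positives, 100 AUC
repeats and 10,000 permutations. These sizes give stable statistics while
keeping the whole suite in the tens of seconds.

## Known limitations

Unweighted distances treat all interactions as equally reliable; the
z-score inherits the degree-binning resolution (coarse bins blur the
reference distribution); the separation score is undefined in sign terms
for drugs whose targets coincide almost exactly with the disease module
boundary; and the exposure classes are hard sign thresholds — pairs near
`s_AB = 0` or `z = 0` flip class under small data perturbations. The
ranking deliberately uses `s_AB` alone.
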