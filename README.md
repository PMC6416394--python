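# netcombo

Network-based prediction of efficacious drug combinations on the human
protein–protein interactome.

Drug combinations treat complex diseases such as hypertension and cancer,
but the space of candidate pairs is combinatorially large and true negatives
are essentially unreported. `netcombo` implements a mechanism-driven,
network-medicine screen: it quantifies where each drug's targets sit
relative to a disease's protein module in the interactome, classifies every
drug–drug–disease triple into one of six *exposure classes*, and ranks the
**Complementary Exposure** pairs — both drugs inside the disease module, but
with topologically separated target neighborhoods — as predicted efficacious
combinations. Overlapping-Exposure pairs are flagged as candidate adverse
interactions.

## The two core statistics

**Drug–disease proximity z-score.** For drug targets *X* and disease
proteins *Y* on the interactome, the closest distance is

    d(X, Y) = (1/‖Y‖) Σ_{y∈Y} min_{x∈X} d(x, y)

with *d(x, y)* the unweighted shortest-path length. The observed *d* is
standardized against a reference distribution of distances between random
protein sets that match *X* and *Y* in size and degree distribution
(degree-binned sampling): `z = (d − μ)/σ`. `z < 0` places the drug's
targets inside the disease neighborhood.

**Drug–drug separation.** For two target modules *A*, *B*:

    s_AB = ⟨d_AB⟩ − (⟨d_AA⟩ + ⟨d_BB⟩)/2

where `⟨d_AB⟩` is the symmetric closest distance between the sets (shared
targets contribute 0) and `⟨d_AA⟩`, `⟨d_BB⟩` are within-set
nearest-neighbor means. `s_AB < 0` — overlapping network footprints;
`s_AB ≥ 0` — topologically separated.

The sign pattern `(s_AB, z_A, z_B)` yields six classes: P1 Overlapping,
P2 Complementary, P3 Indirect, P4 Single, P5 Non-exposure, P6 Independent
Action. Only P2 is associated with therapeutic efficacy; predictions are
P2 pairs ranked by increasing `s_AB`.

The package also implements the surrounding toolkit: four alternative
set-distance baselines (closest, shortest, exponential kernel, topological
centre), five pharmacological similarity metrics (MACCS-style fingerprint
Tanimoto, Smith–Waterman target-sequence similarity, cross-tissue
co-expression, Wang GO semantic similarity, hierarchical ATC clinical
similarity), target-overlap statistics with exact hypergeometric tails,
balanced-resampling ROC/AUC, permutation enrichment tests and bootstrap
controls, plus a deterministic planted-module fixture generator so the whole
pipeline is testable without any data download.

## Worked example

Generate a synthetic planted-module interactome (six 30-node communities,
one of them the disease module; five planted drugs) and run the classifier:

```bash
netcombo simulate --seed 7 --out demo
netcombo classify --network demo/interactome.tsv \
    --drug-targets demo/drug_targets.tsv \
    --disease-genes demo/disease_genes.txt \
    --n-random 200 --min-bin-size 30 --seed 7 --out demo/run
# classified 10 pairs: 2 P2 predictions, 1 P1 adverse flags
```

`demo/run/exposure.tsv` (abridged):

```
drug_a  drug_b  s_ab    z_a     z_b     exposure_class
drugA   drugB    0.75   -5.17   -5.00   P2
drugA   drugC   -1.00   -5.17   -5.16   P1
drugA   drugD    2.12   -5.17    3.88   P4
drugD   drugE   -0.75    3.88    3.92   P5
```

drugA and drugB were planted in the two sub-clusters of the disease
community: both hit the disease module (z ≈ −5) while their targets stay
separated (s = 0.75), so the pair is classified Complementary Exposure and
appears first in `demo/run/predictions_p2.tsv`. drugC copies most of
drugA's targets (s = −1.0 with both z < 0 → Overlapping Exposure, flagged
as a candidate adverse interaction in `adverse_flags_p1.tsv`). drugD and
drugE sit in a distant community (z ≈ +3.9): paired with an in-module drug
they are Single Exposure (P4), paired with each other Non-exposure (P5).

The same operations are available as library calls
(`netcombo.separation`, `netcombo.proximity_z`, `netcombo.classify_all`,
`netcombo.rank_complementary`, …), which the CLI wraps thinly.

## Applying it to real data

The loaders consume plain delimited text: a two-column PPI edge list, a
long-format drug–target table (drug, target, affinity type, affinity in
µM — rows above 10 µM are dropped and drugs need ≥ 2 surviving targets),
one-gene-per-line disease gene sets, and two-column benchmark pair lists.
`tests/test_acceptance.py::test_published_corpus_reproduction` documents
the expected corpus statistics when the full published interactome and
drug–target tables are placed under `data/full/` (those tables are not
redistributed here).

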