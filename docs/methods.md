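# Methods

This note documents the models, conventions and parameter choices behind
`darkpath`, in the order the pipeline runs them, together with what the
synthetic study does and does not demonstrate.

## Pathway model and reference FIs

The pathway database is a reaction-level event hierarchy: pathways contain
sub-pathways and reactions; reactions connect physical entities (proteins,
complexes, entity sets, small molecules) through input, output, catalyst,
activator and inhibitor roles. The on-disk format is a versioned JSON
document validated on load (referential integrity, acyclic hierarchy,
pairwise-disjoint role lists). Gene symbols are uppercased at load and all
gene pairs are stored as lexicographically sorted 2-tuples.

Reference functional interactions are extracted with three rules: all
pairs of distinct protein components within a complex (nested complexes
and sets flattened), all input–input pairs of a reaction, and all
input–catalyst pairs. Regulator–input pairs are excluded by default
(`include_regulators=True` adds them) because regulation edges are
directional while the FI set is undirected. These rules reproduce the
dominant pair classes of curated-pathway FI extraction while remaining
auditable; the exact historical rule set is not restated anywhere
authoritative, so the choice is exposed as configuration.

## Expression processing

Bulk-style counts pass through: (1) removal of samples with RIN ≤ 6.0
(boundary inclusive) and of groups left with fewer than 30 samples; (2)
PCA outlier flagging on log₂(cpm+1) with genes centered — the sample score
is its loading on PC1, the component is oriented so the heavier tail is
positive, and samples with standardized score z ≥ 3 are flagged; (3)
counts-per-million normalization and pairwise Spearman correlation.
Constant genes get missing correlations, never zeros. Spearman is
rank-based, so cpm vs log-cpm is immaterial.

Top-percentile pair selection returns exactly ⌈pct/100 · P⌉ pairs over the
P non-missing off-diagonal pairs, with ties broken by (value descending,
pair key ascending) for reproducibility.

## Odds-ratio vetting

Each binary channel is cross-tabulated against the reference FIs over the
pair universe (all unordered pairs over the database's genes by default —
the appropriate background is genuinely ambiguous, so it is an argument).
Zero cells receive the Haldane–Anscombe +0.5 correction on all four cells
so sparse channels still get a finite ratio. Retention requires OR
strictly greater than 5.0.

## FI classifier

`FIClassifier` is a scikit-learn estimator wrapping a random forest with
the production configuration as defaults: 200 trees, `max_depth=10`,
`class_weight='balanced'`, `min_samples_leaf=1`, `min_samples_split=2`,
`random_state=42`. Training pairs are reference FIs (positives) plus
uniformly sampled non-FI pairs; the default negative:positive ratio is
100:1 where the pair universe allows it (the synthetic pipeline uses 10:1
because its universe of ~7,000 pairs cannot support 100:1 without
exhausting the non-FI pool). Evaluation repeats ten stratified 75/25
splits and averages AUC, precision, recall and F1; the final model refits
on all data. A grid search over the ensemble hyperparameters is available
but off by default. Persisted models embed their channel names and refuse
to score feature matrices with mismatched columns. Predicted FIs are
pairs with score ≥ 0.8 (inclusive).

## Enrichment score

For a gene with n predicted partners inside the background universe
(default: all genes in the database), each pathway of size K in a universe
of N genes is tested with the one-sided upper tail of Binomial(n, K/N) at
the observed overlap k; k = 0 gives exactly 1. P-values are BH-adjusted
across pathways *within* the gene (multiple testing is per-protein, not
global), and the enrichment score is −log₁₀ FDR with the FDR floored at
1e-300 to keep scores finite. The BH step delegates to
`statsmodels.stats.multitest.multipletests`; the test suite checks it
against an independently hand-written step-up implementation.

## Fuzzy-logic simulation

A pathway compiles to a bipartite network: entity nodes carry activities
in [0, 1], reaction nodes transfer them. Updates are synchronous. A
reaction's firing level is min over the Hill-transformed activities of its
inputs and catalysts, multiplied by ∏(1 − hill(inhibitor)), and
max-combined with hill(activator) terms. A produced entity takes the max
firing level over its producing reactions; source entities are clamped.
Defaults: Hill K = 0.5, n = 4 (a symmetric sigmoid with midpoint 0.5),
100 steps, convergence tolerance 1e-6.

The default initial state sets every entity to 1.0 — a fully active
resting baseline. This deviates from the "sources 1, produced 0"
alternative deliberately: with dead produced entities, AND-gated reactions
never fire, the baseline fixes at zero, and every inhibition impact is
structurally zero. A live baseline lets both perturbation directions
register. Initial state remains configurable per call.

Perturbation injects each partner's FI score s onto its protein entity
node every step: activation max-combines s with the computed activity,
inhibition multiplies by (1 − s). Both keep activities in [0, 1] and make
s = 0 the exact null. Because FI direction is not predicted, a gene–
pathway pair is scored twice — all partners assumed activating, then all
assumed inhibiting. The impact on an output entity is
(AUC_perturbed − AUC_baseline)/T with trapezoidal AUC over the shared
fixed horizon (comparison runs disable early convergence so traces align),
and the reported activation/inhibition score averages impacts over the
deduplicated set of reaction-output entities. Impacts are reported signed;
min–max scaling to [0, 1] for display is provided separately.

## Literature annotation score

Abstracts match a gene when any alias occurs as a word-boundary-delimited
token; all-uppercase aliases (gene symbols) match case-sensitively, other
aliases case-insensitively — a minimal rule that avoids symbol hits inside
longer tokens without a full NER system. A pathway's text representation
is the embedding of its own summation plus the summations of every event
inside it (events without text are skipped, not zero-filled); similarity
to an abstract is the mean cosine over those event embeddings. For a
gene–pathway score, the gene's matched abstracts are ranked by mean
similarity across all pathways under analysis, at most k = 1,000 kept, and
the score is the mean similarity of the kept abstracts to the target
pathway. Genes with no matched abstract get a missing value, never zero.

Embedding providers are pluggable behind a two-member contract (`dim`,
`embed`). The package ships a deterministic hashing embedder — token
hashing via blake2b into per-token pseudo-random vectors, summed and
normalized, 384 dimensions — used by all tests, and an optional wrapper
for sentence-transformer models where that package is installed. The
hashing embedder captures token overlap only, not meaning: synthetic
corpora must plant topical similarity as shared vocabulary.

## Validation statistics

Per-gene agreement between two scoring channels intersects the two score
vectors' pathway ids, requires at least 10 shared pathways, and computes
Pearson r with a two-sided p-value; zero-variance vectors are missing.
The skew summary counts positive vs negative r (exact two-sided binomial
test against 0.5) and compares −log₁₀ p and |r| between the sign groups
with both Welch t and Mann–Whitney (the choice between them is left to
the caller; both are reported). Group comparisons (Welch t, one-way
ANOVA, Mann–Whitney) delegate to scipy; identical constant groups are
reported as no effect (p = 1) instead of NaN.

In the agreement experiment each channel contributes, per gene, its
*interacting pathways*: pathways whose enrichment FDR is below 0.05. The
correlation is computed over pathways significant in both channels. This
is what makes the null well-behaved: correlating complete score vectors
padded with zeros produces a systematic negative sign bias (a sparse
spike vector against a zero-inflated, right-skewed vector is below its
mean more often than above), an artifact we verified by permutation. The
co-expression channel of the experiment uses the top 10% positively
correlated pairs — at 200 genes this reproduces the per-gene partner
density that a top-0.1% cut yields at transcriptome scale.

## Synthetic study design

The generators are pure functions of (config, seed); every byte of output
is reproducible.

- **Pathway database.** Disjoint gene blocks per top-level pathway; a
  chain of reactions whose co-participants (second substrates, catalysts,
  occasional inhibitors) are drawn from anywhere in the block; a closing
  complex of up to four members. The chain is covered by eleven
  overlapping reaction-window sub-pathways per top-level pathway,
  emulating the redundancy of curated hierarchies where one biological
  module appears as many nested entries — this redundancy is what lets a
  single module give a gene ten or more significantly enriched pathway
  entries, as required for the correlation analysis. Defaults: 120 genes,
  6 pathways of 6–14 genes, 30% tagged Tdark.
- **Feature channels.** Channel i contains each FI pair with probability
  p₁ (coverage) and each non-FI pair with the probability that makes the
  expected odds ratio hit its target. Default coverages descend from 0.56
  to 0.20 across six informative channels — mirroring the coverage ladder
  of real feature collections where GO-process sharing covers over half of
  the positives — with odds-ratio targets 40 down to 6, plus two null
  channels at OR 1. Empirical odds ratios land within ±30% of target.
- **Expression.** Poisson-lognormal counts: gene i has log-mean
  base_i + 0.8·x_i with x mixing a per-pathway latent factor (weight
  √ρ, default ρ = 0.7) and white noise. Planted features: one sample with
  RIN 5.0, a five-sample under-sized group, and one sample displaced on
  half the genes (the PCA outlier).
- **Corpus.** Every pathway-member gene receives an equal number of
  abstracts mentioning its symbol; at least one per gene is on-topic
  (reuses the pathway summation's topic tokens), the rest use filler
  vocabulary. With the hashing embedder this plants a recoverable
  pathway–literature signal.
- **Agreement experiment.** 200 genes, 13 pathways of 12–15 genes,
  200 cells; the FI channel uses the curated reference FIs directly,
  isolating the scoring stages from classifier noise. Setting ρ = 0
  removes the planted agreement: almost no gene then has 10 pathways
  significant in both channels, and no positive skew remains.

What passing on this study shows: the implementation recovers planted
structure of realistic shape at desk scale, every stage is internally
consistent against independent oracles, and the whole chain is
deterministic. What it does not show: performance on real data — real
feature channels are noisier and correlated with each other, real pathway
hierarchies are deeper and overlapping in gene content, real literature
is not bag-of-words, and the published full-scale figures (classifier AUC
0.89 on curated-database positives, the specific correlation magnitudes
and p-values) depend on those full-scale inputs.

## Numerical conventions and degenerate inputs

- Pair keys: uppercased, lexicographically sorted, self-pairs rejected.
- Odds ratio: +0.5 on all cells only when some cell is zero.
- Binomial tail via `scipy.stats.binom.sf(k−1, n, K/N)`; invalid counts
  raise.
- FDR floor 1e-300 before −log₁₀.
- Min–max scaling of a constant vector returns all 0.5 (documented
  convention for display-style comparisons).
- Empty filter results warn rather than failing silently; genes without
  partners or abstracts yield empty/missing results with a warning, never
  fabricated zeros.
- Model persistence is a versioned joblib blob with embedded channel
  names; loading refuses on version or channel mismatch.

## Known limitations

- The fuzzy-logic update rule, initial state and perturbation semantics
  are declared conventions (configurable), not a reconstruction of any
  specific published simulator; absolute simulation-score magnitudes are
  therefore not comparable across rule choices.
- Negative sampling treats unannotated pairs as negatives; some are
  surely true interactions, which biases measured precision downward.
- The enrichment background defaults to the database's own gene universe;
  against a genome-wide background the scores would shrink.
- The hashing embedder is a token-overlap model; it validates plumbing
  and ranking logic, not semantic retrieval quality.
- `build_training_set` materializes the non-FI pair list in memory, which
  is fine up to a few thousand genes but not at transcriptome scale.
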