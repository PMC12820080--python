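# Methods

## Pipeline overview

`semharm` treats rating-scale items as short documents.  Each item's
description is preprocessed (illustrative parentheticals stripped,
lowercased, whitespace collapsed), embedded, and compared by cosine
similarity.  Downstream stages consume only the similarity matrix and the
item metadata, so the embedding backend is pluggable behind a single
contract (deterministic map from text to a fixed-width vector).

### Preprocessing

Only parenthetical groups whose content begins with `e.g.` or `i.e.`
(case-insensitive) are removed.  Rating scales use parentheses for two very
different things: illustrative patient examples, which dilute the item's
core meaning, and synonym lists such as "(Word salad, Jargon Aphasia)",
which *are* core meaning.  A prefix rule separates the two without a parse;
extra prefixes are configurable.  The rule is idempotent and re-scans after
each removal so a stripped group cannot shield a nested one.  Word counts
are whitespace-token counts of the raw description, taken before any
preprocessing, so they are invariant to the cleaning flags.

Construct description paragraphs are embedded exactly as given, without
illustrative stripping: in construct definitions the `e.g.` clauses carry
the named phenomena themselves.

### Embedding backends

- **Reference backend**: the published `all-mpnet-base-v2`
  sentence-transformer (768 dimensions).  If the `sentence-transformers`
  package or the weights are unavailable, construction raises
  `BackendUnavailableError`; there is deliberately no silent fallback, so a
  result can always be attributed to the backend that produced it.
- **Mock backend**: tokens are hashed (BLAKE2, stable across processes)
  into 4,096 count slots; the count vector is multiplied by a Gaussian
  projection matrix generated from the seed alone and L2-normalized.
  Texts sharing more tokens have higher expected cosine; disjoint texts are
  near-orthogonal at the default 256 dimensions.  The mock is not a
  language model — it captures lexical overlap, not meaning — but it is
  bitwise deterministic, which is what the offline tests and the synthetic
  study need.

### Similarity

Cosine similarity is reported under three maps: `raw_cosine` (identity),
`clip01` (`max(0, cos)`, the default) and `affine01` (`(cos+1)/2`).  The
default preserves the numeric value of the (almost always positive)
cosines of natural text while keeping the stated [0, 1] range; `affine01`
is offered where strict monotonicity over negative cosines matters.  The
matrix is symmetrized exactly (`(S + Sᵀ)/2`) and the item-level diagonal is
pinned to 1.  Scale-level matrices put centroid cosines off-diagonal and
the mean pairwise within-scale item cosine on the diagonal (self-pairs
excluded); a single-item scale has no within-scale consistency and gets a
NaN there.

### Backbone sparsification and clustering

Every non-backbone item keeps exactly one edge: its highest-similarity
link into the backbone scale.  Backbone items keep one edge to their most
similar other backbone item (`include_intra_backbone=True` by default) —
without some intra-backbone linkage every cluster would contain exactly
one backbone item by construction.  Exact similarity ties resolve to the
earliest item in bank order and are flagged on the edge rather than broken
silently.  Clusters default to connected components (parameter-free,
deterministic); weighted greedy modularity is available where finer
communities are wanted.  Labels are assigned 1..K by descending cluster
size, ties by smallest member id.  The number of clusters is emergent and
never forced.

A structural property worth knowing: with top-1 intra-backbone linkage the
component structure of the whole graph equals that of the backbone's
nearest-neighbour subgraph, because every outside item hangs off a single
backbone node.  Top-1 nearest-neighbour graphs over roughly exchangeable
points fragment easily (for 5 such points the graph is connected only
about 57% of the time, by simulation), so a semantic group anchored by
several backbone items can split into two clusters even when the
underlying similarities are clean.  This shows up in the synthetic study
as occasional splinter clusters beyond the generating themes and is the
main driver of run-to-run variability in cluster recovery; see
Limitations.

### Agreement statistics

Fleiss' kappa with counts `n_ij` (raters per item × category):

    P_i = (Σ_j n_ij² − m) / (m(m−1));  P̄ = mean_i P_i
    p_j = Σ_i n_ij / (Nm);             P̄_e = Σ_j p_j²
    κ   = (P̄ − P̄_e) / (1 − P̄_e)
    κ_j = 1 − Σ_i n_ij(m − n_ij) / [N m (m−1) p_j (1 − p_j)]

Standard errors are the classic large-sample forms (Fleiss–Nee–Landis):
the null-style variance for the overall κ and `sqrt(2 / (N m (m−1)))` per
category; confidence intervals are κ ± z·SE at a configurable level
(default 95%).  For k = 2 the per-category kappas collapse onto the
overall κ exactly, which the tests exploit as a consistency check.

The machine clustering can be folded in as one extra rater, which is the
reading that yields a single pooled statistic with per-category values.
Machine clusters are anonymous integers while experts rate against named
group descriptions, so the correspondence is recovered by majority vote
(`majority_machine_map`) before folding in.  The per-item human-vs-machine
view is served separately by `disagreement_ranking` (share of raters
matching the machine label, descending).

### Clinical alignment

Items that no participant scored above zero are removed (as are
zero-variance constant columns, flagged separately — correlation is
undefined there).  Each backbone item is then paired with the partner-scale
item of maximal *signed* Pearson correlation (Spearman optional): the
pairing is meant to capture phenomena that co-occur, and an absolute-value
rule would pair clinical opposites.  Excluded items are excluded from
candidacy as well.  Patients and controls are pooled; a group filter exists
but the default mirrors computing correlations across the whole sample.

The co-cluster count is tested with the exact one-sided binomial upper
tail, computed in exact rational arithmetic for n ≤ 64 (rounded to float
once, at the end) and via the regularized survival function above that.
The default chance level is flat, 1/(number of clusters); a
size-weighted alternative (Σ share²) is provided since flat chance ignores
unequal cluster sizes.

## Synthetic data generator

The generator provides ground truth for every stage:

- **Item banks.** Four themes, each with a 20-word core vocabulary
  (pairwise disjoint, disjoint from a 30-word shared filler pool).  An item
  of length L draws ⌈wL⌉ tokens from its theme's core vocabulary and the
  rest from filler; the mixing weight w (default 0.8) controls
  between-theme separation monotonically — at w = 1 themes share no content
  words, at w = 0 themes are unrecoverable.  Default layout: 7 scales with
  5/7/4/3/1/2/3 items per theme (100 items), the backbone scale sized like
  a real 20-item instrument.  Per-scale text lengths are deliberately
  uneven (95/30/14/90/40/20/25 tokens) to mirror how unevenly real
  instruments document their items: two verbose scales, one terse, the
  rest mid-range.
- **Expert raters.** Each of m raters (default 6) labels each item with its
  true theme with probability a (fidelity, default 0.9), otherwise
  uniformly over all k categories — including the truth, so the effective
  correct probability is a + (1−a)/k.  This matters when building
  Monte-Carlo oracles for the expected kappa.
- **Participant ratings.** Per participant, one latent severity per theme,
  s_t ~ N(0,1); item score λ·s_theme + σ·ε (defaults λ = 0.8, σ = 0.5),
  discretized to 0–4 at equal-probability cut points of the marginal
  N(0, λ²+σ²) — simplicity over realism in the threshold placement.
  Zero-inflation is applied after discretization (so planted all-zero
  columns are exact), with a higher zero rate for controls (0.3) than
  patients (0.1), giving patients the higher mean total score.  Default
  sample: 200 participants, half patients.

What the generator does *not* emulate: linguistically realistic psychiatric
prose (the mock backend only sees token overlap anyway), item severity
anchors, rater covariates, hub-structured themes in which one prototypical
item is everyone's nearest neighbour, and diagnosis heterogeneity.
Passing tests therefore demonstrate that the machinery is correct and that
recovery behaves sensibly under a known data-generating process — not that
any particular real-world corpus will cluster into four groups.

## Determinism and seeds

Every random choice flows from explicit integer seeds;
`numpy.random.default_rng` streams are derived per stage by hashing the
stage name (`stage_seed`), so stages are independently reproducible and a
full pipeline run is byte-identical across repetitions.  The bank text and
the ratings use distinct streams from the same config seed.

## Problem sizes used in the test suite

The distribution-level checks use 100-item banks at mock dimension 256:
20 seeds for cluster-recovery medians, 100 replicates for the end-to-end
alignment study, 10,000 vectorized replicates for the kappa Monte-Carlo
expectation, 1,000 random tables for the kappa formula oracles, and 200
random fixtures for the graph-construction oracles.

## Known limitations

- Embedding similarity conflates antonyms: severity anchors phrased as
  opposites ("too slow" / "too fast") embed as near-duplicates in
  transformer models, so polarity distinctions that hinge on direction
  rather than topic need the construct-classification route, not raw
  similarity.
- Top-1 backbone linkage fragments: as described above, components of a
  nearest-neighbour graph over exchangeable backbone items split with
  substantial probability, producing splinter clusters.  Raising the
  intra-backbone degree or using modularity communities changes this
  behaviour; both are exposed as options rather than silently altered
  defaults.
- The asymptotic kappa standard errors are large-sample approximations;
  for small item counts a bootstrap would be preferable.
- The exact binomial test treats pairs as independent draws, which is an
  approximation whenever several backbone items select the same partner.
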