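# semharm

Semantic harmonization of psychopathology rating scales.

Clinical constructs such as formal thought disorder (FTD) are measured by
many rating instruments (TLC, TALD, CLANG, PANSS, SAPS-SANS, TLI, BIT, ...)
that describe overlapping symptoms with inconsistent terminology: the same
term can name different phenomena, and different terms the same one.
`semharm` compares instruments through the *text* of their items rather
than through participant scores: item descriptions are embedded in a dense
vector space, pairwise cosine similarity quantifies conceptual overlap, and
a sparsified cross-scale similarity network yields semantic clusters that
can be validated against published construct splits, against expert raters,
and against participant-level data.  It is intended for researchers
harmonizing symptom measurements across instruments and studies.

## Method

For items with cleaned description texts $t_1, \dots, t_n$ and an embedding
$v_i = f(t_i) \in \mathbb{R}^d$:

- **Similarity.** $S_{ij} = \cos(v_i, v_j)$, reported on $[0, 1]$ (negative
  cosines clipped; raw and affine maps available).  Scale-level similarity
  uses centroid vectors, with each scale's *within-scale consistency* (mean
  pairwise item similarity) on the diagonal.
- **Backbone sparsification.** One scale is designated the backbone; every
  other item keeps only its single highest-similarity edge into the
  backbone, and each backbone item keeps one edge to its nearest backbone
  neighbour.  Connected components of this graph are the semantic clusters
  (greedy modularity communities are available as an alternative).
- **Construct polarity.** Items are assigned to the construct description
  (e.g. positive vs negative FTD) of maximal cosine similarity; agreement
  with a reference classification is scored by accuracy and a 2×2 Pearson
  $\chi^2$ test.
- **Expert agreement.** With $n_{ij}$ raters placing item $i$ in category
  $j$ ($m$ raters, $k$ categories), Fleiss'
  $\kappa = (\bar P - \bar P_e)/(1 - \bar P_e)$ with per-category
  $\kappa_j = 1 - \sum_i n_{ij}(m - n_{ij}) / [N m (m-1) p_j (1 - p_j)]$,
  both with asymptotic standard errors and confidence intervals.  The
  machine clustering can be folded in as an additional rater.
- **Clinical alignment.** Each backbone item is paired with its strongest
  cross-scale correlate over participants (all-zero and constant items
  excluded first); the number of pairs sharing a semantic cluster is tested
  against chance $p_0$ with the exact one-sided binomial tail
  $P(X \ge k), X \sim \mathrm{Bin}(n, p_0)$.

Two embedding backends implement one contract: the published
`all-mpnet-base-v2` sentence-transformer (768-d; an explicit error when the
package or weights are absent) and a fully deterministic mock (hashed
token counts through a seeded random projection) that makes the entire
pipeline testable offline.  Because real scale texts are copyrighted and
the expert/participant data unpublished, the package ships a synthetic
generator with known ground truth (themed item texts, noisy expert raters,
latent-factor ordinal ratings) used throughout the analyses and tests.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic
data (later scripts consume the outputs of earlier ones):

```sh
python analysis/01_simulate_dataset.py --seed 1
python analysis/02_similarity_matrices.py --seed 1
python analysis/03_polarity_validation.py --seed 1
python analysis/04_backbone_clustering.py --seed 1
python analysis/05_expert_agreement.py
python analysis/06_clinical_alignment.py
```

At seed 1 this prints, among other output:

```
30 of 30 items (100.0%) match the generating construct
chi2(1, N=30) = 30.00, p = 4.32e-08
...
5 clusters, sizes [25, 25, 25, 19, 6]
adjusted Rand index vs generating themes: 0.935
...
overall                  0.876  0.013  [0.851, 0.900]
...
18 of 20 strongest-correlate pairs fall in the same semantic cluster (chance 0.20)
exact binomial p = 3.27e-11
```

Reading: the two-construct classification recovers the generating split
perfectly; backbone clustering recovers the four generating themes almost
exactly (the fifth, small cluster is a splinter of one theme — see
`docs/methods.md`); seven raters (six simulated experts plus the machine)
agree substantially ($\kappa = 0.876$); and items paired by clinical
correlation co-cluster far more often than the 1-in-5 chance level.

The same operations are exposed as a CLI (`semharm simulate | embed |
polarity | cluster | agreement | align`) for use on real, user-supplied
item banks, expert tables, and ratings CSVs; see `semharm --help`.

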