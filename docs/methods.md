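# Methods

This note documents the models and procedures implemented in `phytoscreen`,
the defaults and numerical choices behind them, what the synthetic studies
do and do not emulate, and the known limitations.

## Feature generation

### Latent knowledge block (width 300)

Compound names are preprocessed by lowercasing, mapping Greek letters to
their alphabetic names (α → alpha; the full lower/upper-case table is built
from the Unicode character names, plus the micro sign), and splitting on
punctuation while preserving intra-word hyphens. Each token is looked up in
a pre-built word-vector table (word2vec text dialect; n-gram rows are
prefixed `NG:`). Out-of-vocabulary tokens are composed from their character
n-grams of lengths 3–6 over the boundary-padded form `<token>`; the token
vector is the **mean** of the available n-gram vectors, and a multi-word
name is the mean over its token vectors. Mean rather than sum composition
keeps vector norms comparable between in- and out-of-vocabulary names and
across name lengths, at the cost of deviating from the sum used when such
embeddings are trained; since only relative geometry (cosine similarity,
downstream weights) matters here, the scale-stable choice is preferred. A
name resolving to nothing yields a zero vector with a warning, and is
excluded from cosine statistics. The default width of 300 matches standard
pre-trained sub-word embeddings.

Embedding quality is audited with the ATC-code check: drugs sharing an ATC
prefix at a given level (prefix lengths 1/3/4/5/7 for levels 1–5) should be
more cosine-similar than size-matched random groups, increasingly so at
deeper levels. The random baseline is drawn once with a fixed seed.

### Molecular interaction block (width 285 at reference scale)

The restart walk iterates p_{t+1} = (1−r)·Wᵀ·p_t + r·p₀ with r = 0.7,
where W is the column-normalized adjacency of the undirected
protein-interaction network. Seeds: direct targets weight 1.0, indirect
(expression/metabolite-level) effects 0.3; the raw weight vector is
normalized to sum to one, preserving the 10:3 ratio, because the iteration
propagates a probability vector. Convergence is declared when the L1
residual falls below 10⁻⁸ (at most 1000 iterations, else an error carrying
the last residual). Zero-degree columns are left all-zero: the restart term
re-injects their mass, and no teleportation semantics are invented. Since
rows of Wᵀ sum to at most one, iterates stay within [0, 1]; the fixed point
equals the linear solve p = r·(I − (1−r)·Wᵀ)⁻¹·p₀, which the tests use as
an oracle.

The stationary vector is restricted to the disease-associated protein list
and reduced by PCA, keeping the smallest number of components whose
cumulative explained-variance ratio reaches 0.8. The basis is fitted on
**training rows only** and applied unchanged to all rows, preventing
held-out compounds from leaking into the fitted transform; if the data rank
cannot reach the threshold, the full rank is used with a warning.

### Chemical property block (width 101 at reference scale)

The descriptor schema is configuration: ordered columns typed `zscore`
(physicochemical), `passthrough` (log-scale lipophilicity, solubility, skin
permeability, synthetic accessibility), or `categorical` with an enumerated
category list. The shipped default mirrors a SwissADME export and encodes
to 101 columns (7 + 11 + 83); the exact category inventory of the original
101-column layout is not recoverable, so the default is a documented
choice, not a contract. Z-scoring uses the sample (n−1) standard deviation
estimated on training rows; constant columns are dropped with a warning;
unseen categories are an error by design (schemas must enumerate).
Descriptor-group similarity uses cosine on the encoded block against a
size-matched random baseline; the interquartile check reports the fraction
of raw numeric descriptors whose natural-compound median falls inside the
drug interquartile range.

## The partially connected network

Per disease, an independent binary classifier:

1. two partially connected layers whose weight matrices are masked
   block-diagonally (latent → interaction → chemical block order, fixed so
   masks and checkpoints are reproducible). Layer-1 hidden widths at the
   reference widths are 200/160/68; the second partial layer reuses the
   same per-block widths (nothing forces another choice, and reuse keeps
   the parameter count predictable). For other input widths each block gets
   ⌈2nᵢ/3⌉ (minimum 4) hidden units, the approximate reference ratio;
2. concatenation (implicit in the block-diagonal mask), then fully
   connected layers of 256 and 64 units — modest sizes that train in
   seconds at desk scale and are configurable;
3. a single sigmoid output.

Every hidden layer is affine → batch normalization → ReLU (normalization
before the nonlinearity; momentum 0.9, ε 10⁻⁵; batch statistics in
training, running statistics at inference). Weights are He-initialized:
zero-mean Gaussian with SD √(2/nₗ), where nₗ counts only the unit's
*unmasked* inputs. The loss is class-weighted binary cross-entropy,
L = −Σ [w₊·y·ln ŷ + w₋·(1−y)·ln(1−ŷ)] with w_c = N/(2·N_c) (so
w₊N₊ = w₋N₋ = N/2 and balanced data gives unit weights), probabilities
clipped at 10⁻⁷ against ln 0. Optimization is Adam (lr 10⁻⁴, β₁ 0.9,
β₂ 0.999, batch 64) for up to 3000 epochs with early stopping on validation
loss (patience 30) and restoration of the best epoch; masked entries are
re-zeroed after every update, so ‖W ⊙ (1−mask)‖ = 0 at every checkpoint.
The whole stack is plain numpy with hand-written backpropagation; training
is single-threaded and bit-reproducible under a fixed seed.

Edge accounting: a partial layer trains Σ nᵢ·mᵢ weights; at the reference
widths that is 112,468 against 314,188 for the published fully connected
comparison layer (which used a wider middle hidden block of 190 units),
i.e. the partial layer keeps ≈ 36% of the dense edge count. The
`edge_counts` helper reports the kept and reduced fractions both ways.

## Network-proximity baselines

All five scores use unweighted shortest paths; pairs with no path are
excluded from means (a warning or error when nothing remains) rather than
imputed — this only matters on disconnected graphs.

- **closest**: mean over targets of the distance to the nearest disease gene;
- **shortest**: mean over all finite target–gene pairs;
- **kernel**: −(1/|G|)·Σ_g ln[(1/|T|)·Σ_t e^{−(d(t,g)+1)}], exponentially
  downweighting long paths;
- **centre**: mean distance from targets to the disease gene with the
  largest closeness centrality (unscaled, computed over each gene's
  reachable set in the full network; lexicographic tie-break);
- **separation**: s = ⟨d_TG⟩ − (⟨d_TT⟩+⟨d_GG⟩)/2, where the between-set
  term is the symmetric closest-based mean (shared nodes contribute 0) and
  within-set terms use the nearest *other* member (singletons contribute 0).

For ranking, distances are negated so that larger = stronger; the
propagation alternative scores a disease by the summed stationary mass on
its gene set.

## Evaluation and literature statistics

Splits are 6:2:2 (largest-remainder apportionment, stratified by label
pattern by default) or k-fold, deterministic under seed. AUROC is the
rank-based (Mann-Whitney) formulation with midranks for ties; accuracy uses
a 0.5 threshold; report dispersions are sample standard deviations.

The literature suite ranks all (compound, disease) score cells, takes the
top and bottom ⌈10%⌉ and a size-matched random set (fixed seed, drawn
once), and compares them on per-pair statistics over an abstract corpus:
co-occurrence n_c (documents containing both terms, multi-word terms
matched as contiguous token sequences after preprocessing — no synonym
expansion), Jaccard index over posting sets, and one-sided (enrichment)
Fisher's exact p from the 2×2 document-containment table, counting pairs
below a 0.001 threshold. One-sided is the appropriate direction because the
question is over-reporting of predicted pairs. Set contrasts use the
two-sided Mann-Whitney U test: exact permutation enumeration when both
samples have ≤ 8 values (correct under ties; identical samples give p = 1),
the tie-corrected normal approximation above — full enumeration beyond
that size is combinatorially infeasible and the approximation is standard
well below n = 20.

## Synthetic studies

The generator plants a recoverable signal under one config (bit-identical
reruns under a fixed seed; every artifact round-trips through the package's
readers):

- **network**: preferential attachment (default 300 nodes, 3 edges per new
  node), matching the heavy-tailed degree structure of real interaction
  networks but not their clustering or annotation biases;
- **disease modules**: breadth-first balls of 12 genes around random roots
  (connected; may overlap);
- **compounds**: 150 profiles of 5 targets (70% direct). A compound is
  positive with probability 0.4 and then assigned exactly one disease,
  drawing at least half its targets from inside that module — module
  members rather than the distance-1 halo, which in a scale-free graph is
  hub-contaminated enough to bury the propagation signal. Negatives draw
  targets uniformly. Labels can be flipped symmetrically with a noise rate
  (default 0);
- **descriptors**: class-conditional Gaussians (positives shifted by 1 SD)
  and multinomials over a compact schema;
- **embeddings**: group centroid + isotropic noise per name, groups aligned
  to the assigned disease.

On the default study the full pipeline reaches held-out AUROC ≥ 0.85 (in
practice 1.0: the planted signal is deliberately strong and redundant
across blocks). The permutation control retrains on label-permuted data;
because the latent block clusters compounds into a handful of groups, a
*single* permutation draw has a wide null distribution, so the control
averages held-out AUROC over 5 independent permutations — the standard
permutation-null estimate — and lands near 0.5. Passing these tests shows
the machinery recovers a signal it should recover and finds none where
none exists; it does **not** show real-data performance, since the
synthetic blocks are cleaner, lower-dimensional in effect, and mutually
redundant in a way real evidence channels are not.

Problem sizes throughout (300-node networks, 150 compounds, 3 diseases,
25–100 random graphs in oracle sweeps) are chosen so the full suite runs in
minutes on one CPU while still exercising every code path at non-trivial
scale.

## Reference benchmark data

`src/phytoscreen/data/reference_benchmarks.json` ships published
per-disease AUROC tables (15 diseases × several model and baseline
variants) and summary literature statistics, used by worked examples and
the acceptance script: the package recomputes the table means (0.900 for
the partially connected model, 0.794 logistic regression, 0.832/0.883 on
natural-compound test sets) and the high- vs randomly-ranked co-occurrence
ratio (3.8) from the per-disease and per-set values. The printed "±"
dispersions of those tables are fold-level quantities not derivable from
the per-disease values and are not reproduced.

## Known limitations

- Real corpora and databases (PubMed, DrugBank-scale tables, full-size
  interaction networks) are out of scope; readers accept pre-merged tables
  and pre-trained vector tables, and descriptor computation from structures
  is not performed.
- One independent binary model per disease: no multi-label weight sharing,
  no calibration across diseases.
- The literature index does exact token-sequence matching only; synonymy
  and named-entity normalization are upstream concerns.
- Weighted or directed networks and tissue-specific interactomes are not
  supported.
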