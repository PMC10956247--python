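# Methods

This note documents the modelling choices, defaults and numerical
conventions of `gnnmotif`, and what the synthetic benchmark does and does
not establish.

## Corpus model

A corpus is a set of equal-length DNA windows (default 101 bp, i.e. a
50-bp flank on either side of a footprint centre, `floor((start+end)/2)` in
1-based coordinates).  Each positive window is paired with a uniformly
random permutation of its own bases.  Shuffling destroys all positional
structure while conserving composition exactly, so a classifier that
separates the pair classes must exploit arrangement — k-mer identity and
k-mer co-occurrence — rather than GC content.  Windows containing letters
outside A/C/G/T are dropped (k-mer identity is undefined over N).

Pairs are assigned to train/validation/test as units at 80/10/10
(validation and test sizes are the rounded targets, training takes the
remainder).  Keeping a positive and its shuffle in the same split prevents
composition leakage across splits; whether the original protocol paired at
split time is unknown, so this is the conservative choice.

Coordinates are 1-based inclusive throughout the library; BED input/output
converts to and from 0-based half-open form at the file boundary.

## Graph

All unique k-mers at width `lenk` (default 5, configurable 3–8; at 5 the
vocabulary is at most 4^5 = 1024, so dense matrices are cheap) and all
sequences are nodes.  Edge weights:

- **Coexisting** (k-mer–k-mer): `-log(Q/(P·P'))` over sequence-level
  presence, natural log.  A pair that co-occurs more often than
  independence predicts gets a *negative* weight; pairs that never
  co-occur, and the diagonal, carry no edge (0).  The sign is kept as
  stated because the motif-merge test below ("positive-corpus weight
  *smaller* than background weight") is self-consistent with it.
- **Similarity**: raw Hamming distance (0..lenk, diagonal 0).  Note this
  weights *dissimilar* pairs more; a `lenk - Hamming` transform is
  available (`sim_transform="lenk-minus-hamming"`) since propagation over
  raw distances is counterintuitive, but the literal form is the default.
- **Jaccard**: intersection-over-union of occurrence sets (diagonal 1).
- **Inclusive** (k-mer–sequence): `tf · log(n/num)`; 0 when the k-mer is
  absent or present in every sequence.

Initial k-mer embeddings are the three k-mer views with each row divided
by its **L1 norm** (all-zero rows stay zero).  The coexisting view is
signed, and dividing by a signed row sum can explode near cancellation, so
the L1 form is the default and the signed-sum variant is kept as
`normalize="signed"` for strict comparisons.  Initial embeddings are
therefore m-dimensional (one coordinate per k-mer), which is what makes
the first-layer product `E · W · W_train` dimensionally consistent.

## Network and training

Three layers: per-view k-mer embedding (widths `dc = ds = dj = 50`),
inclusive aggregation into a sequence embedding (`dsq = 150`), logistic
output.  `dsq = dc + ds + dj` is required when motif discovery is enabled,
because discovery compares k-mer and sequence embeddings in one space.

Two choices here are deliberate deviations from a literal reading of the
architecture, both forced by optimization behaviour observed on the
benchmark corpus:

1. **Output layer.**  A per-sequence-node output weight row would leave
   held-out nodes with untrained random weights and make transductive
   prediction vacuous, so the default output layer is a single shared
   weight vector plus scalar bias (standard transductive node
   classification).  The per-node variant exists behind
   `per_node_output=True` for fidelity experiments.
2. **Inclusive aggregation scale.**  Summing ~100 incident tf-idf weights
   per 101-bp sequence node yields logits of magnitude ~45 at
   initialization: the sigmoid saturates and full-batch Adam oscillates
   between saturation extremes.  Averaging instead (L1 normalization)
   makes per-step logit movement so small that 30 epochs at lr 0.001
   barely move the loss.  The default divides each sequence's incident
   weights by the square root of their L1 sum — the usual
   graph-convolution compromise — which trains stably within the 30-epoch
   budget.  `inclu_norm` accepts `"sqrt"`, `"l1"` and `"none"`.

Trainable matrices are Glorot-style initialized (zero-mean normal, scale
`1/sqrt(fan_in)`); all randomness flows from one integer seed.  Training
runs 30 full-batch epochs of Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8) at
`lr = 0.001 · exp(-0.001 · e)` with `e` counted from 0.  Validation and
test labels never contribute gradient; their nodes stay in the graph.

The objective per training sequence is the iterative loss
`BCE_e + BCE_{e-1}·σ(BCE_{e-1})` with `BCE_0 = 0`.  The carried term uses
the *cached, detached* previous-epoch BCE: it re-weights the reported loss
trajectory (penalizing sequences that were badly predicted last epoch)
without introducing second-order gradient terms, and at epoch 1 the
objective is exactly BCE, so the first update is identical under either
loss.  Reported probabilities are clipped to [1e-12, 1-1e-12] inside the
loss *value* only; the gradient is taken through the logit as `ŷ - y`, the
standard with-logits formulation, so saturated predictions still learn.

Backpropagation is hand-derived (the model is four matrix products, three
ReLUs and a sigmoid) and verified against central finite differences in
the test suite at 1e-4 relative tolerance.

## Motif discovery

The affinity between k-mer p and sequence i is a score between `Msc(p)`
and `Esq(i)`.  The pipeline default is the **dot product**: with
nonnegative post-ReLU embeddings, cosine similarity concentrates in a
narrow band (observed standard deviation ~1e-3), so centring by the
background mean passes a large fraction of background k-mers; the dot
product keeps the learned magnitude, which is where the signal lives
(observed background seed rate ~9% versus 100% for planted-motif k-mers).
Cosine remains available (`metric="cosine"`) and is the documented default
of the low-level scorer.

The background level is the grand mean of the affinity matrix computed on
the negative corpus (its own k-mer vocabulary against its own sequences).
Seeds are k-mers with strictly positive denoised affinity in a given
positive sequence; every occurrence of a seed is expanded around its
centre base `ck = strk + ceil((lenk-1)/2)` into flanks
`kl = [ck-lenk+1, ck]` and `kr = [ck+1, ck+lenk]` (occurrences whose
flanks leave the sequence are skipped), giving candidates of exactly
`2·lenk` bases.

A candidate survives when the flank pair's coexisting weight on
positive-corpus counts is **less than** the same quantity on
negative-corpus counts.  A pair never co-occurring in negatives has
background +∞ (absence of background co-occurrence is the strongest
enrichment evidence) and always survives; a pair never co-occurring in
positives is rejected.  Surviving candidates that share at least one
position merge transitively (adjacency alone does not merge), which is
the mechanism producing variable-length sites.

Site subsequences are grouped by exact length; within a group each site
greedily joins the first cluster whose running consensus it matches with
at most 25% mismatching positions, else founds a new cluster.  Clusters
with ≥ `min_sites` members (default 5) become PWMs with pseudocount 0.25:
`(count + 0.25)/(nsites + 1)` per cell.  This assembly stage (grouping,
threshold, pseudocount) is this package's own design; the upstream method
defines sites, not their summarization.

## Synthetic benchmark

The generator plants 1–3 non-overlapping instances per positive sequence,
sampled column-wise from configurable PWMs, over an i.i.d. uniform
background (an optional first-order Markov background exists but is off
by default — the negatives are shuffles, so the i.i.d. null matches).
PWM columns hit a requested information content by temperature-sharpening
Dirichlet draws with per-column bisection.  Defaults: 150 positives,
101 bp, width-8 PWM at 1.8 bits/column — strong but not consensus-exact
sites, sized so graph construction plus training takes a few seconds on
one CPU.

What passing on this benchmark shows: the graph carries enough signal to
separate arrangement from composition, training converges under the
stated schedule, and the discovery stage recovers a strongly planted PWM
with high site recall.  What it does not show: behaviour under realistic
chromatin backgrounds (repeats, CpG islands, Tn5 sequence bias), motif
instances on the reverse strand (the generator plants forward-strand
only, and the model has no reverse-complement awareness), degenerate
low-information motifs, or overlapping sites of cooperating factors.

## Numerical conventions and edge cases

- Ratios with zero denominators in evaluation report 0 with a flag
  (keeping AEMR computable); the probability threshold counts ties as
  positive; MCC may be negative, in which case the radar area is still
  evaluated literally and the report is flagged (a radar chart cannot
  display a negative radius).
- PR area uses step-wise interpolation (trapezoidal PR interpolation is
  optimistic).
- Footprint ranking breaks score ties by (contig, start) for run-to-run
  stability.
- Simulation rejects configurations whose instances cannot be placed
  without overlap after bounded retries rather than silently planting
  fewer.
- All file writes through the CLI are atomic (temp file + rename), and
  every run directory carries a provenance JSON (config hash, seed,
  version).

## Known limitations

- Single-strand model: sites and k-mers are not reverse-complement
  collapsed.
- The vocabulary grows as 4^lenk; dense views are impractical beyond
  lenk = 8.
- Full-batch training holds all m×m views in memory (~8 MB at lenk = 5,
  ~0.5 GB at lenk = 7).
- The coexisting-probability background test is weak when negatives are
  per-sequence shuffles (both corpora share marginal k-mer statistics);
  it becomes more informative with genomic background negatives, which
  the CLI accepts but the benchmark does not exercise.
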