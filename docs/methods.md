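# Methods

## Model

`topicgrad` treats every cell of a gene-by-cell count matrix as a
document and every gene as a word: latent Dirichlet allocation (LDA)
with K topics assigns each cell a mixture θ_d over topics
(θ_d ~ Dirichlet_K(α)) and each topic a distribution φ_k over genes
(φ_k ~ Dirichlet_G(β)). A topic is a latent transcriptional program — a
weighted gene set — and θ provides a soft, gradient-like embedding of
cells that complements hard clustering when the biology is a continuum
(e.g. hormone-response kinetics across a treatment time course).

Inference is collapsed Gibbs sampling: θ and φ integrate out
analytically and only per-token topic labels z are resampled, one full
pass per sweep, from

P(z_i = k | z_-i) ∝ (n_dk + α) · (n_kw + β) / (n_k + Gβ),

where n_dk, n_kw, n_k are token counts excluding token i. Point
estimates are the posterior means θ_dk = (n_dk + α)/(n_d + Kα) and
φ_kw = (n_kw + β)/(n_k + Gβ) evaluated on the final sweep's counts
(default) or on counts averaged over every 10th post-burn-in sweep.

## Input transform

Raw counts would let the few most highly expressed genes dominate every
topic, so the sampler input is built per cell as:

1. restrict to the most variable genes (default 5,000);
2. centered log-ratio transform with a pseudo count c (default 1):
   CLR(x)_i = ln((x_i + c)/g(x + c)), g the geometric mean over all G
   components — ratio-based and hence invariant to sequencing depth;
3. clamp negative components (genes below the cell's geometric mean) to
   zero, since LDA word frequencies must be non-negative and
   below-average expression carries no positive evidence for a program;
4. multiply by a scale factor (default 10) and round half away from
   zero (banker's rounding would be platform-convention dependent).

Variable genes are ranked by a vst-style statistic: a lowess trend
(span 0.3) of log10 variance on log10 mean predicts each gene's
expected variance; counts are standardized against it, clipped at
√N, and genes are ordered by the variance of the clipped values (ties
broken by name). When the spread of log-means is degenerate (< 0.1
decade) the local regression would chase individual gene variances, so
a flat median trend is used instead.

## Model selection

Each fitted model is scored by perplexity on its input,
exp(−L/T) with L the token log-likelihood Σ ln Σ_k θ_dk φ_kw and T the
token total; lower is better, a uniform model scores exactly G. The
rate of perplexity change, RPC_j = |P(k_{j+1}) − P(k_j)|/(k_{j+1} −
k_j), is computed for adjacent K pairs of a sweep (default K = 10..100
step 10). The selected K is the shared endpoint of the adjacent RPC
pair with the largest *relative* drop (ties resolved to the last, i.e.
the end of a uniform decay); if RPC never decreases the first pair's
right endpoint is returned with a warning. A literal "first pair where
RPC stops decreasing" rule was rejected: on sampled perplexities RPC
typically rises just before a genuine elbow (the perplexity drop
accelerates toward the data's topic count) and bounces at float
precision on the plateau, so an exact comparison fires both too early
and too late; the relative-drop form of the same plateau criterion is
insensitive to both and locates the planted K reliably in simulation.

Sweeps default to a screening configuration (200 sweeps, burn-in 100,
counts averaged every 10th post-burn-in sweep) because RPC differences
need low-variance perplexity estimates; final fits default to 500
sweeps, burn-in 250, final-state estimates.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| α | 50 | per-cell topic concentration; `alpha_mode="scaled"` uses α/K, the convention of much of the topic-modeling literature |
| β | 0.1 | per-topic gene concentration; smaller → sparser topics |
| pseudo count c | 1 | added before the log; guards zeros |
| scale factor | 10 | CLR-to-integer token resolution |
| n_features | 5,000 | variable-gene vocabulary size |
| iterations / burn-in | 500 / 250 | Gibbs sweeps for a final fit |
| top-gene signature n | 50 | genes per topic for signatures, transfer, overlap, enrichment |

## Downstream statistics

**Signatures and scores.** A topic's signature is its top-n genes by φ
(ties lexicographic). Per-cell topic scores are θ or per-topic
Z-normalized θ; Z-normalization uses the sample standard deviation
(ddof = 1, the convention of R's `scale`), returning zeros with a
warning for constant topics.

**Transfer.** Signatures are scored on an independent count matrix by
the binned-control module score: expression is library-size scaled to
the median depth and log1p-transformed; genes are cut into 25
equal-frequency bins by average expression; each signature gene draws
100 control genes with replacement from its bin; the score is the mean
signature expression minus the mean over the control pool. Scores are
seeded and deterministic. Note the score is exactly zero by
construction when a signature has no bin-mates (controls collapse onto
the signature itself) — meaningful universes need well-populated bins.

**Delta-control Z-score.** For labeled time courses, scores are
Z-scored across all cells (globally, not within arms) and the median Z
of the control group is subtracted; control cells therefore sit at
median zero and treated groups shift by their response. The statistic
is invariant to affine transformation of the input scores.

**Enrichment.** Each (topic signature, gene set) pair is tested by the
inclusive upper tail P(X ≥ overlap) of the hypergeometric distribution
within a gene universe — the model vocabulary by default, or its
intersection with the annotated genes (`universe="intersection"`),
since the test is only meaningful over genes observable by both sides.
Factors are ranked per topic by ascending raw p (ties: larger overlap,
then name); Benjamini–Hochberg adjusted p-values are reported across
the whole table. Gene matching is exact and case-sensitive after
whitespace stripping; alias resolution is a consumer responsibility.

## Synthetic data

`generate_lda_corpus` draws corpora from the model's own generative
story (φ_k ~ Dirichlet_G(β_gen = 0.1), θ_d ~ Dirichlet_K(α_gen = 0.5),
fixed depth per cell by default, negative-binomial optionally). Pure
Dirichlet draws do not make topics identifiable, so each φ row
concentrates `anchor_strength` of its mass on a disjoint block of
G // K anchor genes and the row's values are rearranged so the block
carries its largest probabilities — a heavy Dirichlet tail could
otherwise outrank a weak anchor, and the recorded anchors must be each
row's top genes by construction. `generate_response_gradient` emulates
a hormone-response time course: for a cell in group g with ramp value
r_g and base mixture u, θ = (1 − r_g·E)·u with r_g added to each of the
E effect topics, so the expected effect-topic weight between two groups
differs by (r_g − r_g')·(1 − E/K) and a zero ramp makes groups
exchangeable.

The generator emulates mixed-membership token sampling only: no
dropout, ambient RNA, doublets, batch effects or gene–gene correlation
beyond topic structure. Passing recovery tests therefore demonstrates
correctness of the inference machinery, not robustness to scRNA-seq
noise.

Recovery experiments feed the generated counts to the sampler directly:
the corpus *is* the bag-of-words the generative model produced, so this
is the matched validation of the inference. The CLR pipeline exists for
real, depth-varying counts; applying it to these fixed-depth token
corpora log-compresses the planted structure and is validated instead
by its own invariants (zero component sums, scale invariance,
monotonicity, worked examples) and by pipeline smoke tests.

## Numerical choices and edge cases

* All sampler randomness comes from one seeded generator per fit;
  token visitation order is fixed (cells, then genes, then
  multiplicity), so identical seed + input gives bit-identical θ/φ, and
  every CLI run is byte-identical on rerun (manifests record no
  timestamps).
* The unnormalized full conditional is evaluated in double precision
  and sampled by inverse CDF on its cumulative sum; at these scales no
  log-space computation is needed.
* Cells whose row becomes all-zero after the CLR transform are flagged,
  retained, skipped by the sampler, and receive uniform θ (the prior
  mean).
* θ/φ are serialized with 6 significant digits, beyond the sampler
  noise floor; write/read round trips agree to ~5e-6 relative error.
* Topic matching between models uses Hungarian assignment on cosine
  similarity and equals the exhaustive best permutation (verified for
  K ≤ 6).

## Validation problem sizes

The acceptance script and heavy tests use: 2-cell/3-gene/6-token
corpora with exact posterior enumeration (64 states, 5,000 retained
sweeps, 3 seeds); reference-scale recovery (N=500, G=200, K=5,
depth=500, anchor strength 0.5; 3 seeds; 500-sweep fits); K = 2..10
sweeps on 10 such corpora at the screening defaults; one transfer pair
sharing planted φ; gradient corpora of 4 × 100 cells, 150 genes, depth
300 (20 null seeds). These sizes make every quantity recomputable on a
single CPU in a few minutes.

## Known limitations

* Perplexity is computed on training data, as in the elbow heuristic
  this package implements; a held-out split is exposed but not the
  default, so the absolute perplexities are optimistic.
* The CLR clamp discards below-geometric-mean structure by design;
  datasets whose signal is predominantly *down*-regulation are better
  served by inspecting topics depleted in θ than by the clamped input.
* Module scores inherit the binned-control method's sensitivity to
  sparse expression bins (see above).
* No alias/ortholog mapping: gene universes must share a namespace.
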