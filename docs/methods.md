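# Methods

## Model

The core model is latent Dirichlet allocation and its supervised restriction.
A corpus of M reviews over a vocabulary of V tokens is modeled with K topics:
each topic k has a word distribution φ_k ~ Dirichlet(β), each document d has
a topic mixture θ_d ~ Dirichlet(α), and each token is generated by drawing a
topic z ~ Categorical(θ_d) and a word w ~ Categorical(φ_z).

Inference is collapsed Gibbs sampling: θ and φ are integrated out and each
token's topic is resampled from

    p(z_i = k | z_−i, w) ∝ (n_dk + α) · (n_kw + β) / (n_k + V·β),

with all counts excluding token i. Point estimates are the Rao-Blackwellized
forms θ_dk = (n_dk + α)/(N_d + K·α) and φ_kw = (n_kw + β)/(n_k + V·β).

**Labeled-LDA** is the identical sampler with each document's admissible
topics restricted to its annotated label set, so the K = 9 topics coincide
with the taxonomy labels and the annotations supply the supervision. The two
models share one code path: a document labeled with all nine topics is
unconstrained, and a fully-labeled corpus yields a bit-identical sampler
trajectory to unsupervised LDA under the same seed (this is tested).

**Classification** of new reviews uses fold-in: Gibbs sampling of the new
document's topic assignments with φ held fixed at the trained values, then
the 1/L rule — assign label k when θ_k strictly exceeds 1/L. A uniform row
therefore yields no labels; that is reported, not treated as an error.

**Topic-number selection** for exploratory LDA uses held-out per-word
perplexity, exp(−Σ_d log p(w_d) / Σ_d N_d) with p(w) = Σ_k θ_dk·φ_kw and
held-out θ obtained by fold-in against the trained φ (document fold-in, not
document completion — the simplest estimator consistent with the formula;
the curve metadata records this). The recommended K is the smallest grid
point whose relative improvement over the previous point falls below a
threshold (default 5%), with negative improvements clamped to zero so a
threshold of 0 degenerates to the largest grid point. The full curve is
always reported: perplexity decreases roughly monotonically in K, so the
elbow is a starting point and the final choice should weigh topic
interpretability (K = 30 is the conventional exploratory default here).

## Default parameters

| Parameter | Default | Why |
|---|---|---|
| α (doc-topic prior) | 50/K | standard collapsed-Gibbs heuristic |
| β (topic-word prior) | 0.01 | sparse topics; standard practice |
| sweeps / burn-in / lag | 1000 / 500 / 10 | chains at these sizes mix well before burn-in ends |
| estimate mode | average post-burn-in samples | lower-variance θ for the downstream 1/L threshold (single-sample mode available) |
| fold-in sweeps / burn-in / lag | 200 / 100 / 5 | per-document chains are short and mix fast |
| ratio floor | 1/9 | uniform baseline over the 9-topic taxonomy |
| effect bands | 0.01 / 0.20 / 0.50 / 0.80 | the banding convention used for review-topic contrasts; deliberately narrower than Cohen's classic 0.2/0.5/0.8 benchmarks |

Sweeps visit documents in corpus order and tokens in sequence order, and all
randomness comes from a self-contained xorshift64* stream seeded by the user
seed, so runs are bit-reproducible across platforms. The inner loop is
numba-jitted; the default synthetic experiment (3,000 documents, ~90 tokens
each, 1,000 sweeps) trains in a few seconds on one CPU.

## Statistics layer

Group contrasts operate on **thresholded continuous topic ratios**, not on
binary containment indicators: published summary triples (Δu, d, t) for this
kind of analysis are numerically consistent with continuous ratios and
inconsistent with binary variables, and `t_from_printed_summary` makes that
consistency checkable — it recovers s_pooled = Δu/d and returns
t = Δu / (s_pooled·√(1/n₁+1/n₂)). Containment fractions (share of reviews
with a positive thresholded ratio) are computed separately for figure-style
summaries.

Cohen's d uses the pooled standard deviation; Welch's unequal-variance t with
Welch–Satterthwaite degrees of freedom is the default inference (a
pooled-variance Student t is available — at these group sizes the two are
numerically close, which is also why published t values cannot distinguish
them). p-values are kept exact internally; the "<.001" truncation is applied
only in formatted report output. No multiple-testing correction is applied by
default, mirroring the uncorrected convention of this analysis style; a
`p_adjust` flag exposes Bonferroni/FDR via statsmodels for users who want it.

Degenerate inputs: zero pooled variance (or both group variances zero) yields
an undefined marker (`None`) for that topic only; undefined metrics are
excluded from averages with a warning, never zero-filled.

## Evaluation aggregation

Within a group, precision and recall are micro-averaged over labels. Two F
aggregates are reported because published per-group F values for this task
are not always the harmonic mean of the printed per-group P and R: `f_micro`
(harmonic mean of micro-averaged P and R) and `f_macro_topics` (arithmetic
mean of per-label F within the group). The summary row is the arithmetic
mean of per-group values; applied to the packaged nine-disease benchmark
table this reproduces its published average row at printed precision.

## Synthetic data: what it does and does not show

The generator draws corpora from exactly the process labeled-LDA inverts:
group-dependent Bernoulli (or fixed-cardinality) label sets, Dirichlet
mixtures restricted to the label set, and tokens from per-label word
distributions. The default preset mirrors the published data shape — nine
disease subcorpora with sizes proportional to the published review counts
scaled to 3,000 documents, mean lengths 0.2× the published per-review word
counts (negative-binomial, dispersion 10), per-disease doctor pools scaled
the same way, and hospital levels drawn A/B/C = 0.55/0.30/0.15 independent
of content. Planted prevalences follow the direction of the published group
contrasts (symptoms high in acute-disease reviews, financing and diagnosis
high in chronic ones, etc.). α_true = 2.0 keeps within-document label
mixtures away from extreme skew, reflecting that an annotated label is
substantively present in its review; β_true = 0.05 gives well-separated
topics at V = 500. Label-set cardinality is a free parameter (default
1–3 labels with probabilities 0.35/0.40/0.25) since no cardinality
statistics are published for the original annotations.

Because generator and model match, recovery experiments are a *correctness*
check of the sampler and pipeline, not evidence about real reviews: real
text violates the bag-of-words exchangeability, its topics are correlated
and unevenly sized, annotations are noisy, and Chinese segmentation errors
propagate. The ~0.97 held-out macro-F on the preset is therefore an upper
bound of sorts; the published benchmark on real reviews (average F = 0.816)
is the realistic reference point. Raw-text rendering exercises the
preprocessing contract (entity surfaces, synonym variants, inserted
stopwords are all invertible by construction) but makes no attempt at
linguistically realistic text.

## Numerical and design choices

- **Pipeline order**: segment → POS filter → stopwords → entity rules →
  thesaurus. Entity rules run before synonym replacement so entity surface
  variants never depend on thesaurus coverage (entity rules are the more
  specific transformation). Placeholder tokens are never rewritten by any
  rule; first matching rule wins; the generic `#NUMBER#` rule is ordered
  last as the catch-all.
- **Tokenizer**: a pluggable hook (whitespace default). Segmentation quality
  is not this package's contribution; any segmenter that returns tokens (and
  optionally parallel POS tags) plugs in, keeping the pipeline
  language-agnostic and testable offline. Person/location/organization
  recognition is supported only through user-supplied gazetteer rules — the
  packaged rules cover the pattern-matchable entity classes (temperature,
  age, height, weight, money, percent, date, time, number).
- **1/L boundary**: strict inequality ("higher than" the uniform baseline);
  ratio flooring zeroes entries strictly below 1/9.
- **Effect-band edges**: closed on the lower edge (d = 0.20 → "large"), since
  the printed ranges abut without specifying edges; |d| > 2 reports "huge".
- **Vocabulary**: first-appearance order with a frequency floor;
  out-of-vocabulary tokens are dropped at bag-of-words time but the document
  row is retained (an empty document gets the uniform prior θ row, with a
  warning at fold-in).
- **Doctor counts in summaries** are per group, not globally unique — a
  doctor reviewed under two diseases counts in both rows, matching how
  per-disease physician counts are conventionally tabulated (their sum may
  exceed the number of unique doctors).
- **Problem sizes** in the test-suite and acceptance experiments (3,000-document
  preset, 600-document K-scan corpus, 5,000 simulation replicates) are chosen
  as desk-scale mirrors that keep the full suite in the tens of seconds while
  leaving comfortable statistical margins.

## Known limitations

- Topics for exploratory LDA are exchangeable (label switching); only
  labeled-LDA topics have fixed identities. Recovery experiments therefore
  use greedy cosine matching.
- The sampler is single-chain; no convergence diagnostics beyond the
  recovery tests are built in.
- Hyperparameters are fixed, not optimized; no asymmetric priors.
- The pipeline counts topic prevalence; it does not model sentiment, so a
  review dwelling on financing negatively and one praising low costs
  contribute identically to the F topic.
- Perplexity-based K selection is estimator-dependent (held-out split and
  fold-in scheme); treat the curve qualitatively.
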