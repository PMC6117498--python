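# reviewminer

Taxonomy-guided topic mining of web-based physician reviews.

Physician review websites let patients rate doctors and leave free-text
comments. Those comments are multifaceted — a single star rating flattens
away what the patient actually cared about: the doctor's manner, their
competence, the prescription, the bill, the queue. `reviewminer` implements a
pipeline that classifies each review into a fixed nine-topic taxonomy and
then asks *which patient groups care about which topics*:

- **Taxonomy** — nine topics in three domains. Physician-related: medical
  ethics (ME), medical competence (MC), medical advice & prescription (MAP),
  communication skills (CS). System-related: financing (F), operation
  process (OP). Patient-related: patient profile (PP), symptoms (S),
  diagnosis & pathogenesis (DAP).
- **Preprocessing** — a pluggable tokenizer hook, part-of-speech filtering to
  content words, stopword removal, synonym canonicalization via a thesaurus,
  and rule-based entity normalization that collapses surface forms like
  `39°C` / `40°C` onto a single placeholder token `#BODY_TEMPERATURE#`.
- **Exploratory LDA** — collapsed Gibbs sampling with held-out per-word
  perplexity, `exp(−Σ_d log p(w_d) / Σ_d N_d)`, to guide the choice of the
  topic count K.
- **Labeled-LDA classification** — the same collapsed Gibbs sampler with each
  document's topic support restricted to its annotated label set, so topics
  coincide with the taxonomy labels. New reviews are classified by fold-in
  inference and the 1/L rule: assign label k when θ_k > 1/L.
- **Interest mining** — per-review topic ratios floored at 1/9, group
  containment fractions, and per-topic two-group contrasts: Δu = mean
  difference, Cohen *d* = Δu / s_pooled, Welch's *t* with Satterthwaite
  degrees of freedom, and effect-size bands
  (small < 0.01 ≤ medium < 0.20 ≤ large < 0.50 ≤ very large < 0.80 ≤ huge).
- **Synthetic corpus generator** — the original review corpus is not public,
  so the package ships a generator that draws labeled multi-topic corpora
  from the labeled-LDA generative process, with nine disease subcorpora
  mirroring the published data shape and planted group-dependent label
  prevalences, making every stage testable end to end.

## Worked example

```python
import reviewminer as rm

# generate a desk-scale corpus shaped like a real review dataset
config = rm.reference_shape_config(total_docs=1000, vocab_size=300, seed=7)
corpus, truth = rm.generate_corpus(config)
taxonomy = rm.load_taxonomy()

vocab = rm.build_vocabulary(corpus)
bows = rm.docs_to_bow(corpus, vocab)

# train labeled-LDA on the annotated reviews
state = rm.fit_labeled_lda(bows, vocab.V, [r.labels for r in corpus],
                           taxonomy, iterations=500, burn_in=250, seed=7)
result = rm.estimate_theta_phi(state)

# contrast acute vs chronic patients on thresholded topic ratios
scheme = rm.load_grouping_scheme("acute_vs_chronic")
ratios = rm.topic_ratios(result.theta, taxonomy.label_ids,
                         groups=rm.group_tags_for_corpus(corpus, scheme))
table = rm.comparison_table(rm.compare_groups(ratios, scheme), format_p=True)
print(table[["topic", "delta_u", "cohen_d", "welch_t", "p", "band"]]
      .round(3).to_string(index=False))
```

Output:

```
topic  delta_u  cohen_d  welch_t     p       band
   ME    0.013    0.079    0.996 0.320     medium
   MC    0.000    0.001    0.010 0.992      small
  MAP    0.011    0.069    0.899 0.369     medium
   CS   -0.071   -0.414   -7.326 <.001      large
    F   -0.066   -0.343   -5.229 <.001      large
   OP   -0.003   -0.019   -0.263 0.793     medium
   PP    0.053    0.321    3.646 <.001      large
    S    0.100    0.590    6.461 <.001 very large
  DAP   -0.035   -0.191   -2.871 0.004     medium
```

Each row is one taxonomy topic. `delta_u` is the acute-group mean topic
ratio minus the chronic-group mean; positive values mean acute-disease
patients dwell on the topic more. The generator planted exactly this
structure — symptoms (S) and patient profile (PP) elevated in the acute
group, communication (CS), financing (F) and diagnosis (DAP) elevated in the
chronic group — and the pipeline recovers each planted shift with the right
sign, a significant Welch test, and an effect-size band that scales with the
planted gap, while the unshifted topics (MC, OP) sit near d ≈ 0.

The same steps are available from a shell:

```bash
reviewminer generate --seed 7 --docs 1000 --out corpus.jsonl --truth truth.json
reviewminer preprocess --in raw.jsonl --out clean.jsonl --rules entities.tsv \
    --thesaurus syn.tsv --stopwords stop.txt
reviewminer select-k --in clean.jsonl --grid 5,10,20,30,40
reviewminer fit-llda --in clean.jsonl --out model.json
reviewminer classify --model model.json --in clean.jsonl --out labels.jsonl
reviewminer evaluate --pred labels.jsonl --gold clean.jsonl --by disease
reviewminer compare --model model.json --in clean.jsonl --scheme acute_vs_chronic
```

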