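# fieldscape

Machine reading of a two-field scientific literature: how do two
neighboring disciplines — here ecology and conservation biology —
share, exchange, and drift apart in the topics they write about and
the papers they cite?

`fieldscape` is a tested Python implementation of that analysis as a
reusable pipeline:

* **Topic model** — latent Dirichlet allocation fitted by collapsed
  Gibbs sampling (`fieldscape.lda.GibbsLDA`, a scikit-learn style
  estimator), with NPMI topic-coherence model selection over k and
  fold-in inference for held-out text.
* **Field-biased topics** — per-topic differences of median
  log10(topic probability) between fields, discretized "aboutness" at
  a τ = 0.05 threshold, relative risks with continuity correction, and
  top-m biased topic sets (`fieldscape.field_bias`).
* **Trends** — median (quantile) regression of per-article topic loads
  with the field x bias x year interaction and bootstrap inference;
  polynomial count-trend models selected by AIC plus nested F-tests;
  Shannon topic diversity with bootstrap CIs (`fieldscape.trends`).
* **Landscapes** — exact t-SNE embedding of topic mixtures under
  Hellinger distance, per-field Gaussian-kernel density surfaces,
  field boundaries, period maps, citation-weighted maps, and
  journal x topic clustering (`fieldscape.landscape`).
* **Citations** — DOI/title resolution of bibliographies against the
  corpus, cross-field citation tables, and per-article cross-citation
  weights (`fieldscape.citations`).
* **Synthetic corpora** — a generator that plants known ground truth
  (field-biased Dirichlet priors, a quadratic post-2005 decline of
  ecology content in conservation, corpus growth, topic-distance-
  driven citations) so the whole pipeline can be validated against
  what was planted (`fieldscape.synthetic`).

The core update the topic model is built on, the collapsed Gibbs
conditional for token assignment z in document d, word w:

    p(z = t | z_-i, w) ∝ (n_dt + α) · (n_tw + β) / (n_t· + V β)

with φ and θ reported as smoothed means of post-burn-in count tables.
See `docs/methods.md` for the full model, parameter defaults and their
rationale, and what the synthetic generator does and does not emulate.

## Worked example

Generate the default synthetic two-field corpus, fit the topic model,
and ask the two headline questions — which topics are field-biased,
and what happened to ecology content in conservation over time:

```python
import numpy as np
from fieldscape import corpus_io, field_bias, lda, synthetic, trends

truth = synthetic.make_truth(seed=10)               # k=10, 3 biased topics/field
corpus = synthetic.generate_corpus(truth, seed=11)  # ~2000 articles, 2000-2014
vocab = corpus_io.build_vocabulary(corpus.documents, min_df=0.0, max_df=1.0)
X = corpus_io.vectorize(corpus.documents, vocab)

fit = lda.fit_lda(X, k=10, seed=12)
table = field_bias.field_bias_table(fit.doc_topic_, corpus.fields)
eco_set, cons_set = field_bias.top_biased_topics(table, m=3)

about = field_bias.discretize(fit.doc_topic_, tau=0.05)
counts = field_bias.count_about_articles(about, eco_set, corpus.years, corpus.fields)
cons = counts.query("field == 'conservation'")
pf = trends.fit_polynomial_trends(cons["year"].values, cons["count"].values)
qr = trends.bias_trend_quantreg(fit.doc_topic_, corpus.fields, corpus.years,
                                eco_set, cons_set, B=1000, seed=13)
```

Output:

```
2008 articles, 492 stems, 603552 tokens
ecology-biased topics: [0, 1, 8] conservation-biased: [4, 5, 7]
conservation articles about ecology topics: order 2 trend, peak 2006.3
field:bias:year interaction = 0.0131 (bootstrap p = 0.002)
```

Reading the numbers: the three recovered ecology-biased topics (delta
≈ +2.2 decades of median probability, relative risk ≈ 8) and three
conservation-biased topics (delta ≈ −2.1, RR ≈ 0.13) are exactly the
planted ones up to topic relabeling.  The yearly count of conservation
articles with ecological content is best described by a quadratic with
an interior peak (~2006): it rose, peaked shortly after 2005, then
declined despite corpus growth.  The positive three-way interaction
with small bootstrap p says the two fields' median topic loads diverged
over time — each field increasingly about its own topics.

A command-line interface wraps the same stages:

```
fieldscape simulate --seed 1 --output run/
fieldscape run --config run/config.yaml
fieldscape citations run/refs.csv run/corpus.jsonl --output run/
```

`fieldscape run` executes ingest → vocabulary → fit → bias → trends →
landscape → citations, writes every artifact (CSV/MTX/NPY/YAML) plus a
per-stage manifest, and skips stages whose inputs and configuration
are unchanged.

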