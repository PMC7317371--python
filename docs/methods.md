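# Methods

`fieldscape` reimplements, as a tested pipeline, a machine-reading
analysis of how two neighboring literatures — ecology and conservation
biology — relate and diverge over time: topic modeling of a two-field
corpus, field-bias statistics on the inferred topic mixtures, temporal
trend models, 2-D topic landscapes, and cross-field citation analysis.
Because the article corpora such analyses run on are typically
paywalled and not redistributable, the package ships a synthetic-corpus
generator that plants known ground truth with the same statistical
structure, so every stage can be validated end to end.

## Topic model

Documents are modeled by latent Dirichlet allocation: document d draws
a topic mixture θ_d ~ Dirichlet(α1_k), topic t draws a word
distribution φ_t ~ Dirichlet(β1_V), and each token picks a topic from
θ_d then a stem from φ_t.  Inference is collapsed Gibbs sampling: θ
and φ are integrated out and per-token assignments are resampled from

    p(z = t | rest) ∝ (n_dt + α) (n_tw + β) / (n_t· + Vβ).

We chose collapsed Gibbs over variational inference because it is
deterministic given a seed and exactly testable: on corpora with a
handful of tokens the sampler's stationary distribution can be compared
with the posterior enumerated over all k^N assignment configurations
(the suite holds this to total-variation < 0.05 at 50,000 samples), and
an independent variational implementation (scikit-learn's
`LatentDirichletAllocation`) is available as a cross-check oracle.

Defaults: α = 1/k, β = 0.01 (symmetric; configurable), n_iter = 1500
sweeps with burn_in = 1000 and every 10th post-burn-in sweep averaged
into the count tables.  Earlier, shorter defaults (500/200) left the
chain visibly unconverged on desk-scale corpora (~600k tokens, k=10):
the joint log-likelihood trace was still climbing and occasionally one
planted topic had not separated.  The trace is stored on every fit
(`log_likelihood_trace_`); if it has not plateaued, run longer.
φ and θ point estimates are smoothed posterior means, so log10 θ is
finite everywhere — required by the bias statistics below.

Model size k is selected by mean topic coherence: for each topic, the
mean pairwise NPMI of its top-10 words under boolean document
co-occurrence, NPMI(a,b) = log(p(ab)/(p(a)p(b))) / (−log p(ab)), with
an ε = 1e-12 guard so disjoint pairs stay finite near −1.  Sliding
window variants exist; the boolean-document variant is exactly
computable from the document-term matrix and is exposed as the package
measure.  Ties in the argmax break toward smaller k.

## Corpus ingestion

Text is lowercased, split on non-alphabetic characters, tokens shorter
than two letters dropped, and each token replaced by its Porter stem
(the classic 1980 rules, implemented in `fieldscape.porter` and tested
against the published example vocabulary).  No stop list is applied;
document-frequency filters do that work: a stem is kept iff
min_df·D ≤ df ≤ max_df·D (defaults 0.001 and 0.80), with stems exactly
at a boundary retained.  Document frequency is counted on stems, after
stemming.  Vocabulary columns are ordered lexicographically so every
downstream matrix is bit-reproducible.

## Field-bias statistics

Two routes, computed and written side by side:

* **Median-delta.**  Per topic, delta = median log10 θ over ecology
  articles minus the same over conservation articles; positive delta =
  ecology-biased.  Medians use the lower-median convention (an observed
  order statistic, stable under even counts).
* **Relative risk.**  An article is "about" a topic when θ strictly
  exceeds τ = 0.05.  RR = about-fraction(ecology) /
  about-fraction(conservation); when either count is zero, 0.5 is added
  to that topic's counts and denominators (Haldane–Anscombe) and the
  row is flagged.

Top-m biased sets (default m matches the planted sets; m = 10 for a
k = 50 model) are taken from the delta ranking by default, with the RR
ranking reported alongside; on synthetic corpora the two agree on the
planted topics.

## Trend models

* **Median regression.**  Per-article topic loads (summed θ over a
  biased set; each article contributes one row per set) are modeled as
  load ~ field * bias * year (year centered), fitted at q = 0.5 via
  statsmodels' QuantReg.  The three-way interaction asks whether the
  fields' own- versus other-field loads diverge over time.  Inference
  is a pair-resampling bootstrap (B = 1000, article rows as the unit)
  with sign-crossing two-sided p-values, (2·min(#below, #above)+2)/(B+1).
  The point fit is verified in the suite against the brute-force
  minimum over all lines through data-point pairs (an LP-vertex
  property of the check loss).
* **Polynomial count trends.**  Yearly about-counts are fitted by OLS
  at orders 1–3 on centered year.  A higher order is accepted only when
  it lowers AIC **and** its nested F-test against the currently
  accepted model has p < 0.05; order 3 is only reachable through an
  accepted order 2 (hierarchical ANOVA).  If the accepted model already
  fits exactly (SSR below numerical noise), escalation stops.  A chosen
  concave quadratic with an interior vertex reports its peak year
  −b/2a.
* **Shannon diversity.**  H = −Σ p ln p (nats; base switchable) over
  topic about-occurrence frequencies, per year bin and field, with
  95% percentile bootstrap CIs resampling articles.

## Landscapes

Articles are embedded to 2-D by exact t-SNE (no Barnes–Hut; desk-scale
D) on pairwise Hellinger distances between θ rows —
H(p,q) = sqrt(1 − Σ√(p q)) — with perplexity 30, early exaggeration 12
and learning rate 200; Euclidean input is switchable.  The t-SNE input
metric is a package choice: Hellinger is the natural metric on
probability vectors and is used for all other clustering here.

Per-field densities are product-Gaussian KDEs evaluated on a shared
200×200 lattice over the padded bounding box, bandwidth per axis by
Scott's rule (σ n^{-1/6}), normalized to integrate to 1 over the grid.
The KDE is implemented directly (a separable vectorized kernel sum)
rather than through `scipy.stats.gaussian_kde`, whose full-covariance
kernel differs from the diagonal product kernel specified here; the
suite pins it to a brute-force O(N·G²) double loop at rel. err < 1e-8.
The field boundary is the cell set with total density ≥ 5% of the
maximum and |log(d_eco/d_cons)| ≤ log 1.5 — where articles are about
evenly split between fields — returned per connected component.
Weighted variants reuse the same code with per-point weights (e.g.
cross-field citation counts) normalized to sum 1.  Journal structure:
journal × topic matrices of lower-median log10 θ, rows and columns
clustered by average linkage on Hellinger distances of the renormalized
linear-scale profiles.

## Citations

References (citing id, DOI, title) resolve against the corpus by exact
DOI first, then by normalized title (lowercase, all non-alphanumerics
removed); titles normalizing to more than one corpus article stay
unresolved and are flagged.  Self-citations are excluded and duplicate
references deduplicated before graph statistics.  The 2×2
citing-field × cited-field table is row-normalized to percentages;
the resolved fraction uses the full bibliography size as denominator.
Per-article cross-citation weights count resolved citations received
from the other field.  The top-cited subgraph ranks by within-corpus
in-degree (ties by id).

## Synthetic corpus generator

The generator is first-class, tested code; its defaults define the
study conditions used by the validation suite.

* **Structure.**  k = 10 topics over V = 500 vocabulary symbols; φ rows
  from a symmetric Dirichlet(0.05), giving sparse, heavy-tailed,
  well-separated word profiles.  Three topics are ecology-biased, three
  conservation-biased, four shared.  Vocabulary symbols are 3-letter
  consonant-only strings (no vowels, `s`, or `y`) — fixed points of the
  Porter stemmer — so a corpus written to JSONL and re-ingested
  reproduces the planted counts exactly.
* **Field priors.**  Dirichlet concentrations: 0.5 on shared topics,
  2.0 on a field's own biased topics, 0.15 on the other field's.
* **Temporal signals** (both in conservation, mirroring the two
  dynamics the analysis is designed to detect):
  1. the concentration on ecology-biased topics follows a quadratic in
     year, symmetric about the peak (default 2005) with half-width
     peak − year_min, so it returns to baseline at 2010 and continues
     below it toward 2014 (floored at 0.1× so concentrations stay
     positive).  Amplitude 0.5: conservation's ecology content rises
     ~50% to the peak, then falls well below its 2000 level — a
     rise-then-post-peak decline in about-counts despite corpus growth;
  2. the concentration on conservation's own topics rises linearly at
     3%/yr (`cons_specialization`), a steady specialization that drives
     the positive field:bias:year interaction and a slow diversity
     decline.  An optional `specialization_rate` concentrates all of
     conservation's mass on its own topics after the peak year, used to
     plant abrupt homogenization for diversity-trend tests.
* **Sizes.**  54 documents per field per year at growth 1.03/yr over
  2000–2014 → D ≈ 2000; document lengths Poisson(300).  These sizes are
  the package's desk-scale operating point: large enough for stable θ
  inference and year-level counts, small enough that a full fit takes
  under a minute.  Growth 1.03 keeps the ecology count series close
  enough to linear that polynomial selection is not dominated by the
  exponential's curvature.
* **Citations.**  Per document, Poisson(30) references, 8% of them
  resolvable (mirroring the ~8% within-corpus resolution rate of real
  bibliometric corpora).  A resolvable reference cites an
  earlier-or-same-year document with probability
  ∝ exp(−Hellinger(θ_i, θ_j)/0.3), damped by (1 − assortativity)
  across fields (default assortativity 0.7).

**What the generator does not emulate:** real English word statistics
(symbols are abstract), journal-level structure beyond two interchange-
able labels per field, author effects, document-length/topic
correlations, and citation dynamics beyond the distance kernel
(no preferential attachment, no recency decay).  Passing tests
therefore show that the pipeline recovers the planted statistical
structure at desk scale — not that it would resolve the much subtler
signals of a real 32k-article corpus, where preprocessing noise,
topic-label ambiguity and metadata errors dominate.

## Numerical and design choices

* Seeds: every stochastic routine takes an explicit seed; the pipeline
  derives per-stage seeds from one master seed by stable hashing of the
  stage name, so adding a stage never perturbs earlier stages.
* The Gibbs estimator follows the scikit-learn protocol
  (`get_params`/`set_params`, `fit`, `transform`, trailing-underscore
  attributes) and composes with sklearn tooling; the bias, trend and
  citation analyses are deliberately plain functions over arrays and
  DataFrames — they are one-shot statistics, not refittable models.
* "Quantile regression at the median" is used for the trend model the
  original literature describes as quintile regression; the design and
  the response (per-article loads with year as covariate) are stated
  above because the upstream description is ambiguous.
* Degenerate inputs: empty documents infer uniform θ with a warning;
  zero about-counts trigger the RR continuity correction; singleton
  KDE subsets fall back to a 5%-of-extent bandwidth; constant
  bootstrap statistics yield zero-width intervals with a warning.
* Known limitations: exact t-SNE is O(D²) memory and time (fine to
  ~5000 articles); the coherence variant is boolean-document NPMI, not
  a sliding-window C_v; no multiple-testing control is applied across
  topics (by design, matching the analysis being reimplemented); the
  polynomial selection rule has the usual ~5% false-escalation rate of
  an α = 0.05 F-screen, so on truly linear series an occasional
  quadratic call is expected.
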