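# Methods

## The importance model

The unit of modeling is a (formula, decoction piece) pair. Its importance —
the Monarch–Minister–Assistant–Guide role, encoded 4..1 — is approximated by
an affine model over three features:

* **x1, commonness**: the fraction of corpus formulas containing the piece,
  f(t)/N, in [0, 1]. On large corpora (tens of thousands of formulas) this
  is of order 1e-4..1e-2, which is why the reference coefficient w1 is
  large (52.8). On small corpora x1 is much bigger and dominates the score;
  scores therefore rank formulas *within* one corpus and are not comparable
  across corpora of different sizes.
* **x2, name match**: 1 if the piece's canonical name, or any raw synonym
  the dictionary maps to it, occurs as a substring of the formula name.
  Matching runs on canonicalized terms, so 蛇黄丸 matches the piece 蛇含石.
* **x3, relative dose**: the piece's dose in this formula divided by its
  *general dose*, defined as the count-weighted mean of all resolved doses
  of that piece across the corpus (grams scale). An alternative x3 — the
  Gaussian kernel dose relevance below — is selectable via
  `compute_features(..., x3_mode="kernel")`. The ratio is the default
  because the annotated reference rows have x3 magnitudes consistent with
  small dose ratios.

The model `y = w0 + w1·x1 + w2·x2 + w3·x3` is fit by ordinary least squares
(`numpy.linalg.lstsq` behind a scikit-learn estimator interface). Fitting
requires at least 4 rows and a full-rank design; the training RMS is stored
on the fitted object. The bundled `reference_model()` carries the
coefficients of a 400-row expert annotation study (w0=3.0705, w1=52.8231,
w2=0.8773, w3=0.0470; reported deviation 0.719). On the nine-row annotation
excerpt that ships with the package, that model's RMS deviation is 0.540,
and rounding its predictions reproduces the annotated weights of the two
rows with a name match (Gentiana macrophylla → 4) and without (niter → 3).

Two cells of the bundled excerpt are typographically ambiguous in the
source material (the cinnabar and clove x3 values could carry one more
trailing digit); the shorter reading is recorded, and the docstring of
`reference_rows` notes the alternative.

## Dose relevance kernel

For a piece with n *distinct* observed doses t_i (grams), the relevance of
a query dose t is the kernel density estimate

    f(t|S) = 1/(n·h·√(2π)) · Σ_i exp(−d(t, t_i)² / (2h²))

with dose distance d the absolute difference of grams-normalized doses —
unit conversion is the only normalization the standardization pipeline
guarantees, so no other metric is defensible. Each kernel carries the 1/h
normalization of a proper Gaussian density, so f integrates to one over the
dose axis regardless of h (property-tested by numerical quadrature, 1e-3
tolerance). Counts of repeated identical doses do not enter the kernel sum
(n counts distinct values); they do enter the general dose and the
bandwidth. The bandwidth defaults to Silverman's rule h = 1.06·σ·m^(−1/5)
on the piece's observed doses (m = total observation count, σ the
count-weighted standard deviation), floored at 0.1 g so single-valued or
zero-variance observation sets still yield a usable kernel; a fixed h is
configurable (`KernelConfig`).

## Commonness vs. rarity

Two corpus-frequency quantities coexist deliberately. The *feature* x1 is
the plain fraction f(t)/N. The *full-text ranking weight* is the inverse
document frequency w(t) = ln(N/f(t)) (natural log), zero for a term in
every formula and strictly decreasing in f(t); the ratio is read with N the
number of formulas, the standard IDF convention, since any other reading
makes the ratio dimensionally incoherent.

## Standardization

Segmentation is forward maximum matching against the term dictionary: at
each position the longest dictionary term wins, unmatched characters become
single-character tokens of semantic type "unknown". Tokens tile the input
exactly (0-based, half-open spans). This is a deliberate deterministic
design: every downstream computation consumes only dictionary terms, so a
statistical segmenter would add variance without adding signal. Term
normalization is a dictionary lookup and is idempotent (canonical terms map
to themselves). Dose normalization multiplies by a per-unit grams factor
from a user-editable table; the built-in default uses the late-imperial
convention 1 两 = 37.3 g (and 钱/分/厘/斤 accordingly), but historical unit
factors varied by dynasty and serious corpus work should supply its own
table. Unknown units never abort ingestion: the dose is kept with its raw
value and unit, flagged unresolved, and excluded from dose-based features
and statistics.

The semi-structured block dialect (labeled 【field】 lines, composition
entries `name value unit（note）` joined by ；) is an exchange format
designed to be exactly invertible: `render_blocks` followed by
`extract_formula` is the identity on every generated corpus, which the
suite tests at corpus scale.

## Retrieval semantics

Multi-piece queries intersect postings (AND); the combination score is the
arithmetic mean of the per-piece predicted weights, chosen so scores are
comparable across query sizes. Importance sort is score descending, ties by
formation year ascending (older first) then formula id; year sort is year
ascending, unknown years last. Features are computed from the live index at
query time — there is no score cache, and re-ranking against a frozen index
ignores formulas the index has not seen (documented staleness contract).
For ranking only, a query piece whose dose is unresolved in a particular
formula contributes x3 = 0 (the strict `compute_features` raises instead);
this keeps retrieval total without inventing a dose. Full-text queries
segment the keywords with the same dictionary, intersect token postings,
and rank by Σ IDF × term frequency over name plus original text; ties break
by formula id. Facet queries are pure conjunctive filters; a year
constraint matches only formulas with a known year. Unknown query pieces
produce an empty result with a warning, not an error.

## Synthetic corpora

The generator emulates exactly the structure the features feed on:

* piece usage: each formula draws 2–12 distinct pieces from a Zipf law over
  the vocabulary (default exponent 1.0, vocabulary 100) — a few workhorse
  herbs and a long tail, as in real formularies;
* roles: one Monarch (4) and one Minister (3) per formula, the rest
  Assistant/Guide (2/1) at random;
* doses: each piece has its own lognormal law (log-mean uniform over
  [0.7, 2.7] ≈ 2–15 g, log-sd over [0.2, 0.5]), multiplied by role/2 so
  Monarch doses run about twice the piece's base scale and Guide doses
  half; doses are rounded to 0.1 of the written unit, and 15% of doses are
  written in a historical unit (钱);
* names: with probability 0.7 the formula name embeds its Monarch piece
  (人参汤-style); otherwise the name comes from a character pool disjoint
  from piece names, so accidental name matches cannot occur;
* metadata: years uniform over [-200, 1912] with 10% unknown, departments,
  efficacy and nature/flavor/meridian tags from small configurable
  vocabularies.

One seed drives four independent sub-streams (piece laws, compositions,
names, metadata) via `SeedSequence.spawn`, so extending one stream never
perturbs the others. Defaults were chosen once as a realistic small-corpus
regime; tests and the evaluation keep them fixed.

What the generator does **not** emulate: real classical-Chinese phrasing
(blocks are structurally, not linguistically, realistic), dialectal dose
units, scribal variants beyond the bundled 蛇黄→蛇含石 synonym, and the
scale of historical formularies. Passing tests therefore demonstrate
algorithmic correctness and statistical behavior under a controlled law,
not linguistic robustness on archival text.

Annotated training rows for recovery studies are drawn with feature ranges
matching the reference annotation excerpt's magnitudes (x1 ∈ [1e-4, 0.01],
x2 ~ Bernoulli(0.3), x3 ∈ [0.01, 3]); the latent y is the affine model plus
Gaussian noise, optionally rounded and clipped to the 1..4 scale.

## Numerical and design notes

* OLS recovery is verified by simulation: at n = 400 and noise sd 0.1,
  refit coefficients fall within 3 standard errors of truth in ≥ 19/20
  seeds (standard errors from the usual σ²(XᵀX)⁻¹ estimate).
* Retrieval is verified against brute-force scans: on ten 200-formula
  corpora, every 1- and 2-piece query, every facet query and sampled
  combined queries must return the exact brute-force result set, and the
  importance order must equal a brute-force sort of the scores.
* Ties everywhere are broken deterministically (documented above), so
  identical corpus + model + query gives identical output.
* The corpus format is JSON lines and the index persists as JSON that
  embeds the corpus and dictionary, rebuilding postings on load — index
  construction is cheap and deterministic, so persisting postings would
  only add an invalidation hazard.
* Problem sizes in the test suite (corpora of 200 formulas, vocabulary
  100, 400-row training sets, 20-seed recovery studies) were chosen as the
  smallest sizes at which the statistical assertions have comfortable
  power.

## Limitations

* The importance model is linear; interaction effects (e.g. name match
  mattering more for rare pieces) are out of scope, as are regularized or
  nonlinear variants.
* Piece queries are AND-only; no OR, fuzzy, or approximate matching.
* The reference coefficients cannot be refit here: the 400-row annotation
  study is not distributed, only its nine-row excerpt.
* Historical unit conversion is a single static table per run; per-dynasty
  unit systems must be handled by running with period-specific tables.
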