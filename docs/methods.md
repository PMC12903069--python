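# Methods

## Classification model

`exposource` treats exposure-source labeling as grounded multi-label text
classification. The unit of output is a validated label set over the active
category vocabulary — by default the five exposure-relevant categories
`MEDICAL` (medications approved for human use or in late-stage clinical
trials), `ENDOGENOUS` (compounds produced by the human body, excluding
essential nutrients that cannot be synthesized internally), `FOOD` (naturally
occurring food compounds and additives), `PERSONAL CARE` (non-medicated
compounds in skincare, beauty or fitness products) and `INDUSTRIAL`
(synthetic compounds not used in medical, food or personal-care contexts) —
plus the reserved fallback `INFO`. `INFO` is exclusive by construction: it
denotes absence of classification-relevant evidence and never co-occurs with
a substantive category. A compound may carry several labels at once (e.g.
endogenously produced compounds that are also marketed drugs), and the
assumption throughout is that evidence for each category is judged
independently from the retrieved text.

The model never sees the compound in isolation: the prompt is the pure
function `render(spec, text)` of a structured `PromptSpec` (role preamble,
ordered category definitions, multi-label instruction, grounding reminder,
INFO instruction, output instruction) and the retrieved evidence, which is
appended verbatim after a fixed delimiter line. Keeping the definitions
mutually exclusive is deliberate: a precise `MEDICAL` boundary keeps
veterinary drugs and withdrawn compounds from silently inflating other
categories, and users tuning precision/recall trade-offs are expected to do
so by editing the definitions (the spec file is plain JSON/TOML), not the
code.

## Retrieval cascade

Evidence is retrieved by name, in a total, deterministic order:
Wikipedia(name), Wikipedia(synonym 1..k), PubMed(name), PubMed(synonym 1..k);
the first hit wins and no later source is consulted. The source preference
(encyclopedic body text before abstracts) reflects that abstracts
over-represent biomedical usage; exhausting Wikipedia across all terms before
the first PubMed query is our resolution of an ordering the workflow leaves
open — it preserves the source preference at the cost of occasionally
choosing a synonym's encyclopedia page over the name's abstracts.

Parameters, with defaults chosen to match the workflow's stated operating
point: `max_synonyms` = 5 (top synonyms in the provider's listed order,
case-insensitively deduplicated, never containing the query name),
`max_abstracts` = 3 (concatenated with blank-line separators in the
adapter's relevance order), LLM `temperature` = 0.

"Minimal processing" of retrieved text is defined here as: strip markup tags
and numeric citations, drop wiki-style heading syntax and trailing
reference/external-link sections, collapse whitespace runs, truncate to a
configurable character budget (default 50,000 characters — bounds prompt
cost and fixes a reproducible truncation point). Cleaning is idempotent.
Wikipedia redirects are followed; disambiguation pages count as a miss, since
their listing text is not evidence about the chemical. Transient transport
failures are retried 3 times with backoff; a name lookup that still fails
raises an error naming the compound, while a failed *synonym* lookup degrades
to an empty synonym list with a warning so one flaky service cannot abort a
batch. An optional on-disk cache stores the final document per compound;
cached re-retrieval performs zero adapter calls and returns byte-identical
documents.

Synonym expansion is powerful but known to be semantically unsafe for
polysemous trade names (one string naming both a drug and an unrelated
product); every document therefore records `matched_term` so such hits are
auditable downstream.

## Response normalization

Model output is requested as a plain-text comma-separated list (empirically
more stable than structured formats). Parsing splits on commas, trims
whitespace/quotes/trailing periods, uppercases, and exact-matches against the
vocabulary plus `INFO`. A token within Levenshtein distance ≤ 2 of exactly
one canonical label is repaired with a recorded warning (real LLM output
contains occasional misspellings such as "ENDOGENEOUS"); an ambiguous or
unmatched token raises a parse error carrying the token and the verbatim
response — the parser never emits a label outside the vocabulary. `INFO`
co-occurring with substantive labels is dropped with a warning, preserving
its absence-of-evidence semantics. On a parse failure the backend is re-asked
once with a short format reminder; a second failure yields a record flagged
`failed` with the raw response preserved, and batches tolerate failures up to
a configurable fraction (default 0.5) before aborting.

## Benchmark metrics

Per-category precision, recall and F1 are computed over label-set
membership (TP/FP/FN counted per compound), alongside the exact-set
agreement fraction and the histogram of symmetric-difference sizes. Zero
denominators leave a metric undefined (`None`) rather than silently zero.
An `INFO` prediction is treated as "no substantive prediction": by default
such pairs are excluded from the metrics (mirroring evaluations reported
over the classified subset); with `include_info=True` they are kept and
count as disagreement with any non-empty reference. `strip_category`
supports re-evaluating agreement after removing a dominant category from
both sides (pairs whose reference empties are dropped; predictions that
empty become an explicit no-prediction marker that disagrees with any
reference). Reproducibility across repeated runs is summarized as
per-compound occurrence rates of a focal label. Point metrics only — no
confidence intervals are reported, matching how such benchmarks are usually
presented; bootstrap CIs can be layered on by resampling pairs externally.

## Context refinement and exposure profiles

Sample context resolves multi-label over-representation: BIOSPECIMEN keeps
the `ENDOGENOUS`/`FOOD` part of a multi-label set (both survive if both are
present), FOOD_EXTRACT reduces any multi-label set containing `FOOD` to
`FOOD` only, PRODUCT_OR_SURFACE keeps the `PERSONAL CARE`/`INDUSTRIAL` part,
and NONE applies no refinement (appropriate when no dominant exposure source
is expected, e.g. environmental dust). Singletons are never modified, the
rules never empty a set or introduce a label, and refinement is idempotent —
all verified exhaustively over the 31 non-empty subsets × 4 contexts.

A dataset's exposure profile sums each compound's detection frequency (the
caller-supplied fraction of samples in which it is detected; upstream MS
processing is out of scope) into every category it carries, then
sum-normalizes. Full-frequency crediting is the default because a compound's
presence supports each of its sources equally; an even fractional-split mode
(`split_frequency=True`) is available for sensitivity analysis. `INFO` rows
are excluded from profiles (absence of evidence is not a source) but counted
in the profile metadata. Profiles are scale-invariant in the frequencies and
sum to 1 within 1e-9.

## Synthetic corpus and mock backends

The fixture generator emulates the retrieval situations a real batch
encounters, with defaults: 200 compounds, primary-category probability 0.18
per category (remainder 0.10 unretrievable), multi-label rate 0.3 (one or
two extra categories), synonym-only rate 0.2 (compound documented only under
an alias listed in its synonym file), PubMed-only rate 0.2. These rates make
every cascade rung and the INFO path well-populated at a size that runs in
seconds. Signal tokens are artificial (`SIGNAL_<CATEGORY>`) precisely so the
mock classification is unambiguous: end-to-end truth recovery demonstrates
that retrieval, prompt assembly, grounding and parsing are correct, not that
any language model understands chemistry. Passing these tests therefore says
nothing about real-world classification accuracy, which depends on the live
corpora and the chosen LLM. The mock emits matches in the fixed canonical
category order; `NoisyBackend` adds seed-deterministic formatting noise
(case changes, stray whitespace/periods, single-character duplications and
deletions), each perturbation pre-verified to remain uniquely recoverable so
the noise tests measure parser robustness rather than constructed ambiguity.

## Numerical and design notes

* Determinism: all randomness flows through explicit seeds (`random.Random`);
  fixture bundles are byte-identical across runs, and batch classification
  with the mock backend is byte-identical across platforms.
* Edit distance is a standard dynamic-programming Levenshtein on ≤ 13-char
  tokens; the distance-2 repair threshold is safe because canonical category
  names are mutually distant.
* Live adapters (Wikipedia action API, NCBI E-utilities, PubChem PUG REST)
  use only the standard library and are exercised by none of the tests;
  remote LLM backends are left to the user via the two-method `LLMBackend`
  protocol, keeping credentials and SDK choices out of the package.
* Known limitations: retrieval quality bounds classification quality
  (poorly documented compounds fall to `INFO`); polysemous synonyms can
  retrieve the wrong referent (auditable via `matched_term`, not auto-
  detected); the evaluator assumes references are substantive (INFO-labeled
  reference rows are skipped when loading benchmark tables); no
  asynchronous/parallel querying — batches are serial for reproducibility,
  which is the binding constraint for very large live runs.
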