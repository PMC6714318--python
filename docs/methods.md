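# Methods

## The extraction model

`clinex` treats concept extraction as an ensemble decision problem. Each
backend extractor is a black box that maps a document to surface mentions;
the framework's own contribution is everything after that: negation
filtering, normalization to ranked code candidates, and a two-stage
weighting scheme that decides (a) which mentions from different extractors
denote the same concept and (b) which concepts were really extracted.

**Stage 1 — term similarity.** Every mention is normalized to at most ten
code candidates ranked best-first (the top-10 interface of a UMLS-style
terminology service). For two normalized terms *a*, *b*, let α be the
number of shared (code_system, code) pairs between their full candidate
lists divided by 10, and β the number shared between their top-3 lists
divided by 3. The pair weight is

    w(a, b) = α/4 + 3β/4  ∈ [0, 1],

and the terms are "equal" when w > γ (strict). The denominators are the
fixed capacities 10 and 3, not the actual list lengths: a term with a
short candidate list can only be penalized, never inflated. A term with no
candidates has w = 0 against everything and can only group with mentions
sharing its normalized surface (via per-extractor dedup), never across
extractors. β is computed as the intersection of *both* top-3 sets over 3;
weighting the top of the ranking 3× reflects that rank-1–3 candidates are
far more likely to be the intended sense.

Entities are the connected components of the "equal" relation (computed by
union-find; transitive closure). Pairwise equality alone would depend on
comparison order; components give a well-defined, input-order-invariant
partition. The cluster representative is the member with the most code
candidates (richest evidence), ties broken by earliest span, then
lexicographic surface.

**Stage 2 — extractor confidence.** Each extractor *i* has weight
ω_i ∈ [0, 1], estimated by measuring its single-extractor F1 on a held-out
annotated sample and sum-normalizing, so Σω = 1 over the roster. An
entity's cumulative weight is Σω_i over the *distinct* extractors
contributing members (an extractor counts once regardless of mention
count). The entity is accepted iff that sum > θ (strict). Both thresholds
are strict: weight exactly at threshold is rejected/not merged.

Monotonicity follows directly: raising γ can only delete merge edges
(entity count non-decreasing); raising θ can only shrink the accepted set;
the κ filter can only remove mentions (recall with κ on ≤ recall with κ
off). These are asserted as property tests.

## Negation

A rule-based NegEx-style detector. Sentences are split at `. ! ? ;`
followed by whitespace; tokens are whitespace-delimited, matched to
trigger phrases after lowercasing and stripping surrounding punctuation.
Pseudo-triggers ("no increase", "gram negative") are checked before real
triggers and consume their tokens without opening a scope. A pre-trigger
("no", "denies", "without") negates up to `window` tokens forward, cut by
a terminator ("but", "however", …) or the sentence end; post-triggers
("was ruled out", "unlikely") scope backward symmetrically. Overlapping
scopes within a sentence are merged. Any character overlap between a
mention's span and a scope flags the mention; mentions without spans are
located by their first surface occurrence. The default window is 5 tokens,
the standard convention for this family of algorithms; the trigger list
ships as an editable `phrase<TAB>role` text resource
(`clinex/data/negex_triggers.tsv`) so deployments can extend it.

This detector uses cue words only — no semantics, no uncertainty classes —
so double negation, negation expressed morphologically, and scope
ambiguity across clauses are known failure modes. That is the reason the
κ switch exists rather than negation being unconditional: on corpora where
gold annotations count negated mentions as present, filtering hurts
recall.

## Evaluation

Predictions are matched to gold annotations greedily one-to-one: a code
pass first (an entity matches a gold row when any member's primary code
appears in the row's codes — the entity-level reading of code identity,
since a merged synonym cluster should match through any member), then a
surface pass on normalized surface equality. TP = matched rows annotated
present; FN = present rows left unmatched. FP counts matched rows
annotated absent, plus — for exhaustive-style gold where every true
mention is annotated — predictions matching nothing. For label-style gold
(a fixed term list marked present/absent per document, with no claim of
exhaustiveness) unmatched predictions are ignored
(`unmatched_prediction_is_fp=False`).

Counts are micro-aggregated (summed over documents before computing
precision/recall/F1); macro averaging is exposed for comparison but micro
is the default because per-document metrics are ill-defined on documents
with no gold. All 0/0 ratios are defined as 0. Residual error is
decomposed as fp/(fp+fn) and fn/(fp+fn), undefined (reported absent) when
there is no error.

Hyperparameter tuning is an exhaustive grid over (κ, γ, θ) with the
argmax-F1 cell reported; ties prefer smaller θ, then smaller γ, then κ
off — the least aggressive configuration among equals.

## Synthetic study conditions

The generator emulates the structure of annotated clinical corpora, not
their language. Defaults, chosen once as a realistic operating point:

| parameter | default | rationale |
|---|---|---|
| n_docs | 50 | enough documents for stable micro metrics at desk scale |
| lexicon_size | 40 | dozens of distinct concepts, as in condition-focused gold sets |
| entities_per_doc | 2–5 | typical concept density of a short discharge note |
| negation_rate | 0.15 | negation affects roughly one in six clinical findings |
| sensitivities | 0.9 / 0.8 / 0.7 | a clearly ordered three-extractor roster |
| spurious_rate | 0.5 / doc | moderate false-mention pressure per extractor |

The lexicon mixes fixed clinical stubs (asthma, hematoma, orthostatic
hypotension, …) with pronounceable pseudo-terms; every fourth entry spawns
a near-synonym (`<surface> disorder`) sharing its two top-ranked codes, so
similarity-based merging is genuinely exercised (such pairs have
w ≥ 0.25). Documents embed each gold entity in template prose; a
`negation_rate` fraction use negation-trigger templates and are annotated
absent, so the κ filter is rewarded for removing them. Document sampling
never places a surface and its near-synonym in the same document, keeping
"distinct concepts per document" well defined. Simulated extractors emit
each supported gold mention with their sensitivity (true spans) and add
Poisson-distributed spurious lexicon terms (no spans). All generators are
pure functions of the spec seed, via independent seeded streams per stage.

What passing tests on these corpora show: the integration arithmetic,
threshold behaviour, weight estimation and evaluation logic are correct,
and ensembling helps under controlled error rates. What they do not show:
performance on real clinical language — no abbreviation ambiguity, no
misspellings, no section structure, no tokenization drift between
backends, and negation always phrased by a known trigger. Reported
numbers on synthetic corpora characterize the method under its
assumptions, not expected clinical accuracy.

## Numerical and interface conventions

- Spans are 0-based half-open [start, end) character offsets; UTF-8
  everywhere.
- Surface lookup normalization: lowercase, strip punctuation, collapse
  whitespace, fall back to stripping a trailing "s" ("hematomas" →
  "hematoma"). No stemming beyond that.
- Candidate lists are truncated to 10 wherever assembled; ranks must be
  contiguous from 1.
- Per-document dedup key: top-ranked code when available, else normalized
  surface; the earliest mention by span start represents the group.
- ω maps are validated to [0, 1]; estimation from all-zero F1s is a
  degenerate-input error rather than a silent uniform fallback.
- Mock extractors match fixture surfaces case-insensitively on word
  boundaries, longest surface first, tolerating a simple plural; they are
  pure functions of (text, fixture).
- A failed backend is dropped for the whole run and the remaining
  extractors keep their configured ω (no renormalization): the ensemble
  degrades by losing that extractor's votes, which lowers cumulative
  weights rather than silently re-inflating the survivors.
- The pipeline's de-identification hook is a pass-through slot applied to
  document text before extraction, left as the mount point for external
  anonymization tooling; no de-identification is implemented here.
- REST adapters are contract-only: request building and response parsing
  are pure, tested functions; live calls are not exercised anywhere in the
  test suite and the adapters are best-effort against vendor schemas.

## Known limitations

- Negation handling is lexical; advanced context/uncertainty detection is
  out of scope.
- No word-sense disambiguation and no cross-code-system translation; one
  code system per lexicon run.
- Gold matching is document-level (presence of a concept), not
  span-level; boundary quality of extractors is not scored.
- Grid tuning is exhaustive enumeration; no continuous optimization of
  γ/θ.
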