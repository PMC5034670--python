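# Methods

This note documents the models, rules and numerical choices behind
`gbdmap`, the assumptions they rest on, and what the shipped tests do
and do not demonstrate.

## The classification model

The classifier is a deterministic knowledge-based pipeline. For each
trial record (id + three free-text fields: health condition, public
title, scientific title) it derives *pathways*
`field → concept → ICD-10 code/block → GBD category` and then selects
the final category set by prioritization. There is no training step and
no randomness anywhere in classification; identical inputs and switches
always produce identical output.

### Annotation

The built-in annotator is an exact, greedy, leftmost-longest dictionary
matcher over normalized tokens (lowercased, punctuation mapped to
spaces). It stands in for a full concept recognizer: the downstream
stages only consume (field, CUI) pairs, so externally produced
annotations can be substituted through the JSON ingestion path. Design
choices:

* **No fuzzy matching in v1.** Exact matching keeps false-positive
  behavior auditable; misspelled mentions are simply missed. The typo
  perturbation in the fixture module quantifies that cost.
* **Spans** are 0-based half-open character intervals into the original
  field text; every annotation's `matched_text` equals the slice.
* **Disorder filter.** Only concepts with ≥ 1 semantic type from the
  disorder group (default: the 11 packaged DISO-group type codes,
  configurable per lexicon) can be annotated.
* **WSD surrogate.** When a span matches several concepts, the optional
  disambiguation step keeps the concept whose preferred name has the
  highest normalized `difflib.SequenceMatcher` ratio to the matched
  text, ties broken by smallest CUI. This is a deterministic stand-in
  for an interactive disambiguation service; its output is by
  construction a subset of the undisambiguated output with at most one
  concept per span.

### Concept → ICD-10 (Restrict-to-ICD10 style)

A concept's own crosswalk entries win. Only if there are none does the
algorithm ascend the is-a hierarchy breadth-first and return the union
of crosswalk entries at the first depth where any ancestor is mapped.
The traversal uses ancestors only (no sibling or "related concept"
hops) and stops at the shallowest productive depth — the minimal
deterministic reading of the restrict-to family of mappings. The
operation is monotone in the crosswalk: adding a direct entry can only
add to, or replace the fallback of, the result.

### ICD-10 → GBD category (unique inclusion)

A grouping assigns ICD-10 codes and blocks to categories; expansion of
those assignments yields a code map that construction-time validation
requires to be collision-free across non-residual categories. A
four-character code projects to its mapped category, falling back to
its three-character parent; a three-character code projects only when
it and all of its known four-character extensions lie in a single
category (so `P37`, split between tuberculosis and neglected tropical
diseases, projects to nothing). Residual catch-all categories are
loadable for bookkeeping but never assignable.

Blocks are expanded over the *syntactic grid* — every three-character
code with its ten one-decimal extensions, clipped to the endpoints,
optionally intersected with a caller-supplied universe — rather than
against the official ICD-10 tabular list, which is not redistributable.
A bare end code (`…–F39`) is an exact endpoint; a `.9` end
(`…–F39.9`) covers all extensions. This follows from the total order
placing the minor-less code immediately before its `.0` extension, and
keeps expansion deterministic. Block projection restricts candidate
codes to those the grouping knows about (or their three-character
parents), then unions the per-code projections; a metamorphic test
asserts equality with the brute-force per-code union.

### Enrichment

The expert table (CUI → category ids) is consulted *per concept*, and
only for concepts whose automatic route yields nothing; pathways built
from it carry no ICD-10 code. Stage order is load-bearing and tested:
enrichment can never override an automatic projection, and enabling it
can never increase the number of "No GBD" trials. The package ships an
empty template plus synthetic fixtures; a real curation drops in as a
two-column TSV.

### Prioritization

Two rules, isolated in one function so alternates can be configured:

1. **Field priority** (switchable): if any pathway from the condition
   field reaches a category, only condition-field pathways are
   retained. When the condition field yields nothing — empty fields,
   entry errors, "Healthy volunteers" — title pathways are used, since
   otherwise such records could never be classified at all.
2. **Multiplicity:** each candidate category is scored by its number of
   distinct (CUI, ICD-10 spec) supports among retained pathways (an
   enrichment route is the single pair (CUI, ∅)). If the maximum score
   is ≥ 2, candidates scoring 1 are dropped; otherwise all are kept.
   The threshold-2 reading of "consistently supported beats isolated"
   is this package's design choice; the support unit deliberately
   ignores the field so a mention repeated across fields is not
   double-counted.

Multi-label output is allowed. An empty final set is the "No GBD"
outcome (`no_gbd` is derived from the category set, so the two can
never disagree). The switches WSD × enrichment × field-priority span
the eight variants exposed as `ALL_VARIANTS`; `BEST_VARIANT` names the
all-on combination.

## The packaged 28-class grouping

`data/gbd28.tsv` encodes the 28-category consensus grouping of the GBD
2010 cause list plus its two excluded residual categories ("Other
infectious diseases"; "Other endocrine, nutritional, blood, and immune
disorders"). **The ICD-10 assignments are this package's curation**:
the authoritative cause-by-cause ICD crosswalk is licensed and not
redistributable, so standard ICD-10 chapter ranges were assigned to
each category, preserving the documented structural facts (M16/M16.9
in Musculoskeletal disorders; F30–F39.9 wholly inside Mental and
behavioral disorders; P37.0 under Tuberculosis and P37.3 under
Neglected tropical diseases, leaving P37 unprojectable; mutual
exclusivity of all non-residual assignments). Analyses needing the
official mapping should load their own grouping TSV — the format is
four columns, one spec per row. `data/gbd28_names.tsv` carries the
defining disease names per category for the verbatim baseline. Only
ICD-10 is supported; ICD-9 is out of scope.

## Evaluation layer

* **Exact matching**: per-trial hit iff predicted set equals gold set
  (both empty counts as a hit), reported overall and stratified by gold
  complexity (one category / two or more / none), optionally per data
  source.
* **Per-category metrics**: one-vs-rest 2×2 tables over trials, with
  "No GBD" scored as its own pseudo-category (positive ⇔ empty set).
  Multi-label trials are positive for each of their categories.
* **Undefined values are absent, not 0 or 100**: Sen with no gold
  positives, PPV with no predicted positives, LR+ when tp = 0 or
  fp = 0, LR− when fn = 0 or tn = 0 are all reported as missing (`-`
  in the TSV). Likelihood ratios are computed from raw counts, not from
  rounded percentages.
* **Intervals**: proportions get two-sided 95 % Wilson score intervals
  (asymmetric, well-behaved at the boundaries; implemented in closed
  form and cross-checked in tests against an independent reference
  implementation); likelihood ratios get the standard log-ratio normal
  approximation. Endpoints are exact 0/1 when the count is 0/n.
* **Weighted averages** of Sen and Spe weight each category — including
  "No GBD" — by its gold-positive trial count; zero-weight or undefined
  categories drop out of the average, and an all-empty gold set raises.

## The synthetic-data generator

`simulate.generate_bundle` emits a self-consistent bundle (lexicon,
grouping, trials CSV, gold TSV, enrichment TSV) in exactly the formats
the loaders read. Each synthetic category owns one ICD-10 letter
(`X00–X99.9`); each concept's crosswalk lands inside its own category;
trial texts are templated from the concepts' terms; gold labels are
fixed at generation time so classifier bugs cannot redefine truth.
Defaults — 200 trials, 6 categories, 4 terms per category, 10 % empty
conditions, 5 % each of title-only, healthy-volunteer, ambiguous-term
and multi-label trials, no enrichment-only trials — are one fixed
choice of a plausibly messy registry corpus, not tuned quantities.

Designed-in guarantees, which the tests rely on:

* On an unperturbed bundle with `p_ambiguous_term = 0`, **every**
  variant achieves 100 % exact matching. Empty-condition and
  title-only trials carry their terms in the titles (exercising the
  field-priority fallback); healthy-volunteer trials contain no
  lexicon term and are gold No-GBD; multi-label trials mention one
  term per gold category with equal support counts; every fourth
  concept has its codes on a synthetic parent, exercising hierarchy
  ascent.
* Ambiguous terms are registered under two CUIs in different
  categories (single-code senses, and the gold sense's preferred name
  equals the term with the smaller CUI), co-mentioned with an
  unambiguous gold-category term — so WSD, the multiplicity rule and
  the tie-break all pull toward gold and the 100 % guarantee survives
  `p_ambiguous_term > 0`.
* `p_enrichment_only` (default 0) makes a trial's only route run
  through the enrichment table; such corpora separate the
  enrichment-on and -off variants and drive the monotonicity property
  tests.

What the generator does **not** emulate: real registry language
(abbreviations, multilingual noise, misspellings beyond the seeded typo
model, nested or discontinuous mentions), realistic category prevalence,
or genuinely contested gold labels. A perfect score on clean synthetic
corpora therefore validates the pipeline's internal consistency — term
matching, projection, prioritization, IO round-trips — not performance
on real registry text, which depends on the quality of the lexicon
supplied.

`perturb` applies seeded character-level typos (adjacent swap, drop,
double) and synonym swaps (same-concept term replacement) to the text
fields, leaving ids and gold untouched; exact matching is empirically
non-increasing in typo rate across seeds.

## Problem sizes and determinism

The shipped suites use corpora of 25–500 trials, 3–6 categories, 100
generator seeds for the variant-property checks and 1,000 random blocks
for the expansion oracle — sizes chosen so the whole suite completes in
well under a minute while still exercising every branch. All randomness
flows through explicitly seeded NumPy generators (the property-test
framework runs derandomized); `scripts/acceptance.py` derives all of
its seeds from `--seed`.

## Known limitations

* English-only matching; tokens are ASCII-alphanumeric runs, so accented
  or non-Latin terms are treated as separators.
* Exact matching only: no stemming, abbreviation expansion or spelling
  correction.
* The restrict-to fallback uses ancestors only; terminologies whose
  mappings live on "related" (non-ancestor) concepts need those edges
  re-expressed as parents or the crosswalk filled directly.
* The packaged grouping's ICD ranges are a curation approximation (see
  above), adequate for structure-dependent behavior but not for
  reproducing published per-category counts.
* The multiplicity rule's threshold (2) is fixed; trials whose true
  category has a single isolated support alongside a doubly-supported
  noise category will be misclassified.
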