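# gbdmap

Knowledge-based classification of registered clinical trials onto the
Global Burden of Disease (GBD) 2010 cause taxonomy.

## The problem

Clinical trial registries (the WHO ICTRP, clinicaltrials.gov and the
national registries they aggregate) describe the condition studied by a
trial in free text — the "Health Condition(s) or Problem(s) studied"
field plus the public and scientific titles — not in any standardized
disease taxonomy. That makes it impossible to compare, at scale, where
health research effort goes against where the burden of disease lies.
`gbdmap` closes that gap: it maps each trial record to a 28-class
grouping of the GBD cause list (or any user-supplied grouping), so
trial counts can be set against burden estimates category by category.

It is a tool for clinical-trial informaticians and public-health
researchers: a library plus a `gbdmap` command-line interface.

## The method

The classifier is knowledge-based, not statistical. For a trial record
it derives *pathways* — traced routes
`field → concept → ICD-10 code → GBD category` — through five stages:

1. **Annotation.** Each text field is scanned by a deterministic
   leftmost-longest dictionary matcher over a mini-metathesaurus
   (concepts with UMLS-style CUIs, synonym terms, an is-a hierarchy and
   a concept→ICD-10 crosswalk, loadable from open TSV files). Only
   concepts with a disorder-group semantic type are kept. An optional
   word-sense-disambiguation step keeps one concept per matched span.
   Externally produced annotations (e.g. converted MetaMap output) can
   be ingested instead.
2. **Concept → ICD-10** (Restrict-to-ICD10 style): a concept's own
   crosswalk entries, else the union of entries at the shallowest
   mapped ancestor depth.
3. **ICD-10 → GBD category** under a unique-inclusion rule: a code is
   assigned only if it and its known four-character extensions fall
   inside a single non-residual category (`P37` famously fails: `P37.0`
   is tuberculous, `P37.3` a neglected tropical disease). Blocks like
   `F30–F39.9` are split into their 110 constituent codes and project
   to the union of per-code assignments.
4. **Expert enrichment** (optional): a curated concept→category table
   consulted only for concepts with no automatic route.
5. **Prioritization.** Optionally restrict to condition-field pathways
   when they yield anything (titles serve as fallback); then keep the
   categories supported by ≥ 2 distinct (concept, code) pairs whenever
   any category is, discarding isolated, likely-noise candidates. An
   empty result is the "No GBD" outcome.

The three switches (WSD, enrichment, field priority) give the 2×2×2
grid of eight classifier variants. A verbatim-match baseline — category
assigned iff one of its defining disease names appears word-bounded in
the text — is included for comparison, as is an evaluation layer:
exact-matching stratified by gold-label complexity, per-category
sensitivity / specificity / PPV with 95 % Wilson intervals, likelihood
ratios LR+ = Sen/(1−Spe) and LR− = (1−Sen)/Spe with log-normal
intervals, and gold-weighted averages across categories.

## Worked example

```python
import gbdmap as g

grouping = g.packaged_grouping()            # 28 categories + 2 residual
lexicon  = ...                              # e.g. g.load_lexicon("lexicon_dir/")

trial = g.TrialRecord(
    "NCT0000001",
    condition="Knee Osteoarthritis; Hip Osteoarthritis",
    public_title="Knee and Hip Osteoarthritis Study",
    scientific_title="A randomized trial in knee osteoarthritis and hip osteoarthritis",
)
result = g.classify_trial(trial, lexicon, grouping, config=g.BEST_VARIANT)
print(sorted(result.categories), result.no_gbd)
for p in result.trace:
    print(p.field_name, p.cui, p.icd10, "->", p.category_id)
```

With a lexicon holding the knee/hip osteoarthritis concepts this prints

```
['musculoskeletal'] False
condition C0029410 M16 -> musculoskeletal
condition C0029410 M16.9 -> musculoskeletal
condition C0409959 M17 -> musculoskeletal
condition C0409959 M17.9 -> musculoskeletal
...
```

— every pathway (hip osteoarthritis via the coxarthrosis codes M16 and
M16.9, knee osteoarthritis via M17 and M17.9) arrives at the same
category, so the trial is classified *Musculoskeletal disorders* under
every variant.

The same flow from the shell, on a synthetic corpus generated by the
fixture module (no licensed resources needed):

```bash
gbdmap simulate --seed 42 --out demo/data
# wrote bundle with 200 trials, 48 concepts -> demo/data
gbdmap classify --input demo/data/trials.csv --format csv \
    --lexicon demo/data/lexicon --grouping demo/data/grouping.tsv \
    --enrichment demo/data/enrichment.tsv --out demo/pred.tsv
# classified 200 trials (15 No GBD) -> demo/pred.tsv
gbdmap evaluate --pred demo/pred.tsv --gold demo/data/gold.tsv \
    --grouping demo/data/grouping.tsv --out demo/report
# exact matching 100.0% (200/200) -> demo/report.tsv, demo/report.json
```

The 15 "No GBD" trials are the generated healthy-volunteer records; on
a clean (noise-free) bundle the classifier recovers every gold label,
which is the generator's designed-in contract. `gbdmap variants` runs
all eight switch combinations, `gbdmap baseline` the verbatim-name
baseline, and `gbdmap.simulate.perturb` injects seeded typos and
synonym swaps to study degradation.

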