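# archeq — query-expansion retrieval for openEHR archetypes

openEHR archetypes are reusable clinical content models (blood pressure,
medication order, health summary …) hosted in repositories whose search is a
plain substring match over the archetype's concept name and description.
Archetype names use professional medical wording, but searchers — clinicians
of varying specialty and especially lay users — reach for synonyms: *fetal
heartbeat* instead of *fetal heartrate*, *health abstract* instead of
*health summary*. A substring backend cannot bridge that gap, so direct
search misses its target for most lay queries.

`archeq` fixes the query instead of the repository. For an original search
term *q* it runs three steps:

1. **Term segmentation** — *q* is split into sub-terms
   *s₁ … s_m* by dictionary-based forward maximum matching (needed for
   scriptio-continua languages such as Chinese, where words are unspaced).
2. **Term expansion** — each sub-term is mapped to its Top-N nearest
   neighbours by cosine similarity in a skip-gram (Word2Vec) embedding
   space trained on a general corpus, giving Σᵢ nᵢ *expansion terms*.
3. **Term combination** — one candidate per sub-term is chosen in every
   possible way and rejoined in order, giving Πᵢ nᵢ *combination terms*
   (two sub-terms at Top-3 → 6 expansion and 9 combination terms; at
   Top-10 → 20 and 100).

All substitutes (plus the original term) are searched against the archetype
index; hits are merged by archetype id and re-ranked by
cos(v(q), v(name)), where v(·) is the mean embedding of a phrase's
in-vocabulary tokens. Runs are scored with

- **P@K** = (1/N) Σᵢ δ(i, K), where δ(i, K) = 1 iff query *i* has an
  acceptable archetype in its top K (K ∈ {3, 5}),
- **AP** = mean of P@3 and P@5 for one test set,
- **MAP** = arithmetic mean of AP over test sets,

and compared against **baseline mode** (searching the unexpanded term).

The package is audience-facing for health-informatics engineers evaluating
retrieval over archetype repositories, and ships a synthetic-data module so
the whole pipeline is testable offline: a generated script-continuous
language with *planted synonym pairs* (a professional token and a lay
partner occurring interchangeably in identical sentence templates), a toy
archetype index over that vocabulary, and gold query sets built by
swapping professional name tokens for their lay partners.

## Worked example

Generate a synthetic study, train embeddings, and search:

```
archeq simulate --outdir fx --seed 42 --n-sentences 800 --n-archetypes 40 \
                --n-queries 8 --levels low
archeq train --corpus fx/corpus.txt --out model.txt --dim 32 --epochs 2 --seed 42
archeq expand pidoraki --model model.txt --lexicon fx/lexicon.txt \
              --language xx --top-n 3
```

```
original term : pidoraki
sub-terms     : pido, raki
expansion terms (Top 3, sum: 6):
  zudo
  dusi
  nebi
  tota
  pumi
combination terms (Top 3, sum: 9):
  zudotota
  zudozudo
  zudopumi
  ...
```

`pido` is the planted lay synonym of the professional token `zudo`, and the
embedding recovers that: `zudo` is its first expansion term. The sums 6 and
9 are the 2·3 expansion and 3² combination counts for a two-sub-term query
at Top-3 (5 expansion terms are listed because duplicates across sub-term
lists are merged). Searching a gold query whose name token `zudo` was
replaced by `pido`:

```
archeq search pidototamibu --index fx/index.jsonl --model model.txt \
              --lexicon fx/lexicon.txt --language xx --top-n 3 --out run.tsv
```

```
query         rank  archetype_id                              similarity  matched_terms
pidototamibu  1     openEHR-EHR-EVALUATION.zudo_tota_mibu.v1  0.999842    zudo
pidototamibu  2     openEHR-EHR-EVALUATION.mibu_ropu_raki.v1  0.999568    raki
pidototamibu  3     openEHR-EHR-INSTRUCTION.dusi_tota.v1      0.999174    dusi
```

The gold archetype (`…zudo_tota_mibu.v1`) is ranked first — retrieved by
the expansion term `zudo` and promoted by its semantic similarity to the
query — while the same search with `--baseline` returns nothing, because
`pidototamibu` is not a substring of any archetype's text.
`archeq evaluate --run run.tsv --gold fx/gold_low.tsv` then prints the
P@3/P@5/AP report; on this seed the expanded run scores P@5 = 1.0 and the
baseline 0.0.

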