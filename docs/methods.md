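# Methods

## The retrieval model

The package addresses vocabulary mismatch in archetype retrieval: the
repository backend is a case-insensitive contiguous substring match over an
archetype's concept name, description and keywords (phrase-level, no
tokenization — `completes_search`), and a query phrased with a synonym of
the concept name therefore returns nothing. The method substitutes the
query rather than changing the backend:

1. **Segmentation.** The query is split into sub-terms. The built-in
   segmenter is dictionary-based forward maximum matching (greedy longest
   match left to right, single-character fallback for out-of-lexicon
   material); any object with a `segment(text) -> list[str]` method can be
   plugged in instead. Whitespace always separates chunks, so the same
   segmenter handles both spaced and unspaced scripts.
2. **Expansion.** Each sub-term is expanded to the Top-N tokens by cosine
   similarity in a skip-gram embedding space, with N ∈ {3, 5, 10} as the
   standard thresholds. The query token itself is excluded from its
   neighbour list. An out-of-vocabulary sub-term contributes itself as its
   only candidate and is flagged, so partial expansion still occurs.
3. **Combination.** The cartesian product over the per-sub-term candidate
   lists, rejoined in original sub-term order — with no delimiter for
   script-continuous languages (language codes `zh`, `ja`, `th`, and the
   synthetic `xx`), a single space otherwise. Enumeration is
   rank-lexicographic (first sub-term's rank varies slowest). With one
   sub-term there is nothing to combine and the list is empty.

Substitutes are deduplicated after case-folding and whitespace
normalization, but the raw counts Σᵢnᵢ and Πᵢnᵢ are kept for bookkeeping,
since the count laws (6/10/20 expansion and 9/25/100 combination terms for
a two-sub-term query at Top-3/5/10) are properties of the construction,
not of the deduplicated output. Combinations pair expansion candidates
only (not an expanded sub-term with the original other sub-term): that is
the reading under which the Πᵢnᵢ law holds exactly.

Retrieval searches every substitute plus the original term (so the
expanded hit set always dominates the baseline hit set), merges hits by
archetype id, and ranks by cosine similarity between the mean token
vectors of the query and of each hit's concept name. Undefined phrase
vectors (all tokens out of vocabulary) score 0 rather than being dropped,
preserving recall; ties break by ascending archetype id, making the
ranking a deterministic permutation of the hit set.

## Embedding training

The trainer is skip-gram with negative sampling, implemented directly on
numpy: for each centre word and a dynamically shrunk window (the effective
half-width is drawn uniformly from 1..window per centre, as in standard
Word2Vec), context words are positive targets and `negative` draws from
the unigram distribution raised to the 3/4 power are negatives; updates
use a learning rate decaying linearly from 0.025 to 1e-4. Defaults:
dim=100, window=5, epochs=5, min_count=1, negative=5 — skip-gram being the
standard architecture for synonym mining on modest corpora. Training is
seeded and single-threaded, so identical inputs give bit-identical
vectors. Input vectors (the `w_in` matrix) are the word representations;
sigmoid inputs are clipped at ±30 for numerical safety. Models are
exchanged in the word2vec text format at 6 significant digits, which
round-trips neighbour rankings exactly in practice.

Phrase vectorization is the unweighted mean of in-vocabulary token
vectors — the simplest convention consistent with needing a single
similarity per multi-word pair. Multi-word similarity semantics and the
choice to exclude the query token from its own neighbours are deliberate
design decisions where the method description leaves room; both are
localized (`phrase_vector`, `nearest_neighbors`) and easily overridden.

## Evaluation metrics

δ(i, K) is 1 iff any acceptable archetype id for query *i* occurs in its
top K; P@K averages δ over the N gold queries; AP is the mean of P@K over
the configured cutoffs (default {3, 5}); MAP is the arithmetic mean of AP
over test sets. A query may accept several ids and several queries may
share one target. Gold queries absent from a run score δ = 0 and are
listed in the report instead of raising. Reports round half-even to 3
decimals for display but always retain raw values, and tests compare raw
values at 5e-4 — printed tables in the literature round this family of
numbers inconsistently (0.9625 appears as 0.963, 0.6375 as 0.637), so the
raw value is authoritative here.

Structural invariants checked by the suite: P@5 ≥ P@3 (prefix
containment), min(P@K) ≤ AP ≤ max(P@K), permutation invariance in the
gold order, and monotonicity under promoting a gold id into the top-K.

## Synthetic study conditions

The generators emulate the statistical structure the method exploits,
not any real corpus:

- **Language.** Tokens are distinct 4-character CV syllable pairs written
  without spaces (language code `xx`), so the maximum-matching segmenter
  is genuinely exercised as in the Chinese setting, and — because all
  lexicon entries have equal length — segmentation of generated text is
  exact. A space-delimited mode (`language="en"`) exists for readability.
- **Planted synonyms.** 24 base tokens, 6 of which are "professional"
  terms paired with a lay partner from outside the base vocabulary. Each
  pair owns 3 sentence templates (3–5 tokens, one slot); corpus sentences
  are 60% template sentences (pair chosen uniformly, member uniformly,
  template uniformly) and 40% filler over the non-pair vocabulary. Pair
  members appear *only* via their templates, making the two members'
  contexts statistically exchangeable — the property that lets skip-gram
  recover the pair. Default corpus size is 2,000 sentences, at which
  recovery into mutual top-3 neighbours is reliable across seeds.
- **Index and gold.** 60 archetypes with 2–3-token concept names over the
  base vocabulary. Gold queries take a target name and replace each
  professional token by its lay partner with probability equal to the
  perturbation rate; the rate stands in for the searcher's professional
  level (low = 1.0, medium = 0.6, high = 0.3 — a lay searcher paraphrases
  all of the name, a professional most of none; the mapping is a package
  choice, chosen once as three well-separated points of the knob). At
  rate 1 the query shares no replaceable token with the name, forcing a
  baseline miss by construction.

What passing tests show: the pipeline recovers planted distributional
synonyms and converts them into retrieval success that direct substring
search cannot achieve, with exactly the claimed count and metric
arithmetic. What they do not show: performance on real clinical text —
real synonymy is graded rather than exchangeable, real segmentation is
ambiguous, embedding quality depends on corpus domain coverage, and real
repositories are larger and noisier.

## Problem sizes and numerical choices

The acceptance script and the standard fixtures run at the conditions
above (2,000 sentences, dim 100, 5 epochs, 60 archetypes, 20 queries per
level, 5 recovery seeds). The 20-seed expansion-vs-baseline sweep in the
test suite uses a scaled study (1,400 sentences, dim 48, 3 epochs) — the
package's chosen size for a many-replicate check, at which the effect is
already saturated. Cosine values are clipped to [−1, 1] against rounding
drift; zero vectors have similarity 0 by convention. Archetype ids accept
both the canonical dotted grammar (`openEHR-EHR-OBSERVATION.fetal_heart.v1`)
and the dash-form spelling seen in some repository listings.

## Known limitations

- Substring semantics only: no fuzzy or edit-distance matching, no
  element-level (inside-archetype) search.
- No grammar-aware filtering of combination terms; ungrammatical
  combinations are generated and accepted, as their low ranking after
  re-ranking is part of the method's behaviour.
- Single-sense embeddings: polysemous tokens get one vector.
- The evaluation covers success-at-K only; no graded relevance or
  recall-oriented metrics.
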