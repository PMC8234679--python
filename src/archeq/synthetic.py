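"""Synthetic corpora, archetype indexes and gold sets for offline testing.

Real evaluations of archetype retrieval need a live repository and a
Wikipedia-scale embedding corpus; neither fits in a test suite.  This
module generates miniature stand-ins with the statistical structure the
method relies on:

* a synthetic *script-continuous* language (fixed-length syllabic tokens
  written without spaces, mirroring the Chinese setting) with **planted
  synonym pairs** — a "professional" token and a "lay" partner that occur
  interchangeably in identical sentence templates, so a skip-gram model
  can recover the pair from context alone;
* a toy archetype index whose concept names are short phrases over that
  vocabulary; and
* gold query sets built by replacing professional concept-name tokens
  with their planted lay partners at a configurable perturbation rate —
  the knob standing in for the searcher's medical professional level
  (a lay searcher paraphrases more of the name).

All generators are pure functions of their seeds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .embeddings import Corpus
from .expansion import QueryTerm, joiner_for_language
from .evaluation import GoldEntry
from .index import Archetype, ArchetypeIndex

__all__ = [
    "SynonymSpec",
    "GoldSpec",
    "default_synonym_spec",
    "generate_corpus",
    "generate_index",
    "generate_gold",
    "lexicon_for",
    "LEVEL_RATES",
]

SLOT = "{}"

# perturbation rate by "professional level" of the searcher: a lay (low
# level) searcher replaces every replaceable professional token with its
# lay synonym; higher-level searchers keep more of the professional name
LEVEL_RATES = {"low": 1.0, "medium": 0.6, "high": 0.3}

_CONSONANTS = "bdfgklmnprstvz"
_VOWELS = "aeiou"


def _token_pool(rng: np.random.Generator) -> list[str]:
    """All distinct 2-syllable (4-char) tokens, shuffled deterministically.

    Fixed-length tokens make forward maximum matching over unspaced text
    unambiguous: every boundary is recovered exactly.
    """
    syllables = [c + v for c, v in itertools.product(_CONSONANTS, _VOWELS)]
    pool = [a + b for a, b in itertools.product(syllables, syllables) if a != b]
    rng.shuffle(pool)
    return pool


@dataclass
class SynonymSpec:
    """Recipe for a corpus with planted synonym pairs.

    ``synonym_pairs[i]`` is a (professional, lay) token pair; both members
    appear in the corpus only through the slot of the pair's own
    ``context_templates[i]`` (each template is a token list containing one
    ``"{}"`` slot), drawn interchangeably — which is what makes their
    contexts statistically exchangeable and the pair recoverable by
    skip-gram training.
    """

    base_vocabulary: list[str]
    synonym_pairs: list[tuple[str, str]]
    context_templates: list[list[list[str]]]
    n_sentences: int = 2000
    seed: int = 0
    template_share: float = 0.6

    def __post_init__(self) -> None:
        if len(self.context_templates) != len(self.synonym_pairs):
            raise ValueError("one template list is required per synonym pair")
        for pro, lay in self.synonym_pairs:
            if pro == lay:
                raise ValueError(f"synonym pair ({pro!r}, {lay!r}) is degenerate")
        for tmpl_list in self.context_templates:
            if not tmpl_list:
                raise ValueError("a synonym pair has no context templates")
            for tmpl in tmpl_list:
                if tmpl.count(SLOT) != 1:
                    raise ValueError(f"template {tmpl!r} must contain exactly one slot")

    @property
    def professional_tokens(self) -> list[str]:
        return [p for p, _ in self.synonym_pairs]

    @property
    def lay_tokens(self) -> list[str]:
        return [l for _, l in self.synonym_pairs]

    def lay_for(self, token: str) -> str | None:
        for pro, lay in self.synonym_pairs:
            if token == pro:
                return lay
        return None


def default_synonym_spec(
    n_vocab: int = 24,
    n_pairs: int = 6,
    templates_per_pair: int = 3,
    n_sentences: int = 2000,
    seed: int = 0,
) -> SynonymSpec:
    """Build the standard study conditions: ``n_vocab`` base tokens, of
    which ``n_pairs`` are professional terms given a lay partner, each
    pair with its own context templates over the remaining vocabulary."""
    if n_pairs >= n_vocab:
        raise ValueError("need more vocabulary than synonym pairs")
    rng = np.random.default_rng(seed)
    pool = _token_pool(rng)
    base = pool[:n_vocab]
    lay = pool[n_vocab : n_vocab + n_pairs]
    pairs = list(zip(base[:n_pairs], lay))
    filler = base[n_pairs:]

    templates: list[list[list[str]]] = []
    for i in range(n_pairs):
        tmpls = []
        for _ in range(templates_per_pair):
            length = int(rng.integers(3, 6))
            ctx = [filler[int(j)] for j in rng.integers(0, len(filler), size=length - 1)]
            slot_pos = int(rng.integers(0, length))
            ctx.insert(slot_pos, SLOT)
            tmpls.append(ctx)
        templates.append(tmpls)

    return SynonymSpec(
        base_vocabulary=base,
        synonym_pairs=pairs,
        context_templates=templates,
        n_sentences=n_sentences,
        seed=seed,
    )


def generate_corpus(spec: SynonymSpec) -> Corpus:
    """Emit ``n_sentences`` tokenized sentences.

    A ``template_share`` fraction are template sentences: a synonym pair
    is chosen uniformly, one of its members uniformly, and one of the
    pair's templates uniformly, the member filling the slot.  The rest
    are filler sentences of 3-5 tokens over the non-pair vocabulary, so
    ordinary vocabulary also receives contexts of its own.
    """
    rng = np.random.default_rng(spec.seed)
    filler = [t for t in spec.base_vocabulary if t not in set(spec.professional_tokens)]
    sentences: list[list[str]] = []
    for _ in range(spec.n_sentences):
        if spec.synonym_pairs and rng.random() < spec.template_share:
            i = int(rng.integers(len(spec.synonym_pairs)))
            member = spec.synonym_pairs[i][int(rng.integers(2))]
            tmpl_list = spec.context_templates[i]
            tmpl = tmpl_list[int(rng.integers(len(tmpl_list)))]
            sentences.append([member if t == SLOT else t for t in tmpl])
        else:
            k = int(rng.integers(3, 6))
            sentences.append(
                [filler[int(j)] for j in rng.integers(0, len(filler), size=k)]
            )
    return Corpus(sentences)


_RM_TYPES = ("OBSERVATION", "EVALUATION", "COMPOSITION", "ACTION", "INSTRUCTION")


def generate_index(
    vocab: list[str],
    n_archetypes: int,
    seed: int = 0,
    language: str = "xx",
) -> ArchetypeIndex:
    """A toy archetype index with 2-3-token concept names over ``vocab``.

    Ids follow the openEHR grammar; names are joined by the language's
    convention (no delimiter for the synthetic script-continuous language
    ``xx``).  Deterministic per seed; raises when the vocabulary cannot
    supply ``n_archetypes`` distinct names.
    """
    if len(vocab) < 2:
        raise ValueError("vocabulary too small to name archetypes")
    rng = np.random.default_rng(seed)
    joiner = joiner_for_language(language)
    records: list[Archetype] = []
    seen_names: set[str] = set()
    attempts = 0
    while len(records) < n_archetypes:
        attempts += 1
        if attempts > 50 * n_archetypes:
            raise ValueError(
                f"vocabulary exhausted: cannot build {n_archetypes} distinct names"
            )
        k = min(int(rng.integers(2, 4)), len(vocab))
        toks = list(rng.choice(vocab, size=k, replace=False))
        name = joiner.join(toks)
        if name in seen_names:
            continue
        seen_names.add(name)
        rm_type = _RM_TYPES[len(records) % len(_RM_TYPES)]
        concept = "_".join(toks)
        records.append(
            Archetype(
                archetype_id=f"openEHR-EHR-{rm_type}.{concept}.v1",
                concept_name=name,
                language=language,
            )
        )
    return ArchetypeIndex.from_records(records, source_path=f"synthetic(seed={seed})")


@dataclass
class GoldSpec:
    """Recipe for a gold query set at one professional level.

    ``rate`` is the fraction of replaceable (professional) concept-name
    tokens replaced by their planted lay synonym; ``level`` is a free
    label.  When ``rate`` is None it is looked up from :data:`LEVEL_RATES`.
    """

    level: str = "low"
    rate: float | None = None
    n_queries: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate is None:
            if self.level not in LEVEL_RATES:
                raise ValueError(
                    f"no default rate for level {self.level!r}; set rate explicitly"
                )
            self.rate = LEVEL_RATES[self.level]
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError("perturbation rate must lie in [0, 1]")


def generate_gold(
    index: ArchetypeIndex,
    spec: GoldSpec,
    synonyms: SynonymSpec,
    language: str = "xx",
) -> list[GoldEntry]:
    """Gold entries whose queries are perturbed concept names.

    Each query takes a target archetype's concept-name tokens and
    replaces each professional token with its lay partner with
    probability ``spec.rate`` (at rate 1 every replaceable token is
    replaced, so the query shares no replaceable token with the name and
    direct substring search must miss).  The gold id is the source
    archetype's.  Only archetypes with at least one plantable token are
    used; raises when none exists.
    """
    rng = np.random.default_rng(spec.seed)
    joiner = joiner_for_language(language)
    token_set = set(synonyms.base_vocabulary) | set(synonyms.lay_tokens)

    def name_tokens(rec: Archetype) -> list[str]:
        if joiner:
            return rec.concept_name.split(joiner)
        # unspaced names: fixed-length tokens, split by scanning
        toks, text = [], rec.concept_name
        i = 0
        while i < len(text):
            for length in range(min(8, len(text) - i), 0, -1):
                if text[i : i + length] in token_set:
                    toks.append(text[i : i + length])
                    i += length
                    break
            else:
                toks.append(text[i])
                i += 1
        return toks

    plantable = [
        rec
        for rec in index
        if any(synonyms.lay_for(t) is not None for t in name_tokens(rec))
    ]
    if not plantable:
        raise ValueError("no archetype has a plantable synonym token")

    entries: list[GoldEntry] = []
    seen_queries: set[str] = set()
    attempts = 0
    while len(entries) < spec.n_queries:
        attempts += 1
        if attempts > 200 * spec.n_queries:
            raise ValueError(
                f"cannot build {spec.n_queries} distinct queries at "
                f"rate {spec.rate} from {len(plantable)} plantable archetypes"
            )
        rec = plantable[int(rng.integers(len(plantable)))]
        toks = []
        for t in name_tokens(rec):
            lay = synonyms.lay_for(t)
            if lay is not None and rng.random() < spec.rate:
                toks.append(lay)
            else:
                toks.append(t)
        query = joiner.join(toks)
        if query in seen_queries:
            continue
        seen_queries.add(query)
        entries.append(
            GoldEntry(
                query=QueryTerm(query, language=language),
                acceptable_ids=frozenset({rec.archetype_id}),
                level_tag=spec.level,
            )
        )
    return entries


def lexicon_for(synonyms: SynonymSpec) -> frozenset[str]:
    """The segmentation lexicon covering the synthetic language: base
    vocabulary plus all planted lay partners."""
    return frozenset(synonyms.base_vocabulary) | frozenset(synonyms.lay_tokens)


@dataclass
class StudyFixtures:
    """One complete synthetic study: corpus, index and per-level gold sets."""

    synonyms: SynonymSpec
    corpus: Corpus
    index: ArchetypeIndex
    gold: dict[str, list[GoldEntry]]


def make_study(
    seed: int = 0,
    n_sentences: int = 2000,
    n_archetypes: int = 60,
    n_queries: int = 20,
    levels: tuple[str, ...] = ("low",),
) -> StudyFixtures:
    """Wire the generators into the standard offline study conditions:
    a planted-synonym corpus, a 60-archetype index over the same
    vocabulary, and ``n_queries`` gold queries per requested level."""
    synonyms = default_synonym_spec(n_sentences=n_sentences, seed=seed)
    corpus = generate_corpus(synonyms)
    index = generate_index(synonyms.base_vocabulary, n_archetypes, seed=seed + 1)
    gold = {
        level: generate_gold(
            index,
            GoldSpec(level=level, n_queries=n_queries, seed=seed + 2 + i),
            synonyms,
        )
        for i, level in enumerate(levels)
    }
    return StudyFixtures(synonyms=synonyms, corpus=corpus, index=index, gold=gold)
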