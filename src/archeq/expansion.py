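"""Query expansion: term segmentation, term expansion, term combination.

A raw search term is first segmented into sub-terms (dictionary-based
forward maximum matching by default — the workhorse segmenter for
scriptio-continua text such as Chinese, where words are not delimited by
spaces).  Each sub-term is then expanded to its Top-N embedding
neighbours, and finally one candidate per sub-term is chosen in every
possible way and joined back into a phrase, giving the combination terms.
Expansion terms and combination terms together form the substitute set
that is searched in place of the original term.

Counting follows the cartesian bookkeeping of the method: for m >= 2
sub-terms with n_i candidates each there are sum(n_i) expansion terms and
prod(n_i) combination terms before deduplication (e.g. two sub-terms at
Top-3 give 6 expansion and 9 combination terms; at Top-10, 20 and 100).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Protocol, Sequence

from .embeddings import EmbeddingModel, nearest_neighbors

__all__ = [
    "QueryTerm",
    "SegmentedQuery",
    "ExpansionSet",
    "SubstituteSet",
    "Tokenizer",
    "MaxMatchTokenizer",
    "WhitespaceTokenizer",
    "joiner_for_language",
    "segment_query",
    "expand_subterm",
    "combine_expansions",
    "build_substitutes",
    "save_substitutes",
]

# primary language subtags written without inter-word spaces
_CONTINUOUS_SCRIPTS = {"zh", "ja", "th", "xx"}


def joiner_for_language(language: str) -> str:
    """Joining convention for recombining sub-terms: no delimiter for
    script-continuous languages (Chinese etc., and the synthetic language
    code ``xx``), a single space otherwise."""
    primary = language.split("-")[0].lower() if language else ""
    return "" if primary in _CONTINUOUS_SCRIPTS else " "


@dataclass(frozen=True)
class QueryTerm:
    """A raw search string with its language code."""

    text: str
    language: str = "en"

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise ValueError("query term is empty")


@dataclass
class SegmentedQuery:
    """The ordered sub-terms of one query; joining them with the
    language's convention reconstructs the original text."""

    original: QueryTerm
    subterms: list[str]


class Tokenizer(Protocol):
    def segment(self, text: str) -> list[str]: ...


class MaxMatchTokenizer:
    """Dictionary-based forward maximum matching.

    At each position the longest lexicon word starting there is consumed;
    if none matches, a single character is emitted as its own token.
    Whitespace separates chunks and never appears inside tokens.
    """

    def __init__(self, lexicon: Iterable[str]):
        self.lexicon = frozenset(w for w in lexicon if w)
        if not self.lexicon:
            raise ValueError("lexicon is empty")
        self._max_len = max(len(w) for w in self.lexicon)

    def segment(self, text: str) -> list[str]:
        tokens: list[str] = []
        for chunk in text.split():
            i = 0
            while i < len(chunk):
                for length in range(min(self._max_len, len(chunk) - i), 0, -1):
                    cand = chunk[i : i + length]
                    if cand in self.lexicon:
                        tokens.append(cand)
                        i += length
                        break
                else:
                    tokens.append(chunk[i])
                    i += 1
        return tokens


class WhitespaceTokenizer:
    """Splits on whitespace — adequate for space-delimited languages."""

    def segment(self, text: str) -> list[str]:
        return text.split()


def segment_query(term: QueryTerm, tokenizer: Tokenizer) -> SegmentedQuery:
    """Divide the original search term into ordered sub-terms."""
    subterms = tokenizer.segment(term.text.strip())
    if not subterms:
        raise ValueError(f"segmentation of {term.text!r} produced no sub-terms")
    return SegmentedQuery(original=term, subterms=subterms)


@dataclass
class ExpansionSet:
    """Per-sub-term candidate lists (each of length <= threshold_n) plus
    flags for sub-terms that were out of vocabulary."""

    per_subterm: list[list[str]]
    threshold_n: int
    oov_flags: list[bool] = field(default_factory=list)


def expand_subterm(model: EmbeddingModel, subterm: str, n: int) -> tuple[list[str], bool]:
    """Top-``n`` synonym candidates for one sub-term.

    Returns ``(candidates, oov_flag)``.  An out-of-vocabulary sub-term
    contributes itself as its only candidate (flagged) so that partial
    expansion still happens rather than aborting the query.
    """
    if n < 1:
        raise ValueError("n must be positive")
    if subterm not in model:
        return [subterm], True
    return [nb.token for nb in nearest_neighbors(model, subterm, n)], False


def expand_query(model: EmbeddingModel, segmented: SegmentedQuery, n: int) -> ExpansionSet:
    per_subterm, flags = [], []
    for sub in segmented.subterms:
        cands, oov = expand_subterm(model, sub, n)
        per_subterm.append(cands)
        flags.append(oov)
    return ExpansionSet(per_subterm=per_subterm, threshold_n=n, oov_flags=flags)


def combine_expansions(
    segmented: SegmentedQuery, expansions: ExpansionSet, joiner: str | None = None
) -> list[str]:
    """Cartesian combination terms: one candidate per sub-term, joined in
    the original sub-term order.

    Empty for a single sub-term.  Enumeration is rank-lexicographic: the
    first sub-term's rank varies slowest.
    """
    if len(expansions.per_subterm) != len(segmented.subterms):
        raise ValueError(
            f"expansion lists ({len(expansions.per_subterm)}) misaligned with "
            f"sub-terms ({len(segmented.subterms)})"
        )
    if len(segmented.subterms) < 2:
        return []
    if joiner is None:
        joiner = joiner_for_language(segmented.original.language)
    return [joiner.join(choice) for choice in itertools.product(*expansions.per_subterm)]


def _norm(term: str) -> str:
    return " ".join(term.split()).casefold()


@dataclass
class SubstituteSet:
    """All substitutes generated from one original search term.

    ``expansion_terms`` and ``combination_terms`` are deduplicated (after
    case-folding and whitespace normalization); the raw pre-deduplication
    counts sum(n_i) and prod(n_i) are kept in ``raw_expansion_count`` and
    ``raw_combination_count`` for Table-style bookkeeping.  ``provenance``
    maps each substitute to the (sub-term, rank) pairs that produced it.
    """

    original: QueryTerm
    subterms: list[str]
    threshold_n: int
    expansion_terms: list[str]
    combination_terms: list[str]
    raw_expansion_count: int
    raw_combination_count: int
    provenance: dict[str, list[tuple[str, int]]]
    oov_subterms: list[str]

    def all_search_terms(self) -> list[str]:
        """Every term to run against the index: the original first, then
        expansion terms, then combination terms (deduplicated)."""
        out: list[str] = []
        seen: set[str] = set()
        for t in [self.original.text, *self.expansion_terms, *self.combination_terms]:
            key = _norm(t)
            if key not in seen:
                seen.add(key)
                out.append(t)
        return out


def build_substitutes(
    model: EmbeddingModel,
    term: QueryTerm,
    n: int,
    tokenizer: Tokenizer,
) -> SubstituteSet:
    """Run the three steps end to end for one original search term."""
    segmented = segment_query(term, tokenizer)
    expansions = expand_query(model, segmented, n)

    provenance: dict[str, list[tuple[str, int]]] = {}
    expansion_terms: list[str] = []
    seen: set[str] = set()
    raw_expansion = 0
    for sub, cands in zip(segmented.subterms, expansions.per_subterm):
        for rank, cand in enumerate(cands, start=1):
            raw_expansion += 1
            provenance.setdefault(cand, []).append((sub, rank))
            if _norm(cand) not in seen:
                seen.add(_norm(cand))
                expansion_terms.append(cand)

    joiner = joiner_for_language(term.language)
    raw_combos = combine_expansions(segmented, expansions, joiner)
    combination_terms: list[str] = []
    seen_combo: set[str] = set()
    for i, combo in enumerate(raw_combos):
        ranks = _unrank(i, [len(c) for c in expansions.per_subterm])
        provenance.setdefault(combo, []).extend(
            (sub, r + 1) for sub, r in zip(segmented.subterms, ranks)
        )
        if _norm(combo) not in seen_combo:
            seen_combo.add(_norm(combo))
            combination_terms.append(combo)

    return SubstituteSet(
        original=term,
        subterms=list(segmented.subterms),
        threshold_n=n,
        expansion_terms=expansion_terms,
        combination_terms=combination_terms,
        raw_expansion_count=raw_expansion,
        raw_combination_count=len(raw_combos),
        provenance=provenance,
        oov_subterms=[
            s for s, f in zip(segmented.subterms, expansions.oov_flags) if f
        ],
    )


def _unrank(i: int, sizes: list[int]) -> list[int]:
    """Mixed-radix digits of i (first sub-term's rank varies slowest)."""
    digits = [0] * len(sizes)
    for pos in range(len(sizes) - 1, -1, -1):
        digits[pos] = i % sizes[pos]
        i //= sizes[pos]
    return digits


def save_substitutes(subs: SubstituteSet, path: str | Path) -> None:
    """Audit export: JSONL with term, kind, provenance and ranks."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for kind, terms in (
            ("expansion", subs.expansion_terms),
            ("combination", subs.combination_terms),
        ):
            for t in terms:
                fh.write(
                    json.dumps(
                        {
                            "term": t,
                            "kind": kind,
                            "provenance": [
                                {"subterm": s, "rank": r}
                                for s, r in subs.provenance.get(t, [])
                            ],
                        },
                        ensure_ascii=False,
                    )
                    + "\n"
                )
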