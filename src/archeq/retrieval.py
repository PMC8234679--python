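"""Retrieval: run substitutes against the index and re-rank semantically.

Every substitute (the original term always included) is searched with the
substring backend; hits are merged and deduplicated by archetype id, then
ordered by descending cosine similarity between the phrase vectors of the
original query and each hit's concept name.  Ties and hits whose phrase
vector is undefined (all tokens out of vocabulary, scored 0) break by
ascending archetype id, so ranking is a deterministic permutation of the
hit set.

Baseline mode searches the unexpanded original term only; because the
original is always among the expanded run's search terms, the expanded hit
set dominates (is a superset of) the baseline hit set for every query.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .embeddings import EmbeddingModel, phrase_similarity
from .expansion import (
    QueryTerm,
    SubstituteSet,
    Tokenizer,
    build_substitutes,
)
from .index import Archetype, ArchetypeIndex, completes_search

__all__ = [
    "RetrievalHit",
    "RankedResults",
    "search_substitutes",
    "rank_results",
    "retrieve",
    "save_run",
    "load_run",
]


@dataclass
class RetrievalHit:
    """One archetype hit: which substitutes retrieved it and its semantic
    similarity to the original query (0 when undefined)."""

    archetype: Archetype
    matched_terms: list[str]
    similarity: float = 0.0


@dataclass
class RankedResults:
    """Deduplicated hits for one query, ordered by (similarity desc,
    archetype_id asc)."""

    query: QueryTerm
    hits: list[RetrievalHit] = field(default_factory=list)
    n_substitutes_used: int = 0

    def archetype_ids(self) -> list[str]:
        return [h.archetype.archetype_id for h in self.hits]


def search_substitutes(
    index: ArchetypeIndex, substitutes: SubstituteSet
) -> list[RetrievalHit]:
    """Union of substring-search results over all substitute terms,
    merged by archetype id with matched terms accumulated (unranked,
    archetype-id order)."""
    terms = substitutes.all_search_terms()
    if not terms:
        raise ValueError("substitute set is empty")
    merged: dict[str, RetrievalHit] = {}
    for term in terms:
        if not term.strip():
            continue
        for rec in completes_search(index, term):
            hit = merged.get(rec.archetype_id)
            if hit is None:
                merged[rec.archetype_id] = RetrievalHit(rec, [term])
            elif term not in hit.matched_terms:
                hit.matched_terms.append(term)
    return [merged[k] for k in sorted(merged)]


def rank_results(
    model: EmbeddingModel,
    original: QueryTerm,
    hits: list[RetrievalHit],
    tokenizer: Tokenizer,
) -> RankedResults:
    """Score each hit by cosine(phrase(original), phrase(concept_name))
    and sort descending; id order breaks ties."""
    query_tokens = tokenizer.segment(original.text.strip())
    for hit in hits:
        name_tokens = tokenizer.segment(hit.archetype.concept_name.strip())
        if not query_tokens or not name_tokens:
            hit.similarity = 0.0
        else:
            hit.similarity = phrase_similarity(model, query_tokens, name_tokens)
    ordered = sorted(
        hits, key=lambda h: (-h.similarity, h.archetype.archetype_id)
    )
    return RankedResults(query=original, hits=ordered)


def retrieve(
    index: ArchetypeIndex,
    model: EmbeddingModel,
    original: QueryTerm,
    n: int,
    tokenizer: Tokenizer,
    baseline: bool = False,
) -> RankedResults:
    """End-to-end retrieval for one query.

    Expanded mode builds the substitute set (segmentation -> Top-``n``
    expansion -> combination), searches every substitute plus the original
    term, and re-ranks semantically.  ``baseline=True`` searches the
    unexpanded original term only, still re-ranked for comparability.
    """
    if baseline:
        try:
            recs = completes_search(index, original.text)
        except ValueError:
            recs = []
        hits = [RetrievalHit(rec, [original.text]) for rec in recs]
        ranked = rank_results(model, original, hits, tokenizer)
        ranked.n_substitutes_used = 1
        return ranked
    subs = build_substitutes(model, original, n, tokenizer)
    hits = search_substitutes(index, subs)
    ranked = rank_results(model, original, hits, tokenizer)
    ranked.n_substitutes_used = len(subs.all_search_terms())
    return ranked


def save_run(results: list[RankedResults], path: str | Path) -> None:
    """Write a retrieval run as TSV: query, rank, archetype_id,
    similarity, matched_terms (|-separated) — the evaluation input."""
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["query", "rank", "archetype_id", "similarity", "matched_terms"])
        for res in results:
            for rank, hit in enumerate(res.hits, start=1):
                writer.writerow(
                    [
                        res.query.text,
                        rank,
                        hit.archetype.archetype_id,
                        f"{hit.similarity:.6g}",
                        "|".join(hit.matched_terms),
                    ]
                )


def load_run(path: str | Path) -> dict[str, list[str]]:
    """Read a run TSV back as query -> ordered archetype id list."""
    run: dict[str, list[str]] = {}
    with Path(path).open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            run.setdefault(row["query"], []).append(row["archetype_id"])
    return run
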