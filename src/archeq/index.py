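"""Archetype repository: records, tabular I/O, and substring search.

The searchable unit is an openEHR archetype record (id, localized concept
name, free-text description, keywords).  Search mimics the "complete"
search of archetype repositories such as HMC: a case-insensitive contiguous
substring match over all text fields, with no tokenization.  Phrase-level
substring semantics is deliberate — it reproduces the characteristic
failure mode of direct term search (e.g. a query "fetal heartbeat" misses
an archetype named "fetal heartrate"), which is exactly what query
expansion is meant to fix.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "Archetype",
    "ArchetypeIndex",
    "ARCHETYPE_ID_RE",
    "is_valid_archetype_id",
    "load_index",
    "save_index",
    "completes_search",
    "IndexFormatError",
]

# Canonical openEHR ids look like openEHR-EHR-OBSERVATION.fetal_heart.v1;
# repository listings sometimes print a dash before the concept segment
# (openEHR-EHR-COMPOSITION-health-summary.v1), so both spellings validate.
ARCHETYPE_ID_RE = re.compile(
    r"^openEHR-EHR-[A-Z][A-Z_]*[.\-][A-Za-z0-9][A-Za-z0-9_\-]*\.v\d+$"
)

CSV_FIELDS = ("archetype_id", "concept_name", "language", "description", "keywords")


class IndexFormatError(ValueError):
    """Raised for malformed index files or invariant violations."""


def is_valid_archetype_id(archetype_id: str) -> bool:
    return bool(ARCHETYPE_ID_RE.match(archetype_id))


@dataclass(frozen=True)
class Archetype:
    """One archetype record.

    ``concept_name`` must be non-empty after trimming and ``archetype_id``
    must satisfy the openEHR id grammar.
    """

    archetype_id: str
    concept_name: str
    language: str = ""
    description: str = ""
    keywords: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not is_valid_archetype_id(self.archetype_id):
            raise IndexFormatError(
                f"invalid archetype id {self.archetype_id!r}: does not match "
                "the openEHR grammar openEHR-EHR-<TYPE>.<concept>.v<digits>"
            )
        if not self.concept_name.strip():
            raise IndexFormatError(
                f"archetype {self.archetype_id}: concept_name is empty"
            )
        if not isinstance(self.keywords, tuple):
            object.__setattr__(self, "keywords", tuple(self.keywords))

    def searchable_text(self) -> str:
        """Concatenation of all text fields, case-folded, for matching."""
        parts = [self.concept_name, self.description, *self.keywords]
        # newline separator so a phrase query can never straddle two fields
        return "\n".join(p for p in parts if p).casefold()


@dataclass
class ArchetypeIndex:
    """A collection of archetypes keyed by unique id, iterated in id order."""

    records: dict[str, Archetype] = field(default_factory=dict)
    source_path: str = ""

    def add(self, archetype: Archetype) -> None:
        if archetype.archetype_id in self.records:
            raise IndexFormatError(
                f"duplicate archetype id {archetype.archetype_id!r}"
            )
        self.records[archetype.archetype_id] = archetype

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[Archetype]:
        for key in sorted(self.records):
            yield self.records[key]

    def __contains__(self, archetype_id: str) -> bool:
        return archetype_id in self.records

    def __getitem__(self, archetype_id: str) -> Archetype:
        return self.records[archetype_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ArchetypeIndex):
            return NotImplemented
        return self.records == other.records

    @classmethod
    def from_records(
        cls, records: Iterable[Archetype], source_path: str = ""
    ) -> "ArchetypeIndex":
        index = cls(source_path=source_path)
        for rec in records:
            index.add(rec)
        return index


def _record_from_mapping(obj: dict, where: str) -> Archetype:
    try:
        archetype_id = obj["archetype_id"]
        concept_name = obj["concept_name"]
    except KeyError as exc:
        raise IndexFormatError(f"{where}: missing required field {exc}") from None
    keywords = obj.get("keywords") or ()
    if isinstance(keywords, str):
        keywords = tuple(k for k in keywords.split(";") if k)
    try:
        return Archetype(
            archetype_id=archetype_id,
            concept_name=concept_name,
            language=obj.get("language") or "",
            description=obj.get("description") or "",
            keywords=tuple(keywords),
        )
    except IndexFormatError as exc:
        raise IndexFormatError(f"{where}: {exc}") from None


def load_index(path: str | Path, format: str | None = None) -> ArchetypeIndex:
    """Load an archetype index from a JSONL or CSV file.

    ``format`` is ``"jsonl"`` or ``"csv"``; when omitted it is inferred
    from the file suffix.  Records failing the id grammar, duplicate ids,
    and malformed lines raise :class:`IndexFormatError` naming the line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"index file not found: {path}")
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "jsonl")
    index = ArchetypeIndex(source_path=str(path))
    if fmt == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise IndexFormatError(
                        f"{path}:{lineno}: invalid JSON ({exc.msg})"
                    ) from None
                index.add(_record_from_mapping(obj, f"{path}:{lineno}"))
    elif fmt == "csv":
        with path.open(encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "archetype_id" not in reader.fieldnames:
                raise IndexFormatError(
                    f"{path}: CSV header must include 'archetype_id'"
                )
            for lineno, row in enumerate(reader, start=2):
                index.add(_record_from_mapping(row, f"{path}:{lineno}"))
    else:
        raise ValueError(f"unknown index format {fmt!r}")
    return index


def save_index(index: ArchetypeIndex, path: str | Path, format: str | None = None) -> None:
    """Write the index as JSONL or CSV (UTF-8); output is re-loadable and
    byte-stable across repeated saves (records are written in id order)."""
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "jsonl")
    if fmt == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for rec in index:
                fh.write(
                    json.dumps(
                        {
                            "archetype_id": rec.archetype_id,
                            "concept_name": rec.concept_name,
                            "language": rec.language,
                            "description": rec.description,
                            "keywords": list(rec.keywords),
                        },
                        ensure_ascii=False,
                    )
                    + "\n"
                )
    elif fmt == "csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, quoting=csv.QUOTE_ALL)
            writer.writerow(CSV_FIELDS)
            for rec in index:
                writer.writerow(
                    [
                        rec.archetype_id,
                        rec.concept_name,
                        rec.language,
                        rec.description,
                        ";".join(rec.keywords),
                    ]
                )
    else:
        raise ValueError(f"unknown index format {fmt!r}")


def completes_search(index: ArchetypeIndex, term: str) -> list[Archetype]:
    """Substring search over all text fields.

    Returns every archetype whose case-folded concept name, description or
    keywords contain the case-folded query as a contiguous substring,
    ordered by archetype id.  The query is trimmed of surrounding
    whitespace; interior whitespace is significant.
    """
    needle = term.strip().casefold()
    if not needle:
        raise ValueError("search term is empty")
    return [rec for rec in index if needle in rec.searchable_text()]
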