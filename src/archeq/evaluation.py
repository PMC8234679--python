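"""Ranked-retrieval evaluation: P@K, AP and MAP.

The metrics follow the success-at-K convention used for archetype
retrieval benchmarks: for each of the N gold queries an indicator
delta(i, K) is 1 when any acceptable archetype id appears among that
query's top K results, and

    P@K = sum_i delta(i, K) / N
    AP  = mean of P@r over the configured cutoffs r (default r in {3, 5})
    MAP = arithmetic mean of the per-test-set AP values.

Note that AP here averages the set-level P@K values over cutoffs; it is
not the area-under-precision-recall AP of general IR.  Reports carry both
raw values and values rounded half-even to a configurable number of
decimals; raw values are authoritative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from statistics import fmean
from typing import Iterable, Sequence

from .expansion import QueryTerm
from .index import is_valid_archetype_id

__all__ = [
    "GoldEntry",
    "EvalConfig",
    "MetricsReport",
    "delta",
    "precision_at_k",
    "average_precision",
    "mean_average_precision",
    "evaluate_run",
    "load_gold",
    "save_gold",
]


@dataclass(frozen=True)
class GoldEntry:
    """One gold query: the acceptable target archetype ids and a free
    test-set label (e.g. low/medium/high professional level)."""

    query: QueryTerm
    acceptable_ids: frozenset[str]
    level_tag: str = ""

    def __post_init__(self) -> None:
        if not self.acceptable_ids:
            raise ValueError(f"gold entry {self.query.text!r} has no acceptable ids")
        for aid in self.acceptable_ids:
            if not is_valid_archetype_id(aid):
                raise ValueError(
                    f"gold entry {self.query.text!r}: invalid archetype id {aid!r}"
                )
        if not isinstance(self.acceptable_ids, frozenset):
            object.__setattr__(self, "acceptable_ids", frozenset(self.acceptable_ids))


@dataclass
class EvalConfig:
    """Cutoffs and report rounding.  ``k_values`` must be strictly
    increasing; AP averages over all of them (R = |k_values|)."""

    k_values: tuple[int, ...] = (3, 5)
    rounding: int = 3

    def __post_init__(self) -> None:
        if not self.k_values:
            raise ValueError("k_values is empty")
        if list(self.k_values) != sorted(set(self.k_values)) or self.k_values[0] < 1:
            raise ValueError("k_values must be strictly increasing positive integers")

    @property
    def R(self) -> int:
        return len(self.k_values)


@dataclass
class MetricsReport:
    """Metric values for one run: per-cutoff P@K, their mean AP, and —
    when the gold entries span several level tags — per-set APs and MAP."""

    n_queries: int
    p_at_k: dict[int, float]
    ap: float
    per_set_aps: dict[str, float] = field(default_factory=dict)
    map_value: float | None = None
    missing_queries: list[str] = field(default_factory=list)
    rounding: int = 3

    def rounded(self) -> dict:
        r = self.rounding
        out = {
            "N": self.n_queries,
            "p_at_k": {f"P@{k}": round(v, r) for k, v in self.p_at_k.items()},
            "ap": round(self.ap, r),
        }
        if self.per_set_aps:
            out["per_set_aps"] = {s: round(v, r) for s, v in self.per_set_aps.items()}
        if self.map_value is not None:
            out["map"] = round(self.map_value, r)
        if self.missing_queries:
            out["missing_queries"] = list(self.missing_queries)
        return out

    def to_json(self) -> str:
        payload = self.rounded()
        payload["raw"] = {
            "p_at_k": {f"P@{k}": v for k, v in self.p_at_k.items()},
            "ap": self.ap,
            "per_set_aps": dict(self.per_set_aps),
            "map": self.map_value,
        }
        return json.dumps(payload, indent=2, ensure_ascii=False)


def delta(returned: Sequence[str], gold: GoldEntry, K: int) -> int:
    """1 iff any acceptable id occurs within the first K returned ids."""
    if K < 1:
        raise ValueError("K must be >= 1")
    return int(any(rid in gold.acceptable_ids for rid in returned[:K]))


def precision_at_k(
    run: dict[str, list[str]], golds: Sequence[GoldEntry], K: int
) -> float:
    """Fraction of gold queries whose top-K contains an acceptable id.

    Queries absent from the run count delta = 0.
    """
    if not golds:
        raise ValueError("gold set is empty")
    hits = sum(delta(run.get(g.query.text, []), g, K) for g in golds)
    return hits / len(golds)


def average_precision(p_values: dict[int, float], config: EvalConfig) -> float:
    """Mean of P@r over the configured cutoffs."""
    missing = [k for k in config.k_values if k not in p_values]
    if missing:
        raise ValueError(f"missing P@K values for cutoffs {missing}")
    return fmean(p_values[k] for k in config.k_values)


def mean_average_precision(ap_values: Iterable[float]) -> float:
    """Arithmetic mean of per-test-set AP values."""
    values = list(ap_values)
    if not values:
        raise ValueError("no AP values to average")
    return fmean(values)


def evaluate_run(
    run: dict[str, list[str]],
    golds: Sequence[GoldEntry],
    config: EvalConfig | None = None,
) -> MetricsReport:
    """Full report for one run against a gold set.

    When the gold entries carry more than one level tag, per-set APs and
    the overall MAP are included.  Gold queries missing from the run are
    scored 0 and listed in ``missing_queries``.
    """
    config = config or EvalConfig()
    if not golds:
        raise ValueError("gold set is empty")
    p_at_k = {K: precision_at_k(run, golds, K) for K in config.k_values}
    ap = average_precision(p_at_k, config)
    report = MetricsReport(
        n_queries=len(golds),
        p_at_k=p_at_k,
        ap=ap,
        missing_queries=[g.query.text for g in golds if g.query.text not in run],
        rounding=config.rounding,
    )
    tags = {g.level_tag for g in golds}
    if len(tags) > 1:
        for tag in sorted(tags):
            subset = [g for g in golds if g.level_tag == tag]
            sub_p = {K: precision_at_k(run, subset, K) for K in config.k_values}
            report.per_set_aps[tag] = average_precision(sub_p, config)
        report.map_value = mean_average_precision(report.per_set_aps.values())
    return report


def load_gold(path: str | Path, language: str = "en") -> list[GoldEntry]:
    """Read a gold TSV: query <TAB> level_tag <TAB> semicolon-separated
    acceptable archetype ids."""
    entries: list[GoldEntry] = []
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}"
                )
            query, tag, ids = parts
            entries.append(
                GoldEntry(
                    query=QueryTerm(query, language=language),
                    acceptable_ids=frozenset(i for i in ids.split(";") if i),
                    level_tag=tag,
                )
            )
    return entries


def save_gold(entries: Sequence[GoldEntry], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for e in entries:
            fh.write(
                f"{e.query.text}\t{e.level_tag}\t{';'.join(sorted(e.acceptable_ids))}\n"
            )
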