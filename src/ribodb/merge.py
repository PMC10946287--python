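"""Reference/candidate database integration and the chained multi-source merge.

The pairwise rule: for each candidate entry in input order, if its full
7-rank taxonomy string is new to the merged set, the entry is added; if the
taxonomy is already present, the candidate sequence is compared against the
sequences carrying that exact taxonomy and the entry is skipped only when
it is identical to, or a contiguous substring of, one of them (one
directional: a merged sequence being a substring of the candidate does not
block addition). Accepted candidates join the merged set immediately, so a
later candidate is also checked against them. Existing entries are never
modified or removed.

Comparison is forward-strand only; curation and taxonomy unification are
expected to have run first, so taxonomy identity is exact string equality
on the unified 7-rank form.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace as dc_replace
from typing import Optional, Sequence

from .taxio import DatabaseEntry, format_taxonomy_string

__all__ = ["MergeDecision", "MergeReport", "merge_pair", "merge_chain"]


@dataclass(frozen=True)
class MergeDecision:
    candidate_id: str
    action: str  # added_new_taxon | added_new_sequence | skipped_duplicate
    matched_reference_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.action not in {"added_new_taxon", "added_new_sequence", "skipped_duplicate"}:
            raise ValueError(f"unknown merge action {self.action!r}")
        if self.action == "skipped_duplicate" and self.matched_reference_id is None:
            raise ValueError("skipped_duplicate requires matched_reference_id")


@dataclass
class MergeReport:
    """Per-source composition of the merged database."""

    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def percentages(self) -> dict[str, float]:
        total = self.total
        if total == 0:
            return {}
        return {src: 100.0 * n / total for src, n in self.counts.items()}


def _check_curated(entries: Sequence[DatabaseEntry], label: str) -> None:
    for entry in entries:
        if entry.taxonomy.is_empty:
            raise ValueError(
                f"{label} entry {entry.id!r} has an empty taxonomy; "
                "merge inputs must be curated first"
            )


def merge_pair(
    reference: Sequence[DatabaseEntry], candidate: Sequence[DatabaseEntry]
) -> tuple[list[DatabaseEntry], list[MergeDecision]]:
    """Integrate ``candidate`` into ``reference``; see module docstring.

    Ids colliding with ids already in the merged set are disambiguated by
    prefixing the candidate's source label.
    """
    _check_curated(reference, "reference")
    _check_curated(candidate, "candidate")

    merged = list(reference)
    by_taxon: dict[str, list[DatabaseEntry]] = defaultdict(list)
    ids = set()
    for entry in merged:
        by_taxon[format_taxonomy_string(entry.taxonomy)].append(entry)
        ids.add(entry.id)

    decisions: list[MergeDecision] = []
    for entry in candidate:
        taxon = format_taxonomy_string(entry.taxonomy)
        holders = by_taxon.get(taxon)
        if holders is None:
            action, matched = "added_new_taxon", None
        else:
            matched = next(
                (h.id for h in holders if entry.sequence in h.sequence), None
            )
            action = "skipped_duplicate" if matched is not None else "added_new_sequence"
        decisions.append(MergeDecision(entry.id, action, matched))
        if action != "skipped_duplicate":
            if entry.id in ids:
                entry = dc_replace(entry, id=f"{entry.source}:{entry.id}")
            ids.add(entry.id)
            merged.append(entry)
            by_taxon[taxon].append(entry)
    return merged, decisions


def merge_chain(
    databases: Sequence[Sequence[DatabaseEntry]],
) -> tuple[list[DatabaseEntry], MergeReport]:
    """Left fold of :func:`merge_pair` over ``databases`` in the given order.

    The first database is the initial reference; each retained entry keeps
    its source label and the report tallies the per-source composition of
    the result.
    """
    if not databases:
        raise ValueError("merge_chain requires at least one database")
    merged = list(databases[0])
    _check_curated(merged, "reference")
    for candidate in databases[1:]:
        merged, _ = merge_pair(merged, candidate)
    report = MergeReport()
    for entry in merged:
        report.counts[entry.source] = report.counts.get(entry.source, 0) + 1
    return merged, report
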