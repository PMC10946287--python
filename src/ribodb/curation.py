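"""Curation filters and taxonomy unification for a reference database.

Four removal rules are applied in a fixed order, then synonym unification:

1. kingdom filter — keep only Bacteria/Archaea (configurable);
2. unknown-label filter — drop entries whose species label is empty or whose
   lineage contains an unknown-species pattern ("uncultured", "unidentified",
   "candidate" by default; case-insensitive substrings);
3. rank-sparsity filter — drop entries annotated only at kingdom and species
   (a hallmark of poorly characterised environmental isolates);
4. cross-kingdom filter — drop entries whose species resolves, through the
   synonym map, to a canonical lineage outside the allowed kingdoms (e.g. a
   plant species filed under Bacteria);
5. unification — replace every rank label by its canonical name from the
   synonym map; unmapped labels pass through unchanged but are counted.

Unification runs last so that removals are judged on the original labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Optional, Sequence

from .cluster import (
    MergePolicy,
    compress_species_names,
    expand_label,
    merge_rank_names,
)
from .taxio import DatabaseEntry, SynonymMap, TaxonomyString

__all__ = [
    "CurationRules",
    "CurationReport",
    "filter_kingdoms",
    "flag_unknown_labels",
    "flag_rank_sparse",
    "unify_taxonomy",
    "detect_cross_kingdom",
    "curate_database",
]

DEFAULT_UNKNOWN_PATTERNS = ("uncultured", "unidentified", "candidate")
DEFAULT_ALLOWED_KINGDOMS = frozenset({"Bacteria", "Archaea"})

# unification must never collapse labels to "Unknown"; the >max_names rule
# belongs to clustering only
_UNIFY_POLICY = MergePolicy(max_names=10**9)


@dataclass(frozen=True)
class CurationRules:
    """Which filters run and with what parameters."""

    unknown_patterns: tuple[str, ...] = DEFAULT_UNKNOWN_PATTERNS
    allowed_kingdoms: frozenset[str] = DEFAULT_ALLOWED_KINGDOMS
    drop_rank_sparse: bool = True
    filter_kingdoms: bool = True
    filter_unknown: bool = True
    drop_cross_kingdom: bool = True
    unify: bool = True

    def __post_init__(self) -> None:
        if self.filter_unknown and not self.unknown_patterns:
            raise ValueError("pattern list must be non-empty when pattern filtering is enabled")

    @classmethod
    def disabled(cls) -> "CurationRules":
        """Rules with every filter and the unification step switched off."""
        return cls(
            drop_rank_sparse=False,
            filter_kingdoms=False,
            filter_unknown=False,
            drop_cross_kingdom=False,
            unify=False,
        )


@dataclass
class CurationReport:
    """Accounting of a curation run.

    Invariant: ``input_count == output_count + sum(removed_by_rule.values())``.
    """

    input_count: int = 0
    removed_by_rule: dict[str, int] = field(default_factory=dict)
    renamed_count: int = 0
    unmapped_labels: dict[str, int] = field(default_factory=dict)
    output_count: int = 0

    def check(self) -> None:
        removed = sum(self.removed_by_rule.values())
        if self.input_count != self.output_count + removed:
            raise AssertionError(
                f"curation accounting broken: {self.input_count} != "
                f"{self.output_count} + {removed}"
            )


def filter_kingdoms(
    entries: Sequence[DatabaseEntry], rules: CurationRules = CurationRules()
) -> tuple[list[DatabaseEntry], int]:
    """Keep entries whose kingdom is allowed; returns (retained, n_removed)."""
    if not rules.filter_kingdoms:
        return list(entries), 0
    kept = [e for e in entries if e.taxonomy.kingdom in rules.allowed_kingdoms]
    return kept, len(entries) - len(kept)


def flag_unknown_labels(
    taxonomy: TaxonomyString, rules: CurationRules = CurationRules()
) -> bool:
    """True iff the species label is empty or any rank label contains an
    unknown-species pattern (case-insensitive substring match)."""
    if taxonomy.species == "":
        return True
    patterns = tuple(p.lower() for p in rules.unknown_patterns)
    return any(
        pat in label.lower() for label in taxonomy.ranks if label for pat in patterns
    )


def flag_rank_sparse(taxonomy: TaxonomyString) -> bool:
    """True iff only kingdom and species are annotated (phylum..genus empty)."""
    return (
        taxonomy.kingdom != ""
        and taxonomy.species != ""
        and all(taxonomy.ranks[i] == "" for i in range(1, 6))
    )


def _unify_label(label: str, is_species: bool, synonyms: SynonymMap) -> str:
    """Canonicalize one label; clustered labels unify each member name."""
    if label == "":
        return label
    direct = synonyms.lookup(label)
    if direct is not None:
        return direct.canonical
    names = expand_label(label)
    if len(names) <= 1:
        return label
    mapped = {synonyms.canonical(n) for n in names}
    if is_species:
        return compress_species_names(mapped, _UNIFY_POLICY)
    return merge_rank_names(mapped, _UNIFY_POLICY)


def unify_taxonomy(
    taxonomy: TaxonomyString, synonyms: SynonymMap
) -> tuple[TaxonomyString, bool]:
    """Replace each rank label by its canonical name where the map knows it.

    Labels absent from the map pass through unchanged. Clustered
    (multi-name) labels unify each component name independently and are
    re-assembled with the clustering grammar. Returns the (possibly new)
    taxonomy and whether anything changed.
    """
    new_labels = tuple(
        _unify_label(label, idx == 6, synonyms)
        for idx, label in enumerate(taxonomy.ranks)
    )
    changed = new_labels != taxonomy.ranks
    return (TaxonomyString(new_labels) if changed else taxonomy), changed


def detect_cross_kingdom(
    taxonomy: TaxonomyString,
    synonyms: SynonymMap,
    rules: CurationRules = CurationRules(),
) -> bool:
    """True iff the species' canonical record places it outside the allowed
    kingdoms (a misannotation such as a plant filed under Bacteria).

    Species absent from the synonym map cannot be judged and return False.
    """
    if taxonomy.species == "":
        return False
    entry = synonyms.lookup(taxonomy.species)
    if entry is None or entry.kingdom == "":
        return False
    return entry.kingdom not in rules.allowed_kingdoms


def curate_database(
    entries: Sequence[DatabaseEntry],
    rules: CurationRules = CurationRules(),
    synonyms: Optional[SynonymMap] = None,
) -> tuple[list[DatabaseEntry], CurationReport]:
    """Apply all curation rules in order, then unification.

    The report accounts for every removal; idempotent for fixed rules and
    synonyms.
    """
    synonyms = synonyms if synonyms is not None else SynonymMap()
    report = CurationReport(input_count=len(entries))

    kept, n_kingdom = filter_kingdoms(entries, rules)
    if rules.filter_kingdoms:
        report.removed_by_rule["kingdom_filter"] = n_kingdom

    if rules.filter_unknown:
        before = len(kept)
        kept = [e for e in kept if not flag_unknown_labels(e.taxonomy, rules)]
        report.removed_by_rule["unknown_labels"] = before - len(kept)

    if rules.drop_rank_sparse:
        before = len(kept)
        kept = [e for e in kept if not flag_rank_sparse(e.taxonomy)]
        report.removed_by_rule["rank_sparse"] = before - len(kept)

    if rules.drop_cross_kingdom:
        before = len(kept)
        kept = [e for e in kept if not detect_cross_kingdom(e.taxonomy, synonyms, rules)]
        report.removed_by_rule["cross_kingdom"] = before - len(kept)

    out: list[DatabaseEntry] = []
    if rules.unify:
        for entry in kept:
            new_tax, changed = unify_taxonomy(entry.taxonomy, synonyms)
            if changed:
                report.renamed_count += 1
                out.append(dc_replace(entry, taxonomy=new_tax))
            else:
                out.append(entry)
            for label in entry.taxonomy.ranks:
                for name in expand_label(label) if label else ():
                    if name not in synonyms:
                        report.unmapped_labels[name] = (
                            report.unmapped_labels.get(name, 0) + 1
                        )
    else:
        out = kept

    report.output_count = len(out)
    report.check()
    return out, report
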