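"""100%-identity clustering with merged ("clustered") taxonomic nomenclature.

After extracting a hypervariable region, many identical (or contained)
sequences carry different taxonomies. Sequences that are identical to, or
substrings of, a longer representative are grouped into one cluster, and the
member lineages are merged rank by rank:

* kingdom..genus: distinct names sorted alphabetically and joined with
  ``-`` (e.g. ``g__Lactobacillus-Limosilactobacillus``);
* species: names grouped by genus token, the first full binomial of each
  group kept and later members contributing only their epithet, groups
  joined with ``:`` (e.g.
  ``s__Lactobacillus_crispatus:Limosilactobacillus_fermentum-oris``);
* a rank collecting more than ``max_names`` distinct names (default 10)
  collapses to the placeholder ``Unknown``.

The greedy longest-first assignment (CD-HIT-like) is the reference
semantics; representatives are chosen deterministically (longest sequence,
ties broken by sequence then id).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .taxio import DatabaseEntry, TaxonomyString

__all__ = [
    "Cluster",
    "MergePolicy",
    "cluster_identical",
    "merge_rank_names",
    "compress_species_names",
    "expand_label",
    "merge_cluster_taxonomy",
    "cluster_database",
]


@dataclass(frozen=True)
class MergePolicy:
    """Grammar parameters for merged cluster labels."""

    max_names: int = 10
    unknown_placeholder: str = "Unknown"
    name_separator: str = "-"
    genus_group_separator: str = ":"

    def __post_init__(self) -> None:
        if self.max_names < 1:
            raise ValueError("max_names must be >= 1")


DEFAULT_POLICY = MergePolicy()


@dataclass
class Cluster:
    """One 100%-identity cluster.

    The representative is a longest member; every member sequence equals or
    is a substring of the representative's sequence.
    """

    representative_id: str
    member_ids: list[str] = field(default_factory=list)
    merged_taxonomy: TaxonomyString | None = None


def cluster_identical(entries: Sequence[DatabaseEntry]) -> list[Cluster]:
    """Greedy longest-first clustering at 100% identity with containment.

    Entries are visited longest sequence first (ties: sequence, then id);
    an entry joins the first existing cluster whose representative contains
    its sequence, otherwise it founds a new cluster. Every input id lands in
    exactly one cluster.
    """
    order = sorted(entries, key=lambda e: (-len(e.sequence), e.sequence, e.id))
    clusters: list[Cluster] = []
    reps: list[str] = []  # representative sequences, parallel to clusters
    for entry in order:
        for cluster, rep_seq in zip(clusters, reps):
            if entry.sequence in rep_seq:
                cluster.member_ids.append(entry.id)
                break
        else:
            clusters.append(Cluster(representative_id=entry.id, member_ids=[entry.id]))
            reps.append(entry.sequence)
    return clusters


def merge_rank_names(names: Iterable[str], policy: MergePolicy = DEFAULT_POLICY) -> str:
    """Merge distinct rank names: sorted (case-insensitively), ``-``-joined.

    More than ``policy.max_names`` distinct names collapse to the
    placeholder. A single name is returned unchanged.
    """
    distinct = sorted(set(names), key=lambda n: (n.lower(), n))
    if not distinct:
        return ""
    if len(distinct) > policy.max_names:
        return policy.unknown_placeholder
    return policy.name_separator.join(distinct)


def _genus_token(name: str) -> str | None:
    """Genus part of a ``Genus_epithet`` name; None for free-text names."""
    if "_" in name:
        genus = name.split("_", 1)[0]
        if genus:
            return genus
    return None


def compress_species_names(
    names: Iterable[str], policy: MergePolicy = DEFAULT_POLICY
) -> str:
    """Compress species names per genus group.

    ``Genus_epithet`` names sharing a genus token form one group: the
    alphabetically first full name is kept and later members contribute only
    their epithet, joined with ``-``. Groups (sorted alphabetically) are
    joined with ``:``. Free-text names form their own verbatim group. More
    than ``policy.max_names`` distinct names collapse to the placeholder.
    """
    distinct = sorted(set(names), key=lambda n: (n.lower(), n))
    if not distinct:
        return ""
    if len(distinct) > policy.max_names:
        return policy.unknown_placeholder
    groups: dict[str, list[str]] = {}
    order: list[str] = []
    for name in distinct:
        genus = _genus_token(name)
        key = genus if genus is not None else f"\x00{name}"
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(name)
    parts: list[str] = []
    for key in order:
        members = groups[key]
        if key.startswith("\x00"):
            parts.append(members[0])
            continue
        head = members[0]
        epithets = [m.split("_", 1)[1] for m in members[1:]]
        parts.append(policy.name_separator.join([head, *epithets]))
    parts.sort(key=lambda p: (p.lower(), p))
    return policy.genus_group_separator.join(parts)


def expand_label(label: str, policy: MergePolicy = DEFAULT_POLICY) -> frozenset[str]:
    """Expand a (possibly clustered) label back into its member name set.

    The inverse of :func:`merge_rank_names` / :func:`compress_species_names`:
    ``:`` separates genus groups; within a group whose first token is of
    ``Genus_epithet`` form, later ``-``-joined tokens re-attach the group's
    genus; otherwise tokens are plain names. The placeholder (``Unknown``)
    and the empty label expand to the empty set.
    """
    if label == "" or label == policy.unknown_placeholder:
        return frozenset()
    names: set[str] = set()
    for group in label.split(policy.genus_group_separator):
        tokens = group.split(policy.name_separator)
        genus = _genus_token(tokens[0])
        if genus is None:
            names.update(t for t in tokens if t)
            continue
        names.add(tokens[0])
        for token in tokens[1:]:
            if token:  # bare epithet: re-attach the group's genus
                names.add(f"{genus}_{token}")
    return frozenset(names)


def merge_cluster_taxonomy(
    taxonomies: Sequence[TaxonomyString], policy: MergePolicy = DEFAULT_POLICY
) -> TaxonomyString:
    """Merge member lineages into one clustered lineage.

    Kingdom through genus merge via :func:`merge_rank_names`; species via
    :func:`compress_species_names`. Empty labels are ignored.
    """
    if not taxonomies:
        raise ValueError("cannot merge an empty set of taxonomies")
    labels: list[str] = []
    for idx in range(7):
        names = [t.ranks[idx] for t in taxonomies if t.ranks[idx]]
        if idx == 6:
            labels.append(compress_species_names(names, policy))
        else:
            labels.append(merge_rank_names(names, policy))
    return TaxonomyString(tuple(labels))


def cluster_database(
    entries: Sequence[DatabaseEntry], policy: MergePolicy = DEFAULT_POLICY
) -> tuple[list[DatabaseEntry], list[Cluster]]:
    """Cluster a database and emit one entry per cluster.

    Each output entry carries the representative's id, sequence and source
    and the merged taxonomy; the returned clusters record membership (the
    sidecar table written by the CLI).
    """
    by_id = {e.id: e for e in entries}
    if len(by_id) != len(entries):
        raise ValueError("duplicate entry ids in clustering input")
    clusters = cluster_identical(entries)
    out: list[DatabaseEntry] = []
    for cluster in clusters:
        rep = by_id[cluster.representative_id]
        merged = merge_cluster_taxonomy(
            [by_id[m].taxonomy for m in cluster.member_ids], policy
        )
        cluster.merged_taxonomy = merged
        out.append(DatabaseEntry(rep.id, rep.sequence, merged, source=rep.source))
    return out, clusters
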