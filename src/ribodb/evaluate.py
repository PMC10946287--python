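"""Benchmark classifier output against a mock community.

For every rank, a multi-class confusion matrix is tallied over the union of
expected and assigned labels: a taxon id ``T_i`` scores TP on a sequence
when it matches both the assigned and the expected label, FP when it
matches only the assigned, FN when only the expected, TN when neither.
Matching is containment-aware: clustered labels (``-``/``:`` grammar) match
when one name is included in the other's expansion, so e.g.
``Amylolactobacillus_amylophilus-Lactobacillus_iners`` matches
``Lactobacillus_iners``.

Per-taxon scores follow the standard definitions::

    accuracy  = (TP + TN) / (TP + FP + TN + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    f1        = 2 * precision * recall / (precision + recall)

0/0 ratios score 0 and are flagged, so fully missed rare taxa penalize the
weighted means rather than vanishing. Per-rank scores are integrated as the
abundance-weighted mean ``s = sum(a_i s_i) / sum(a_i)`` with the expected
relative abundances as weights. Compositional agreement is additionally
scored as the Bray-Curtis distance between expected and assigned
compositions (unassigned mass kept as its own label).

Taxonomy unification (synonym canonicalization) is applied to both sides
before any comparison.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _scipy_braycurtis

from .cluster import expand_label
from .curation import unify_taxonomy
from .mockgen import AssignmentTable, MockCommunity
from .taxio import RANK_NAMES, SynonymMap, TaxonomyString

__all__ = [
    "ConfusionCounts",
    "TaxonScores",
    "RankMetrics",
    "expand_clustered_name",
    "names_match",
    "confusion_counts",
    "metrics_from_counts",
    "weighted_mean",
    "bray_curtis",
    "evaluate_dataset",
    "summarize_configurations",
]

UNASSIGNED_LABEL = "Unassigned"


def expand_clustered_name(label: str) -> frozenset[str]:
    """Member names of a (possibly clustered) label.

    ``:`` separates genus groups; within a ``Genus_epithet``-headed group,
    ``-``-joined epithets re-attach the genus; other labels split on ``-``
    only. ``Unknown`` and the empty label expand to the empty set.
    """
    return expand_label(label)


def names_match(assigned_label: str, expected_label: str) -> bool:
    """True iff the labels are identical or their expansions intersect.

    Symmetric; empty labels match nothing (an unassigned sequence matches
    no taxon).
    """
    if not assigned_label or not expected_label:
        return False
    if assigned_label == expected_label:
        return True
    return bool(expand_label(assigned_label) & expand_label(expected_label))


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-taxon confusion tallies at one rank.

    Invariant: ``tp + fp + fn + tn`` equals the number of evaluated
    sequences.
    """

    taxon: str
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_counts(
    expected: Mapping[str, TaxonomyString],
    assigned: Mapping[str, TaxonomyString],
    rank: str | int,
) -> list[ConfusionCounts]:
    """Tally TP/FP/FN/TN at ``rank`` for every taxon in the union of labels.

    ``expected`` and ``assigned`` must cover the same sequence ids. Matching
    uses :func:`names_match`; the tally is sequence-level (each sequence
    counts once). Implemented with an inverted expansion index so clustered
    labels stay cheap; tests cross-check it against a brute-force double
    loop.
    """
    if set(expected) != set(assigned):
        raise ValueError("expected and assigned tables cover different sequence ids")

    exp_labels = {sid: tax.label(rank) for sid, tax in expected.items()}
    asn_labels = {sid: tax.label(rank) for sid, tax in assigned.items()}
    taxa = sorted(
        {l for l in exp_labels.values() if l} | {l for l in asn_labels.values() if l}
    )

    # name -> taxa whose expansion contains it; label -> taxa equal to it
    by_name: dict[str, set[str]] = defaultdict(set)
    for taxon in taxa:
        by_name[taxon].add(taxon)
        for name in expand_label(taxon):
            by_name[name].add(taxon)

    match_cache: dict[str, frozenset[str]] = {}

    def matched_taxa(label: str) -> frozenset[str]:
        if not label:
            return frozenset()
        hit = match_cache.get(label)
        if hit is None:
            taxa_hit: set[str] = set(by_name.get(label, ()))
            for name in expand_label(label):
                taxa_hit |= by_name.get(name, set())
            hit = frozenset(taxa_hit)
            match_cache[label] = hit
        return hit

    n = len(exp_labels)
    tp: dict[str, int] = defaultdict(int)
    fp: dict[str, int] = defaultdict(int)
    fn: dict[str, int] = defaultdict(int)
    for sid in exp_labels:
        a_hits = matched_taxa(asn_labels[sid])
        e_hits = matched_taxa(exp_labels[sid])
        for taxon in a_hits & e_hits:
            tp[taxon] += 1
        for taxon in a_hits - e_hits:
            fp[taxon] += 1
        for taxon in e_hits - a_hits:
            fn[taxon] += 1
    return [
        ConfusionCounts(
            taxon=t,
            tp=tp[t],
            fp=fp[t],
            fn=fn[t],
            tn=n - tp[t] - fp[t] - fn[t],
        )
        for t in taxa
    ]


@dataclass(frozen=True)
class TaxonScores:
    taxon: str
    precision: float
    recall: float
    f1: float
    accuracy: float
    undefined: frozenset[str] = frozenset()  # metrics whose ratio was 0/0


def _ratio(num: int, den: int, name: str, flags: set[str]) -> float:
    if den == 0:
        flags.add(name)
        return 0.0
    return num / den


def metrics_from_counts(counts: ConfusionCounts) -> TaxonScores:
    """Per-taxon accuracy, precision, recall and F1 (harmonic mean).

    0/0 ratios return 0 and are flagged in ``undefined``.
    """
    flags: set[str] = set()
    precision = _ratio(counts.tp, counts.tp + counts.fp, "precision", flags)
    recall = _ratio(counts.tp, counts.tp + counts.fn, "recall", flags)
    if precision + recall == 0:
        flags.add("f1")
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    accuracy = _ratio(counts.tp + counts.tn, counts.total, "accuracy", flags)
    return TaxonScores(counts.taxon, precision, recall, f1, accuracy, frozenset(flags))


def weighted_mean(scores: Sequence[float], weights: Sequence[float]) -> float:
    """Abundance-weighted mean ``sum(a_i s_i) / sum(a_i)``; 0 when all
    weights vanish."""
    if len(scores) != len(weights):
        raise ValueError("scores and weights must have equal length")
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    total = np.sum(w)
    if total == 0:
        return 0.0
    # elementwise product + identical summation keeps all-equal scores exact
    return float(np.sum(np.asarray(scores, dtype=float) * w) / total)


@dataclass
class RankMetrics:
    """Per-taxon scores and their abundance-weighted means at one rank."""

    rank: str
    taxa: list[TaxonScores]
    weights: dict[str, float]
    weighted: dict[str, float]  # metric name -> weighted mean

    @property
    def n(self) -> int:
        return len(self.taxa)


def rank_metrics(
    counts: Sequence[ConfusionCounts], weights: Mapping[str, float], rank: str
) -> RankMetrics:
    """Score every taxon and integrate with expected-abundance weights
    (taxa absent from the expected composition weigh 0)."""
    scores = [metrics_from_counts(c) for c in counts]
    w = [float(weights.get(s.taxon, 0.0)) for s in scores]
    weighted = {
        metric: weighted_mean([getattr(s, metric) for s in scores], w)
        for metric in ("precision", "recall", "f1", "accuracy")
    }
    return RankMetrics(rank=rank, taxa=scores, weights=dict(weights), weighted=weighted)


def bray_curtis(
    expected_comp: Mapping[str, float], assigned_comp: Mapping[str, float]
) -> float:
    """Bray-Curtis distance over the union of taxa; 0 iff identical, 1 for
    disjoint compositions."""
    taxa = sorted(set(expected_comp) | set(assigned_comp))
    if not taxa:
        return 0.0
    e = np.array([expected_comp.get(t, 0.0) for t in taxa])
    a = np.array([assigned_comp.get(t, 0.0) for t in taxa])
    if e.sum() == 0 and a.sum() == 0:
        return 0.0
    return float(_scipy_braycurtis(e, a))


def _unify_table(
    table: Mapping[str, TaxonomyString], synonyms: Optional[SynonymMap]
) -> dict[str, TaxonomyString]:
    if synonyms is None:
        return dict(table)
    return {sid: unify_taxonomy(tax, synonyms)[0] for sid, tax in table.items()}


def evaluate_dataset(
    mock: MockCommunity,
    assignment: AssignmentTable,
    synonyms: Optional[SynonymMap] = None,
) -> pd.DataFrame:
    """Score an assignment table against a mock community.

    Both sides are unified first; then, per sample and per rank, the
    abundance-weighted confusion-matrix metrics and the Bray-Curtis distance
    between expected and assigned composition (unassigned mass as its own
    label) are computed. Returns a tidy frame with one row per
    (sample, rank): columns sample, rank, precision, recall, f1, accuracy,
    bray_curtis, n_taxa.
    """
    expected = _unify_table(mock.expected_taxonomy(), synonyms)
    assigned = _unify_table(assignment, synonyms)
    missing = set(expected) - set(assigned)
    if missing:
        raise ValueError(f"assignment table lacks sequence ids {sorted(missing)[:5]}")
    extra = set(assigned) - set(expected)
    if extra:
        raise ValueError(f"assignment table has unknown sequence ids {sorted(extra)[:5]}")

    rows = []
    for rank in RANK_NAMES:
        counts = confusion_counts(expected, assigned, rank)
        for sample in mock.samples:
            seq_w = mock.sequence_weights(sample)
            # expected/assigned composition at this rank
            exp_comp: dict[str, float] = defaultdict(float)
            asn_comp: dict[str, float] = defaultdict(float)
            for sid, w in seq_w.items():
                exp_comp[expected[sid].label(rank)] += w
                asn_label = assigned[sid].label(rank)
                asn_comp[asn_label if asn_label else UNASSIGNED_LABEL] += w
            metrics = rank_metrics(counts, exp_comp, rank)
            rows.append(
                {
                    "sample": sample,
                    "rank": rank,
                    **metrics.weighted,
                    "bray_curtis": bray_curtis(exp_comp, asn_comp),
                    "n_taxa": metrics.n,
                }
            )
    return pd.DataFrame(rows)


def summarize_configurations(
    tables: Mapping[str, pd.DataFrame],
) -> pd.DataFrame:
    """Mean and standard deviation of each metric per (configuration, rank);
    the best configuration per rank (highest mean F1) is flagged."""
    if not tables:
        raise ValueError("no configurations to summarize")
    frames = []
    for config, df in tables.items():
        frames.append(df.assign(configuration=config))
    combined = pd.concat(frames, ignore_index=True)
    metrics = ["precision", "recall", "f1", "accuracy", "bray_curtis"]
    grouped = combined.groupby(["configuration", "rank"], sort=False)[metrics]
    summary = grouped.agg(["mean", "std"])
    summary.columns = [f"{m}_{stat}" for m, stat in summary.columns]
    summary = summary.reset_index()
    summary["best"] = False
    for rank, sub in summary.groupby("rank"):
        best_idx = sub["f1_mean"].idxmax()
        summary.loc[best_idx, "best"] = True
    return summary
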