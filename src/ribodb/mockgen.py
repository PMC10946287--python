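"""Synthetic fixtures: reference databases, in-silico mock communities and
perturbed classifier output.

Everything downstream of database construction is benchmarked against mock
communities: sets of samples with known member taxa, member sequences and
expected relative abundances. This module generates

* random fixture databases (consistent seven-rank lineages over a small
  generated name pool, optionally with engineered duplicate/substring/
  curation-rule entries),
* mock communities drawn from a database (five samples by default, with
  normalized-uniform or log-normal abundance profiles), and
* simulated classifier output: each sequence keeps its true taxonomy with
  probability ``1 - error_rate - unassigned_rate``, receives a uniformly
  drawn wrong taxonomy with probability ``error_rate`` and an empty
  assignment with probability ``unassigned_rate``.

All randomness flows through one explicit integer seed; identical seeds
yield identical artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .taxio import CompositionTable, DatabaseEntry, TaxonomyString

__all__ = [
    "MockTaxon",
    "MockCommunity",
    "AssignmentTable",
    "build_mock_community",
    "simulate_assignment",
    "generate_fixture_database",
    "realize_primer",
    "embed_amplicon",
]

#: Classifier-output surrogate: sequence id -> assigned taxonomy
#: (all-empty taxonomy = unassigned).
AssignmentTable = dict[str, TaxonomyString]


@dataclass(frozen=True)
class MockTaxon:
    taxon_id: str  # species label
    taxonomy: TaxonomyString
    sequence_ids: tuple[str, ...]


@dataclass
class MockCommunity:
    """A set of samples with known composition over known sequences."""

    name: str
    seed: int
    taxa: list[MockTaxon]
    samples: list[str]
    abundance: dict[str, dict[str, float]]  # sample -> taxon_id -> rel. abundance
    sequences: dict[str, str] = field(default_factory=dict)  # seq id -> sequence

    def __post_init__(self) -> None:
        for sample in self.samples:
            total = sum(self.abundance[sample].values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"sample {sample!r}: abundances sum to {total}, expected 1"
                )
        known_ids = set(self.sequences)
        for taxon in self.taxa:
            missing = set(taxon.sequence_ids) - known_ids
            if missing:
                raise ValueError(
                    f"taxon {taxon.taxon_id!r}: unknown sequence ids {sorted(missing)}"
                )

    @property
    def sequence_ids(self) -> list[str]:
        return [sid for t in self.taxa for sid in t.sequence_ids]

    def expected_taxonomy(self) -> dict[str, TaxonomyString]:
        """Truth table: sequence id -> its taxon's lineage."""
        return {sid: t.taxonomy for t in self.taxa for sid in t.sequence_ids}

    def sequence_weights(self, sample: str) -> dict[str, float]:
        """Per-sequence expected abundance (taxon abundance split evenly
        across the taxon's member sequences)."""
        weights: dict[str, float] = {}
        for taxon in self.taxa:
            share = self.abundance[sample][taxon.taxon_id] / len(taxon.sequence_ids)
            for sid in taxon.sequence_ids:
                weights[sid] = share
        return weights

    def expected_composition(self, rank: str | int) -> CompositionTable:
        """Per-sample composition aggregated to labels at ``rank``."""
        abundances: dict[str, dict[str, float]] = {}
        for sample in self.samples:
            comp: dict[str, float] = {}
            for taxon in self.taxa:
                label = taxon.taxonomy.label(rank)
                comp[label] = comp.get(label, 0.0) + self.abundance[sample][taxon.taxon_id]
            abundances[sample] = comp
        return CompositionTable(samples=list(self.samples), abundances=abundances)


def _draw_abundances(
    rng: np.random.Generator, n_taxa: int, model: str
) -> np.ndarray:
    if model == "uniform":
        raw = rng.uniform(size=n_taxa)
    elif model == "lognormal":
        # sigma 2.0: heavy-tailed, gut-like profile with a few dominant taxa
        raw = rng.lognormal(mean=0.0, sigma=2.0, size=n_taxa)
    else:
        raise ValueError(f"unknown abundance model {model!r}")
    return raw / raw.sum()


def build_mock_community(
    database: Sequence[DatabaseEntry],
    n_taxa: int,
    n_samples: int = 5,
    abundance_model: str = "uniform",
    seed: int = 0,
    name: str = "mock",
) -> MockCommunity:
    """Draw ``n_taxa`` species (without replacement) and per-sample profiles.

    Each drawn species contributes its first database sequence; every sample
    receives an independent abundance draw from ``abundance_model``
    ("uniform": normalized uniform variates; "lognormal": normalized
    log-normal variates, sigma=2).
    """
    rng = np.random.default_rng(seed)
    by_species: dict[str, DatabaseEntry] = {}
    for entry in database:
        sp = entry.taxonomy.species
        if sp and sp not in by_species:
            by_species[sp] = entry
    species = list(by_species)
    if n_taxa > len(species):
        raise ValueError(
            f"requested {n_taxa} taxa but database has only "
            f"{len(species)} species-resolved entries"
        )
    chosen = [species[i] for i in rng.choice(len(species), size=n_taxa, replace=False)]
    taxa = [
        MockTaxon(sp, by_species[sp].taxonomy, (by_species[sp].id,)) for sp in chosen
    ]
    samples = [f"S{i + 1}" for i in range(n_samples)]
    abundance = {
        sample: dict(
            zip(chosen, (float(a) for a in _draw_abundances(rng, n_taxa, abundance_model)))
        )
        for sample in samples
    }
    sequences = {by_species[sp].id: by_species[sp].sequence for sp in chosen}
    return MockCommunity(
        name=name, seed=seed, taxa=taxa, samples=samples,
        abundance=abundance, sequences=sequences,
    )


def simulate_assignment(
    mock: MockCommunity,
    database: Sequence[DatabaseEntry],
    error_rate: float,
    unassigned_rate: float = 0.0,
    seed: int = 0,
) -> AssignmentTable:
    """Perturbed truth table standing in for a classifier's output.

    Wrong assignments draw uniformly from database entries with a different
    species label; unassigned sequences get the all-empty taxonomy.
    """
    if error_rate < 0 or unassigned_rate < 0 or error_rate + unassigned_rate > 1:
        raise ValueError("require 0 <= error_rate + unassigned_rate <= 1")
    rng = np.random.default_rng(seed)
    truth = mock.expected_taxonomy()
    pool = list(database)
    table: AssignmentTable = {}
    for sid in mock.sequence_ids:
        u = rng.random()
        if u < error_rate:
            true_sp = truth[sid].species
            while True:
                wrong = pool[int(rng.integers(len(pool)))]
                if wrong.taxonomy.species != true_sp:
                    table[sid] = wrong.taxonomy
                    break
        elif u < error_rate + unassigned_rate:
            table[sid] = TaxonomyString()
        else:
            table[sid] = truth[sid]
    return table


# ---------------------------------------------------------------------------
# Fixture databases
# ---------------------------------------------------------------------------

_SYLLABLES = (
    "ba", "ce", "di", "fo", "ga", "hu", "ki", "lo", "mi", "nu",
    "pa", "re", "si", "to", "vu", "xa", "ze", "la", "cus", "rix",
)


def _make_name(rng: np.random.Generator, used: set[str], n_syllables: int = 3) -> str:
    for _ in range(20):
        parts = [
            _SYLLABLES[int(rng.integers(len(_SYLLABLES)))] for _ in range(n_syllables)
        ]
        name = "".join(parts).capitalize()
        if name not in used:
            used.add(name)
            return name
    # syllable space exhausted: disambiguate deterministically
    name = f"{name}{len(used)}"
    used.add(name)
    return name


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(4, size=length))


def generate_fixture_database(
    n_species: int,
    seed: int = 0,
    with_overlaps: bool = False,
    seq_length: tuple[int, int] = (150, 400),
    source: str = "fixture",
    embed_region=None,
) -> list[DatabaseEntry]:
    """Random reference database with consistent lineages.

    A genus always carries the same upper lineage; species labels are
    ``Genus_epithet`` and unique. ``with_overlaps`` appends engineered
    entries: an identical-sequence pair (same and different taxonomy), a
    substring pair, an "uncultured" species and a rank-sparse lineage, so
    merge, cluster and curation rules all have work to do. When
    ``embed_region`` is a :class:`~ribodb.regions.PrimerPair`, every
    generated sequence is a full amplicon (padding + forward primer +
    insert + reverse-complemented reverse primer + padding) with the insert
    length drawn inside the region's bounds, so region extraction has work
    to do as well.
    """
    rng = np.random.default_rng(seed)
    used: set[str] = set()
    n_phyla = max(2, n_species // 12)
    n_genera = max(2, n_species // 3)
    phyla = []
    for _ in range(n_phyla):
        kingdom = "Bacteria" if rng.random() < 0.9 else "Archaea"
        phyla.append(
            (
                kingdom,
                _make_name(rng, used),
                _make_name(rng, used),  # class
                _make_name(rng, used),  # order
                _make_name(rng, used),  # family
            )
        )
    genera = []
    for _ in range(n_genera):
        lineage = phyla[int(rng.integers(len(phyla)))]
        genera.append((*lineage, _make_name(rng, used)))

    if embed_region is not None:
        lo = max(seq_length[0], embed_region.min_length)
        hi = min(seq_length[1], embed_region.max_length)
        if lo > hi:
            lo, hi = embed_region.min_length, embed_region.max_length
        seq_length = (lo, hi)

    entries: list[DatabaseEntry] = []
    counter = 0

    def add(sequence: str, taxonomy: TaxonomyString) -> DatabaseEntry:
        nonlocal counter
        counter += 1
        entry = DatabaseEntry(f"{source}{counter:06d}", sequence, taxonomy, source)
        entries.append(entry)
        return entry

    for i in range(n_species):
        lineage = genera[int(rng.integers(len(genera)))]
        epithet = _make_name(rng, used, 2).lower()
        species = f"{lineage[5]}_{epithet}"
        tax = TaxonomyString((*lineage, species))
        length = int(rng.integers(seq_length[0], seq_length[1] + 1))
        seq = _random_sequence(rng, length)
        if embed_region is not None:
            seq = embed_amplicon(seq, embed_region, rng)
        add(seq, tax)

    if with_overlaps and entries:
        first, second = entries[0], entries[min(1, len(entries) - 1)]
        # identical sequence, identical taxonomy (dereplication fodder)
        add(first.sequence, first.taxonomy)
        # identical sequence, different taxonomy (clustering fodder)
        add(first.sequence, second.taxonomy)
        # substring pair (merge skip / containment clustering fodder)
        sub = second.sequence[len(second.sequence) // 4 : 3 * len(second.sequence) // 4]
        add(sub, first.taxonomy)
        # curation fodder
        lineage = genera[0]
        add(
            _random_sequence(rng, 200),
            TaxonomyString((*lineage, "uncultured_bacterium")),
        )
        add(
            _random_sequence(rng, 200),
            TaxonomyString(("Bacteria", "", "", "", "", "", "bacterium_teXX")),
        )
    return entries


# ---------------------------------------------------------------------------
# Amplicon construction helpers (for region-extraction fixtures)
# ---------------------------------------------------------------------------


def realize_primer(primer: str, rng: np.random.Generator) -> str:
    """Replace each degenerate IUPAC letter by one concrete base (seeded)."""
    from .regions import IUPAC_SETS

    out = []
    for letter in primer:
        choices = sorted(IUPAC_SETS[letter])
        out.append(choices[int(rng.integers(len(choices)))])
    return "".join(out)


def embed_amplicon(
    insert: str,
    primer_pair,
    rng: np.random.Generator,
    pad_length: int = 30,
) -> str:
    """``PAD + FWD + insert + revcomp(REV) + PAD`` with concrete primer
    realizations — a full-length sequence the extractor should reduce back
    to ``insert``."""
    from Bio.Seq import Seq

    fwd = realize_primer(primer_pair.forward, rng)
    rev = realize_primer(primer_pair.reverse, rng)
    left = _random_sequence(rng, pad_length)
    right = _random_sequence(rng, pad_length)
    return left + fwd + insert + str(Seq(rev).reverse_complement()) + right


# ---------------------------------------------------------------------------
# On-disk mock community layout
# ---------------------------------------------------------------------------


def write_mock_community(mock: MockCommunity, out_dir) -> None:
    """Write a community directory: ``community.json`` (taxa, abundances,
    seed), ``members.fasta``, ``expected-taxonomy.tsv`` and one
    ``composition.<rank>.tsv`` per rank."""
    import json
    from pathlib import Path

    from .taxio import (
        RANK_NAMES,
        SequenceRecord,
        format_taxonomy_string,
        write_composition_table,
        write_fasta,
        write_taxonomy_table,
    )

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "name": mock.name,
        "seed": mock.seed,
        "samples": mock.samples,
        "taxa": [
            {
                "taxon_id": t.taxon_id,
                "taxonomy": format_taxonomy_string(t.taxonomy),
                "sequence_ids": list(t.sequence_ids),
            }
            for t in mock.taxa
        ],
        "abundance": mock.abundance,
    }
    (out_dir / "community.json").write_text(json.dumps(payload, indent=2))
    write_fasta(
        [SequenceRecord(sid, seq) for sid, seq in mock.sequences.items()],
        out_dir / "members.fasta",
    )
    write_taxonomy_table(mock.expected_taxonomy(), out_dir / "expected-taxonomy.tsv")
    for rank in RANK_NAMES:
        write_composition_table(
            mock.expected_composition(rank), out_dir / f"composition.{rank}.tsv"
        )


def read_mock_community(mock_dir) -> MockCommunity:
    """Load a community directory written by :func:`write_mock_community`."""
    import json
    from pathlib import Path

    from .taxio import parse_taxonomy_string, read_fasta

    mock_dir = Path(mock_dir)
    payload = json.loads((mock_dir / "community.json").read_text())
    sequences = {r.id: r.sequence for r in read_fasta(mock_dir / "members.fasta")}
    taxa = [
        MockTaxon(
            t["taxon_id"],
            parse_taxonomy_string(t["taxonomy"]),
            tuple(t["sequence_ids"]),
        )
        for t in payload["taxa"]
    ]
    return MockCommunity(
        name=payload["name"],
        seed=payload["seed"],
        taxa=taxa,
        samples=list(payload["samples"]),
        abundance={s: dict(v) for s, v in payload["abundance"].items()},
        sequences=sequences,
    )
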