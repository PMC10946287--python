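"""Record types and readers/writers for the interchange formats of the pipeline.

Databases travel between stages as a plain FASTA file paired with a
two-column tab-separated taxonomy table (the interchange convention of the
QIIME2 ecosystem: optional ``Feature ID\\tTaxon`` header). Taxonomy strings
use the Greengenes convention: seven ranks, ``k__`` through ``s__`` prefixes,
semicolon separated, e.g. ``k__Bacteria; p__Firmicutes; c__Bacilli; ...``.

Sequences are uppercased at read time and RNA ``U`` is mapped to ``T``, so
sources that ship rRNA-style sequences interoperate with DNA-style ones.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "IUPAC_DNA",
    "RANK_NAMES",
    "RANK_PREFIXES",
    "SequenceRecord",
    "TaxonomyString",
    "SynonymEntry",
    "SynonymMap",
    "CompositionTable",
    "DatabaseEntry",
    "FastaParseError",
    "TaxonomyParseError",
    "read_fasta",
    "write_fasta",
    "parse_taxonomy_string",
    "format_taxonomy_string",
    "read_taxonomy_table",
    "write_taxonomy_table",
    "read_synonym_table",
    "read_composition_table",
    "write_composition_table",
    "load_database",
    "write_database",
]

#: 15-letter IUPAC nucleotide alphabet (includes N).
IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")

RANK_NAMES = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")


class FastaParseError(ValueError):
    """Malformed FASTA input."""


class TaxonomyParseError(ValueError):
    """Malformed taxonomy string or table."""


@dataclass(frozen=True)
class SequenceRecord:
    """One sequence with its identifier and provenance label.

    ``sequence`` must be non-empty, uppercase IUPAC DNA. ``source`` names the
    database the record came from (used for merge provenance reporting).
    """

    id: str
    sequence: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        bad = set(self.sequence) - IUPAC_DNA
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-IUPAC characters {sorted(bad)!r} in sequence"
            )


@dataclass(frozen=True)
class TaxonomyString:
    """An ordered seven-rank lineage, kingdom through species.

    Labels are stored without their ``k__``-style prefixes; absent ranks are
    empty strings. ``parse`` / ``str()`` round-trip on the canonical form.
    """

    ranks: tuple[str, str, str, str, str, str, str] = ("",) * 7

    def __post_init__(self) -> None:
        if len(self.ranks) != 7:
            raise ValueError(f"taxonomy must have exactly 7 ranks, got {len(self.ranks)}")
        object.__setattr__(self, "ranks", tuple(self.ranks))

    # -- rank accessors -------------------------------------------------
    @property
    def kingdom(self) -> str:
        return self.ranks[0]

    @property
    def phylum(self) -> str:
        return self.ranks[1]

    @property
    def genus(self) -> str:
        return self.ranks[5]

    @property
    def species(self) -> str:
        return self.ranks[6]

    def label(self, rank: str | int) -> str:
        """Label at ``rank`` (name like ``"genus"`` or index 0..6)."""
        return self.ranks[_rank_index(rank)]

    def replace(self, rank: str | int, label: str) -> "TaxonomyString":
        ranks = list(self.ranks)
        ranks[_rank_index(rank)] = label
        return TaxonomyString(tuple(ranks))

    @property
    def is_empty(self) -> bool:
        return all(r == "" for r in self.ranks)

    @classmethod
    def parse(cls, text: str) -> "TaxonomyString":
        return parse_taxonomy_string(text)

    def __str__(self) -> str:
        return format_taxonomy_string(self)


def _rank_index(rank: str | int) -> int:
    if isinstance(rank, int):
        if not 0 <= rank < 7:
            raise IndexError(f"rank index {rank} out of range 0..6")
        return rank
    try:
        return RANK_NAMES.index(rank)
    except ValueError:
        raise KeyError(f"unknown rank name {rank!r}") from None


def parse_taxonomy_string(text: str) -> TaxonomyString:
    """Parse a Greengenes-style prefixed lineage.

    Whitespace around semicolons is tolerated; absent trailing (or skipped
    intermediate) ranks become empty labels. Prefixes must appear in
    canonical ``k__ .. s__`` order; an out-of-order, repeated or unknown
    prefix raises :class:`TaxonomyParseError`. The empty string parses to the
    all-empty lineage (used for unassigned records).
    """
    labels = [""] * 7
    tokens = [t.strip() for t in text.split(";")]
    while tokens and tokens[-1] == "":
        tokens.pop()
    prev = -1
    for token in tokens:
        prefix = token[:3]
        if prefix not in RANK_PREFIXES:
            raise TaxonomyParseError(
                f"token {token!r} does not start with a known rank prefix"
            )
        idx = RANK_PREFIXES.index(prefix)
        if idx <= prev:
            raise TaxonomyParseError(
                f"rank prefix {prefix!r} out of order in {text!r}"
            )
        labels[idx] = token[3:].strip()
        prev = idx
    return TaxonomyString(tuple(labels))


def format_taxonomy_string(tax: TaxonomyString) -> str:
    """Canonical form: all seven ranks, ``"; "``-separated, prefixed."""
    return "; ".join(p + l for p, l in zip(RANK_PREFIXES, tax.ranks))


@dataclass(frozen=True)
class SynonymEntry:
    canonical: str
    taxid: Optional[int]
    kingdom: str


@dataclass
class SynonymMap:
    """Taxon name -> canonical NCBI-style name with taxid and kingdom.

    Lookup is case-sensitive on stored keys with a case-insensitive fallback
    (a name differing only in case from a stored key resolves to that key's
    entry). Canonical names always map to themselves.
    """

    entries: dict[str, SynonymEntry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # canonical self-mapping; lowercase index for the fallback
        for entry in list(self.entries.values()):
            self.entries.setdefault(
                entry.canonical, SynonymEntry(entry.canonical, entry.taxid, entry.kingdom)
            )
        self._lower = {k.lower(): k for k in self.entries}

    def lookup(self, name: str) -> Optional[SynonymEntry]:
        entry = self.entries.get(name)
        if entry is not None:
            return entry
        key = self._lower.get(name.lower())
        return self.entries[key] if key is not None else None

    def canonical(self, name: str) -> str:
        """Canonical name for ``name``; unknown names pass through unchanged."""
        entry = self.lookup(name)
        return entry.canonical if entry is not None else name

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, name: str) -> bool:
        return self.lookup(name) is not None


@dataclass
class CompositionTable:
    """Per-sample relative abundances keyed by taxon label.

    Invariant: each sample's abundances are non-negative and sum to 1
    within 1e-9.
    """

    samples: list[str]
    abundances: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for sample in self.samples:
            if sample not in self.abundances:
                raise ValueError(f"sample {sample!r} missing from abundances")
            vals = self.abundances[sample]
            if any(v < 0 for v in vals.values()):
                raise ValueError(f"sample {sample!r}: negative abundance")
            total = sum(vals.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"sample {sample!r}: abundances sum to {total!r}, expected 1"
                )

    def taxa(self) -> list[str]:
        seen: dict[str, None] = {}
        for sample in self.samples:
            for taxon in self.abundances[sample]:
                seen.setdefault(taxon, None)
        return list(seen)

    def to_dataframe(self) -> pd.DataFrame:
        taxa = self.taxa()
        data = {
            t: [self.abundances[s].get(t, 0.0) for s in self.samples] for t in taxa
        }
        return pd.DataFrame(data, index=pd.Index(self.samples, name="sample"))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CompositionTable":
        samples = [str(s) for s in df.index]
        abundances = {
            s: {str(t): float(df.loc[idx, t]) for t in df.columns}
            for s, idx in zip(samples, df.index)
        }
        return cls(samples=samples, abundances=abundances)


@dataclass(frozen=True)
class DatabaseEntry:
    """One reference-database record: the (taxon, sequence) pair."""

    id: str
    sequence: str
    taxonomy: TaxonomyString
    source: str = ""

    @property
    def record(self) -> SequenceRecord:
        return SequenceRecord(self.id, self.sequence, self.source)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

_RNA_TO_DNA = str.maketrans({"U": "T", "u": "t"})


def read_fasta(path: str | Path, source: str = "") -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    The header up to the first whitespace becomes the id; sequences are
    uppercased and U is mapped to T. Raises :class:`FastaParseError` for
    sequence data before the first header (naming the line number) and for
    duplicate ids.
    """
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: sequence data before first FASTA header"
                )
            break
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).translate(_RNA_TO_DNA).upper()
        records.append(SequenceRecord(id=rec.id, sequence=seq, source=source))
    return records


def write_fasta(
    records: Iterable[SequenceRecord | DatabaseEntry],
    path: str | Path,
    wrap: int = 60,
) -> Path:
    """Write records as FASTA (wrapped at ``wrap`` columns; 0 = single line)."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            if wrap:
                bio = _BioSeqRecord(Seq(rec.sequence), id=rec.id, description="")
                SeqIO.write(bio, fh, "fasta")
            else:
                fh.write(f">{rec.id}\n{rec.sequence}\n")
    return path


# ---------------------------------------------------------------------------
# Taxonomy tables
# ---------------------------------------------------------------------------

_TAX_HEADER = ("Feature ID", "Taxon")


def read_taxonomy_table(path: str | Path) -> dict[str, TaxonomyString]:
    """Read a two-column TSV of id -> taxonomy string.

    An optional ``Feature ID\\tTaxon`` header line is skipped. An
    unparseable taxonomy raises :class:`TaxonomyParseError` naming the id.
    """
    path = Path(path)
    mapping: dict[str, TaxonomyString] = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for rowno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if rowno == 1 and row[0].strip() == _TAX_HEADER[0]:
                continue
            if len(row) < 2:
                raise TaxonomyParseError(
                    f"{path}: line {rowno}: expected two tab-separated columns"
                )
            feature_id = row[0].strip()
            if feature_id in mapping:
                raise TaxonomyParseError(f"{path}: duplicate feature id {feature_id!r}")
            try:
                mapping[feature_id] = parse_taxonomy_string(row[1])
            except TaxonomyParseError as exc:
                raise TaxonomyParseError(
                    f"{path}: taxonomy for id {feature_id!r} unparseable: {exc}"
                ) from exc
    return mapping


def write_taxonomy_table(
    mapping: Mapping[str, TaxonomyString], path: str | Path
) -> Path:
    """Write id -> taxonomy as TSV with the ``Feature ID\\tTaxon`` header."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TAX_HEADER)
        for feature_id, tax in mapping.items():
            writer.writerow([feature_id, format_taxonomy_string(tax)])
    return path


# ---------------------------------------------------------------------------
# Synonym tables
# ---------------------------------------------------------------------------


def read_synonym_table(path: str | Path) -> SynonymMap:
    """Read a 4-column TSV (name, canonical name, taxid, kingdom).

    Lines starting with ``#`` and an optional ``name\\tcanonical...`` header
    are skipped. A name mapped to two different canonicals is an error;
    canonical self-mappings are added automatically.
    """
    path = Path(path)
    entries: dict[str, SynonymEntry] = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for rowno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if rowno == 1 and row[0].strip().lower() == "name":
                continue
            if len(row) < 4:
                raise ValueError(
                    f"{path}: line {rowno}: expected 4 tab-separated columns"
                )
            name, canonical, taxid_text, kingdom = (c.strip() for c in row[:4])
            taxid = int(taxid_text) if taxid_text else None
            entry = SynonymEntry(canonical, taxid, kingdom)
            existing = entries.get(name)
            if existing is not None and existing.canonical != canonical:
                raise ValueError(
                    f"{path}: name {name!r} mapped to both "
                    f"{existing.canonical!r} and {canonical!r}"
                )
            entries[name] = entry
    return SynonymMap(entries)


# ---------------------------------------------------------------------------
# Composition tables
# ---------------------------------------------------------------------------


def read_composition_table(path: str | Path) -> CompositionTable:
    """Read a wide TSV: first column sample id, remaining columns taxa."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CompositionTable.from_dataframe(df)


def write_composition_table(table: CompositionTable, path: str | Path) -> Path:
    path = Path(path)
    table.to_dataframe().to_csv(path, sep="\t", index_label="sample")
    return path


# ---------------------------------------------------------------------------
# Database = FASTA + taxonomy table
# ---------------------------------------------------------------------------


def load_database(
    fasta_path: str | Path, taxonomy_path: str | Path, source: str = ""
) -> list[DatabaseEntry]:
    """Load a FASTA + taxonomy-TSV pair into database entries.

    Every sequence id must have a taxonomy row; the converse is not required
    (extra taxonomy rows are ignored).
    """
    records = read_fasta(fasta_path, source=source)
    taxonomy = read_taxonomy_table(taxonomy_path)
    entries: list[DatabaseEntry] = []
    for rec in records:
        if rec.id not in taxonomy:
            raise KeyError(
                f"sequence id {rec.id!r} has no row in taxonomy table {taxonomy_path}"
            )
        entries.append(
            DatabaseEntry(rec.id, rec.sequence, taxonomy[rec.id], source=source)
        )
    return entries


def write_database(entries: Iterable[DatabaseEntry], out_prefix: str | Path) -> tuple[Path, Path]:
    """Write entries as ``<prefix>.fasta`` and ``<prefix>.tax.tsv``."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    entries = list(entries)
    fasta = write_fasta(entries, Path(str(out_prefix) + ".fasta"))
    tax = write_taxonomy_table(
        {e.id: e.taxonomy for e in entries}, Path(str(out_prefix) + ".tax.tsv")
    )
    return fasta, tax
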