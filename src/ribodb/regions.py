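"""Hypervariable-region extraction by degenerate primer matching.

An amplicon region is located by finding the forward primer on the forward
strand and the reverse complement of the reverse primer downstream of it;
the extracted region is the subsequence strictly between the two primer
sites (primers excluded), accepted only within the region's length bounds.
If the forward strand yields nothing, the reverse-complemented sequence is
searched the same way. Primer letters follow the IUPAC degeneracy code;
matching tolerates up to ``max_mismatch`` positions (default 0).

Default primer pairs for the commonly used regions (V4, V1-V3, V3-V4,
V3-V5) are the conventional Earth-Microbiome-style choices; users can
override them from a YAML config.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from pathlib import Path
from typing import Optional, Sequence

import yaml
from Bio.Seq import Seq

from .taxio import IUPAC_DNA, DatabaseEntry, SequenceRecord, format_taxonomy_string

__all__ = [
    "IUPAC_SETS",
    "PrimerPair",
    "DEFAULT_PRIMERS",
    "load_primer_config",
    "iupac_match",
    "find_primer",
    "extract_region",
    "extract_region_db",
    "dereplicate",
]

#: IUPAC nucleotide degeneracy table.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("GC"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


@dataclass(frozen=True)
class PrimerPair:
    """A named amplicon region: forward/reverse primers plus length bounds.

    The reverse primer is given 5'->3' on the reverse strand (the
    conventional way primers are published); its reverse complement is what
    is searched on the forward strand.
    """

    region_name: str
    forward: str
    reverse: str
    min_length: int
    max_length: int
    max_mismatch: int = 0

    def __post_init__(self) -> None:
        for name, primer in (("forward", self.forward), ("reverse", self.reverse)):
            if not primer:
                raise ValueError(f"{name} primer must be non-empty")
            bad = set(primer.upper()) - IUPAC_DNA
            if bad:
                raise ValueError(
                    f"{name} primer contains non-IUPAC characters {sorted(bad)!r}"
                )
        if self.min_length > self.max_length:
            raise ValueError("min_length must be <= max_length")


#: Conventional primer pairs for the shipped regions (overridable via YAML).
DEFAULT_PRIMERS: dict[str, PrimerPair] = {
    "V4": PrimerPair("V4", "GTGYCAGCMGCCGCGGTAA", "GGACTACNVGGGTWTCTAAT", 200, 300),
    "V1-V3": PrimerPair("V1-V3", "AGAGTTTGATCMTGGCTCAG", "ATTACCGCGGCTGCTGG", 400, 600),
    "V3-V4": PrimerPair("V3-V4", "CCTACGGGNGGCWGCAG", "GACTACHVGGGTATCTAATCC", 350, 500),
    "V3-V5": PrimerPair("V3-V5", "CCTACGGGAGGCAGCAG", "CCGTCAATTCMTTTRAGT", 450, 650),
}


def load_primer_config(path: str | Path) -> dict[str, PrimerPair]:
    """Load primer pairs from YAML.

    Layout: mapping region name -> {forward, reverse, min_length,
    max_length, max_mismatch (optional)}.
    """
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh) or {}
    primers: dict[str, PrimerPair] = {}
    for region, cfg in raw.items():
        primers[region] = PrimerPair(
            region_name=region,
            forward=str(cfg["forward"]).upper(),
            reverse=str(cfg["reverse"]).upper(),
            min_length=int(cfg["min_length"]),
            max_length=int(cfg["max_length"]),
            max_mismatch=int(cfg.get("max_mismatch", 0)),
        )
    return primers


def iupac_match(primer: str, window: str, max_mismatch: int = 0) -> bool:
    """True iff ``window`` matches ``primer`` with at most ``max_mismatch``
    mismatching positions.

    A position matches when the window letter's IUPAC set is a subset of
    the primer letter's set; for concrete window bases this is plain set
    membership, and it makes any primer match itself at 0 mismatches.
    """
    if len(primer) != len(window):
        raise ValueError(
            f"primer length {len(primer)} != window length {len(window)}"
        )
    mismatches = 0
    for p, w in zip(primer, window):
        try:
            hit = IUPAC_SETS[w] <= IUPAC_SETS[p]
        except KeyError as exc:
            raise ValueError(f"non-IUPAC letter {exc.args[0]!r}") from None
        if not hit:
            mismatches += 1
            if mismatches > max_mismatch:
                return False
    return True


def find_primer(sequence: str, primer: str, max_mismatch: int = 0, start: int = 0) -> Optional[int]:
    """0-based index of the leftmost primer hit at or after ``start``; None if absent."""
    m = len(primer)
    for i in range(start, len(sequence) - m + 1):
        if iupac_match(primer, sequence[i : i + m], max_mismatch):
            return i
    return None


def _reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _extract_forward(
    sequence: str, pair: PrimerPair, max_mismatch: int
) -> Optional[str]:
    fwd_start = find_primer(sequence, pair.forward, max_mismatch)
    if fwd_start is None:
        return None
    insert_start = fwd_start + len(pair.forward)
    rc_rev = _reverse_complement(pair.reverse)
    rev_start = find_primer(sequence, rc_rev, max_mismatch, start=insert_start)
    if rev_start is None:
        return None
    insert = sequence[insert_start:rev_start]
    if not pair.min_length <= len(insert) <= pair.max_length:
        return None
    return insert


def extract_region(
    record: SequenceRecord | DatabaseEntry,
    primer_pair: PrimerPair,
    max_mismatch: Optional[int] = None,
) -> Optional[SequenceRecord]:
    """Extract the amplicon region from one record; None when absent.

    The forward strand is tried first, then the reverse complement of the
    record. Leftmost primer hits win; the extracted subsequence excludes
    both primers and must lie within the pair's length bounds.
    """
    mm = primer_pair.max_mismatch if max_mismatch is None else max_mismatch
    for sequence in (record.sequence, _reverse_complement(record.sequence)):
        insert = _extract_forward(sequence, primer_pair, mm)
        if insert is not None:
            return SequenceRecord(record.id, insert, getattr(record, "source", ""))
    return None


def extract_region_db(
    database: Sequence[DatabaseEntry],
    primer_pair: PrimerPair,
    max_mismatch: Optional[int] = None,
) -> tuple[list[DatabaseEntry], int]:
    """Per-entry extraction over a database; taxonomy is carried over.

    Entries without an extractable region are dropped; returns the new
    database and the dropped count.
    """
    out: list[DatabaseEntry] = []
    dropped = 0
    for entry in database:
        hit = extract_region(entry, primer_pair, max_mismatch)
        if hit is None:
            dropped += 1
        else:
            out.append(
                DatabaseEntry(entry.id, hit.sequence, entry.taxonomy, entry.source)
            )
    return out, dropped


def dereplicate(database: Sequence[DatabaseEntry]) -> list[DatabaseEntry]:
    """Collapse entries with identical (sequence, full taxonomy string),
    keeping the first-seen id. Identical sequences with different taxonomy
    are retained: resolving those is the clustering stage's job."""
    seen: set[tuple[str, str]] = set()
    out: list[DatabaseEntry] = []
    for entry in database:
        key = (entry.sequence, format_taxonomy_string(entry.taxonomy))
        if key not in seen:
            seen.add(key)
            out.append(entry)
    return out
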