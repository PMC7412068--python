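"""Sequence and alignment input/output.

Reads plain and aligned FASTA through Biopython, normalizes the alphabet to
uppercase IUPAC DNA, and binds species labels to records either from a
two-column sidecar TSV (id <tab> species) or from a regex applied to the
record header. Coordinates everywhere in the toolkit are 0-based, half-open,
on the plus strand of the stored sequence; reported product sizes are
1-based lengths.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

from .errors import AlignmentError, FastaParseError

#: Concrete bases.
BASES = "ACGT"
#: IUPAC one-letter DNA codes (concrete + ambiguity).
IUPAC = set("ACGTRYSWKMBDHVN")
#: Ambiguity code -> set of concrete bases it denotes.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"), "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC DNA string (gaps preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SeqRecord:
    """An uppercase DNA sequence with an identifier.

    ``seq`` is validated against the IUPAC DNA alphabet on construction;
    gaps (``-``) are only legal when the record lives in an alignment.
    """

    id: str
    seq: str
    description: str = ""

    def __post_init__(self):
        if not self.seq:
            raise FastaParseError(f"record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.seq)

    def degapped(self) -> "SeqRecord":
        return SeqRecord(self.id, self.seq.replace("-", ""), self.description)


def _validate_alphabet(seq: str, rec_id: str, allow_gaps: bool, line: int | None) -> None:
    allowed = IUPAC | ({"-"} if allow_gaps else set())
    bad = set(seq) - allowed
    if bad:
        which = ", ".join(sorted(bad))
        raise FastaParseError(
            f"record {rec_id!r} contains illegal character(s): {which}"
            + (" ('U' suggests RNA input)" if "U" in bad else ""),
            line=line,
        )


def _header_lines(path: Path) -> dict[str, int]:
    """1-based line number of each record header, for error reporting."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            if raw.startswith(">"):
                rec_id = raw[1:].split(None, 1)[0] if raw[1:].strip() else ""
                out.setdefault(rec_id, i)
    return out


def read_fasta(path: str | Path, allow_gaps: bool = False) -> list[SeqRecord]:
    """Read a FASTA file into validated, uppercased records.

    Raises :class:`FastaParseError` naming the offending line for malformed
    headers, empty sequences, or characters outside the IUPAC DNA alphabet
    ('U' is rejected).
    """
    path = Path(path)
    lines = _header_lines(path)
    records: list[SeqRecord] = []
    with open(path) as fh:
        first = fh.read(1)
        if first and first != ">":
            raise FastaParseError("expected '>' header as first non-empty content", line=1)
    for bio in SeqIO.parse(str(path), "fasta"):
        line = lines.get(bio.id)
        if not bio.id:
            raise FastaParseError("record header carries no identifier", line=line)
        seq = str(bio.seq).upper()
        if not seq:
            raise FastaParseError(f"record {bio.id!r} has an empty sequence", line=line)
        _validate_alphabet(seq, bio.id, allow_gaps, line)
        records.append(SeqRecord(id=bio.id, seq=seq, description=bio.description))
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    """Write records as wrapped FASTA; round-trips byte-for-byte through read_fasta."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.description if rec.description else rec.id
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


@dataclass
class SpeciesAlignment:
    """Aligned, species-labeled sequences: the primer designer's substrate.

    Invariants (enforced): equal aligned lengths, every record labeled,
    at least two species with at least one record each.
    """

    records: list[SeqRecord]
    species_of: dict[str, str]
    length: int = field(init=False)

    def __post_init__(self):
        if not self.records:
            raise AlignmentError("alignment has no records")
        lengths = {len(r.seq) for r in self.records}
        if len(lengths) != 1:
            offenders = [r.id for r in self.records if len(r.seq) != len(self.records[0].seq)]
            raise AlignmentError(f"ragged alignment; offending ids: {', '.join(offenders)}")
        self.length = len(self.records[0].seq)
        unlabeled = [r.id for r in self.records if r.id not in self.species_of]
        if unlabeled:
            raise AlignmentError(f"records without species label: {', '.join(unlabeled)}")
        if len(self.species) < 2:
            raise AlignmentError("alignment must contain at least two species")

    @property
    def species(self) -> list[str]:
        """Species names in first-appearance order."""
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(self.species_of[r.id], None)
        return list(seen)

    def records_of(self, species: str) -> list[SeqRecord]:
        return [r for r in self.records if self.species_of[r.id] == species]

    def column(self, i: int) -> list[str]:
        return [r.seq[i] for r in self.records]

    def consensus(self, species: str) -> str:
        """Per-column majority consensus of one species (ties: alphabetical base,
        then gap; N and gaps lose to any concrete base)."""
        recs = self.records_of(species)
        if not recs:
            raise AlignmentError(f"unknown species {species!r}")
        out = []
        for i in range(self.length):
            col = [r.seq[i] for r in recs]
            concrete = [c for c in col if c in BASES]
            pool = concrete if concrete else col
            counts: dict[str, int] = {}
            for c in pool:
                counts[c] = counts.get(c, 0) + 1
            best = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
            out.append(best)
        return "".join(out)


def read_labels_tsv(path: str | Path) -> dict[str, str]:
    """Two-column TSV (record id, species name) -> mapping."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise AlignmentError(f"labels TSV line {i}: expected 2 tab-separated columns")
            mapping[parts[0]] = parts[1]
    return mapping


def labels_from_regex(records: Iterable[SeqRecord], pattern: str) -> dict[str, str]:
    """Extract species from each record's header via the pattern's first group."""
    rx = re.compile(pattern)
    mapping: dict[str, str] = {}
    for rec in records:
        m = rx.search(rec.description or rec.id)
        if not m or not m.groups():
            raise AlignmentError(
                f"record {rec.id!r}: header does not match species pattern {pattern!r}"
            )
        mapping[rec.id] = m.group(1)
    return mapping


def load_species_alignment(
    path: str | Path,
    labels: str | Path | Mapping[str, str],
    *,
    header_regex: bool = False,
) -> SpeciesAlignment:
    """Load an aligned FASTA and bind species labels.

    ``labels`` is a sidecar TSV path (default), a ready mapping, or — with
    ``header_regex=True`` — a regex whose first group captures the species
    from each header.
    """
    records = read_fasta(path, allow_gaps=True)
    if header_regex:
        species_of = labels_from_regex(records, str(labels))
    elif isinstance(labels, Mapping):
        species_of = dict(labels)
    else:
        species_of = read_labels_tsv(labels)
    return SpeciesAlignment(records=records, species_of=species_of)
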