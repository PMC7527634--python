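"""DNA sequence records, FASTA input/output and label transport.

A record is a plain string over the 4-letter alphabet {A, C, G, T} carrying an
optional class label: ``hotspot`` (a chromosomal region with elevated meiotic
recombination frequency, the positive class) or ``coldspot`` (depressed
frequency, the negative class).  Labels travel either as a ``|hotspot`` /
``|coldspot`` suffix on the FASTA header or in a two-column sidecar TSV
(id, label).  All residues are uppercased on read; ambiguity codes (N, ...)
are rejected unless ``strip_ambiguous`` is set, in which case the offending
records are dropped and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FastaParseError, ParameterError, ValidationError

logger = logging.getLogger(__name__)

HOTSPOT = "hotspot"
COLDSPOT = "coldspot"
LABELS = (HOTSPOT, COLDSPOT)

_ALPHABET = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: numeric encoding used throughout: 0 = hotspot (positive), 1 = coldspot.
LABEL_CODES = {HOTSPOT: 0, COLDSPOT: 1}

LabelSource = Literal["header-token", "sidecar-table", "none"]


def reverse_complement(residues: str) -> str:
    """Reverse-complement a DNA string (exchange A<->T, C<->G, reverse).

    Involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    _check_alphabet(residues, "sequence")
    return residues.translate(_COMPLEMENT)[::-1]


def _check_alphabet(residues: str, what: str) -> None:
    bad = set(residues) - _ALPHABET
    if bad:
        raise ValidationError(
            f"{what} contains characters outside {{A,C,G,T}}: {sorted(bad)}"
        )


@dataclass(frozen=True)
class DnaSequence:
    """One DNA record with an optional hotspot/coldspot label.

    residues are stored uppercase; construction validates the alphabet and a
    minimum length of 3 (the shortest k-mer any extractor uses).
    """

    id: str
    residues: str
    label: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        _check_alphabet(self.residues, f"record {self.id!r}")
        if len(self.residues) < 3:
            raise ValidationError(
                f"record {self.id!r} has length {len(self.residues)} < 3"
            )
        if self.label is not None and self.label not in LABELS:
            raise ValidationError(
                f"record {self.id!r} has unknown label {self.label!r}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "DnaSequence":
        return DnaSequence(self.id, reverse_complement(self.residues), self.label)


@dataclass
class SequenceDataset:
    """An ordered collection of records with unique ids."""

    records: list[DnaSequence] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate record ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[DnaSequence]:
        return iter(self.records)

    def __getitem__(self, i: int) -> DnaSequence:
        return self.records[i]

    @property
    def n_pos(self) -> int:
        return sum(1 for r in self.records if r.label == HOTSPOT)

    @property
    def n_neg(self) -> int:
        return sum(1 for r in self.records if r.label == COLDSPOT)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def labels(self) -> list[Optional[str]]:
        return [r.label for r in self.records]

    def numeric_labels(self) -> list[int]:
        """Labels encoded 0 = hotspot, 1 = coldspot; raises if any unlabeled."""
        out = []
        for r in self.records:
            if r.label is None:
                raise ValidationError(f"record {r.id!r} is unlabeled")
            out.append(LABEL_CODES[r.label])
        return out

    def subset(self, indices: Iterable[int]) -> "SequenceDataset":
        return SequenceDataset([self.records[i] for i in indices])


def _split_header_label(raw_id: str) -> tuple[str, Optional[str]]:
    if "|" in raw_id:
        stem, _, token = raw_id.rpartition("|")
        if token.lower() in LABELS:
            return stem, token.lower()
    return raw_id, None


def _read_sidecar(path: Path) -> dict[str, str]:
    table: dict[str, str] = {}
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise FastaParseError(f"{path}:{ln}: expected two tab-separated columns")
        rid, label = parts[0].strip(), parts[1].strip().lower()
        if label not in LABELS:
            raise ValidationError(f"{path}:{ln}: unknown label {label!r}")
        table[rid] = label
    return table


def read_fasta(
    path: str | Path,
    label_source: LabelSource = "header-token",
    sidecar: str | Path | None = None,
    strip_ambiguous: bool = False,
) -> SequenceDataset:
    """Read a FASTA file into a validated :class:`SequenceDataset`.

    Parameters
    ----------
    label_source
        ``header-token``: a trailing ``|hotspot`` / ``|coldspot`` on the header
        id carries the label.  ``sidecar-table``: labels come from a headerless
        two-column TSV (id, label) given via *sidecar*.  ``none``: all records
        unlabeled.
    strip_ambiguous
        Drop (and log) records containing characters outside {A,C,G,T} instead
        of raising.
    """
    path = Path(path)
    _validate_fasta_layout(path)
    side = None
    if label_source == "sidecar-table":
        if sidecar is None:
            raise ParameterError("sidecar-table label source needs a sidecar path")
        side = _read_sidecar(Path(sidecar))

    records: list[DnaSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        raw_id = rec.id
        residues = str(rec.seq).upper()
        if label_source == "header-token":
            rid, label = _split_header_label(raw_id)
        elif label_source == "sidecar-table":
            rid, label = raw_id, side.get(raw_id)  # type: ignore[union-attr]
        else:
            rid, label = _split_header_label(raw_id)[0], None
        try:
            records.append(DnaSequence(rid, residues, label))
        except ValidationError:
            if strip_ambiguous and set(residues) - _ALPHABET:
                logger.warning("dropping record %r: ambiguous residues", rid)
                continue
            raise
    return SequenceDataset(records)


def _validate_fasta_layout(path: Path) -> None:
    """Reject files whose first non-blank line is not a FASTA header."""
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}:{ln}: expected a '>' FASTA header, got {line[:30]!r}"
                )
            return
    # empty file: fine, yields an empty dataset


def write_fasta(dataset: SequenceDataset, path: str | Path) -> None:
    """Write records as uppercase, 60-column-wrapped FASTA.

    Labeled records get a ``|label`` header suffix so that
    ``read_fasta(write_fasta(d))`` round-trips ids, residues and labels.
    """
    out = []
    for r in dataset:
        rid = f"{r.id}|{r.label}" if r.label else r.id
        out.append(SeqRecord(Seq(r.residues), id=rid, description=""))
    with open(path, "w") as fh:
        SeqIO.write(out, fh, "fasta")
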