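"""Reading and validation of protein sequences and labeled interaction pairs.

Proteins arrive as FASTA; interaction examples arrive as a tab-separated file
``idA <TAB> idB <TAB> label`` where the label is one of ``1``/``+`` (interacting)
or ``0``/``-`` (non-interacting).  Sequences are reduced to the 20 standard
amino-acid letters before any featurization: selenocysteine (U), pyrrolysine
(O) and the ambiguity codes (B, Z, X, J) are stripped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("autoppi")

#: The 20 standard amino acids, alphabetical one-letter codes.
STANDARD_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_AMINO_ACIDS)

POSITIVE_TOKENS = {"1", "+", "positive", "pos"}
NEGATIVE_TOKENS = {"0", "-", "−", "negative", "neg"}


class SequenceError(ValueError):
    """Raised for malformed FASTA/pair input or empty cleaned sequences."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein identifier plus its (uppercase) amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("protein record has an empty identifier")
        if not self.sequence:
            raise SequenceError(f"protein {self.id!r} has an empty sequence")


@dataclass(frozen=True)
class PairExample:
    """An ordered protein pair with an interaction label.

    ``label`` is ``True`` for interacting (the positive class C+), ``False``
    for non-interacting (C-), or ``None`` for prediction-only input.
    """

    id_a: str
    id_b: str
    label: bool | None = None


@dataclass
class LabeledPairSet:
    """The training corpus C = C+ ∪ C- as two lists of ordered pairs."""

    positives: list[PairExample] = field(default_factory=list)
    negatives: list[PairExample] = field(default_factory=list)

    def __post_init__(self) -> None:
        pos = {(p.id_a, p.id_b) for p in self.positives}
        neg = {(p.id_a, p.id_b) for p in self.negatives}
        both = pos & neg
        if both:
            raise SequenceError(
                f"{len(both)} ordered pair(s) appear in both classes, e.g. {sorted(both)[0]}"
            )

    def __len__(self) -> int:
        return len(self.positives) + len(self.negatives)

    @property
    def all_pairs(self) -> list[PairExample]:
        return list(self.positives) + list(self.negatives)


def clean_sequence(seq: str) -> str:
    """Remove every non-standard residue, preserving order and uppercasing.

    Raises :class:`SequenceError` if nothing remains — such a sequence cannot
    be featurized.
    """
    cleaned = "".join(c for c in seq.upper() if c in _STANDARD_SET)
    if not cleaned:
        raise SequenceError("sequence contains no standard amino acids after cleaning")
    return cleaned


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a (multi-)FASTA file into :class:`ProteinRecord` objects.

    The id is the header token up to the first whitespace; sequences are
    uppercased but NOT cleaned (cleaning happens at featurization so the raw
    record round-trips).  Duplicate ids and sequence text before the first
    header are rejected with the offending line number.
    """
    path = Path(path)
    # pre-scan for data before any header so the error can name the line
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise SequenceError(
                    f"{path}:{lineno}: sequence data before the first FASTA header"
                )
            break

    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise SequenceError(f"{path}: FASTA entry with an empty header")
        if not str(rec.seq):
            raise SequenceError(f"{path}: FASTA entry {rec.id!r} has an empty sequence")
        if rec.id in seen:
            raise SequenceError(f"{path}: duplicate protein id {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as wrapped FASTA (inverse of :func:`read_fasta`)."""
    seq_records = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def _parse_label(token: str) -> bool:
    t = token.strip().lower()
    if t in POSITIVE_TOKENS:
        return True
    if t in NEGATIVE_TOKENS:
        return False
    raise SequenceError(f"unknown pair label token {token!r} (expected 1/0 or +/-)")


def read_pairs(path: str | Path, proteins: Iterable[ProteinRecord]) -> LabeledPairSet:
    """Read a labeled pair TSV and resolve every id against ``proteins``.

    A header line is auto-detected by a non-label token ("label") in the third
    column.  Duplicate identical lines are retained with a warning — repeated
    observations of a pair are legitimate training weight.
    """
    path = Path(path)
    known = {p.id for p in proteins}
    positives: list[PairExample] = []
    negatives: list[PairExample] = []
    missing: set[str] = set()
    seen_lines: set[tuple[str, str, str]] = set()

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped.strip():
                continue
            fields = stripped.split("\t")
            if len(fields) < 3:
                raise SequenceError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, got {len(fields)}"
                )
            id_a, id_b, token = fields[0].strip(), fields[1].strip(), fields[2].strip()
            if lineno == 1 and token.lower() == "label":
                continue  # header row
            label = _parse_label(token)
            for pid in (id_a, id_b):
                if pid not in known:
                    missing.add(pid)
            key = (id_a, id_b, token)
            if key in seen_lines:
                logger.warning("%s:%d: duplicate pair line %s retained", path, lineno, key)
            seen_lines.add(key)
            (positives if label else negatives).append(
                PairExample(id_a=id_a, id_b=id_b, label=label)
            )

    if missing:
        raise SequenceError(
            f"{path}: {len(missing)} pair id(s) not present in the protein set: "
            + ", ".join(sorted(missing)[:10])
        )
    return LabeledPairSet(positives=positives, negatives=negatives)


def write_pairs(pairs: LabeledPairSet, path: str | Path) -> None:
    """Write a LabeledPairSet back to the pair-TSV format (with header)."""
    with open(path, "w") as fh:
        fh.write("idA\tidB\tlabel\n")
        for p in pairs.positives:
            fh.write(f"{p.id_a}\t{p.id_b}\t1\n")
        for p in pairs.negatives:
            fh.write(f"{p.id_a}\t{p.id_b}\t0\n")
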