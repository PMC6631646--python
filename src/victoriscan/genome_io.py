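"""Sequence and annotation I/O, and the coordinate contract.

Everything in this package speaks 1-based, inclusive nucleotide coordinates
on the plus strand, the convention used for genome map positions throughout
the virology literature (and in every position this package reports).
Conversion to Python's half-open slices happens only inside function bodies,
never at an interface.

The canonical alphabet is RNA ({A,C,G,U}); FASTA input written in DNA style
(T) is normalized to U on read, and the original style is remembered so that
round-tripped FASTA looks like the input.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = frozenset("ACGU")

#: Deterministic single-base resolution of IUPAC ambiguity codes, used only
#: when reading with on_ambiguous="mask" (first base of the code's set).
IUPAC_MASK = {
    "N": "A", "R": "A", "Y": "C", "S": "C", "W": "A", "K": "G",
    "M": "A", "B": "C", "D": "A", "H": "A", "V": "A",
}


class GenomeIOError(ValueError):
    """Raised for malformed sequence/annotation input or output requests."""


@dataclass(frozen=True, order=True)
class Interval:
    """A 1-based, inclusive span of nucleotides (or residues)."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise GenomeIOError(
                f"invalid interval [{self.start}, {self.end}]: "
                "need 1 <= start <= end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, other: "Interval") -> bool:
        return self.start <= other.start and other.end <= self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.start <= other.end and other.start <= self.end

    def intersection(self, other: "Interval") -> "Interval | None":
        lo, hi = max(self.start, other.start), min(self.end, other.end)
        return Interval(lo, hi) if lo <= hi else None

    def as_list(self) -> list[int]:
        return [self.start, self.end]


@dataclass(frozen=True)
class GenomeRecord:
    """A named plus-strand sequence over {A,C,G,U}.

    ``dna_style`` records whether the input used T; FASTA output converts
    back so round trips preserve the input's alphabet style.
    """

    id: str
    sequence: str
    dna_style: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise GenomeIOError("record id must be non-empty")
        if len(self.sequence) < 1:
            raise GenomeIOError(f"record {self.id!r}: empty sequence")
        bad = next(
            (i for i, c in enumerate(self.sequence) if c not in RNA_ALPHABET),
            None,
        )
        if bad is not None:
            raise GenomeIOError(
                f"record {self.id!r}: non-nucleotide character "
                f"{self.sequence[bad]!r} at position {bad + 1}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def subseq(self, interval: Interval) -> str:
        """Sequence at a 1-based inclusive interval."""
        if interval.end > self.length:
            raise GenomeIOError(
                f"interval [{interval.start}, {interval.end}] exceeds "
                f"genome length {self.length}"
            )
        return self.sequence[interval.start - 1 : interval.end]


def normalize_sequence(
    raw: str, *, record_id: str = "?", on_ambiguous: str = "reject"
) -> tuple[str, bool]:
    """Uppercase, T->U. Returns (sequence, dna_style).

    Non-{A,C,G,U} IUPAC codes are rejected (default) with the 1-based
    offending position, or masked to a deterministic concrete base.
    """
    up = raw.upper().replace("\n", "").replace(" ", "")
    dna_style = "T" in up and "U" not in up
    seq = up.replace("T", "U")
    if on_ambiguous not in ("reject", "mask"):
        raise GenomeIOError(f"unknown on_ambiguous mode {on_ambiguous!r}")
    chars = []
    for i, c in enumerate(seq):
        if c in RNA_ALPHABET:
            chars.append(c)
        elif on_ambiguous == "mask" and c in IUPAC_MASK:
            chars.append(IUPAC_MASK[c])
        else:
            raise GenomeIOError(
                f"record {record_id!r}: non-nucleotide character {c!r} "
                f"at position {i + 1}"
            )
    return "".join(chars), dna_style


def read_fasta(path: str | Path, *, on_ambiguous: str = "reject") -> list[GenomeRecord]:
    """Read a FASTA file into GenomeRecords (ids = header up to whitespace)."""
    path = Path(path)
    records: list[GenomeRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq, dna_style = normalize_sequence(
            str(rec.seq), record_id=rec.id, on_ambiguous=on_ambiguous
        )
        if not seq:
            raise GenomeIOError(f"record {rec.id!r}: empty sequence")
        records.append(GenomeRecord(id=rec.id, sequence=seq, dna_style=dna_style))
    if not records:
        raise GenomeIOError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, *, width: int = 70) -> None:
    seqrecords = []
    for r in records:
        seq = r.sequence.replace("U", "T") if r.dna_style else r.sequence
        seqrecords.append(SeqRecord(Seq(seq), id=r.id, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecords)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Gff3Feature:
    """One GFF3 row (plus strand; 1-based inclusive, as GFF3 itself)."""

    type: str
    interval: Interval
    attributes: tuple[tuple[str, str], ...] = ()
    score: str = "."
    strand: str = "+"
    phase: str = "."

    def attr_string(self) -> str:
        if not self.attributes:
            return "."
        return ";".join(f"{k}={_gff3_escape(v)}" for k, v in self.attributes)


def _gff3_escape(value: str) -> str:
    return (
        value.replace("%", "%25")
        .replace(";", "%3B")
        .replace("=", "%3D")
        .replace(",", "%2C")
        .replace("\t", "%09")
        .replace("\n", "%0A")
    )


def features_from_layout(layout, signals=None) -> list[Gff3Feature]:
    """Flatten a BicistronicLayout (+ optional RecodingSignalSet) to GFF3 rows.

    Uses only attribute access, so it accepts any layout/signal objects with
    the documented fields.
    """
    feats: list[Gff3Feature] = []
    if layout.utr5 is not None:
        feats.append(Gff3Feature("five_prime_UTR", layout.utr5, (("ID", "utr5"),)))
    feats.append(
        Gff3Feature(
            "CDS", layout.orf1.interval,
            (("ID", "orf1"), ("Name", "ORF1_CP"), ("frame_label", str(layout.orf1.frame))),
            phase="0",
        )
    )
    if layout.bridge is not None:
        feats.append(Gff3Feature("region", layout.bridge, (("ID", "bridge"),)))
    if getattr(layout, "overlap", None) is not None:
        feats.append(Gff3Feature("region", layout.overlap, (("ID", "orf_overlap"),)))
    feats.append(
        Gff3Feature(
            "CDS", layout.orf2.interval,
            (("ID", "orf2"), ("Name", "ORF2_RDRP"), ("frame_label", str(layout.orf2.frame))),
            phase="0",
        )
    )
    if layout.utr3 is not None:
        feats.append(Gff3Feature("three_prime_UTR", layout.utr3, (("ID", "utr3"),)))
    if signals is not None:
        for i, hit in enumerate(getattr(signals, "slippery", ()) or ()):
            feats.append(
                Gff3Feature(
                    "sequence_feature", hit.interval,
                    (("ID", f"slippery_{i}"), ("Name", "slippery_site"),
                     ("heptamer", hit.heptamer), ("mismatches", str(hit.mismatches))),
                )
            )
        for i, hit in enumerate(getattr(signals, "facilitators", ()) or ()):
            feats.append(
                Gff3Feature(
                    "sequence_feature", hit.interval,
                    (("ID", f"facilitator_{i}"), ("Name", hit.motif)),
                )
            )
        for i, hit in enumerate(getattr(signals, "utr_motifs", ()) or ()):
            feats.append(
                Gff3Feature(
                    "sequence_feature", hit.interval,
                    (("ID", f"utr_motif_{i}"), ("Name", hit.motif_id),
                     ("distance_to_orf1_start", str(hit.distance_to_orf1_start))),
                )
            )
    return feats


def write_gff3(record: GenomeRecord, features: Sequence[Gff3Feature], path: str | Path) -> None:
    """Write GFF3 (version 3 header, 1-based inclusive coordinates, + strand)."""
    for f in features:
        if f.interval.end > record.length:
            raise GenomeIOError(
                f"feature {f.type} [{f.interval.start},{f.interval.end}] "
                f"outside genome {record.id!r} (length {record.length})"
            )
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {record.id} 1 {record.length}\n")
        for f in features:
            fh.write(
                "\t".join(
                    [
                        record.id,
                        "victoriscan",
                        f.type,
                        str(f.interval.start),
                        str(f.interval.end),
                        f.score,
                        f.strand,
                        f.phase,
                        f.attr_string(),
                    ]
                )
                + "\n"
            )
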