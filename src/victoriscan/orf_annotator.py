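"""Plus-strand ORF finding and bicistronic layout classification.

Victorivirus-like genomes carry two long ORFs on the plus strand: ORF1
(capsid protein, CP) followed by ORF2 (RNA-dependent RNA polymerase, RdRp),
separated by an inter-ORF "bridge" (or, in other Totiviridae, overlapping).
This module finds maximal AUG-to-stop ORFs and decomposes a genome into
5'UTR / ORF1 / bridge / ORF2 / 3'UTR.

Conventions:
  * ORF intervals INCLUDE the stop codon, so aa_length == nt/3 - 1.
  * "Maximal" ORF: from the 5'-most in-frame AUG after the previous in-frame
    stop, to the next in-frame stop.
  * Frame label of a position p is ((p - 1) mod 3) + 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import FrozenSet, Iterable, Sequence

from .genome_io import GenomeRecord, Interval

STOP_CODONS = frozenset({"UAA", "UAG", "UGA"})
DEFAULT_START_CODONS = frozenset({"AUG"})

ROLE_ORF1 = "ORF1_CP"
ROLE_ORF2 = "ORF2_RDRP"
ROLE_OTHER = "other"


class LayoutError(ValueError):
    """Raised when a genome cannot be decomposed into a bicistronic layout."""


def frame_of(position: int) -> int:
    """Reading-frame label (1/2/3) of a 1-based plus-strand position."""
    if position < 1:
        raise ValueError(f"position must be >= 1, got {position}")
    return (position - 1) % 3 + 1


@dataclass(frozen=True)
class Orf:
    """An open reading frame; interval includes the stop codon."""

    interval: Interval
    frame: int
    aa_length: int
    role: str = ROLE_OTHER

    def __post_init__(self) -> None:
        if self.interval.length % 3 != 0:
            raise ValueError("ORF interval length must be a multiple of 3")
        if self.aa_length != self.interval.length // 3 - 1:
            raise ValueError("aa_length inconsistent with interval length")
        if self.frame != frame_of(self.interval.start):
            raise ValueError("frame inconsistent with start position")

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def coding_interval(self) -> Interval:
        """The interval translated into protein (stop codon excluded)."""
        return Interval(self.interval.start, self.interval.end - 3)

    @property
    def stop_codon(self) -> Interval:
        return Interval(self.interval.end - 2, self.interval.end)


@dataclass(frozen=True)
class BicistronicLayout:
    """5'UTR / ORF1 / bridge (or overlap) / ORF2 / 3'UTR decomposition.

    Exactly one of ``bridge`` / ``overlap`` is set when the ORFs are
    separated / overlapping; both are None when they abut exactly.
    ``relative_frame_offset`` is ORF2's codon-phase offset relative to ORF1,
    reported in {0, +1, -1} with +1 == -2 (mod 3).
    """

    utr5: Interval | None
    orf1: Orf
    bridge: Interval | None
    overlap: Interval | None
    orf2: Orf
    utr3: Interval | None
    relative_frame_offset: int
    genome_length: int

    def region_lengths(self) -> dict[str, int]:
        return {
            "utr5": self.utr5.length if self.utr5 else 0,
            "orf1": self.orf1.interval.length,
            "bridge": self.bridge.length if self.bridge else 0,
            "orf2": self.orf2.interval.length,
            "utr3": self.utr3.length if self.utr3 else 0,
        }


def find_orfs(
    record: GenomeRecord,
    min_aa: int = 100,
    start_codons: Iterable[str] = DEFAULT_START_CODONS,
) -> list[Orf]:
    """All maximal start-to-stop ORFs on the three plus-strand frames.

    Returns ORFs with ``aa_length >= min_aa`` sorted by start position.
    An ORF is opened at the 5'-most in-frame start codon after the previous
    in-frame stop and closed at the next in-frame stop; ORFs without a stop
    before the genome end are not reported (no run-off ORFs).
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    starts = frozenset(s.upper().replace("T", "U") for s in start_codons)
    seq = record.sequence
    n = record.length
    orfs: list[Orf] = []
    for offset in range(3):
        pending_start: int | None = None  # 1-based position of the opening AUG
        for i in range(offset, n - 2, 3):
            codon = seq[i : i + 3]
            if codon in STOP_CODONS:
                if pending_start is not None:
                    interval = Interval(pending_start, i + 3)
                    aa = interval.length // 3 - 1
                    if aa >= min_aa:
                        orfs.append(
                            Orf(interval, frame_of(pending_start), aa, ROLE_OTHER)
                        )
                    pending_start = None
            elif pending_start is None and codon in starts:
                pending_start = i + 1
    orfs.sort(key=lambda o: (o.start, o.end))
    return orfs


def _nested(a: Orf, b: Orf) -> bool:
    return b.interval.contains(a.interval) or a.interval.contains(b.interval)


def classify_layout(record: GenomeRecord, orfs: Sequence[Orf]) -> BicistronicLayout:
    """Decompose a genome into the bicistronic CP/RdRp layout.

    ORF1 is the ORF with the 5'-most start among the two longest non-nested
    ORFs; ORF2 is the longest ORF starting after ORF1's start.  Ties break
    deterministically: earlier start wins, then longer.
    """
    if len(orfs) < 2:
        raise LayoutError("not bicistronic: fewer than two qualifying ORFs")
    by_size = sorted(orfs, key=lambda o: (-o.aa_length, o.start, -o.end))
    primary = by_size[0]
    secondary = next((o for o in by_size[1:] if not _nested(o, primary)), None)
    if secondary is None:
        raise LayoutError("not bicistronic: all other ORFs nested in the longest")
    orf1_raw = primary if primary.start <= secondary.start else secondary
    candidates = [o for o in orfs if o.start > orf1_raw.start]
    if not candidates:
        raise LayoutError("not bicistronic: no ORF downstream of ORF1")
    orf2_raw = sorted(candidates, key=lambda o: (-o.aa_length, o.start, -o.end))[0]

    orf1 = replace(orf1_raw, role=ROLE_ORF1)
    orf2 = replace(orf2_raw, role=ROLE_ORF2)

    utr5 = Interval(1, orf1.start - 1) if orf1.start > 1 else None
    utr3 = Interval(orf2.end + 1, record.length) if orf2.end < record.length else None
    if orf2.start > orf1.end + 1:
        bridge: Interval | None = Interval(orf1.end + 1, orf2.start - 1)
        overlap: Interval | None = None
    elif orf2.start == orf1.end + 1:
        bridge = overlap = None
    else:
        bridge = None
        overlap = Interval(orf2.start, min(orf1.end, orf2.end))

    offset = (orf2.start - orf1.start) % 3
    relative = {0: 0, 1: +1, 2: -1}[offset]
    return BicistronicLayout(
        utr5=utr5,
        orf1=orf1,
        bridge=bridge,
        overlap=overlap,
        orf2=orf2,
        utr3=utr3,
        relative_frame_offset=relative,
        genome_length=record.length,
    )


def annotate(
    record: GenomeRecord,
    min_aa: int = 100,
    start_codons: Iterable[str] = DEFAULT_START_CODONS,
) -> BicistronicLayout:
    """find_orfs + classify_layout in one call."""
    return classify_layout(record, find_orfs(record, min_aa, start_codons))
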