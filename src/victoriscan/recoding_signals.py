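"""Recoding-signal scanners: slippery heptamers, stop/restart facilitators,
conserved 5'UTR motifs, and Ala/Gly/Pro-rich protein regions.

Two noncanonical translation mechanisms compete as explanations for RdRp
expression from a bicistronic totivirid genome:

  * -1 programmed ribosomal frameshift, signalled by a slippery heptamer of
    the consensus class X XXY YYZ (positions 1-3 homogeneous, 4-6
    homogeneous, 7 free) plus a downstream structure;
  * coupled termination/reinitiation ("stop/restart"), facilitated by the
    overlapping stop/start tetramers AUGA or UAAUG near the ORF1 stop.

The scanners here report motif occurrences with genome coordinates, Hamming
distances to the consensus class, and codon-phase bookkeeping; they do not
decide the mechanism (see pmf_evidence.adjudicate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product as _iterproduct
from typing import Iterable, Sequence

from .genome_io import GenomeRecord, Interval
from .orf_annotator import BicistronicLayout, frame_of

BASES = "ACGU"
FACILITATOR_MOTIFS = ("AUGA", "UAAUG")
#: conserved victorivirus 5'UTR octamer and its extended 15-mer
DEFAULT_UTR_MOTIFS = ("AGGGUUCC", "AGGGUUCCGUUGAUC")


@dataclass(frozen=True)
class SlipperyHit:
    """A 7-mer at Hamming distance ``mismatches`` from the X XXY YYZ class.

    ``phase_note`` is the heptamer start's codon phase relative to an ORF
    start (0 = first codon position), or None when no anchor was supplied.
    In the canonical alignment the heptamer's last six bases form two
    0-frame codons, i.e. phase 2.
    """

    interval: Interval
    heptamer: str
    mismatches: int
    phase_note: int | None = None


@dataclass(frozen=True)
class FacilitatorHit:
    interval: Interval
    motif: str  # "AUGA" or "UAAUG"
    stop_frame_consistent: bool


@dataclass(frozen=True)
class MotifHit:
    interval: Interval
    motif_id: str
    #: nt between motif end and ORF1 start, exclusive of both
    distance_to_orf1_start: int


@dataclass(frozen=True)
class CompositionRegion:
    """A maximal protein region whose {A,G,P} content reaches threshold."""

    interval: Interval  # 1-based aa positions
    fraction: float


@dataclass(frozen=True)
class RecodingSignalSet:
    """Bundle of all signal hits for one genome, as consumed downstream."""

    slippery: tuple[SlipperyHit, ...] = ()
    facilitators: tuple[FacilitatorHit, ...] = ()
    utr_motifs: tuple[MotifHit, ...] = ()
    agp_regions: tuple[CompositionRegion, ...] = ()


def slippery_mismatches(
    heptamer: str,
    x_bases: Iterable[str] | None = None,
    y_bases: Iterable[str] | None = None,
    z_bases: Iterable[str] | None = None,
) -> int:
    """Minimum Hamming distance from a 7-mer to the X XXY YYZ class.

    By default X, Y, Z range over all four bases (the consensus states no
    base restrictions); pass subsets to impose the classical stricter
    pattern (e.g. z_bases="ACU").
    """
    if len(heptamer) != 7:
        raise ValueError("slippery candidates are exactly 7 nt")
    xs = tuple(x_bases) if x_bases else tuple(BASES)
    ys = tuple(y_bases) if y_bases else tuple(BASES)
    zs = tuple(z_bases) if z_bases else tuple(BASES)
    best = 7
    for x, y, z in _iterproduct(xs, ys, zs):
        d = sum(c != x for c in heptamer[0:3])
        d += sum(c != y for c in heptamer[3:6])
        d += heptamer[6] != z
        best = min(best, d)
    return best


def scan_slippery(
    record: GenomeRecord,
    window: Interval,
    max_mismatch: int = 1,
    *,
    orf_frame_anchor: int | None = None,
    x_bases: Iterable[str] | None = None,
    y_bases: Iterable[str] | None = None,
    z_bases: Iterable[str] | None = None,
) -> list[SlipperyHit]:
    """All 7-mers in ``window`` within ``max_mismatch`` of the consensus class.

    Overlapping hits are all reported, sorted by (mismatches, start).
    ``orf_frame_anchor`` (an ORF start position) annotates each hit with its
    codon phase relative to that ORF.
    """
    if window.end > record.length:
        raise ValueError("window outside genome")
    if window.length < 7:
        raise ValueError(f"window of {window.length} nt is shorter than 7 nt")
    if max_mismatch not in (0, 1, 2):
        raise ValueError("max_mismatch must be 0, 1 or 2")
    hits = []
    for start in range(window.start, window.end - 5):
        hept = record.subseq(Interval(start, start + 6))
        mm = slippery_mismatches(hept, x_bases, y_bases, z_bases)
        if mm <= max_mismatch:
            phase = (
                (start - orf_frame_anchor) % 3
                if orf_frame_anchor is not None
                else None
            )
            hits.append(SlipperyHit(Interval(start, start + 6), hept, mm, phase))
    hits.sort(key=lambda h: (h.mismatches, h.interval.start))
    return hits


def junction_window(
    layout: BicistronicLayout, upstream: int = 40, downstream: int = 10
) -> Interval:
    """Default junction scan span: the ORF1 stop codon plus flanks.

    40 nt upstream through 10 nt downstream of the stop covers the span of
    the experimentally mapped ~38-nt stop/restart element of the prototype
    victorivirus, i.e. the biologically relevant neighbourhood.
    """
    stop = layout.orf1.stop_codon
    return Interval(
        max(1, stop.start - upstream),
        min(layout.genome_length, stop.end + downstream),
    )


def scan_facilitators(
    record: GenomeRecord, orf1_stop: Interval, window_nt: int = 40
) -> list[FacilitatorHit]:
    """AUGA / UAAUG occurrences within +/- window_nt of the ORF1 stop codon.

    Each hit is flagged ``stop_frame_consistent`` when its embedded stop
    triplet (UGA of AUGA; UAA of UAAUG) lies in ORF1's codon phase.
    """
    if window_nt < 5:
        raise ValueError("window_nt must be >= 5")
    lo = max(1, orf1_stop.start - window_nt)
    hi = min(record.length, orf1_stop.end + window_nt)
    region = record.subseq(Interval(lo, hi))
    hits = []
    for motif in FACILITATOR_MOTIFS:
        stop_offset = 1 if motif == "AUGA" else 0  # index of stop triplet
        pos = region.find(motif)
        while pos != -1:
            start = lo + pos
            stop_start = start + stop_offset
            consistent = (stop_start - orf1_stop.start) % 3 == 0
            hits.append(
                FacilitatorHit(
                    Interval(start, start + len(motif) - 1), motif, consistent
                )
            )
            pos = region.find(motif, pos + 1)
    hits.sort(key=lambda h: (h.interval.start, h.motif))
    return hits


def scan_utr_motifs(
    record: GenomeRecord,
    layout: BicistronicLayout,
    motif_set: Sequence[str] = DEFAULT_UTR_MOTIFS,
) -> list[MotifHit]:
    """Exact occurrences of conserved motifs inside the 5'UTR.

    Both the octamer and its extended 15-mer are reported when present (the
    longer hit contains the shorter one).  ``distance_to_orf1_start`` counts
    the nt strictly between the motif end and the ORF1 start.
    """
    if not motif_set:
        raise ValueError("motif_set must be non-empty")
    if layout.utr5 is None:
        return []
    utr = record.subseq(layout.utr5)
    hits = []
    for motif in motif_set:
        m = motif.upper().replace("T", "U")
        pos = utr.find(m)
        while pos != -1:
            start = layout.utr5.start + pos
            end = start + len(m) - 1
            hits.append(MotifHit(Interval(start, end), m, layout.orf1.start - end - 1))
            pos = utr.find(m, pos + 1)
    hits.sort(key=lambda h: (h.interval.start, h.interval.end))
    return hits


def find_agp_rich(
    protein: str, window_aa: int = 20, threshold: float = 0.5
) -> list[CompositionRegion]:
    """Maximal regions where sliding windows are Ala/Gly/Pro-rich.

    Every window of ``window_aa`` residues with an {A,G,P} fraction >=
    threshold is marked; overlapping qualifying windows are merged and the
    fraction is recomputed over each merged region.
    """
    if window_aa < 5:
        raise ValueError("window_aa must be >= 5")
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    n = len(protein)
    if n < window_aa:
        warnings.warn(
            f"protein of {n} aa shorter than window ({window_aa} aa); "
            "no composition scan performed"
        )
        return []
    agp = [c in "AGP" for c in protein]
    count = sum(agp[:window_aa])
    qualifying: list[tuple[int, int]] = []  # 1-based inclusive windows
    for start0 in range(0, n - window_aa + 1):
        if start0 > 0:
            count += agp[start0 + window_aa - 1] - agp[start0 - 1]
        if count / window_aa >= threshold:
            qualifying.append((start0 + 1, start0 + window_aa))
    regions: list[CompositionRegion] = []
    for s, e in qualifying:
        if regions and s <= regions[-1].interval.end + 1:
            merged = Interval(regions[-1].interval.start, max(regions[-1].interval.end, e))
            regions[-1] = CompositionRegion(merged, 0.0)
        else:
            regions.append(CompositionRegion(Interval(s, e), 0.0))
    out = []
    for r in regions:
        frac = sum(agp[r.interval.start - 1 : r.interval.end]) / r.interval.length
        out.append(CompositionRegion(r.interval, frac))
    return out


def scan_all(
    record: GenomeRecord,
    layout: BicistronicLayout,
    *,
    max_mismatch: int = 1,
    junction_upstream: int = 40,
    junction_downstream: int = 10,
    facilitator_window: int = 40,
    utr_motif_set: Sequence[str] = DEFAULT_UTR_MOTIFS,
    cp_protein: str | None = None,
    agp_window: int = 20,
    agp_threshold: float = 0.5,
) -> RecodingSignalSet:
    """Run every scanner with its junction/UTR defaults and bundle the hits."""
    window = junction_window(layout, junction_upstream, junction_downstream)
    slippery = scan_slippery(
        record, window, max_mismatch, orf_frame_anchor=layout.orf1.start
    )
    facilitators = scan_facilitators(
        record, layout.orf1.stop_codon, facilitator_window
    )
    motifs = scan_utr_motifs(record, layout, utr_motif_set)
    agp: tuple[CompositionRegion, ...] = ()
    if cp_protein is not None and len(cp_protein) >= agp_window:
        agp = tuple(find_agp_rich(cp_protein, agp_window, agp_threshold))
    return RecodingSignalSet(
        slippery=tuple(slippery),
        facilitators=tuple(facilitators),
        utr_motifs=tuple(motifs),
        agp_regions=agp,
    )
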