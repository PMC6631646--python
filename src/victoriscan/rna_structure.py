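"""Heuristic stem-loop and H-type pseudoknot detection.

This is an explicitly approximate structure module: perfect (bulge-free)
helices are enumerated exhaustively within a window and scored with a toy
additive scheme (GC/CG = 3, AU/UA = 2, GU/UG = 1; no loop penalty by
default).  The scheme is deterministic and oracle-checkable; it supports
presence/absence and topology calls (hairpin vs. crossing stems), not free
energies.  An H-type pseudoknot is a pair of crossing stems: the second
stem's 5' arm sits inside the first stem's loop and its 3' arm lies
downstream of the first stem's 3' arm.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_io import GenomeRecord, Interval

PAIR_SCORE = {
    ("G", "C"): 3.0, ("C", "G"): 3.0,
    ("A", "U"): 2.0, ("U", "A"): 2.0,
    ("G", "U"): 1.0, ("U", "G"): 1.0,
}


def can_pair(a: str, b: str) -> bool:
    return (a, b) in PAIR_SCORE


@dataclass(frozen=True)
class Stem:
    """A perfect helix: arm5 position i+t pairs with arm3 position end-t."""

    arm5: Interval
    arm3: Interval
    pairs: int
    score: float

    def __post_init__(self) -> None:
        if self.arm5.length != self.pairs or self.arm3.length != self.pairs:
            raise ValueError("arm lengths must equal the number of pairs")
        if self.arm5.end >= self.arm3.start:
            raise ValueError("arm5 must lie strictly 5' of arm3")

    @property
    def loop(self) -> Interval | None:
        """The enclosed interval between the arms (None when arms abut)."""
        if self.arm3.start - self.arm5.end < 2:
            return None
        return Interval(self.arm5.end + 1, self.arm3.start - 1)

    @property
    def loop_length(self) -> int:
        return self.arm3.start - self.arm5.end - 1

    def positions(self) -> set[int]:
        return set(range(self.arm5.start, self.arm5.end + 1)) | set(
            range(self.arm3.start, self.arm3.end + 1)
        )


@dataclass(frozen=True)
class StemLoop:
    stem: Stem
    loop: Interval


@dataclass(frozen=True)
class Pseudoknot:
    stem1: Stem
    stem2: Stem
    span: Interval
    score: float

    def positions(self) -> set[int]:
        return self.stem1.positions() | self.stem2.positions()


def _stem_score(seq: str, i0: int, j0: int, k: int) -> float:
    """Score of the helix whose outer pair is (i0, j0), 0-based, k pairs."""
    return sum(PAIR_SCORE[(seq[i0 + t], seq[j0 - t])] for t in range(k))


def enumerate_stems(
    record: GenomeRecord,
    window: Interval,
    min_pairs: int = 3,
    max_loop: int | None = None,
) -> list[Stem]:
    """All maximal perfect helices inside ``window``.

    Maximal: the outer pair cannot be extended outward within the window,
    and the helix runs inward to the first non-pairing position (or until
    the arms would meet).  ``max_loop`` caps the enclosed loop length (None
    = unrestricted, the right setting when stems feed the pseudoknot
    search).
    """
    if window.end > record.length:
        raise ValueError("window outside genome")
    seq = record.sequence
    lo, hi = window.start - 1, window.end - 1  # 0-based bounds
    stems: list[Stem] = []
    for i in range(lo, hi):
        for j in range(hi, i, -1):
            if not can_pair(seq[i], seq[j]):
                continue
            # outward-maximal only
            if i - 1 >= lo and j + 1 <= hi and can_pair(seq[i - 1], seq[j + 1]):
                continue
            k = 0
            while (
                i + k < j - k  # arms stay disjoint (loop >= 0)
                and can_pair(seq[i + k], seq[j - k])
            ):
                k += 1
            if k < min_pairs:
                continue
            loop_len = (j - k) - (i + k) + 1
            if max_loop is not None and loop_len > max_loop:
                continue
            stems.append(
                Stem(
                    arm5=Interval(i + 1, i + k),
                    arm3=Interval(j - k + 2, j + 1),
                    pairs=k,
                    score=_stem_score(seq, i, j, k),
                )
            )
    # drop shifted registers: a stem both of whose arms lie inside a longer
    # stem's arms is a diagonal shift of it and adds nothing
    kept = [
        s
        for s in stems
        if not any(
            t.pairs > s.pairs
            and t.arm5.contains(s.arm5)
            and t.arm3.contains(s.arm3)
            for t in stems
        )
    ]
    kept.sort(key=lambda s: (-s.score, s.arm5.start, s.arm3.start))
    return kept


def find_stem_loops(
    record: GenomeRecord,
    window: Interval,
    min_pairs: int = 3,
    min_loop: int = 3,
    max_loop: int = 12,
) -> list[StemLoop]:
    """Hairpins: stems with a short enclosed loop free of stronger stems.

    A stem is kept only if its loop contains no arm of a strictly stronger
    overlapping stem (that stronger stem would preempt the hairpin).
    Results are sorted by score, ties by 5' position.
    """
    stems = enumerate_stems(record, window, min_pairs, max_loop=max_loop)
    candidates = [s for s in stems if s.loop is not None and s.loop_length >= min_loop]
    all_stems = enumerate_stems(record, window, min_pairs, max_loop=None)
    out = []
    for s in candidates:
        loop = s.loop
        preempted = any(
            other.score > s.score
            and (loop.contains(other.arm5) or loop.contains(other.arm3))
            for other in all_stems
        )
        if not preempted:
            out.append(StemLoop(stem=s, loop=loop))
    out.sort(key=lambda sl: (-sl.stem.score, sl.stem.arm5.start))
    return out


def is_h_type(s1: Stem, s2: Stem) -> bool:
    """Crossing condition: s2.arm5 inside s1's loop, s2.arm3 3' of s1.arm3."""
    loop = s1.loop
    return (
        loop is not None
        and loop.contains(s2.arm5)
        and s2.arm3.start > s1.arm3.end
    )


def pseudoknot_candidates(
    record: GenomeRecord,
    window: Interval,
    min_pairs: int = 3,
    max_span: int | None = None,
    min_score: float = 0.0,
) -> list[Pseudoknot]:
    """Every stem pair satisfying the H-type crossing condition.

    Sorted by (-score, span start).  Arm disjointness (no position paired
    twice) follows from the topology: arm5 of stem2 sits strictly inside
    stem1's loop and arm3 of stem2 strictly downstream of stem1.
    """
    stems = enumerate_stems(record, window, min_pairs, max_loop=None)
    pks: list[Pseudoknot] = []
    for s1 in stems:
        for s2 in stems:
            if s1 is s2 or not is_h_type(s1, s2):
                continue
            span = Interval(s1.arm5.start, s2.arm3.end)
            if max_span is not None and span.length > max_span:
                continue
            score = s1.score + s2.score
            if score < min_score:
                continue
            pks.append(Pseudoknot(s1, s2, span, score))
    pks.sort(key=lambda p: (-p.score, p.span.start, p.span.end))
    return pks


def find_pseudoknots(
    record: GenomeRecord,
    window: Interval,
    min_pairs: int = 3,
    max_span: int | None = None,
    min_score: float = 0.0,
) -> list[Pseudoknot]:
    """Greedy span-disjoint selection from the candidate list, by score.

    The full candidate list is available via :func:`pseudoknot_candidates`;
    this primary report keeps the best-scoring pseudoknot, then the best
    whose span does not overlap an already selected one, and so on —
    mirroring how tandem junction pseudoknots are reported.
    """
    selected: list[Pseudoknot] = []
    for pk in pseudoknot_candidates(record, window, min_pairs, max_span, min_score):
        if all(not pk.span.overlaps(s.span) for s in selected):
            selected.append(pk)
    selected.sort(key=lambda p: p.span.start)
    return selected


def dot_bracket(
    window: Interval, structure: StemLoop | Pseudoknot
) -> str:
    """Serialize a structure over ``window`` as dot-bracket notation.

    Round brackets mark stem 1, square brackets stem 2 of a pseudoknot
    (e.g. ``(((..[[[..)))..]]]``).
    """
    chars = ["."] * window.length
    def mark(stem: Stem, open_c: str, close_c: str) -> None:
        for p in range(stem.arm5.start, stem.arm5.end + 1):
            chars[p - window.start] = open_c
        for p in range(stem.arm3.start, stem.arm3.end + 1):
            chars[p - window.start] = close_c

    if isinstance(structure, StemLoop):
        mark(structure.stem, "(", ")")
    else:
        mark(structure.stem1, "(", ")")
        mark(structure.stem2, "[", "]")
    return "".join(chars)
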