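"""Translation, protein masses, and candidate translation-product models.

The translation-strategy question for a bicistronic totivirid genome boils
down to which polypeptides the plus-strand mRNA can yield:

  * two separate products (CP from ORF1, RdRp from ORF2) via coupled
    termination/reinitiation — the victorivirus rule;
  * a CP-RdRp fusion via a -1 ribosomal frameshift at a slippery site near
    the ORF1 stop — the totivirus rule;
  * an N-terminally extended RdRp initiated at a noncanonical start in the
    inter-ORF bridge, in ORF2's frame.

Each candidate is modelled as a ``ProductModel`` with an explicit genomic
path (interval + frame segments), residue count, and molecular mass.
Masses are average isotopic by default because they are compared with
SDS-PAGE band sizes; monoisotopic tables are available for MS work.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from Bio.Seq import Seq

from .genome_io import GenomeRecord, Interval
from .orf_annotator import STOP_CODONS, BicistronicLayout, frame_of
from .recoding_signals import RecodingSignalSet, SlipperyHit

STRATEGY_SEPARATE = "separate_stop_restart"
STRATEGY_FUSION_SLIP = "fusion_minus1_at_slip"
STRATEGY_FUSION_READTHROUGH = "fusion_readthrough"
STRATEGY_BRIDGE_EXTENDED = "bridge_extended_orf2"

#: Average isotopic residue masses (Da), Expasy-style, plus water.
AVERAGE_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594,
    "N": 114.1038, "D": 115.0886, "Q": 128.1307, "K": 128.1741,
    "E": 129.1155, "M": 131.1926, "H": 137.1411, "F": 147.1766,
    "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_AVERAGE = 18.0153

MONO_RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
WATER_MONO = 18.010565


class TranslationError(ValueError):
    """Raised for out-of-frame intervals or unexpected internal stops."""


def translate_str(rna: str) -> str:
    """Standard-code translation of an in-frame RNA string; stops as '*'."""
    if len(rna) % 3 != 0:
        raise TranslationError(f"sequence length {len(rna)} not a multiple of 3")
    return str(Seq(rna).translate())


def translate(
    record: GenomeRecord,
    interval: Interval,
    frame_check: bool = True,
    *,
    allow_internal_stop: bool = False,
) -> str:
    """Translate a genomic interval; trailing stop dropped.

    An internal stop raises :class:`TranslationError` citing the genomic
    position of the stop codon, unless ``allow_internal_stop`` keeps the
    '*' sentinel residues in the output.
    """
    if frame_check and interval.length % 3 != 0:
        raise TranslationError(
            f"interval [{interval.start},{interval.end}] length "
            f"{interval.length} is not a multiple of 3"
        )
    rna = record.subseq(interval)
    rna = rna[: len(rna) - len(rna) % 3]
    aa = translate_str(rna)
    if aa.endswith("*"):
        aa = aa[:-1]
    if not allow_internal_stop and "*" in aa:
        pos = interval.start + 3 * aa.index("*")
        raise TranslationError(
            f"internal stop codon at genome position {pos} "
            f"(residue {aa.index('*') + 1})"
        )
    return aa


def molecular_mass(protein: str, kind: str = "average") -> float:
    """Protein mass in Da: sum of residue masses plus one water.

    The empty string returns the mass of water.  ``kind`` selects the
    average (default; SDS-PAGE comparisons) or monoisotopic table.
    """
    if kind == "average":
        table, water = AVERAGE_RESIDUE_MASS, WATER_AVERAGE
    elif kind == "monoisotopic":
        table, water = MONO_RESIDUE_MASS, WATER_MONO
    else:
        raise ValueError(f"unknown mass kind {kind!r}")
    total = water
    for c in protein:
        try:
            total += table[c]
        except KeyError:
            raise ValueError(f"unknown residue {c!r}") from None
    return total


@dataclass(frozen=True)
class ProductModel:
    """A candidate translation product with its genomic path.

    ``genomic_path`` is an ordered list of (Interval, frame) segments;
    ``aa_length`` counts residues (stops excluded); ``mass_da`` is the
    protein mass under the chosen table.  ``flags`` records departures from
    the nominal model, e.g. a slip-frame path that terminated at a bridge
    stop codon.
    """

    strategy: str
    name: str
    genomic_path: tuple[tuple[Interval, int], ...]
    aa_length: int
    mass_da: float
    protein: str
    flags: tuple[str, ...] = ()

    def path_covers(self, interval: Interval) -> bool:
        return any(seg.overlaps(interval) for seg, _ in self.genomic_path)


def _stop_agnostic_read(record: GenomeRecord, start: int, stop_scan: bool) -> tuple[str, int]:
    """Read codons from ``start`` to the first stop (or the last full codon).

    Returns (residues, end_position_of_last_codon_read).  With
    ``stop_scan`` the read halts before the first stop codon.
    """
    seq = record.sequence
    residues = []
    pos = start
    while pos + 2 <= record.length:
        codon = seq[pos - 1 : pos + 2]
        if stop_scan and codon in STOP_CODONS:
            break
        residues.append(translate_str(codon))
        pos += 3
    return "".join(residues), pos - 1


def _best_slippery(hits: Sequence[SlipperyHit]) -> SlipperyHit:
    return sorted(hits, key=lambda h: (h.mismatches, -h.interval.start))[0]


def separate_products(
    record: GenomeRecord, layout: BicistronicLayout, mass_kind: str = "average"
) -> list[ProductModel]:
    """The two stop/restart products: CP from ORF1 and RdRp from ORF2."""
    out = []
    for orf, name in ((layout.orf1, "CP"), (layout.orf2, "RdRp")):
        coding = orf.coding_interval
        protein = translate(record, coding)
        out.append(
            ProductModel(
                strategy=STRATEGY_SEPARATE,
                name=name,
                genomic_path=((coding, orf.frame),),
                aa_length=len(protein),
                mass_da=molecular_mass(protein, mass_kind),
                protein=protein,
            )
        )
    return out


def fusion_at_slip(
    record: GenomeRecord,
    layout: BicistronicLayout,
    slip: SlipperyHit,
    shift: int = -1,
    mass_kind: str = "average",
) -> ProductModel:
    """The mechanistic frameshift fusion at a slippery heptamer.

    Join convention, applied uniformly: the ribosome completes the
    heptamer's last ORF1-frame codon, then resumes ``-shift`` nt back
    (shift=-1: one nt).  The shifted read continues to the first stop codon
    in the new frame; if that stop falls before ORF2's start the model is
    flagged ``terminated_in_bridge`` rather than suppressed.
    """
    if shift not in (-1, -2, +1):
        raise ValueError("shift must be -1, -2 or +1")
    orf1 = layout.orf1
    # end of the last ORF1-frame codon covering the heptamer's end
    offset = (slip.interval.end - orf1.start + 1) % 3
    c_end = slip.interval.end + (3 - offset) % 3
    seg1 = Interval(orf1.start, c_end)
    head = translate(record, seg1)
    resume = c_end + 1 + (shift if shift < 0 else shift)
    tail, tail_end = _stop_agnostic_read(record, resume, stop_scan=True)
    flags = []
    new_frame = frame_of(resume)
    if new_frame == layout.orf2.frame:
        flags.append("reaches_orf2_frame")
    stop_pos = tail_end + 1
    if stop_pos < layout.orf2.start:
        flags.append("terminated_in_bridge")
    protein = head + tail
    path: list[tuple[Interval, int]] = [(seg1, orf1.frame)]
    if tail:
        path.append((Interval(resume, tail_end), new_frame))
    return ProductModel(
        strategy=STRATEGY_FUSION_SLIP,
        name=f"CP-RdRp fusion (-1 slip at {slip.interval.start})"
        if shift == -1
        else f"CP-RdRp fusion ({shift:+d} slip at {slip.interval.start})",
        genomic_path=tuple(path),
        aa_length=len(protein),
        mass_da=molecular_mass(protein, mass_kind),
        protein=protein,
        flags=tuple(flags),
    )


def fusion_readthrough(
    record: GenomeRecord, layout: BicistronicLayout, mass_kind: str = "average"
) -> ProductModel:
    """Size estimate for the hypothetical full CP+bridge+RdRp chain.

    This is the SDS-PAGE-style expectation for a fusion product: CP
    residues, then the bridge and ORF2 read in ORF2's frame to the ORF2
    stop.  Stop codons encountered in the bridge are excluded from the
    residue count and flagged; the estimate exists to compare a band mass
    against a genuine two-ORF chain, whatever the precise shift mechanism.
    """
    orf1, orf2 = layout.orf1, layout.orf2
    seg1 = orf1.coding_interval
    head = translate(record, seg1)
    # first ORF2-frame codon start after ORF1's coding region
    j0 = orf1.end - 2
    while (j0 - orf2.start) % 3 != 0:
        j0 += 1
    seg2 = Interval(j0, orf2.end - 3)
    mid = translate(record, seg2, allow_internal_stop=True)
    n_stops = mid.count("*")
    chain = head + mid.replace("*", "")
    flags = (f"path_contains_{n_stops}_stops",) if n_stops else ()
    return ProductModel(
        strategy=STRATEGY_FUSION_READTHROUGH,
        name="CP-RdRp full chain estimate",
        genomic_path=((seg1, orf1.frame), (seg2, orf2.frame)),
        aa_length=len(chain),
        mass_da=molecular_mass(chain, mass_kind),
        protein=chain,
        flags=flags,
    )


def bridge_extended_product(
    record: GenomeRecord,
    layout: BicistronicLayout,
    bridge_start: int,
    mass_kind: str = "average",
) -> ProductModel:
    """RdRp extended N-terminally from a noncanonical start in the bridge.

    ``bridge_start`` must be in ORF2's codon phase.  Stops between the
    start and ORF2 (possible on genomes whose bridge is not open in ORF2's
    frame) are excluded from the chain and flagged.
    """
    orf2 = layout.orf2
    if frame_of(bridge_start) != orf2.frame:
        raise ValueError(
            f"bridge start {bridge_start} is not in ORF2's frame ({orf2.frame})"
        )
    seg = Interval(bridge_start, orf2.end - 3)
    aa = translate(record, seg, allow_internal_stop=True)
    n_stops = aa.count("*")
    chain = aa.replace("*", "")
    flags = (f"path_contains_{n_stops}_stops",) if n_stops else ()
    return ProductModel(
        strategy=STRATEGY_BRIDGE_EXTENDED,
        name=f"bridge-extended RdRp (start {bridge_start})",
        genomic_path=((seg, orf2.frame),),
        aa_length=len(chain),
        mass_da=molecular_mass(chain, mass_kind),
        protein=chain,
        flags=flags,
    )


def model_products(
    record: GenomeRecord,
    layout: BicistronicLayout,
    signals: RecodingSignalSet | Sequence[SlipperyHit] | None = None,
    *,
    shift: int = -1,
    bridge_start: int | None = None,
    include_readthrough: bool = True,
    mass_kind: str = "average",
) -> list[ProductModel]:
    """All candidate products for a layout given the detected signals.

    Always emits the two separate stop/restart products.  A slippery hit
    adds the mechanistic slip fusion (and, by default, the full-chain
    readthrough estimate).  ``bridge_start`` adds a bridge-extended RdRp
    model.
    """
    products = separate_products(record, layout, mass_kind)
    if isinstance(signals, RecodingSignalSet):
        slippery: Sequence[SlipperyHit] = signals.slippery
    else:
        slippery = tuple(signals or ())
    # a slip can only precede termination: the heptamer must end by the
    # last sense codon of ORF1
    slippery = tuple(
        h for h in slippery if h.interval.end <= layout.orf1.end - 3
    )
    if slippery:
        best = _best_slippery(slippery)
        products.append(fusion_at_slip(record, layout, best, shift, mass_kind))
        if include_readthrough:
            products.append(fusion_readthrough(record, layout, mass_kind))
    if bridge_start is not None:
        products.append(
            bridge_extended_product(record, layout, bridge_start, mass_kind)
        )
    return products
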