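"""In-silico protease digestion, frame-indexed peptide mapping, and
translation-strategy adjudication from band evidence.

The workflow mirrors a peptide-mass-fingerprinting experiment on a gel
band: digest candidate proteins with trypsin, map each observed peptide
onto stop-agnostic six-frame translations of the genome, assign each
placement to a genomic region (ORF1 / bridge / ORF2 / spanning / other),
and then decide which translation strategy the combined band-mass and
region evidence supports.

Matching is exact string matching of peptide sequences — PMF experiments
report identified sequences, not spectra — and stop codons translate to a
'*' sentinel that can never match a peptide, which rules out biologically
impossible placements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import Seq

from .genome_io import GenomeRecord, Interval
from .orf_annotator import BicistronicLayout, frame_of
from .protein_products import (
    STRATEGY_BRIDGE_EXTENDED,
    STRATEGY_FUSION_READTHROUGH,
    STRATEGY_FUSION_SLIP,
    STRATEGY_SEPARATE,
    ProductModel,
)

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

REGION_ORF1 = "ORF1"
REGION_BRIDGE = "bridge"
REGION_ORF2 = "ORF2"
REGION_SPANNING = "spanning"
REGION_OTHER = "other"

VERDICT_SEPARATE = "two_separate_products"
VERDICT_FUSION = "fusion_product"
VERDICT_BRIDGE_EXTENDED = "bridge_extended_rdrp"
VERDICT_INCONCLUSIVE = "inconclusive"


@dataclass(frozen=True)
class Peptide:
    sequence: str
    source: str = "observed"  # or "simulated"

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError("peptides must have length >= 1")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise ValueError(f"invalid residue(s) {sorted(bad)} in peptide")


def digest(protein: str, enzyme: str = "trypsin", missed_cleavages: int = 0) -> list[Peptide]:
    """Ordered tryptic peptides: cleave after K or R, not before P.

    With ``missed_cleavages`` = m, every concatenation of up to m+1
    adjacent fragments is emitted, ordered by (start, length).
    """
    if enzyme != "trypsin":
        raise ValueError(f"unsupported enzyme {enzyme!r}")
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    n = len(protein)
    # cleavage after 1-based residue i
    sites = [
        i
        for i in range(1, n)
        if protein[i - 1] in "KR" and protein[i] != "P"
    ]
    bounds = [0] + sites + [n]
    fragments = [
        protein[bounds[k] : bounds[k + 1]] for k in range(len(bounds) - 1)
    ]
    peptides = []
    for k in range(len(fragments)):
        for m in range(missed_cleavages + 1):
            if k + m + 1 > len(fragments):
                break
            peptides.append(
                Peptide("".join(fragments[k : k + m + 1]), source="simulated")
            )
    return peptides


@dataclass(frozen=True)
class FrameIndex:
    """Stop-agnostic frame translations with residue -> codon back-maps.

    Plus-strand frames are keyed 1..3; with ``include_reverse`` frames of
    the reverse complement are keyed -1..-3 (coordinates still reported on
    the plus strand).
    """

    record: GenomeRecord
    frames: dict[int, str]

    def codon_interval(self, frame: int, residue_index: int) -> Interval:
        """Genome interval of the codon for 1-based ``residue_index``."""
        if residue_index < 1 or residue_index > len(self.frames[frame]):
            raise ValueError(f"residue {residue_index} outside frame {frame}")
        if frame > 0:
            start = frame + 3 * (residue_index - 1)
            return Interval(start, start + 2)
        f = -frame
        rc_start = f + 3 * (residue_index - 1)  # 1-based on revcomp
        rc_end = rc_start + 2
        n = self.record.length
        return Interval(n - rc_end + 1, n - rc_start + 1)

    def peptide_interval(self, frame: int, residue_start: int, length: int) -> Interval:
        first = self.codon_interval(frame, residue_start)
        last = self.codon_interval(frame, residue_start + length - 1)
        lo = min(first.start, last.start)
        hi = max(first.end, last.end)
        return Interval(lo, hi)


def build_frame_index(record: GenomeRecord, include_reverse: bool = False) -> FrameIndex:
    """Translate all plus-strand (and optionally reverse) frames."""
    if record.length < 3:
        raise ValueError("genome too short to translate")
    frames: dict[int, str] = {}
    seq = record.sequence
    for f in (1, 2, 3):
        sub = seq[f - 1 :]
        sub = sub[: len(sub) - len(sub) % 3]
        frames[f] = str(Seq(sub).translate()) if sub else ""
    if include_reverse:
        rc = str(Seq(seq).reverse_complement_rna())
        for f in (1, 2, 3):
            sub = rc[f - 1 :]
            sub = sub[: len(sub) - len(sub) % 3]
            frames[-f] = str(Seq(sub).translate()) if sub else ""
    return FrameIndex(record=record, frames=frames)


@dataclass(frozen=True)
class PeptideMatch:
    peptide: Peptide
    frame: int
    genome_interval: Interval
    region: str


def assign_region(interval: Interval, layout: BicistronicLayout) -> str:
    """ORF1 / bridge / ORF2 containment, spanning across boundaries, else other."""
    named = [
        (REGION_ORF1, layout.orf1.interval),
        (REGION_BRIDGE, layout.bridge),
        (REGION_ORF2, layout.orf2.interval),
        (REGION_OTHER, layout.utr5),
        (REGION_OTHER, layout.utr3),
        (REGION_OTHER, layout.overlap),
    ]
    touched = []
    for name, region in named:
        if region is None:
            continue
        if region.contains(interval):
            return name
        if region.overlaps(interval):
            touched.append(name)
    return REGION_SPANNING if len(touched) >= 2 else REGION_OTHER


def map_peptides(
    peptides: Iterable[Peptide],
    index: FrameIndex,
    layout: BicistronicLayout | None = None,
) -> tuple[list[PeptideMatch], list[Peptide]]:
    """Exact placements of each peptide on every frame translation.

    All placements of every peptide are reported ('*' sentinels break
    matches implicitly).  Returns (matches, unmatched peptides).
    """
    matches: list[PeptideMatch] = []
    unmatched: list[Peptide] = []
    for pep in peptides:
        found = False
        for frame, aa in sorted(index.frames.items(), key=lambda kv: -kv[0]):
            pos = aa.find(pep.sequence)
            while pos != -1:
                gi = index.peptide_interval(frame, pos + 1, len(pep.sequence))
                region = assign_region(gi, layout) if layout else REGION_OTHER
                matches.append(PeptideMatch(pep, frame, gi, region))
                found = True
                pos = aa.find(pep.sequence, pos + 1)
        if not found:
            unmatched.append(pep)
    matches.sort(key=lambda m: (m.genome_interval.start, m.frame))
    return matches, unmatched


@dataclass(frozen=True)
class EvidenceSummary:
    counts: dict[str, int]  # "region/frameN" -> match count
    band_mass_da: float
    verdict: str
    rationale: str
    n_matches: int


def _within(mass: float, band: float, tol: float) -> bool:
    return abs(band - mass) <= tol * mass


def adjudicate(
    matches: Sequence[PeptideMatch],
    band_mass_da: float,
    products: Sequence[ProductModel],
    *,
    tolerance: float = 0.15,
) -> EvidenceSummary:
    """Decide the translation strategy a gel band's PMF evidence supports.

    Ordered decision rules (the rationale records which fired):

    1. two_separate_products — peptides from both ORF1 and ORF2 regions,
       band mass within tolerance of both separate-product masses, and no
       single-chain product covering both ORFs matches the band mass;
    2. fusion_product — band mass within tolerance of a fusion model whose
       genomic path covers both ORF1 and ORF2;
    3. bridge_extended_rdrp — ORF2-frame peptides in the bridge and a
       bridge-extended model within tolerance of the band mass;
    4. otherwise inconclusive.

    The default +/-15% tolerance reflects SDS-PAGE band-size imprecision.
    """
    counts: dict[str, int] = {}
    for m in matches:
        key = f"{m.region}/frame{m.frame}"
        counts[key] = counts.get(key, 0) + 1
    regions = {m.region for m in matches}
    notes: list[str] = []

    separate = sorted(
        (p for p in products if p.strategy == STRATEGY_SEPARATE),
        key=lambda p: p.genomic_path[0][0].start,
    )
    if len(separate) < 2:
        raise ValueError("adjudication requires the two separate product models")
    orf1_path = separate[0].genomic_path[0][0]
    orf2_path = separate[1].genomic_path[0][0]
    orf2_frame = separate[1].genomic_path[0][1]
    chains = [
        p
        for p in products
        if p.strategy in (STRATEGY_FUSION_SLIP, STRATEGY_FUSION_READTHROUGH)
        and p.path_covers(orf1_path)
        and p.path_covers(orf2_path)
    ]
    extended = [p for p in products if p.strategy == STRATEGY_BRIDGE_EXTENDED]

    if not matches:
        notes.append("warning: no mapped peptides; evidence is empty")
        return EvidenceSummary(counts, band_mass_da, VERDICT_INCONCLUSIVE,
                               "; ".join(notes), 0)

    # rule 1
    both_regions = REGION_ORF1 in regions and REGION_ORF2 in regions
    band_fits_separate = all(
        _within(p.mass_da, band_mass_da, tolerance) for p in separate
    )
    chain_explains_band = any(
        _within(p.mass_da, band_mass_da, tolerance) for p in chains
    )
    if both_regions and band_fits_separate and not chain_explains_band:
        notes.append(
            "rule 1 fired: ORF1- and ORF2-region peptides present, band mass "
            "consistent with both separate products and with no single chain"
        )
        return EvidenceSummary(counts, band_mass_da, VERDICT_SEPARATE,
                               "; ".join(notes), len(matches))
    notes.append("rule 1 not satisfied")

    # rule 2
    fitting_chain = next(
        (p for p in chains if _within(p.mass_da, band_mass_da, tolerance)), None
    )
    if fitting_chain is not None:
        notes.append(
            f"rule 2 fired: band mass matches {fitting_chain.name!r} "
            "covering both ORFs"
        )
        return EvidenceSummary(counts, band_mass_da, VERDICT_FUSION,
                               "; ".join(notes), len(matches))
    notes.append("rule 2 not satisfied")

    # rule 3
    orf2_frame_bridge = any(
        m.region == REGION_BRIDGE and m.frame == orf2_frame for m in matches
    )
    fitting_ext = next(
        (p for p in extended if _within(p.mass_da, band_mass_da, tolerance)), None
    )
    if orf2_frame_bridge and fitting_ext is not None:
        notes.append(
            f"rule 3 fired: ORF2-frame bridge peptides and band mass matches "
            f"{fitting_ext.name!r}"
        )
        return EvidenceSummary(counts, band_mass_da, VERDICT_BRIDGE_EXTENDED,
                               "; ".join(notes), len(matches))
    notes.append("rule 3 not satisfied")
    return EvidenceSummary(counts, band_mass_da, VERDICT_INCONCLUSIVE,
                           "; ".join(notes), len(matches))


# ---------------------------------------------------------------------------
# Peptide TSV I/O
# ---------------------------------------------------------------------------

def read_peptide_tsv(path: str | Path, source: str = "observed") -> list[Peptide]:
    """Read peptides from a TSV (column 1 = sequence; '#' lines skipped)."""
    peptides = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        token = line.split("\t")[0].strip()
        if lineno == 1 and token.lower() in ("sequence", "peptide"):
            continue
        try:
            peptides.append(Peptide(token.upper(), source=source))
        except ValueError as exc:
            raise ValueError(f"{path}, line {lineno}: {exc}") from exc
    return peptides


def write_matches_tsv(
    matches: Sequence[PeptideMatch], unmatched: Sequence[Peptide], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tframe\tstart\tend\tregion\n")
        for m in matches:
            fh.write(
                f"{m.peptide.sequence}\t{m.frame}\t{m.genome_interval.start}"
                f"\t{m.genome_interval.end}\t{m.region}\n"
            )
        for p in unmatched:
            fh.write(f"{p.sequence}\t.\t.\t.\tunmatched\n")
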