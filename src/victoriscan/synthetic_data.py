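"""Victorivirus-like synthetic genomes with exact truth layouts, plus
simulated peptide-mass-fingerprint observations.

The ``paper_layout`` preset emulates the study organism's genome geometry:
a 5120-nt plus strand decomposed as 5'UTR (266 nt) + ORF1 (2298 nt incl.
stop; capsid protein, 765 aa) + inter-ORF bridge (322 nt) + ORF2 (2157 nt
incl. stop; RdRp, 718 aa) + 3'UTR (77 nt), with the conserved 5'UTR 15-mer
AGGGUUCCGUUGAUC planted at 204 (octamer at [204,211], 55 nt upstream of the
ORF1 AUG), the near-consensus slippery heptamer CCAAAAU immediately before
the ORF1 stop at [2555,2561], no stop/restart facilitator, and ORF2-frame
codons for the bridge peptide TASDLDLYLK at [2593,2622].

Construction guarantees that re-annotating the genome reproduces the truth
coordinates: an ORF1-frame stop is planted in the last three 5'UTR nt and
an ORF2-frame stop in the last three bridge nt (UAG in both cases, which
cannot create an AUGA/UAAUG facilitator substring at either junction), so
the maximal-ORF starts are pinned at the true starts.  Residual stochastic
hazards — an accidental second UTR motif, an accidental facilitator or
perfect slippery 7-mer in the junction window, a duplicate peptide anchor —
are removed by bounded deterministic retries seeded from (seed, attempt).

Everything else (codon choice inside ORFs, UTR composition, synonymous
codons of the planted peptide) is uniform-random: the generator emulates
coordinate geometry and planted signals, not victorivirus base composition
or codon usage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genome_io import GenomeRecord, Interval
from .orf_annotator import STOP_CODONS, frame_of
from .pmf_evidence import Peptide, build_frame_index, digest
from .protein_products import molecular_mass, translate, translate_str
from .recoding_signals import slippery_mismatches

BASES = "ACGU"
ALL_CODONS = [a + b + c for a in BASES for b in BASES for c in BASES]
NONSTOP_CODONS = [c for c in ALL_CODONS if c not in STOP_CODONS]
CODONS_BY_AA: dict[str, list[str]] = {}
for _codon in NONSTOP_CODONS:
    CODONS_BY_AA.setdefault(translate_str(_codon), []).append(_codon)
AGP_CODONS = CODONS_BY_AA["A"] + CODONS_BY_AA["G"] + CODONS_BY_AA["P"]

FACILITATORS = ("AUGA", "UAAUG")
MAX_ATTEMPTS = 200


@dataclass(frozen=True)
class GenomeParams:
    """Component geometry and planted-signal parameters.

    Lengths are nt; ORF lengths include the stop codon and must be
    multiples of 3.  Positions are genome coordinates implied by the
    lengths.  Defaults reproduce the paper_layout preset.
    """

    utr5_len: int = 266
    orf1_nt: int = 2298
    bridge_len: int = 322
    orf2_nt: int = 2157
    utr3_len: int = 77
    utr_motif: str = "AGGGUUCCGUUGAUC"
    utr_motif_start: int | None = 204  # genome coordinate; None = no motif
    slippery: str | None = "CCAAAAU"  # planted ending 3 nt before ORF1 end
    facilitator: str | None = None  # "UAAUG" or "AUGA", spanning the ORF1 stop
    peptide_anchor: str | None = "TASDLDLYLK"
    #: offset of the anchor's first nt from ORF2 start (upstream, in ORF2's
    #: frame); 294 places TASDLDLYLK at [2593,2622] on the paper layout
    peptide_anchor_upstream: int = 294
    #: make every ORF2-frame codon in the bridge a sense codon (required for
    #: fusion / bridge-extended product scenarios)
    bridge_frame1_open: bool = False
    #: plant an H-type pseudoknot cassette (GC arms, A loops) in the bridge
    plant_pseudoknot: bool = False
    #: 0-based nt offset of the cassette from the bridge start
    pseudoknot_offset: int = 100
    pseudoknot_arm: int = 5
    pseudoknot_loop: int = 4
    agp_tail: bool = True
    gc: float = 0.5

    def __post_init__(self) -> None:
        if self.orf1_nt % 3 or self.orf2_nt % 3:
            raise ValueError("ORF lengths must be multiples of 3")
        if self.utr5_len < 20 or self.bridge_len < 12 or self.utr3_len < 3:
            raise ValueError("regions too short for a victorivirus-like layout")
        if self.orf1_nt < 150 or self.orf2_nt < 150:
            raise ValueError("ORFs must be at least 50 codons")
        if self.slippery is not None:
            if len(self.slippery) != 7:
                raise ValueError("slippery heptamer must be 7 nt")
            if (
                self.slippery[1:4] in STOP_CODONS
                or self.slippery[4:7] in STOP_CODONS
            ):
                raise ValueError("slippery heptamer would plant an in-frame stop")
        if self.facilitator is not None and self.facilitator not in FACILITATORS:
            raise ValueError(f"facilitator must be one of {FACILITATORS}")
        if self.plant_pseudoknot:
            if self.bridge_frame1_open:
                raise ValueError(
                    "cannot combine plant_pseudoknot with bridge_frame1_open "
                    "(the cassette would overwrite sense codons)"
                )
            end = self.pseudoknot_offset + self.pseudoknot_cassette_length
            if end > self.bridge_len - 3:
                raise ValueError("pseudoknot cassette does not fit in the bridge")
            anchor = self.anchor_interval
            if anchor is not None:
                cas_start = self.bridge_interval.start + self.pseudoknot_offset
                cassette = Interval(cas_start, cas_start + self.pseudoknot_cassette_length - 1)
                pad = Interval(max(1, anchor.start - 3), anchor.end)
                if cassette.overlaps(pad):
                    raise ValueError("pseudoknot cassette overlaps the peptide anchor")

    # --- derived coordinates ------------------------------------------------
    @property
    def genome_length(self) -> int:
        return (
            self.utr5_len + self.orf1_nt + self.bridge_len
            + self.orf2_nt + self.utr3_len
        )

    @property
    def orf1_interval(self) -> Interval:
        return Interval(self.utr5_len + 1, self.utr5_len + self.orf1_nt)

    @property
    def bridge_interval(self) -> Interval:
        o1 = self.orf1_interval
        return Interval(o1.end + 1, o1.end + self.bridge_len)

    @property
    def orf2_interval(self) -> Interval:
        b = self.bridge_interval
        return Interval(b.end + 1, b.end + self.orf2_nt)

    @property
    def slippery_interval(self) -> Interval | None:
        if self.slippery is None:
            return None
        end = self.orf1_interval.end - 3
        return Interval(end - 6, end)

    @property
    def pseudoknot_cassette_length(self) -> int:
        return 4 * self.pseudoknot_arm + 3 * self.pseudoknot_loop

    @property
    def pseudoknot_arm_intervals(self) -> dict[str, Interval] | None:
        """Genome coordinates of the planted cassette's four arms."""
        if not self.plant_pseudoknot:
            return None
        a, l = self.pseudoknot_arm, self.pseudoknot_loop
        s = self.bridge_interval.start + self.pseudoknot_offset
        out = {}
        pos = s
        for name, length in (
            ("stem1_arm5", a), ("loop1", l), ("stem2_arm5", a), ("loop2", l),
            ("stem1_arm3", a), ("loop3", l), ("stem2_arm3", a),
        ):
            if name.startswith("stem"):
                out[name] = Interval(pos, pos + length - 1)
            pos += length
        return out

    @property
    def anchor_interval(self) -> Interval | None:
        if self.peptide_anchor is None:
            return None
        start = self.orf2_interval.start - self.peptide_anchor_upstream
        return Interval(start, start + 3 * len(self.peptide_anchor) - 1)


@dataclass(frozen=True)
class TruthLayout:
    """Ground-truth coordinates and planted signals of a generated genome."""

    genome_length: int
    utr5: Interval
    orf1: Interval
    bridge: Interval
    orf2: Interval
    utr3: Interval
    orf1_frame: int
    orf2_frame: int
    utr_motif: str | None
    utr_motif_interval: Interval | None
    slippery_heptamer: str | None
    slippery_interval: Interval | None
    slippery_mismatches: int | None
    facilitator: str | None
    facilitator_interval: Interval | None
    peptide_anchor: str | None
    peptide_anchor_interval: Interval | None
    agp_region_aa: Interval | None
    bridge_frame1_open: bool
    seed: int
    pseudoknot_arms: dict[str, Interval] | None = None

    def to_layout(self) -> "BicistronicLayout":
        """The truth coordinates as a BicistronicLayout object."""
        from .orf_annotator import BicistronicLayout, Orf

        orf1 = Orf(self.orf1, self.orf1_frame, self.orf1.length // 3 - 1, "ORF1_CP")
        orf2 = Orf(self.orf2, self.orf2_frame, self.orf2.length // 3 - 1, "ORF2_RDRP")
        offset = {0: 0, 1: +1, 2: -1}[(self.orf2.start - self.orf1.start) % 3]
        return BicistronicLayout(
            utr5=self.utr5,
            orf1=orf1,
            bridge=self.bridge,
            overlap=None,
            orf2=orf2,
            utr3=self.utr3,
            relative_frame_offset=offset,
            genome_length=self.genome_length,
        )

    @property
    def bridge_orf2_frame_start(self) -> int:
        """First ORF2-frame codon start inside the bridge."""
        start = self.bridge.start
        while (start - self.orf2.start) % 3 != 0:
            start += 1
        return start


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> list[str]:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return list(rng.choice(list("ACGU"), size=n, p=p)) if n else []


def _random_nonstop_codons(rng: np.random.Generator, n: int) -> list[str]:
    return list(rng.choice(NONSTOP_CODONS, size=n)) if n else []


def _reverse_translate(rng: np.random.Generator, protein: str) -> str:
    return "".join(rng.choice(CODONS_BY_AA[aa]) for aa in protein)


def _build_attempt(params: GenomeParams, rng: np.random.Generator) -> list[str]:
    """One construction pass; returns the genome as a mutable char list."""
    gc = params.gc
    chars: list[str] = []

    # 5'UTR: random, ORF1-frame stop planted in the last 3 nt
    utr5 = _random_bases(rng, params.utr5_len, gc)
    utr5[-3:] = list("UAG")
    if params.utr_motif_start is not None:
        m = params.utr_motif
        s = params.utr_motif_start - 1
        if s + len(m) > params.utr5_len - 3:
            raise ValueError("UTR motif does not fit inside the 5'UTR")
        utr5[s : s + len(m)] = list(m)
    chars.extend(utr5)

    # ORF1: AUG + sense codons + stop
    n_codons = params.orf1_nt // 3 - 2  # between start and stop
    body = _random_nonstop_codons(rng, n_codons)
    if params.agp_tail and n_codons > 80:
        # Ala/Gly/Pro-rich stretch near the CP C-terminus (last ~60 codons,
        # leaving 5 codons clear of the slippery-site overwrite)
        for k in range(n_codons - 65, n_codons - 5):
            if rng.random() < 0.8:
                body[k] = str(rng.choice(AGP_CODONS))
    stop = "UAG"
    if params.facilitator == "UAAUG":
        stop = "UAA"
    elif params.facilitator == "AUGA":
        stop = "UGA"
    if params.slippery is not None:
        hept = params.slippery
        # last two sense codons carry heptamer nt 2-7; the codon before
        # them must end with heptamer nt 1
        body[-1] = hept[4:7]
        body[-2] = hept[1:4]
        third_base = hept[0]
        candidates = [c for c in NONSTOP_CODONS if c[2] == third_base]
        body[-3] = str(rng.choice(candidates))
        if params.facilitator == "AUGA" and hept[6] != "A":
            raise ValueError("AUGA facilitator needs a slippery heptamer ending in A")
    chars.extend("AUG")
    chars.extend("".join(body))
    chars.extend(stop)

    # bridge: random, ORF2-frame stop in the last 3 nt (unless open)
    bridge = _random_bases(rng, params.bridge_len, gc)
    orf2_start0 = params.utr5_len + params.orf1_nt + params.bridge_len  # 0-based
    bridge_start0 = params.utr5_len + params.orf1_nt
    if params.bridge_frame1_open:
        # overwrite every complete ORF2-frame codon in the bridge with a
        # sense codon
        j = orf2_start0 - 3
        while j >= bridge_start0:
            codon = str(rng.choice(NONSTOP_CODONS))
            for t in range(3):
                bridge[j - bridge_start0 + t] = codon[t]
            j -= 3
    else:
        bridge[-3:] = list("UAG")
    if params.plant_pseudoknot:
        comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
        a, l = params.pseudoknot_arm, params.pseudoknot_loop
        s1a = "".join(rng.choice(list("GC"), size=a))
        s2a = "".join(rng.choice(list("GC"), size=a))
        rc = lambda s: "".join(comp[c] for c in reversed(s))
        cassette = s1a + "A" * l + s2a + "A" * l + rc(s1a) + "A" * l + rc(s2a)
        off = params.pseudoknot_offset
        bridge[off : off + len(cassette)] = list(cassette)
    if params.facilitator == "UAAUG":
        bridge[0], bridge[1] = "U", "G"
    if params.peptide_anchor is not None:
        anchor = params.anchor_interval
        if anchor is None or anchor.start <= params.bridge_interval.start:
            raise ValueError("peptide anchor does not fit inside the bridge")
        if (anchor.start - params.orf2_interval.start) % 3 != 0:
            raise ValueError("peptide anchor start is not in ORF2's frame")
        codons = _reverse_translate(rng, params.peptide_anchor)
        a0 = anchor.start - 1 - bridge_start0
        bridge[a0 : a0 + len(codons)] = list(codons)
        # a tryptic boundary (Arg codon) directly upstream, when it fits
        if a0 >= 3 and not (
            params.facilitator == "UAAUG" and a0 - 3 < 2
        ):
            bridge[a0 - 3 : a0] = list("AGA")
        if anchor.end > params.bridge_interval.end - 3 and not params.bridge_frame1_open:
            raise ValueError("peptide anchor collides with the bridge stop")
    chars.extend(bridge)

    # ORF2: AUG + sense codons + stop
    n2 = params.orf2_nt // 3 - 2
    chars.extend("AUG")
    chars.extend("".join(_random_nonstop_codons(rng, n2)))
    chars.extend("UAG")

    # 3'UTR
    chars.extend(_random_bases(rng, params.utr3_len, gc))
    assert len(chars) == params.genome_length
    return chars


def _junction_ok(seq: str, params: GenomeParams) -> bool:
    """Reject accidental facilitators / perfect slippery 7-mers near the
    ORF1 stop (the planted facilitator, if any, is exempted)."""
    orf1 = params.orf1_interval
    stop_start, stop_end = orf1.end - 2, orf1.end
    lo = max(1, stop_start - 45)
    hi = min(len(seq), stop_end + 45)
    window = seq[lo - 1 : hi]
    planted: set[int] = set()
    if params.facilitator == "UAAUG":
        planted.add(stop_start)
    elif params.facilitator == "AUGA":
        planted.add(stop_start - 1)
    for motif in FACILITATORS:
        pos = window.find(motif)
        while pos != -1:
            if lo + pos not in planted:
                return False
            pos = window.find(motif, pos + 1)
    slip_lo = max(1, stop_start - 40)
    slip_hi = min(len(seq), stop_end + 10)
    for s in range(slip_lo, slip_hi - 5):
        if slippery_mismatches(seq[s - 1 : s + 6]) == 0:
            return False
    return True


def _utr_motif_ok(seq: str, params: GenomeParams) -> bool:
    if params.utr_motif_start is None:
        return True
    utr = seq[: params.utr5_len]
    octamer = params.utr_motif[:8]
    return utr.count(octamer) == 1


def _anchor_ok(seq: str, params: GenomeParams) -> bool:
    if params.peptide_anchor is None:
        return True
    record = GenomeRecord(id="tmp", sequence=seq)
    idx = build_frame_index(record)
    total = sum(aa.count(params.peptide_anchor) for aa in idx.frames.values())
    return total == 1


def generate_genome(
    preset: str = "paper_layout",
    params: GenomeParams | None = None,
    seed: int = 0,
) -> tuple[GenomeRecord, TruthLayout]:
    """Generate a victorivirus-like genome with a known truth layout.

    ``preset='paper_layout'`` uses the default :class:`GenomeParams`;
    ``preset='custom'`` requires explicit ``params``.  Deterministic for a
    fixed (params, seed).
    """
    if preset == "paper_layout":
        if params is not None:
            raise ValueError("paper_layout preset takes no custom params")
        params = GenomeParams()
    elif preset == "custom":
        if params is None:
            raise ValueError("custom preset requires params")
    else:
        raise ValueError(f"unknown preset {preset!r}")

    last_error = "no attempt made"
    for attempt in range(MAX_ATTEMPTS):
        rng = np.random.default_rng([seed, attempt])
        seq = "".join(_build_attempt(params, rng))
        if not _utr_motif_ok(seq, params):
            last_error = "duplicate 5'UTR motif"
            continue
        if not _junction_ok(seq, params):
            last_error = "accidental junction motif"
            continue
        if not _anchor_ok(seq, params):
            last_error = "duplicate peptide anchor"
            continue
        record = GenomeRecord(id=f"synthetic_victorivirus_seed{seed}", sequence=seq)
        truth = _truth_from_params(params, seed)
        return record, truth
    raise RuntimeError(
        f"genome generation failed after {MAX_ATTEMPTS} attempts ({last_error})"
    )


def _truth_from_params(params: GenomeParams, seed: int) -> TruthLayout:
    orf1, orf2 = params.orf1_interval, params.orf2_interval
    motif_iv = None
    if params.utr_motif_start is not None:
        motif_iv = Interval(
            params.utr_motif_start,
            params.utr_motif_start + len(params.utr_motif) - 1,
        )
    fac_iv = None
    if params.facilitator == "UAAUG":
        fac_iv = Interval(orf1.end - 2, orf1.end + 2)
    elif params.facilitator == "AUGA":
        fac_iv = Interval(orf1.end - 3, orf1.end)
    agp = None
    n_codons = params.orf1_nt // 3 - 2
    if params.agp_tail and n_codons > 80:
        # aa positions of the enriched stretch on CP (1-based; aa 1 = Met)
        agp = Interval(n_codons - 63, n_codons - 4)
    return TruthLayout(
        genome_length=params.genome_length,
        utr5=Interval(1, params.utr5_len),
        orf1=orf1,
        bridge=params.bridge_interval,
        orf2=orf2,
        utr3=Interval(orf2.end + 1, params.genome_length),
        orf1_frame=frame_of(orf1.start),
        orf2_frame=frame_of(orf2.start),
        utr_motif=params.utr_motif if params.utr_motif_start else None,
        utr_motif_interval=motif_iv,
        slippery_heptamer=params.slippery,
        slippery_interval=params.slippery_interval,
        slippery_mismatches=(
            slippery_mismatches(params.slippery) if params.slippery else None
        ),
        facilitator=params.facilitator,
        facilitator_interval=fac_iv,
        peptide_anchor=params.peptide_anchor,
        peptide_anchor_interval=params.anchor_interval,
        agp_region_aa=agp,
        bridge_frame1_open=params.bridge_frame1_open,
        seed=seed,
        pseudoknot_arms=params.pseudoknot_arm_intervals,
    )


def random_custom_params(rng: np.random.Generator) -> GenomeParams:
    """A random internally consistent custom layout (used by property tests)."""
    orf1_nt = 3 * int(rng.integers(110, 320))
    orf2_nt = 3 * int(rng.integers(110, 320))
    utr5 = int(rng.integers(60, 260))
    bridge = int(rng.integers(60, 280))
    utr3 = int(rng.integers(30, 100))
    motif = "AGGGUUCC" if rng.random() < 0.5 else "AGGGUUCCGUUGAUC"
    motif_start = int(rng.integers(1, utr5 - len(motif) - 3))
    facilitator = "UAAUG" if rng.random() < 0.5 else None
    # anchor upstream offset: a multiple of 3 placing a 10-aa anchor plus a
    # leading Arg codon inside the bridge, clear of both bridge ends
    return GenomeParams(
        utr5_len=utr5,
        orf1_nt=orf1_nt,
        bridge_len=bridge,
        orf2_nt=orf2_nt,
        utr3_len=utr3,
        utr_motif=motif,
        utr_motif_start=motif_start,
        slippery="CCAAAAU",
        facilitator=facilitator,
        peptide_anchor=None,
        gc=float(rng.uniform(0.35, 0.65)),
    )


# ---------------------------------------------------------------------------
# Simulated PMF observations
# ---------------------------------------------------------------------------

SCENARIOS = ("separate", "fusion", "bridge_extended")


@dataclass(frozen=True)
class PmfTruth:
    scenario: str
    band_mass_da: float
    true_products: tuple[str, ...]  # protein sequences
    decoys: tuple[str, ...]
    bridge_extension_start: int | None = None


def scenario_products(
    record: GenomeRecord, truth: TruthLayout, scenario: str
) -> tuple[list[str], float, int | None]:
    """(product proteins, band mass, bridge-extension start) for a scenario."""
    cp = translate(record, Interval(truth.orf1.start, truth.orf1.end - 3))
    rdrp = translate(record, Interval(truth.orf2.start, truth.orf2.end - 3))
    if scenario == "separate":
        return [cp, rdrp], molecular_mass(cp), None
    if not truth.bridge_frame1_open:
        raise ValueError(
            f"scenario {scenario!r} requires a genome generated with "
            "bridge_frame1_open=True (the bridge must be sense in ORF2's frame)"
        )
    if scenario == "fusion":
        j0 = truth.orf1.end - 2
        while (j0 - truth.orf2.start) % 3 != 0:
            j0 += 1
        tail = translate(record, Interval(j0, truth.orf2.end - 3))
        chain = cp + tail
        return [chain], molecular_mass(chain), None
    if scenario == "bridge_extended":
        start = truth.bridge.start
        while (start - truth.orf2.start) % 3 != 0:
            start += 1
        ext = translate(record, Interval(start, truth.orf2.end - 3))
        return [ext], molecular_mass(ext), start
    raise ValueError(f"unknown scenario {scenario!r}")


def simulate_pmf(
    record: GenomeRecord,
    truth: TruthLayout,
    scenario: str = "separate",
    n_peptides: int = 30,
    seed: int = 0,
    contamination_rate: float = 0.0,
    *,
    min_len: int = 6,
    missed_cleavages: int = 0,
) -> tuple[list[Peptide], PmfTruth]:
    """Sample tryptic peptides from a scenario's true product(s).

    Digests the true product(s), keeps peptides of at least ``min_len``
    residues (shorter tryptic fragments are not confidently identified in
    practice and would place ambiguously), samples ``n_peptides`` uniformly
    without replacement (with replacement once the pool is exhausted), and
    appends ``round(contamination_rate * n_peptides)`` random decoy
    peptides absent from every frame translation.  Deterministic per seed.
    """
    if n_peptides < 1:
        raise ValueError("n_peptides must be >= 1")
    if not (0 <= contamination_rate < 0.5):
        raise ValueError("contamination_rate must be in [0, 0.5)")
    proteins, band_mass, ext_start = scenario_products(record, truth, scenario)
    pool = sorted(
        {
            p.sequence
            for prot in proteins
            for p in digest(prot, missed_cleavages=missed_cleavages)
            if len(p.sequence) >= min_len
        }
    )
    if not pool:
        raise ValueError("scenario product yielded no peptides of usable length")
    rng = np.random.default_rng([seed, 7])
    take = min(n_peptides, len(pool))
    chosen = [str(s) for s in rng.choice(pool, size=take, replace=False)]
    if n_peptides > len(pool):
        chosen += [
            str(s) for s in rng.choice(pool, size=n_peptides - len(pool), replace=True)
        ]
    idx = build_frame_index(record)
    n_decoys = int(round(contamination_rate * n_peptides))
    decoys: list[str] = []
    aa_letters = sorted("ACDEFGHIKLMNPQRSTVWY")
    while len(decoys) < n_decoys:
        length = int(rng.integers(8, 15))
        cand = "".join(rng.choice(aa_letters, size=length))
        if all(cand not in aa for aa in idx.frames.values()):
            decoys.append(cand)
    peptides = [Peptide(s, source="simulated") for s in chosen + decoys]
    pmf_truth = PmfTruth(
        scenario=scenario,
        band_mass_da=band_mass,
        true_products=tuple(proteins),
        decoys=tuple(decoys),
        bridge_extension_start=ext_start,
    )
    return peptides, pmf_truth


# ---------------------------------------------------------------------------
# Standalone pseudoknot fixtures (for the structure module's recovery tests)
# ---------------------------------------------------------------------------

def make_pseudoknot_fixture(
    seed: int,
    arm1: int = 5,
    arm2: int = 5,
    loop1: int = 4,
    loop2: int = 4,
    loop3: int = 4,
    flank: int = 8,
) -> tuple[str, dict[str, Interval]]:
    """A planted H-type pseudoknot: flank S1a L1 S2a L2 S1b L3 S2b flank.

    Stem arms are GC-biased so the planted structure outscores accidental
    helices in the random flanks.  Returns the sequence and the truth arm
    intervals (1-based on the returned sequence).
    """
    rng = np.random.default_rng([seed, 13])
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}

    def arm(n: int) -> str:
        return "".join(rng.choice(list("GC"), size=n))

    def rc(s: str) -> str:
        return "".join(comp[c] for c in reversed(s))

    def loop(n: int) -> str:
        # adenosine loops cannot pair with the G/C arms or with each other,
        # so the planted helices stay the dominant structure
        return "A" * n

    s1a, s2a = arm(arm1), arm(arm2)
    parts = {
        "f5": "".join(rng.choice(list("ACGU"), size=flank)),
        "s1a": s1a,
        "l1": loop(loop1),
        "s2a": s2a,
        "l2": loop(loop2),
        "s1b": rc(s1a),
        "l3": loop(loop3),
        "s2b": rc(s2a),
        "f3": "".join(rng.choice(list("ACGU"), size=flank)),
    }
    seq = "".join(parts.values())
    pos = 1
    coords = {}
    for name, chunk in parts.items():
        coords[name] = Interval(pos, pos + len(chunk) - 1) if chunk else None
        pos += len(chunk)
    truth = {
        "stem1_arm5": coords["s1a"],
        "stem1_arm3": coords["s1b"],
        "stem2_arm5": coords["s2a"],
        "stem2_arm3": coords["s2b"],
    }
    return seq, truth
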