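# Methods

This note documents the models, conventions and numerical choices behind
`victoriscan`, and what its tests do and do not establish.

## Coordinate contract

All interfaces speak 1-based, inclusive plus-strand nucleotide coordinates
(the convention of printed genome maps); conversion to half-open Python
slices happens only inside function bodies. The canonical alphabet is RNA;
FASTA written in DNA style is normalized T→U on read and restored on
write. The frame label of position *p* is ((*p*−1) mod 3)+1. ORF intervals
include the stop codon (aa_length = nt/3 − 1), and an ORF is "maximal":
it opens at the 5′-most in-frame start codon after the previous in-frame
stop and closes at the next in-frame stop. Start codons default to AUG
only; extended start sets (for noncanonical-initiation hypotheses) are an
explicit option, never the default.

## Bicistronic layout classification

Given the maximal ORFs (default minimum 100 aa), ORF1 is the 5′-most
start among the two longest non-nested ORFs and ORF2 the longest ORF
starting after ORF1's start; ties break on earlier start, then length.
Separated ORFs define a bridge interval, overlapping ORFs an overlap
record. The relative codon phase of ORF2 versus ORF1 is reported in
{0, +1, −1} with +1 ≡ −2 (mod 3). Whether a +1 offset is produced by a
−1 shift plus something else, or by reinitiation, is left to the evidence
adjudicator — the layout only reports the arithmetic.

## Recoding-signal scanners

* **Slippery heptamers.** Candidates are scored by minimum Hamming
  distance to the consensus class `N₁N₁N₁ N₂N₂N₂ N₃` with all three bases
  free — the consensus itself imposes no base identities, and optional
  base-class restrictions (e.g. the classical Z ≠ G) are exposed as
  parameters for users who want the stricter pattern. The default
  tolerance of one mismatch is what makes "slippery-like" sites
  reportable. The default junction window runs 40 nt upstream through
  10 nt downstream of the ORF1 stop codon: the experimentally mapped
  stop/restart element of the prototype victorivirus spans ~38 nt, which
  bounds the biologically relevant neighbourhood.
* **Facilitators.** AUGA and UAAUG occurrences near the ORF1 stop are
  reported with a frame-consistency flag (is the embedded stop triplet in
  ORF1's phase?). The scanner does not require the AUG to open ORF2:
  strictness is tunable because genuine facilitators overlap stop and
  start, but genomes lacking them still need a well-defined scan.
* **5′UTR motifs.** Exact matches of the conserved octamer
  `AGGGUUCC` and its extended 15-mer `AGGGUUCCGUUGAUC` inside the 5′UTR,
  each with its gap to the ORF1 start (exclusive of both ends).
* **Ala/Gly/Pro content.** Sliding windows (default 20 aa) whose A/G/P
  fraction reaches a threshold (default 0.5) are merged into maximal
  regions; the fraction is recomputed over each merged region. This flags
  the C-terminal capsid tail characteristic of the genus.

## RNA structure heuristic

The structure module is deliberately not a thermodynamic model. It
enumerates perfect (bulge-free) helices exhaustively within a window,
scores them additively (GC/CG = 3, AU/UA = 2, GU/UG = 1, no loop penalty),
and suppresses shifted registers (a helix both of whose arms lie inside a
longer helix's arms). A hairpin is a stem with loop ≥ 3 nt (default) whose
loop contains no arm of a strictly stronger stem; an H-type pseudoknot is
an ordered pair of crossing stems — stem 2's 5′ arm inside stem 1's loop,
its 3′ arm downstream of stem 1's 3′ arm. The primary pseudoknot report is
a greedy span-disjoint selection by score; the full candidate list stays
available. This supports presence/absence and topology calls and is
validated against brute-force enumeration and planted-structure recovery;
it does not produce free energies, bulged stems, or coordinates comparable
with nearest-neighbour folding programs, whose printed intervals are
therefore treated as qualitative context only.

## Product models and masses

Molecular masses are average-isotopic by default (sums of Expasy-style
residue masses plus one water, 18.0153 Da) because the comparisons that
matter are to SDS-PAGE bands; monoisotopic tables are available for MS
work. Candidate products:

* **Separate CP and RdRp** — translations of the two coding regions.
* **Mechanistic slip fusion** — join convention, applied uniformly: the
  ribosome completes the heptamer's last ORF1-frame codon, then resumes
  one nt back (−1; −2/+1 are options) and reads to the first stop in the
  new frame. The exact junction codon of a real frameshift is ambiguous
  in general; fixing one convention keeps paths and masses well defined.
  A path that stops before ORF2 is flagged `terminated_in_bridge`, never
  suppressed — the failure of the path is itself evidence.
* **Full-chain readthrough estimate** — CP plus the bridge and ORF2 read
  in ORF2's frame, stops excluded from the residue count and flagged.
  This is the SDS-PAGE-style size expectation for a hypothetical CP–RdRp
  fusion (the ~2× band position), needed by the adjudicator whether or
  not the mechanistic path is open.
* **Bridge-extended RdRp** — translation from a configured noncanonical
  start in ORF2's frame inside the bridge, modelling reinitiation
  upstream of the annotated AUG.

## PMF evidence and adjudication

Digestion follows the trypsin rule (cleave after K/R, not before P); with
*m* missed cleavages every concatenation of ≤ *m*+1 adjacent fragments is
emitted. Peptides are matched by exact string comparison against
stop-agnostic frame translations (stops translate to a `*` sentinel that
can never match), with every placement reported and mapped back to genome
coordinates; placements are assigned to ORF1 / bridge / ORF2 / spanning /
other by interval containment — spanning peptides are labelled, not
fractionally split, keeping counts integral.

Adjudication applies ordered rules with a band-mass tolerance of ±15%
(SDS-PAGE imprecision; configurable): (1) peptides from both ORFs, band
mass consistent with both separate products, and no single-chain model
covering both ORFs matching the band → two separate products; (2) band
mass matching a fusion model that actually covers both ORFs → fusion;
(3) ORF2-frame bridge peptides plus a matching bridge-extended model →
bridge-extended RdRp; otherwise inconclusive. Requiring "covers both
ORFs" in rules 1–2 prevents a slip model that terminated in the bridge
(mass ≈ CP) from masquerading as a fusion explanation of a CP-sized band.

## Synthetic data: what it emulates and what it does not

The `paper_layout` preset reproduces a victorivirus genome's geometry —
5′UTR 266 nt, ORF1 2298 nt (765 aa), bridge 322 nt, ORF2 2157 nt
(718 aa), 3′UTR 77 nt, 5120 nt total — with the conserved 15-mer planted
at 204, the one-mismatch heptamer `CCAAAAU` ending 3 nt before the ORF1
stop, no facilitator, an A/G/P-enriched CP tail, and ORF2-frame codons
for the bridge peptide `TASDLDLYLK` at 2593–2622 (preceded by an Arg
codon so the peptide is a genuine tryptic fragment). Synonymous codons
for the anchor are seed-determined: only the peptide, not its nucleotide
encoding, is fixed.

Annotation closure (annotate(generate(...)) == truth) is guaranteed by
construction: a UAG is planted in ORF1's frame in the last three 5′UTR nt
and in ORF2's frame in the last three bridge nt, pinning both maximal-ORF
starts (UAG is chosen because no AUGA/UAAUG substring can arise at either
junction from it). Remaining stochastic hazards — a second UTR motif
occurrence, an accidental facilitator or perfect slippery 7-mer in the
junction window, a duplicate peptide anchor — are eliminated by bounded
deterministic retries seeded from (seed, attempt). Base composition
defaults to GC 0.5 and codons are drawn uniformly from sense codons: the
generator emulates coordinate geometry and planted signals, **not** real
codon usage, depth-of-coverage artefacts, or sequencing error, so passing
tests demonstrate correctness of the pipeline's logic, not performance on
real reads. Genomes for fusion / bridge-extended PMF scenarios are built
with `bridge_frame1_open=True` (a stop-free bridge in ORF2's frame); on
such genomes the maximal ORF2 extends upstream, so scenario tests
adjudicate against the truth layout. Custom generation can additionally
plant an H-type pseudoknot cassette (GC arms, non-pairing A loops) at a
chosen offset in the bridge; the preset plants no structures inside
coding sequence, where arm constraints would conflict with sense codons.

PMF simulation digests the scenario's true product(s), keeps fragments of
≥ 6 aa (shorter tryptic fragments are rarely confidently identified and
would multi-place), samples without replacement, and injects decoy
peptides verified absent from all frame translations. The simulated band
mass is the true product's mass (CP's, for the two-product scenario) —
clean by design; real gels add comigration and degradation the simulator
does not model.

## Problem sizes and determinism

All randomness flows from explicit integer seeds (numpy Generator seeded
with (seed, attempt) tuples). The test suite uses 1,000 random sequences
for the ORF-finder oracle, 100 planted fixtures for pseudoknot recovery
(≥ 95 required), and 200 simulated PMF datasets per scenario
(20 genomes × 10 samplings, ≥ 95% correct verdicts required) — sizes at
which the whole suite runs in well under a minute on one CPU while the
binomial noise on the 95% thresholds stays small. Pipeline reports
contain no timestamps, so identical inputs give byte-identical JSON.

## Known limitations

* Perfect helices only: bulges and internal loops are not modelled, and
  the toy score is not a free energy.
* Exact peptide matching: no mass-tolerance spectral matching, PTMs, or
  FDR control — the evidence layer consumes identified sequences.
* The fusion join convention is one defensible choice among several; all
  derived numbers state it explicitly via the genomic path.
* Reverse-strand scanning is opt-in and lightly exercised: victorivirus
  mRNA is the plus strand.
* Real-isolate masses (e.g. CP/RdRp kDa values of a deposited accession)
  are reproduced only when that accession's FASTA is supplied; the
  synthetic fixture fixes coordinates, not composition.
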