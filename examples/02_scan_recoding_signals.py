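"""Scan a genome for the sequence signals of the two candidate translation
mechanisms: -1 frameshift (slippery heptamer) vs stop/restart (AUGA/UAAUG
facilitators), plus the conserved victorivirus 5'UTR motif and the
Ala/Gly/Pro-rich capsid tail.
"""

from victoriscan import annotate, generate_genome, scan_all, translate

record, truth = generate_genome("paper_layout", seed=42)
layout = annotate(record)
cp = translate(record, layout.orf1.coding_interval)
signals = scan_all(record, layout, cp_protein=cp)

print("slippery-site candidates near the ORF1 stop (X XXY YYZ class):")
for h in signals.slippery:
    print(
        f"  {h.heptamer} at {h.interval.start}-{h.interval.end}, "
        f"{h.mismatches} mismatch(es), codon phase {h.phase_note}"
    )
print(f"stop/restart facilitators (AUGA/UAAUG): {len(signals.facilitators)} found")
print("conserved 5'UTR motifs:")
for m in signals.utr_motifs:
    print(
        f"  {m.motif_id} at {m.interval.start}-{m.interval.end}, "
        f"{m.distance_to_orf1_start} nt upstream of the ORF1 AUG"
    )
print("Ala/Gly/Pro-rich regions on CP:")
for r in signals.agp_regions:
    print(
        f"  residues {r.interval.start}-{r.interval.end} "
        f"({100 * r.fraction:.0f}% A/G/P)"
    )
print()
print(
    "A near-consensus heptamer with no facilitator mirrors the paradoxical "
    "victorivirus signature this toolkit is built to characterize: a "
    "frameshift-like signal on a genome whose genus rule is stop/restart."
)
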