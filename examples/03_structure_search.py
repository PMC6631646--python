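"""Find stem-loops and H-type pseudoknots with the toy helix score.

Recoding signals work together with RNA structure: a pseudoknot or hairpin
just downstream of a slippery site stalls the ribosome.  The search here
enumerates perfect helices (GC=3, AU=2, GU=1) and reports crossing stem
pairs; it is a deterministic heuristic, not a thermodynamic model.
"""

from victoriscan import GenomeRecord, Interval, find_pseudoknots, find_stem_loops
from victoriscan.rna_structure import dot_bracket
from victoriscan.synthetic_data import make_pseudoknot_fixture

# a planted H-type pseudoknot embedded in random flanks
seq, truth = make_pseudoknot_fixture(seed=5, arm1=6, arm2=6)
record = GenomeRecord(id="pk_demo", sequence=seq)
window = Interval(1, record.length)

print(f"sequence ({record.length} nt): {seq}")
print(f"planted stem 1 arms: {truth['stem1_arm5']} / {truth['stem1_arm3']}")
print(f"planted stem 2 arms: {truth['stem2_arm5']} / {truth['stem2_arm3']}")

for pk in find_pseudoknots(record, window, min_pairs=4):
    print(
        f"found pseudoknot, score {pk.score:.0f}: "
        f"stem1 {pk.stem1.arm5}/{pk.stem1.arm3}, "
        f"stem2 {pk.stem2.arm5}/{pk.stem2.arm3}"
    )
    print(f"  {dot_bracket(window, pk)}")

hairpin = GenomeRecord(id="hairpin", sequence="GGGGAAAACCCC")
for sl in find_stem_loops(hairpin, Interval(1, 12), min_pairs=3, min_loop=3):
    print(
        f"hairpin in {hairpin.sequence}: stem {sl.stem.arm5}/{sl.stem.arm3}, "
        f"loop {sl.loop}, score {sl.stem.score:.0f}"
    )
print()
print(
    "Round brackets mark stem 1, square brackets the crossing stem 2 — the "
    "interleaving '(((..[[..)))..]]' pattern is the H-type topology."
)
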