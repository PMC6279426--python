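"""Proteotypic precursor selection and novel-protein calling.

Proteotypic precursors are chosen greedily to cover 90% of the searches
in which a protein was observed (capped at 20); they are the precursors
worth targeting in SRM assay design. Novel (PE2-PE5) proteins are called
from peptides of length >= 9 that are not within one substitution of any
established (PE1) protein, requiring two non-overlapping supporting
peptides.
"""

from speclib import call_novel_proteins, is_saav_of_pe1, select_proteotypic
from speclib.fixtures import FixtureConfig, generate_universe

# --- proteotypic selection on a hand-sized occurrence pattern
searches = {f"s{i}" for i in range(10)}
occurrences = {
    ("AAAGILK", 2): {f"s{i}" for i in range(9)},   # present in 9 of 10
    ("CCDEFVK", 2): {"s9"},                        # covers the last search
    ("MMNPQWK", 2): {f"s{i}" for i in range(5)},   # redundant with the first
}
result = select_proteotypic(searches, occurrences, target_coverage=0.9)
print("proteotypic set:", [k[0] for k in result.precursors],
      f"coverage {result.coverage:.2f}")

# --- novel-protein calling on a universe with planted traps
config = FixtureConfig(seed=6, n_proteins=15)
universe = generate_universe(config)
pe1 = [s for a, s in universe.fasta.items() if universe.pe_levels.get(a) == 1]
novel_peptides = {p for peps in universe.novel_peptides.values() for p in peps}
accepted = novel_peptides | set(universe.saav_traps)
called = call_novel_proteins(
    accepted, universe.fasta, universe.pe_levels, min_length=9
)
print(f"planted novel proteins : {len(universe.novel_peptides)}")
print(f"called novel proteins  : {sorted(called)}")
for trap in universe.saav_traps:
    print(f"SAAV trap {trap!r} rejected:", is_saav_of_pe1(trap, pe1))

# The greedy set stops at 90% coverage with a single precursor; planted
# SAAV traps (one substitution from an established protein) never count
# as novel-protein evidence.
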