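"""Parse HVRI haplotype motifs and tabulate a cohort.

Motifs are sets of rCRS positions where a sequence differs from the
reference inside the 16035-16409 window; the study tables abbreviate
positions by dropping the leading "16".
"""

from haplopipe import motif, motif_distance, parse_motif, tabulate_haplotypes
from haplopipe.synth import build_study_fixture

s1 = parse_motif("298-327")          # shorthand expands to 16298, 16327
s2 = parse_motif("223-298-309-327")
ancestral = motif([16223, 16298, 16327])

print(f"S1 = {s1}")
print(f"S2 = {s2}")
print(f"d(S1, ancestral) = {motif_distance(s1, ancestral)}")  # one mutation
print(f"d(S2, ancestral) = {motif_distance(s2, ancestral)}")  # one mutation
print(f"d(S1, S2)        = {motif_distance(s1, s2)}")

cohort = build_study_fixture().samples
table = tabulate_haplotypes(cohort)
print(f"\n{table.n_samples} individuals carry {table.n_distinct} distinct haplotypes:")
print(table.to_frame().to_string(index=False))
# The dominant haplotype (count 10) is S1; both lineage-C haplotypes sit a
# single mutation away from the ancestral South Siberian C motif.
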