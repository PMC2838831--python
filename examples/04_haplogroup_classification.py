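"""Classify mtDNA and Y haplogroups and call molecular sex.

Walks the diagnostic-marker tree (10400/12705 macrohaplogroup split,
then subclade markers) for three contrasting individuals, runs the
M89->M9->M45->M173->M198 Y cascade for a male, and sexes samples from
amelogenin product lengths.
"""

from haplopipe import call_sex, classify_mtdna, classify_y, load_panel
from haplopipe.synth import build_study_fixture

fixture = build_study_fixture()
panel = load_panel()
by_id = {s.sample_id: s for s in fixture.samples}

for sid in ("100", "117", "120"):   # C4, M*, R* in the published table
    sample = by_id[sid]
    call = classify_mtdna(sample, panel.mtdna)
    steps = " -> ".join(f"{st.marker}:{st.observed}{'+' if st.derived else '-'}"
                        for st in call.path)
    print(f"sample {sid}: {call.label:4s}  [{steps}]")
    for note in call.advisories:
        print(f"    advisory: {note}")

male = by_id["106"]
male.molecular_sex = call_sex(male.amg_bands, panel.amg).sex
ycall = classify_y(male, panel.y)
print(f"\nsample 106: molecular sex {male.molecular_sex}, "
      f"Y haplogroup {ycall.label}")
# '+' marks a derived (defining) allele, '-' an ancestral one.  A star
# label like R* means derived at the macrohaplogroup with every tested
# subclade excluded.
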