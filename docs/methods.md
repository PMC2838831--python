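# Methods

## Scope and data model

The pipeline operates on mitochondrial HVRI *haplotype motifs*: the set
of 1-based rCRS positions, optionally with explicit alleles, at which a
sequence differs from the reference inside an inclusive window
(default 16035–16409, overridable because published analyses sometimes
use 16050–16391). Motifs without explicit alleles compare by position
only — transitions are by far the commonest HVRI mutation and source
tables typically print positions alone — while explicit alleles
compare exactly; a shared position with one side allele-unknown counts
as a match. The study tables abbreviate positions by dropping the
leading "16", so any parsed token below 16000 is expanded by +16000.

Mutational distance is the weighted symmetric difference of site sets
(default weight 1 per position). It is a true metric, which the test
suite verifies exhaustively over every motif in the packaged tables.

## Consensus and authentication

Cloned amplification products are resolved column by column,
independently per position (no phasing across clones): the unique
majority base is called when its support reaches `min_support`,
otherwise the column is `N`. A tie is always `N`, never an arbitrary
pick. `min_support` defaults to 0.75 — stricter than a bare majority,
chosen so that up to two damaged clones out of ten cannot shift a call.
Minority C→T and G→A cells relative to the consensus are reported as
deamination damage flags; all other minority cells as putative
polymerase error. Clone counts outside the routine 8–12 range produce
a warning, not an error.

A sample authenticates when motifs from at least two independent
amplifications agree exactly; any disagreement produces an
inconsistency report naming the positions and excludes the sample
downstream. A lone amplification is an authentication *failure status*,
not an exception, so cohorts with partial replication degrade
gracefully. Jumping-PCR chimeras receive no special detector: a
chimeric amplification disagrees with its replicate and is caught
there, which mirrors how replication-based protocols actually defend
against this artifact. `N` columns are excluded when a consensus is
converted to a motif — an unresolvable position is not evidence of a
variant.

## Screening

Elimination screening flags a sample when its motif lies within
`max_mismatch` mutations of any database entry. The default is 0
(exact identity): "similarity" thresholds in the source material are
unquantified, exact identity reproduces the documented 23→20 outcome
when contaminants are true carry-overs, and the knob is exposed for
sensitivity analysis. Widening the threshold can only grow the flagged
set (tested property). The three reconstructed contaminants in the
fixture copy flagged database entries from two people with one person
duplicated; which two people carried over is not recorded in the
source, so the choice is an argument of the fixture builder.

The amplicon-length check computes per-length success rates and
verdicts true iff rates are non-increasing in length — degraded
endogenous template amplifies short products preferentially, so a
violation hints at modern contamination. Sex concordance compares
amelogenin calls with morphology only where both exist.

## Classification

The marker panel is data (JSON), not code. Each marker carries its
coordinate, defining (derived) allele, assay type, diagnostic product
lengths for APLP/deletion assays, and the haplogroup it implies plus
that haplogroup's parent, so markers form a tree. Band-length pairs
map first-listed allele to first-listed length (10400T→149 bp,
10400C→142 bp; the 9-bp COII/tRNA-Lys deletion shortens its product,
121→112 bp). Observing both diagnostic lengths of one mtDNA marker is
reported as a mixture — a single mitochondrial genome cannot carry
both, so the pattern signals contamination.

Classification walks the tree root-down, descending while the defining
allele is observed. The label is the deepest derived haplogroup; if
any tested child of that node is ancestral the label is starred
(`M*`, `R*`), matching standard star-haplogroup usage. A missing call
at a marker that would be needed to descend further yields an
`incomplete` status naming the marker rather than a silent label.
Two refinements rest on the HVRI motif rather than a coding marker,
and both are surfaced as explicit advisories: K is reported when the
12308G (UK) marker is derived and the motif carries the K-typical
16224/16311 sites (no printed coding marker separates U from K), and
TJ — which appears in exclusion lists without a stated marker — is
noted as a possibility on `R*` calls whose motif carries 16126.
Polarity follows the panel as printed (e.g. HV defined by 14766T);
`defining_allele` in the JSON is the override hook where other
polarity conventions are preferred. One printed inconsistency exists
for the Y marker M173 (text says derived A, a primer table says C);
the panel uses A.

The Y cascade M89→M9→M45→M173→M198 stops at the first ancestral
marker; a sample ancestral at M89 is labelled `pre-F*`. Y
classification of a female-typed sample raises a consistency error.
Amelogenin sexing maps the shorter product (115 bp) to X and the
longer (121 bp) to Y — the source does not state the mapping, and it
is configurable; a Y-only pattern is called male with an X-dropout
warning rather than discarded, since allelic dropout is common in
degraded extracts.

## Median-joining networks

Construction: (i) compute the ε-relaxed minimum spanning network of
the current node set — an edge is feasible iff its weighted distance is
within ε of the minimax (Kruskal merge) level of its endpoints; at ε=0
this is exactly the union of all minimum spanning trees; (ii) for every
linked pair of edges u–v, u–w, propose the majority-consensus median of
{u, v, w} (a position is kept iff carried by ≥2 of the three; an
explicit allele survives only if all carriers agree); (iii) accept new
medians whose connection cost d(u,m)+d(v,m)+d(w,m) is within ε of the
round's minimum; (iv) prune unsampled nodes of spanning degree ≤ 2
(they lie on geodesics and add nothing), remembering discarded medians
so the loop cannot oscillate; repeat to a fixed point.

Defaults: ε = 0 (the feature is named in the source protocol but its
value is unrecorded, and 0 gives the most reduced network); weights
default to 1 for all HVRI positions, with a per-position map for
up-weighting coding-region SNPs, again because the source names the
scheme but not the values. Because those settings are unrecorded, the
exact median-vector set of the published network figure is *not* a
reproducible target; the network module is therefore validated by
properties — all observed haplotypes present with their frequencies,
connectivity, spanning cost never above the observed-haplotype MST
cost (medians are Steiner points), exact recovery of mutation trees
when every node is sampled and ε=0, and input-order invariance via
canonical (position-sorted) tie-breaking. Poly-C length variants
(16182–16193) can be masked before network building, off by default,
matching the convention of excluding length-difference mutations from
network analyses.

The center finder returns the node minimising frequency-weighted total
graph distance to observed nodes, with canonical-order tie-break. On a
frequency-balanced star this is the hub; note that with strongly
unbalanced leaf frequencies the weighted criterion can prefer the
heaviest leaf — the brute-force definition, not a heuristic, decides.

## Synthetic generator

`SimConfig` defaults encode the documented study conditions: 8–12
clones per amplification, 2 independent amplifications per sample, 20
samples. Noise defaults were chosen once as field-realistic for
cloned Sanger reads of well-preserved arid-site material:
`damage_rate` 0.01/base (deamination misreads in clones of degraded
but well-preserved template), `error_rate` 0.002/base (Taq
misincorporation accumulated over ~40 cycles), `jumping_rate`
0.02/clone. Damage is strand-oriented: each clone deaminates either
its Cs (C→T) or its Gs (G→A), orientation a fair coin per clone.
Jumping PCR splices another sample's template at a uniform breakpoint.
All comparisons downstream are positional, so templates are built over
a fixed arbitrary synthetic reference rather than the real rCRS;
allele-unknown motif sites are realised as transitions of the
reference base.

The generator does **not** emulate: realistic fragment-length
distributions, base-quality information, sequence-context-dependent
damage (elevated terminal deamination), heteroplasmy, or nuclear
inserts (NUMTs). Passing tests therefore demonstrate the pipeline's
logic under the stated noise model, not performance on real
chromatograms.

The packaged fixture rebuilds the complete study input from the
transcribed tables: the 20-individual cohort, the 19-entry (12
excavators + 7 laboratory researchers) elimination database, the
marker panel, and the 23-sequence screen input. Per-marker
observations for each individual are generated from the reported
haplogroup via the panel (derived along the root-to-label chain,
ancestral at every tested off-chain marker), so the classifiers
genuinely re-derive the haplogroup column rather than reading it.

One transcription note: the source's amplification-efficiency ordering
mentions a 399-bp amplicon alongside the 235- and 209-bp HVRI
products, but the primer table lists only the latter two; the 399-bp
product is presumed to span the full HVRI region and is not added to
the panel.

## Problem sizes and numerics

Everything runs at desk scale: the cohort is 20 samples, networks have
≤ ~15 nodes, property tests use ≤ 8-leaf trees, 100-clone or
100-lineage simulations, and 200 attempts per amplicon length; the
whole suite completes in a few seconds. Floating-point tolerances:
distances on unit/weighted integers are exact; MSN feasibility and
median acceptance use a 1e-12 slack; network validation checks edge
weights to 1e-9. Degenerate inputs are defined rather than accidental:
empty motif = reference-identical; empty haplotype table, empty clone
set and a sequencing marker passed to the band caller raise errors;
an empty elimination database retains everything with a warning.

## Known limitations

* Star labels depend on the panel's marker set: `R*` means "derived at
  R, ancestral at the tested subclades", not a claim about clades the
  panel does not cover.
* The consensus caller is a majority rule, not a likelihood model; it
  has no notion of per-base quality and treats clones as independent.
* Contamination screening is identity/threshold-based; it cannot
  estimate a contamination fraction.
* The median-joining implementation treats sites as binary
  presence/absence; recurrent or multi-state mutations at one position
  are collapsed.
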