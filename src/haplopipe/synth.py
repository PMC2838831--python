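"""Synthetic data emulating the study's inputs, plus the packaged fixture.

Two kinds of input are generated:

* *noisy clone sets* — each sample's haplotype is turned into a template
  sequence over the HVRI window and "cloned" with the classic
  ancient-DNA error modes: cytosine-deamination damage (C→T on one
  strand orientation, G→A on the other, orientation drawn per clone),
  polymerase misincorporation, and jumping-PCR chimeras that recombine
  two templates at a uniform breakpoint;
* *star-shaped haplotype populations* — lineages derived independently
  from an ancestral motif by random site toggles, the geometry a
  median-joining network should recover as a star.

The packaged study fixture (20-individual cohort, 19-entry elimination
database, marker panel, 23-sequence screen input) is rebuilt here from
the transcribed tables, with per-marker observations generated to match
each individual's reported haplogroup so the classifiers can be run on
it end to end.

All comparisons downstream are positional, so templates are built over
an arbitrary fixed synthetic reference rather than the real rCRS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import DiagnosticMarker, MarkerPanel, PanelBundle, load_panel
from .consensus import CloneSet
from .core import (
    DEFAULT_WINDOW,
    EliminationDB,
    HaplotypeMotif,
    SampleRecord,
    VariantSite,
    read_elimination_db,
    read_sample_table,
)

_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_REFERENCE_SEED = 2003  # fixes the synthetic reference, independent of run seeds


@dataclass
class SimConfig:
    """Study-condition defaults for the clone simulator.

    ``clones_per_amplification`` and ``amplifications_per_sample``
    mirror the reported protocol (8-12 clones from two independent
    amplifications).  ``damage_rate`` is the per-base probability of a
    deamination misread in one clone, ``error_rate`` the per-base
    polymerase misincorporation probability, ``jumping_rate`` the
    per-clone probability of a chimeric crossover with another template.
    """

    seed: int = 0
    n_samples: int = 20
    clones_per_amplification: tuple[int, int] = (8, 12)
    amplifications_per_sample: int = 2
    damage_rate: float = 0.01
    error_rate: float = 0.002
    jumping_rate: float = 0.02
    contaminant_count: int = 3
    window: tuple[int, int] = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        for name in ("damage_rate", "error_rate", "jumping_rate"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name}={p} outside [0, 1]")


def synthetic_reference(window: tuple[int, int] = DEFAULT_WINDOW) -> str:
    """Deterministic pseudo-random reference sequence over the window."""
    rng = np.random.default_rng(_REFERENCE_SEED)
    span = window[1] - window[0] + 1
    return "".join(rng.choice(_BASES, size=span))


def template_from_motif(motif: HaplotypeMotif, reference: str | None = None) -> str:
    """Apply a motif to the reference: explicit alleles verbatim,
    allele-unknown sites as transitions of the reference base."""
    ref = reference if reference is not None else synthetic_reference(motif.window)
    seq = list(ref)
    low = motif.window[0]
    for site in motif.sites:
        if site.kind != "substitution":
            continue
        idx = site.position - low
        seq[idx] = site.allele if site.allele else _TRANSITION[seq[idx]]
    return "".join(seq)


def generate_clone_sets(
    templates: Mapping[str, HaplotypeMotif],
    cfg: SimConfig,
    discordant_templates: Mapping[str, HaplotypeMotif] | None = None,
) -> list[CloneSet]:
    """Simulate cloned amplification products for each sample.

    ``discordant_templates`` optionally substitutes a different template
    for a sample's *last* amplification, to emulate irreproducible
    results that replicate merging must catch.
    """
    rng = np.random.default_rng(cfg.seed)
    reference = synthetic_reference(cfg.window)
    discordant_templates = discordant_templates or {}
    sample_ids = sorted(templates)
    sequences = {sid: template_from_motif(templates[sid], reference) for sid in sample_ids}
    out: list[CloneSet] = []
    lo, hi = cfg.clones_per_amplification
    for sid in sample_ids:
        for amp in range(1, cfg.amplifications_per_sample + 1):
            template = sequences[sid]
            if amp == cfg.amplifications_per_sample and sid in discordant_templates:
                template = template_from_motif(discordant_templates[sid], reference)
            n_clones = int(rng.integers(lo, hi + 1))
            clones = []
            for _ in range(n_clones):
                clones.append(
                    _noisy_clone(template, sid, sequences, sample_ids, cfg, rng)
                )
            out.append(CloneSet(sample_id=sid, amplification_id=f"A{amp}",
                                clones=clones, window=cfg.window))
    return out


def _noisy_clone(template: str, sid: str, sequences: Mapping[str, str],
                 sample_ids: Sequence[str], cfg: SimConfig,
                 rng: np.random.Generator) -> str:
    seq = template
    # jumping-PCR chimera: prefix from own template, suffix from another's
    if len(sample_ids) > 1 and rng.random() < cfg.jumping_rate:
        others = [s for s in sample_ids if s != sid]
        partner = sequences[others[int(rng.integers(len(others)))]]
        breakpoint_ = int(rng.integers(1, len(seq)))
        seq = seq[:breakpoint_] + partner[breakpoint_:]
    chars = np.array(list(seq))
    # deamination: C->T on one strand orientation, G->A on the other
    if cfg.damage_rate > 0:
        target = "C" if rng.random() < 0.5 else "G"
        product = "T" if target == "C" else "A"
        hit = (chars == target) & (rng.random(len(chars)) < cfg.damage_rate)
        chars[hit] = product
    # polymerase misincorporation: uniform among the three other bases
    if cfg.error_rate > 0:
        err = rng.random(len(chars)) < cfg.error_rate
        for idx in np.nonzero(err)[0]:
            options = [b for b in "ACGT" if b != chars[idx]]
            chars[idx] = options[int(rng.integers(3))]
    return "".join(chars)


def generate_star_population(
    ancestral: HaplotypeMotif,
    n: int,
    mutations_per_lineage: int | Callable[[np.random.Generator], int] = 1,
    seed: int = 0,
    positions: Sequence[int] | None = None,
) -> dict[HaplotypeMotif, int]:
    """Derive ``n`` lineages from an ancestral motif by random site toggles.

    ``mutations_per_lineage`` is either a fixed count or a sampler
    (e.g. ``lambda rng: rng.poisson(0.8)``).  With at most one mutation
    per lineage the resulting median-joining network is a star centred
    on the ancestral motif.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    window = ancestral.window
    pool = list(positions) if positions is not None else list(range(window[0], window[1] + 1))
    counts: dict[HaplotypeMotif, int] = {}
    for _ in range(n):
        k = (mutations_per_lineage(rng) if callable(mutations_per_lineage)
             else int(mutations_per_lineage))
        current = set(ancestral.positions)
        for pos in rng.choice(pool, size=min(k, len(pool)), replace=False):
            pos = int(pos)
            current.symmetric_difference_update({pos})
        m = HaplotypeMotif(tuple(VariantSite(p) for p in sorted(current)), window)
        counts[m] = counts.get(m, 0) + 1
    return counts


def simulate_length_efficiency(
    success_prob: Mapping[int, float],
    n_per_length: int,
    seed: int = 0,
) -> list[tuple[str, int, bool]]:
    """Per-amplicon PCR attempts with a stated success probability per length."""
    rng = np.random.default_rng(seed)
    attempts = []
    for length in sorted(success_prob):
        p = success_prob[length]
        for i in range(n_per_length):
            attempts.append((f"s{i}", length, bool(rng.random() < p)))
    return attempts


# ---------------------------------------------------------------------------
# The packaged study fixture
# ---------------------------------------------------------------------------

@dataclass
class StudyFixture:
    """The transcribed study dataset, ready for every pipeline stage.

    ``samples`` carry marker observations generated to match each
    individual's reported haplogroup; their output fields are empty so
    the classifiers genuinely have to run.  ``expected`` keeps the
    reported per-sample calls for comparison.  ``screen_input`` is the
    cohort plus ``contaminant_count`` modern carry-over sequences copied
    from flagged elimination-database entries.
    """

    samples: list[SampleRecord]
    elimination_db: EliminationDB
    panel: PanelBundle
    screen_input: list[SampleRecord]
    expected: pd.DataFrame
    contaminant_ids: list[str] = field(default_factory=list)


def _data_path(name: str):
    return resources.files("haplopipe.data").joinpath(name)


def _path_to_label(panel: MarkerPanel, label: str) -> list[DiagnosticMarker]:
    """Root-to-target chain of markers whose derived state implies ``label``."""
    starred = label.endswith("*")
    core_label = label[:-1] if starred else label
    target = None
    for mk in panel.markers.values():
        if mk.implies == core_label:
            target = mk
            break
        if mk.motif_refine and mk.motif_refine.get("label") == core_label:
            target = mk
            break
    if target is None:
        if core_label == panel.root_label:
            return []
        raise KeyError(f"no marker chain reaches haplogroup {label!r}")
    chain = [target]
    while chain[0].parent is not None:
        parent_marker = panel.marker_for(chain[0].parent)
        chain.insert(0, parent_marker)
    return chain


def marker_calls_for_label(panel: MarkerPanel, label: str) -> dict[str, str]:
    """Observed alleles that make the tree walk end at ``label``.

    Markers on the root-to-label chain read derived; every tested
    sibling or child off the chain reads ancestral.
    """
    chain = _path_to_label(panel, label)
    on_path = {mk.name for mk in chain}
    calls = {mk.name: mk.defining_allele for mk in chain}
    path_labels = {panel.root_label} | {mk.implies for mk in chain}
    for node_label in path_labels:
        for child in panel.children_of(node_label):
            if child.name not in on_path:
                calls[child.name] = child.ancestral_allele or "ancestral"
    return calls


def observed_value_for(marker: DiagnosticMarker, allele: str) -> str:
    """Raw observation string for an allele: band length for band assays."""
    if marker.assay in ("APLP", "deletion-length") and allele in (marker.band_lengths or {}):
        return str(marker.band_lengths[allele])
    return allele


def build_study_fixture(
    contaminant_people: tuple[str, str] = ("E4", "L4"),
    duplicated_person: str = "E4",
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> StudyFixture:
    """Rebuild the complete study input from the packaged tables.

    The three contaminant sequences in the screen input are exact copies
    of flagged elimination-database haplotypes from two people, one of
    them duplicated; which two carried over is not recorded in the
    source, so the choice is an argument.
    """
    panel = load_panel()
    with resources.as_file(_data_path("xiaohe_cohort.tsv")) as p:
        cohort = read_sample_table(p, window)
    with resources.as_file(_data_path("investigator_haplotypes.tsv")) as p:
        db = read_elimination_db(p, window)

    expected_rows = []
    for rec in cohort:
        expected_rows.append(
            {
                "sample_id": rec.sample_id,
                "haplotype": str(rec.motif),
                "mtdna_hg": rec.mtdna_haplogroup,
                "y_hg": rec.y_haplogroup,
                "morph_sex": rec.morphological_sex,
                "mol_sex": rec.molecular_sex,
            }
        )
    expected = pd.DataFrame(expected_rows)

    samples: list[SampleRecord] = []
    for rec, row in zip(cohort, expected_rows):
        s = SampleRecord(
            sample_id=rec.sample_id,
            motif=rec.motif,
            morphological_sex=rec.morphological_sex,
            replicated=rec.replicated,
        )
        s.coding_calls = marker_calls_for_label(panel.mtdna, row["mtdna_hg"])
        if row["y_hg"]:
            s.y_calls = marker_calls_for_label(panel.y, row["y_hg"])
        if row["mol_sex"] == "male":
            s.amg_bands = frozenset((panel.amg.x_length, panel.amg.y_length))
        elif row["mol_sex"] == "female":
            s.amg_bands = frozenset((panel.amg.x_length,))
        samples.append(s)

    by_person = {e.person_id: e for e in db.entries}
    order = [duplicated_person] + [p for p in contaminant_people if p != duplicated_person]
    motifs = [by_person[duplicated_person].motif] + [by_person[p].motif for p in order[1:]]
    motifs.insert(1, by_person[duplicated_person].motif)  # the duplicated carry-over
    contaminants = []
    for i, m in enumerate(motifs[:3], 1):
        contaminants.append(SampleRecord(sample_id=f"contam-{i}", motif=m))
    screen_input = samples + contaminants

    return StudyFixture(
        samples=samples,
        elimination_db=db,
        panel=panel,
        screen_input=screen_input,
        expected=expected,
        contaminant_ids=[c.sample_id for c in contaminants],
    )


def fixture_observations_frame(fixture: StudyFixture) -> pd.DataFrame:
    """Marker observations TSV rows (band lengths for band assays)."""
    rows = []
    for s in fixture.samples:
        for name, allele in sorted(s.coding_calls.items()):
            mk = fixture.panel.mtdna.markers[name]
            rows.append({"sample_id": s.sample_id, "marker": name,
                         "observed": observed_value_for(mk, allele)})
        for name, allele in sorted(s.y_calls.items()):
            mk = fixture.panel.y.markers[name]
            rows.append({"sample_id": s.sample_id, "marker": name,
                         "observed": observed_value_for(mk, allele)})
    return pd.DataFrame(rows, columns=["sample_id", "marker", "observed"])
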