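"""Hierarchical haplogroup assignment, APLP band calling and AMG sexing.

The marker panel is data, not code: a JSON document describing each
diagnostic marker (coordinate, defining allele, assay type, diagnostic
product lengths for APLP / deletion assays) and its parent haplogroup,
so the markers form a tree.  Classification walks the tree root-down,
descending while the defining allele is observed (derived) and stopping
at the deepest derived node.  A node whose tested children are all
ancestral gets a star suffix (e.g. ``R*``, ``M*``): membership in the
macrohaplogroup with every tested subclade excluded.

Allele polarity follows the assay definitions as printed in the source
panel (e.g. HV defined by 14766T); ``defining_allele`` in the JSON is
the override hook if a different polarity convention is needed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from .core import HaplotypeMotif, SampleRecord, contains_motif, motif


class PanelError(ValueError):
    """The marker panel is structurally invalid."""


class AssayError(ValueError):
    """An observation is impossible for the assay (e.g. unknown band)."""


class ConsistencyError(ValueError):
    """Observations contradict each other (e.g. Y calls on a female)."""


@dataclass(frozen=True)
class DiagnosticMarker:
    """One diagnostic site of the haplogroup tree."""

    name: str
    defining_allele: str
    implies: str
    parent: str | None
    assay: str = "sequencing"  # sequencing | APLP | deletion-length
    position: int | None = None
    ancestral_allele: str | None = None
    band_lengths: dict[str, int] | None = None
    expected_motif: tuple[int, ...] = ()
    motif_refine: dict | None = None

    def __post_init__(self) -> None:
        if self.implies == self.parent:
            raise PanelError(f"marker {self.name}: implies == parent")
        if self.assay in ("APLP", "deletion-length"):
            if not self.band_lengths or len(set(self.band_lengths.values())) < 2:
                raise PanelError(
                    f"marker {self.name}: {self.assay} assay needs >=2 distinct band lengths"
                )


class MarkerPanel:
    """A tree of diagnostic markers, keyed by the haplogroup each implies."""

    def __init__(self, markers: Iterable[DiagnosticMarker], root_label: str = "root",
                 motif_advisories: list[dict] | None = None):
        self.markers = {m.name: m for m in markers}
        self.root_label = root_label
        self.motif_advisories = motif_advisories or []
        labels = {m.implies for m in self.markers.values()}
        self._children: dict[str | None, list[DiagnosticMarker]] = {}
        for m in self.markers.values():
            if m.parent is not None and m.parent not in labels:
                raise PanelError(f"marker {m.name}: unknown parent {m.parent!r}")
            self._children.setdefault(m.parent, []).append(m)
        self._assert_tree()

    def _assert_tree(self) -> None:
        seen: set[str] = set()
        stack = [None]
        while stack:
            label = stack.pop()
            for m in self._children.get(label, []):
                if m.name in seen:
                    raise PanelError(f"marker {m.name} reachable twice; not a tree")
                seen.add(m.name)
                stack.append(m.implies)
        if seen != set(self.markers):
            orphans = set(self.markers) - seen
            raise PanelError(f"markers unreachable from root: {sorted(orphans)}")

    def children_of(self, label: str | None) -> list[DiagnosticMarker]:
        key = None if label == self.root_label else label
        return self._children.get(key, [])

    def marker_for(self, label: str) -> DiagnosticMarker | None:
        for m in self.markers.values():
            if m.implies == label:
                return m
        return None


@dataclass
class AmelogeninAssay:
    """X/Y product lengths of the amelogenin sexing amplicon."""

    x_length: int = 115
    y_length: int = 121

    @property
    def registered(self) -> frozenset[int]:
        return frozenset((self.x_length, self.y_length))


@dataclass
class PanelBundle:
    mtdna: MarkerPanel
    y: MarkerPanel
    amg: AmelogeninAssay


def load_panel(path: str | Path | None = None) -> PanelBundle:
    """Load a panel JSON; default is the packaged study panel."""
    if path is None:
        text = resources.files("haplopipe.data").joinpath("marker_panel.json").read_text()
        doc = json.loads(text)
    else:
        with open(path) as fh:
            doc = json.load(fh)
    return PanelBundle(
        mtdna=_panel_from_dict(doc["mtdna"]),
        y=_panel_from_dict(doc["y"]),
        amg=_amg_from_dict(doc.get("amg", {})),
    )


def _panel_from_dict(d: dict) -> MarkerPanel:
    markers = []
    for m in d["markers"]:
        markers.append(
            DiagnosticMarker(
                name=m["name"],
                defining_allele=str(m["defining_allele"]),
                implies=m["implies"],
                parent=m.get("parent"),
                assay=m.get("assay", "sequencing"),
                position=m.get("position"),
                ancestral_allele=m.get("ancestral_allele"),
                band_lengths={k: int(v) for k, v in m["band_lengths"].items()}
                if m.get("band_lengths")
                else None,
                expected_motif=tuple(m.get("expected_motif", ())),
                motif_refine=m.get("motif_refine"),
            )
        )
    return MarkerPanel(markers, root_label=d.get("root_label", "root"),
                       motif_advisories=d.get("motif_advisories"))


def _amg_from_dict(d: dict) -> AmelogeninAssay:
    bands = d.get("band_lengths")
    if not bands:
        return AmelogeninAssay()
    by_chrom = {chrom: int(length) for length, chrom in bands.items()}
    return AmelogeninAssay(x_length=by_chrom["X"], y_length=by_chrom["Y"])


# ---------------------------------------------------------------------------
# Band-length genotyping (APLP / deletion assays)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BandCall:
    allele: str | None
    status: str  # ok | no-call | mixture


def call_allele_from_bands(marker: DiagnosticMarker, observed_lengths: Iterable[int]) -> BandCall:
    """Translate observed product lengths into an allele call.

    Both alleles observed at once is flagged as a mixture: a single
    mtDNA cannot carry both, so this pattern signals contamination.
    """
    if marker.assay not in ("APLP", "deletion-length"):
        raise AssayError(f"marker {marker.name} is a {marker.assay} assay, not band-based")
    observed = {int(x) for x in observed_lengths}
    matched = sorted(a for a, length in marker.band_lengths.items() if length in observed)
    if not matched:
        return BandCall(None, "no-call")
    if len(matched) > 1:
        return BandCall(None, "mixture")
    return BandCall(matched[0], "ok")


# ---------------------------------------------------------------------------
# Haplogroup calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PathStep:
    marker: str
    observed: str
    derived: bool
    implies: str


@dataclass
class HaplogroupCall:
    label: str
    path: list[PathStep] = field(default_factory=list)
    terminal: bool = True
    advisories: list[str] = field(default_factory=list)
    status: str = "ok"  # ok | incomplete | conflict
    missing_marker: str | None = None

    def descends_from(self, label: str) -> bool:
        """True if the call passed through (or ended at) haplogroup ``label``."""
        if self.label == label or self.label == label + "*":
            return True
        return any(step.derived and step.implies == label for step in self.path)


def _is_derived(marker: DiagnosticMarker, observed: str) -> bool:
    obs = str(observed).strip()
    if obs.lower() in ("ancestral", "anc"):
        return False
    return obs.upper() == marker.defining_allele.upper()


def _walk(panel: MarkerPanel, calls: Mapping[str, str],
          sample_motif: HaplotypeMotif | None) -> HaplogroupCall:
    label = panel.root_label
    last_marker: DiagnosticMarker | None = None
    path: list[PathStep] = []
    while True:
        children = panel.children_of(label)
        derived_markers: list[DiagnosticMarker] = []
        untested: list[DiagnosticMarker] = []
        for mk in children:
            obs = calls.get(mk.name)
            if obs is None or str(obs).strip() in ("", "-"):
                untested.append(mk)
                continue
            derived = _is_derived(mk, str(obs))
            path.append(PathStep(mk.name, str(obs), derived, mk.implies))
            if derived:
                derived_markers.append(mk)
        if len(derived_markers) > 1:
            names = [m.name for m in derived_markers]
            return HaplogroupCall(label=label, path=path, terminal=False,
                                  status="conflict",
                                  advisories=[f"conflicting derived markers: {names}"])
        if derived_markers:
            last_marker = derived_markers[0]
            label = last_marker.implies
            continue
        # no child derived: stop here
        terminal = not children
        call = HaplogroupCall(label=label if terminal else label + "*",
                              path=path, terminal=terminal)
        if untested:
            call.status = "incomplete"
            call.missing_marker = untested[0].name
        break

    _apply_motif_annotations(call, last_marker, panel, sample_motif)
    return call


def _apply_motif_annotations(call: HaplogroupCall, last_marker: DiagnosticMarker | None,
                             panel: MarkerPanel, sample_motif: HaplotypeMotif | None) -> None:
    if sample_motif is None or last_marker is None:
        return
    window = sample_motif.window
    if last_marker.motif_refine and call.terminal:
        req = motif(last_marker.motif_refine["requires"], window)
        if contains_motif(sample_motif, req):
            call.advisories.append(
                f"label refined {call.label} -> {last_marker.motif_refine['label']} "
                f"by HVRI motif {req} (no coding marker distinguishes them)"
            )
            call.label = last_marker.motif_refine["label"]
        else:
            call.advisories.append(
                f"HVRI motif does not support refinement to {last_marker.motif_refine['label']}"
            )
    if last_marker.expected_motif:
        exp = motif(last_marker.expected_motif, window)
        if contains_motif(sample_motif, exp):
            call.advisories.append(f"HVRI motif consistent with {last_marker.implies} ({exp})")
        else:
            call.advisories.append(
                f"HVRI motif lacks sites expected for {last_marker.implies} ({exp})"
            )
    # purely motif-based side notes (clades with no printed coding marker)
    for adv in panel.motif_advisories:
        if call.label == adv["parent"] + "*":
            req = motif(adv["requires"], window)
            if contains_motif(sample_motif, req):
                call.advisories.append(
                    f"HVRI motif would also be consistent with {adv['label']} (untested)"
                )


def classify_mtdna(sample: SampleRecord, panel: MarkerPanel) -> HaplogroupCall:
    """Assign an mtDNA haplogroup from diagnostic coding-region calls.

    Requires at least the two macrohaplogroup root markers (10400 for M,
    12705 for R) to be observed; the HVRI motif is only used for
    advisories and for refinements the coding panel cannot resolve.
    """
    call = _walk(panel, sample.coding_calls, sample.motif)
    if call.status == "ok":
        sample.mtdna_haplogroup = call.label
    return call


def classify_y(sample: SampleRecord, panel: MarkerPanel) -> HaplogroupCall:
    """Walk the Y-SNP cascade (M89 -> M9 -> M45 -> M173 -> M198).

    The cascade stops at the first ancestral marker; the label is the
    deepest derived haplogroup, starred when a tested child is ancestral.
    """
    if sample.molecular_sex == "female":
        raise ConsistencyError(
            f"sample {sample.sample_id}: Y haplogroup requested for a female-typed sample"
        )
    call = _walk(panel, sample.y_calls, None)
    if call.status == "ok":
        sample.y_haplogroup = call.label
    return call


# ---------------------------------------------------------------------------
# Molecular sexing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SexCall:
    sex: str  # male | female | no-call
    note: str = ""


def call_sex(amg_bands: Iterable[int], assay: AmelogeninAssay) -> SexCall:
    """Sex an individual from amelogenin amplicon lengths.

    Both X and Y products present -> male; the X product alone ->
    female; the Y product alone is still male, but flagged, since X
    allelic dropout (common in degraded templates) is the likely cause;
    no registered product -> no-call.
    """
    bands = {int(b) for b in amg_bands}
    unregistered = bands - assay.registered
    if unregistered:
        raise AssayError(f"unregistered AMG band lengths: {sorted(unregistered)}")
    has_x = assay.x_length in bands
    has_y = assay.y_length in bands
    if has_x and has_y:
        return SexCall("male")
    if has_x:
        return SexCall("female")
    if has_y:
        return SexCall("male", note="X-band dropout: Y product only")
    return SexCall("no-call")


# ---------------------------------------------------------------------------
# Observation ingestion
# ---------------------------------------------------------------------------

def observations_to_calls(raw: Mapping[str, str], panel: MarkerPanel) -> dict[str, str]:
    """Convert raw per-marker observations into allele calls.

    Band-based assays accept comma-separated product lengths ("149" or
    "149,142"); sequencing assays take the allele string verbatim.
    Mixtures and no-calls propagate as such.
    """
    calls: dict[str, str] = {}
    for name, value in raw.items():
        mk = panel.markers.get(name)
        value = str(value).strip()
        if mk is None or not value or value == "-":
            continue
        if mk.assay in ("APLP", "deletion-length") and value.replace(",", "").replace(" ", "").isdigit():
            bc = call_allele_from_bands(mk, (int(tok) for tok in value.replace(",", " ").split()))
            if bc.status == "ok":
                calls[name] = bc.allele
            elif bc.status == "mixture":
                calls[name] = "mixture"
        else:
            calls[name] = value
    return calls


def read_observations(path: str | Path) -> dict[str, dict[str, str]]:
    """Read a marker-observation TSV (sample_id, marker, observed)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out: dict[str, dict[str, str]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["sample_id"]), {})[str(row["marker"])] = str(row["observed"])
    return out
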