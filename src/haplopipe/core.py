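"""Haplotype-motif algebra and table I/O for mtDNA HVRI data.

An HVRI *haplotype motif* is the set of positions (optionally with
alleles) at which a sequence differs from the revised Cambridge
Reference Sequence (rCRS) inside a stated window.  Motifs are the atom
of every downstream comparison: contamination screening, haplogroup
advisories and network construction all operate on them.

Coordinates are 1-based rCRS positions.  The default comparison window
is the classic HVRI amplicon, positions 16035-16409 inclusive.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Default HVRI window (inclusive, rCRS coordinates).
DEFAULT_WINDOW: tuple[int, int] = (16035, 16409)

#: Poly-cytosine stretch around 16184-16193 whose length variants are
#: conventionally excluded from network analyses.
LENGTH_VARIANT_REGION: tuple[int, int] = (16182, 16193)

_BASES = frozenset("ACGT")


class MotifParseError(ValueError):
    """A motif token could not be interpreted."""


class CoordinateError(ValueError):
    """A position falls outside the comparison window."""


class WindowMismatchError(ValueError):
    """Two motifs with different windows were compared."""


@dataclass(frozen=True, order=True)
class VariantSite:
    """One difference from the rCRS.

    ``allele`` is the observed base for substitutions, an event tag
    (e.g. ``"del9"``) for deletions, or ``None`` when the source only
    reports the position (transition implied).
    """

    position: int
    allele: str | None = None
    kind: str = "substitution"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.kind not in ("substitution", "deletion"):
            raise ValueError(f"unknown site kind {self.kind!r}")
        if self.kind == "deletion" and self.allele in _BASES:
            raise ValueError("deletion sites carry an event tag, not a base")
        if self.kind == "substitution" and self.allele is not None:
            object.__setattr__(self, "allele", self.allele.upper())
            if self.allele not in _BASES:
                raise ValueError(f"bad substitution allele {self.allele!r}")

    def matches(self, other: "VariantSite") -> bool:
        """Positional match; explicit alleles must agree, unknown wildcard."""
        if self.position != other.position:
            return False
        if self.allele is None or other.allele is None:
            return True
        return self.allele == other.allele


@dataclass(frozen=True)
class HaplotypeMotif:
    """An ordered set of variant sites within an inclusive window."""

    sites: tuple[VariantSite, ...]
    window: tuple[int, int] = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.sites, key=lambda s: (s.position, s.allele or "")))
        keys = [(s.position, s.allele) for s in ordered]
        if len(set(keys)) != len(keys):
            dupes = [k for k, c in Counter(keys).items() if c > 1]
            raise MotifParseError(f"duplicate sites in motif: {dupes}")
        low, high = self.window
        for s in ordered:
            if s.kind == "substitution" and not (low <= s.position <= high):
                raise CoordinateError(
                    f"position {s.position} outside window [{low}, {high}]"
                )
        object.__setattr__(self, "sites", ordered)

    # -- set-like views -------------------------------------------------
    @property
    def positions(self) -> frozenset[int]:
        return frozenset(s.position for s in self.sites)

    def allele_at(self, position: int) -> str | None:
        for s in self.sites:
            if s.position == position:
                return s.allele
        return None

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)

    def __str__(self) -> str:
        return format_motif(self)

    def _check_window(self, other: "HaplotypeMotif") -> None:
        if self.window != other.window:
            raise WindowMismatchError(
                f"window {self.window} != {other.window}; re-project before comparing"
            )

    def without_region(self, region: tuple[int, int] = LENGTH_VARIANT_REGION) -> "HaplotypeMotif":
        """Drop sites inside ``region`` (poly-C length-variant masking)."""
        low, high = region
        kept = tuple(s for s in self.sites if not (low <= s.position <= high))
        return replace(self, sites=kept)

    def sort_key(self) -> tuple:
        """Canonical ordering key used for deterministic tie-breaks."""
        return tuple((s.position, s.allele or "") for s in self.sites)


def motif(positions: Iterable[int], window: tuple[int, int] = DEFAULT_WINDOW) -> HaplotypeMotif:
    """Convenience constructor from bare positions (allele-unknown)."""
    return HaplotypeMotif(tuple(VariantSite(p) for p in positions), window)


def parse_motif(text: str, window: tuple[int, int] = DEFAULT_WINDOW) -> HaplotypeMotif:
    """Parse a motif string like ``"298-327"`` or ``"16189 16192 16311"``.

    Tokens are integers, hyphen- or whitespace-separated, optionally
    suffixed by an allele letter (``"260T"``).  Tokens below 16000 are
    shorthand with the ``16`` prefix elided and are expanded by +16000.
    An empty string is the CRS-identical (empty) motif.
    """
    text = text.strip()
    if not text or text == "-":
        return HaplotypeMotif((), window)
    tokens = text.replace("-", " ").split()
    sites = []
    for tok in tokens:
        allele: str | None = None
        body = tok
        if body and body[-1].isalpha():
            allele = body[-1].upper()
            body = body[:-1]
        if not body.isdigit():
            raise MotifParseError(f"malformed motif token {tok!r}")
        pos = int(body)
        if pos < 16000:
            pos += 16000
        if not (window[0] <= pos <= window[1]):
            raise CoordinateError(
                f"token {tok!r} -> {pos} outside window {window}"
            )
        sites.append(VariantSite(pos, allele))
    return HaplotypeMotif(tuple(sites), window)


def format_motif(m: HaplotypeMotif) -> str:
    """Canonical hyphen-joined representation (full coordinates)."""
    parts = []
    for s in m.sites:
        suffix = ""
        if s.kind == "deletion":
            suffix = f"({s.allele})"
        elif s.allele is not None:
            suffix = s.allele
        parts.append(f"{s.position}{suffix}")
    return "-".join(parts)


def _differing_positions(a: HaplotypeMotif, b: HaplotypeMotif) -> frozenset[int]:
    """Positions at which the two motifs disagree.

    A position differs when it appears in exactly one motif, or in both
    with conflicting explicit alleles.  A shared position with at least
    one allele-unknown side matches (transitions implied).
    """
    out = set()
    for pos in a.positions | b.positions:
        if pos not in a.positions or pos not in b.positions:
            out.add(pos)
            continue
        aa, ba = a.allele_at(pos), b.allele_at(pos)
        if aa is not None and ba is not None and aa != ba:
            out.add(pos)
    return frozenset(out)


def motif_distance(
    a: HaplotypeMotif,
    b: HaplotypeMotif,
    weights: Mapping[int, float] | None = None,
) -> float:
    """Weighted size of the symmetric difference of the two site sets.

    Each differing position contributes its weight (default 1).  The
    result is a metric over motifs sharing a window: non-negative, zero
    iff equal, symmetric, and it satisfies the triangle inequality.
    """
    a._check_window(b)
    diff = _differing_positions(a, b)
    if weights is None:
        return float(len(diff))
    for pos, w in weights.items():
        if w <= 0:
            raise ValueError(f"weight for position {pos} must be positive")
    return float(sum(weights.get(p, 1.0) for p in diff))


def contains_motif(h: HaplotypeMotif, m: HaplotypeMotif) -> bool:
    """True iff every site of ``m`` occurs in ``h`` (wildcard alleles)."""
    h._check_window(m)
    return all(any(hs.matches(ms) for hs in h.sites) for ms in m.sites)


def tabulate_haplotypes(samples: Sequence["SampleRecord"]) -> "HaplotypeTable":
    """Frequency table of motifs over a cohort."""
    counts: Counter[HaplotypeMotif] = Counter(s.motif for s in samples)
    return HaplotypeTable(dict(counts))


@dataclass
class HaplotypeTable:
    counts: dict[HaplotypeMotif, int]

    @property
    def n_distinct(self) -> int:
        return len(self.counts)

    @property
    def n_samples(self) -> int:
        return sum(self.counts.values())

    def count(self, m: HaplotypeMotif) -> int:
        return self.counts.get(m, 0)

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.counts.items(), key=lambda kv: kv[0].sort_key())
        return pd.DataFrame(
            {"haplotype": [format_motif(m) for m, _ in rows],
             "count": [c for _, c in rows]}
        )


@dataclass
class SampleRecord:
    """One individual: motif, marker observations, sex evidence, calls.

    The three output fields (``mtdna_haplogroup``, ``y_haplogroup``,
    ``molecular_sex``) stay empty until the respective classifier runs.
    """

    sample_id: str
    motif: HaplotypeMotif
    coding_calls: dict[str, str] = field(default_factory=dict)
    y_calls: dict[str, str] = field(default_factory=dict)
    amg_bands: frozenset[int] = frozenset()
    morphological_sex: str = "unknown"  # male | female | unknown
    replicated: bool = False
    mtdna_haplogroup: str = ""
    y_haplogroup: str = ""
    molecular_sex: str = ""  # male | female | no-call | ""


@dataclass(frozen=True)
class EliminationEntry:
    person_id: str
    role: str  # excavator | laboratory
    sex: str
    motif: HaplotypeMotif
    flagged: bool = False


@dataclass
class EliminationDB:
    """Haplotypes of everyone who handled the samples (modern controls)."""

    entries: list[EliminationEntry]

    def __len__(self) -> int:
        return len(self.entries)

    def flagged_entries(self) -> list[EliminationEntry]:
        return [e for e in self.entries if e.flagged]


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

SAMPLE_COLUMNS = ["sample_id", "haplotype", "mtdna_hg", "y_hg", "morph_sex", "mol_sex"]


def read_sample_table(path: str | Path, window: tuple[int, int] = DEFAULT_WINDOW) -> list[SampleRecord]:
    """Read a cohort TSV (sample_id, haplotype, mtdna_hg, y_hg, morph_sex, mol_sex).

    The haplogroup/sex columns are treated as previously reported values
    and stored on the record; '-' or blank means absent.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    records = []
    for _, row in df.iterrows():
        rec = SampleRecord(
            sample_id=str(row["sample_id"]),
            motif=parse_motif(row.get("haplotype", ""), window),
            morphological_sex=_norm_sex(row.get("morph_sex", "")),
            replicated=str(row.get("replicated", "")).lower() in ("1", "true", "yes"),
        )
        rec.mtdna_haplogroup = _dash_to_empty(row.get("mtdna_hg", ""))
        rec.y_haplogroup = _dash_to_empty(row.get("y_hg", ""))
        rec.molecular_sex = _norm_sex(row.get("mol_sex", ""))
        records.append(rec)
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in sample table")
    return records


def write_sample_table(samples: Sequence[SampleRecord], path: str | Path) -> None:
    rows = []
    for s in samples:
        rows.append(
            {
                "sample_id": s.sample_id,
                "haplotype": format_motif(s.motif),
                "mtdna_hg": s.mtdna_haplogroup or "-",
                "y_hg": s.y_haplogroup or "-",
                "morph_sex": s.morphological_sex or "-",
                "mol_sex": s.molecular_sex or "-",
            }
        )
    pd.DataFrame(rows, columns=SAMPLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_elimination_db(path: str | Path, window: tuple[int, int] = DEFAULT_WINDOW) -> EliminationDB:
    """Read an elimination DB TSV (person_id, role, sex, haplotype, flagged)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    entries = []
    for _, row in df.iterrows():
        entries.append(
            EliminationEntry(
                person_id=str(row["person_id"]),
                role=str(row["role"]),
                sex=_norm_sex(row.get("sex", "")),
                motif=parse_motif(row["haplotype"], window),
                flagged=str(row.get("flagged", "")).lower() in ("1", "true", "yes", "*"),
            )
        )
    return EliminationDB(entries)


def read_config(path: str | Path) -> dict:
    """Read a JSON analysis config (window, weights, thresholds...).

    Position-keyed weight maps arrive with string keys from JSON and are
    converted back to integers.
    """
    with open(path) as fh:
        cfg = json.load(fh)
    if "window" in cfg:
        cfg["window"] = tuple(int(x) for x in cfg["window"])
    if "weights" in cfg and cfg["weights"] is not None:
        cfg["weights"] = {int(k): float(v) for k, v in cfg["weights"].items()}
    return cfg


def _norm_sex(value: str) -> str:
    v = str(value).strip().lower()
    if v in ("male", "m"):
        return "male"
    if v in ("female", "f"):
        return "female"
    if v in ("", "-", "na", "unknown", "no-call"):
        return "" if v in ("", "-") else v
    raise ValueError(f"unrecognised sex value {value!r}")


def _dash_to_empty(value: str) -> str:
    v = str(value).strip()
    return "" if v == "-" else v
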