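"""Authenticity battery for ancient-DNA haplotype results.

Three checks, mirroring standard aDNA authentication practice:

* elimination-database screening — every everyone-who-touched-the-bones
  haplotype is compared against every sample motif, and matches (within
  ``max_mismatch`` mutations) are removed as putative contamination;
* amplicon-length vs amplification-efficiency monotonicity — degraded
  endogenous templates amplify short products more readily than long
  ones, so efficiency should fall with amplicon size;
* molecular vs morphological sex concordance — amelogenin sexing must
  agree with the osteological assignment wherever both exist.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .core import EliminationDB, SampleRecord, motif_distance

logger = logging.getLogger(__name__)


@dataclass
class ScreenReport:
    """Partition of the input into retained and contamination-flagged."""

    retained: list[str]
    flagged: list[tuple[str, str, float]]  # (sample_id, person_id, distance)
    max_mismatch: float = 0.0

    @property
    def flagged_samples(self) -> set[str]:
        return {sid for sid, _, _ in self.flagged}

    def validate(self, input_ids: Sequence[str]) -> None:
        retained = set(self.retained)
        flagged = self.flagged_samples
        if retained & flagged:
            raise AssertionError("retained and flagged sets overlap")
        if retained | flagged != set(input_ids):
            raise AssertionError("retained + flagged do not partition the input")


def screen_contamination(
    samples: Sequence[SampleRecord],
    db: EliminationDB,
    max_mismatch: float = 0.0,
) -> ScreenReport:
    """Flag samples whose motif lies within ``max_mismatch`` of any DB entry.

    The default ``max_mismatch=0`` demands exact haplotype identity; the
    knob exists for sensitivity analysis.  Every match at or under the
    threshold is reported with its distance.
    """
    if len(db) == 0:
        logger.warning("elimination database is empty; no samples can be flagged")
    retained: list[str] = []
    flagged: list[tuple[str, str, float]] = []
    for s in samples:
        hits = []
        for entry in db.entries:
            d = motif_distance(s.motif, entry.motif)
            if d <= max_mismatch:
                hits.append((s.sample_id, entry.person_id, d))
        if hits:
            flagged.extend(hits)
            logger.info("sample %s flagged: matches %s", s.sample_id,
                        [(p, d) for _, p, d in hits])
        else:
            retained.append(s.sample_id)
    report = ScreenReport(retained=retained, flagged=flagged, max_mismatch=max_mismatch)
    report.validate([s.sample_id for s in samples])
    return report


def retained_samples(samples: Sequence[SampleRecord], report: ScreenReport) -> list[SampleRecord]:
    keep = set(report.retained)
    return [s for s in samples if s.sample_id in keep]


@dataclass
class LengthEfficiencyReport:
    rates: dict[int, float]  # length (bp) -> success rate, ascending length
    attempts: dict[int, int]
    monotone: bool
    excluded: list[int] = field(default_factory=list)


def check_length_efficiency(
    attempts: Sequence[tuple[str, int, bool]],
) -> LengthEfficiencyReport:
    """Per-amplicon-length success rates and an inverse-correlation verdict.

    ``attempts`` rows are (sample_id, amplicon_length_bp, success).  The
    verdict is true iff success rates are non-increasing in length —
    the signature of amplifying degraded (authentic) rather than intact
    (contaminant) template.
    """
    totals: dict[int, int] = {}
    successes: dict[int, int] = {}
    for _, length, success in attempts:
        totals[length] = totals.get(length, 0) + 1
        successes[length] = successes.get(length, 0) + bool(success)
    excluded = [length for length, n in totals.items() if n == 0]
    for length in excluded:
        logger.warning("amplicon length %d bp has zero attempts; excluded", length)
    lengths = sorted(length for length in totals if totals[length] > 0)
    if len(lengths) < 2:
        raise ValueError("need attempts at >=2 distinct amplicon lengths")
    rates = {length: successes[length] / totals[length] for length in lengths}
    values = [rates[length] for length in lengths]
    monotone = all(a >= b for a, b in zip(values, values[1:]))
    return LengthEfficiencyReport(
        rates=rates, attempts={length: totals[length] for length in lengths},
        monotone=monotone, excluded=sorted(excluded),
    )


@dataclass
class SexConcordanceReport:
    n_compared: int
    n_concordant: int
    conflicts: list[tuple[str, str, str]]  # (sample_id, morphological, molecular)

    @property
    def concordant(self) -> bool:
        return not self.conflicts


def check_sex_concordance(samples: Sequence[SampleRecord]) -> SexConcordanceReport:
    """Compare molecular to morphological sex where both are assigned."""
    compared = 0
    conflicts: list[tuple[str, str, str]] = []
    for s in samples:
        if s.morphological_sex not in ("male", "female"):
            continue
        if s.molecular_sex not in ("male", "female"):
            continue
        compared += 1
        if s.morphological_sex != s.molecular_sex:
            conflicts.append((s.sample_id, s.morphological_sex, s.molecular_sex))
    return SexConcordanceReport(
        n_compared=compared, n_concordant=compared - len(conflicts),
        conflicts=conflicts,
    )


def write_screen_report(report: ScreenReport, path) -> None:
    """TSV: one row per input sample with its status and any DB match."""
    import pandas as pd

    rows = [
        {"sample_id": sid, "status": "flagged", "matched_person": pid, "distance": d}
        for sid, pid, d in report.flagged
    ]
    rows += [
        {"sample_id": sid, "status": "retained", "matched_person": "", "distance": ""}
        for sid in report.retained
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
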