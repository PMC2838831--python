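"""Clone-consensus calling and replicate authentication.

Cloned amplification products from degraded templates carry two noise
modes on top of the endogenous sequence: cytosine-deamination damage
(C→T on one strand, read as G→A on the other) and polymerase
misincorporation.  Sequencing 8-12 clones per amplification lets the
endogenous base be recovered by column-wise majority, with minority
C→T / G→A singletons recorded as damage and everything else as
putative polymerase error.  Authentication then demands that motifs
from independent amplifications of the same individual agree exactly.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import DEFAULT_WINDOW, HaplotypeMotif, VariantSite

logger = logging.getLogger(__name__)

#: Clone counts the protocol considers routine; outside -> warning.
EXPECTED_CLONE_RANGE: tuple[int, int] = (8, 12)

AMBIGUOUS = "N"


@dataclass
class CloneSet:
    """Aligned clone sequences from one amplification of one sample."""

    sample_id: str
    amplification_id: str
    clones: list[str]
    window: tuple[int, int] = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        if not self.clones:
            raise ValueError(f"{self.sample_id}/{self.amplification_id}: empty clone set")
        span = self.window[1] - self.window[0] + 1
        self.clones = [c.upper() for c in self.clones]
        lengths = {len(c) for c in self.clones}
        if lengths != {span}:
            raise ValueError(
                f"{self.sample_id}/{self.amplification_id}: clone lengths {sorted(lengths)} "
                f"!= window span {span}"
            )

    def __len__(self) -> int:
        return len(self.clones)


@dataclass
class ConsensusCall:
    sample_id: str
    amplification_id: str
    consensus: str
    support: list[float]
    damage_flags: list[tuple[int, int, str]] = field(default_factory=list)
    error_flags: list[tuple[int, int, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    window: tuple[int, int] = DEFAULT_WINDOW

    def motif(self, reference: str) -> HaplotypeMotif:
        """Differences of the consensus from a reference over the window.

        Ambiguous (no-call) columns are skipped: a position that could
        not be resolved is not evidence of a variant.
        """
        if len(reference) != len(self.consensus):
            raise ValueError("reference length != consensus length")
        sites = []
        for i, (c, r) in enumerate(zip(self.consensus, reference.upper())):
            if c == AMBIGUOUS or c == r:
                continue
            sites.append(VariantSite(self.window[0] + i, c))
        return HaplotypeMotif(tuple(sites), self.window)


def call_consensus(
    cs: CloneSet,
    min_support: float = 0.75,
    min_clones: int = 3,
    expected_range: tuple[int, int] = EXPECTED_CLONE_RANGE,
) -> ConsensusCall:
    """Column-wise majority consensus over a clone set.

    Per position: the majority base when it is unique and its support
    (fraction of clones) reaches ``min_support``; otherwise an ``N``
    no-call — a tie is never broken arbitrarily.  Minority C→T and G→A
    cells (relative to the consensus base) are damage flags; any other
    minority substitution is a putative polymerase error.
    """
    n = len(cs)
    warnings: list[str] = []
    if n < min_clones:
        warnings.append(f"only {n} clones (<{min_clones}); call is low-confidence")
    if not (expected_range[0] <= n <= expected_range[1]):
        warnings.append(
            f"clone count {n} outside routine range {expected_range[0]}-{expected_range[1]}"
        )
    for w in warnings:
        logger.warning("%s/%s: %s", cs.sample_id, cs.amplification_id, w)

    consensus_chars: list[str] = []
    support: list[float] = []
    for col in range(len(cs.clones[0])):
        counts = Counter(clone[col] for clone in cs.clones)
        (top_base, top_n), = counts.most_common(1)
        tied = [b for b, c in counts.items() if c == top_n]
        frac = top_n / n
        if len(tied) > 1 or frac < min_support:
            consensus_chars.append(AMBIGUOUS)
            support.append(max(counts[b] / n for b in tied))
        else:
            consensus_chars.append(top_base)
            support.append(frac)

    consensus = "".join(consensus_chars)
    damage_flags: list[tuple[int, int, str]] = []
    error_flags: list[tuple[int, int, str]] = []
    for col, cons in enumerate(consensus):
        if cons == AMBIGUOUS:
            continue
        pos = cs.window[0] + col
        for idx, clone in enumerate(cs.clones):
            base = clone[col]
            if base == cons:
                continue
            if (cons, base) in (("C", "T"), ("G", "A")):
                damage_flags.append((pos, idx, f"{cons}>{base}"))
            else:
                error_flags.append((pos, idx, f"{cons}>{base}"))

    return ConsensusCall(
        sample_id=cs.sample_id,
        amplification_id=cs.amplification_id,
        consensus=consensus,
        support=support,
        damage_flags=damage_flags,
        error_flags=error_flags,
        warnings=warnings,
        window=cs.window,
    )


@dataclass
class MergeResult:
    """Outcome of cross-amplification authentication for one sample."""

    sample_id: str
    status: str  # authenticated | inconsistent | unreplicated
    motif: HaplotypeMotif | None = None
    disagreements: tuple[int, ...] = ()
    n_replicates: int = 0

    @property
    def authenticated(self) -> bool:
        return self.status == "authenticated"


def merge_replicates(
    calls: Sequence[ConsensusCall],
    reference: str,
    require_replication: bool = True,
    min_replicates: int = 2,
) -> MergeResult:
    """Merge independent amplifications of one sample into one motif.

    All replicate motifs identical -> authenticated; any disagreement ->
    an inconsistency report naming the discordant positions (the sample
    is excluded downstream).  A single replicate, when replication is
    required, is an authentication failure, not an exception.
    """
    if not calls:
        raise ValueError("no consensus calls to merge")
    sample_ids = {c.sample_id for c in calls}
    if len(sample_ids) != 1:
        raise ValueError(f"calls from multiple samples: {sorted(sample_ids)}")
    sample_id = calls[0].sample_id

    motifs = [c.motif(reference) for c in calls]
    if require_replication and len(calls) < min_replicates:
        return MergeResult(sample_id, "unreplicated", motif=motifs[0],
                           n_replicates=len(calls))
    first = motifs[0]
    disagreeing: set[int] = set()
    for other in motifs[1:]:
        for pos in first.positions ^ other.positions:
            disagreeing.add(pos)
        for pos in first.positions & other.positions:
            if first.allele_at(pos) != other.allele_at(pos):
                disagreeing.add(pos)
    if disagreeing:
        return MergeResult(sample_id, "inconsistent",
                           disagreements=tuple(sorted(disagreeing)),
                           n_replicates=len(calls))
    return MergeResult(sample_id, "authenticated", motif=first,
                       n_replicates=len(calls))


# ---------------------------------------------------------------------------
# FASTA I/O — headers encode ``sample_id|amplification_id``
# ---------------------------------------------------------------------------

def read_clone_fasta(path: str | Path,
                     window: tuple[int, int] = DEFAULT_WINDOW) -> list[CloneSet]:
    """Group clone records by (sample, amplification) from one FASTA."""
    groups: dict[tuple[str, str], list[str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = rec.id.split("|")
        if len(fields) < 2:
            raise ValueError(
                f"clone header {rec.id!r} must be 'sample_id|amplification_id[|clone]'"
            )
        groups.setdefault((fields[0], fields[1]), []).append(str(rec.seq))
    return [
        CloneSet(sample_id=s, amplification_id=a, clones=clones, window=window)
        for (s, a), clones in sorted(groups.items())
    ]


def write_clone_fasta(clone_sets: Iterable[CloneSet], path: str | Path) -> None:
    records = []
    for cs in clone_sets:
        for i, seq in enumerate(cs.clones, 1):
            records.append(
                SeqRecord(Seq(seq), id=f"{cs.sample_id}|{cs.amplification_id}|c{i}",
                          description="")
            )
    SeqIO.write(records, str(path), "fasta")


def write_consensus_report(calls: Sequence[ConsensusCall], path: str | Path) -> None:
    """TSV summary: one row per amplification."""
    import pandas as pd

    rows = []
    for c in calls:
        rows.append(
            {
                "sample_id": c.sample_id,
                "amplification_id": c.amplification_id,
                "n_ambiguous": c.consensus.count(AMBIGUOUS),
                "n_damage_flags": len(c.damage_flags),
                "n_error_flags": len(c.error_flags),
                "min_support": min(c.support) if c.support else 1.0,
                "warnings": "; ".join(c.warnings),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
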