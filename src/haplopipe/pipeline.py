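"""End-to-end orchestration: clones → consensus → screen → classify → network.

The stage order mirrors how an ancient-DNA study argues: authenticate
first (replicate agreement, elimination screening), then profile the
authenticated samples (sexing, mtDNA and Y haplogroups), then summarise
(haplotype table, median-joining network).  Every summary count in the
report is recomputed from the per-sample table before the report is
returned, so a report that prints is internally consistent.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .classify import (
    PanelBundle,
    classify_mtdna,
    classify_y,
    call_sex,
    load_panel,
    observations_to_calls,
    read_observations,
)
from .consensus import call_consensus, merge_replicates, read_clone_fasta
from .core import (
    DEFAULT_WINDOW,
    EliminationDB,
    SampleRecord,
    format_motif,
    read_elimination_db,
    read_sample_table,
    tabulate_haplotypes,
)
from .network import build_mj_network, export_network
from .screen import check_sex_concordance, retained_samples, screen_contamination
from .synth import synthetic_reference

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and samples."""


@dataclass
class PipelineConfig:
    window: tuple[int, int] = DEFAULT_WINDOW
    weights: dict[int, float] | None = None
    epsilon: float = 0.0
    max_mismatch: float = 0.0
    min_support: float = 0.75
    require_replication: bool = True
    mask_length_variants: bool = False
    panel_path: str | None = None
    seed: int = 0

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["window"] = list(self.window)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.resolved(), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class PipelineReport:
    table: pd.DataFrame
    summary: dict
    network_paths: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)
    screen_flagged: list[tuple[str, str, float]] = field(default_factory=list)
    failures: list[dict] = field(default_factory=list)

    def verify_consistency(self) -> None:
        """Summary counts must be recomputable from the per-sample table."""
        t = self.table
        recomputed = {
            "n_authenticated": len(t),
            "n_distinct_haplotypes": t["haplotype"].nunique() if len(t) else 0,
            "n_haplogroups": t.loc[t["mtdna_hg"] != "-", "mtdna_hg"].nunique() if len(t) else 0,
            "n_molecular_males": int((t["mol_sex"] == "male").sum()) if len(t) else 0,
            "n_molecular_females": int((t["mol_sex"] == "female").sum()) if len(t) else 0,
        }
        for key, value in recomputed.items():
            if self.summary.get(key) != value:
                raise AssertionError(
                    f"summary[{key!r}]={self.summary.get(key)} != recomputed {value}"
                )


def samples_from_clones(
    clones_fasta: str | Path,
    cfg: PipelineConfig,
) -> tuple[list[SampleRecord], list[dict]]:
    """Consensus + replicate-merge stage: clone FASTA to authenticated motifs."""
    clone_sets = read_clone_fasta(clones_fasta, cfg.window)
    reference = synthetic_reference(cfg.window)
    by_sample: dict[str, list] = {}
    for cs in clone_sets:
        by_sample.setdefault(cs.sample_id, []).append(
            call_consensus(cs, min_support=cfg.min_support)
        )
    samples: list[SampleRecord] = []
    failures: list[dict] = []
    for sid in sorted(by_sample):
        result = merge_replicates(by_sample[sid], reference,
                                  require_replication=cfg.require_replication)
        if result.authenticated:
            samples.append(SampleRecord(sample_id=sid, motif=result.motif))
        else:
            failures.append(
                {"stage": "consensus", "sample_id": sid, "status": result.status,
                 "disagreements": list(result.disagreements)}
            )
            logger.warning("sample %s excluded at consensus stage: %s", sid, result.status)
    return samples, failures


def attach_observations(
    samples: Sequence[SampleRecord],
    observations: Mapping[str, Mapping[str, str]],
    panel: PanelBundle,
) -> None:
    """Fold raw marker observations into the sample records.

    Mitochondrial markers go to ``coding_calls``, Y markers to
    ``y_calls``; rows for marker ``AMG`` carry comma-separated product
    lengths and populate ``amg_bands``.
    """
    for s in samples:
        raw = dict(observations.get(s.sample_id, {}))
        amg = raw.pop("AMG", None)
        if amg:
            s.amg_bands = frozenset(int(tok) for tok in str(amg).replace(",", " ").split())
        mt_raw = {k: v for k, v in raw.items() if k in panel.mtdna.markers}
        y_raw = {k: v for k, v in raw.items() if k in panel.y.markers}
        s.coding_calls.update(observations_to_calls(mt_raw, panel.mtdna))
        s.y_calls.update(observations_to_calls(y_raw, panel.y))


def profile_samples(samples: Sequence[SampleRecord], panel: PanelBundle) -> list[dict]:
    """Sexing and haplogroup classification for every sample, in place."""
    failures: list[dict] = []
    for s in samples:
        if s.amg_bands:
            s.molecular_sex = call_sex(s.amg_bands, panel.amg).sex
        elif not s.molecular_sex:
            s.molecular_sex = "no-call"
        if s.coding_calls:
            call = classify_mtdna(s, panel.mtdna)
            if call.status != "ok":
                failures.append({"stage": "classify_mtdna", "sample_id": s.sample_id,
                                 "status": call.status, "marker": call.missing_marker})
        if s.y_calls and s.molecular_sex == "male":
            call = classify_y(s, panel.y)
            if call.status != "ok":
                failures.append({"stage": "classify_y", "sample_id": s.sample_id,
                                 "status": call.status, "marker": call.missing_marker})
    return failures


def summarise(samples: Sequence[SampleRecord]) -> tuple[pd.DataFrame, dict]:
    rows = []
    for s in samples:
        rows.append(
            {
                "sample_id": s.sample_id,
                "haplotype": format_motif(s.motif) or "CRS",
                "mtdna_hg": s.mtdna_haplogroup or "-",
                "y_hg": s.y_haplogroup or "-",
                "morph_sex": s.morphological_sex or "-",
                "mol_sex": s.molecular_sex or "-",
            }
        )
    table = pd.DataFrame(
        rows, columns=["sample_id", "haplotype", "mtdna_hg", "y_hg", "morph_sex", "mol_sex"]
    )
    haplo = tabulate_haplotypes(samples) if samples else None
    hg_counts = Counter(s.mtdna_haplogroup for s in samples if s.mtdna_haplogroup)
    y_counts = Counter(s.y_haplogroup for s in samples if s.y_haplogroup)
    concordance = check_sex_concordance(samples)
    summary = {
        "n_authenticated": len(samples),
        "n_distinct_haplotypes": haplo.n_distinct if haplo else 0,
        "n_haplogroups": len(hg_counts),
        "haplogroup_counts": dict(sorted(hg_counts.items())),
        "y_haplogroup_counts": dict(sorted(y_counts.items())),
        "n_molecular_males": sum(1 for s in samples if s.molecular_sex == "male"),
        "n_molecular_females": sum(1 for s in samples if s.molecular_sex == "female"),
        "n_sex_compared": concordance.n_compared,
        "n_sex_concordant": concordance.n_concordant,
        "sex_conflicts": concordance.conflicts,
    }
    return table, summary


def run_pipeline(
    cfg: PipelineConfig,
    out_dir: str | Path,
    clones_fasta: str | Path | None = None,
    sample_table: str | Path | None = None,
    observations_tsv: str | Path | None = None,
    elimination_db: str | Path | EliminationDB | None = None,
) -> PipelineReport:
    """Run every stage and write report.tsv / summary.json / network files.

    Motifs come either from a clone FASTA (consensus + replication) or
    from a pre-typed sample table; a sample table alongside clones
    contributes the metadata columns (morphological sex).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    panel = load_panel(cfg.panel_path)
    failures: list[dict] = []

    if clones_fasta is not None:
        samples, failures = samples_from_clones(clones_fasta, cfg)
        if sample_table is not None:
            meta = {r.sample_id: r for r in read_sample_table(sample_table, cfg.window)}
            for s in samples:
                if s.sample_id in meta:
                    s.morphological_sex = meta[s.sample_id].morphological_sex
    elif sample_table is not None:
        samples = read_sample_table(sample_table, cfg.window)
        for s in samples:  # reported calls are inputs only; recompute everything
            s.mtdna_haplogroup = s.y_haplogroup = s.molecular_sex = ""
    else:
        raise StageError("input: need a clone FASTA or a sample table")

    if observations_tsv is not None:
        attach_observations(samples, read_observations(observations_tsv), panel)

    flagged: list[tuple[str, str, float]] = []
    if elimination_db is not None:
        db = (elimination_db if isinstance(elimination_db, EliminationDB)
              else read_elimination_db(elimination_db, cfg.window))
        report = screen_contamination(samples, db, cfg.max_mismatch)
        flagged = report.flagged
        samples = retained_samples(samples, report)

    failures += profile_samples(samples, panel)
    table, summary = summarise(samples)

    network_paths: list[str] = []
    if samples:
        net = build_mj_network(
            tabulate_haplotypes(samples).counts,
            weights=cfg.weights, epsilon=cfg.epsilon,
            mask_length_variants=cfg.mask_length_variants,
        )
        network_paths.append(str(export_network(net, out_dir / "network.graphml", "graphml")))
        network_paths.append(str(export_network(net, out_dir / "network.dot", "dot")))

    report = PipelineReport(
        table=table,
        summary=summary,
        network_paths=network_paths,
        metadata={"seed": cfg.seed, "config_digest": cfg.digest(),
                  "version": __version__, "config": cfg.resolved()},
        screen_flagged=flagged,
        failures=failures,
    )
    report.verify_consistency()
    _write_report(report, out_dir)
    return report


def _write_report(report: PipelineReport, out_dir: Path) -> None:
    report.table.to_csv(out_dir / "report.tsv", sep="\t", index=False)
    payload = {
        "summary": report.summary,
        "screen_flagged": [list(x) for x in report.screen_flagged],
        "failures": report.failures,
        "metadata": report.metadata,
        "network_paths": [Path(p).name for p in report.network_paths],
    }
    (out_dir / "summary.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    with open(out_dir / "run.log", "w") as fh:
        fh.write(f"haplopipe {__version__} config={report.metadata['config_digest']}\n")
        fh.write(json.dumps(report.metadata["config"], indent=2, sort_keys=True) + "\n")


def run_study_fixture(out_dir: str | Path | None = None,
                      cfg: PipelineConfig | None = None) -> PipelineReport:
    """Run the whole pipeline on the packaged study fixture.

    Screens the 23-sequence input against the investigator database,
    then profiles the retained cohort; the report's summary reproduces
    every published count.
    """
    from .synth import build_study_fixture

    cfg = cfg or PipelineConfig()
    fixture = build_study_fixture(window=cfg.window)
    screen = screen_contamination(fixture.screen_input, fixture.elimination_db,
                                  cfg.max_mismatch)
    samples = retained_samples(fixture.screen_input, screen)
    failures = profile_samples(samples, fixture.panel)
    table, summary = summarise(samples)
    summary["n_screen_input"] = len(fixture.screen_input)
    summary["n_screen_flagged"] = len(screen.flagged_samples)

    network_paths: list[str] = []
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        net = build_mj_network(tabulate_haplotypes(samples).counts,
                               weights=cfg.weights, epsilon=cfg.epsilon)
        network_paths.append(str(export_network(net, out_dir / "network.graphml")))

    report = PipelineReport(
        table=table, summary=summary, network_paths=network_paths,
        metadata={"seed": cfg.seed, "config_digest": cfg.digest(),
                  "version": __version__, "config": cfg.resolved()},
        screen_flagged=screen.flagged, failures=failures,
    )
    report.verify_consistency()
    if out_dir is not None:
        _write_report(report, out_dir)
    return report
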