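"""End-to-end orchestration: ingest -> normalize -> statistics -> reports.

``run_full`` is the programmatic equivalent of the ``analyze`` CLI
subcommand: it reads every DEMO/DRUG/REAC quarterly file in a directory,
deduplicates cases, computes per-pair disproportionality statistics for
the configured events, ranks top-N lists, classifies the multi-event Venn
sets, optionally profiles a drug panel, and writes the report TSVs plus a
stage-tagged plain-text log.  Outputs are staged and moved into place, so
reruns on the same inputs are byte-identical.
"""

from __future__ import annotations

import glob
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import fixtures
from .classify import (
    PanelProfile,
    TopNList,
    VennClassification,
    classify_venn,
    export_reports,
    profile_panel,
    rank_top_n,
)
from .disproportionality import (
    DEFAULT_CRITERIA,
    SignalCriteria,
    SignalStats,
    Z_95,
    round_half_up,
    signal_table,
)
from .errors import ConfigError, IngestError
from .ingest import (
    AssembleLog,
    CaseReport,
    ParseLog,
    SUSPECT_ROLES,
    assemble_cases,
    deduplicate,
    merge_quarters,
    parse_table,
)
from .normalize import SynonymTable, TermMap, normalize_key


@dataclass(frozen=True)
class RunConfig:
    """Settings for one full analysis run."""

    input_dir: str | Path
    out_dir: str | Path
    events: tuple[str, ...]
    top_n: int = 30
    z: float = Z_95
    roles: tuple[str, ...] | str = SUSPECT_ROLES
    criteria: SignalCriteria = DEFAULT_CRITERIA
    min_count: int = 1
    synonyms_path: str | Path | None = None
    term_map_path: str | Path | None = None
    panel: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not self.events:
            raise ConfigError("analyze: events must be non-empty")
        if self.top_n < 1:
            raise ConfigError(f"analyze: top_n must be >= 1, got {self.top_n}")
        if self.z <= 0:
            raise ConfigError(f"analyze: z must be positive, got {self.z}")


@dataclass
class IngestSummary:
    parse_logs: list[ParseLog] = field(default_factory=list)
    assemble_log: AssembleLog | None = None
    demo_records: int = 0
    drug_records: int = 0
    reac_records: int = 0
    deduplicated_cases: int = 0
    missing_caseid: int = 0

    def lines(self) -> list[str]:
        out = [log.summary() for log in sorted(self.parse_logs, key=lambda l: l.path)]
        out.append(
            f"ingest: demo={self.demo_records} drug={self.drug_records} "
            f"reac={self.reac_records} deduplicated_cases={self.deduplicated_cases} "
            f"missing_caseid={self.missing_caseid}"
        )
        if self.assemble_log is not None:
            out.append(self.assemble_log.summary())
        return out


def _find_quarter_files(input_dir: Path, table: str) -> list[Path]:
    paths = sorted(
        {Path(p) for pattern in (f"{table}*.txt", f"{table.lower()}*.txt")
         for p in glob.glob(str(input_dir / pattern))}
    )
    return paths


def load_cases(
    input_dir: str | Path,
    synonyms: SynonymTable | None = None,
    term_map: TermMap | None = None,
) -> tuple[list[CaseReport], IngestSummary]:
    """Parse, merge and deduplicate every quarterly file set in a directory."""
    input_dir = Path(input_dir)
    if not input_dir.is_dir():
        raise IngestError(f"ingest: input directory {input_dir} does not exist")
    summary = IngestSummary()
    tables: dict[str, list] = {}
    for table in ("DEMO", "DRUG", "REAC"):
        paths = _find_quarter_files(input_dir, table)
        if not paths:
            raise IngestError(f"ingest: no {table} files found in {input_dir}")
        quarters = []
        for path in paths:
            records, log = parse_table(path, table)
            summary.parse_logs.append(log)
            quarters.append(records)
        tables[table] = merge_quarters(quarters)

    summary.demo_records = len(tables["DEMO"])
    summary.drug_records = len(tables["DRUG"])
    summary.reac_records = len(tables["REAC"])

    dedup = deduplicate(tables["DEMO"])
    summary.missing_caseid = dedup.missing_caseid
    cases, assemble_log = assemble_cases(
        dedup, tables["DRUG"], tables["REAC"], synonyms=synonyms, term_map=term_map
    )
    summary.assemble_log = assemble_log
    summary.deduplicated_cases = len(cases)
    return cases, summary


def stats_frame(stats: Sequence[SignalStats]) -> pd.DataFrame:
    """Full-precision results table (one row per drug–event pair)."""
    rows = []
    for s in stats:
        t = s.table
        rows.append(
            {
                "drug": s.drug,
                "event": s.event,
                "a": t.a if t else s.frequency,
                "b": t.b if t else "",
                "c": t.c if t else "",
                "d": t.d if t else "",
                "ror": s.ror,
                "ror_low": s.ror_low,
                "ror_high": s.ror_high,
                "prr": s.prr,
                "prr_low": s.prr_low,
                "prr_high": s.prr_high,
                "chi2": "" if s.chi2 is None else round_half_up(s.chi2, 4),
                "corrected": int(s.corrected),
                "is_signal": int(s.is_signal),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "drug", "event", "a", "b", "c", "d",
            "ror", "ror_low", "ror_high", "prr", "prr_low", "prr_high",
            "chi2", "corrected", "is_signal",
        ],
    )


@dataclass
class RunResult:
    out_dir: Path
    files: list[Path]
    summary: IngestSummary
    lists: list[TopNList]
    classification: VennClassification
    profile: PanelProfile | None
    stats: list[SignalStats]


def run_full(config: RunConfig) -> RunResult:
    """Execute every stage in order and write the report set atomically."""
    synonyms = (
        SynonymTable.from_tsv(config.synonyms_path) if config.synonyms_path else None
    )
    term_map = TermMap.from_tsv(config.term_map_path) if config.term_map_path else None
    events = tuple(normalize_key(e) for e in config.events)

    cases, summary = load_cases(config.input_dir, synonyms=synonyms, term_map=term_map)
    stats = signal_table(
        cases,
        events=events,
        roles=config.roles,
        z=config.z,
        criteria=config.criteria,
        min_count=config.min_count,
    )
    by_event: dict[str, list[SignalStats]] = {event: [] for event in events}
    for s in stats:
        by_event[s.event].append(s)
    lists = [rank_top_n(by_event[event], config.top_n, event=event) for event in events]
    classification = classify_venn(lists)

    profile = None
    if config.panel is not None:
        panel = tuple(
            synonyms.canonicalize(name) if synonyms else normalize_key(name)
            for name in config.panel
        )
        cell_map = {(s.drug, s.event): s for s in stats}
        profile = profile_panel(panel, list(events), cell_map, criteria=config.criteria)

    extra = {"signal_stats.tsv": stats_frame(stats)}
    log_lines = summary.lines()
    log_lines.append(
        f"analyze: events={len(events)} pairs={len(stats)} "
        f"signals={sum(s.is_signal for s in stats)}"
    )
    extra["run_log.txt"] = pd.DataFrame({"log": log_lines})

    files = export_reports(
        config.out_dir,
        lists=lists,
        classification=classification,
        profile=profile,
        extra_frames=extra,
    )
    return RunResult(
        out_dir=Path(config.out_dir),
        files=files,
        summary=summary,
        lists=lists,
        classification=classification,
        profile=profile,
        stats=stats,
    )


def run_fixture_venn() -> VennClassification:
    """Classification of the packaged published top-30 lists."""
    return fixtures.fixture_venn()
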