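"""Reading FAERS-style quarterly ASCII extracts into deduplicated cases.

The public quarterly extracts ship one "$"-delimited text file per table
and quarter (DEMO18Q1.txt, DRUG18Q1.txt, REAC18Q1.txt, ...), each with a
header row.  A safety report (a *case*, keyed by CASEID) may appear in
several quarters as successive versions, each version carrying its own
PRIMARYID; disproportionality counts must include each case exactly once,
so ingest keeps, per case, the record with the highest CASEVERSION,
breaking ties by latest FDA_DT and then by greatest PRIMARYID.  The
tie-break chain is total, which makes deduplication deterministic and
independent of input line order.

Parsing is deliberately forgiving at the line level (FAERS files contain
the occasional malformed row) and strict at the schema level: a header
missing a required column is a fatal error, while a bad data line is
skipped and counted in the parse log.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import IngestError, SchemaError
from .normalize import SynonymTable, TermMap, normalize_drug, normalize_term

ROLE_CODES = ("PS", "SS", "C", "I")
#: default role filter: suspect drugs only (primary + secondary suspect)
SUSPECT_ROLES = ("PS", "SS")
ALL_ROLES = ROLE_CODES

#: required header columns per table (case-insensitive match)
SCHEMAS: Mapping[str, tuple[str, ...]] = {
    "DEMO": ("primaryid", "caseid", "caseversion", "fda_dt"),
    "DRUG": ("primaryid", "drugname", "role_cod"),
    "REAC": ("primaryid", "pt"),
}


@dataclass(frozen=True)
class RawDemoRecord:
    primaryid: str
    caseid: str | None
    caseversion: int
    fda_date: str | None  # YYYYMMDD


@dataclass(frozen=True)
class RawDrugRecord:
    primaryid: str
    drug_seq: int | None
    drugname: str
    role_code: str


@dataclass(frozen=True)
class RawReacRecord:
    primaryid: str
    pt: str


@dataclass(frozen=True)
class CaseReport:
    """One deduplicated safety report.

    ``drugs`` is a set of (canonical name, role code) pairs and
    ``reactions`` a set of preferred terms; repeated mentions within a
    case collapse to set membership so they can never inflate counts.
    """

    caseid: str
    primaryid: str
    fda_date: str | None
    drugs: frozenset[tuple[str, str]]
    reactions: frozenset[str]

    def drug_names(self, roles: Sequence[str] | str = SUSPECT_ROLES) -> set[str]:
        """Drug names mentioned with one of the given role codes."""
        if roles == "all":
            roles = ALL_ROLES
        allowed = set(roles)
        return {name for name, role in self.drugs if role in allowed}


@dataclass
class ParseLog:
    path: str
    schema: str
    parsed: int = 0
    skipped: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_skipped(self) -> int:
        return len(self.skipped)

    def summary(self) -> str:
        return f"{self.schema} {self.path}: parsed={self.parsed} skipped={self.n_skipped}"


def _read_lines(path: Path) -> list[str]:
    try:
        data = path.read_bytes()
    except FileNotFoundError as exc:
        raise IngestError(f"ingest: missing file {path}") from exc
    except OSError as exc:
        raise IngestError(f"ingest: cannot read {path}: {exc}") from exc
    # permissive decode: FAERS extracts contain stray non-UTF-8 bytes
    return io.StringIO(data.decode("utf-8", errors="replace")).read().splitlines()


def parse_table(path: str | Path, schema: str):
    """Parse one quarterly file into raw records.

    Returns ``(records, log)``.  Fields are selected by header name, never
    by position; data lines whose field count does not match the header or
    whose required keys are missing/invalid are skipped and recorded in the
    log with their line number.
    """
    schema = schema.upper()
    if schema not in SCHEMAS:
        raise SchemaError(f"ingest: unknown schema {schema!r} (expected one of {sorted(SCHEMAS)})")
    path = Path(path)
    lines = _read_lines(path)
    log = ParseLog(path=str(path), schema=schema)
    if not lines:
        raise SchemaError(f"ingest: {path}: empty file, no header")

    header = [col.strip().lower() for col in lines[0].split("$")]
    index = {col: i for i, col in enumerate(header)}
    for col in SCHEMAS[schema]:
        if col not in index:
            raise SchemaError(f"ingest: {path}: header lacks required column {col!r}")

    records: list = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("$")
        if len(fields) != len(header):
            log.skipped.append((lineno, f"field count {len(fields)} != header {len(header)}"))
            continue

        def get(col: str) -> str:
            return fields[index[col]].strip()

        primaryid = get("primaryid")
        if not primaryid:
            log.skipped.append((lineno, "missing primaryid"))
            continue

        if schema == "DEMO":
            raw_version = get("caseversion")
            try:
                caseversion = int(raw_version) if raw_version else 0
            except ValueError:
                log.skipped.append((lineno, f"bad caseversion {raw_version!r}"))
                continue
            if caseversion < 0:
                log.skipped.append((lineno, f"negative caseversion {caseversion}"))
                continue
            fda_date = get("fda_dt") or None
            records.append(
                RawDemoRecord(
                    primaryid=primaryid,
                    caseid=get("caseid") or None,
                    caseversion=caseversion,
                    fda_date=fda_date,
                )
            )
        elif schema == "DRUG":
            drugname = get("drugname")
            if not drugname:
                log.skipped.append((lineno, "empty drugname"))
                continue
            role = get("role_cod").upper()
            if role not in ROLE_CODES:
                log.skipped.append((lineno, f"unknown role_cod {role!r}"))
                continue
            seq: int | None = None
            if "drug_seq" in index:
                raw_seq = get("drug_seq")
                if raw_seq:
                    try:
                        seq = int(raw_seq)
                    except ValueError:
                        seq = None
            records.append(
                RawDrugRecord(primaryid=primaryid, drug_seq=seq, drugname=drugname, role_code=role)
            )
        else:  # REAC
            pt = get("pt")
            if not pt:
                log.skipped.append((lineno, "empty pt"))
                continue
            records.append(RawReacRecord(primaryid=primaryid, pt=pt))
        log.parsed += 1
    return records, log


def merge_quarters(tables: Sequence[Sequence]) -> list:
    """Concatenate parsed quarter tables; no deduplication happens here."""
    merged: list = []
    for table in tables:
        merged.extend(table)
    return merged


@dataclass
class DedupResult:
    """Outcome of case-level deduplication over merged DEMO records."""

    #: caseid -> retained DEMO record (records without a caseid are keyed
    #: by their primaryid and counted in ``missing_caseid``)
    retained: dict[str, RawDemoRecord]
    missing_caseid: int = 0

    @property
    def by_case(self) -> dict[str, str]:
        """caseid -> retained primaryid."""
        return {cid: rec.primaryid for cid, rec in self.retained.items()}

    @property
    def retained_primaryids(self) -> set[str]:
        return {rec.primaryid for rec in self.retained.values()}


def _dedup_key(record: RawDemoRecord) -> tuple:
    # max caseversion, then latest fda date, then greatest primaryid
    return (record.caseversion, record.fda_date or "", record.primaryid)


def deduplicate(demo: Iterable[RawDemoRecord]) -> DedupResult:
    """Retain exactly one DEMO record per case.

    The winner per CASEID is the record maximizing
    (caseversion, fda_date, primaryid) lexicographically — the standard
    "latest version" rule with a deterministic tie-break chain, so the
    result is invariant under input order.
    """
    retained: dict[str, RawDemoRecord] = {}
    missing = 0
    for record in demo:
        if record.caseid is None:
            key = record.primaryid
            missing += 1
        else:
            key = record.caseid
        incumbent = retained.get(key)
        if incumbent is None or _dedup_key(record) > _dedup_key(incumbent):
            retained[key] = record
    return DedupResult(retained=retained, missing_caseid=missing)


@dataclass
class AssembleLog:
    dropped_drug_records: int = 0
    dropped_reac_records: int = 0

    def summary(self) -> str:
        return (
            f"assemble: dropped_drug={self.dropped_drug_records} "
            f"dropped_reac={self.dropped_reac_records}"
        )


def assemble_cases(
    dedup: DedupResult,
    drug_records: Iterable[RawDrugRecord],
    reac_records: Iterable[RawReacRecord],
    synonyms: SynonymTable | None = None,
    term_map: TermMap | None = None,
):
    """Join drug and reaction records onto retained cases.

    Only records whose primaryid belongs to a retained case version are
    kept; the rest (superseded versions, orphans) are counted in the log.
    Names and terms pass through the normalization tables.

    Returns ``(cases, log)`` where ``cases`` is a list of
    :class:`CaseReport` sorted by caseid for determinism.
    """
    pid_to_case: dict[str, tuple[str, RawDemoRecord]] = {
        rec.primaryid: (cid, rec) for cid, rec in dedup.retained.items()
    }
    drugs_by_pid: dict[str, set[tuple[str, str]]] = {}
    reacs_by_pid: dict[str, set[str]] = {}
    log = AssembleLog()

    for drec in drug_records:
        if drec.primaryid not in pid_to_case:
            log.dropped_drug_records += 1
            continue
        name = normalize_drug(drec.drugname, synonyms)
        drugs_by_pid.setdefault(drec.primaryid, set()).add((name, drec.role_code))
    for rrec in reac_records:
        if rrec.primaryid not in pid_to_case:
            log.dropped_reac_records += 1
            continue
        term = normalize_term(rrec.pt, term_map)
        reacs_by_pid.setdefault(rrec.primaryid, set()).add(term)

    cases = [
        CaseReport(
            caseid=cid,
            primaryid=pid,
            fda_date=rec.fda_date,
            drugs=frozenset(drugs_by_pid.get(pid, ())),
            reactions=frozenset(reacs_by_pid.get(pid, ())),
        )
        for pid, (cid, rec) in pid_to_case.items()
    ]
    cases.sort(key=lambda case: case.caseid)
    return cases, log
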