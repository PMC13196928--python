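"""Ranking, multi-event intersection and panel profiling of signals.

Given per-event disproportionality results, this module (i) ranks the
top-N drugs per event by report frequency, (ii) intersects the per-event
lists to classify drugs by how many event lists they appear in — a drug in
all lists is a *high* multi-event signaling drug, one in exactly all-but-one
lists a *medium* one — and (iii) profiles a fixed drug panel across the
events, reporting which panel drugs are signal-positive for every event.

Ranking is strictly by frequency descending, with deterministic
tie-breaks (higher ROR, then drug name).  Venn membership is computed on
canonical drug names, so brand/generic splits must be resolved by the
normalization step before classification.
"""

from __future__ import annotations

import math
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .disproportionality import (
    DEFAULT_CRITERIA,
    SignalCriteria,
    SignalStats,
    flag_signal,
    format_ror_ci,
    round_half_up,
)
from .errors import ConfigError


@dataclass(frozen=True)
class TopNList:
    """Top-N drugs for one event, ranked by report frequency descending."""

    event: str
    n: int
    entries: tuple[SignalStats, ...]

    def __post_init__(self) -> None:
        if len(self.entries) > self.n:
            raise ValueError(f"{self.event}: {len(self.entries)} entries exceed n={self.n}")
        drugs = [s.drug for s in self.entries]
        if len(set(drugs)) != len(drugs):
            raise ValueError(f"{self.event}: duplicate drugs in top-N list")
        freqs = [s.frequency for s in self.entries]
        if any(f is not None for f in freqs):
            known = [f for f in freqs if f is not None]
            if known != sorted(known, reverse=True):
                raise ValueError(f"{self.event}: frequencies not non-increasing")

    @property
    def drugs(self) -> tuple[str, ...]:
        return tuple(s.drug for s in self.entries)


def rank_top_n(stats: Iterable[SignalStats], n: int, event: str | None = None) -> TopNList:
    """Rank one event's statistics by frequency and truncate to ``n``.

    Ties in frequency break by higher ROR, then lexicographic drug name.
    """
    pool = list(stats)
    if event is None:
        events = {s.event for s in pool}
        if len(events) > 1:
            raise ConfigError(f"rank_top_n: stats span multiple events {sorted(events)}")
        event = next(iter(events)) if events else ""
    else:
        pool = [s for s in pool if s.event == event]
    pool.sort(key=lambda s: (-(s.frequency or 0), -s.ror, s.drug))
    return TopNList(event=event, n=n, entries=tuple(pool[: max(n, 0)]))


@dataclass(frozen=True)
class VennClassification:
    """Per-drug membership across event-specific top-N lists."""

    events: tuple[str, ...]
    membership: Mapping[str, frozenset[str]]
    high_set: frozenset[str]
    medium_set: frozenset[str]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for drug in sorted(self.membership, key=lambda d: (-len(self.membership[d]), d)):
            events = self.membership[drug]
            if drug in self.high_set:
                label = "high"
            elif drug in self.medium_set:
                label = "medium"
            else:
                label = "other"
            rows.append(
                {
                    "drug": drug,
                    "n_events": len(events),
                    "events": ",".join(sorted(events)),
                    "classification": label,
                }
            )
        return pd.DataFrame(rows, columns=["drug", "n_events", "events", "classification"])


def classify_venn(lists: Sequence[TopNList]) -> VennClassification:
    """Intersect per-event top-N lists into high/medium signal sets.

    High = present in every list; medium = present in exactly all-but-one.
    The result is invariant under list order and within-list order.
    """
    if len(lists) < 2:
        raise ConfigError("classify_venn: need at least two event lists")
    events = [lst.event for lst in lists]
    if len(set(events)) != len(events):
        raise ConfigError(f"classify_venn: duplicate event terms in {events}")
    membership: dict[str, set[str]] = {}
    for lst in lists:
        for drug in lst.drugs:
            membership.setdefault(drug, set()).add(lst.event)
    k = len(events)
    frozen = {drug: frozenset(evs) for drug, evs in membership.items()}
    high = frozenset(drug for drug, evs in frozen.items() if len(evs) == k)
    medium = frozenset(drug for drug, evs in frozen.items() if len(evs) == k - 1)
    return VennClassification(
        events=tuple(events), membership=frozen, high_set=high, medium_set=medium
    )


@dataclass(frozen=True)
class PanelProfile:
    """A fixed drug panel profiled across a fixed event list."""

    panel: tuple[str, ...]
    events: tuple[str, ...]
    cells: Mapping[tuple[str, str], SignalStats]
    #: panel drugs whose signal flag is true for every event
    all_positive: tuple[str, ...]
    #: (drug, event) pairs absent from the stats source (degenerate rows)
    missing: frozenset[tuple[str, str]] = frozenset()

    def positive_events(self, drug: str) -> frozenset[str]:
        return frozenset(
            event for event in self.events if self.cells[(drug, event)].is_signal
        )

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for drug in self.panel:
            for event in self.events:
                s = self.cells[(drug, event)]
                rows.append(
                    {
                        "drug": drug,
                        "event": event,
                        "frequency": s.frequency,
                        "ror": s.ror if not math.isnan(s.ror) else "",
                        "ci_low": s.ror_low if not math.isnan(s.ror_low) else "",
                        "ci_high": s.ror_high if not math.isnan(s.ror_high) else "",
                        "signal": int(s.is_signal),
                        "missing": int((drug, event) in self.missing),
                    }
                )
        return pd.DataFrame(
            rows,
            columns=["drug", "event", "frequency", "ror", "ci_low", "ci_high", "signal", "missing"],
        )

    def to_wide_frame(self) -> pd.DataFrame:
        rows = []
        for drug in self.panel:
            row: dict[str, str] = {"drug": drug}
            for event in self.events:
                s = self.cells[(drug, event)]
                row[event] = (
                    "" if math.isnan(s.ror) else format_ror_ci(s.ror, s.ror_low, s.ror_high)
                )
            rows.append(row)
        return pd.DataFrame(rows, columns=["drug", *self.events])


def _degenerate_stats(drug: str, event: str) -> SignalStats:
    nan = float("nan")
    return SignalStats(
        drug=drug, event=event, frequency=0, ror=nan, ror_low=nan, ror_high=nan, prr=None
    )


def profile_panel(
    panel: Sequence[str],
    events: Sequence[str],
    stats_source: Mapping[tuple[str, str], SignalStats] | Callable[[str, str], SignalStats | None],
    criteria: SignalCriteria = DEFAULT_CRITERIA,
) -> PanelProfile:
    """Fill the |panel| x |events| signal matrix for a named drug panel.

    ``stats_source`` maps (canonical drug, event) to statistics; a pair it
    cannot supply yields a degenerate, never-positive row flagged in
    ``missing`` rather than being dropped.
    """
    lookup: Callable[[str, str], SignalStats | None]
    if callable(stats_source):
        lookup = stats_source
    else:
        lookup = lambda drug, event: stats_source.get((drug, event))  # noqa: E731
    cells: dict[tuple[str, str], SignalStats] = {}
    missing: set[tuple[str, str]] = set()
    for drug in panel:
        for event in events:
            stats = lookup(drug, event)
            if stats is None:
                stats = _degenerate_stats(drug, event)
                missing.add((drug, event))
            cells[(drug, event)] = stats
    all_positive = tuple(
        drug
        for drug in panel
        if events and all(cells[(drug, event)].is_signal for event in events)
    )
    return PanelProfile(
        panel=tuple(panel),
        events=tuple(events),
        cells=cells,
        all_positive=all_positive,
        missing=frozenset(missing),
    )


def count_all_positive(
    profile: PanelProfile,
    event_overrides: Mapping[str, frozenset[str] | set[str]] | None = None,
) -> int:
    """Number of panel drugs positive for every event.

    ``event_overrides`` replaces the table-derived positive-event subset
    for specific drugs with an externally stated one (used to reconcile a
    published table with the accompanying per-drug text statements).
    """
    total = 0
    for drug in profile.panel:
        positives = profile.positive_events(drug)
        if event_overrides and drug in event_overrides:
            positives = frozenset(event_overrides[drug])
        if positives == frozenset(profile.events):
            total += 1
    return total


# ---------------------------------------------------------------------------
# report export
# ---------------------------------------------------------------------------


def _event_slug(event: str) -> str:
    return event.lower().replace(" ", "_")


def _top_n_frame(lst: TopNList) -> pd.DataFrame:
    rows = []
    for rank, s in enumerate(lst.entries, start=1):
        rows.append(
            {
                "Ranking": rank,
                "Medication": s.drug,
                "Frequency": s.frequency if s.frequency is not None else "",
                "ROR(95% CI)": format_ror_ci(s.ror, s.ror_low, s.ror_high),
                "PRR": "" if s.prr is None else f"{round_half_up(s.prr):.2f}",
            }
        )
    return pd.DataFrame(
        rows, columns=["Ranking", "Medication", "Frequency", "ROR(95% CI)", "PRR"]
    )


def export_reports(
    out_dir: str | Path,
    lists: Sequence[TopNList] = (),
    classification: VennClassification | None = None,
    profile: PanelProfile | None = None,
    extra_frames: Mapping[str, pd.DataFrame] | None = None,
) -> list[Path]:
    """Write plot-ready TSV reports atomically; byte-stable for fixed inputs.

    Files land in ``out_dir`` (created if needed): one ``top{n}_{event}.tsv``
    per list, ``venn.tsv``, ``panel_wide.tsv``/``panel_long.tsv`` and any
    extra named frames.  Everything is staged in a temporary sibling
    directory and moved into place, so a crashed run never leaves a
    half-written report set.
    """
    out_dir = Path(out_dir)
    frames: dict[str, pd.DataFrame] = {}
    for lst in lists:
        frames[f"top{lst.n}_{_event_slug(lst.event)}.tsv"] = _top_n_frame(lst)
    if classification is not None:
        frames["venn.tsv"] = classification.to_frame()
    if profile is not None:
        frames["panel_wide.tsv"] = profile.to_wide_frame()
        frames["panel_long.tsv"] = profile.to_long_frame()
    if extra_frames:
        frames.update(extra_frames)

    out_dir.parent.mkdir(parents=True, exist_ok=True)
    try:
        staging = Path(tempfile.mkdtemp(prefix=f".{out_dir.name}.", dir=out_dir.parent))
    except OSError as exc:
        raise IOError(f"export: cannot stage reports next to {out_dir}: {exc}") from exc
    written: list[Path] = []
    try:
        for name in sorted(frames):
            frames[name].to_csv(staging / name, sep="\t", index=False, lineterminator="\n")
        out_dir.mkdir(exist_ok=True)
        for name in sorted(frames):
            target = out_dir / name
            os.replace(staging / name, target)
            written.append(target)
    finally:
        if staging.exists():
            for leftover in staging.iterdir():
                leftover.unlink()
            staging.rmdir()
    return written
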