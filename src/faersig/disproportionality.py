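"""Case-level 2x2 disproportionality statistics: ROR, PRR, chi-squared.

For a drug D and adverse event E over a deduplicated case set of size N,

    a = cases reporting D and E          b = cases reporting D without E
    c = cases reporting E without D      d = cases reporting neither

The reporting odds ratio ROR = (a*d)/(b*c) compares the odds of E among
reports mentioning D with the odds among all other reports; the
proportional reporting ratio PRR = [a/(a+b)] / [c/(c+d)] compares the
corresponding report proportions.  Confidence intervals use the log-normal
(Woolf) approximation:

    ln ROR +- z * sqrt(1/a + 1/b + 1/c + 1/d)
    ln PRR +- z * sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d))

When any cell is zero the Haldane–Anscombe correction adds 0.5 to all four
cells (recorded on the result); non-degenerate tables are never altered.
The chi-squared statistic uses Yates' continuity correction,
N*(max(0, |ad-bc| - N/2))^2 / ((a+b)(c+d)(a+c)(b+d)).

A drug–event pair is flagged as a signal when it meets the configured
criterion; the default is the ROR rule (a >= 3 and the 95% CI lower bound
above 1), with the classical PRR rule (a >= 3, PRR >= 2, chi2 >= 4)
available as configuration.  Flags indicate reporting disproportionality,
not causation.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

from .errors import EstimateError
from .ingest import CaseReport, SUSPECT_ROLES
from .normalize import normalize_key

Z_95 = 1.96


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 case counts for one drug–event pair against the background."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            value = getattr(self, name)
            if value < 0 or value != int(value):
                raise ValueError(f"cell {name} must be a non-negative integer, got {value!r}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    @property
    def has_zero_cell(self) -> bool:
        return min(self.cells) == 0


def _working_cells(t: ContingencyTable, correction: bool) -> tuple[tuple[float, float, float, float], bool]:
    """Haldane–Anscombe: +0.5 to every cell iff any cell is zero."""
    if t.has_zero_cell:
        if not correction:
            raise EstimateError(f"zero cell in table {t.cells} and continuity correction disabled")
        return (t.a + 0.5, t.b + 0.5, t.c + 0.5, t.d + 0.5), True
    return (float(t.a), float(t.b), float(t.c), float(t.d)), False


def ror_estimate(
    t: ContingencyTable, z: float = Z_95, correction: bool = True
) -> tuple[float, float, float]:
    """Reporting odds ratio with Woolf (log-normal) confidence interval.

    Returns ``(ror, ci_low, ci_high)``.
    """
    (a, b, c, d), _ = _working_cells(t, correction)
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    half = z * se
    log_ror = math.log(ror)
    return ror, math.exp(log_ror - half), math.exp(log_ror + half)


def prr_estimate(
    t: ContingencyTable, z: float = Z_95, correction: bool = True
) -> tuple[float, float, float]:
    """Proportional reporting ratio with log-normal confidence interval."""
    if t.a + t.b == 0 or t.c + t.d == 0:
        raise EstimateError(f"degenerate margin in table {t.cells}: PRR undefined")
    (a, b, c, d), _ = _working_cells(t, correction)
    prr = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    half = z * se
    log_prr = math.log(prr)
    return prr, math.exp(log_prr - half), math.exp(log_prr + half)


def chi2_yates(t: ContingencyTable) -> float:
    """Yates-continuity-corrected chi-squared statistic of the raw table."""
    a, b, c, d = (float(x) for x in t.cells)
    n = a + b + c + d
    margins = ((a + b), (c + d), (a + c), (b + d))
    if min(margins) == 0:
        raise EstimateError(f"zero margin in table {t.cells}: chi-squared undefined")
    diff = max(0.0, abs(a * d - b * c) - n / 2)
    return n * diff * diff / (margins[0] * margins[1] * margins[2] * margins[3])


@dataclass(frozen=True)
class SignalCriteria:
    """Signal-detection thresholds (configuration, not code).

    ``method`` selects the rule used for the boolean flag:
    ``"ror"``  — a >= min_count and ROR CI lower bound > ror_ci_low;
    ``"prr"``  — a >= min_count and PRR >= prr_min and chi2 >= chi2_min.
    """

    method: str = "ror"
    min_count: int = 3
    ror_ci_low: float = 1.0
    prr_min: float = 2.0
    chi2_min: float = 4.0

    def __post_init__(self) -> None:
        if self.method not in ("ror", "prr"):
            raise ValueError(f"unknown signal criterion method {self.method!r}")


DEFAULT_CRITERIA = SignalCriteria()


@dataclass(frozen=True)
class SignalStats:
    """All disproportionality statistics for one drug–event pair."""

    drug: str
    event: str
    frequency: int | None  # the count a; None for published rows without counts
    ror: float
    ror_low: float
    ror_high: float
    prr: float | None
    prr_low: float | None = None
    prr_high: float | None = None
    chi2: float | None = None
    corrected: bool = False
    is_signal: bool = False
    table: ContingencyTable | None = None

    def __post_init__(self) -> None:
        if math.isnan(self.ror):  # degenerate placeholder row
            return
        if not (self.ror_low <= self.ror <= self.ror_high):
            raise ValueError(
                f"{self.drug}/{self.event}: ROR {self.ror} outside its CI "
                f"({self.ror_low}, {self.ror_high})"
            )

    @classmethod
    def from_published(
        cls,
        drug: str,
        event: str,
        ror: float,
        ror_low: float,
        ror_high: float,
        frequency: int | None = None,
        prr: float | None = None,
        criteria: SignalCriteria = DEFAULT_CRITERIA,
    ) -> "SignalStats":
        """Wrap estimates transcribed from a published table (no raw cells)."""
        stats = cls(
            drug=normalize_key(drug),
            event=normalize_key(event),
            frequency=frequency,
            ror=ror,
            ror_low=ror_low,
            ror_high=ror_high,
            prr=prr,
        )
        return replace(stats, is_signal=flag_signal(stats, criteria))


def flag_signal(stats: SignalStats, criteria: SignalCriteria = DEFAULT_CRITERIA) -> bool:
    """Apply the configured signal criterion to computed statistics.

    A pair whose report count is unknown (published tables print CIs but
    not always counts) is assessed on the CI criterion alone.
    """
    count_ok = stats.frequency is None or stats.frequency >= criteria.min_count
    if criteria.method == "ror":
        return count_ok and stats.ror_low > criteria.ror_ci_low
    chi2 = stats.chi2 if stats.chi2 is not None else 0.0
    prr = stats.prr if stats.prr is not None else 0.0
    return count_ok and prr >= criteria.prr_min and chi2 >= criteria.chi2_min


def compute_stats(
    drug: str,
    event: str,
    table: ContingencyTable,
    z: float = Z_95,
    criteria: SignalCriteria = DEFAULT_CRITERIA,
    correction: bool = True,
) -> SignalStats:
    """Full statistics bundle for one pair from its 2x2 table."""
    ror, ror_low, ror_high = ror_estimate(table, z=z, correction=correction)
    prr, prr_low, prr_high = prr_estimate(table, z=z, correction=correction)
    try:
        chi2 = chi2_yates(table)
    except EstimateError:
        chi2 = None
    stats = SignalStats(
        drug=drug,
        event=event,
        frequency=table.a,
        ror=ror,
        ror_low=ror_low,
        ror_high=ror_high,
        prr=prr,
        prr_low=prr_low,
        prr_high=prr_high,
        chi2=chi2,
        corrected=table.has_zero_cell,
        table=table,
    )
    return replace(stats, is_signal=flag_signal(stats, criteria))


# ---------------------------------------------------------------------------
# counting over case sets
# ---------------------------------------------------------------------------


def build_contingency(
    cases: Sequence[CaseReport],
    drug: str,
    event: str,
    roles: Sequence[str] | str = SUSPECT_ROLES,
) -> ContingencyTable:
    """Count the 2x2 table for one pair; the counting unit is the case."""
    a = b = c = d = 0
    for case in cases:
        has_drug = drug in case.drug_names(roles)
        has_event = event in case.reactions
        if has_drug and has_event:
            a += 1
        elif has_drug:
            b += 1
        elif has_event:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


@dataclass
class PairCounts:
    """Single-pass marginal and joint counts over a case set."""

    n_cases: int
    drug_totals: Counter
    event_totals: Counter
    pair_totals: Counter

    def contingency(self, drug: str, event: str) -> ContingencyTable:
        a = self.pair_totals.get((drug, event), 0)
        n_drug = self.drug_totals.get(drug, 0)
        n_event = self.event_totals.get(event, 0)
        return ContingencyTable(a, n_drug - a, n_event - a, self.n_cases - n_drug - n_event + a)


def count_pairs(
    cases: Iterable[CaseReport],
    events: Sequence[str] | None = None,
    roles: Sequence[str] | str = SUSPECT_ROLES,
) -> PairCounts:
    """One pass over the case set collecting drug, event and pair counts.

    ``events`` restricts the events of interest; drugs are never
    restricted (the comparator is every other drug in the database).
    """
    event_filter = set(events) if events is not None else None
    n = 0
    drug_totals: Counter = Counter()
    event_totals: Counter = Counter()
    pair_totals: Counter = Counter()
    for case in cases:
        n += 1
        reactions = case.reactions if event_filter is None else case.reactions & event_filter
        names = case.drug_names(roles)
        for term in reactions:
            event_totals[term] += 1
        for name in names:
            drug_totals[name] += 1
            for term in reactions:
                pair_totals[(name, term)] += 1
    return PairCounts(n_cases=n, drug_totals=drug_totals, event_totals=event_totals, pair_totals=pair_totals)


def signal_table(
    cases: Sequence[CaseReport],
    events: Sequence[str] | None = None,
    roles: Sequence[str] | str = SUSPECT_ROLES,
    z: float = Z_95,
    criteria: SignalCriteria = DEFAULT_CRITERIA,
    min_count: int = 1,
    pairs: str = "observed",
) -> list[SignalStats]:
    """Statistics for drug–event pairs over a deduplicated case set.

    ``pairs="observed"`` enumerates pairs with at least ``min_count``
    co-reports; ``pairs="all"`` crosses every reported drug with every
    event of interest (zero-count pairs included, Haldane-corrected).
    """
    counts = count_pairs(cases, events=events, roles=roles)
    if pairs == "observed":
        keys = [key for key, a in counts.pair_totals.items() if a >= min_count]
    elif pairs == "all":
        keys = [(drug, event) for drug in counts.drug_totals for event in counts.event_totals]
    else:
        raise ValueError(f"pairs must be 'observed' or 'all', got {pairs!r}")
    keys.sort()
    return [
        compute_stats(drug, event, counts.contingency(drug, event), z=z, criteria=criteria)
        for drug, event in keys
    ]


# ---------------------------------------------------------------------------
# report formatting
# ---------------------------------------------------------------------------


def round_half_up(x: float, digits: int = 2) -> float:
    """Decimal half-up rounding as used in published tables."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def format_ror_ci(ror: float, low: float, high: float) -> str:
    """Render ``8.87(7.92-9.93)`` style estimate strings (2 dp, half-up)."""
    return f"{round_half_up(ror):.2f}({round_half_up(low):.2f}-{round_half_up(high):.2f})"
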