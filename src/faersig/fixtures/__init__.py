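"""Packaged fixtures: the published top-30 tables, panel ROR table,
brand/generic synonyms and the 12-drug pulmonary-hypertension panel.

These TSVs are transcriptions of published full-database results.  They
are *data about the publication* — recomputing them would require the
multi-gigabyte source database — and serve as the reference surface for
the classification logic: the Venn intersection of the four top-30 lists,
the brand/generic overlap with the PH panel, and the per-cell signal
flags of the panel ROR table.

Two known quirks of the published tables are preserved rather than
repaired (see docs/methods.md): the chest-pain list's Pomalyst row prints
no CI (the running text's 1.08 (0.94-1.24) is used, with the printed PRR
kept as-is), and the panel table's riociguat row has all four CI lower
bounds above 1 while the accompanying text relates riociguat to only
three symptoms.  ``TEXT_EVENT_SUBSETS`` carries the text's per-drug event
subsets so both readings can be computed explicitly.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from ..classify import (
    PanelProfile,
    TopNList,
    VennClassification,
    classify_venn,
    profile_panel,
)
from ..disproportionality import SignalStats
from ..normalize import SynonymTable, normalize_key

#: the four post-lung-surgery symptoms, as preferred terms
EVENTS = ("DYSPNOEA", "COUGH", "PALPITATIONS", "CHEST PAIN")

_EVENT_FILES = {
    "DYSPNOEA": "top30_dyspnoea.tsv",
    "COUGH": "top30_cough.tsv",
    "PALPITATIONS": "top30_palpitations.tsv",
    "CHEST PAIN": "top30_chest_pain.tsv",
}

#: per-drug positive-event subsets stated drug-by-drug in the published
#: text for the three panel drugs it singles out; the riociguat subset
#: conflicts with the panel table's own CI row (which would be positive
#: for all four events)
TEXT_EVENT_SUBSETS: dict[str, frozenset[str]] = {
    "ILOPROST": frozenset({"DYSPNOEA", "COUGH", "CHEST PAIN"}),
    "RIOCIGUAT": frozenset({"COUGH", "PALPITATIONS", "CHEST PAIN"}),
    "SILDENAFIL": frozenset({"DYSPNOEA", "PALPITATIONS"}),
}


def _fixture_path(name: str) -> Path:
    return Path(str(resources.files(__package__) / name))


def default_synonyms() -> SynonymTable:
    """Brand -> generic synonyms for the PH panel (Opsumit -> Macitentan, ...)."""
    return SynonymTable.from_tsv(_fixture_path("synonyms.tsv"), label="packaged synonyms")


def ph_panel(normalized: bool = True) -> list[str]:
    """The 12-drug pulmonary-hypertension panel.

    With ``normalized=True`` names pass through the packaged synonym table
    (Adcirca -> TADALAFIL, Adempas -> RIOCIGUAT), matching how the panel
    is intersected with analysis output.
    """
    lines = _fixture_path("ph_panel.txt").read_text(encoding="utf-8").splitlines()
    names = [line.strip() for line in lines if line.strip() and not line.startswith("#")]
    if not normalized:
        return names
    table = default_synonyms()
    return [table.canonicalize(name) for name in names]


def published_top30(event: str, synonyms: SynonymTable | None = None) -> TopNList:
    """One published top-30 list as a :class:`TopNList` of transcribed stats."""
    event = normalize_key(event)
    if event not in _EVENT_FILES:
        raise KeyError(f"no packaged top-30 list for {event!r}; have {sorted(_EVENT_FILES)}")
    frame = pd.read_csv(_fixture_path(_EVENT_FILES[event]), sep="\t")
    entries = []
    for row in frame.itertuples(index=False):
        name = row.medication if synonyms is None else synonyms.canonicalize(row.medication)
        entries.append(
            SignalStats.from_published(
                drug=name,
                event=event,
                frequency=int(row.frequency),
                ror=float(row.ror),
                ror_low=float(row.ror_low),
                ror_high=float(row.ror_high),
                prr=float(row.prr),
            )
        )
    # published list order is by the table's ranking column, which is not
    # strictly frequency-sorted; re-rank so the TopNList invariant holds
    entries.sort(key=lambda s: (-(s.frequency or 0), -s.ror, s.drug))
    return TopNList(event=event, n=30, entries=tuple(entries))


def published_top30_all(synonyms: SynonymTable | None = None) -> list[TopNList]:
    return [published_top30(event, synonyms=synonyms) for event in EVENTS]


def fixture_venn(synonyms: SynonymTable | None = None) -> VennClassification:
    """Venn classification of the four published top-30 lists."""
    return classify_venn(published_top30_all(synonyms=synonyms))


def published_panel_table() -> pd.DataFrame:
    """The published 12-drug x 4-event ROR/CI table (long format)."""
    return pd.read_csv(_fixture_path("ph_panel_ror.tsv"), sep="\t")


def fixture_panel_profile() -> PanelProfile:
    """Panel profile from the published panel ROR table.

    Drug names are normalized with the packaged synonym table; flags are
    the ROR criterion applied to the printed CIs (report counts are not
    printed in that table, so the count threshold is vacuous here).
    """
    table = default_synonyms()
    frame = published_panel_table()
    cells: dict[tuple[str, str], SignalStats] = {}
    for row in frame.itertuples(index=False):
        drug = table.canonicalize(row.drug)
        event = normalize_key(row.event)
        cells[(drug, event)] = SignalStats.from_published(
            drug=drug,
            event=event,
            ror=float(row.ror),
            ror_low=float(row.ror_low),
            ror_high=float(row.ror_high),
        )
    return profile_panel(ph_panel(normalized=True), list(EVENTS), cells)
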