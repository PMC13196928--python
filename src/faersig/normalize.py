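"""Canonicalization of verbatim drug names and adverse-event terms.

Spontaneous reports mix brand names, generics and free-text spellings
("OPSUMIT", "opsumit 10mg" vs the active substance macitentan), and
adverse-event terms arrive as verbatim strings that regulatory practice
maps onto a controlled terminology of preferred terms (e.g. "heart
attack" -> "Myocardial infarction").  The controlled dictionary itself is
licensed, so this module takes user-supplied two-column mapping tables
instead of bundling one: unmapped inputs pass through key-normalized and
are counted, never dropped, which keeps synthetic pipelines dictionary-free.

Key normalization = trim, collapse internal whitespace, uppercase.  Both
mapping directions are idempotent by construction: canonical names map to
themselves, and a table whose canonical value is itself a mapped key is
rejected at load time.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .errors import ConfigError

_WS = re.compile(r"\s+")


def normalize_key(text: str) -> str:
    """Uppercase, trim and collapse internal whitespace.

    Raises :class:`ConfigError` on empty / whitespace-only input.
    """
    if text is None:
        raise ConfigError("empty name or term")
    key = _WS.sub(" ", str(text).strip()).upper()
    if not key:
        raise ConfigError("empty name or term")
    return key


@dataclass
class MappingTable:
    """A verbatim -> canonical mapping with idempotent semantics."""

    entries: dict[str, str] = field(default_factory=dict)
    label: str = ""
    #: number of canonicalize() calls that found no mapping (pass-through)
    unmapped: Counter = field(default_factory=Counter, repr=False, compare=False)

    def __post_init__(self) -> None:
        normalized: dict[str, str] = {}
        for raw_key, raw_value in self.entries.items():
            key = normalize_key(raw_key)
            value = normalize_key(raw_value)
            if key in normalized and normalized[key] != value:
                raise ConfigError(
                    f"{self.label or 'mapping table'}: duplicate key {key!r} "
                    f"maps to both {normalized[key]!r} and {value!r}"
                )
            normalized[key] = value
        # idempotence: every canonical value must map to itself
        for value in list(normalized.values()):
            if normalized.setdefault(value, value) != value:
                raise ConfigError(
                    f"{self.label or 'mapping table'}: canonical name {value!r} "
                    f"is itself remapped to {normalized[value]!r}"
                )
        self.entries = normalized

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]] | Mapping[str, str], label: str = "") -> "MappingTable":
        if isinstance(pairs, Mapping):
            pairs = pairs.items()
        return cls(entries=dict(pairs), label=label)

    @classmethod
    def from_tsv(cls, path: str | Path, label: str | None = None) -> "MappingTable":
        """Load a two-column TSV (verbatim <TAB> canonical); '#' comments allowed."""
        path = Path(path)
        pairs: list[tuple[str, str]] = []
        for lineno, line in enumerate(path.read_text(encoding="utf-8", errors="replace").splitlines(), 1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split("\t")
            if len(parts) < 2:
                raise ConfigError(f"{path}:{lineno}: expected two tab-separated columns")
            pairs.append((parts[0], parts[1]))
        return cls.from_pairs(pairs, label=label if label is not None else str(path))

    def canonicalize(self, raw: str) -> str:
        key = normalize_key(raw)
        mapped = self.entries.get(key)
        if mapped is None:
            self.unmapped[key] += 1
            return key
        return mapped

    def __len__(self) -> int:
        return len(self.entries)


class SynonymTable(MappingTable):
    """Brand/verbatim drug name -> canonical drug name."""


class TermMap(MappingTable):
    """Verbatim adverse-event term -> preferred term."""


def normalize_drug(name: str, table: SynonymTable | None = None) -> str:
    """Canonical drug name: mapped if present, else the key-normalized input."""
    if table is None:
        return normalize_key(name)
    return table.canonicalize(name)


def normalize_term(term: str, table: TermMap | None = None) -> str:
    """Preferred adverse-event term: mapped if present, else pass-through."""
    if table is None:
        return normalize_key(term)
    return table.canonicalize(term)
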