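"""Symptom item catalog.

A catalog is the ordered list of symptoms an instrument asks about. The
bundled default reproduces a 38-item modified Memorial Symptom Assessment
Scale (MSAS): the 32 original items plus hot flashes, chest tightness,
difficulty breathing, abdominal cramps, increased appetite and weight gain.
Each item is rated for occurrence (yes/no in the past week) and, when
present, severity (1-4) and distress (0-4).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

__all__ = ["SymptomItem", "ItemCatalog", "default_catalog", "load_catalog"]


@dataclass(frozen=True)
class SymptomItem:
    """One symptom in the instrument.

    Attributes
    ----------
    code : short stable identifier, unique within a catalog.
    label : human-readable display name.
    index : 0-based position within the catalog.
    """

    code: str
    label: str
    index: int


class ItemCatalog:
    """Ordered, code-addressable collection of :class:`SymptomItem`."""

    def __init__(self, items: Iterable[tuple[str, str]]):
        self.items = [SymptomItem(code, label, i) for i, (code, label) in enumerate(items)]
        codes = [it.code for it in self.items]
        if len(set(codes)) != len(codes):
            dupes = sorted({c for c in codes if codes.count(c) > 1})
            raise ValueError(f"duplicate item codes in catalog: {dupes}")
        self._by_code = {it.code: it for it in self.items}

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, code: str) -> SymptomItem:
        return self._by_code[code]

    def __contains__(self, code: str) -> bool:
        return code in self._by_code

    def __eq__(self, other) -> bool:
        return isinstance(other, ItemCatalog) and self.items == other.items

    @property
    def codes(self) -> list[str]:
        return [it.code for it in self.items]

    @property
    def labels(self) -> list[str]:
        return [it.label for it in self.items]

    def index_of(self, code: str) -> int:
        return self._by_code[code].index


def load_catalog(path: str | Path) -> ItemCatalog:
    """Read a two-column (code,label) CSV catalog file."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "code" not in reader.fieldnames:
            raise ValueError(f"catalog file {path} must have a 'code' column")
        rows = [(r["code"], r.get("label", r["code"])) for r in reader]
    return ItemCatalog(rows)


def default_catalog() -> ItemCatalog:
    """The bundled 38-item modified MSAS catalog."""
    ref = resources.files("symclust.data") / "item_catalog.csv"
    with resources.as_file(ref) as path:
        return load_catalog(path)
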