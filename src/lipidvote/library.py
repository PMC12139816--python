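"""Lipid/metabolite formula library and exact-formula classification.

Entries carry a LIPID MAPS-style category — FA (fatty acyls), GP
(glycerophospholipids), PK (polyketides), PR (prenol lipids), SP
(sphingolipids) — or NONLIPID for decoy metabolite entries.  Classification is
exact element-count lookup; a formula matching only decoys classifies as
NOT_LIPID and an unknown formula as NOT_CATEGORIZED.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .chem import Formula, formula_from_string, formula_to_string, monoisotopic_mass

CATEGORIES: tuple[str, ...] = ("FA", "GP", "PK", "PR", "SP")
NONLIPID = "NONLIPID"
NOT_LIPID = "NOT_LIPID"
NOT_CATEGORIZED = "NOT_CATEGORIZED"


@dataclass(frozen=True)
class LipidLibraryEntry:
    name: str
    category: str
    elements: Formula
    neutral_mass: float = field(default=0.0)

    def __post_init__(self):
        if self.category not in CATEGORIES and self.category != NONLIPID:
            raise ValueError(f"unknown category {self.category!r} for {self.name!r}")
        computed = monoisotopic_mass(self.elements)
        if self.neutral_mass == 0.0:
            object.__setattr__(self, "neutral_mass", computed)
        elif abs(self.neutral_mass - computed) > 1e-6:
            raise ValueError(
                f"{self.name!r}: stated mass {self.neutral_mass} disagrees with "
                f"{formula_to_string(self.elements)} ({computed:.6f})"
            )

    @property
    def formula(self) -> str:
        return formula_to_string(self.elements)


class LipidLibrary:
    """Indexed collection of entries supporting exact-formula classification."""

    def __init__(self, entries: list[LipidLibraryEntry]):
        if not entries:
            raise ValueError("empty library")
        names = [e.name for e in entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate entry names in library")
        self.entries = list(entries)
        self._by_formula: dict[Formula, set[str]] = {}
        for e in entries:
            self._by_formula.setdefault(e.elements, set()).add(e.category)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def lipids(self) -> list[LipidLibraryEntry]:
        return [e for e in self.entries if e.category != NONLIPID]

    def classify(self, elements: Formula) -> frozenset[str]:
        """Category set for an exact formula match.

        Lipid matches return their categories; decoy-only matches return
        {NOT_LIPID}; no match returns {NOT_CATEGORIZED}.
        """
        cats = self._by_formula.get(elements)
        if cats is None:
            return frozenset({NOT_CATEGORIZED})
        lipid_cats = cats - {NONLIPID}
        return frozenset(lipid_cats) if lipid_cats else frozenset({NOT_LIPID})


def read_library(path: str | Path) -> LipidLibrary:
    """Read a library TSV with columns name, formula (Hill notation), category."""
    df = pd.read_csv(path, sep="\t")
    required = {"name", "formula", "category"}
    if not required.issubset(df.columns):
        raise ValueError(f"library TSV {path} missing columns {required - set(df.columns)}")
    entries = [
        LipidLibraryEntry(
            name=row["name"],
            category=row["category"],
            elements=formula_from_string(row["formula"]),
        )
        for _, row in df.iterrows()
    ]
    return LipidLibrary(entries)


def write_library(library: LipidLibrary, path: str | Path) -> None:
    pd.DataFrame(
        {
            "name": [e.name for e in library],
            "formula": [e.formula for e in library],
            "category": [e.category for e in library],
        }
    ).to_csv(path, sep="\t", index=False)


def default_library() -> LipidLibrary:
    """The bundled library: 100 lipids (20 per category) plus 15 metabolite decoys."""
    with resources.as_file(
        resources.files("lipidvote.data").joinpath("lipid_library.tsv")
    ) as p:
        return read_library(p)
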