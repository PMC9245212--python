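"""Genus taxonomy: the species -> (sub)section mapping used as classifier targets.

An identifier can be trained on either of two class systems derived from the
same taxonomy table: the full species list, or the coarser list of sections
and subsections.  The bundled fixture covers the genus *Hebeloma* — 123
currently accepted species arranged in 21 (sub)sections — but any table with
the same two-column shape works.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

ClassMode = Literal["species", "section"]

__all__ = ["Taxon", "TaxonomyTable", "load_taxonomy", "ClassMode"]


@dataclass(frozen=True)
class Taxon:
    """One species and the (sub)section it belongs to."""

    species_name: str
    section_name: str


@dataclass
class TaxonomyTable:
    """Ordered list of taxa plus the closed set of section labels.

    Species order is the file order; section labels are ordered by first
    appearance, so both class systems are deterministic across runs.
    """

    taxa: list[Taxon]
    section_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[str, None] = {}
        for t in self.taxa:
            if t.species_name in seen:
                raise ValueError(f"duplicate species name: {t.species_name!r}")
            seen[t.species_name] = None
        if not self.section_labels:
            order: dict[str, None] = {}
            for t in self.taxa:
                order.setdefault(t.section_name, None)
            self.section_labels = list(order)
        else:
            known = set(self.section_labels)
            for t in self.taxa:
                if t.section_name not in known:
                    raise ValueError(
                        f"section {t.section_name!r} of {t.species_name!r} "
                        "not in section_labels"
                    )
        self._section_of = {t.species_name: t.section_name for t in self.taxa}

    def __len__(self) -> int:
        return len(self.taxa)

    def class_list(self, mode: ClassMode) -> list[str]:
        """Class labels for the requested class system, in stable order."""
        if mode == "species":
            return [t.species_name for t in self.taxa]
        if mode == "section":
            return list(self.section_labels)
        raise ValueError(f"unknown class mode: {mode!r} (use 'species' or 'section')")

    def section_of(self, species_name: str) -> str:
        """The unique section a species belongs to."""
        try:
            return self._section_of[species_name]
        except KeyError:
            raise KeyError(f"unknown species: {species_name!r}") from None

    def label_for(self, species_name: str, mode: ClassMode) -> str:
        return species_name if mode == "species" else self.section_of(species_name)


def _read_rows(handle: Iterable[str], origin: str) -> list[Taxon]:
    reader = csv.DictReader(handle)
    if reader.fieldnames is None or not {"species", "section"} <= set(reader.fieldnames):
        raise ValueError(f"{origin}: expected a CSV with header 'species,section'")
    taxa = []
    for i, row in enumerate(reader, start=2):
        sp = (row.get("species") or "").strip()
        sec = (row.get("section") or "").strip()
        if not sp or not sec:
            raise ValueError(f"{origin}: line {i}: empty species or section field")
        taxa.append(Taxon(sp, sec))
    if not taxa:
        raise ValueError(f"{origin}: no taxa found")
    return taxa


def load_taxonomy(source: str | Path | None = None) -> TaxonomyTable:
    """Load a taxonomy table from a CSV file, or the bundled Hebeloma fixture.

    Parameters
    ----------
    source
        Path to a UTF-8 CSV with header ``species,section``.  ``None`` loads
        the bundled genus fixture (123 species, 21 (sub)sections).
    """
    if source is None:
        ref = resources.files("morphoident.data") / "hebeloma_taxonomy.csv"
        with ref.open("r", encoding="utf-8") as fh:
            return TaxonomyTable(_read_rows(fh, "bundled taxonomy"))
    path = Path(source)
    with path.open("r", encoding="utf-8") as fh:
        return TaxonomyTable(_read_rows(fh, str(path)))
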