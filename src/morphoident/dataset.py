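"""Collection records: CSV I/O, group eligibility, per-class 70/30 split and
single-missing-character training augmentation.

A collection is one gathered specimen with its recorded character values.
For a given character group a collection can join a training or testing set
only if it is complete for the group — optionally allowing one missing
character, which is then filled on the *training* side with the species'
training-set average for that character ("data augmentation").  Test records
are never imputed: the fill value needs the species label, which is exactly
what prediction must not see.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .encoding import (
    CHARACTERS,
    CharacterGroup,
    ContinuousCharacterDef,
    DiscreteCharacterDef,
)

__all__ = [
    "CollectionRecord",
    "DatasetSplit",
    "read_collections_csv",
    "write_collections_csv",
    "eligible",
    "split_by_class",
    "augment_training_missing",
    "train_fraction_count",
]

RESERVED_COLUMNS = ("collection_id", "species", "continent")
MULTI_STATE_SEP = ";"
#: CSV sentinel for a discrete character observed with *no* state present
#: (a valid all-zero observation), as opposed to an empty cell = not recorded.
EMPTY_STATE_SET = "none"


@dataclass
class CollectionRecord:
    """One collection: identifier, optional labels, raw character values.

    ``values`` maps character name -> float (continuous), frozenset of state
    labels (discrete), or a fractional per-state numpy vector (discrete value
    produced by augmentation).  Missing characters are simply absent.
    """

    collection_id: str
    species: str | None = None
    continent: str | None = None
    values: dict[str, object] = field(default_factory=dict)

    def get(self, name: str) -> object | None:
        if name == "continent":
            return self.continent
        return self.values.get(name)

    def is_missing(self, name: str) -> bool:
        v = self.get(name)
        if v is None:
            return True
        return isinstance(v, float) and math.isnan(v)

    def copy(self) -> "CollectionRecord":
        return replace(self, values=dict(self.values))


def read_collections_csv(path: str | Path) -> list[CollectionRecord]:
    """Read collection records from CSV.

    Empty cells become missing characters; discrete cells may hold several
    simultaneous states separated by ';' (e.g. ``O2;O3``).  Columns that match
    no known character raise a warning and are ignored.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "collection_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'collection_id'")
    known = set(RESERVED_COLUMNS) | set(CHARACTERS)
    for col in df.columns:
        if col not in known:
            warnings.warn(f"{path}: ignoring unknown column {col!r}")
    records: list[CollectionRecord] = []
    seen_ids: set[str] = set()
    for pos, row in enumerate(df.itertuples(index=False), start=2):
        row_d = dict(zip(df.columns, row))
        cid = row_d["collection_id"].strip()
        if cid in seen_ids:
            raise ValueError(f"{path}: line {pos}: duplicate collection_id {cid!r}")
        seen_ids.add(cid)
        species = row_d.get("species", "").strip() or None
        continent = row_d.get("continent", "").strip() or None
        values: dict[str, object] = {}
        for name, cdef in CHARACTERS.items():
            if name == "continent" or name not in row_d:
                continue
            cell = row_d[name].strip()
            if not cell:
                continue
            if isinstance(cdef, ContinuousCharacterDef):
                try:
                    values[name] = float(cell)
                except ValueError:
                    raise ValueError(
                        f"{path}: line {pos}: malformed number {cell!r} "
                        f"in column {name!r}"
                    ) from None
            elif cell.lower() == EMPTY_STATE_SET:
                values[name] = frozenset()
            else:
                states = frozenset(s.strip() for s in cell.split(MULTI_STATE_SEP) if s.strip())
                unknown = states - set(cdef.states)
                if unknown:
                    raise ValueError(
                        f"{path}: line {pos}: unknown state(s) {sorted(unknown)} "
                        f"in column {name!r}"
                    )
                values[name] = states
        records.append(CollectionRecord(cid, species, continent, values))
    return records


def write_collections_csv(records: Sequence[CollectionRecord], path: str | Path) -> None:
    """Write records to CSV, the inverse of :func:`read_collections_csv`."""
    char_cols = [
        n for n in CHARACTERS if n != "continent"
        and any(not r.is_missing(n) for r in records)
    ]
    cols = list(RESERVED_COLUMNS) + char_cols
    rows = []
    for r in records:
        row: dict[str, str] = {
            "collection_id": r.collection_id,
            "species": r.species or "",
            "continent": r.continent or "",
        }
        for n in char_cols:
            v = r.get(n)
            if v is None:
                row[n] = ""
            elif isinstance(v, (set, frozenset)):
                cdef = CHARACTERS[n]
                assert isinstance(cdef, DiscreteCharacterDef)
                row[n] = (
                    MULTI_STATE_SEP.join(s for s in cdef.states if s in v)
                    if v else EMPTY_STATE_SET
                )
            elif isinstance(v, np.ndarray):
                raise ValueError(
                    f"{r.collection_id}: fractional augmented value for {n!r} "
                    "cannot be written to CSV"
                )
            else:
                row[n] = repr(float(v))
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def eligible(
    record: CollectionRecord, group: CharacterGroup, allow_one_missing: bool = False
) -> bool:
    """Whether a record can enter a training/testing set for this group.

    With ``allow_one_missing`` (the augmentation pathway) a single missing
    group character is permitted; otherwise the record must be complete.
    """
    n_missing = sum(record.is_missing(m.name) for m in group.members)
    return n_missing <= (1 if allow_one_missing else 0)


def train_fraction_count(n: int, fraction: float = 0.7) -> int:
    """Training-set size for a class of n collections: round(fraction * n),
    half rounded up, floored at 1 so singleton species stay trainable."""
    return max(1, int(math.floor(fraction * n + 0.5)))


@dataclass
class DatasetSplit:
    """Disjoint train/test partition of eligible collection ids."""

    train_ids: set[str]
    test_ids: set[str]
    seed: int

    def subset(self, records: Sequence[CollectionRecord], which: str) -> list[CollectionRecord]:
        ids = self.train_ids if which == "train" else self.test_ids
        return [r for r in records if r.collection_id in ids]


def split_by_class(
    records: Sequence[CollectionRecord],
    labels: Sequence[str] | Mapping[str, str] | None = None,
    fraction: float = 0.7,
    seed: int = 0,
) -> DatasetSplit:
    """Assign ~70% of each class to training and the rest to testing.

    Sampling is uniform and independent within each class — no balancing on
    any other property — and fully deterministic given ``seed``.  ``labels``
    defaults to the records' species labels.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    if labels is None:
        label_of = {r.collection_id: r.species for r in records}
    elif isinstance(labels, Mapping):
        label_of = {r.collection_id: labels[r.collection_id] for r in records}
    else:
        if len(labels) != len(records):
            raise ValueError("labels must parallel records")
        label_of = {r.collection_id: lab for r, lab in zip(records, labels)}
    by_class: dict[str, list[str]] = {}
    for r in records:
        lab = label_of[r.collection_id]
        if lab is None:
            raise ValueError(f"collection {r.collection_id!r} has no class label")
        by_class.setdefault(lab, []).append(r.collection_id)
    for lab, ids in by_class.items():
        if not ids:
            raise ValueError(f"class {lab!r} has no collections")
    rng = np.random.default_rng(seed)
    train: set[str] = set()
    test: set[str] = set()
    for lab in sorted(by_class):
        ids = sorted(by_class[lab])
        perm = rng.permutation(len(ids))
        k = train_fraction_count(len(ids), fraction)
        for j, p in enumerate(perm):
            (train if j < k else test).add(ids[p])
    return DatasetSplit(train_ids=train, test_ids=test, seed=seed)


def augment_training_missing(
    train_records: Sequence[CollectionRecord], group: CharacterGroup
) -> list[CollectionRecord]:
    """Fill a single missing group character with the species' training average.

    A missing continuous value becomes the arithmetic mean of that species'
    other raw training values for the character (encoded normally afterwards);
    a missing discrete character becomes the per-state mean of the species'
    multi-hot vectors, i.e. a fractional vector in [0, 1]^dims.  Records of a
    species with no donor value for the missing character are dropped with a
    warning.  Non-missing values are never altered.
    """
    out: list[CollectionRecord] = []
    for rec in train_records:
        missing = [m for m in group.members if rec.is_missing(m.name)]
        if len(missing) > 1:
            raise ValueError(
                f"collection {rec.collection_id!r} is missing "
                f"{len(missing)} group characters; at most one can be augmented"
            )
        if not missing:
            out.append(rec)
            continue
        member = missing[0]
        if rec.species is None:
            raise ValueError(
                f"collection {rec.collection_id!r} needs a species label "
                "for augmentation"
            )
        donors = [
            r for r in train_records
            if r.species == rec.species
            and r.collection_id != rec.collection_id
            and not r.is_missing(member.name)
        ]
        if not donors:
            warnings.warn(
                f"dropping {rec.collection_id!r}: no other training collection "
                f"of {rec.species!r} records {member.name!r}"
            )
            continue
        filled = rec.copy()
        if isinstance(member, ContinuousCharacterDef):
            filled.values[member.name] = float(
                np.mean([float(d.get(member.name)) for d in donors])
            )
        else:
            hot = np.zeros(member.dims)
            for d in donors:
                v = d.get(member.name)
                if isinstance(v, np.ndarray):
                    hot += v
                else:
                    hot += np.array([1.0 if s in v else 0.0 for s in member.states])
            filled.values[member.name] = hot / len(donors)
        out.append(filled)
    return out
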