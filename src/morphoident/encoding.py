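"""Character -> feature encoding onto the unit cube.

Every character of a collection is mapped, independently of all others, to
one or more feature values in [0, 1]:

* a continuously-valued character (a measurement) is pushed through the
  empirical CDF of its training-set values, so the feature is the estimated
  probability P(X <= y) and training features spread out over [0, 1];
* a discretely-valued multi-state character contributes one 0/1 slot per
  state (multi-hot: several states may be present at once).

Concatenating the encoded members of a character group gives the feature
vector — a point on or in the N-dimensional unit cube — that the neural
classifier consumes.

The empirical CDF uses Hazen plotting positions F(x_(i)) = (i - 0.5)/n at
the sorted training values, linear interpolation between adjacent distinct
values, tied values collapsed to a single knot at their mean plotting
position, and clamping to 0 below the training minimum and 1 above the
training maximum.  This keeps F single-valued, strictly inside (0, 1) at
every training value, and monotone everywhere.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence, Union

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .dataset import CollectionRecord

__all__ = [
    "EmpiricalDistribution",
    "ContinuousCharacterDef",
    "DiscreteCharacterDef",
    "CharacterGroup",
    "CHARACTERS",
    "fit_empirical_distribution",
    "encode_continuous",
    "encode_discrete",
    "assemble_feature_vector",
    "group_dimension",
    "load_character_groups",
]


@dataclass(frozen=True)
class EmpiricalDistribution:
    """Empirical CDF of a continuous character fitted on training values."""

    knots: np.ndarray  # ascending distinct training values
    probs: np.ndarray  # Hazen plotting position at each knot, in (0, 1)

    @classmethod
    def fit(cls, training_values: Sequence[float]) -> "EmpiricalDistribution":
        values = np.asarray(training_values, dtype=float)
        bad = np.flatnonzero(~np.isfinite(values))
        if bad.size:
            raise ValueError(f"non-finite training values at indices {bad.tolist()}")
        n = values.size
        if n < 2:
            raise ValueError(f"need at least 2 training values, got {n}")
        if np.min(values) == np.max(values):
            raise ValueError(
                f"degenerate distribution: all {n} training values equal "
                f"{values[0]!r} (zero spread)"
            )
        order = np.sort(values)
        positions = (np.arange(1, n + 1) - 0.5) / n
        knots, start = np.unique(order, return_index=True)
        # mean plotting position over each run of ties
        stops = np.append(start[1:], n)
        probs = np.array(
            [positions[a:b].mean() for a, b in zip(start, stops)], dtype=float
        )
        return cls(knots=knots, probs=probs)

    def cdf(self, y: float | np.ndarray) -> float | np.ndarray:
        """F(y): 0 below the training range, 1 above, interpolated inside."""
        arr = np.asarray(y, dtype=float)
        if np.isnan(arr).any():
            raise ValueError("NaN passed to cdf; missing values are handled upstream")
        out = np.interp(arr, self.knots, self.probs)
        out = np.where(arr < self.knots[0], 0.0, out)
        out = np.where(arr > self.knots[-1], 1.0, out)
        return float(out) if np.isscalar(y) else out

    @property
    def median(self) -> float:
        return float(np.interp(0.5, self.probs, self.knots))


def fit_empirical_distribution(training_values: Sequence[float]) -> EmpiricalDistribution:
    """Fit the empirical CDF of a continuous character from training values only."""
    return EmpiricalDistribution.fit(training_values)


def encode_continuous(value: float, dist: EmpiricalDistribution) -> float:
    """Feature value F(y) = P(X <= y) under the fitted training distribution."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise ValueError("NaN/None is not encodable; missingness is handled upstream")
    return float(dist.cdf(float(value)))


@dataclass(frozen=True)
class ContinuousCharacterDef:
    name: str
    units: str = ""
    distribution: EmpiricalDistribution | None = None

    @property
    def dims(self) -> int:
        return 1

    def with_distribution(self, dist: EmpiricalDistribution) -> "ContinuousCharacterDef":
        return replace(self, distribution=dist)


@dataclass(frozen=True)
class DiscreteCharacterDef:
    name: str
    states: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.states) < 1:
            raise ValueError(f"{self.name}: need at least one state")
        if len(set(self.states)) != len(self.states):
            raise ValueError(f"{self.name}: duplicate state labels")

    @property
    def dims(self) -> int:
        return len(self.states)


CharacterDef = Union[ContinuousCharacterDef, DiscreteCharacterDef]


def encode_discrete(
    states_present: Iterable[str], cdef: DiscreteCharacterDef
) -> np.ndarray:
    """Multi-hot 0/1 vector: slot i is 1 iff state i is present."""
    present = set(states_present)
    unknown = present - set(cdef.states)
    if unknown:
        raise ValueError(
            f"unknown state(s) {sorted(unknown)} for character {cdef.name!r}; "
            f"known states: {list(cdef.states)}"
        )
    return np.array([1.0 if s in present else 0.0 for s in cdef.states])


#: Registry of the characters recorded for a collection.  States for the
#: ordinal spore characters (ornamentation O1-O4, perispore loosening P0-P3,
#: dextrinoidity D0-D4), the six primary cheilocystidia shapes and the three
#: mycorrhizal host-plant families follow the recording conventions of the
#: genus database; measurements are collection averages.
CHARACTERS: dict[str, CharacterDef] = {
    c.name: c
    for c in [
        ContinuousCharacterDef("latitude", "degrees"),
        ContinuousCharacterDef("longitude", "degrees"),
        ContinuousCharacterDef("altitude", "m"),
        ContinuousCharacterDef("lamellae", "count"),
        ContinuousCharacterDef("spore_length", "um"),
        ContinuousCharacterDef("spore_width", "um"),
        ContinuousCharacterDef("spore_q", "ratio"),
        ContinuousCharacterDef("cheilocystidia_length", "um"),
        ContinuousCharacterDef("cheilocystidia_apex_width", "um"),
        ContinuousCharacterDef("cheilocystidia_am", "ratio"),
        ContinuousCharacterDef("cheilocystidia_ab", "ratio"),
        ContinuousCharacterDef("cheilocystidia_bm", "ratio"),
        ContinuousCharacterDef("basidia_q", "ratio"),
        ContinuousCharacterDef("stipe_width", "mm"),
        DiscreteCharacterDef("spore_ornamentation", ("O1", "O2", "O3", "O4")),
        DiscreteCharacterDef("perispore_loosening", ("P0", "P1", "P2", "P3")),
        DiscreteCharacterDef("dextrinoidity", ("D0", "D1", "D2", "D3", "D4")),
        DiscreteCharacterDef(
            "cheilocystidia_shape",
            (
                "cylindrical",
                "ventricose-lageniform",
                "clavate-gently",
                "clavate-stipitate",
                "clavate-ventricose",
                "pyriform",
            ),
        ),
        DiscreteCharacterDef("plant_family", ("Pinaceae", "Salicaceae", "Fagaceae")),
        # Continent enters identifiers only as a post-hoc filter, never as a
        # feature ("Is Europe / Is North America" style exclusion).
        DiscreteCharacterDef("continent", ("Europe", "North America")),
    ]
}


@dataclass
class CharacterGroup:
    """An ordered set of character definitions used together as one input.

    ``filter_only`` members (continent) never enter the feature vector; they
    are retained so a group knows which filtering features it supports.
    """

    id: str
    members: list[CharacterDef]
    filter_only: list[str] = field(default_factory=list)

    @property
    def feature_names(self) -> list[str]:
        return [m.name for m in self.members]

    @property
    def total_dims(self) -> int:
        return sum(m.dims for m in self.members)

    def member(self, name: str) -> CharacterDef:
        for m in self.members:
            if m.name == name:
                return m
        raise KeyError(f"{name!r} is not a feature member of group {self.id}")

    def with_fitted(self, distributions: Mapping[str, EmpiricalDistribution]) -> "CharacterGroup":
        """Copy of the group with empirical distributions attached to members."""
        members: list[CharacterDef] = []
        for m in self.members:
            if isinstance(m, ContinuousCharacterDef):
                if m.name not in distributions:
                    raise ValueError(f"no fitted distribution for {m.name!r}")
                members.append(m.with_distribution(distributions[m.name]))
            else:
                members.append(m)
        return CharacterGroup(self.id, members, list(self.filter_only))


def group_dimension(group: CharacterGroup) -> int:
    """Total feature dimensionality: continuous members contribute 1, discrete
    members one dimension per state."""
    return group.total_dims


def _missing(value: object) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return False


def _encode_member(value: object, member: CharacterDef) -> np.ndarray:
    if isinstance(member, ContinuousCharacterDef):
        if member.distribution is None:
            raise ValueError(
                f"character {member.name!r} has no fitted distribution; "
                "fit on the training set before encoding"
            )
        return np.array([encode_continuous(float(value), member.distribution)])
    # discrete: a state set, or an already-fractional multi-hot vector
    # produced by training-set augmentation
    if isinstance(value, np.ndarray):
        if value.shape != (member.dims,):
            raise ValueError(
                f"fractional value for {member.name!r} has shape {value.shape}, "
                f"expected ({member.dims},)"
            )
        if (value < 0).any() or (value > 1).any():
            raise ValueError(f"fractional value for {member.name!r} outside [0, 1]")
        return value.astype(float)
    if isinstance(value, (set, frozenset, list, tuple)):
        return encode_discrete(value, member)
    if isinstance(value, str):
        return encode_discrete({value}, member)
    raise TypeError(f"cannot encode value {value!r} for character {member.name!r}")


def assemble_feature_vector(record: "CollectionRecord", group: CharacterGroup) -> np.ndarray:
    """Concatenate the encoded group members, in member order.

    The record must carry a value for every feature member (augmentation of a
    single missing character happens upstream, on the training set).
    """
    missing = [m.name for m in group.members if _missing(record.get(m.name))]
    if missing:
        raise ValueError(
            f"collection {record.collection_id!r} is missing required "
            f"character(s) for group {group.id}: {missing}"
        )
    parts = [_encode_member(record.get(m.name), m) for m in group.members]
    vec = np.concatenate(parts)
    assert vec.shape == (group.total_dims,)
    return vec


def encode_records(records: Sequence["CollectionRecord"], group: CharacterGroup) -> np.ndarray:
    """Feature matrix (n_records, total_dims) for complete records."""
    return np.vstack([assemble_feature_vector(r, group) for r in records])


def fit_group_distributions(
    group: CharacterGroup, records: Sequence["CollectionRecord"]
) -> CharacterGroup:
    """Fit every continuous member's empirical CDF on the records' observed
    raw values (training set only) and return the fitted group."""
    dists: dict[str, EmpiricalDistribution] = {}
    for m in group.members:
        if isinstance(m, ContinuousCharacterDef):
            vals = [
                float(r.get(m.name))
                for r in records
                if not _missing(r.get(m.name)) and not isinstance(r.get(m.name), np.ndarray)
            ]
            try:
                dists[m.name] = fit_empirical_distribution(vals)
            except ValueError as e:
                raise ValueError(f"cannot fit {m.name!r}: {e}") from None
    return group.with_fitted(dists)


def load_character_groups(
    source: str | Path | None = None,
) -> dict[str, CharacterGroup]:
    """Load character groups from a ``group_id,character,role`` CSV.

    ``None`` loads the bundled fixture of the nine tested groups CG1-CG9 plus
    the two small section-specialist groups CGA/CGB.
    """
    if source is None:
        ref = resources.files("morphoident.data") / "character_groups.csv"
        with ref.open("r", encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh))
    else:
        with Path(source).open("r", encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh))
    groups: dict[str, CharacterGroup] = {}
    for row in rows:
        gid = row["group_id"].strip()
        name = row["character"].strip()
        role = (row.get("role") or "feature").strip()
        if name not in CHARACTERS:
            raise ValueError(f"group {gid}: unknown character {name!r}")
        g = groups.setdefault(gid, CharacterGroup(gid, []))
        if role == "filter_only":
            g.filter_only.append(name)
        elif role == "feature":
            g.members.append(CHARACTERS[name])
        else:
            raise ValueError(f"group {gid}: unknown role {role!r}")
    return groups
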