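"""Prediction-time behaviour of a calibrated identifier.

Three operations transform class-probability vectors after the network has
produced them, and all three conserve total probability:

* ``chain`` — a generalist first-pass identifier I over all classes S hands
  the mass it places on a subset T to a specialist second-pass identifier J
  trained only on T: for s in T, P(s) = P_J(s) * sum_{t in T} P_I(t), so the
  total over all species stays 1;
* ``apply_trigger`` — chaining fires only when the first pass puts at least
  a threshold (default 90%) of its mass on T, otherwise the first-pass
  prediction stands;
* ``continent_filter`` — classes excluded for the record's filter value
  (e.g. species unknown on the record's continent) get probability exactly
  zero and the survivors are renormalized.  The exclusion map can be
  supplied by an expert or implied from the training set: a class is
  "known to" a continent iff a training collection of that class came from
  it.  Implied filters inherit the training set's blind spots — a species
  whose few training collections all happen to come from one continent is
  filtered to zero anywhere else, even on a perfectly characteristic record
  — so a warning is emitted whenever filtering zeroes a class that carried
  appreciable probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np

from .encoding import assemble_feature_vector

if TYPE_CHECKING:  # pragma: no cover
    from .dataset import CollectionRecord
    from .model import CalibratedIdentifier

__all__ = [
    "Prediction",
    "ChainSpec",
    "FilterSpec",
    "predict",
    "chain",
    "chain_probabilities",
    "apply_trigger",
    "continent_filter",
    "filter_probabilities",
    "imply_filter_from_training",
]

_SUM_TOL = 1e-6


@dataclass(frozen=True)
class Prediction:
    """Ordered class labels with their probabilities for one collection."""

    classes: tuple[str, ...]
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.shape != (len(self.classes),):
            raise ValueError("one probability per class required")
        if (p < -_SUM_TOL).any():
            raise ValueError("negative probability")
        if abs(p.sum() - 1.0) > _SUM_TOL:
            raise ValueError(f"probabilities sum to {p.sum()}, not 1")
        object.__setattr__(self, "probabilities", p)

    def probability_of(self, label: str) -> float:
        return float(self.probabilities[self.classes.index(label)])

    @property
    def ranking(self) -> list[str]:
        """Classes by descending probability; ties keep class-list order."""
        order = np.argsort(-self.probabilities, kind="stable")
        return [self.classes[i] for i in order]

    def top(self, n: int = 5) -> list[tuple[str, float]]:
        return [(c, self.probability_of(c)) for c in self.ranking[:n]]


def predict(identifier: "CalibratedIdentifier", record: "CollectionRecord") -> Prediction:
    """Class probabilities for one complete record.

    No imputation happens here: a record missing any group character is
    rejected with the list of missing names.
    """
    if identifier.group is None:
        raise ValueError("identifier has no character group; use predict_proba")
    x = assemble_feature_vector(record, identifier.group)
    probs = identifier.predict_proba(x[None, :])[0]
    return Prediction(tuple(identifier.classes), probs)


@dataclass
class ChainSpec:
    """First-pass identifier + section specialist + the subset it covers."""

    first_pass: "CalibratedIdentifier"
    second_pass: "CalibratedIdentifier"
    subset: frozenset[str] = field(default_factory=frozenset)
    trigger_threshold: float = 0.90

    def __post_init__(self) -> None:
        if not self.subset:
            self.subset = frozenset(self.second_pass.classes)
        first = set(self.first_pass.classes)
        second = set(self.second_pass.classes)
        if self.subset != second:
            raise ValueError("second-pass classes must equal the chained subset T")
        if not self.subset <= first:
            raise ValueError("subset T must be contained in the first-pass classes")


def chain_probabilities(
    first: Prediction, second: Prediction, subset: frozenset[str]
) -> Prediction:
    """Combine a generalist and a specialist prediction.

    For s not in T the first-pass probability stands; for s in T the
    specialist's probability is scaled by the first pass's total mass on T,
    so the result sums to 1.
    """
    if subset >= set(first.classes):
        # full coverage: the first pass's mass on T is 1 by definition, so
        # the specialist's prediction is reproduced exactly
        mass_on_subset = 1.0
    else:
        mass_on_subset = sum(
            p for c, p in zip(first.classes, first.probabilities) if c in subset
        )
    out = np.array(
        [
            second.probability_of(c) * mass_on_subset
            if c in subset
            else first.probability_of(c)
            for c in first.classes
        ]
    )
    return Prediction(first.classes, out)


def chain(spec: ChainSpec, record: "CollectionRecord") -> Prediction:
    """Always-chained prediction (no trigger)."""
    return chain_probabilities(
        predict(spec.first_pass, record), predict(spec.second_pass, record), spec.subset
    )


def apply_trigger(spec: ChainSpec, record: "CollectionRecord") -> Prediction:
    """Chain only when the first pass puts >= threshold mass on the subset."""
    first = predict(spec.first_pass, record)
    mass = sum(p for c, p in zip(first.classes, first.probabilities) if c in spec.subset)
    if mass >= spec.trigger_threshold:
        return chain_probabilities(first, predict(spec.second_pass, record), spec.subset)
    return first


@dataclass
class FilterSpec:
    """Exclusion zones of a filtering feature.

    ``exclusion`` maps a feature value (e.g. continent name) to the set of
    classes excluded for records with that value.
    """

    feature: str = "continent"
    exclusion: Mapping[str, frozenset[str]] = field(default_factory=dict)
    source: str = "implied-from-training"

    def excluded_for(self, value: str | None) -> frozenset[str]:
        if value is None:
            return frozenset()
        return self.exclusion.get(value, frozenset())


def filter_probabilities(
    prediction: Prediction, excluded: frozenset[str], warn_threshold: float = 0.01
) -> Prediction:
    """Zero the excluded classes and renormalize the survivors."""
    if not excluded:
        return prediction
    if not excluded < set(prediction.classes):
        extra = excluded - set(prediction.classes)
        if extra:
            raise ValueError(f"excluded classes not in prediction: {sorted(extra)}")
        raise ValueError("cannot exclude every class")
    keep = np.array([c not in excluded for c in prediction.classes])
    survivors = prediction.probabilities * keep
    total = survivors.sum()
    if total <= 0:
        raise ValueError("no admissible class: all probability mass excluded")
    for c, p in zip(prediction.classes, prediction.probabilities):
        if c in excluded and p >= warn_threshold:
            warnings.warn(
                f"filter zeroes {c!r}, which held probability {p:.3f}; "
                "implied exclusion zones can hide genuine novelties"
            )
    return Prediction(prediction.classes, survivors / total)


def continent_filter(
    prediction: Prediction, record: "CollectionRecord", filter_spec: FilterSpec
) -> Prediction:
    """Apply the exclusion zone for the record's filter value.

    A record with an unknown filter value is returned unchanged — filtering
    is disabled rather than guessed.
    """
    value = record.get(filter_spec.feature)
    if isinstance(value, (set, frozenset)):
        value = next(iter(value)) if len(value) == 1 else None
    excluded = filter_spec.excluded_for(value if isinstance(value, str) else None)
    return filter_probabilities(prediction, excluded)


def imply_filter_from_training(
    train_records: Sequence["CollectionRecord"],
    classes: Sequence[str],
    feature: str = "continent",
    labels: Mapping[str, str] | None = None,
) -> FilterSpec:
    """Derive exclusion zones from the training set.

    For every observed feature value v, the excluded set is the classes with
    zero training collections carrying value v.  ``labels`` maps collection
    id -> class label (defaults to the records' species labels).
    """
    known: dict[str, set[str]] = {}
    any_value = False
    for r in train_records:
        v = r.get(feature)
        if isinstance(v, (set, frozenset)):
            vals = [s for s in v]
        elif isinstance(v, str):
            vals = [v]
        else:
            vals = []
        if not vals:
            continue
        any_value = True
        lab = labels[r.collection_id] if labels is not None else r.species
        if lab is None:
            continue
        for s in vals:
            known.setdefault(s, set()).add(lab)
    if not any_value:
        raise ValueError(f"feature {feature!r} is missing from every training record")
    exclusion = {
        v: frozenset(c for c in classes if c not in seen) for v, seen in known.items()
    }
    return FilterSpec(feature=feature, exclusion=exclusion, source="implied-from-training")
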