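"""Synthetic genus generator.

Real training data for a character-based identifier is a curated herbarium
database that cannot be bundled, so this module draws whole genera with the
statistical structure the identifier assumes: species nested in sections
(species in a section share a section-level shift, which is what makes
section assignment easier than species assignment), per-species continuous
character distributions, per-species discrete state probabilities, heavy
class imbalance (collection counts log-uniform from singletons to
hundreds), per-species continent weights, and a single-missing-character
missingness mechanism that matches the augmentation precondition.

Size-like measurements (spore and cystidia dimensions, ratios) are drawn
normal on the log scale — their real marginals are unimodal and
right-skewed — while counts and coordinates are normal on the raw scale.
Genus-level location/scale defaults are realistic for a Hebeloma-like
agaric genus (average spore length near 11 um, ranging roughly 5-20 um
across species; about 60 full-length lamellae; cystidia near 45 um).

Everything is driven by one integer seed: the same spec yields the same
genus, the same collections and byte-identical CSV output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dataset import CollectionRecord
from .encoding import CHARACTERS, DiscreteCharacterDef, load_character_groups
from .model import TrainingConfig, fit_identifier
from .taxonomy import Taxon, TaxonomyTable

__all__ = [
    "GenusSpec",
    "SyntheticTruth",
    "draw_genus",
    "simulate_collections",
    "end_to_end_recovery",
]

# genus-level location, within-species spread, and scale of each continuous
# character: (mu, sd, on_log_scale)
CONTINUOUS_PARAMS: dict[str, tuple[float, float, bool]] = {
    "latitude": (50.0, 4.0, False),
    "longitude": (10.0, 15.0, False),
    "altitude": (600.0, 250.0, False),
    "lamellae": (60.0, 8.0, False),
    "spore_length": (math.log(11.0), 0.08, True),
    "spore_width": (math.log(6.5), 0.07, True),
    "spore_q": (math.log(1.75), 0.05, True),
    "cheilocystidia_length": (math.log(45.0), 0.12, True),
    "cheilocystidia_apex_width": (math.log(7.5), 0.10, True),
    "cheilocystidia_am": (math.log(1.3), 0.06, True),
    "cheilocystidia_ab": (math.log(1.2), 0.06, True),
    "cheilocystidia_bm": (math.log(1.15), 0.05, True),
    "basidia_q": (math.log(1.3), 0.05, True),
    "stipe_width": (math.log(3.0), 0.15, True),
}

# longitude offset applied per collection continent (keeps the geographic
# characters informative about the continent without a dedicated feature)
CONTINENT_LON_OFFSET = {"Europe": 0.0, "North America": -100.0}

DISCRETE_BASE_LOGIT = {
    "spore_ornamentation": -1.0,
    "perispore_loosening": -1.0,
    "dextrinoidity": -1.0,
    "cheilocystidia_shape": -1.5,
    "plant_family": -1.0,
}


@dataclass
class GenusSpec:
    """Parameters of a synthetic genus.

    ``separation`` scales the spread of species-level character means
    relative to the within-species spread; section-level shifts are drawn at
    the full ``separation`` scale and species-level shifts at half of it, so
    congeners in one section resemble each other more than species across
    sections do.
    """

    n_sections: int = 4
    species_per_section: int | tuple[int, int] = 5
    collections_per_species: int | tuple[int, int] = (3, 200)
    missing_rate: float = 0.1
    separation: float = 3.0
    continents: tuple[str, ...] = ("Europe", "North America")
    p_both_continents: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.n_sections < 1:
            raise ValueError("invalid n_sections: must be >= 1")
        lo, hi = self._range(self.species_per_section)
        if lo < 1:
            raise ValueError("invalid species_per_section: must be >= 1")
        lo, hi = self._range(self.collections_per_species)
        if lo < 1:
            raise ValueError("invalid collections_per_species: must be >= 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("invalid missing_rate: must be in [0, 1)")
        if self.separation <= 0:
            raise ValueError("invalid separation: must be > 0")
        if not self.continents:
            raise ValueError("invalid continents: need at least one")
        if not 0 <= self.p_both_continents <= 1:
            raise ValueError("invalid p_both_continents: must be in [0, 1]")

    @staticmethod
    def _range(value: int | tuple[int, int]) -> tuple[int, int]:
        if isinstance(value, int):
            return value, value
        lo, hi = value
        return int(lo), int(hi)


@dataclass
class SpeciesParams:
    name: str
    section: str
    continuous_mu: dict[str, float]
    state_probs: dict[str, np.ndarray]
    continent_weights: dict[str, float]
    n_collections: int


@dataclass
class SyntheticTruth:
    """Realized per-species parameters and planned collection counts."""

    taxonomy: TaxonomyTable
    species: list[SpeciesParams] = field(default_factory=list)


def _log_uniform_int(rng: np.random.Generator, lo: int, hi: int) -> int:
    if lo == hi:
        return lo
    return int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))


def draw_genus(spec: GenusSpec) -> tuple[TaxonomyTable, SyntheticTruth]:
    """Draw the taxonomy and the per-species true parameters."""
    spec.validate()
    rng = np.random.default_rng([spec.seed, 0])
    sp_lo, sp_hi = spec._range(spec.species_per_section)
    col_lo, col_hi = spec._range(spec.collections_per_species)

    taxa: list[Taxon] = []
    species: list[SpeciesParams] = []
    discrete = {
        n: d
        for n, d in CHARACTERS.items()
        if isinstance(d, DiscreteCharacterDef) and n != "continent"
    }
    for s in range(spec.n_sections):
        section = f"section_{s + 1:02d}"
        # shared section-level shifts
        cont_section = {
            name: spec.separation * sd * rng.standard_normal()
            for name, (_, sd, _) in CONTINUOUS_PARAMS.items()
        }
        disc_section = {
            name: spec.separation * rng.standard_normal(d.dims)
            for name, d in discrete.items()
        }
        n_species = int(rng.integers(sp_lo, sp_hi + 1))
        for k in range(n_species):
            name = f"species_{s + 1:02d}_{k + 1:02d}"
            taxa.append(Taxon(name, section))
            mu = {
                cname: g_mu + cont_section[cname] + 0.5 * spec.separation * sd * rng.standard_normal()
                for cname, (g_mu, sd, _) in CONTINUOUS_PARAMS.items()
            }
            probs = {}
            for cname, d in discrete.items():
                logit = (
                    DISCRETE_BASE_LOGIT[cname]
                    + disc_section[cname]
                    + 0.5 * spec.separation * rng.standard_normal(d.dims)
                )
                probs[cname] = 1.0 / (1.0 + np.exp(-logit))
            home = spec.continents[int(rng.integers(len(spec.continents)))]
            weights = {home: 1.0}
            if len(spec.continents) > 1 and rng.random() < spec.p_both_continents:
                other = [c for c in spec.continents if c != home]
                second = other[int(rng.integers(len(other)))]
                weights = {home: 0.75, second: 0.25}
            species.append(
                SpeciesParams(
                    name=name,
                    section=section,
                    continuous_mu=mu,
                    state_probs=probs,
                    continent_weights=weights,
                    n_collections=_log_uniform_int(rng, col_lo, col_hi),
                )
            )
    table = TaxonomyTable(taxa)
    return table, SyntheticTruth(taxonomy=table, species=species)


def simulate_collections(truth: SyntheticTruth, spec: GenusSpec) -> list[CollectionRecord]:
    """Draw collection records from the realized species parameters.

    With probability ``missing_rate`` a record loses exactly one character
    (never more), matching the single-missing-character augmentation rule.
    """
    spec.validate()
    rng = np.random.default_rng([spec.seed, 1])
    records: list[CollectionRecord] = []
    counter = 0
    for sp in truth.species:
        conts = list(sp.continent_weights)
        cont_p = np.array([sp.continent_weights[c] for c in conts])
        cont_p = cont_p / cont_p.sum()
        for _ in range(sp.n_collections):
            counter += 1
            continent = conts[int(rng.choice(len(conts), p=cont_p))]
            values: dict[str, object] = {}
            for cname, (_, sd, on_log) in CONTINUOUS_PARAMS.items():
                v = sp.continuous_mu[cname] + sd * rng.standard_normal()
                if cname == "longitude":
                    v += CONTINENT_LON_OFFSET.get(continent, 0.0)
                values[cname] = float(math.exp(v)) if on_log else float(v)
            for cname, p in sp.state_probs.items():
                d = CHARACTERS[cname]
                assert isinstance(d, DiscreteCharacterDef)
                present = rng.random(d.dims) < p
                values[cname] = frozenset(
                    s for s, hit in zip(d.states, present) if hit
                )
            if spec.missing_rate and rng.random() < spec.missing_rate:
                victim = list(values)[int(rng.integers(len(values)))]
                del values[victim]
            records.append(
                CollectionRecord(
                    collection_id=f"SYN{counter:05d}",
                    species=sp.name,
                    continent=continent,
                    values=values,
                )
            )
    return records


def end_to_end_recovery(
    spec: GenusSpec,
    group=None,
    config: TrainingConfig | None = None,
    modes: Sequence[str] = ("species", "section"),
):
    """Generate a genus, calibrate identifiers, and score them on held-out data.

    Runs draw -> simulate -> split -> augment -> fit -> evaluate for each
    requested class mode and returns ``{mode: MetricReport}``.  The default
    training configuration uses AdamW with AMSGrad at a single learning rate
    (0.005) so a recovery run stays fast; pass a full config to grid-search.
    """
    from .metrics import evaluate  # local import; metrics sits above model

    if group is None:
        group = load_character_groups()["CG7"]
    if config is None:
        config = TrainingConfig(
            optimizer="adamw", amsgrad=True, learning_rates=(0.005,), seed=spec.seed
        )
    taxonomy, truth = draw_genus(spec)
    records = simulate_collections(truth, spec)
    reports = {}
    for mode in modes:
        fit = fit_identifier(
            records, group, mode=mode, taxonomy=taxonomy, config=config
        )
        reports[mode] = evaluate(fit.identifier, fit.test_records, taxonomy=taxonomy)
    return reports
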