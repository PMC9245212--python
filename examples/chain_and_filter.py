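"""Second-pass chaining and continent filtering.

Shows the two post-hoc enhancements of a calibrated identifier:

* chaining: when the first pass is confident (>= 90% mass) that a
  collection belongs to one section, a specialist identifier trained only
  on that section redistributes the mass within it;
* continent filtering: classes unknown on the record's continent (in the
  training set) are zeroed and the survivors renormalized — including the
  blind-spot hazard where the filter zeroes the *true* species because its
  few training collections all came from the other continent.
"""

import warnings

import morphoident as mi

spec = mi.GenusSpec(n_sections=3, species_per_section=3,
                    collections_per_species=24, separation=3.0, seed=11)
taxonomy, truth = mi.draw_genus(spec)
records = mi.simulate_collections(truth, spec)
groups = mi.load_character_groups()
config = mi.TrainingConfig(optimizer="adamw", amsgrad=True,
                           learning_rates=(0.005,), seed=spec.seed)

# first pass: whole genus; second pass: specialist on one section
first = mi.fit_identifier(records, groups["CG7"], "species", taxonomy, config)
section = taxonomy.section_labels[0]
in_section = [r for r in records if taxonomy.section_of(r.species) == section]
second = mi.fit_identifier(in_section, groups["CGA"], "species", None, config)
chain_spec = mi.ChainSpec(first.identifier, second.identifier,
                          frozenset(second.identifier.classes), 0.90)

rec = next(r for r in first.test_records
           if r.species in chain_spec.subset
           and mi.eligible(r, second.identifier.group))
base = mi.predict(first.identifier, rec)
mass = sum(base.probability_of(c) for c in chain_spec.subset)
out = mi.apply_trigger(chain_spec, rec)
print(f"Query {rec.collection_id} (true: {rec.species})")
print(f"  first-pass mass on {section}: {mass:.3f} "
      f"-> second pass {'fired' if mass >= 0.9 else 'not triggered'}")
print("  top 3 after trigger:", [(c, round(p, 3)) for c, p in out.top(3)])
print("  total probability:", round(float(out.probabilities.sum()), 6), "\n")

# continent filter implied from the training set, with a forced blind spot
victim = first.identifier.classes[0]
train = []
for r in records:
    if r.collection_id in first.split.train_ids:
        r = r.copy()
        if r.species == victim:
            r.continent = "North America"  # victim now 'unknown' in Europe
        train.append(r)
fspec = mi.imply_filter_from_training(train, first.identifier.classes)
query = next(r.copy() for r in first.test_records if r.species == victim)
query.continent = "Europe"
pred = mi.predict(first.identifier, query)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    filtered = mi.continent_filter(pred, query, fspec)
print(f"Blind-spot hazard: {victim} trained only from North America")
print(f"  unfiltered probability of the true species: "
      f"{pred.probability_of(victim):.3f}")
print(f"  filtered probability:                       "
      f"{filtered.probability_of(victim):.3f}")
print("The filter zeroes the correct answer: implied exclusion zones only")
print("know what the training set happened to contain.")
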