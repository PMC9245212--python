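"""Calibrating species and section identifiers on a synthetic genus.

Draws a well-separated genus of 20 species in 4 sections, simulates 40
collections per species, splits 70/30 within each class, augments
single-missing training records, calibrates one identifier per class
system, and scores both on the held-out 30%.
"""

import morphoident as mi

spec = mi.GenusSpec(
    n_sections=4,
    species_per_section=5,
    collections_per_species=40,
    separation=3.0,   # between-species spread in units of within-species sd
    missing_rate=0.1,  # ~10% of records lose one character
    seed=1,
)
taxonomy, truth = mi.draw_genus(spec)
records = mi.simulate_collections(truth, spec)
print(f"Synthetic genus: {len(taxonomy)} species, "
      f"{len(taxonomy.section_labels)} sections, {len(records)} collections\n")

group = mi.load_character_groups()["CG7"]
config = mi.TrainingConfig(
    optimizer="adamw", amsgrad=True, learning_rates=(0.005,), seed=spec.seed
)

for mode in ("species", "section"):
    fit = mi.fit_identifier(records, group, mode=mode, taxonomy=taxonomy, config=config)
    report = mi.evaluate(fit.identifier, fit.test_records, taxonomy=taxonomy)
    s = report.scaled()
    print(f"{mode} identifier (CG7, {len(fit.identifier.classes)} classes), "
          f"test n={s['n']}:")
    print(f"  Top-1 {s['top1']}, Top-3 {s['top3']}, Top-5 {s['top5']}, "
          f"MRR {s['mrr']}, macro-F1 {s['macro_f1']}  (all /100)")

print("\nSection assignment is the coarser task — fewer classes, shared")
print("section-level character shifts — so its scores sit at or above the")
print("species scores, the qualitative pattern expected of real genera.")
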