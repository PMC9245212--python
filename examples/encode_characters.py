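"""Encoding characters onto the unit cube.

Fits an empirical CDF to a handful of spore-length measurements, encodes
new values through it, and shows how a character group's feature vector is
assembled from continuous and multi-state characters.
"""

import morphoident as mi

# --- continuous characters: empirical-CDF features -------------------------
training_spore_lengths = [8.0, 10.0, 11.0, 12.0, 14.0]  # um, training set only
dist = mi.fit_empirical_distribution(training_spore_lengths)

print("Empirical CDF fitted on", training_spore_lengths)
for y in (7.0, 10.5, 11.0, 14.0, 20.0):
    print(f"  F({y:5.1f} um) = {mi.encode_continuous(y, dist):.3f}")
print("The feature is P(X <= y) among training collections: the median maps")
print("to 0.5, values outside the observed range clamp to 0 or 1.\n")

# --- discrete characters: one 0/1 slot per state ----------------------------
orn = mi.CHARACTERS["spore_ornamentation"]
vec = mi.encode_discrete({"O2", "O3"}, orn)
print(f"Spore ornamentation O2+O3 over states {list(orn.states)} -> {vec.tolist()}")
print("Several states may be present at once (multi-hot).\n")

# --- character groups --------------------------------------------------------
groups = mi.load_character_groups()
print("Bundled character groups and their feature dimensionalities:")
for gid in sorted(groups):
    g = groups[gid]
    print(f"  {gid}: {len(g.members):2d} characters -> {mi.group_dimension(g):2d} dims")
print("\nCG1 (19 dims) uses only spores + geography; CG8 (32 dims) adds")
print("lamellae, cystidia measurements/ratios/shape and basidia Q; CG9 (33)")
print("swaps two ratio characters for the associating plant family.")
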