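# Methods

## The identification model

A collection is the classification unit: one gathered specimen with
recorded macro/microscopic characters. Given a character group — an
ordered subset of the available characters — a collection is represented
as a point in the unit cube and mapped to a probability vector over a
closed class list, either the species of the genus or its (sub)sections.
Two assumptions are inherited from the data-collection process and are not
modelled: the expert species assignments used as training labels are taken
as ground truth (no label noise), and character measurements carry no
explicit error term.

### Encoding

Continuous characters are encoded through the empirical CDF of the
*training* values only; test and query values pass through the frozen
CDF. The CDF places Hazen plotting positions F(x₍ᵢ₎) = (i − 0.5)/n at the
sorted training values, interpolates linearly between adjacent distinct
values, collapses tied values to a single knot at their mean plotting
position, and clamps to 0 below the training minimum and 1 above the
maximum. Consequences that the tests rely on: F is monotone, single-valued
and in (0, 1) at every training value; a training sample pushed through its
own CDF is nearly uniform (the Kolmogorov–Smirnov statistic against U(0,1)
is 0.5/n plus interpolation error); the training median encodes to 0.5
(±1/n). A character whose training values are all identical carries no
information under this encoding and is rejected as degenerate rather than
silently encoded. NaN inputs are an error: missingness is handled before
encoding, never inside it.

Discrete multi-state characters contribute one 0/1 slot per state,
multi-hot, so simultaneous states ("O2; O3") are representable. Latitude,
longitude and altitude are encoded like any other continuous character; no
wraparound is applied to longitude (the genus fixture's range does not
cross the antimeridian, and a synthetic genus inherits whatever range its
spec draws).

The character registry and the group memberships (CG1–CG9 plus the two
small section-specialist groups CGA/CGB) are data, not code: a
`group_id,character,role` CSV shipped with the package and replaceable by
the user. The continent pair is `filter_only` in every group — it never
enters a feature vector and exists only for post-hoc filtering. Stipe
width is registered as an available character although no bundled group
uses it; user-defined groups may.

### Dataset handling

Within every class, 70% of collections are assigned to training and 30% to
testing, independently per class with no balancing on any other property.
The training count for a class of n is max(1, ⌊0.7 n + 0.5⌋) — explicit
half-up rounding rather than the platform's banker's rounding, and floored
at 1 so singleton species remain trainable (they then simply have no test
records).

Augmentation admits a training record missing exactly one group character:
a missing continuous value is filled with the arithmetic mean of the
species' other raw training values for that character and then encoded
normally; a missing discrete character is filled with the species'
per-state training frequencies — a fractional multi-hot vector, which stays
inside the cube. Records of a species with no donor value are dropped with
a warning. Augmentation is training-only by design: the fill value is
conditioned on the species label, which is exactly what prediction must
not see, so test records must be complete for the group.

### Network and calibration

The network shape is a rule, not a hyperparameter: one or two hidden
layers, each of dimension max(N, M) for N input features and M classes,
ReLU or Mish activations, softmax output. The loss is the *sum* (not mean)
of natural-log cross-entropies over the training set. Training is
full-batch gradient descent — at these sizes (tens of features, hundreds
to thousands of rows) an epoch is a handful of matrix products, and
removing mini-batching removes a nondeterminism source. Optimizers: SGD,
Adam, AdamW, the latter two optionally with AMSGrad (five combinations).
AdamW uses decoupled weight decay 0.01 by default; Adam and SGD use none.
Weight initialization is uniform in ±1/√fan_in from a generator seeded by
the run seed, so identical configurations produce byte-identical weights.

Default learning-rate grids: {0.0001, 0.0002, 0.0005, 0.001, 0.002, 0.005,
0.01, 0.02, 0.05} for Adam/AdamW and {0.05, 0.1, 0.2} for SGD. Each rate
runs for at most 1000 epochs, stopping early when the loss has failed to
improve by 1e-9 for 50 consecutive epochs; the parameters kept are the
best-loss ones seen, so the final training loss never exceeds the initial
one even if late steps overshoot. The winning rate is chosen by MRR on a
per-class 15% carve-out of the training data — the test set plays no role
in selection — and the winner is then retrained on the full training set
at that rate. A diverged rate (NaN/inf loss) is recorded in the score
table and skipped; only if every rate diverges does calibration fail.

Degenerate cases behave predictably: a single-class problem yields constant
probability 1 and zero loss; at very small hidden widths ReLU can start
with every hidden unit dead (zero gradient, uniform output forever), which
Mish avoids — irrelevant at the rule's realistic widths but worth knowing
when building toy problems.

The deployable artifact bundles the fitted group (encoding knots and
probabilities per continuous character), network weights, class list, and
provenance (seed, optimizer, selected rate, per-rate score table, config
digest) into one versioned JSON archive. JSON numbers use Python's
shortest-repr floats, which round-trip bit-exactly; a loaded archive
predicts identically to the in-memory identifier.

### Prediction-time operations

`predict` rejects incomplete records (no silent imputation) and returns
the full probability vector with a ranking that breaks probability ties by
class-list order. For scoring, ties are handled pessimistically: the true
class ranks after every tied competitor, making reported Top-N
conservative and deterministic.

Chaining: for first pass I over classes S and specialist J over T ⊂ S, the
combined probability is P_I,s for s ∉ T and P_J,s · Σ_{t∈T} P_I,t for
s ∈ T, which conserves total probability by construction (the specialist
redistributes exactly the mass the first pass placed on T). When T = S the
subset mass is 1 by definition and the specialist's prediction is
reproduced exactly. The trigger applies the chain only when the first
pass's mass on T is ≥ 90% (≥, not >); with both chaining and filtering
active, chaining is applied first.

Filtering: classes in the exclusion zone for the record's filter value get
exactly 0 and survivors are renormalized. Exclusion zones may be
expert-supplied or implied from the training set (a class is "known to" a
continent iff a training record of that class has it). The implied source
is the default but is hazard-prone: a species whose few training
collections happen to come from one continent is zeroed everywhere else,
even on a record of that very species, so the filter warns whenever it
zeroes a class holding ≥ 1% probability. A record with an unknown filter
value is left unfiltered rather than guessed. If a filter would zero all
mass, that is an error, not a renormalization of nothing.

### Metrics

Rank K = position of the true class in the descending probability order
under the pessimistic tie rule. Top-N is the proportion with rank ≤ N
(N = 1, 3, 5); MRR is the mean of 1/rank; macro-F1 is the unweighted mean
of per-class F1 = 2PR/(P+R) with P = TP/(TP+FP), R = TP/(TP+FN), where
top-1 predictions define the confusion counts. The macro average runs over
classes with at least one true test instance; classes appearing only as
false positives are listed in the per-class table (their F1 is 0) but not
averaged, and classes absent from both truth and predictions are excluded
— a test set cannot measure them. Zero denominators yield 0. Reports carry
both the 0–1 scale and the conventional /100 presentation.

## The synthetic genus generator

The generator exists so that calibration, chaining, filtering and the
metrics are testable end-to-end without a curated collections database. It
draws a two-level hierarchy: per character, a section-level shift shared by
the section's species (standard deviation = separation × within-species
sd) plus an independent species-level shift at half that scale. Sections
therefore differ more than congeners within a section, which is what makes
section assignment the easier task — a qualitative property the recovery
tests assert, not a quantity calibrated to any particular dataset.

Size-like characters (spore and cystidia dimensions and ratios, stipe
width) are normal on the log scale; counts and coordinates are normal raw.
Genus-level defaults are realistic for a Hebeloma-like agaric: average
spore length centred near 11 µm and ranging roughly 5–20 µm across
species at the default separation, about 60 full-length lamellae, cystidia
near 45 µm. Discrete state probabilities come from a logistic model with
the same section/species shift structure. Each species has a home
continent, 15% of species occur on a second one, and collection longitude
carries a continent offset so geography is informative. Collection counts
per species are log-uniform in [3, 200] by default — singletons through
abundant species, so class imbalance and the singleton-goes-to-training
rule are exercised. Missingness removes at most one character per record
(with the configured probability), matching the augmentation precondition.

What the generator does **not** emulate: measurement error and
inter-observer subjectivity in discrete codes, correlations between
characters within a species (characters are drawn independently given the
species), real geographic clustering, label noise, and any resemblance to
an actual genus' parameter values. Passing recovery tests therefore show
that the pipeline recovers structure the model assumes; they do not
predict accuracy on real collections, where those unmodelled effects
dominate the error budget.

## Problem sizes used in tests and the acceptance script

The recovery harness uses genera of 20 species in 4 sections with 40
collections per species at separation 3.0, five seeds, with a single
learning rate (AdamW + AMSGrad at 0.005) rather than the full nine-rate
grid; at these sizes one calibration takes a few seconds and the whole
recovery block well under a minute, while leaving the qualitative
conclusions (held-out species Top-1 ≥ 0.9, section never harder than
species) unchanged. The conservation checks use 10,000 random cube points
through a fitted network and 1,000 random probability vectors per
transformation; the uniformization check uses n = 500 training values.

## Known limitations

* The identifier answers *what*, not *why*: no per-character attribution
  of a prediction is provided.
* No uncertainty on the probabilities themselves (no ensembling or
  bootstrap; a single calibrated network per identifier).
* Character groups are fixed inputs; the package does not search for good
  groups automatically.
* The implied continent filter inherits training-set blind spots by
  construction; treat its zeros as "unknown to the training set", not
  "impossible".
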