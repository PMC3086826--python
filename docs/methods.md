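# Methods

## The linkage model

Deterministic linkage accepts a pair only on complete agreement of a
stated identifier combination. With no person-level unique identifier,
accuracy comes from the *order* of combinations: the first iteration
uses the most distinctive key available (Medicare stem + name suffix +
full demographics), and each later iteration relaxes exactly one thing —
a postcode slot, a suffix letter, one demographic variable — so that a
record matched early can never be claimed by a looser rule. Removal of
matched records from both pools after every iteration is what gives the
plan its precedence semantics; it also makes the per-iteration counts a
partition of the cohort (`remaining_i = remaining_{i-1} - linked_i`).

Acceptance within an iteration is one-to-one and simultaneous: a key
value occurring more than once on either side links nobody in that
iteration. This is the conservative reading of "accept only on identical
identifiers" for a one-to-one linkage; the alternative (arbitrary
tie-breaking) manufactures false positives from families and
demographic twins. Ambiguous records stay eligible for later, more
specific-in-a-different-way iterations, and every ambiguity is logged
with its candidate count for audit.

Consequences worth knowing:

* permuting iterations can change the result — plans are versioned
  artefacts (YAML configs, golden-pinned in the tests), not incidental
  orderings;
* cumulative links over a plan prefix are monotone: appending
  iterations never unlinks anyone;
* input row order is irrelevant (set semantics per iteration).

## Privacy-preserving keys

Selected field values are joined with a reserved separator (stripped
from all data at normalisation, making serialisation injective) and
digested with **HMAC-SHA-256** under a run secret. A keyed digest rather
than a plain hash means an adversary holding the digests cannot
dictionary-attack the identifier space without the key. Digest equality
equals plaintext equality up to SHA-256 collisions; the test suite
certifies digest-space runs against a plaintext brute-force matcher.
Encryption is applied per composite key, not per field, so no per-field
frequency information leaks. If **any** selected field is missing the
whole key is missing and the record sits out that iteration — a partial
key would otherwise let missingness act as a wildcard.

## Normalisation

* suffix: diacritics stripped, non-alphabetic characters removed,
  uppercased, first 3 letters; missing if fewer than 3 remain;
* Medicare stem: digits only, first 8; missing if fewer than 8;
* country of birth: uppercase, whitespace collapsed, exact comparison
  (no fuzzy country matching);
* hospital names (validation only): additionally punctuation-stripped;
* postcodes: an ordered list of up to 4 distinct codes per person; slot
  *k* is only touched by iterations naming slot *k*;
* sex: strictly M/F; anything else is a row diagnostic.

Readers never silently drop a row: every input row becomes exactly one
record or one diagnostic.

## Parameters that matter

| parameter | default | meaning |
|-----------|---------|---------|
| `window_days` | 10 | date tolerance (inclusive, both admission and discharge) when corroborating a confirmed admission; discharge skipped when the gold record lacks it |
| Wilson CI | 95% | interval for sensitivity; Wilson chosen over the Wald interval for small-n behaviour (Clopper–Pearson gives the same values at the reported precision) |
| secret | — | run-scoped HMAC key; changing it changes every digest but no match decision |

The ±10-day inclusive reading on both dates is the strictest
interpretation that still tolerates medical-record abstraction slop; the
window widening is monotone in the number of corroborated events
(tested).

## The synthetic generator

`simdata.generate` emulates the study conditions of a cohort linked to a
state-wide admissions dataset:

* every cohort participant has exactly one true hospital person (the
  truth mapping is the identity), so ground-truth sensitivity/PPV are
  computable;
* Medicare stem availability: 100% cohort-side, 80% hospital-side
  (defaults);
* day-of-birth entry errors offset the date by a uniform 2–10 days
  (sign random); gross errors shift the year by a uniform 1–40 years —
  the two error magnitudes observed in disagreeing links;
* postcode churn pushes a new postcode into slot 1 hospital-side,
  displacing matches to later postcode-slot iterations;
* families share a Medicare stem; half of generated relatives also share
  the 3-letter suffix (CHRISTOPHER/CHRISTINE), reproducing the
  family-member mismatch mode;
* hospital-side suffixes occasionally derive from a middle name;
* distractor population: unrelated hospital-only persons at 2× the
  cohort size by default, plus optional demographic *twins* (same DOB,
  sex, country, postcodes; different name and card) via `twin_rate` or
  `inject_twins`.

Rates the source conditions do not quantify (postcode churn 0.10,
day-error 0.02, gross 0.005, COB 0.01, sex 0.005, middle-name suffix
0.02, family share 0.05) were fixed once at values plausible for a
multi-decade administrative collection; they are ordinary knobs, not
fitted quantities. Medicare-number change on family-circumstance change
is exposed (`medicare_change_rate`) and defaults to 0 because its
real-world rate is unknown.

What the generator does **not** model: hospital catchment geography,
Medicare check-digit structure, realistic name frequencies, correlated
errors (e.g. a clerk mangling several fields of one record), or cohort
members genuinely absent from the hospital data. Passing tests therefore
demonstrate algorithmic correctness and directional behaviour (error
rates degrade demographics-only linkage; the suffix suppresses twin
false positives), not the match proportions any particular real dataset
would yield.

## The final plan's expansion

The three-stage final plan is generated from its relaxation rules:
stage A (Medicare stem + suffix) = full-key postcode sweep, the sweep
under each of the three 2-letter suffix variants, drop-one over
{postcode, COB, sex, day, month, year} (dropping "postcode" removes the
slot sweep, leaving one iteration), suffix variants × drop-one, then
drop-two over all 15 variable pairs (45 iterations: 5 postcode-containing
pairs collapse to one iteration each, 10 pairs sweep 4 slots); stage B
(Medicare stem) = sweep + drop-one; stage C (suffix) = sweep. Stage
anchors are never dropped within their own stage, suffix-variant
iterations retain the full demographic set, and no iteration relaxes
more than two demographic variables. The generator emits **174**
iterations; published step numberings of comparable plans do not
enumerate cleanly from any consistent rule set, so the rules are treated
as the method and the expansion is regression-pinned by golden files.

## Numerical and degenerate-input choices

* all randomness flows through one `numpy` generator per call; same
  seed, same world, byte-identical CSVs;
* ties/ordering: links and logs are sorted by ID so exports are stable;
* empty plan, duplicate record IDs, empty HMAC secret, cross-spec digest
  comparison, non-one-to-one truth mappings: all raise immediately
  rather than degrade;
* `ground_truth_metrics` on a run with zero links reports PPV 1.0 (no
  link made is false) and sensitivity 0;
* leap-day birth dates shifted into a non-leap year clamp to 28 February.

## Problem sizes

The shipped tests and the acceptance script run cohorts of 100–2000 with
distractor multipliers up to 3 and the 174-iteration final plan; a
2000-participant world links in about a second on one core. These sizes
give binomial noise small enough for 3-standard-deviation rate-recovery
checks while keeping the whole suite fast; the engine itself is linear
in records × iterations and has no size-specific constants.

## Known limitations

* One cohort participant per hospital person is enforced; a cohort
  containing true duplicates of one person will leave the duplicates
  ambiguous forever rather than share the hospital record.
* No probabilistic (Fellegi–Sunter) scoring, string similarity, phonetic
  encodings, or clerical-review queue — exact equality only, by design.
* Specificity on real data is not estimable from within the package;
  `ground_truth_metrics` provides it only where truth is known
  (synthetic worlds).
* The agreement report adjudicates nothing: it counts disagreements and
  exports the pairs; deciding which run is right needs external
  information.
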