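# Methods

This note documents the models, parameters and design choices behind
`arisurv`: what each stage computes, which knobs matter, what the
synthetic data do and do not emulate, and the numerical conventions used
throughout.

## Terminology and ECL subset

A terminology is a directed acyclic graph of *is-a* edges (child →
parent); polyhierarchy (multiple parents) is permitted but not required.
Acyclicity is enforced on every edge insertion. Descendant queries are
answered from a transitive closure computed lazily once per graph state
and invalidated on any mutation, so queries always reflect the current
graph. Codes are opaque strings: the synthetic terminology uses readable
identifiers, and genuine SNOMED CT identifiers pass through unchanged.

The ECL evaluator covers the subset actually used by descendant/exclusion
style codelist rules: `<<C`, `<C`, bare `C`, infix `AND`, `OR`, `MINUS`,
and parentheses. Full ECL (refinements, attributes, member-of) is out of
scope. Unary constraints bind tightest; the three infix operators share
one precedence level and associate left-to-right. Because mixed unbracketed
chains are easy to misread, the canonical printer emits fully
parenthesised output, and the shipped rules always bracket `MINUS`
exclusions explicitly. The parser is a small hand-written
recursive-descent parser (six productions) that reports the character
position of any syntax error; empty input is an error.

## Indicator hierarchy and codelists

The three-level ARI model is data, not code: a JSON document listing the
five level-2 groups and the 16 level-3 indicators with their ECL rules
(1 ILI, 3 ECLD, 4 LRTI, 6 URTI, 2 ARI-NOS). Structural invariants
(unique ids, every level-3 under a declared group, no childless group) are
validated on load; the canonical 16/1-3-4-6-2 shape is checked separately
so that reduced hierarchies remain usable in unit tests and exploratory
work. Level-2 and level-1 codelists are always unions of their children —
only level 3 is authored. A code may legitimately appear in several
level-3 codelists (that is what polyhierarchy means); the ambiguity is
resolved at case classification time, not by editing codelists.

The validation set-analysis between two codelists reports sizes,
intersection and both differences; its percentage change (and every other
reported percentage) is `100·(new − old)/old`, rounded half-up to one
decimal at presentation only. An empty baseline makes the percentage
undefined and is flagged rather than coerced.

`code_frequency_coverage` ranks codes by descending event count (ties
broken lexicographically) and returns the shortest prefix whose cumulative
share reaches the threshold — the "k codes account for 90% of events"
statistic of codelist-usage audits.

## Case detection

Events are filtered against the level-1 codelist, grouped per patient and
scanned in date order. The deduplication window defaults to 28 days with
**rolling** semantics: an event opens a new case iff it falls strictly
more than `window_days` after the immediately preceding ARI event, so a
gap of exactly 28 days continues the episode, and a chain of events 28
days apart forms one case of unbounded length. The alternative reading —
a window anchored at the episode's index event — is provided as
`mode="fixed"` for sensitivity analysis; the two disagree exactly when
repeat coding stretches an episode past the window, which the generator's
1–21-day repeat gaps can produce. Rolling is the default because it is the
literal reading of "more than 28 days from the previous recorded event".

Classification collects every level-3 indicator matched by any
constituent event and picks the one whose level-2 group ranks highest in
the configurable priority order ILI > ECLD > LRTI > URTI > ARI-NOS;
within the winning group the earliest matching event decides, then the
lexicographically smallest level-3 id. ILI ranks first because it is the
influenza-specific indicator kept as its own group precisely for
surveillance primacy; ARI-NOS ranks last because it is the residual
"no specific information" group. Same-day events are ordered
deterministically (date, best level-2 priority of the code, code) and can
never split across episodes. Registration windows are deliberately not
applied here: case extraction counts all events, and denominator-quality
filtering happens in the surveillance layer.

## Surveillance rates

Weeks follow ISO-8601; the default reporting period is the 52 weeks from
ISO week 39 to week 38 of the following year, parameterised as
`(start_year, start_week, n_weeks)`. Age bands 0–17, 18–69 and 70+ are
computed in completed years **at the case index date** (configurable in
principle; computing at season start was rejected as it misbands patients
who cross a boundary mid-season). Risk-group membership is a boolean
supplied in the patient register; clinical risk-group definitions are out
of scope.

Denominator reliability is not defined in published surveillance reports,
so the package uses an explicit, configurable stand-in: a practice is
reliable over the period iff it reports a **positive list size for every
week** and its week-on-week relative list-size change never exceeds
**20%**. Cases from unreliable practices are dropped before any counting.

The `all` stratum's denominator is the summed weekly list size of
reliable practices. Stratified denominators cannot come from list sizes
(which carry no demographics), so they are patient counts from the
register of those practices, with age evaluated at each week's Monday; the
generator keeps list sizes equal to the patient roster so both
denominators agree. Rates are `100000 · cases / denominator`, left NaN
where the denominator is zero. Median weekly rates use the mean-of-central
values convention for even counts. Internal arithmetic is full precision;
half-up rounding to one decimal is applied only to reported medians and
percentages.

## Old-versus-new reconciliation

The legacy algorithm is a flat level-1 codelist run through the same
filter-and-deduplicate machinery (no classification is possible). Old and
new case sets are matched on `(patient_id, index_date)`: cases present in
both are shared, new-only cases are *newly included*, old-only cases
*newly excluded*, which makes
`new_total = old_total + included − excluded` an exact identity. Matching
on episode content instead was rejected because episode merges would break
the identity and make the reconciliation depend on repeat-coding
intensity.

## Synthetic data

The generator emulates the structure of a sentinel network season, not
any real population:

* **Terminology** (~150 concepts): one subtree per level-3 indicator with
  a seeded number of descendants (two levels deep in places), a handful of
  cross-edges creating genuine multi-parent concepts, and six decoy
  clusters (chronic, non-infective, recurrent, other) grafted inside host
  subtrees and excluded from the level-3 rules with `MINUS`. Cross-edges
  never connect the legacy-visible family (ILI/LRTI/URTI) with the
  legacy-invisible one (ECLD/ARI-NOS), so each code's membership of the
  legacy flat list is unambiguous and every episode is either wholly
  visible or wholly invisible to the old algorithm.
* **Population**: default 20 practices × 500 patients. Age bands are drawn
  0–17 / 18–69 / 70+ with weights 0.21 / 0.65 / 0.14 (approximating an
  English practice roster), risk-group prevalence 0.25. List sizes are
  constant per practice; with probability 0.1 a practice drops 1–3 register
  weeks and thereby fails the reliability filter.
* **Events**: per patient-week, episode onset fires with probability
  `rate(w)/100000` where each level-2 group's weekly intensity is a
  baseline times a Gaussian winter bump,
  `baseline · (1 + (m−1)·exp(−(w−w₀)²/2σ²))`. Defaults (baseline per
  100,000/week; peak multiplier; peak week; width): URTI 140/3.0/15/5,
  LRTI 67/3.0/16/5, ILI 3/4.0/14/3, ECLD 12/2.5/16/6, ARI-NOS
  20/2.5/15/5 — levels chosen so season medians land near typical
  English primary-care values and the peak sits around the calendar new
  year. Each episode emits a geometric number of repeat codings
  (continuation probability 0.4, capped at 5) at uniform 1–21-day gaps;
  codes are drawn from the episode's level-3 codelist with Zipf-like
  weights (exponent 1.6) so a few codes dominate recording. Miscodes are
  injected independently at 0.001 per patient-week, split across decoy
  classes 43.7% chronic / 30.0% non-infective / 14.4% recurrent / 11.9%
  other. No published data describe within-episode coding frequency, so
  the repeat-coding defaults are invented and labelled as such.

Two constructions make ground truth exact rather than approximate: the
next episode may only start strictly more than the deduplication window
after the previous episode's last coding, and decoys are rejected within
window + max-repeat-gap + 2 days of any true event or other decoy. Hence
with miscoding disabled the detected case count equals the true episode
count exactly, and with miscoding enabled every decoy forms exactly one
legacy-only case.

What the generator does **not** emulate: real SNOMED codes or codelists,
real incidence levels or age-specific attack rates, practice-size
heterogeneity, reporting lags, registration churn, or coding-behaviour
drift. Passing tests therefore demonstrate algorithmic correctness and
bookkeeping exactness under controlled conditions, not epidemiological
validity on real records.

All draws come from a single `numpy` generator seeded from the config
(child streams per artefact are spawned deterministically); identical
config and seed give byte-identical CSVs.

## Verification sizes and statistics

The test suite cross-checks every core operation against an independent
brute-force oracle: repeated-edge-expansion reachability and naive set
algebra for ECL (200 random DAGs of ≤40 nodes), a straight-line scan for
deduplication (500 random streams, both modes), exhaustive prefix search
for coverage, sort-and-pick for medians, and a from-scratch naive
reimplementation of the full detection pipeline on a simulated season.
Parameter recovery runs the default 10,000-patient, 52-week season and
compares detected weekly counts to the configured intensity with a
chi-square goodness-of-fit test on the shape (expected counts normalised
to the observed total, degrees of freedom reduced accordingly, α = 0.01).
Episode-onset blocking after each episode suppresses incidence by roughly
1–2%, which the shape normalisation absorbs; at these sizes the residual
distortion is well inside Poisson noise.

## Known limitations

* The reliability rule is a plausible stand-in, not a published
  definition; sites with real denominator-quality metadata should replace
  it.
* Flat-codelist runs cannot be stratified by level-2 group, so
  old-versus-new rate comparisons are reported at level 1 only.
* Episodes spanning the period boundary are counted by index date; a case
  whose index falls in the final week but whose events continue past it is
  still one case in the period.
* No baseline or threshold statistics (moving epidemic method, multi-year
  averages) and no severity indicator are included.
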