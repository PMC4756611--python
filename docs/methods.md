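# Methods

This note documents the models, conventions and numerical choices behind
`xsm`, in the order a user meets them: score semantics, the equilibration
mass balance, the matched-design analyses, appearance-time bounding, and
the synthetic campaign generator that every analysis is tested against.

## Score semantics and data model

A campaign is three flat tables (plates, time-stamped droplet image
scores, tested crystals). Image scores live on a 0–10 scale where 0
collapses every non-crystalline class (clear drop, precipitate, droplet
error): the analyses only ever consult the hit boundary, so finer
non-crystalline classes would be dead weight. The two binary read-outs
are:

* **hit** — conclusive Image Score ≥ 3 (microcrystals or better);
* **diffracting** — Crystal Quality Score ≥ 1 (confirmed protein
  diffraction of a harvested crystal).

When a droplet was annotated at several inspections, the **last recorded
score wins**, including rescission (a late 0 after an earlier 5 means no
hit). Two scores sharing a timestamp are broken by file order (later row
wins); this mirrors last-recorded semantics and is the only defensible
rule absent audit metadata. Wells are canonicalized to 1–96 row-major
(A1=1 … H12=96); both numeric and alphanumeric addresses are accepted on
input, numeric is written on output. Dates are ISO 8601 and same-day
comparisons use the calendar date as written — no timezone arithmetic.

## Vapour-diffusion equilibration

A p:q protein:precipitant sitting drop over a reservoir of the precipitant
cocktail equilibrates, under the assumptions that (i) only water vapour
moves, (ii) the protein never changes phase and (iii) equilibration runs
to completion, by shrinking until its precipitant matches the reservoir.
Every solute is therefore concentrated by

    factor = (p + q) / q

so 2:1, 1:1 and 1:2 drops concentrate 3-, 2- and 1.5-fold. A drop with no
precipitant part has no driver and is rejected. The reservoir defaults to
the precipitant stock; a separate reservoir concentration is exposed for
generality (factors below 1 then mean water flows into the drop). Solute
conservation (final concentration × final volume = post-mix concentration
× drop volume) holds to floating-point round-off and is asserted over
randomized specs in the tests.

Protein budgets are pure drop arithmetic — a p:q drop of volume V holds
V·p/(p+q) protein — deliberately excluding dead volume and dispensing
losses, which would require inventing a robot model. The standard
96-condition screen with 2:1/1:1/1:2 drops at 150 nl consumes 21.6 µl per
plate; the recommended four-screen, two-temperature experiment consumes
exactly 172.8 µl.

## Subwell-combination analysis

Per plate, every well whose conclusive scores contain a hit contributes
one of the seven non-empty subsets of {A, B, C}. Plates are stratified by
their number of crystallizing wells (1…10 and a ">10" bucket — the exact
binning of large counts does not affect the read-out); within a stratum,
combination proportions run over wells and sum to 1, with supporting plate
and well counts reported. Plates sharing a protein are *not* deduplicated:
the analysis emulates a plain hit-identification exercise in which every
plate is an independent experiment. "A and C only" outliers are retained.
Plates with ≤ 5 crystallizing wells are rare ("difficult") crystallizers;
more makes them promiscuous ("easy"). Classification requires at least one
crystallizing well; hit-free plates are excluded upstream.

## Matched designs

*Temperature pairs* require exact equality of target, sample (purification
batch and fresh/frozen state), screen, setup date, concentration and
co-crystallization compounds, with one plate at 277 K and one at 293 K,
and at least one diffracting crystal on either plate (so protein quality
is not limiting). A plate eligible for several pairs is matched in
lexicographic plate-id order with a logged warning — determinism over
unknowable lab history.

*Screen groups* are 3–4 same-temperature plates of pairwise-distinct
screens (JCSG, LFS, HCS, HIN) sharing the same keys except concentration,
which only needs to be *similar*: all members within a relative tolerance
(default 10%, CLI-adjustable) of the group minimum. Candidates are scanned
in (concentration, plate-id) order and grouped greedily, giving a
deterministic maximal non-overlapping assignment; a plate duplicating a
screen already in the open group is left out rather than breaking the
group. Raising the tolerance never loses groups (tested).

## Strategy counterfactuals

All strategies are droplet-subset restrictions of the recorded hits, so
the full experiment's success contains every restricted strategy's success
by construction (asserted pair-by-pair in tests):

* **Temperature exclusivity.** Each pair is classified per endpoint (hits,
  diffracting) as 277-only / 293-only / both; pairs with no event at an
  endpoint are excluded with their count reported. Pair rarity uses the
  union of crystallizing wells across both plates — a pair is one
  experiment on one sample. The diffracting endpoint inherits the
  harvesting bias of the source process (crystals tend to be harvested at
  one temperature) and is reported as-is with that caveat.
* **Screens vs drops** (288 droplets, 21.6 µl): strategy 1 = one 1:1
  droplet in each of three screens; strategy 2 = all three ratios in one
  screen, reported per screen rather than as an argmax. A group counts as
  missed-by-both when no droplet of the three plates holds a hit. Only
  groups containing the full combination are evaluated; groups lacking a
  required subwell in their layout are skipped and logged.
* **Temperatures vs drops** (192 droplets): two droplets (2:1 + 1:2) at a
  single temperature vs one 1:1 droplet at both; misses are counted
  against pairs where the full six-droplet experiment found a hit. (The
  printed protein volume for 192 droplets in the source analysis does not
  match the drop arithmetic — 192 × 75 nl = 14.4 µl — so only the
  arithmetic is implemented.)

## Appearance-time bounding

The appearance time of a crystal is bounded by the last recorded
inspection without it and the first inspection annotated with it.
Curation corrections (an explicit file, never image inference) move the
upper bound to the earliest image actually showing the crystal; a
correction naming a day that is not an inspection of that droplet is an
error. A crystal is *late* when its (possibly corrected) upper bound
exceeds 30 days. Because curation and raw annotation can disagree, the
late fraction is reported on either basis (`bound` vs `annotation`)
rather than conflating the two. The cumulative appearance curve steps
only on actual inspection days and ends at 1. Inspections after day 56
are accepted if present in the data; the schedule constant only drives
the simulator.

## Screen performance

Success rates are structures (direct + optimized-from-screen) per screen
set up, in percent; screens with zero plates are omitted with a warning.
Optimized structures are attributed via an explicit source-screen field on
the crystal record. Success rates are not generalizable beyond the
proteins actually screened — the module docstring carries this warning,
and no cross-dataset claim is derived from them.

The internal diversity of a screen is the mean pairwise distance over its
conditions. The distance is pluggable (symmetry, range [0, 1] and
d(x,x)=0 are enforced); the default is a Gower-style component-overlap
measure — shared components contribute one minus the concentration ratio
(min/max, same units), unshared components contribute 1, averaged over the
component union. This is a documented stand-in, *not* the published
cocktail-distance, so diversity values are comparable within this package
only. Condition "overlap" between screens can be probed as distance below
a user-chosen threshold.

Descriptive summaries report per-screen resolution quartiles and the
Pearson correlation of protein concentration against molecular mass per
subwell, restricted to direct-from-screen depositions (only there is the
mixing ratio unambiguous). Statistics over fewer than three points, or
with zero variance, are reported as undefined (NaN) rather than as a
number.

## Synthetic campaign generator

The generator emulates the statistical structure of a ten-year screening
database that is not itself available, and keeps the full latent record so
every analysis can be checked for parameter recovery.

**Structure.** Each target gets 2 sessions (purification batches); each
session sets up 3 or 4 distinct screens from {JCSG, LFS, HCS, HIN}, each
at both 277 and 293 K — yielding the matched pairs and groups the strategy
analyses consume. The default 150 targets give ~2100 plates.

**Hit model.** Each screen-experiment is rare with probability 0.77 (the
fraction of hit-containing plates with ≤ 5 crystallizing wells in the
emulated database); its crystallizing-well count is Poisson (rate 2.5
rare, 20 promiscuous) truncated to 1–5 or 6–96. The class is drawn per
screen-experiment rather than per target: a target-level draw would give
the plate-level rare fraction a clustered sampling variance far above
binomial at fixed plate count, defeating any precise recovery statement;
with per-experiment draws the recovered fraction is exactly binomial in
the number of experiments (the recovery tests deduplicate the two plates
of a pair, which share the draw).

**Temperature structure.** Each experiment first draws a regime: exclusive
to one temperature (probability 0.45 for rare, 0.05 for promiscuous
experiments, sides equiprobable) or shared. Shared experiments give each
condition both temperatures with probability 0.7, else one side at
random, and coverage of both temperatures is enforced. The regime is drawn
at the experiment level — a flat per-condition model cannot pin the
pair-level exclusive fraction, because small experiments drift into
apparent exclusivity with probability ((1−s)/2)^k — so the recovery target
is the actual generative parameter.

**Subwells.** Hit subwells follow independent Bernoullis with logit
probabilities base −1.1 plus offsets A +0.4, B 0.0, C −0.2, favouring the
protein-concentrating 2:1 drop as observed in real screening data;
conditions are forced non-empty (weighted single-subwell fallback after
repeated empty draws, preserving any configured symmetry).

**Timing.** Appearance days mix an early log-normal (median 4 d, σ 0.9,
truncated to the day-28 inspection) with a 2% late component (30 d + a
log-normal offset of median 10 d, truncated to day 56 so every true hit is
observable). The gap (28, 30] is empty by construction, which makes the
bound-based late dichotomy exact. Any heavy-tailed late form would do —
the analyses only bin by inspection day.

**Scoring noise.** Latent truth and observation are decoupled, but noise
perturbs *inspections*, not conclusive outcomes: each annotation of a hit
is independently missed with probability 0.03 (delaying the observed
first-annotation day to the next inspection), a zero score is recorded at
the inspection preceding first appearance (the image a curator would
verify), transient false positives (5 × 10⁻⁴ per droplet) score 3–5 at one
inspection and are rescinded by a later 0, and ~1% of droplets carry
benign 0–2 annotations. The conclusive last score therefore stays faithful
to the latent state, reflecting that final annotations are curated far
more carefully than interim ones. The noise rates are order-of-magnitude
guesses — no inter-scorer variability estimate exists for the source
process — and are explicit configuration.

**Protein and diffraction.** Concentrations are log-normal around
10 mg/ml (σ 0.3, shared within a session so pairs match exactly and
groups match within tolerance); masses are log-normal around 30 kDa and
drawn independently of concentration, so the expected conc–mass
correlation is 0. Diffraction is a single Bernoulli (p = 0.45, loosely
echoing the fraction of purified targets that ever yielded diffracting
crystals) per screen-experiment — a protein-quality property — with 1–2
crystal records placed on randomly chosen observed hit droplets, ~50%
deposited, resolutions log-normal around 2.2 Å. Drawing diffraction per
droplet instead would make the "at least one diffracting crystal"
eligibility filters correlate with hit counts and hence with temperature
category, visibly biasing the recovered exclusive fraction (to ~0.35 in
trial runs); the per-experiment draw keeps eligibility independent of the
recovered quantities. Hit-containing non-diffracting experiments emit a
quality-0 tested crystal 20% of the time, exercising the diffraction
filters.

**Determinism.** One `numpy` generator seeded from the config drives all
draws in a fixed order; identical config and seed give byte-identical CSV
output (tested).

**What the generator does not emulate.** No chemistry: which cocktail
crystallizes which protein family is not modelled, conditions are
exchangeable within a screen, and screens differ only in name — so
passing tests say nothing about real chemical-space coverage, screen
overlap or cocktail-specific kinetics. Inspection times are nominal
(no backlog jitter), plates have no missing or corrupt images, and
harvesting behaviour (the bias that inflates diffracting-endpoint
exclusivity in real data) is not simulated. Recovery results demonstrate
the *pipeline* is correct, not that real campaigns satisfy the model.

## Recovery statistics

Recovery tests run 20 seeds of the default ~2100-plate campaign
(~1050 experiments, ~500 eligible pairs, ~700 crystals per seed; roughly
2 s per seed, keeping the suite comfortably fast). For each seed the
recovered count is checked against the central 95% binomial acceptance
region at the configured value and the realized number of independent
units; at least 17 of 20 seeds must pass per parameter, since by the CI's
own definition ~1 seed in 20 is expected outside. A pooled check across
all seeds at the 99.9% level guards against small systematic bias.
Residual biases are understood and small relative to one standard error:
annotation misses can push a day-(14,28] appearance past the 30-day
boundary (+~0.001 on the late mass), and a late hit missed at its only
inspection is unobservable (−~0.0004).

## Known limitations

* The diversity score is a stand-in distance; absolute values are not
  comparable to published cocktail-distance diversities.
* The diffracting-crystal exclusivity endpoint reproduces, by design, any
  harvesting bias present in the input data.
* Matching disambiguation (lexicographic ids, greedy concentration
  clustering) is a stated convention, not a reconstruction of lab
  reality.
* The generator's plate mix is balanced by construction (every session
  has both temperatures and 3–4 screens); real campaigns are ragged, and
  the matching code tolerates but is not stress-tested against heavy
  raggedness beyond what the unit tests construct.
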