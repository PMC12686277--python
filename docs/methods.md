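# Methods

`lineagebias` quantifies the structural biases that ascendant genealogies
impose on period fertility and mortality estimates.  It does so entirely
in silico: a demographic microsimulation produces a fully-recorded
synthetic population; hypothetical genealogists reconstruct their family
trees from the survivors; and the same demographic measures are computed
from the full population and from the genealogical subsets.  The
difference between the two is, by construction, the bias of the
reconstruction process — there is no record-linkage noise, no elite
oversampling, no transcription error.

## The microsimulation model

The engine is a discrete-event, individual-level simulation under
competing risks.  Its entire parameterisation is a rate schedule: monthly
age-specific fertility hazards for women and monthly age-specific death
hazards for both sexes, piecewise constant over single-year age bands and
calendar-year segments.

* **Event scheduling.**  Every living individual carries exactly one
  scheduled event.  For each risk the individual is exposed to, a waiting
  time is drawn from the piecewise-exponential distribution implied by the
  hazards (inverse CDF over accumulated hazard); the shortest waiting time
  wins.  Equal waiting times resolve to death before birth so that
  execution is deterministic given the draws.
* **Segments.**  When the calendar year changes, every living individual
  is rescheduled under the new rates.  Because hazards are piecewise
  constant, waiting times are memoryless within a segment and this
  rescheduling leaves the event-time distribution exactly invariant.
* **Monthly execution.**  All events due in a month execute in random
  order; the month counter then advances.  Time is a global month index
  (`year * 12 + month`), ages are completed months.
* **Births.**  A birth creates a new individual (probability of a male
  birth 0.5122 by default), links it to its mother, and reschedules her.
  A minimum birth interval of nine months is enforced by *shifting* the
  drawn waiting time past the interval rather than by zeroing the hazard;
  shifting preserves the total number of births the input rates imply,
  which the input-recovery validation below confirms.  When a woman still
  inside the interval is rescheduled at a segment boundary, accrual
  restarts at the month after her last birth, again keeping the event-time
  distribution invariant under rescheduling.
* **Partnerships.**  Lacking usable long-run marriage rates, partnerships
  form at a previously single woman's birth: among living never-married
  men aged 15+, the candidate is chosen whose inclusion minimises the
  squared difference between the observed husband-minus-wife age-gap
  histogram and a Normal(mean 2, sd 3) target; ties break to the smallest
  pid.  Partnerships are lifelong; widowed men are not re-matched.  The
  recorded father is the mother's partner provided he was alive at
  conception (nine months before the birth).
* **Initial population and burn-in.**  The initial cohort has ages uniform
  on [0, 50) years and random sex.  A long burn-in (default 100 years) at
  the first year's rates erases this arbitrary structure before the main
  period; a tail (default 50 years) at the final year's rates closes the
  registry so that late mid-year denominators are consistent.
* **Replication.**  A study runs K replicates (default 10) with identical
  inputs and seeds base+1..base+K.  All randomness flows from one root
  seed through named substreams (scheduling, sex assignment, within-month
  shuffling), so experiments can re-randomise extraction without
  perturbing the demographic history.

## Rate inputs

Schedules can be read from HFD-style ASFR tables and HMD-style mortality
tables (`Mx_1x1` or `qx`), from a native long-format CSV, or generated
synthetically.  Annual quantities convert to monthly hazards by ASFR/12
and m(x)/12, and q(x) through the constant-hazard inversion −ln(1−q)/12;
q = 1 rows are capped at a monthly hazard of 1.

The synthetic generator exists so the full pipeline runs with no external
data.  Fertility uses a unimodal (Gaussian-shaped) age schedule with mode
28 years on the 15–49 span, renormalised exactly to a yearly TFR target.
Mortality uses a Siler hazard — infant exponential decay, background
constant, senescent Gompertz — blended between a high-mortality and a
modern low-mortality anchor; the blend parameter is tuned per year by
Brent root-finding so the period life table hits the year's e0 target
within 0.05 years.  The `sweden_like` preset follows the broad Swedish
trajectory 1751–2022: TFR fluctuating above four children per woman
before 1900, declining linearly to 1.8 by 1935 and hovering near
replacement after; e0 rising logistically from ~35 to ~82 years with
infant mortality collapsing by two orders of magnitude.  What the
generator does **not** emulate: parity-specific fertility, familial
clustering of rates, fertility–mortality correlations, migration, or
mortality crises (famines, epidemics).  Passing tests therefore speak to
the structural geometry of genealogical reconstruction, not to every
feature of real Swedish data.

## Genealogical reconstruction

Genealogists are a 10% simple random sample of individuals aged 18+ and
alive at the end of the final main year.  Each traces direct ancestors up
to nine generations (at most 2 + 4 + … + 2^9 = 1022 positions); positions
with unrecorded parents are simply absent, and pedigree collapse
legitimately duplicates a pid within one tree.  The unit of accounting is
the *attribution* — one row per (genealogist, member, kin type,
generation) — so that with-duplicates statistics weight members by their
number of appearances while the deduplicated member set remains a pure
view.  Experiment 2 adds every child of every direct ancestor (collateral
kin up to 7x-great-aunts/uncles).  Experiment 3 removes, from the
deduplicated complete lineages, a random fraction of (A) children dead
before age five or (B) women who reached 15 and stayed childless —
eligibility is registry ground truth, and the random order of eligible
members is drawn once per seed so removal sets are nested across
proportions.

## Measures

Rates are classic period occurrence/exposure quantities with mid-year
denominators: alive at the July month index, age in completed years at
that month.  In a subset, a birth is counted only when the child *and*
its mother are members — precisely the mechanism that makes ancestor-only
trees underestimate fertility.  Cells with zero exposure are *undefined*,
distinct from zero, and excluded from comparisons.  TFR is the age-sum of
defined single-age ASFR; e0 comes from a period life table with
q = m/(1 + (1−a)m), a(0) = 0.07 + 1.7·m(0), a = 0.5 otherwise, radix
100,000 and an open interval at 100 with e(100) = 1/m(100).  Any standard
a(x) choice moves e0 by under 0.1 year at these mortality levels.

Numerical choices for sparse subset tables: undefined m(x) below the first
observed death age is treated as 0 — the subset genuinely records no
deaths there, and this *is* the source of the e0 overestimation, not an
artifact; undefined cells at older ages carry the last defined rate
forward; a dataset with no deaths past 100 at all uses an open-interval
hazard of 0.05/year instead of dividing by zero; q > 1 (possible in tiny
cells) is clamped with a warning.

## Bias summaries and coverage

Per replicate and calendar year, bias is subset minus full-simulation
value; window summaries average these differences (and the per-year
percentage differences) over covered years, then across replicates.
Ancestor-type subsets cannot cover recent events: members of the
genealogists' own generation stop being added at the genealogists'
births.  A year therefore counts as covered only up to the 10th
percentile of genealogist birth years (for fertility, 15 years earlier
still, because once the youngest traced generation enters reproductive
ages it contributes female exposure whose offspring are structurally
invisible) and only with minimum exposure (100 woman-years for fertility,
200 person-years for e0).  Uncovered years are excluded from window means
rather than imputed.

### The with-duplicates TFR ≈ 1 identity

Every female direct-ancestor position carries exactly one in-lineage
birth, so the duplicate-weighted TFR of an ancestors-only subset is
structurally near one regardless of the true fertility level.  It is not
exactly one: women who die after their in-lineage birth leave the
denominator while the birth stays counted, lifting the level by a few
percent in high-mortality regimes (~1.04–1.06 at e0 ≈ 40–50), and rapid
fertility-timing change adds small period distortions.  At desk scale the
per-year estimate also carries Monte Carlo noise of a few percent, so the
packaged check evaluates the identity on 25-year windows with births and
exposures pooled across years and replicates; pooled exposures in the
hundreds of thousands of woman-years make the window estimates essentially
structural.

## Desk-scale study configurations

The canonical runs in `lineagebias.study` (used by the tests and by
`scripts/acceptance.py`) are sized for a single CPU:

* **Preset run** — `sweden_like` rates 1873–2022 (150 main years),
  initial cohort 2,000, 100-year burn-in, 50-year tail, 2 replicates
  (~40,000–46,000 individuals ever alive per replicate, ~10,000 alive at
  the reference date).
* **Input recovery** — constant rates (TFR 4.3, e0 40), initial cohort
  3,000, 50-year burn-in, 50 main years, 10 replicates; recovered TFR is
  within 5% and e0 within 1 year of the input-implied values, and pooled
  5-year age-band rates sit within Monte Carlo error of the inputs (the
  band null is the exposure-weighted mean of the input single-age rates —
  with steep hazards a band's person-years concentrate at its younger
  ages, and an unweighted mean would fake an old-age mortality deficit).
* **Direction suite** — constant high-infant-mortality regime (TFR 4.5,
  e0 38), initial cohort 1,500, 160 main years, 2 replicates, omission
  grid 25/50/75/100%.

At these scales the observed effects mirror the full-scale pattern:
ancestors-only trees underestimate TFR by roughly 1.7–2.7 children per
woman and overestimate female e0 by ~25%; adding all collateral kin
shrinks the e0 bias by an order of magnitude; omitting early-deceased
children inflates e0 monotonically in the omission proportion and
depresses TFR; omitting childless women moves the measures in the same
directions but far more weakly.  One deliberately scale-dependent
difference: with collateral kin included (Experiment 2), desk-scale runs
show a *negative* fertility bias, because with a few hundred genealogists
many collateral women's children fall outside the union of trees; with
tens of thousands of genealogists the union covers nearly every surviving
lineage and the selection of high-fertility ancestor mothers dominates,
turning the bias positive.  The direction checks therefore constrain only
the effects that are structural at any scale.

## Known limitations

* Individual vital rates are independent across kin: no familial
  clustering, no fertility–mortality correlation, no parity-specific
  scheduling.
* The marriage market is a matching heuristic, not a behavioural model;
  widowed men never re-partner.
* Mid-year denominators and monthly event timing introduce small
  (sub-percent) discretisation effects, visible as a ~0.3–0.5 year
  upward drift in recovered e0 at desk scale — well inside the stated
  recovery tolerance but not exactly zero.
* Only structural biases are modelled; accuracy ("precision") bias and
  socioeconomic (elite) selection are out of scope by design.
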