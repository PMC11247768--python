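# Methods

## Model

`rarecohort` treats a rare-disease cohort as a stratified thinning of a
population frame. The frame is a state × single-year-age table (0–84 plus an
85+ pool, the granularity at which US census age tables are published), with
sex and race splits held per state and a ZIP code list per state. Ages are
harmonised into seven groups — `<5, 5-14, 15-19, 20-24, 25-39, 40-60, >60` —
read as a contiguous integer partition: `<5` = 0–4, `40-60` includes 60,
`>60` = 61 and up. This is the only gap-free reading of the printed labels.

For each (state, age-group) stratum with population *N*, the patient count
is `Binomial(N, 1/D)` where 1/*D* is the disease prevalence (stored as an
integer denominator to avoid precision drift). A deterministic
`rounded-expectation` mode is also provided; because independent per-stratum
rounding annihilates small frames (every cell rounds to zero), this mode
apportions `round(total/D)` over strata by largest remainder, which keeps
the cohort total equal to the rounded total expectation while staying
proportional per stratum.

Each patient is then generated through a fixed chain:

1. **ZIP** — uniform over the state's list (the source statistics do not
   weight ZIPs by population).
2. **Sex / race** — categorical draw from `w·p_disease + (1−w)·p_state`.
   The blend weight *w* defaults to 1 (pure disease distribution) because
   the published cohort-level expected marginals equal the disease
   distributions exactly; *w* < 1 lets users pull marginals toward local
   census structure. Census splits are applied per state, not per state ×
   age (finer resolution is not specified by the sources).
3. **Age** — single year inside the stratum's group, weighted by the
   state's single-year counts. A draw landing in the 85+ pool is resolved
   uniformly to 85–99, since the census table has no upper bound.
4. **Clinical values** — `Normal(μ, σ)` truncated to the published
   [low, high] via `scipy.stats.truncnorm`. In every packaged profile the
   printed μ ± σ spans (or sits inside) the printed range, so the
   truncation is symmetric or nearly so and the sample mean stays at μ.
   σ = 0 is accepted as a point mass.
5. **Vital status** — Bernoulli with probability `rate_per_100k / 100 000`
   for the patient's age group: the simplest per-patient reading of a
   "death rate per 100,000" table. It is *not* a survival model; rates are
   not integrated over exposure time.
6. **Dates** — integer age *a* is defined by the floor convention
   (anniversary counts). Living patients get a birth date uniform over the
   exact window `(ref − (a+1)y, ref − a·y]` so that age at the reference
   date (default 2023-01-01) equals *a*. For deceased patients the drawn
   stratum age is the age at death: the birth date is drawn from the same
   window and the death date uniform over
   `[birth + a·y, min(ref, birth + (a+1)y − 1 day)]`, which is never empty
   for that birth window; consequently all deaths fall within the year
   before the reference date. Diagnosis = birth + lag, with the lag drawn
   from the profile's truncated normal in its own unit (converted at
   30.44 days/month and 365.25 days/year) and clamped into
   [birth, min(reference, death)]; a clamped diagnosis is flagged in the
   record (`diagnosis_clamped`), which matters for newborns whose drawn lag
   exceeds their lifetime so far. Leap-day boundaries are handled by
   explicit window correction against the floor-age predicate rather than
   calendar arithmetic alone.

## Randomness and reproducibility

One root seed is expanded into per-stratum child streams via
`numpy.random.SeedSequence([seed, state_code_as_int, group_index])`. The
first draw on a stratum's stream is its binomial count, so counts can be
replayed independently of record generation (the count-oracle test does
exactly this). Results are therefore invariant to iteration order and
byte-identical across runs with equal inputs.

## Parameters that matter

| Parameter | Units | Default | Note |
|---|---|---|---|
| `prevalence_denominator` | persons/case | per profile (3300 / 10311 / 6000) | integer |
| `race_blend`, `sex_blend` | – | 1.0 | weight on the disease distribution |
| `count_mode` | – | `binomial` | published totals differ from expectations, implying stochastic counts |
| `reference_date` | date | 2023-01-01 | ages of living patients are as of this date |
| death rates | per 100,000 | per profile | per-patient Bernoulli probability |
| diagnosis lag | days/months/years | per profile | truncated normal in the profile's unit |

The CF profile's printed sex percentages total 101%; they are rescaled
proportionally at load (male 51.7/101, female 49.3/101) and a warning is
recorded rather than silently absorbing the discrepancy.

## Synthetic demographics

Real census retrieval is out of scope. `make_toy_demographics` synthesises a
frame with exact integer conservation (multinomial splits of the requested
total over states, then over single-year ages), an age pyramid following
configurable group shares (default: the grouped shape of the 2020 US
pyramid — 5.9 / 12.5 / 6.6 / 6.6 / 20.5 / 25.6 / 22.3 percent), sex splits
jittered in 48.5–51.5% male, and race splits Dirichlet-distributed around a
plausible national mix (12.5 / 61.5 / 26). What it does **not** emulate:
state-to-state correlation between race and geography, migration, cohort
effects, or any within-state age–sex interaction. Passing tests on this
frame therefore demonstrates the generator's statistical contract
(convergence of generated marginals to configured parameters, structural
invariants), not demographic realism of any particular US state.

## Validation reports

`summarize` computes exact integer counts; display rounding (2 decimals) is
applied only at serialisation. `compare_to_expected` checks the total count,
female share, race shares and deceased count against the values the profile
and frame imply. Tolerances default to three binomial standard errors:
for the deceased count, each frame member is marginally a deceased patient
with probability `r/D`, so the count is Binomial(N, r/D) and its standard
error is essentially √E[deceased] — the thinning-only variance would be too
tight for high-mortality groups. The 3σ default stands in for the sources'
unquantified "no significant differences" claim and is configurable.

## Problem sizes

Full-scale runs in the acceptance script use synthetic frames of 340M (SCD),
1.05B (CF) and 620M (DMD) people — sized so each cohort exceeds 100,000
records — and 100,000-draw sampler checks; a full cohort generates in a few
seconds. These sizes give binomial standard errors of ≲ 0.16 percentage
points on the checked marginals, comfortably inside the ±0.5-point
convergence band used in the tests.

## Known limitations

- Cross-sectional only: no longitudinal trajectories, comorbidities or
  treatment events, and no genetic or imaging modalities.
- Mortality is a per-patient probability, not a hazard; deceased patients'
  death dates all fall in the year before the reference date, and their
  diagnosis-to-death ordering is enforced by clamping rather than joint
  modelling.
- No privacy mechanism is needed or provided: records are sampled from
  public statistics, not derived from real patients.
- Race/sex blending uses state-level census splits; age-specific splits are
  not modelled.
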