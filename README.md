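# rarecohort

Synthetic rare-disease patient cohorts generated from published summary
statistics.

Rare-disease data is scarce and uniquely sensitive: registries are small,
patients are highly re-identifiable, and real records usually cannot be
shared. That blocks the development of exactly the software — registry
systems, biobank platforms, anonymisation pipelines — that rare-disease
research needs. `rarecohort` sidesteps the dilemma by generating fully
synthetic patient datasets whose statistical structure is driven entirely by
public statistics: prevalence, race and sex ratios, diagnosis-lag
distributions, per-age-group death rates and clinical laboratory reference
distributions. The output is a flat CSV of patient records (state, ZIP, sex,
race, birth/diagnosis/death dates, clinical values) suitable as development
and test data; it encodes no real person.

Three curated disease profiles ship with the package:

| Disease | ORPHA | Prevalence | Clinical parameters |
|---|---|---|---|
| Sickle Cell Disease (SCD) | 232 | 1/3300 | haemoglobin (CBC), reticulocyte count |
| Cystic Fibrosis (CF) | 586 | 1/10311 | sweat chloride |
| Duchenne Muscular Dystrophy (DMD) | 98896 | 1/6000 | creatine kinase |

## Model

Generation is hierarchical and stratified. The sampling frame is a
demographics table: per-state populations by single year of age (0–84 plus
an 85+ pool), with state-level sex/race splits and ZIP code lists. Ages are
harmonised into seven groups (`<5, 5-14, 15-19, 20-24, 25-39, 40-60, >60`).
For each (state, age-group) stratum with population *N* and disease
prevalence 1/*D*, the patient count is drawn

> n ~ Binomial(N, 1/D)   (or round(N/D) in deterministic mode)

and each patient is then built through the chain
ZIP → sex → age → race → clinical values → vital status → dates:

- **sex, race** — drawn from `w·p_disease + (1−w)·p_state`, a mixture of the
  disease-specific distribution and the state's census split with blend
  weight `w ∈ [0,1]` (default 1: the disease distribution dominates).
- **age** — single year within the stratum's group, weighted by the state's
  single-year population counts.
- **clinical values, diagnosis lag** — Normal(μ, σ) truncated to the
  published [low, high] range (the printed μ ± σ spans the printed range, so
  truncation is intrinsic to the specification).
- **vital status** — deceased with probability `rate_per_100k / 100 000` for
  the patient's age group; deceased records carry an age-at-death-consistent
  death date on or before the reference date (2023-01-01 by default).
- **dates** — birth date uniform over all dates giving the drawn integer age
  at the reference date; diagnosis = birth + lag, clamped into the lifespan.

One root seed drives everything through per-stratum child RNG streams, so
identical inputs give byte-identical output CSVs.

## Worked example

```
rarecohort generate --disease SCD --toy-states 3 --toy-pop 30000000 \
    --seed 7 --out scd_cohort.csv --report scd_report.json
```

This synthesises a 3-state, 30-million-person frame, generates the SCD
cohort it implies, and validates the result:

```
INFO rarecohort: seed=7 profile=SCD hash=0591a65519c12fac
INFO rarecohort: wrote 9105 records to scd_cohort.csv
INFO rarecohort: metric                                result    expected       tol  status
INFO rarecohort: total_patients                       9105.00     9092.00    286.06  pass
INFO rarecohort: female_percent                         49.27       50.00      1.57  pass
INFO rarecohort: race_percent[African-American]         73.55       73.10      1.39  pass
INFO rarecohort: race_percent[European-American]         2.92        3.00      0.54  pass
INFO rarecohort: race_percent[Others]                   23.53       23.90      1.34  pass
INFO rarecohort: deceased_patients                       0.00        0.18      3.00  pass
```

30M people at prevalence 1/3300 imply ~9092 patients; the binomial draw gave
9105. Sex and race marginals match the configured SCD distribution (50.00%
female; 73.10% African-American) within three binomial standard errors at
n = 9105, which is the report's default pass tolerance. The first records:

```
patient_id,state,zip,sex,race,age_years,date_of_birth,date_of_diagnosis,vital_status,date_of_death,complete_blood_count,reticulocyte_count,diagnosis_clamped
SCD-0000001,AA,00002,female,Others,4,2018-11-04,2019-04-29,alive,,7.323532932150004,2.3557596498606856,false
SCD-0000002,AA,00004,male,African-American,1,2021-06-11,2021-11-12,alive,,6.596668796276484,2.436340854197102,false
```

The same machinery is available as a library:

```python
import rarecohort as rc

profile = rc.builtin_profiles()["CF"]
table = rc.make_toy_demographics(n_states=3, total_population=50_000_000, seed=0)
cohort = rc.generate_cohort(profile, table, rc.GenerationSettings(seed=0))
report = rc.summarize(cohort, table)
```

User-supplied diseases and demographics are plain JSON files with the same
schema as the packaged ones (`rarecohort generate --profile my_disease.json
--demographics my_table.json ...`).

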