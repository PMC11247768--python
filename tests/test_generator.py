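"""Record-level samplers, date arithmetic and cohort assembly."""

from datetime import date, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rarecohort as rc
from rarecohort.generator import (
    GenerationError,
    _floor_age,
    _shift_years,
    apportion_counts,
    stratum_rng,
)


class TestStratumCounts:
    def test_zero_population(self, rng):
        assert rc.draw_stratum_count(0, 3300, "binomial", rng) == 0
        assert rc.draw_stratum_count(0, 3300, "rounded-expectation", rng) == 0

    def test_rounded_expectation(self, rng):
        # population of the youngest age stratum in a published national frame
        assert rc.draw_stratum_count(19_392_551, 10_311, "rounded-expectation", rng) == 1881

    def test_binomial_mean_matches_expectation(self, rng):
        # Monte-Carlo oracle: mean of Binomial(n, p) draws ~ n*p
        expected = 19_392_551 / 10_311
        draws = [rc.draw_stratum_count(19_392_551, 10_311, "binomial", rng) for _ in range(200)]
        se = np.sqrt(expected) / np.sqrt(200)
        assert np.mean(draws) == pytest.approx(expected, abs=3 * se)

    def test_unknown_mode_rejected(self, rng):
        with pytest.raises(GenerationError):
            rc.draw_stratum_count(10, 5, "magic", rng)

    def test_apportionment_preserves_rounded_total(self):
        pops = [608, 1280, 676, 676, 2113, 2644, 2314]  # ~10311 split over 7 groups
        counts = apportion_counts(pops, 10_311)
        assert sum(counts) == 1
        assert all(c >= 0 for c in counts)

    def test_apportionment_is_proportional_at_scale(self):
        pops = [1_000_000, 3_000_000, 6_000_000]
        counts = apportion_counts(pops, 1000)
        assert counts == [1000, 3000, 6000]


class TestMixtureSampling:
    def test_pure_profile_dmd_sex(self, dmd, rng):
        state = rc.normalize_categorical({"male": 50, "female": 50})
        draws = rc.sample_sex(dmd.sex_dist, state, 1.0, rng, size=10_000)
        assert np.mean(draws == "male") > 0.995

    def test_blend_zero_reduces_to_state_split(self, dmd, rng):
        state = rc.normalize_categorical({"male": 30, "female": 70})
        draws = rc.sample_sex(dmd.sex_dist, state, 0.0, rng, size=100_000)
        assert np.mean(draws == "male") == pytest.approx(0.30, abs=0.01)

    def test_half_blend_mixture_arithmetic(self, rng):
        profile = rc.normalize_categorical({"male": 1.0, "female": 0.0})
        state = rc.normalize_categorical({"male": 0.5, "female": 0.5})
        draws = rc.sample_sex(profile, state, 0.5, rng, size=100_000)
        assert np.mean(draws == "male") == pytest.approx(0.75, abs=0.01)

    def test_race_half_blend_symmetric(self, rng):
        profile = rc.normalize_categorical(
            {"African-American": 0.8, "European-American": 0.2, "Others": 0.0}
        )
        state = rc.normalize_categorical(
            {"African-American": 0.2, "European-American": 0.8, "Others": 0.0}
        )
        draws = rc.sample_race(profile, state, 0.5, rng, size=100_000)
        assert np.mean(draws == "African-American") == pytest.approx(0.5, abs=0.01)

    def test_scd_race_marginal(self, scd, rng):
        state = rc.normalize_categorical(
            {"African-American": 13, "European-American": 60, "Others": 27}
        )
        draws = rc.sample_race(scd.race_dist, state, 1.0, rng, size=100_000)
        assert np.mean(draws == "African-American") == pytest.approx(0.731, abs=0.005)

    def test_blend_outside_unit_interval_rejected(self, scd, rng):
        state = rc.normalize_categorical({"male": 50, "female": 50})
        with pytest.raises(GenerationError):
            rc.sample_sex(scd.sex_dist, state, 1.5, rng)


class TestSampleAge:
    def test_uniform_within_group(self, rng):
        group = rc.age_to_group(0)
        pop = {str(a): 1000 for a in range(5)}
        draws = rc.sample_age(group, pop, rng, size=100_000)
        for a in range(5):
            assert np.mean(draws == a) == pytest.approx(0.2, abs=0.01)

    def test_degenerate_single_age(self, rng):
        group = rc.age_to_group(7)
        assert rc.sample_age(group, {"7": 12}, rng) == 7

    def test_open_group_reaches_past_census_cap(self, rng):
        group = rc.age_to_group(90)
        pop = {"70": 100, "85+": 100}
        draws = rc.sample_age(group, pop, rng, size=5000)
        assert draws.min() >= 61
        assert draws.max() > 84  # the 85+ pool is spread over 85-99
        assert set(np.unique(draws)) <= set(range(61, 100))

    def test_empty_group_rejected(self, rng):
        with pytest.raises(GenerationError):
            rc.sample_age(rc.age_to_group(30), {"3": 5}, rng)


class TestTruncatedNormal:
    def test_symmetric_truncation_preserves_mean(self, scd, rng):
        hgb = scd.clinical_params[0]
        draws = rc.sample_clinical(hgb, rng, size=100_000)
        assert draws.mean() == pytest.approx(8.5, abs=0.05)

    def test_values_stay_in_printed_range(self, dmd, rng):
        ck = dmd.clinical_params[0]
        draws = rc.sample_clinical(ck, rng, size=10_000)
        assert draws.min() >= 350.0
        assert draws.max() <= 23_200.0

    def test_zero_spread_is_point_mass(self, rng):
        dist = rc.RangeDistribution(low=1.0, high=3.0, mu=2.0, spread=0.0)
        assert rc.truncated_normal(dist, rng) == 2.0
        assert np.all(rc.truncated_normal(dist, rng, size=5) == 2.0)


class TestVitalStatus:
    def test_near_certain_death_rate(self, dmd, rng):
        draws = rc.assign_vital_status(">60", dmd.death_rates, rng, size=10_000)
        assert np.mean(draws == "deceased") > 0.995

    def test_zero_rate_always_alive(self, rng):
        rates = rc.DeathRateTable(
            rate_per_100k={g.label: 0.0 for g in rc.AGE_GROUPS}
        )
        draws = rc.assign_vital_status("<5", rates, rng, size=1000)
        assert np.all(draws == "alive")

    def test_bernoulli_rate_calibration(self, scd, rng):
        # Monte-Carlo oracle for the published 25-39 rate of 2.75/100k
        p = 2.75e-5
        n = 1_000_000
        draws = rc.assign_vital_status("25-39", scd.death_rates, rng, size=n)
        frac = np.mean(draws == "deceased")
        assert frac == pytest.approx(p, abs=3 * np.sqrt(p * (1 - p) / n))


class TestBirthDates:
    def test_age_zero_window(self, rng):
        ref = date(2023, 1, 1)
        for _ in range(200):
            d = rc.birth_date_for(0, ref, rng)
            assert date(2022, 1, 1) < d <= ref

    def test_age_ten_window(self, rng):
        ref = date(2023, 1, 1)
        for _ in range(200):
            d = rc.birth_date_for(10, ref, rng)
            assert date(2012, 1, 1) < d <= date(2013, 1, 1)

    @settings(derandomize=True, max_examples=300)
    @given(
        age=st.integers(min_value=0, max_value=100),
        ref=st.dates(min_value=date(1990, 1, 1), max_value=date(2060, 12, 31)),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_floor_age_invariant(self, age, ref, seed):
        d = rc.birth_date_for(age, ref, np.random.default_rng(seed))
        assert _floor_age(d, ref) == age

    def test_negative_age_rejected(self, rng):
        with pytest.raises(GenerationError):
            rc.birth_date_for(-1, date(2023, 1, 1), rng)


class TestDeathDates:
    def test_age_zero_death_within_first_year(self, rng):
        dob = date(2022, 6, 1)
        ref = date(2023, 1, 1)
        for _ in range(100):
            d = rc.death_date_for(dob, 0, ref, rng)
            assert dob <= d <= ref
            assert d < date(2023, 6, 1)

    def test_window_interval_arithmetic(self, rng):
        dob = date(2000, 6, 15)
        ref = date(2023, 1, 1)
        for _ in range(300):
            d = rc.death_date_for(dob, 20, ref, rng)
            assert date(2020, 6, 15) <= d <= date(2021, 6, 14)

    @settings(derandomize=True, max_examples=300)
    @given(
        dob=st.dates(min_value=date(1940, 1, 1), max_value=date(2020, 12, 31)),
        age=st.integers(min_value=0, max_value=80),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_floor_age_at_death_invariant(self, dob, age, seed):
        ref = date(2023, 1, 1)
        try:
            d = rc.death_date_for(dob, age, ref, np.random.default_rng(seed))
        except GenerationError:
            # only valid when the whole age window lies after the reference date
            assert _shift_years(dob, age) > ref - timedelta(days=2)
            return
        assert _floor_age(dob, d) == age
        assert d <= ref

    def test_impossible_window_rejected(self, rng):
        with pytest.raises(GenerationError):
            rc.death_date_for(date(2020, 1, 1), 10, date(2021, 1, 1), rng)


class TestDiagnosisDates:
    def test_mean_offset_scd(self, scd, rng):
        draws = rc.sample_diagnosis_offset(scd.diagnosis, rng, size=100_000)
        assert draws.mean() == pytest.approx(5.5, abs=0.05)

    def test_cf_offsets_within_printed_range(self, cf, rng):
        draws = rc.sample_diagnosis_offset(cf.diagnosis, rng, size=10_000)
        assert draws.min() >= 2.0
        assert draws.max() <= 3.0

    def test_newborn_diagnosis_clamped_to_reference(self, dmd, rng):
        ref = date(2023, 1, 1)
        dob = date(2022, 12, 1)  # DMD lag is 1-3 years: always clamped
        diag, clamped = rc.diagnosis_date_for(dob, dmd.diagnosis, ref, rng)
        assert diag == ref
        assert clamped

    def test_diagnosis_between_birth_and_reference(self, scd, rng):
        ref = date(2023, 1, 1)
        dob = date(2010, 3, 14)
        diag, clamped = rc.diagnosis_date_for(dob, scd.diagnosis, ref, rng)
        assert dob <= diag <= ref
        assert not clamped


class TestGenerateCohort:
    def test_single_state_rounded_expectation_yields_one_patient(self, cf):
        table = rc.make_toy_demographics(1, 10_311, seed=1)
        settings_ = rc.GenerationSettings(seed=3, count_mode="rounded-expectation")
        cohort = rc.generate_cohort(cf, table, settings_)
        assert len(cohort.records) == 1

    def test_seed_reproducibility(self, scd, tmp_path):
        table = rc.make_toy_demographics(2, 300_000, seed=5)
        settings_ = rc.GenerationSettings(seed=11)
        a = rc.generate_cohort(scd, table, settings_)
        b = rc.generate_cohort(scd, table, settings_)
        assert a == b
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        rc.write_cohort(a, pa)
        rc.write_cohort(b, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_record_invariants(self, dmd):
        # DMD has high death rates, so this exercises the deceased branch
        table = rc.make_toy_demographics(2, 12_000_000, seed=9)
        cohort = rc.generate_cohort(dmd, table, rc.GenerationSettings(seed=2))
        assert len(cohort.records) > 500
        zips = {s.state_code: set(s.zip_codes) for s in table.states}
        ref = cohort.settings.reference_date
        assert sum(cohort.stratum_counts.values()) == len(cohort.records)
        n_dead = 0
        for r in cohort.records:
            assert r.zip in zips[r.state_code]
            assert r.date_of_birth <= r.date_of_diagnosis <= ref
            if r.vital_status == "deceased":
                n_dead += 1
                assert r.date_of_diagnosis <= r.date_of_death <= ref
                assert _floor_age(r.date_of_birth, r.date_of_death) == r.age_years
            else:
                assert r.date_of_death is None
                assert _floor_age(r.date_of_birth, ref) == r.age_years
        assert n_dead > 0
        ids = [r.patient_id for r in cohort.records]
        assert len(set(ids)) == len(ids)

    def test_counts_match_independent_binomial_oracle(self, scd):
        # brute-force oracle: replay each stratum's child stream directly
        table = rc.make_toy_demographics(1, 1_000_000, seed=4)
        cohort = rc.generate_cohort(scd, table, rc.GenerationSettings(seed=17))
        state = table.states[0]
        for gi, group in enumerate(rc.AGE_GROUPS):
            oracle_rng = stratum_rng(17, state.state_code, gi)
            pop = state.pop_in_group(group)
            expect = int(oracle_rng.binomial(pop, 1 / 3300)) if pop else 0
            key = f"{state.state_code}:{group.label}"
            assert cohort.stratum_counts[key] == expect

    def test_clinical_values_within_ranges(self, scd):
        table = rc.make_toy_demographics(1, 3_300_000, seed=6)
        cohort = rc.generate_cohort(scd, table, rc.GenerationSettings(seed=8))
        bounds = {p.name: (p.dist.low, p.dist.high) for p in scd.clinical_params}
        for r in cohort.records:
            for name, (lo, hi) in bounds.items():
                assert lo <= r.clinical[name] <= hi
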