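"""Eligibility, at-risk intervals, Lexis splitting and tallies, with
fine-step brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from excessrisk import (AnalysisSpec, EligibilityRuleSet, SimConfig, WomanRecord,
                        apply_eligibility, at_risk_interval, lexis_split,
                        make_reference_rates, simulate_cohort, tally)
from excessrisk.cohort import Event
from excessrisk.errors import DataError
from excessrisk.persontime import (EXIT_ADMIN, EXIT_AGE85, EXIT_COMPETING,
                                   EXIT_DEATH, EXIT_EVENT, classify_event)


def woman(age_dx=50.0, diag_year=2005, diag_frac=0.0, imd=3, events=(),
          death=None, fu_end=16.0, **kwargs):
    return WomanRecord(id=0, diag_year=diag_year, diag_frac=diag_frac,
                       age_dx=age_dx, imd=imd, events=list(events),
                       death_time=death, fu_end=fu_end, **kwargs)


# ---------------------------------------------------------------------------
# eligibility
# ---------------------------------------------------------------------------

class TestEligibility:
    def test_age_below_20_excluded(self):
        eligible, counts = apply_eligibility([woman(age_dx=19.0)],
                                             EligibilityRuleSet())
        assert not eligible and counts["age_at_diagnosis"] == 1

    def test_age_76_excluded_75_kept(self):
        eligible, _ = apply_eligibility([woman(age_dx=76.0), woman(age_dx=75.0)],
                                        EligibilityRuleSet())
        assert len(eligible) == 1 and eligible[0].age_dx == 75.0

    def test_early_second_invasive_excluded(self):
        w = woman(events=[Event(time=2 / 12, group="lung")])
        eligible, counts = apply_eligibility([w], EligibilityRuleSet())
        assert not eligible
        assert counts["second_invasive_within_3_months"] == 1

    def test_early_noninvasive_not_excluded(self):
        w = woman(events=[Event(time=2 / 12, group="lung", invasive=False)])
        eligible, _ = apply_eligibility([w], EligibilityRuleSet())
        assert len(eligible) == 1

    def test_short_follow_up_excluded(self):
        eligible, counts = apply_eligibility([woman(death=0.2)],
                                             EligibilityRuleSet())
        assert not eligible and counts["short_follow_up"] == 1

    def test_sequential_counting_no_double_count(self):
        # a woman violating both the age and metastatic rules counts only once
        w = woman(age_dx=19.0, metastatic=True)
        _, counts = apply_eligibility([w], EligibilityRuleSet())
        assert counts["age_at_diagnosis"] == 1
        assert counts["metastatic"] == 0

    def test_planted_violations_counted_by_construction(self):
        cohort = [woman() for _ in range(70)]
        cohort += [woman(age_dx=18.0) for _ in range(10)]
        cohort += [woman(metastatic=True) for _ in range(10)]
        cohort += [woman(neoadjuvant=True) for _ in range(10)]
        for i, w in enumerate(cohort):
            w.id = i
        eligible, counts = apply_eligibility(cohort, EligibilityRuleSet())
        assert len(eligible) == 70
        assert counts["age_at_diagnosis"] == 10
        assert counts["metastatic"] == 10
        assert counts["neoadjuvant"] == 10

    def test_rules_toggleable(self):
        rules = EligibilityRuleSet(age_bounds=None, exclude_metastatic=False)
        eligible, counts = apply_eligibility(
            [woman(age_dx=19.0, metastatic=True)], rules)
        assert len(eligible) == 1
        assert "age_at_diagnosis" not in counts


# ---------------------------------------------------------------------------
# at-risk intervals
# ---------------------------------------------------------------------------

class TestAtRiskInterval:
    def test_entry_is_three_months(self):
        iv = at_risk_interval(woman(), AnalysisSpec(target="lung"))
        assert iv.entry == pytest.approx(0.25)

    def test_diagnosis_near_85_zero_length(self):
        # at 84.80 the 85th birthday coincides with entry: no time at risk
        assert at_risk_interval(woman(age_dx=84.80),
                                AnalysisSpec(target="lung")) is None
        assert at_risk_interval(woman(age_dx=84.9),
                                AnalysisSpec(target="lung")) is None

    def test_death_before_event_wins(self):
        w = woman(events=[Event(time=5.0, group="lung")], death=4.0)
        iv = at_risk_interval(w, AnalysisSpec(target="lung"))
        assert iv.exit == 4.0 and iv.reason == EXIT_DEATH

    def test_noninvasive_ignored_under_invasive_spec(self):
        w = woman(events=[Event(time=2.0, group="lung", invasive=False),
                          Event(time=6.0, group="lung")])
        iv = at_risk_interval(w, AnalysisSpec(target="lung"))
        assert iv.exit == 6.0 and iv.reason == EXIT_EVENT

    def test_invasive_censors_noninvasive_analysis(self):
        w = woman(events=[Event(time=2.0, group="uterus"),
                          Event(time=6.0, group="lung", invasive=False)])
        iv = at_risk_interval(w, AnalysisSpec(target="lung",
                                              outcome_class="noninvasive"))
        assert iv.exit == 2.0 and iv.reason == EXIT_COMPETING

    def test_competing_event_exit(self):
        w = woman(events=[Event(time=3.0, group="uterus")])
        iv = at_risk_interval(w, AnalysisSpec(target="lung"))
        assert iv.exit == 3.0 and iv.reason == EXIT_COMPETING
        assert not iv.target_events

    def test_age85_caps_even_with_later_events(self):
        w = woman(age_dx=80.0, events=[Event(time=6.0, group="lung")])
        iv = at_risk_interval(w, AnalysisSpec(target="lung"))
        assert iv.exit == pytest.approx(5.0) and iv.reason == EXIT_AGE85

    def test_admin_exit(self):
        iv = at_risk_interval(woman(fu_end=12.0), AnalysisSpec(target="lung"))
        assert iv.exit == 12.0 and iv.reason == EXIT_ADMIN

    def test_any_time_mode_counts_all_target_events(self):
        w = woman(events=[Event(time=2.0, group="lung"),
                          Event(time=4.0, group="uterus"),
                          Event(time=7.0, group="lung")])
        # first-event: exit at first event
        iv1 = at_risk_interval(w, AnalysisSpec(target="lung"))
        assert iv1.exit == 2.0 and iv1.target_events == [2.0]
        # any-time: full follow-up, both lung events counted
        iv2 = at_risk_interval(w, AnalysisSpec(target="lung", mode="any-time"))
        assert iv2.exit == 12.0 if w.fu_end == 12.0 else iv2.exit == w.fu_end
        assert iv2.target_events == [2.0, 7.0]
        assert iv2.length > iv1.length

    def test_contralateral_classification(self):
        spec = AnalysisSpec(target="breast", contralateral=True)
        assert classify_event(Event(1.0, "breast", "contralateral"), spec) == "target"
        assert classify_event(Event(1.0, "breast", "unknown"), spec) == "target"
        assert classify_event(Event(1.0, "breast", "ipsilateral"), spec) == "competing"
        assert classify_event(Event(1.0, "lung"), spec) == "competing"


# ---------------------------------------------------------------------------
# Lexis splitting
# ---------------------------------------------------------------------------

class TestLexisSplit:
    def test_single_segment_no_split(self):
        # interval inside one band and one year: e-contribution = rate * length
        w = WomanRecord(id=1, diag_year=2005, diag_frac=0.75, age_dx=50.0,
                        imd=3, fu_end=1.25)   # at risk over exactly [2006, 2007)
        spec = AnalysisSpec(target="lung")
        table = make_reference_rates_flat()
        iv = at_risk_interval(w, spec)
        segs = lexis_split(iv, w, 5, table, spec)
        assert len(segs) == 1
        (key, length, rate) = segs[0]
        assert key == (50, 2006, 3)
        assert length == pytest.approx(1.0, abs=1e-9)
        assert rate == pytest.approx(0.001)

    def test_partition_is_exact(self, table, small_cohort):
        spec = AnalysisSpec(target="lung")
        checked = 0
        for w in small_cohort[:200]:
            iv = at_risk_interval(w, spec)
            if iv is None:
                continue
            segs = lexis_split(iv, w, 5, table, spec)
            assert sum(s[1] for s in segs) == pytest.approx(iv.length, abs=1e-9)
            # each segment lies wholly inside one band and one calendar year
            t = iv.entry
            for (band, year, _f), length, _r in segs:
                assert band <= w.age_dx + t + 1e-6
                assert w.age_dx + t + length <= band + 5 + 1e-6
                assert year <= w.diag_date + t + 1e-6
                assert w.diag_date + t + length <= year + 1 + 1e-6
                t += length
            checked += 1
        assert checked > 100

    def test_band_boundary_crossing(self, table):
        # 2.0-year interval crossing one band boundary at 0.7 years in
        w = WomanRecord(id=0, diag_year=2005, diag_frac=0.0, age_dx=54.05,
                        imd=3, fu_end=2.25)
        spec = AnalysisSpec(target="lung")
        iv = at_risk_interval(w, spec)
        segs = lexis_split(iv, w, 5, table, spec)
        # crossing age 55 at t=0.95 (0.7 into the interval) and years 2006, 2007
        lengths = [round(s[1], 6) for s in segs]
        assert sum(lengths) == pytest.approx(2.0)
        by_band = {}
        for (band, _y, _f), length, _r in segs:
            by_band[band] = by_band.get(band, 0.0) + length
        assert by_band[50] == pytest.approx(0.7, abs=1e-9)
        assert by_band[55] == pytest.approx(1.3, abs=1e-9)

    def test_fine_step_oracle(self, table, rng):
        # randomized intervals: segment sums match midpoint-rule accumulation
        spec = AnalysisSpec(target="lung")
        dt = 5e-4
        for _ in range(25):
            age = float(rng.uniform(30, 80))
            w = WomanRecord(id=0, diag_year=int(rng.integers(1995, 2012)),
                            diag_frac=float(rng.integers(0, 12)) / 12,
                            age_dx=age, imd=int(rng.integers(1, 6)),
                            fu_end=float(rng.uniform(0.5, 8.0)))
            iv = at_risk_interval(w, spec)
            if iv is None:
                continue
            segs = lexis_split(iv, w, 5, table, spec)
            e_split = sum(length * rate for _k, length, rate in segs)
            py_split = sum(length for _k, length, _r in segs)
            # oracle: fine midpoint Riemann sum over the raw interval
            m = int(math.ceil(iv.length / dt))
            ts = iv.entry + (np.arange(m) + 0.5) * (iv.length / m)
            e_brute = 0.0
            for t in ts:
                band = 20 + 5 * int((w.age_dx + t - 20) // 5)
                year = int(w.diag_date + t)
                e_brute += table.rate(band, year, w.imd, "lung") * (iv.length / m)
            assert py_split == pytest.approx(iv.length, abs=1e-9)
            assert e_split == pytest.approx(e_brute, abs=1e-6)

    def test_missing_cell_error_names_cell(self):
        table = make_reference_rates_flat(year_range=(2005, 2006))
        w = woman(diag_year=2005, fu_end=5.0)
        spec = AnalysisSpec(target="lung")
        iv = at_risk_interval(w, spec)
        with pytest.raises(DataError, match="year 2007"):
            lexis_split(iv, w, 5, table, spec)

    def test_contralateral_halves_reference_rate(self, table):
        w = woman()
        full = lexis_split(at_risk_interval(w, AnalysisSpec(target="breast")),
                           w, 5, table, AnalysisSpec(target="breast"))
        spec_c = AnalysisSpec(target="breast", contralateral=True)
        halved = lexis_split(at_risk_interval(w, spec_c), w, 5, table, spec_c)
        for (kf, lf, rf), (kh, lh, rh) in zip(full, halved):
            assert kf == kh and lf == lh
            assert rh == pytest.approx(rf / 2)


def make_reference_rates_flat(year_range=(1993, 2022)):
    from excessrisk import RateShapeSpec, make_reference_rates
    spec = RateShapeSpec(cancer_types={"lung": 0.001, "breast": 0.002},
                         age_slope=0.0, deprivation_gradient=0.0,
                         calendar_drift=0.0, mortality_rate_at_reference=0.0,
                         mortality_age_slope=0.0, year_range=year_range)
    return make_reference_rates(spec, seed=0)


# ---------------------------------------------------------------------------
# tallies
# ---------------------------------------------------------------------------

class TestTally:
    def test_single_woman_no_event(self):
        table = make_reference_rates_flat()
        w = WomanRecord(id=0, diag_year=2005, diag_frac=0.25, age_dx=50.25,
                        imd=3, fu_end=1.25)
        res = tally([w], AnalysisSpec(target="lung"), table)
        assert res.O == 0
        assert res.E == pytest.approx(0.001, abs=1e-12)
        assert res.PY == pytest.approx(1.0, abs=1e-9)

    def test_event_on_band_boundary_goes_to_later_band(self):
        table = make_reference_rates_flat()
        # attained age exactly 55 at the event: attributed to band 55
        w = WomanRecord(id=0, diag_year=2005, diag_frac=0.0, age_dx=50.0,
                        imd=3, fu_end=16.0, events=[Event(time=5.0, group="lung")])
        res = tally([w], AnalysisSpec(target="lung"), table)
        strata_with_o = [k for k, s in res.strata.items() if s.o]
        assert strata_with_o == [(55, 2010, 3)]

    def test_totals_match_per_woman_oracle(self, table, small_cohort):
        spec = AnalysisSpec(target="lung")
        res = tally(small_cohort, spec, table)
        O = E = PY = 0.0
        for w in small_cohort:
            iv = at_risk_interval(w, spec)
            if iv is None:
                continue
            O += len(iv.target_events)
            PY += iv.length
            for _k, length, rate in lexis_split(iv, w, 5, table, spec):
                E += length * rate
        assert res.O == O
        assert res.E == pytest.approx(E, rel=1e-12)
        assert res.PY == pytest.approx(PY, rel=1e-12)

    def test_conservation_under_stratum_merging(self, table, small_cohort):
        spec = AnalysisSpec(target="lung")
        fine = tally(small_cohort, spec, table, band_width=5)
        merged = {}
        for (band, year, fifth), s in fine.strata.items():
            key = (band // 10 * 10, year // 5 * 5)   # coarser strata
            agg = merged.setdefault(key, [0, 0.0, 0.0])
            agg[0] += s.o
            agg[1] += s.e
            agg[2] += s.py
        assert sum(v[0] for v in merged.values()) == fine.O
        assert sum(v[1] for v in merged.values()) == pytest.approx(fine.E)
        assert sum(v[2] for v in merged.values()) == pytest.approx(fine.PY)

    def test_any_time_py_geq_first_event(self, table, small_cohort):
        first = tally(small_cohort, AnalysisSpec(target="lung"), table)
        any_t = tally(small_cohort, AnalysisSpec(target="lung", mode="any-time"),
                      table)
        assert any_t.PY >= first.PY
        assert any_t.O >= first.O

    def test_exit_reasons_partition_cohort(self, table, small_cohort):
        spec = AnalysisSpec(target="lung")
        res = tally(small_cohort, spec, table)
        n_contributing = sum(res.exit_reasons.values())
        assert n_contributing + res.dropped_zero_length == len(small_cohort)


@settings(max_examples=50, deadline=None)
@given(age=st.floats(25.0, 80.0), frac=st.integers(0, 11),
       length=st.floats(0.3, 12.0), year=st.integers(1995, 2009))
def test_lexis_partition_property(age, frac, length, year):
    """Segments always partition the interval exactly and never leave a band."""
    table = make_reference_rates_flat()
    w = WomanRecord(id=0, diag_year=year, diag_frac=frac / 12, age_dx=round(age * 12) / 12,
                    imd=3, fu_end=length)
    spec = AnalysisSpec(target="lung")
    iv = at_risk_interval(w, spec)
    if iv is None:
        return
    segs = lexis_split(iv, w, 5, table, spec)
    assert sum(s[1] for s in segs) == pytest.approx(iv.length, abs=1e-9)
    t = iv.entry
    for (band, yr, _f), seg_len, _r in segs:
        assert band <= w.age_dx + t + 1e-6 < band + 5 + 1e-6
        assert yr <= w.diag_date + t + 1e-6 < yr + 2
        t += seg_len
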