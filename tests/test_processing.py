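import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actitraj.processing import (
    LIPA,
    MVPA,
    NONWEAR,
    SB,
    DaySummary,
    ProcessingRules,
    classify_intensity,
    detect_bouts,
    detect_nonwear,
    filter_valid_waves,
    process_epochs,
    summarise_day,
    weekly_mvpa,
)

from conftest import oracle_bouts, oracle_classify, oracle_nonwear

RULES = ProcessingRules()


class TestRules:
    def test_defaults(self):
        assert RULES.sb_upper == 99
        assert RULES.lipa_upper == 1951
        assert RULES.mvpa_lower == 1952

    def test_invalid_cutpoint_ordering_rejected(self):
        with pytest.raises(ValueError):
            ProcessingRules(lipa_upper=1951, mvpa_lower=1953)
        with pytest.raises(ValueError):
            ProcessingRules(sb_upper=2000)


class TestNonwear:
    def test_90_zeros_all_nonwear(self):
        assert detect_nonwear(np.zeros(90)).sum() == 0

    def test_89_zeros_all_wear(self):
        assert detect_nonwear(np.zeros(89)).all()

    def test_interruption_within_allowance_merges(self):
        counts = np.r_[np.zeros(45), [5, 5], np.zeros(45)]
        wear = detect_nonwear(counts)
        assert not wear.any()  # 92 minutes marked, 90 zero minutes total

    def test_interruption_beyond_allowance_splits(self):
        counts = np.r_[np.zeros(45), [5, 5, 5], np.zeros(45)]
        assert detect_nonwear(counts).all()

    def test_interruption_minutes_marked_nonwear(self):
        counts = np.r_[np.zeros(90), [5], np.zeros(10)]
        wear = detect_nonwear(counts)
        assert not wear[:101].any()

    def test_trailing_interruption_not_absorbed(self):
        counts = np.r_[np.zeros(95), [5, 5]]
        wear = detect_nonwear(counts)
        assert not wear[:95].any()
        assert wear[95:].all()

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            detect_nonwear([-1, 0, 0])

    def test_empty_day(self):
        assert detect_nonwear([]).size == 0

    def test_strict_flank_variant_is_stricter(self):
        # interruption flanked by short zero runs: merged by the default rule
        counts = np.r_[np.zeros(20), [5], np.zeros(95)]
        assert not detect_nonwear(counts).any()
        strict = detect_nonwear(counts, ProcessingRules(strict_flanks=True))
        assert strict[:21].all() and not strict[21:].any()

    @settings(max_examples=300, deadline=None)
    @given(st.lists(st.sampled_from([0, 0, 0, 1, 200]), max_size=120))
    def test_matches_oracle_small(self, counts):
        rules = ProcessingRules(nonwear_window=10, nonwear_allowance=2)
        expected = oracle_nonwear(counts, window=10, allowance=2)
        assert detect_nonwear(counts, rules).tolist() == expected


class TestClassify:
    @pytest.mark.parametrize(
        "count,expected", [(0, SB), (99, SB), (100, LIPA), (1951, LIPA), (1952, MVPA), (5000, MVPA)]
    )
    def test_cutpoints(self, count, expected):
        wear = np.ones(1, dtype=bool)
        assert classify_intensity([count], wear)[0] == expected

    def test_nonwear_precedence(self):
        out = classify_intensity([0], [False])
        assert out[0] == NONWEAR

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_intensity([-5], [True])

    def test_random_day_matches_bruteforce(self):
        rng = np.random.default_rng(42)
        counts = rng.integers(0, 4000, size=200)
        wear = rng.random(200) > 0.2
        got = classify_intensity(counts, wear)
        for c, w, g in zip(counts, wear, got):
            assert g == (oracle_classify(c, RULES) if w else NONWEAR)


class TestBouts:
    def test_exact_threshold_mvpa(self):
        classes = [MVPA] * 10
        assert detect_bouts(classes, MVPA, 10) == [(0, 10)]

    def test_broken_run_no_bout(self):
        classes = [MVPA] * 9 + [LIPA] + [MVPA] * 9
        assert detect_bouts(classes, MVPA, 10) == []

    def test_sb_bout_threshold(self):
        assert detect_bouts([SB] * 30, SB, 30) == [(0, 30)]
        assert detect_bouts([SB] * 29, SB, 30) == []

    def test_run_truncated_by_day_boundary_counts(self):
        classes = [SB] * 40 + [LIPA]
        assert detect_bouts(classes, SB, 30) == [(0, 40)]

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.sampled_from([SB, LIPA, MVPA, NONWEAR]), max_size=80),
           st.integers(min_value=1, max_value=6))
    def test_matches_oracle(self, classes, min_len):
        for target in (SB, MVPA):
            assert detect_bouts(classes, target, min_len) == oracle_bouts(classes, target, min_len)


class TestSummarise:
    def test_all_sb_day(self):
        counts = np.r_[np.full(600, 50), np.zeros(840)]
        d = summarise_day(counts)
        assert d.sb_minutes == 600
        assert d.valid
        assert d.sb_bout_count >= 1

    def test_599_wear_minutes_invalid(self):
        counts = np.r_[np.full(599, 50), np.zeros(841)]
        d = summarise_day(counts)
        assert d.wear_minutes == 599
        assert not d.valid

    def test_worked_day_hand_summary(self, worked_fixtures):
        counts, steps = worked_fixtures["worked_day"]
        d = summarise_day(counts, steps)
        assert d == DaySummary(
            wear_minutes=840, sb_minutes=758, lipa_minutes=51, mvpa_minutes=31,
            sb_bout_count=3, sb_bout_minutes=758,
            mvpa_bout_count=2, mvpa_bout_minutes=22,
            total_counts=162990, total_steps=5180, valid=True,
        )

    def test_partition_invariant(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            counts = rng.choice([0, 50, 500, 2500], size=1440, p=[0.55, 0.25, 0.15, 0.05])
            d = summarise_day(counts)
            assert d.sb_minutes + d.lipa_minutes + d.mvpa_minutes == d.wear_minutes
            nonwear = 1440 - d.wear_minutes
            assert nonwear + d.sb_minutes + d.lipa_minutes + d.mvpa_minutes == 1440
            assert d.sb_bout_minutes <= d.sb_minutes
            assert d.mvpa_bout_minutes <= d.mvpa_minutes

    def test_fixture_bouts(self, worked_fixtures):
        counts, _ = worked_fixtures["mvpa_12"]
        d = summarise_day(counts, rules=ProcessingRules())
        assert d.mvpa_bout_count == 1
        assert d.mvpa_bout_minutes == 12


def _day_rows(pid, wave, day, wear_minutes):
    counts = np.r_[np.full(wear_minutes, 50), np.zeros(1440 - wear_minutes)]
    return pd.DataFrame(
        {
            "participant_id": pid, "wave_month": wave, "day_index": day,
            "epoch_index": np.arange(1440), "counts": counts.astype(int), "steps": 0,
        }
    )


class TestFilterValidWaves:
    def _days(self, spec):
        frames = [_day_rows(pid, wave, day, wear)
                  for pid, wave, day, wear in spec]
        return process_epochs(pd.concat(frames, ignore_index=True))

    def test_three_valid_plus_invalid_retained(self):
        spec = [(1, 0, d, 700) for d in range(1, 4)] + [(1, 0, d, 300) for d in range(4, 8)]
        days = self._days(spec)
        retained, waves, acc = filter_valid_waves(days)
        assert waves.loc[0, "retained"]
        assert len(retained) == 3  # invalid days dropped from retained wave

    def test_two_valid_days_dropped(self):
        days = self._days([(1, 0, 1, 700), (1, 0, 2, 700), (1, 0, 3, 300)])
        retained, waves, acc = filter_valid_waves(days)
        assert not waves.loc[0, "retained"]
        assert retained.empty
        assert acc["participants_excluded"] == 1

    def test_participant_without_retained_waves_excluded(self):
        spec = [(1, 0, d, 700) for d in (1, 2, 3)] + [(2, 0, 1, 700)]
        retained, waves, acc = filter_valid_waves(self._days(spec))
        assert acc["participants_in"] == 2
        assert acc["participants_retained"] == 1
        assert set(retained["participant_id"]) == {1}

    def test_raising_wear_threshold_monotone(self):
        rng = np.random.default_rng(5)
        spec = [(1, 0, d, int(w)) for d, w in enumerate(rng.integers(400, 900, 8), 1)]
        days = self._days(spec)
        valid_counts = []
        for threshold in (500, 600, 700, 800):
            rules = ProcessingRules(valid_day_wear=threshold)
            n_valid = sum(
                summarise_day(
                    np.r_[np.full(w, 50), np.zeros(1440 - w)], rules=rules
                ).valid
                for *_, w in spec
            )
            valid_counts.append(n_valid)
        assert valid_counts == sorted(valid_counts, reverse=True)


class TestWeeklyMvpa:
    def test_arithmetic(self):
        minutes, flag = weekly_mvpa([20, 22, 24])
        assert minutes == pytest.approx(154.0)
        assert flag

    def test_zero(self):
        minutes, flag = weekly_mvpa([0, 0, 0])
        assert minutes == 0.0
        assert not flag

    def test_boundary_inclusive(self):
        minutes, flag = weekly_mvpa([150.0 / 7.0] * 3)
        assert minutes == pytest.approx(150.0)
        assert flag

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            weekly_mvpa([])
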