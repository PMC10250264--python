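import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import flankrel as fr
from flankrel.scoring import (REASON_INCORRECT, REASON_NONE, REASON_PRACTICE,
                              REASON_RT_GT_3MAD, REASON_RT_LT_100)

from conftest import make_trials


class TestRtFlags:
    def test_mad_hand_example(self):
        """RTs {400,410,420,430,1000}: median 420, MAD 10, cut 420+30 -> only
        the 1000 ms trial is slow-flagged."""
        t = make_trials([{"rt_ms": r} for r in (400, 410, 420, 430, 1000)])
        out = fr.flag_rt_exclusions(t)
        assert out.rt_gt_3mad.tolist() == [False] * 4 + [True]
        assert not out.rt_lt_100.any()
        assert out.excluded_reason.tolist() == [REASON_NONE] * 4 + [REASON_RT_GT_3MAD]

    def test_constant_rts_mad_zero(self):
        t = make_trials([{"rt_ms": 400.0} for _ in range(6)]
                        + [{"rt_ms": 400.5}])
        out = fr.flag_rt_exclusions(t)
        assert out.rt_gt_3mad.tolist() == [False] * 6 + [True]
        assert not out.rt_lt_100.any()

    def test_fast_guess_floor(self):
        t = make_trials([{"rt_ms": r} for r in (99, 100, 400, 410, 420)])
        out = fr.flag_rt_exclusions(t)
        assert out.rt_lt_100.tolist() == [True, False, False, False, False]
        assert out.excluded_reason.iloc[0] == REASON_RT_LT_100

    def test_practice_never_scored(self):
        t = make_trials([{"block": "practice", "rt_ms": 5000.0}]
                        + [{"rt_ms": r} for r in (400, 410, 420, 430)])
        out = fr.flag_rt_exclusions(t)
        assert out.excluded_reason.iloc[0] == REASON_PRACTICE
        assert not out.rt_gt_3mad.iloc[0]

    def test_too_few_trials_raises(self):
        with pytest.raises(ValueError, match="MAD undefined"):
            fr.flag_rt_exclusions(make_trials([{}, {}, {}]))

    def test_no_iterative_reflagging(self):
        """The cut is computed once on the pre-exclusion set: a trial that
        would only be flagged after removing a bigger outlier stays in."""
        rts = (400, 410, 420, 430, 460, 1000)
        out = fr.flag_rt_exclusions(make_trials([{"rt_ms": r} for r in rts]))
        assert out.rt_gt_3mad.tolist() == [False] * 5 + [True]
        # removing the flagged trial and re-running flags the 460 -- i.e. the
        # single-pass rule really is less aggressive than an iterative one
        again = fr.flag_rt_exclusions(
            make_trials([{"rt_ms": r} for r in rts[:-1]]))
        assert again.rt_gt_3mad.tolist() == [False] * 4 + [True]

    def test_removing_unflagged_trial_preserves_other_flags(self, flagged):
        one = flagged[(flagged.participant == 3) & (flagged.session == 1)]
        keep = one[one.excluded_reason != REASON_RT_GT_3MAD]
        assert (keep.excluded_reason == one.loc[keep.index, "excluded_reason"]).all()

    def test_mad_scope_condition_switch(self):
        # congruent tight around 400, incongruent tight around 700: pooled
        # threshold flags nothing extreme, per-condition flags the 780
        rows = ([{"rt_ms": 400 + d} for d in (-10, -5, 0, 5, 10)]
                + [{"rt_ms": 700 + d, "condition": "incongruent"}
                   for d in (-10, -5, 0, 5, 80)])
        pooled = fr.flag_rt_exclusions(make_trials(rows))
        per_cond = fr.flag_rt_exclusions(
            make_trials(rows), config=fr.ScoringConfig(mad_scope="condition"))
        assert not pooled.rt_gt_3mad.iloc[-1]
        assert per_cond.rt_gt_3mad.iloc[-1]

    def test_median_pct_slow_tail_in_table_band(self, scores):
        """Under the default noise profile the 3MAD rule catches a 3-6% slow
        tail per condition, as in real flanker data."""
        for s in ("1", "2"):
            d = fr.group_descriptives(scores)["synthetic"][s]["median_pct_3mad"]
            assert 3.0 <= d["congruent"] <= 6.0
            assert 3.0 <= d["incongruent"] <= 6.0


class TestScoring:
    def test_four_trial_toy_effect(self):
        t = make_trials([
            {"rt_ms": 500}, {"rt_ms": 520},
            {"rt_ms": 540, "condition": "incongruent"},
            {"rt_ms": 560, "condition": "incongruent"},
        ])
        s = fr.score_participant(t)
        assert s.mean_rt_congruent == 510
        assert s.mean_rt_incongruent == 550
        assert s.flanker_effect == 40

    def test_effect_is_difference_of_condition_means(self):
        t = make_trials(
            [{"rt_ms": 455.0}] * 4
            + [{"rt_ms": 492.0, "condition": "incongruent"}] * 4)
        assert fr.score_participant(t).flanker_effect == pytest.approx(37.0)

    def test_identical_conditions_zero_effect(self):
        t = make_trials([{"rt_ms": 400 + i} for i in range(8)]
                        + [{"rt_ms": 400 + i, "condition": "incongruent"}
                           for i in range(8)])
        assert fr.score_participant(t).flanker_effect == pytest.approx(0.0)

    def test_order_invariance(self, flagged):
        shuffled = flagged.sample(frac=1.0, random_state=1)
        a, _ = fr.score_dataset(flagged)
        b, _ = fr.score_dataset(shuffled)
        pd.testing.assert_frame_equal(
            a.sort_values(["participant", "session"]).reset_index(drop=True),
            b.sort_values(["participant", "session"]).reset_index(drop=True))

    @given(st.lists(st.tuples(st.floats(150, 1500), st.booleans(),
                              st.booleans()),
                    min_size=10, max_size=60))
    @settings(max_examples=25)
    def test_brute_force_effect_oracle(self, raw):
        """Pipeline flanker effect equals an independent filter -> group ->
        mean -> subtract pass to 1e-9."""
        rows = [{"rt_ms": rt, "correct": ok,
                 "condition": "incongruent" if inc else "congruent"}
                for rt, ok, inc in raw]
        if sum(ok for _, ok, _ in raw) < 4:
            with pytest.raises(ValueError, match="MAD undefined"):
                fr.flag_rt_exclusions(make_trials(rows))
            return
        t = fr.flag_rt_exclusions(make_trials(rows))
        valid = t[(t.excluded_reason == REASON_NONE)]
        if (valid.condition == "congruent").sum() == 0 or \
           (valid.condition == "incongruent").sum() == 0:
            scores, _ = fr.score_dataset(t)
            assert len(scores) == 0
            return
        expected = (valid[valid.condition == "incongruent"].rt_ms.mean()
                    - valid[valid.condition == "congruent"].rt_ms.mean())
        assert fr.score_participant(t).flanker_effect == pytest.approx(
            expected, abs=1e-9)

    def test_incorrect_trials_excluded_from_means_but_counted_in_accuracy(self):
        t = make_trials([
            {"rt_ms": 400}, {"rt_ms": 420},
            {"rt_ms": 9000, "correct": False},
            {"rt_ms": 500, "condition": "incongruent"},
            {"rt_ms": 520, "condition": "incongruent"},
        ])
        s = fr.score_participant(t)
        assert s.mean_rt_congruent == 410
        assert s.accuracy == pytest.approx(4 / 5)
        assert s.pct_incorrect_congruent == pytest.approx(100 / 3)

    def test_zero_valid_condition_reported_and_dropped(self):
        t = make_trials([
            {"rt_ms": 400}, {"rt_ms": 410}, {"rt_ms": 420}, {"rt_ms": 430},
            {"rt_ms": 500, "condition": "incongruent", "correct": False},
        ])
        scores, dropped = fr.score_dataset(t)
        assert len(scores) == 0 and len(dropped) == 1
        with pytest.raises(ValueError, match="undefined"):
            fr.score_participant(t)

    def test_duplicate_participant_ids_across_groups_rejected(self):
        t = pd.concat([make_trials([{}] * 4),
                       make_trials([{"group": "h"}] * 4)])
        with pytest.raises(ValueError, match="more than one group"):
            fr.flag_rt_exclusions(t)


class TestParticipantExclusion:
    @staticmethod
    def _scores(rows):
        return pd.DataFrame([
            {"participant": p, "session": s, "accuracy": a, "group": "g"}
            for p, s, a in rows])

    def test_below_60_in_either_session_excluded(self):
        sc = self._scores([(1, 1, 0.59), (1, 2, 0.99),
                           (2, 1, 0.99), (2, 2, 0.99)])
        retained, report = fr.exclude_participants(sc)
        assert retained == [2]
        assert report.set_index("participant").status[1] == "low_accuracy"

    def test_exactly_60_is_retained(self):
        sc = self._scores([(1, 1, 0.60), (1, 2, 0.60)])
        retained, _ = fr.exclude_participants(sc)
        assert retained == [1]

    def test_missing_session_flagged_incomplete(self):
        sc = self._scores([(1, 1, 0.9), (2, 1, 0.9), (2, 2, 0.9)])
        retained, report = fr.exclude_participants(sc)
        assert retained == [2]
        assert report.set_index("participant").status[1] == "incomplete"

    def test_default_profile_has_no_exclusions(self, scores):
        retained, report = fr.exclude_participants(scores)
        assert len(retained) == scores.participant.nunique()
        assert scores.accuracy.min() > 0.80


class TestDescriptives:
    def test_single_participant_sds_missing(self):
        t = make_trials([{"rt_ms": 400 + i} for i in range(4)]
                        + [{"rt_ms": 440 + i, "condition": "incongruent"}
                           for i in range(4)])
        sc, _ = fr.score_dataset(t)
        d = fr.group_descriptives(sc)["g"]["1"]
        assert d["sd_flanker_effect"] is None
        assert d["corr_congruent_incongruent"] is None

    def test_row_order_invariant(self, scores):
        a = fr.group_descriptives(scores)
        b = fr.group_descriptives(scores.sample(frac=1.0, random_state=0))

        def walk(x, y):
            assert type(x) is type(y)
            if isinstance(x, dict):
                assert x.keys() == y.keys()
                for k in x:
                    walk(x[k], y[k])
            elif isinstance(x, float):
                assert x == pytest.approx(y, rel=1e-12)
            else:
                assert x == y

        walk(a, b)


class TestReader:
    def test_roundtrip_and_validation(self, trials, tmp_path):
        path = tmp_path / "t.csv"
        fr.write_trials(trials.head(500), path)
        back = fr.read_trials(path)
        assert len(back) == 500
        assert back.rt_ms.dtype == float

    def test_bad_condition_names_row_number(self, tmp_path):
        df = make_trials([{}, {}, {}, {}])
        df.loc[2, "condition"] = "weird"
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(fr.TrialDataError, match=r"\[4\]"):
            fr.read_trials(path)

    def test_missing_column(self, tmp_path):
        path = tmp_path / "m.csv"
        make_trials([{}]).drop(columns=["rt_ms"]).to_csv(path, index=False)
        with pytest.raises(fr.TrialDataError, match="rt_ms"):
            fr.read_trials(path)
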