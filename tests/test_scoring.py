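import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from keeneye import (
    INDEFINITE,
    PatientProfile,
    SessionRecord,
    TrialResponse,
    UndefinedCoefficientWarning,
    generate_main_schedule,
    ka_all,
    ka_bilateral,
    kef_all,
    omission_percentages,
    score_session,
    simulate_session,
)
from keeneye.protocol import Schedule, configurations_by_id, positions_by_id
from keeneye.scoring import _kpr_from_counts


def _constant_session(schedule, sides, digit_offset=0):
    """Session reporting the same side set on every trial; digit shifted by
    offset mod 4 (0 = always correct)."""
    responses = []
    for t in schedule.trials:
        digit = (t.digit - 1 + digit_offset) % 4 + 1
        responses.append(TrialResponse(frozenset(sides), digit))
    return SessionRecord("const", schedule, responses)


class TestScoreSession:
    def test_all_correct_is_all_zero(self, perfect_session):
        sheet = score_session(perfect_session)
        for name in ("RSU", "LSU", "RSB", "LSB", "RH", "LH", "NIR", "NIL", "NIB"):
            assert getattr(sheet, name) == 0
        assert sum(sheet.position_omissions.values()) == 0
        assert sheet.KA_all == 0 and sheet.KA_bilateral == 0
        assert sheet.KEf_all == 1
        assert sheet.KPrL_all == sheet.KPrR_all == 1
        assert sheet.KPrL_bilateral == sheet.KPrR_bilateral == 1

    def test_always_right_report(self, main_schedule):
        # right-only reports: every left circle missed; on the 21 left
        # unilateral trials the right report is a hallucination
        sheet = score_session(_constant_session(main_schedule, {"right"}))
        assert (sheet.LSU, sheet.LSB) == (21, 33)
        assert (sheet.RSU, sheet.RSB) == (0, 0)
        assert (sheet.RH, sheet.LH) == (21, 0)
        assert sheet.KA_all == 1.0
        assert sheet.KPrL_all == 0.0 and sheet.KPrL_bilateral == 0.0

    def test_empty_reports(self, main_schedule):
        # nothing reported: every presentation missed, no hallucinations;
        # all detection-based denominators vanish, so the coefficients are
        # tagged undefined rather than clamped
        with pytest.warns(UndefinedCoefficientWarning):
            sheet = score_session(_constant_session(main_schedule, set()))
        assert (sheet.LSU, sheet.LSB, sheet.RSU, sheet.RSB) == (21, 33, 21, 33)
        assert (sheet.RH, sheet.LH) == (0, 0)
        assert sheet.KA_all is None and sheet.KA_bilateral is None
        assert sheet.KEf_all is None
        assert sheet.KPrL_all == 0.0 and sheet.KPrR_all == 0.0

    def test_both_reports_no_misses_both_hallucination_types(self, main_schedule):
        sheet = score_session(_constant_session(main_schedule, {"left", "right"}))
        assert (sheet.LSU, sheet.LSB, sheet.RSU, sheet.RSB) == (0, 0, 0, 0)
        assert (sheet.RH, sheet.LH) == (21, 21)

    def test_digit_errors_partition_by_trial_kind(self, main_schedule):
        sheet = score_session(
            _constant_session(main_schedule, {"left", "right"}, digit_offset=1))
        assert sheet.NIB == 33
        assert sheet.NIR + sheet.NIL == 42
        assert sheet.NIR == 21 and sheet.NIL == 21

    def test_position_sum_identity(self, main_schedule):
        profile = PatientProfile(p_base_left=0.3, p_base_right=0.7,
                                 extinction_penalty=0.5, vertical_penalty=0.8)
        for seed in range(5):
            sheet = score_session(simulate_session(profile, main_schedule, seed))
            left = sum(sheet.position_omissions[i] for i in range(1, 8))
            right = sum(sheet.position_omissions[i] for i in range(8, 15))
            assert left == sheet.LSU + sheet.LSB
            assert right == sheet.RSU + sheet.RSB

    def test_permutation_invariance(self, main_schedule):
        profile = PatientProfile(p_base_left=0.4, h_right=0.2, d_correct_uni=0.7)
        record = simulate_session(profile, main_schedule, seed=11)
        rng = np.random.default_rng(0)
        order = rng.permutation(75)
        trials = [main_schedule.trials[i] for i in order]
        # reindex so trial indices stay 0..74
        trials = [type(t)(trial_index=i, config_id=t.config_id, digit=t.digit)
                  for i, t in enumerate(trials)]
        shuffled = SessionRecord(
            "perm",
            Schedule(trials=trials, seed=main_schedule.seed, kind="main"),
            [record.responses[i] for i in order],
        )
        a, b = score_session(record), score_session(shuffled)
        for name in ("RSU", "LSU", "RSB", "LSB", "RH", "LH", "NIR", "NIL", "NIB",
                     "KA_all", "KA_bilateral", "KEf_all"):
            assert getattr(a, name) == getattr(b, name)
        assert a.position_omissions == b.position_omissions

    def test_mirror_antisymmetry(self, main_schedule):
        """Mirroring the whole session (stimuli and reports) across the
        vertical meridian swaps the L/R counts, negates KA and swaps KPr."""
        profile = PatientProfile(p_base_left=0.3, p_base_right=0.9,
                                 h_right=0.1, h_left=0.05)
        record = simulate_session(profile, main_schedule, seed=4)
        flip = {"left": "right", "right": "left"}

        def mirror_pid(p):
            return p + 7 if p <= 7 else p - 7

        config_by_pos = {frozenset(c.position_ids): c.config_id
                         for c in configurations_by_id().values()}
        configs = configurations_by_id()
        trials = []
        for t in main_schedule.trials:
            mirrored_pos = frozenset(mirror_pid(p)
                                     for p in configs[t.config_id].position_ids)
            trials.append(type(t)(trial_index=t.trial_index,
                                  config_id=config_by_pos[mirrored_pos],
                                  digit=t.digit))
        mirrored = SessionRecord(
            "mirror",
            Schedule(trials=trials, seed=main_schedule.seed, kind="main"),
            [TrialResponse(frozenset(flip[s] for s in r.reported_sides),
                           r.reported_digit)
             for r in record.responses],
        )
        a, b = score_session(record), score_session(mirrored)
        assert (a.LSU, a.LSB) == (b.RSU, b.RSB)
        assert (a.RSU, a.RSB) == (b.LSU, b.LSB)
        assert a.RH == b.LH and a.LH == b.RH
        assert b.KA_all == pytest.approx(-a.KA_all)
        assert b.KA_bilateral == pytest.approx(-a.KA_bilateral)
        assert b.KPrL_all == pytest.approx(a.KPrR_all)
        assert b.KPrR_bilateral == pytest.approx(a.KPrL_bilateral)
        # position omissions reflect across the meridian
        for p in range(1, 15):
            assert b.position_omissions[mirror_pid(p)] == a.position_omissions[p]

    def test_invalid_record_rejected(self, main_schedule):
        record = SessionRecord("bad", main_schedule,
                               [TrialResponse(frozenset(), 1)] * 10)
        with pytest.raises(ValueError, match="invalid session"):
            score_session(record)


_response_strategy = st.lists(
    st.tuples(
        st.sets(st.sampled_from(["left", "right"]), max_size=2),
        st.one_of(st.integers(1, 4), st.just(INDEFINITE)),
    ),
    min_size=75, max_size=75,
)


class TestScoreSheetInvariants:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(_response_strategy)
    def test_bounds_and_identities_hold_for_arbitrary_responses(self, raw):
        """Count bounds, the position-sum identity and coefficient ranges
        hold for every possible response pattern."""
        schedule = generate_main_schedule(seed=3)
        record = SessionRecord(
            "hyp", schedule,
            [TrialResponse(frozenset(s), d) for s, d in raw])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UndefinedCoefficientWarning)
            sheet = score_session(record)
        for name in ("RSU", "LSU", "NIR", "NIL"):
            assert 0 <= getattr(sheet, name) <= 21
        for name in ("RSB", "LSB", "NIB"):
            assert 0 <= getattr(sheet, name) <= 33
        assert 0 <= sheet.RH <= 21 and 0 <= sheet.LH <= 21
        left = sum(sheet.position_omissions[i] for i in range(1, 8))
        right = sum(sheet.position_omissions[i] for i in range(8, 15))
        assert left == sheet.LSU + sheet.LSB
        assert right == sheet.RSU + sheet.RSB
        for name in ("KA_bilateral", "KA_all"):
            v = getattr(sheet, name)
            assert v is None or -1 <= v <= 1
        for name in ("KPrR_bilateral", "KPrL_bilateral", "KPrR_all", "KPrL_all"):
            assert 0 <= getattr(sheet, name) <= 1
        if sheet.KEf_all is not None:
            assert -1 <= sheet.KEf_all <= 1


class TestCoefficientFormulas:
    @pytest.mark.parametrize("lsb,rsb,bp,expected", [
        (0, 0, 33, 0.0),
        (33, 0, 33, 1.0),
        (0, 33, 33, -1.0),
        (14, 0, 33, 14 / 52),
    ])
    def test_ka_bilateral(self, lsb, rsb, bp, expected):
        assert ka_bilateral(lsb, rsb, bp) == pytest.approx(expected)

    @pytest.mark.parametrize("lsu,lsb,rsu,rsb,expected", [
        (0, 0, 0, 0, 0.0),
        (21, 33, 0, 0, 1.0),
        (0, 0, 21, 33, -1.0),
        (16, 29, 4, 6, 35 / 53),
    ])
    def test_ka_all(self, lsu, lsb, rsu, rsb, expected):
        assert ka_all(lsu, lsb, rsu, rsb, 54) == pytest.approx(expected)

    def test_kef_all(self):
        assert kef_all(10, 20, 5, 15, 0, 0, 54) == 1.0
        # detections == hallucinations -> 0 (contrived large-H case)
        assert kef_all(21, 33, 21, 32, 1, 0, 54) == 0.0
        assert kef_all(16, 29, 2, 3, 1, 1, 54) == pytest.approx(56 / 60)

    def test_kpr(self):
        assert _kpr_from_counts(33, 0, 33, 54, "bilateral") == 0.0
        assert _kpr_from_counts(0, 0, 33, 54, "all") == 1.0
        assert _kpr_from_counts(29, 16, 33, 54, "all") == pytest.approx(9 / 54)

    def test_out_of_range_counts_rejected(self):
        with pytest.raises(ValueError):
            ka_bilateral(34, 0, 33)
        with pytest.raises(ValueError):
            ka_all(30, 30, 0, 0, 54)
        with pytest.raises(ValueError):
            kef_all(-1, 0, 0, 0, 0, 0, 54)

    def test_zero_denominator_returns_tagged_undefined(self):
        with pytest.warns(UndefinedCoefficientWarning):
            assert ka_bilateral(33, 33, 33) is None
        with pytest.warns(UndefinedCoefficientWarning):
            assert ka_all(21, 33, 21, 33, 54) is None
        with pytest.warns(UndefinedCoefficientWarning):
            assert kef_all(21, 33, 21, 33, 0, 0, 54) is None

    def test_ka_all_monotone_in_left_misses(self):
        base = ka_all(5, 10, 3, 4, 54)
        assert ka_all(6, 10, 3, 4, 54) > base
        assert ka_all(5, 11, 3, 4, 54) > base
        assert ka_all(5, 10, 4, 4, 54) < base
        assert ka_all(5, 10, 3, 5, 54) < base

    def test_consistency_ka_from_kpr(self, main_schedule):
        """KPrL_bilateral == 1 - LSB/BP and KA recomputed from KPr agrees."""
        profile = PatientProfile(p_base_left=0.4, p_base_right=0.8,
                                 extinction_penalty=0.6)
        sheet = score_session(simulate_session(profile, main_schedule, seed=2))
        bp, lp = sheet.constants.bp, sheet.constants.lp
        assert sheet.KPrL_bilateral == pytest.approx(1 - sheet.LSB / bp, abs=1e-12)
        ka_from_kpr = ((sheet.KPrR_bilateral - sheet.KPrL_bilateral)
                       / (sheet.KPrR_bilateral + sheet.KPrL_bilateral))
        assert sheet.KA_bilateral == pytest.approx(ka_from_kpr, abs=1e-12)


class TestOmissionPercentages:
    def test_normalized_by_position_maximum(self, main_schedule):
        sheet = score_session(_constant_session(main_schedule, set()))
        pct = omission_percentages(sheet)
        assert all(v == 100.0 for v in pct.values())
        assert sheet.position_max[2] == 6 and sheet.position_max[1] == 9

    def test_partial(self, perfect_session):
        sheet = score_session(perfect_session)
        sheet.position_omissions[4] = 3
        assert omission_percentages(sheet)[4] == pytest.approx(100 * 3 / 9)
        assert omission_percentages(sheet)[1] == 0.0
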