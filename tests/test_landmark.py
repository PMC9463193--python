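"""Reverse landmark truncation: the per-record rule and arm-level endpoints."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cvclm.generator import GeneratorConfig, generate_cohort
from cvclm.landmark import (
    DEFAULT_LANDMARKS,
    LandmarkError,
    TruncatedRecord,
    apply_landmark,
    premature_removal_fraction,
    summarize_endpoint,
    truncate_record,
)
from cvclm.randomization import ARMS, allocate

from conftest import make_record


def _tr(arm="D14rmv", days=10, definite=False, probable=False, premature=False,
        record_id="T1"):
    return TruncatedRecord(record_id=record_id, arm=arm, contributed_days=days,
                           event_definite=definite, event_probable=probable,
                           premature_removal=premature)


class TestTruncateRecord:
    def test_event_after_landmark_is_erased(self):
        rec = make_record(dwell_days=20, crbsi_class="definite",
                          crbsi_onset_day=16, pathogen="CoNS")
        t = truncate_record(rec, 14)
        assert t.contributed_days == 14
        assert not t.event_definite and not t.event_probable
        assert t.premature_removal

    def test_event_before_landmark_is_kept_with_class(self):
        rec = make_record(dwell_days=10, crbsi_class="probable",
                          crbsi_onset_day=9, pathogen="Candida")
        t = truncate_record(rec, 14)
        assert t.contributed_days == 10
        assert t.event_probable and not t.event_definite
        assert not t.premature_removal

    def test_onset_on_landmark_day_counts(self):
        """The catheter is still in situ on the landmark day itself."""
        rec = make_record(dwell_days=14, crbsi_class="definite",
                          crbsi_onset_day=14, pathogen="CoNS")
        t = truncate_record(rec, 14)
        assert t.contributed_days == 14
        assert t.event_definite
        assert not t.premature_removal

    def test_unbounded_landmark_is_identity(self):
        rec = make_record(dwell_days=40, crbsi_class="definite",
                          crbsi_onset_day=30, pathogen="CoNS")
        t = truncate_record(rec, None)
        assert t.contributed_days == 40
        assert t.event_definite
        assert not t.premature_removal

    def test_bad_landmark_raises(self):
        with pytest.raises(LandmarkError):
            truncate_record(make_record(), 0)

    @settings(max_examples=100, derandomize=True)
    @given(dwell=st.integers(1, 60), onset_frac=st.floats(0, 1),
           landmark=st.integers(1, 30))
    def test_truncation_never_increases_days_or_events(self, dwell, onset_frac, landmark):
        onset = max(1, round(onset_frac * dwell))
        rec = make_record(dwell_days=dwell, crbsi_class="definite",
                          crbsi_onset_day=onset, pathogen="CoNS")
        t = truncate_record(rec, landmark)
        full = truncate_record(rec, None)
        assert t.contributed_days <= full.contributed_days
        assert t.event_definite <= full.event_definite
        assert t.contributed_days <= landmark


class TestApplyLandmark:
    @pytest.fixture
    def allocated(self):
        cohort = generate_cohort(GeneratorConfig(n_records=400, seed=8))
        table = allocate(cohort, block_size=4, seed=9)
        return cohort, table

    def test_control_arm_passes_through_unchanged(self, allocated):
        cohort, table = allocated
        truncated = {t.record_id: t for t in apply_landmark(cohort, table)}
        for rec in cohort:
            if table.arm_of(rec.record_id) == "Control":
                t = truncated[rec.record_id]
                assert t.contributed_days == rec.dwell_days
                assert (t.event_definite or t.event_probable) == (rec.crbsi_class != "none")
                assert not t.premature_removal

    def test_all_unbounded_map_equals_control_computation(self, allocated):
        cohort, table = allocated
        landmarks = {a: None for a in ARMS}
        truncated = apply_landmark(cohort, table, landmarks)
        by_id = {r.record_id: r for r in cohort}
        for t in truncated:
            assert t.contributed_days == by_id[t.record_id].dwell_days
            assert not t.premature_removal

    def test_landmark_postcondition_caps_days(self, allocated):
        cohort, table = allocated
        for t in apply_landmark(cohort, table):
            if t.arm == "D7rmv":
                assert t.contributed_days <= 7

    def test_missing_allocation_raises_with_record_id(self, allocated):
        cohort, table = allocated
        victim = cohort[0].record_id
        del table.assignments[victim]
        with pytest.raises(Exception, match=victim):
            apply_landmark(cohort, table)

    def test_nested_landmarks_are_monotone(self, allocated):
        """For D <= D': events(D) <= events(D') and days(D) <= days(D')."""
        cohort, table = allocated
        prev_events, prev_days = -1, -1
        for D in (7, 14, 21, None):
            landmarks = {a: D for a in ARMS}
            tr = apply_landmark(cohort, table, landmarks)
            events = sum(t.event_definite + t.event_probable for t in tr)
            days = sum(t.contributed_days for t in tr)
            assert events >= prev_events and days >= prev_days
            prev_events, prev_days = events, days

    def test_matches_brute_force_oracle(self, allocated):
        """Arm events and days re-derived by direct per-record iteration."""
        cohort, table = allocated
        truncated = apply_landmark(cohort, table)
        for arm, L in DEFAULT_LANDMARKS.items():
            Lval = float("inf") if L is None else L
            exp_days = exp_def = exp_dp = 0
            for rec in cohort:
                if table.arm_of(rec.record_id) != arm:
                    continue
                exp_days += min(rec.dwell_days, Lval)
                if rec.crbsi_class != "none" and rec.crbsi_onset_day <= Lval:
                    exp_dp += 1
                    exp_def += rec.crbsi_class == "definite"
            ep_d = summarize_endpoint(truncated, arm, "dCRBSI")
            ep_dp = summarize_endpoint(truncated, arm, "dpCRBSI")
            assert ep_d.cvc_days == exp_days
            assert ep_d.events == exp_def
            assert ep_dp.events == exp_dp

    def test_event_classes_are_conserved(self, allocated):
        """dpCRBSI events = definite events + probable events per arm."""
        cohort, table = allocated
        truncated = apply_landmark(cohort, table)
        for arm in ARMS:
            d = summarize_endpoint(truncated, arm, "dCRBSI").events
            dp = summarize_endpoint(truncated, arm, "dpCRBSI").events
            p = sum(t.event_probable for t in truncated if t.arm == arm)
            assert dp == d + p


class TestSummarizeEndpoint:
    def test_control_definite_rate(self):
        recs = [_tr("Control", days=16, definite=i < 50, record_id=f"T{i}")
                for i in range(746)]
        ep = summarize_endpoint(recs, "Control", "dCRBSI")
        assert ep.events == 50 and ep.n_cvc == 746
        assert round(ep.rate_percent, 1) == 6.7

    def test_control_combined_rate(self):
        recs = [_tr("Control", days=16, definite=i < 50, probable=50 <= i < 87,
                    record_id=f"T{i}") for i in range(746)]
        ep = summarize_endpoint(recs, "Control", "dpCRBSI")
        assert ep.events == 87
        assert round(ep.rate_percent, 1) == 11.7

    def test_incidence_density_arithmetic(self):
        # 25 events over 8065 CVC days -> 25/8065*1000 = 3.10 per 1000
        recs = [_tr("D14rmv", days=10, definite=i < 25, record_id=f"T{i}")
                for i in range(745)]
        recs.append(_tr("D14rmv", days=8065 - 7450, record_id="T745"))
        ep = summarize_endpoint(recs, "D14rmv", "dCRBSI")
        assert ep.cvc_days == 8065
        assert ep.incidence_per_1000 == pytest.approx(25 / 8065 * 1000)
        assert round(ep.incidence_per_1000, 2) == 3.10

    def test_empty_arm_and_bad_definition_raise(self):
        with pytest.raises(LandmarkError):
            summarize_endpoint([], "Control", "dCRBSI")
        with pytest.raises(LandmarkError):
            summarize_endpoint([_tr()], "D14rmv", "xCRBSI")


class TestPrematureRemoval:
    def test_extremes(self):
        none = [_tr(premature=False, record_id=f"A{i}") for i in range(5)]
        all_ = [_tr(premature=True, record_id=f"B{i}") for i in range(5)]
        assert premature_removal_fraction(none, "D14rmv") == 0.0
        assert premature_removal_fraction(all_, "D14rmv") == 1.0

    def test_printed_fraction(self):
        recs = [_tr(premature=i < 391, record_id=f"T{i}") for i in range(746)]
        frac = premature_removal_fraction(recs, "D14rmv")
        assert round(frac * 100, 1) == 52.4


def test_dominance_on_large_random_cohort():
    """Truncation dominance at scale: no arm/landmark combination ever gains
    days or events relative to looser truncation (10^4 random records)."""
    cohort = generate_cohort(GeneratorConfig(n_records=10_000, seed=77))
    dwell = np.array([r.dwell_days for r in cohort])
    onset = np.array([r.crbsi_onset_day or 10**9 for r in cohort])
    prev_e, prev_d = -1, -1
    for D in (7, 14, 21, 10**9):
        days = np.minimum(dwell, D)
        ev = (onset <= D)
        assert ev.sum() >= prev_e and days.sum() >= prev_d
        assert np.all(days <= dwell)
        prev_e, prev_d = ev.sum(), days.sum()
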