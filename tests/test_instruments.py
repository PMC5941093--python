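"""Scoring rules of the two screeners and the derived risk outcomes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from askone.instruments import (
    ASQ_DOMAINS,
    AsqCutoffs,
    InputValidationError,
    MChatKey,
    administer_interspersed,
    administer_two_stage,
    derive_outcomes,
    score_asq,
    score_mchat_initial,
    tier_for_count,
)


def _responses(n_risk: int) -> list[int]:
    """n_risk 'yes' answers under the risk-if-yes key."""
    return [1] * n_risk + [0] * (20 - n_risk)


def _flat_cutoffs(refer=20.0, monitor=40.0) -> AsqCutoffs:
    return AsqCutoffs({d: (refer, monitor) for d in ASQ_DOMAINS})


def _asq_items(value: int) -> dict:
    return {d: (value,) * 6 for d in ASQ_DOMAINS}


class TestInitialScoring:
    @pytest.mark.parametrize(
        "count,tier",
        [(0, "low"), (2, "low"), (3, "medium"), (5, "medium"), (7, "medium"),
         (8, "high"), (20, "high")],
    )
    def test_tier_boundaries(self, risk_if_yes_key, count, tier):
        assert score_mchat_initial(_responses(count), risk_if_yes_key) == (count, tier)

    def test_tier_partition_exhaustive_and_exclusive(self):
        tiers = [tier_for_count(c) for c in range(21)]
        assert tiers == ["low"] * 3 + ["medium"] * 5 + ["high"] * 13

    def test_key_direction_respected(self, default_key):
        # all-"no" answers: risk on every risk-if-no item (17 under default key)
        count, tier = score_mchat_initial([0] * 20, default_key)
        assert (count, tier) == (17, "high")
        count, _ = score_mchat_initial([1] * 20, default_key)
        assert count == 3  # the three yes-indicates-risk items

    @pytest.mark.parametrize("bad", [[1] * 19, [1] * 21])
    def test_wrong_item_count_rejected(self, risk_if_yes_key, bad):
        with pytest.raises(InputValidationError, match="20"):
            score_mchat_initial(bad, risk_if_yes_key)

    def test_non_binary_response_names_item(self, risk_if_yes_key):
        resp = _responses(3)
        resp[6] = 2
        with pytest.raises(InputValidationError, match="item 7"):
            score_mchat_initial(resp, risk_if_yes_key)


class TestInterspersedAdministration:
    def test_no_flagged_items(self, risk_if_yes_key):
        rec = administer_interspersed(_responses(0), risk_if_yes_key, {})
        assert rec.final_score == 0 and not rec.at_risk_rf
        assert rec.followup_confirmed == {}

    def test_five_flagged_one_confirmed_is_low_risk(self, risk_if_yes_key):
        follow = {i: (i == 0) for i in range(5)}
        rec = administer_interspersed(_responses(5), risk_if_yes_key, follow)
        assert rec.tier == "medium"
        assert rec.final_score == 1 and not rec.at_risk_rf

    def test_low_tier_can_confirm_at_risk(self, risk_if_yes_key):
        # 2 flagged -> tier low, yet both confirmations make the child at risk
        rec = administer_interspersed(_responses(2), risk_if_yes_key, {0: True, 1: True})
        assert rec.tier == "low" and rec.at_risk_rf

    def test_high_tier_receives_followup(self, risk_if_yes_key):
        rec = administer_interspersed(
            _responses(9), risk_if_yes_key, dict.fromkeys(range(9), False)
        )
        assert rec.tier == "high" and len(rec.followup_confirmed) == 9
        assert rec.final_score == 0

    def test_missing_followup_names_item(self, risk_if_yes_key):
        with pytest.raises(InputValidationError, match="item 3"):
            administer_interspersed(_responses(3), risk_if_yes_key, {0: True, 1: True})

    @given(
        flags=st.lists(st.booleans(), min_size=20, max_size=20),
        confirms=st.lists(st.booleans(), min_size=20, max_size=20),
    )
    @settings(max_examples=200, deadline=None)
    def test_final_never_exceeds_initial_and_confirmation_monotone(
        self, flags, confirms
    ):
        key = MChatKey(tuple([True] * 20))
        resp = [int(f) for f in flags]
        follow = {i: confirms[i] for i in range(20)}
        rec = administer_interspersed(resp, key, follow)
        assert rec.final_score <= rec.initial_count
        # confirming one more flagged item never decreases the final score
        for i, flagged in enumerate(flags):
            if flagged and not confirms[i]:
                more = dict(follow)
                more[i] = True
                rec2 = administer_interspersed(resp, key, more)
                assert rec2.final_score == rec.final_score + 1


class TestTwoStageAgreement:
    @given(
        flags=st.lists(st.booleans(), min_size=20, max_size=20),
        confirms=st.lists(st.booleans(), min_size=20, max_size=20),
    )
    @settings(max_examples=300, deadline=None)
    def test_medium_agrees_low_only_adds(self, flags, confirms):
        key = MChatKey(tuple([True] * 20))
        resp = [int(f) for f in flags]
        follow = {i: confirms[i] for i in range(20)}
        inter = administer_interspersed(resp, key, follow)
        two = administer_two_stage(resp, key, follow)
        if inter.tier == "medium":
            assert inter.at_risk_rf == two.at_risk
            assert inter.final_score == two.final_score
        elif inter.tier == "low":
            # interspersed can only add at-risk classifications here
            assert not two.at_risk

    def test_interspersed_catches_low_tier_children(self, risk_if_yes_key):
        # two flagged, both confirmed: missed by two-stage, caught interspersed
        follow = {0: True, 1: True}
        assert not administer_two_stage(_responses(2), risk_if_yes_key, follow).at_risk
        assert administer_interspersed(_responses(2), risk_if_yes_key, follow).at_risk_rf


class TestAsqScoring:
    def test_all_yes_is_ok_everywhere(self):
        rec = score_asq(_asq_items(10), _flat_cutoffs())
        assert all(c == "ok" for c in rec.domain_class.values())
        assert not rec.global_risk
        assert all(s == 60 for s in rec.domain_sums.values())

    def test_floor_domain_triggers_refer_and_global_risk(self):
        items = _asq_items(10)
        items["communication"] = (0,) * 6
        rec = score_asq(items, _flat_cutoffs(refer=20.0))
        assert rec.domain_class["communication"] == "refer"
        assert rec.global_risk

    def test_monitor_band(self):
        items = _asq_items(10)
        items["fine_motor"] = (5,) * 6  # sum 30, between refer 20 and monitor 40
        rec = score_asq(items, _flat_cutoffs(20.0, 40.0))
        assert rec.domain_class["fine_motor"] == "monitor"
        assert not rec.global_risk

    def test_invalid_item_score_names_location(self):
        items = _asq_items(10)
        items["gross_motor"] = (10, 10, 7, 10, 10, 10)
        with pytest.raises(InputValidationError, match="gross_motor, item 3"):
            score_asq(items, _flat_cutoffs())

    def test_cutoff_invariants_enforced(self):
        with pytest.raises(InputValidationError):
            AsqCutoffs({d: (40.0, 20.0) for d in ASQ_DOMAINS})


class TestOutcomes:
    def test_medium_tier_unconfirmed(self, risk_if_yes_key):
        mchat = administer_interspersed(
            _responses(5), risk_if_yes_key, {i: (i == 0) for i in range(5)}
        )
        asq = score_asq(_asq_items(10), _flat_cutoffs())
        out = derive_outcomes(mchat, asq)
        assert out["MCHAT_R"] == 1 and out["MCHAT_RF"] == 0

    def test_personal_social_or_communication(self, risk_if_yes_key):
        mchat = administer_interspersed(_responses(0), risk_if_yes_key, {})
        items = _asq_items(10)
        items["personal_social"] = (0,) * 6
        out = derive_outcomes(mchat, score_asq(items, _flat_cutoffs()))
        assert out["ASQ_PS"] == 1 and out["ASQ_COMM"] == 0
        assert out["ASQ_PS_OR_COMM"] == 1

    def test_all_clear(self, risk_if_yes_key):
        mchat = administer_interspersed(_responses(0), risk_if_yes_key, {})
        out = derive_outcomes(mchat, score_asq(_asq_items(10), _flat_cutoffs()))
        assert set(out.values()) == {0}
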