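"""Assignment mechanics: membership, overrides, confidence, validity."""

import numpy as np
import pytest

from torpormix import MetabolicDataset, PosteriorSamples, PriorSpec
from torpormix.assign import (
    build_assignment_table,
    confidence,
    membership_probabilities,
    preassign,
    validity,
)
from torpormix.engine import EUTHERMY, FREE, TNZ, TORPOR


def _spec():
    return PriorSpec(stage="step23", m_tnz=1.0, tlc_low=29.0, ta_max=38.0,
                     tlc_fixed=30.0, tlc_l95=29.5)


def _posterior(state_draws, below_index, clamped, draws=None, ndraw=None):
    """Hand-built retained-draw container for mechanics tests."""
    state_draws = np.asarray(state_draws, dtype=np.int8)
    chains, nd, _ = state_draws.shape
    ndraw = nd if ndraw is None else ndraw
    base = {
        "t_be": np.full((chains, ndraw), 38.0),
        "t_bt": np.full((chains, ndraw), 2.0),
        "tmr": np.full((chains, ndraw), 0.05),
        "m_r": np.full((chains, ndraw), 0.4),
        "sd_tnz": np.full((chains, ndraw), 0.05),
        "sd_r": np.full((chains, ndraw), 0.07),
        "sd_c": np.full((chains, ndraw), 0.03),
        "p_t": np.full((chains, ndraw), 0.5),
        "p_e": np.full((chains, ndraw), 0.5),
    }
    if draws:
        base.update(draws)
    return PosteriorSamples(
        draws=base, state_draws=state_draws,
        below_index=np.asarray(below_index), clamped=np.asarray(clamped),
        rhat={}, converged=True, messages=[], m_mean=1.0, spec=_spec(),
    )


class TestMembership:
    def test_frequency_definition(self):
        # 1,900 of 2,000 retained draws in torpor -> membership 0.95
        sd = np.full((1, 2000, 1), TORPOR, dtype=np.int8)
        sd[0, :100, 0] = EUTHERMY
        post = _posterior(sd, [0], [FREE])
        probs = membership_probabilities(post)
        assert probs[0, 1] == pytest.approx(0.95)
        assert probs.sum(axis=1) == pytest.approx(1.0)


class TestPreassign:
    def _data(self):
        #      plateau, euthermic point, torpid point, outlier high, outlier low
        ta = np.array([33.0, 20.0, 20.0, 25.0, 25.0])
        m = np.array([1.0, 2.25, 0.23, 3.0, 0.01])
        return MetabolicDataset(ta, m)

    def test_probabilistic_states_and_overrides(self):
        data = self._data()
        sd = np.zeros((1, 200, 4), dtype=np.int8)
        sd[:, :, 0] = EUTHERMY
        sd[:, :, 1] = TORPOR
        sd[:, :, 2] = EUTHERMY  # sampler undecided; override should flip both
        sd[:, :, 3] = EUTHERMY
        post = _posterior(sd, [1, 2, 3, 4], [FREE] * 4)
        pre = preassign(data, post, tlc=30.0, m_tnz=1.0, m_mean=1.0)
        assert pre.state[0] == TNZ and pre.membership[0] == 1.0
        assert pre.state[1] == EUTHERMY and pre.state[2] == TORPOR
        # record above the predicted euthermic curve is clamped to euthermy,
        # record below the predicted torpor curve is clamped to torpor
        assert pre.state[3] == EUTHERMY and pre.clamped[3] == EUTHERMY
        assert pre.state[4] == TORPOR and pre.clamped[4] == TORPOR
        assert pre.membership[3] == 1.0 and pre.membership[4] == 1.0
        assert pre.overrides_applied

    def test_no_override_without_any_torpor(self):
        data = self._data()
        sd = np.full((1, 200, 4), EUTHERMY, dtype=np.int8)
        post = _posterior(sd, [1, 2, 3, 4], [FREE] * 4)
        pre = preassign(data, post, tlc=30.0, m_tnz=1.0, m_mean=1.0)
        assert not pre.overrides_applied
        assert (pre.clamped[1:] == FREE).all()
        assert (pre.state[1:] == EUTHERMY).all()

    def test_empty_below_set_yields_plateau_only(self):
        data = MetabolicDataset(np.array([33.0, 35.0]), np.array([1.0, 1.1]))
        sd = np.zeros((1, 10, 0), dtype=np.int8)
        post = _posterior(sd, [], [])
        pre = preassign(data, post, tlc=30.0, m_tnz=1.0, m_mean=1.0)
        assert (pre.state == TNZ).all() and (pre.membership == 1.0).all()


class TestConfidence:
    def test_product_rule(self):
        tlc_draws = np.concatenate([np.zeros(90), np.full(10, 50.0)])
        # side probability for a below-T_lc state at ta=25: P(T_lc > 25) = 0.1?
        # choose draws so that P(T_lc > ta) = 0.9
        tlc_draws = np.concatenate([np.full(90, 40.0), np.zeros(10)])
        c = confidence(np.array([25.0]), np.array([EUTHERMY]),
                       np.array([0.9]), tlc_draws)
        assert c[0] == pytest.approx(0.81)

    def test_certain_plateau(self):
        tlc_draws = np.full(100, 20.0)
        c = confidence(np.array([25.0]), np.array([TNZ]), np.array([1.0]),
                       tlc_draws)
        assert c[0] == pytest.approx(1.0)

    def test_median_record_caps_at_half_membership(self):
        tlc_draws = np.linspace(28.0, 32.0, 2001)
        ta = np.array([30.0])  # exactly the posterior median of T_lc
        for state in (TNZ, EUTHERMY):
            c = confidence(ta, np.array([state]), np.array([1.0]), tlc_draws)
            assert c[0] <= 0.5 + 1e-9

    def test_confidence_rises_away_from_tlc(self):
        tlc_draws = np.random.default_rng(0).normal(30, 0.5, 4000)
        tas = np.array([29.9, 29.5, 28.8])
        c = confidence(tas, np.full(3, EUTHERMY), np.ones(3), tlc_draws)
        assert c[0] < c[1] < c[2]


class TestValidity:
    def test_threshold_cases(self):
        assert validity(1.0, 6000) is True
        assert validity(0.5, 6000) is False
        # exactly at the threshold the one-sided test can never reject
        assert validity(0.8, 6000) is False

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        confs = rng.uniform(0.5, 1.0, 200)
        counts = [
            sum(validity(c, 6000, threshold=thr) for c in confs)
            for thr in (0.7, 0.8, 0.9)
        ]
        assert counts[0] >= counts[1] >= counts[2]

    def test_needs_draws(self):
        with pytest.raises(ValueError):
            validity(0.9, 0)


class TestAssignmentTable:
    def test_clamped_membership_and_partition(self):
        ta = np.array([33.0, 20.0, 10.0])
        m = np.array([1.0, 2.2, 0.2])
        data = MetabolicDataset(ta, m)
        sd = np.zeros((1, 500, 2), dtype=np.int8)
        sd[:, :, 0] = EUTHERMY
        sd[:, :, 1] = TORPOR
        clamped = np.array([EUTHERMY, TORPOR])
        post = _posterior(sd, [1, 2], clamped)
        from torpormix.assign import Preassignment

        pre = Preassignment(
            state=np.array([TNZ, EUTHERMY, TORPOR]),
            membership=np.ones(3),
            auto=np.array([True, True, True]),
            clamped=np.array([TNZ, EUTHERMY, TORPOR]),
            overrides_applied=True,
        )
        tlc_draws = np.full(500, 30.0)
        table = build_assignment_table(
            data, post, pre, 30.0, 1.0, 1.0, tlc_draws
        )
        assert list(table["state"]) == ["tnz", "euthermy", "torpor"]
        assert (table["membership"] == 1.0).all()
        assert set(table.columns) >= {
            "ta", "m", "state", "membership", "auto", "confidence", "valid",
            "pred_median", "pred_lo95", "pred_hi95",
        }
        # predicted euthermic value at ta=20 on the frozen draws: 2.25
        assert table["pred_median"][1] == pytest.approx(2.25)
        assert table["pred_lo95"][1] <= table["pred_median"][1] <= table["pred_hi95"][1]
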