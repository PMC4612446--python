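"""Predictive validity, NLL, log Bayes factors, z-standardisation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from scrdcm import (SessionDesign, TrialEvent, CS_PLUS, CS_MINUS,
                    exclude_reinforced, z_standardise, cell_means,
                    predictive_validity, log_bayes_factor, ComparisonResult)
from scrdcm.inversion import SaEstimates


def _estimates(amps, cs_types, reinforced=None, pid="sub-00"):
    n = len(amps)
    reinforced = reinforced or [False] * n
    df = pd.DataFrame({
        "trial": np.arange(n), "cs_type": cs_types,
        "reinforced": [int(r) for r in reinforced],
        "cs_onset": 10.0 + 15.0 * np.arange(n),
        "amplitude": amps, "onset": 11.0 + 15.0 * np.arange(n),
        "duration": 0.3, "evoked_amplitude": 0.0, "objective": -1.0,
        "converged": 1,
    })
    return SaEstimates(df, participant_id=pid)


def _design_for(est):
    trials = [TrialEvent(row.cs_onset, row.cs_type, bool(row.reinforced))
              for row in est.df.itertuples()]
    return SessionDesign(trials)


def _cells(rng, n_p, delta=0.5):
    rows = []
    for p in range(n_p):
        base = rng.normal(0.5, 0.2)
        rows.append({"participant": f"s{p}", "cs_type": CS_PLUS,
                     "sa": base + delta + rng.normal(0, 0.1)})
        rows.append({"participant": f"s{p}", "cs_type": CS_MINUS,
                     "sa": base + rng.normal(0, 0.1)})
    return pd.DataFrame(rows)


def _oracle_fit(cells):
    """Independent oracle: explicit design matrix, normal-equations solve."""
    participants = sorted(set(cells["participant"]))
    y = cells["cs_type"].map({CS_PLUS: 1.0, CS_MINUS: 0.0}).to_numpy()
    dummies = (cells["participant"].to_numpy()[:, None] ==
               np.asarray(participants)[None, :]).astype(float)
    X = np.column_stack([cells["sa"].to_numpy(), dummies])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    n, k = X.shape
    cov = np.linalg.inv(X.T @ X) * rss / (n - k)
    t = beta[0] / math.sqrt(cov[0, 0])
    return rss, t, n


class TestExcludeReinforced:
    def test_counts(self):
        amps = list(np.linspace(0.1, 1.0, 40))
        types = [CS_PLUS] * 20 + [CS_MINUS] * 20
        reinf = [True] * 10 + [False] * 30
        est = _estimates(amps, types, reinf)
        out = exclude_reinforced(est, _design_for(est))
        assert len(out.df) == 30
        assert not out.df["reinforced"].astype(bool).any()

    def test_identity_without_reinforcement(self):
        est = _estimates([0.1, 0.2], [CS_PLUS, CS_MINUS])
        out = exclude_reinforced(est, _design_for(est))
        pd.testing.assert_frame_equal(out.df, est.df)

    def test_all_cs_plus_reinforced_leaves_only_cs_minus(self):
        est = _estimates([0.5, 0.2, 0.6, 0.3],
                         [CS_PLUS, CS_MINUS, CS_PLUS, CS_MINUS],
                         [True, False, True, False])
        out = exclude_reinforced(est, _design_for(est))
        assert set(out.df["cs_type"]) == {CS_MINUS}


class TestZStandardise:
    def test_two_trial_worked_example(self):
        est = _estimates([1.0, 3.0], [CS_PLUS, CS_MINUS])
        out = z_standardise(est)
        np.testing.assert_allclose(out.sa, [-1 / math.sqrt(2), 1 / math.sqrt(2)])

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_mean_zero_sd_one(self, seed):
        rng = np.random.default_rng(seed)
        amps = rng.lognormal(0, 1, size=12)
        est = _estimates(list(amps), [CS_PLUS, CS_MINUS] * 6)
        out = z_standardise(est)
        assert out.sa.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.sa.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_constant_amplitudes_rejected(self):
        est = _estimates([0.4, 0.4, 0.4], [CS_PLUS, CS_MINUS, CS_PLUS])
        with pytest.raises(ValueError, match="zero variance"):
            z_standardise(est)


class TestPredictiveValidity:
    def test_no_signal_gives_zero_t(self):
        rows = []
        for p in range(5):
            v = 0.3 + 0.1 * p
            rows += [{"participant": f"s{p}", "cs_type": CS_PLUS, "sa": v},
                     {"participant": f"s{p}", "cs_type": CS_MINUS, "sa": v}]
        res = predictive_validity(pd.DataFrame(rows))
        assert res.t == 0.0

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        cells = _cells(rng, 5)
        res = predictive_validity(cells)
        rss, t, n = _oracle_fit(cells)
        assert res.rss == pytest.approx(rss, abs=1e-9)
        assert res.t == pytest.approx(t, abs=1e-9)
        assert res.n == n
        assert res.df == n - 6
        assert res.nll == pytest.approx(n * math.log(rss / n), abs=1e-12)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(5)
        cells = _cells(rng, 8)
        res = predictive_validity(cells)
        participants = sorted(set(cells["participant"]))
        y = cells["cs_type"].map({CS_PLUS: 1.0, CS_MINUS: 0.0})
        dummies = pd.get_dummies(cells["participant"], dtype=float)
        X = np.column_stack([cells["sa"], dummies[participants]])
        fit = sm.OLS(y.to_numpy(), X).fit()
        assert res.t == pytest.approx(float(fit.tvalues[0]), abs=1e-9)
        assert res.rss == pytest.approx(float(fit.ssr), abs=1e-9)

    def test_equals_paired_t_test(self):
        rng = np.random.default_rng(1)
        cells = _cells(rng, 12)
        res = predictive_validity(cells)
        plus = cells[cells.cs_type == CS_PLUS].set_index("participant")["sa"]
        minus = cells[cells.cs_type == CS_MINUS].set_index("participant")["sa"]
        t_paired = stats.ttest_rel(plus.sort_index(), minus.sort_index())
        assert res.t == pytest.approx(float(t_paired.statistic), abs=1e-9)
        assert res.df == len(plus) - 1

    def test_scale_invariance_of_nll_and_t(self):
        rng = np.random.default_rng(2)
        cells = _cells(rng, 10)
        res = predictive_validity(cells)
        scaled = cells.assign(sa=cells["sa"] * 1000.0)
        res_s = predictive_validity(scaled)
        assert abs(res_s.nll - res.nll) < 1e-9
        assert abs(res_s.t - res.t) < 1e-9

    def test_shift_invariance_via_participant_constants(self):
        rng = np.random.default_rng(3)
        cells = _cells(rng, 10)
        res = predictive_validity(cells)
        shifted = cells.assign(sa=cells["sa"] + 123.4)
        res_s = predictive_validity(shifted)
        assert abs(res_s.nll - res.nll) < 1e-8
        assert abs(res_s.t - res.t) < 1e-9

    def test_label_recoding_cancels_in_lbf(self):
        rng = np.random.default_rng(4)
        cells_a, cells_b = _cells(rng, 8), _cells(rng, 8)
        lbf = log_bayes_factor(predictive_validity(cells_a),
                               predictive_validity(cells_b))
        coding = {CS_PLUS: 2.0, CS_MINUS: -1.0}
        lbf_re = log_bayes_factor(predictive_validity(cells_a, coding=coding),
                                  predictive_validity(cells_b, coding=coding))
        assert lbf_re == pytest.approx(lbf, abs=1e-9)

    def test_missing_cell_participant_dropped(self, caplog):
        rng = np.random.default_rng(6)
        cells = _cells(rng, 5).drop(index=0)  # s0 loses its CS+ cell
        res = predictive_validity(cells)
        assert res.n == 8

    def test_too_few_participants_rejected(self):
        rng = np.random.default_rng(7)
        with pytest.raises(ValueError, match=">= 3"):
            predictive_validity(_cells(rng, 2))


class TestLogBayesFactor:
    def test_identical_models_give_zero(self):
        r = ComparisonResult(nll=-10.0, rss=1.0, n=40, t=2.0, df=19)
        assert log_bayes_factor(r, r) == 0.0

    def test_halved_rss_formula(self):
        n = 40
        ref = ComparisonResult(nll=n * math.log(2.0 / n), rss=2.0, n=n,
                               t=0.0, df=19)
        res = ComparisonResult(nll=n * math.log(1.0 / n), rss=1.0, n=n,
                               t=0.0, df=19)
        assert log_bayes_factor(res, ref) == pytest.approx(40 * math.log(0.5))

    def test_antisymmetric(self):
        a = ComparisonResult(nll=-5.0, rss=1.0, n=20, t=1.0, df=9)
        b = ComparisonResult(nll=-8.0, rss=0.8, n=20, t=2.0, df=9)
        assert log_bayes_factor(a, b) == -log_bayes_factor(b, a)

    def test_mismatched_n_rejected(self):
        a = ComparisonResult(nll=-5.0, rss=1.0, n=20, t=1.0, df=9)
        b = ComparisonResult(nll=-8.0, rss=0.8, n=22, t=2.0, df=10)
        with pytest.raises(ValueError, match="mismatched"):
            log_bayes_factor(a, b)

    def test_nll_strictly_decreases_with_rss(self):
        n = 30
        nlls = [n * math.log(r / n) for r in (2.0, 1.5, 1.0, 0.5)]
        assert all(b < a for a, b in zip(nlls, nlls[1:]))

    def test_decisiveness_bound(self):
        assert 1.0 / math.exp(3.0) <= 0.05
        r = ComparisonResult(nll=-10.0, rss=1.0, n=40, t=2.0, df=19, lbf=-3.5)
        assert r.decisive
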