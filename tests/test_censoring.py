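"""Left-censored panel imputation, substitution baselines, and evaluation."""

import numpy as np
import pandas as pd
import pytest

from geoexpose.censoring import (
    artificial_censor,
    em_bootstrap_impute,
    evaluate_imputation,
    substitute,
)


def make_complete_panel(rng, n=60, corr=0.95, mu=1.0, sigma=0.6):
    z = rng.multivariate_normal([0, 0], [[1, corr], [corr, 1]], size=n)
    dates = pd.to_datetime("2003-01-01") + pd.to_timedelta(
        rng.integers(0, 3650, n), unit="D")
    rows = []
    for j, s in enumerate(["S0", "S1"]):
        rows.append(pd.DataFrame({
            "unit_id": [f"U{i % 10}" for i in range(n)],
            "date": dates.strftime("%Y-%m-%d"),
            "substance": s,
            "value": np.exp(mu + sigma * z[:, j]),
            "censored": False,
            "dl": 0.01,
        }))
    return pd.concat(rows, ignore_index=True)


class TestSubstitute:
    @pytest.mark.parametrize("rule,dl,expected", [
        ("half_dl", 0.01, 0.005),
        ("dl_over_sqrt2", 3.0, 3.0 / np.sqrt(2)),
        ("zero", 3.0, 0.0),
    ])
    def test_rules(self, tiny_panel, rule, dl, expected):
        panel = tiny_panel.copy()
        panel["dl"] = dl
        panel.loc[panel["censored"], "value"] = dl
        out = substitute(panel, rule)
        cens = tiny_panel["censored"].to_numpy()
        assert np.allclose(out.loc[cens, "value"], expected)
        assert np.allclose(out.loc[~cens, "value"], panel.loc[~cens, "value"])

    def test_unknown_rule(self, tiny_panel):
        with pytest.raises(ValueError, match="rule"):
            substitute(tiny_panel, "dl_over_pi")


class TestArtificialCensor:
    def test_threshold_below_min_censors_nothing(self, rng):
        panel = make_complete_panel(rng)
        out, frac = artificial_censor(panel, panel["value"].min() / 2)
        assert frac == 0.0 and not out["censored"].any()

    def test_threshold_above_max_errors(self, rng):
        panel = make_complete_panel(rng)
        with pytest.raises(ValueError, match="100%"):
            artificial_censor(panel, panel["value"].max() * 2)

    def test_realized_fraction_matches_quantile(self, rng):
        panel = make_complete_panel(rng, n=2500)
        thr = float(panel["value"].quantile(0.82))
        out, frac = artificial_censor(panel, thr)
        assert abs(frac - 0.82) < 0.03
        cens = out["censored"]
        assert np.allclose(out.loc[cens, "value"], thr)
        assert (out.loc[cens, "dl"] == thr).all()


class TestEvaluate:
    def test_perfect_estimate(self, rng):
        panel = make_complete_panel(rng)
        cens, _ = artificial_censor(panel, float(panel["value"].quantile(0.5)))
        mask = cens["censored"].to_numpy()
        sc = evaluate_imputation(panel, panel, censored_mask=mask)
        assert sc["AME"] == 0.0 and sc["RMSE"] == 0.0

    def test_hand_arithmetic(self):
        truth = pd.DataFrame({"value": [1.0, 1.0]})
        est_pm1 = pd.DataFrame({"value": [2.0, 0.0]})   # errors {+1, -1}
        sc = evaluate_imputation(truth, est_pm1, censored_mask=[True, True])
        assert sc["AME"] == 1.0 and sc["RMSE"] == 1.0
        est_02 = pd.DataFrame({"value": [1.0, 3.0]})    # errors {0, 2}
        sc = evaluate_imputation(truth, est_02, censored_mask=[True, True])
        assert sc["AME"] == 1.0 and sc["RMSE"] == pytest.approx(np.sqrt(2))

    def test_no_censored_cells_rejected(self):
        truth = pd.DataFrame({"value": [1.0]})
        with pytest.raises(ValueError):
            evaluate_imputation(truth, truth, censored_mask=[False])


class TestEmBootstrap:
    def test_no_censoring_returns_input(self, rng):
        panel = make_complete_panel(rng, n=40)
        out = em_bootstrap_impute(panel, m=3, seed=0)
        for p in out.panels:
            assert np.allclose(p["value"], panel["value"])

    def test_m_completed_panels(self, rng):
        panel = make_complete_panel(rng, n=80)
        cens, _ = artificial_censor(panel, float(panel["value"].quantile(0.4)),
                                    substances=["S0"])
        out = em_bootstrap_impute(cens, m=8, seed=1)
        assert out.m == 8
        for p in out.panels:
            assert not p["censored"].any()

    def test_imputed_values_in_zero_dl_interval(self, rng):
        panel = make_complete_panel(rng, n=120)
        thr = float(panel["value"].quantile(0.6))
        cens, _ = artificial_censor(panel, thr, substances=["S0"])
        out = em_bootstrap_impute(cens, m=4, seed=2)
        mask = cens["censored"].to_numpy()
        for p in out.panels:
            imp = p.loc[mask, "value"]
            assert (imp > 0).all() and (imp <= thr + 1e-12).all()

    def test_uncensored_cells_identical_across_imputations(self, rng):
        panel = make_complete_panel(rng, n=100)
        cens, _ = artificial_censor(panel, float(panel["value"].quantile(0.5)),
                                    substances=["S0"])
        out = em_bootstrap_impute(cens, m=5, seed=3)
        mask = ~cens["censored"].to_numpy()
        ref = out.panels[0].loc[mask, "value"].to_numpy()
        for p in out.panels[1:]:
            assert np.array_equal(p.loc[mask, "value"].to_numpy(), ref)

    def test_determinism_under_seed(self, rng):
        panel = make_complete_panel(rng, n=60)
        cens, _ = artificial_censor(panel, float(panel["value"].quantile(0.5)),
                                    substances=["S0"])
        a = em_bootstrap_impute(cens, m=3, seed=9)
        b = em_bootstrap_impute(cens, m=3, seed=9)
        for pa, pb in zip(a.panels, b.panels):
            assert np.array_equal(pa["value"].to_numpy(), pb["value"].to_numpy())

    def test_near_perfect_correlation_tracks_partner(self, rng):
        """With latent correlation ~1 the imputation concentrates at the
        conditional regression prediction min(z-hat, DL)."""
        panel = make_complete_panel(rng, n=200, corr=0.999, sigma=0.8)
        thr = float(panel.loc[panel.substance == "S0", "value"].quantile(0.7))
        cens, _ = artificial_censor(panel, thr, substances=["S0"])
        out = em_bootstrap_impute(cens, m=8, seed=4)
        mask = cens["censored"].to_numpy()
        truth = panel.loc[mask, "value"].to_numpy()
        pooled = out.pooled().loc[mask, "value"].to_numpy()
        # log-scale error should be small: partner pins the value down
        err = np.abs(np.log(pooled) - np.log(truth))
        assert np.median(err) < 0.15

    def test_all_censored_single_substance_aborts(self):
        panel = pd.DataFrame({
            "unit_id": ["U1"] * 4, "date": ["2001-01-01"] * 4,
            "substance": ["S0"] * 4, "value": [0.5] * 4,
            "censored": [True] * 4, "dl": [0.5] * 4,
        })
        with pytest.raises(ValueError):
            em_bootstrap_impute(panel, m=3, seed=0)
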