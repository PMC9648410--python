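"""Association statistics against hand values and enumeration oracles."""

from itertools import combinations, product

import numpy as np
import pandas as pd
import pytest

from repstress.datasets import repstress_signature
from repstress.scoring import score_cohort
from repstress.simulate import GeneratorConfig, simulate_cohort
from repstress.stats import (
    drug_contrast,
    group_compare,
    km_logrank,
    paired_dynamics,
    spearman_panel,
)


def mw_exact_oracle(a, b):
    """Two-sided exact Mann–Whitney p by exhaustive relabelling."""
    pool = np.concatenate([a, b])
    m = len(a)

    def u_stat(idx):
        sel = set(idx)
        aa = pool[list(idx)]
        bb = pool[[i for i in range(len(pool)) if i not in sel]]
        return sum((x > y) + 0.5 * (x == y) for x in aa for y in bb)

    u_obs = u_stat(range(m))
    us = np.array([u_stat(idx) for idx in combinations(range(len(pool)), m)])
    return min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))


def wsr_exact_oracle(diffs):
    """Two-sided exact signed-rank p by enumerating all sign assignments."""
    d = np.asarray([x for x in diffs if x != 0], float)
    from scipy.stats import rankdata

    r = rankdata(np.abs(d))
    w_obs = r[d > 0].sum()
    mean_w = r.sum() / 2
    ws = np.array([r[np.array(s, bool)].sum()
                   for s in product([0, 1], repeat=len(d))])
    return np.mean(np.abs(ws - mean_w) >= abs(w_obs - mean_w) - 1e-12)


class TestSpearmanPanel:
    def test_identity_and_reversal(self):
        rng = np.random.default_rng(3)
        t = pd.Series(rng.normal(size=12), index=[f"s{i}" for i in range(12)])
        feats = pd.DataFrame({"same": t, "rev": -t, "noise": rng.normal(size=12)},
                             index=t.index)
        out, order = spearman_panel(feats, t)
        assert out.loc["same", "rho"] == pytest.approx(1.0)
        assert out.loc["rev", "rho"] == pytest.approx(-1.0)
        assert set(order) == set(feats.columns)

    def test_rank_then_pearson_oracle(self):
        feats = pd.DataFrame({"f": [1.0, 3.0, 2.0, 4.0]}, index=list("abcd"))
        t = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        out, _ = spearman_panel(feats, t)
        assert out.loc["f", "rho"] == pytest.approx(0.8)

    def test_monotone_transform_invariance_and_constant_feature(self):
        rng = np.random.default_rng(4)
        t = pd.Series(rng.normal(size=15), index=[f"s{i}" for i in range(15)])
        f = pd.Series(rng.normal(size=15), index=t.index)
        a, _ = spearman_panel(pd.DataFrame({"f": f}), t)
        b, _ = spearman_panel(pd.DataFrame({"f": np.exp(f)}), t)
        assert a.loc["f", "rho"] == pytest.approx(b.loc["f", "rho"])
        c, _ = spearman_panel(pd.DataFrame({"k": np.ones(15), "f": f}, index=t.index), t)
        assert np.isnan(c.loc["k", "rho"])


class TestDrugContrast:
    def make(self, hi, lo, drug="D1"):
        act = pd.DataFrame({drug: hi + lo},
                           index=[f"h{i}" for i in range(len(hi))] +
                                 [f"l{i}" for i in range(len(lo))])
        groups = pd.Series(["high"] * len(hi) + ["low"] * len(lo), index=act.index)
        return act, groups

    def test_enumerated_exact_p(self):
        act, groups = self.make([1.0, 2.0], [3.0, 4.0])
        out = drug_contrast(act, groups)
        assert out.loc["D1", "p_raw"] == pytest.approx(1 / 3)
        assert out.loc["D1", "effect"] == pytest.approx(1.5 - 3.5)

    def test_identical_distributions_not_significant(self):
        act, groups = self.make([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        out = drug_contrast(act, groups)
        assert out.loc["D1", "effect"] == 0.0
        assert not out.loc["D1", "significant"]

    def test_exact_p_matches_enumeration_small_groups(self):
        rng = np.random.default_rng(9)
        for m, n in [(2, 3), (3, 3), (4, 5), (5, 8), (8, 8)]:
            a, b = list(rng.normal(size=m)), list(rng.normal(size=n))
            act, groups = self.make(a, b)
            out = drug_contrast(act, groups)
            assert out.loc["D1", "p_raw"] == pytest.approx(mw_exact_oracle(a, b))

    def test_planted_classes_pass_fdr_with_signs(self):
        c = simulate_cohort(GeneratorConfig(seed=7))
        table = score_cohort(c.expr, repstress_signature())
        res = drug_contrast(c.drugs, table["group"], fdr=0.05)
        for drug, cls in c.truth.drug_classes.items():
            if cls == "rs_targeting":
                assert res.loc[drug, "significant"] and res.loc[drug, "direction"] == "up"
            elif cls == "mapk_like":
                assert res.loc[drug, "significant"] and res.loc[drug, "direction"] == "down"

    def test_null_type_one_error_calibration(self):
        """Independent groups: fraction of raw p < 0.05 stays near nominal."""
        rng = np.random.default_rng(2024)
        n = 60
        act = pd.DataFrame(rng.normal(size=(n, 500)),
                           index=[f"s{i}" for i in range(n)],
                           columns=[f"d{i}" for i in range(500)])
        groups = pd.Series(["high"] * 30 + ["low"] * 30, index=act.index)
        out = drug_contrast(act, groups)
        frac = (out["p_raw"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_one_group_too_small_errors(self):
        act, groups = self.make([1.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            drug_contrast(act, groups)


class TestPairedDynamics:
    def test_enumerated_exact_p(self):
        pre = pd.Series([0.0, 0.0, 0.0], index=list("abc"))
        post = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        delta, p = paired_dynamics(pre, post)
        assert (delta, p) == (2.0, pytest.approx(0.25))
        assert p == pytest.approx(wsr_exact_oracle([1, 2, 3]))

    def test_matches_enumeration_random_pairs(self):
        rng = np.random.default_rng(10)
        for n in (4, 6, 8):
            d = rng.normal(size=n)
            pre = pd.Series(np.zeros(n), index=range(n))
            _, p = paired_dynamics(pre, pre + d)
            assert p == pytest.approx(wsr_exact_oracle(d))

    def test_uniform_shift_and_symmetry(self):
        rng = np.random.default_rng(11)
        pre = pd.Series(rng.normal(size=10), index=range(10))
        delta, p = paired_dynamics(pre, pre + 1.0)
        assert delta == pytest.approx(1.0)
        assert p == pytest.approx(2 * 0.5**10)  # minimal attainable two-sided p
        d2, p2 = paired_dynamics(pre + 1.0, pre)
        assert (d2, p2) == (pytest.approx(-1.0), pytest.approx(p))

    def test_all_zero_differences_error(self):
        pre = pd.Series([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="no signal"):
            paired_dynamics(pre, pre)


class TestGroupCompare:
    def groups(self, *arrays):
        vals = pd.Series(np.concatenate(arrays))
        labels = pd.Series(np.concatenate(
            [[f"g{i}"] * len(a) for i, a in enumerate(arrays)]))
        return vals, labels

    def test_identical_groups_F_zero(self):
        v, g = self.groups([1.0, 2, 3], [1.0, 2, 3])
        assert group_compare(v, g)["F"] == pytest.approx(0.0)

    def test_two_groups_F_equals_t_squared(self):
        rng = np.random.default_rng(13)
        a, b = rng.normal(size=8), rng.normal(1, 1, size=10)
        v, g = self.groups(a, b)
        from scipy.stats import ttest_ind

        t, _ = ttest_ind(a, b, equal_var=True)
        assert group_compare(v, g)["F"] == pytest.approx(t**2)

    def test_trend_slope_recovers_ordered_means(self):
        rng = np.random.default_rng(14)
        arrays = [i + rng.normal(0, 0.01, 20) for i in range(3)]
        v, g = self.groups(*arrays)
        out = group_compare(v, g, mode="trend", group_order=["g0", "g1", "g2"])
        assert out["slope"] == pytest.approx(1.0, abs=0.02)
        assert out["p"] < 1e-10

    def test_pairwise_holm(self):
        rng = np.random.default_rng(15)
        v, g = self.groups(rng.normal(size=10), rng.normal(5, 1, 10), rng.normal(size=10))
        out = group_compare(v, g, mode="pairwise")
        assert len(out["pairs"]) == 3
        for pair in out["pairs"]:
            assert pair["p_adj"] >= pair["p_raw"] - 1e-15

    def test_errors(self):
        v, g = self.groups([1.0, 2.0])
        with pytest.raises(ValueError):
            group_compare(v, g)
        v2, g2 = self.groups([1.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            group_compare(v2, g2)


class TestKmLogrank:
    def test_hand_chi_square(self):
        surv = pd.DataFrame({"time": [1, 2, 3, 4], "event": [1, 1, 1, 1],
                             "group": ["A", "A", "B", "B"]})
        _, chi2, p = km_logrank(surv)
        assert chi2 == pytest.approx(49 / 17, abs=1e-6)
        assert 0 < p < 1

    def test_identical_groups_chi_square_zero(self):
        surv = pd.DataFrame({"time": [1, 2, 3, 1, 2, 3],
                             "event": [1, 0, 1, 1, 0, 1],
                             "group": list("AAABBB")})
        _, chi2, _ = km_logrank(surv)
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_fully_censored_group_contributes_risk_only(self):
        surv = pd.DataFrame({"time": [0.5, 0.6, 1.0, 2.0],
                             "event": [0, 0, 1, 1],
                             "group": ["B", "B", "A", "A"]})
        curves, chi2, _ = km_logrank(surv)
        assert (curves["B"].to_numpy() == 1.0).all()
        # hand KM for A: S(1)=1/2 (B already censored, risk set = {A1, A2})
        a = curves["A"]["A"]
        assert a.loc[1.0] == pytest.approx(0.5)
        assert a.loc[2.0] == pytest.approx(0.0)

    def test_km_monotone_and_time_rescale_invariance(self):
        rng = np.random.default_rng(16)
        surv = pd.DataFrame({
            "time": rng.exponential(5, 40),
            "event": rng.integers(0, 2, 40),
            "group": ["A"] * 20 + ["B"] * 20,
        })
        surv.loc[0, "event"] = 1
        surv.loc[20, "event"] = 1
        curves, chi2, _ = km_logrank(surv)
        for c in curves.values():
            vals = c.to_numpy().ravel()
            assert (np.diff(vals) <= 1e-12).all()
            assert vals[0] == pytest.approx(1.0)
        rescaled = surv.assign(time=surv["time"] * 365.0)
        _, chi2_scaled, _ = km_logrank(rescaled)
        assert chi2_scaled == pytest.approx(chi2)

    def test_errors(self):
        surv = pd.DataFrame({"time": [1, 2], "event": [0, 0], "group": ["A", "B"]})
        with pytest.raises(ValueError, match="no events"):
            km_logrank(surv)
        bad = pd.DataFrame({"time": [1, 2, 3], "event": [1, 1, 1],
                            "group": ["A", "B", "C"]})
        with pytest.raises(ValueError, match="exactly 2 groups"):
            km_logrank(bad)
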