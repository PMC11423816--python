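"""Factorial inference: ANOVA decomposition, Sidak adjustment, post-hoc."""

import numpy as np
import pandas as pd
import pytest

import fiberalign as fa
from fiberalign import compare as cmp


def make_table(cell_means, n_rep=3, noise_sd=3.0, seed=0):
    """Balanced table from a {(density, level): mean} map plus noise."""
    rng = np.random.default_rng(seed)
    rows = []
    for (density, level), m in cell_means.items():
        for rep in range(1, n_rep + 1):
            rows.append(
                {"density": density, "level": level, "replicate": rep,
                 "percent_aligned": float(np.clip(m + rng.normal(0, noise_sd), 0, 100))}
            )
    return pd.DataFrame(rows)


NULL_MEANS = {
    (d, lv): 50.0
    for d in ("confluent", "sparse")
    for lv in ("static", "LSS_6h", "LSS_24h")
}

EFFECT_MEANS = {
    ("confluent", "static"): 50.0,
    ("confluent", "LSS_6h"): 75.0,
    ("confluent", "LSS_24h"): 85.0,
    ("sparse", "static"): 50.0,
    ("sparse", "LSS_6h"): 51.0,
    ("sparse", "LSS_24h"): 52.0,
}


def brute_force_anova(table):
    """Independent oracle: sequential least-squares projections on explicit
    design matrices (intercept -> +density -> +level -> +interaction)."""
    y = table["percent_aligned"].to_numpy(float)
    d = pd.get_dummies(table["density"], drop_first=True).to_numpy(float)
    l = pd.get_dummies(table["level"], drop_first=True).to_numpy(float)
    inter = np.einsum("ij,ik->ijk", d, l).reshape(len(y), -1)
    blocks = [np.ones((len(y), 1)), d, l, inter]

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    out, prev = [], None
    for i in range(1, len(blocks) + 1):
        X = np.hstack(blocks[:i])
        cur = rss(X)
        if prev is not None:
            out.append(prev - cur)
        prev = cur
    ss_resid = prev
    return out, ss_resid  # [ss_density, ss_level, ss_inter], residual


class TestTwoWayAnova:
    def test_decomposition_identity(self):
        table = make_table(EFFECT_MEANS, seed=1)
        an = fa.two_way_anova(table)
        ss = an.table["sum_sq"]
        assert ss.sum() == pytest.approx(an.ss_total, rel=1e-8)
        assert an.table["df"].sum() == len(table) - 1
        assert (ss >= 0).all()

    def test_matches_brute_force_projection(self):
        """F statistics agree with the design-matrix projection oracle."""
        table = make_table(EFFECT_MEANS, seed=2)
        an = fa.two_way_anova(table)
        (ssd, ssl, ssi), ssr = brute_force_anova(table)
        assert an.table.loc["density", "sum_sq"] == pytest.approx(ssd, rel=1e-8)
        assert an.table.loc["level", "sum_sq"] == pytest.approx(ssl, rel=1e-8)
        assert an.table.loc["density:level", "sum_sq"] == pytest.approx(ssi, rel=1e-8)
        assert an.table.loc["Residual", "sum_sq"] == pytest.approx(ssr, rel=1e-8)

    def test_null_design_interaction_rarely_significant(self):
        hits = sum(
            fa.two_way_anova(make_table(NULL_MEANS, seed=s)).p_value("density:level") < 0.05
            for s in range(20)
        )
        assert hits <= 2  # >= 18/20 non-significant

    def test_effect_design_interaction_detected(self):
        """Confluent-only response to flow shows up as interaction."""
        hits = sum(
            fa.two_way_anova(make_table(EFFECT_MEANS, seed=s)).p_value("density:level") < 0.05
            for s in range(20)
        )
        assert hits >= 18

    def test_unbalanced_rejected_with_type2_fallback(self):
        table = make_table(EFFECT_MEANS, seed=3).iloc[:-1]
        with pytest.raises(cmp.UnbalancedDesignError, match="Type-II"):
            fa.two_way_anova(table)
        an = fa.two_way_anova(table, anova_type=2)  # documented fallback
        assert np.isfinite(an.p_value("density:level"))

    def test_single_level_factor_rejected(self):
        table = make_table({("confluent", "static"): 50, ("confluent", "LSS_6h"): 60})
        with pytest.raises(ValueError, match="two levels"):
            fa.two_way_anova(table)

    def test_permutation_cross_check(self):
        """Raw p of the density main effect agrees with a restricted
        permutation test (labels shuffled within level strata)."""
        table = make_table(
            {("confluent", "static"): 50, ("confluent", "LSS_6h"): 54,
             ("sparse", "static"): 49, ("sparse", "LSS_6h"): 50},
            n_rep=4, noise_sd=4.0, seed=5,
        )
        an = fa.two_way_anova(table)
        f_obs = float(an.table.loc["density", "F"])

        # permutation distribution of F_density via projection matrices:
        # permuting density labels within level strata == permuting y
        # within strata against the fixed design
        y = table["percent_aligned"].to_numpy(float)
        d = pd.get_dummies(table["density"], drop_first=True).to_numpy(float)
        l = pd.get_dummies(table["level"], drop_first=True).to_numpy(float)
        inter = np.einsum("ij,ik->ijk", d, l).reshape(len(y), -1)

        def proj(X):
            return X @ np.linalg.pinv(X)

        p1 = proj(np.ones((len(y), 1)))
        p2 = proj(np.hstack([np.ones((len(y), 1)), d]))
        p4 = proj(np.hstack([np.ones((len(y), 1)), d, l, inter]))
        df_res = len(y) - p4.trace().round()
        strata = [idx.to_numpy() for _, idx in table.groupby("level").groups.items()]
        rng = np.random.default_rng(99)
        count = 0
        n_draws = 10_000
        for _ in range(n_draws):
            yp = y.copy()
            for idx in strata:
                yp[idx] = yp[rng.permutation(idx)]
            ss_d = yp @ (p2 - p1) @ yp
            ms_res = yp @ (np.eye(len(y)) - p4) @ yp / df_res
            count += (ss_d / 1.0) / ms_res >= f_obs
        p_perm = count / n_draws
        assert abs(p_perm - an.p_value("density")) < 0.02


class TestSidak:
    @pytest.mark.parametrize(
        "p,m,expected",
        [(0.2, 1, 0.2), (0.0, 7, 0.0), (0.01, 5, 1 - 0.99**5), (1.0, 3, 1.0)],
    )
    def test_closed_form(self, p, m, expected):
        assert fa.sidak_adjust([p], m=m)[0] == pytest.approx(expected, abs=1e-12)

    def test_monotone_never_below_raw(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0, 1, 50)
        adj = fa.sidak_adjust(p)
        assert np.all(adj >= p) and np.all(adj <= 1.0)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fa.sidak_adjust([1.2])


class TestCompareToStatic:
    def test_null_design_no_stars(self):
        n_clean = 0
        for s in range(20):
            table = make_table(NULL_MEANS, seed=s)
            ph = fa.compare_to_static(table, fa.two_way_anova(table))
            n_clean += (ph.contrasts["p_adj"] > 0.05).all()
        assert n_clean >= 18

    def test_effect_design_significance_pattern(self):
        """Confluent LSS-24h vs static clears the paper-style 0.005 bar;
        the matching sparse contrast does not."""
        table = make_table(EFFECT_MEANS, seed=8)
        ph = fa.compare_to_static(table, fa.two_way_anova(table))
        c = ph.contrasts.set_index(["density", "level"])
        assert c.loc[("confluent", "LSS_24h"), "p_adj"] < 0.005
        assert c.loc[("confluent", "LSS_24h"), "stars"] == "***"
        assert c.loc[("sparse", "LSS_24h"), "p_adj"] > 0.005
        assert (ph.contrasts["p_adj"] >= ph.contrasts["p_raw"] - 1e-12).all()

    def test_missing_static_level_rejected(self):
        table = make_table(
            {("confluent", "LSS_6h"): 60, ("confluent", "LSS_24h"): 70,
             ("sparse", "LSS_6h"): 50, ("sparse", "LSS_24h"): 50}
        )
        an = fa.two_way_anova(table)
        with pytest.raises(ValueError, match="static"):
            fa.compare_to_static(table, an)

    def test_per_density_family_option(self):
        table = make_table(EFFECT_MEANS, seed=9)
        an = fa.two_way_anova(table)
        ph_all = fa.compare_to_static(table, an, family="all")
        ph_per = fa.compare_to_static(table, an, family="per_density")
        assert ph_all.family_size == 4 and ph_per.family_size == 2
        assert (ph_per.contrasts["p_adj"] <= ph_all.contrasts["p_adj"] + 1e-12).all()

    def test_simulated_pipeline_tables(self):
        """Distribution-level simulation of the default experiment shows the
        expected contact-dependence pattern."""
        design = fa.default_design()
        table = fa.simulate_replicate_table(design, base_seed=4)
        ph = fa.compare_to_static(table, fa.two_way_anova(table))
        c = ph.contrasts.set_index(["density", "level"])
        assert c.loc[("confluent", "LSS_24h"), "p_adj"] < 0.005
        assert c.loc[("sparse", "LSS_24h"), "p_adj"] > 0.005
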