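"""Factorial inference on percent-aligned replicates.

The design crosses confluence (confluent vs sparse) with flow condition
(static, LSS at one or more durations).  Percent-aligned values per
replicate enter a classical fixed-effects two-way ANOVA with interaction;
post-hoc contrasts compare each flow level against static within each
density, with Sidak family-wise adjustment 1 - (1 - p)^m.

The star notation is configurable.  The source figure legend prints
"**P<0.005; ***P<0.005" -- two star levels with the same threshold, almost
certainly a typo -- so the printed notation is reproduced by default while
the thresholds remain overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "AnovaTable",
    "PosthocResult",
    "UnbalancedDesignError",
    "DEFAULT_STAR_THRESHOLDS",
    "validate_replicate_table",
    "two_way_anova",
    "sidak_adjust",
    "compare_to_static",
]

REQUIRED_COLUMNS = ("density", "level", "replicate", "percent_aligned")

# Most-significant first; p below a threshold earns those stars.
DEFAULT_STAR_THRESHOLDS: tuple[tuple[str, float], ...] = (
    ("***", 0.005),
    ("**", 0.005),
    ("*", 0.05),
)


class UnbalancedDesignError(ValueError):
    """Unbalanced factorial input.

    The classical cell-means decomposition assumes equal replication; pass
    ``anova_type=2`` to fall back to a Type-II sum-of-squares analysis.
    """


@dataclass
class AnovaTable:
    """Sums of squares, df, F and p per effect, plus the residual line."""

    table: pd.DataFrame  # index: density, level, density:level, Residual
    ss_total: float
    n_obs: int

    @property
    def residual_ms(self) -> float:
        return float(self.table.loc["Residual", "sum_sq"] / self.table.loc["Residual", "df"])

    @property
    def residual_df(self) -> float:
        return float(self.table.loc["Residual", "df"])

    def p_value(self, effect: str) -> float:
        return float(self.table.loc[effect, "p_value"])


@dataclass
class PosthocResult:
    contrasts: pd.DataFrame  # density, level, mean_diff, se, t, p_raw, p_adj, stars
    family_size: int
    star_thresholds: tuple = DEFAULT_STAR_THRESHOLDS
    notation: str = "**P<0.005; ***P<0.005"  # printed notation, reproduced verbatim


def validate_replicate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"replicate table missing columns: {missing}")
    pct = table["percent_aligned"].to_numpy(float)
    if np.any(~np.isfinite(pct)) or np.any(pct < 0) or np.any(pct > 100):
        raise ValueError("percent_aligned must be finite and within [0, 100]")
    return table


def _check_balance(table: pd.DataFrame) -> None:
    counts = table.groupby(["density", "level"], sort=False).size()
    densities = table["density"].nunique()
    levels = table["level"].nunique()
    if densities < 2 or levels < 2:
        raise ValueError("both factors need at least two levels for a two-way ANOVA")
    if len(counts) != densities * levels:
        raise UnbalancedDesignError(
            "incomplete factorial: some (density, level) cells are empty; "
            "use anova_type=2 for a Type-II analysis of unbalanced data"
        )
    if counts.min() < 2:
        raise ValueError("every (density, level) cell needs >= 2 replicates")
    if counts.nunique() != 1:
        raise UnbalancedDesignError(
            "unequal replication across cells; the classical decomposition "
            "requires balance -- use anova_type=2 for a Type-II analysis"
        )


def two_way_anova(table: pd.DataFrame, anova_type: int = 1) -> AnovaTable:
    """Two-way fixed-effects ANOVA of percent aligned on density x level.

    The default (``anova_type=1`` on a balanced design) is the classical
    cell-means decomposition: sequential sums of squares coincide with the
    usual main effects and interaction when replication is equal.  F is
    MS_effect / MS_residual; p comes from the F distribution.  Unbalanced
    input raises ``UnbalancedDesignError`` unless ``anova_type=2`` is
    requested explicitly.
    """
    table = validate_replicate_table(table)
    if anova_type == 1:
        _check_balance(table)
    elif anova_type != 2:
        raise ValueError("anova_type must be 1 (balanced classical) or 2 (Type II)")
    model = smf.ols("percent_aligned ~ C(density) * C(level)", data=table).fit()
    raw = sm.stats.anova_lm(model, typ=anova_type)
    rename = {}
    for idx in raw.index:
        name = idx.replace("C(density)", "density").replace("C(level)", "level")
        rename[idx] = name
    raw = raw.rename(index=rename)
    out = pd.DataFrame(
        {
            "sum_sq": raw["sum_sq"],
            "df": raw["df"],
            "F": raw.get("F"),
            "p_value": raw.get("PR(>F)"),
        }
    )
    y = table["percent_aligned"].to_numpy(float)
    ss_total = float(np.sum((y - y.mean()) ** 2))
    return AnovaTable(table=out, ss_total=ss_total, n_obs=len(table))


def sidak_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Sidak family-wise adjustment: p_adj = 1 - (1 - p)^m, clipped to [0,1].

    ``m`` defaults to the number of p-values supplied.
    """
    p = np.atleast_1d(np.asarray(p_values, dtype=np.float64))
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size if m is None else int(m)
    if m < 1:
        raise ValueError("family size must be >= 1")
    return np.clip(1.0 - (1.0 - p) ** m, 0.0, 1.0)


def _stars(p_adj: float, thresholds=DEFAULT_STAR_THRESHOLDS) -> str:
    for stars, thr in thresholds:
        if p_adj < thr:
            return stars
    return "ns"


def compare_to_static(
    table: pd.DataFrame,
    anova: AnovaTable,
    static_level: str = "static",
    star_thresholds=DEFAULT_STAR_THRESHOLDS,
    family: str = "all",
) -> PosthocResult:
    """Contrast each flow level against static within each density.

    Uses the pooled residual mean square from the ANOVA for the standard
    error of each mean difference; raw p from the t distribution on the
    residual df; Sidak adjustment over the family of contrasts (both
    densities jointly by default, ``family="per_density"`` for per-stratum
    adjustment).
    """
    table = validate_replicate_table(table)
    ms, dof = anova.residual_ms, anova.residual_df
    rows = []
    for density, sub in table.groupby("density", sort=False):
        levels = [lv for lv in sub["level"].unique() if lv != static_level]
        if static_level not in set(sub["level"]):
            raise ValueError(f"static level {static_level!r} missing in density {density!r}")
        base = sub.loc[sub["level"] == static_level, "percent_aligned"].to_numpy(float)
        for lv in levels:
            y = sub.loc[sub["level"] == lv, "percent_aligned"].to_numpy(float)
            diff = float(y.mean() - base.mean())
            se = float(np.sqrt(ms * (1.0 / len(y) + 1.0 / len(base))))
            t = diff / se if se > 0 else np.inf * np.sign(diff)
            p_raw = float(2.0 * sps.t.sf(abs(t), dof))
            rows.append(
                {"density": density, "level": lv, "mean_diff": diff,
                 "se": se, "t": t, "p_raw": p_raw}
            )
    res = pd.DataFrame(rows)
    if family == "all":
        res["p_adj"] = sidak_adjust(res["p_raw"].to_numpy())
        m = len(res)
    elif family == "per_density":
        res["p_adj"] = res.groupby("density")["p_raw"].transform(
            lambda p: sidak_adjust(p.to_numpy())
        )
        m = int(res.groupby("density").size().max())
    else:
        raise ValueError("family must be 'all' or 'per_density'")
    res["stars"] = [_stars(p, star_thresholds) for p in res["p_adj"]]
    return PosthocResult(contrasts=res, family_size=m, star_thresholds=tuple(star_thresholds))
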