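"""Behavioral hypothesis tests: Williams-adjusted G-test of independence,
two-way fixed-effects linear models with Type-III tests, and gated Tukey
multiple comparisons."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "GTestResult",
    "AnovaResult",
    "g_test",
    "g_test_adj",
    "two_way_anova",
    "tukey_hsd",
    "TukeyGateError",
]


@dataclass(frozen=True)
class GTestResult:
    G: float
    G_adj: float
    williams_q: float
    df: int
    p_value: float


@dataclass
class AnovaResult:
    """Per-term F tests (Type III) from a two-way fixed-effects fit."""

    table: pd.DataFrame  # index: term; columns: F, df_num, df_den, p
    residual_df: int
    model: object  # fitted statsmodels results

    def term(self, name: str) -> pd.Series:
        return self.table.loc[name]


def g_test(table) -> tuple:
    """Unadjusted likelihood-ratio G statistic and df for an r x c table.

    Uses the ``0 * ln 0 = 0`` convention for empty cells.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    n = obs.sum()
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if n == 0 or np.any(row == 0) or np.any(col == 0):
        raise ValueError("G-test undefined: empty table margin")
    exp = np.outer(row, col) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
    G = 2.0 * terms.sum()
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return float(max(G, 0.0)), df


def williams_q(table) -> float:
    """Williams' correction divisor
    ``q = 1 + (sum(n/row) - 1)(sum(n/col) - 1) / (6 n df)``; always >= 1."""
    obs = np.asarray(table, dtype=float)
    n = obs.sum()
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return float(1.0 + ((n / row).sum() - 1.0) * ((n / col).sum() - 1.0) / (6.0 * n * df))


def g_test_adj(table) -> GTestResult:
    """Williams-adjusted G-test of independence.

    ``G_adj = G / q`` with q the Williams divisor; since q >= 1, the
    adjusted statistic never exceeds the raw one. The p-value is the
    upper chi-square tail at the table's df.
    """
    G, df = g_test(table)
    q = williams_q(table)
    G_adj = G / q
    return GTestResult(G, float(G_adj), q, df, float(stats.chi2.sf(G_adj, df)))


def two_way_anova(
    data: pd.DataFrame,
    response: str,
    factor_a: str = "reartype",
    factor_b: str = "year",
) -> AnovaResult:
    """Two-way fixed-effects model with interaction, Type-III F tests.

    Rows with missing response are dropped (not every fish yields every
    behavioral metric). Sum-to-zero contrasts are used so Type-III sums of
    squares are meaningful under unbalanced cells. An empty factor cell
    leaves the interaction inestimable and raises ValueError.
    """
    df = data[[response, factor_a, factor_b]].dropna().copy()
    for f in (factor_a, factor_b):
        df[f] = df[f].astype(str)
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs >= 2 observed levels")
    cells = df.groupby([factor_a, factor_b]).size()
    full = df[factor_a].nunique() * df[factor_b].nunique()
    if len(cells) < full:
        raise ValueError("empty factor cell: interaction inestimable")
    formula = (
        f"{response} ~ C({factor_a}, Sum) * C({factor_b}, Sum)"
    )
    fit = smf.ols(formula, data=df).fit()
    scale = float(df[response].abs().mean()) or 1.0
    if float(df[response].std(ddof=0)) < 1e-12 * scale:
        # constant response: every sum of squares is 0, so every F is 0
        terms = [factor_a, factor_b, f"{factor_a}:{factor_b}"]
        a = df[factor_a].nunique() - 1
        b = df[factor_b].nunique() - 1
        out = pd.DataFrame(
            {"F": 0.0, "df_num": [a, b, a * b], "df_den": int(fit.df_resid), "p": 1.0},
            index=terms,
        )
        return AnovaResult(out, int(fit.df_resid), fit)
    aov = sm.stats.anova_lm(fit, typ=3)
    aov = aov.drop(index=["Intercept", "Residual"], errors="ignore")
    resid_df = int(fit.df_resid)
    pretty = {
        f"C({factor_a}, Sum)": factor_a,
        f"C({factor_b}, Sum)": factor_b,
        f"C({factor_a}, Sum):C({factor_b}, Sum)": f"{factor_a}:{factor_b}",
    }
    out = pd.DataFrame(
        {
            "F": aov["F"].values,
            "df_num": aov["df"].astype(int).values,
            "df_den": resid_df,
            "p": aov["PR(>F)"].values,
        },
        index=[pretty.get(i, i) for i in aov.index],
    )
    return AnovaResult(out, resid_df, fit)


class TukeyGateError(RuntimeError):
    """Raised when Tukey comparisons are requested without a significant
    interaction (the procedure is gated on it)."""


def tukey_hsd(
    anova: AnovaResult,
    data: pd.DataFrame,
    response: str,
    group: str = "reartype",
    within: str = "year",
    alpha: float = 0.05,
    gate: bool = True,
) -> pd.DataFrame:
    """Tukey(-Kramer) pairwise comparisons of ``group`` within each level
    of ``within``, gated on a significant interaction term.

    Refuses (TukeyGateError) when the gate is requested and the ANOVA
    interaction p-value exceeds ``alpha``.
    """
    inter = f"{group}:{within}"
    if gate:
        if inter not in anova.table.index:
            raise TukeyGateError(f"no interaction term {inter!r} in the ANOVA")
        p_inter = float(anova.table.loc[inter, "p"])
        if p_inter > alpha:
            raise TukeyGateError(
                f"interaction p={p_inter:.3f} > {alpha}: multiple comparisons not warranted"
            )
    df = data[[response, group, within]].dropna()
    rows = []
    for level, sub in df.groupby(within):
        if sub[group].nunique() < 2:
            continue
        res = pairwise_tukeyhsd(sub[response].to_numpy(), sub[group].astype(str).to_numpy(), alpha=alpha)
        frame = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
        frame.insert(0, within, level)
        rows.append(frame)
    if not rows:
        raise ValueError("no stratum had >= 2 groups to compare")
    out = pd.concat(rows, ignore_index=True)
    out = out.rename(columns={"p-adj": "p_adj", "meandiff": "mean_diff"})
    return out
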