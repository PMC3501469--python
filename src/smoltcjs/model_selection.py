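"""Goodness-of-fit, overdispersion (c-hat), QAICc and model ranking.

The GOF machinery follows the RELEASE-style contingency decomposition for
single-release CJS data:

* TEST3.SR per occasion -- among fish detected at occasion i, does having
  been detected before i predict being detected after i?
* TEST3.Sm per occasion -- among fish detected at i and seen again, does
  prior detection predict whether the next detection is immediate?
* TEST2.CT per occasion -- among fish known alive after occasion i, does
  detection at i predict when they are next detected?

Component chi-squares with all expected cells >= 2 (after pooling the
"later" columns) are summed; ``c_hat = chi2 / df`` floored at 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cjs_engine import FitResult, _history_matrix

__all__ = [
    "MArray",
    "GofResult",
    "build_marray",
    "release_gof",
    "qaicc",
    "rank_models",
]

MIN_EXPECTED = 2.0


@dataclass
class MArray:
    """Release-cohort by first-recapture-occasion counts.

    ``released[i]`` counts fish released (or re-released after detection)
    at occasion i; ``m[i, j]`` counts those first detected next at occasion
    j; ``never_seen[i]`` is the remainder. Row conservation:
    ``released[i] == m[i, :].sum() + never_seen[i]``. The source history
    matrix is retained for the contingency-table GOF components.
    """

    released: np.ndarray  # (T,) releases at occasions 0..T-1
    m: np.ndarray  # (T, T): m[i, j-1] = first next detection at occasion j
    never_seen: np.ndarray  # (T,)
    histories: np.ndarray = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        T = len(self.released)
        df = pd.DataFrame(self.m, columns=[f"first_at_{j}" for j in range(1, T + 1)])
        df.insert(0, "occasion", np.arange(T))
        df["released"] = self.released
        df["never_seen"] = self.never_seen
        return df


@dataclass
class GofResult:
    chi2_total: float
    df_total: int
    c_hat: float  # chi2/df floored at 1 (the value applied to QAICc/SEs)
    c_hat_raw: float = float("nan")  # unfloored chi2/df, for null calibration
    components: pd.DataFrame = field(repr=False, default=None)
    warning: str = ""


def build_marray(histories) -> MArray:
    """Reduced m-array over all release/re-release occasions."""
    hist = _history_matrix(histories)
    n, T1 = hist.shape
    T = T1 - 1
    released = np.zeros(T, dtype=int)
    m = np.zeros((T, T), dtype=int)
    never = np.zeros(T, dtype=int)
    for i in range(T):  # release occasions 0..T-1
        at_i = hist[:, i] == 1
        released[i] = int(at_i.sum())
        future = hist[at_i, i + 1:]
        if future.size:
            any_future = future.any(axis=1)
            firsts = np.argmax(future, axis=1)  # offset from i+1
            for off in firsts[any_future]:
                m[i, i + off] += 1
            never[i] = int((~any_future).sum())
        else:
            never[i] = released[i]
    return MArray(released, m, never, histories=hist)


def _pooled_chi2(table: np.ndarray):
    """Pearson chi-square for an r x c table, pooling the trailing columns
    until every expected count is >= MIN_EXPECTED. Returns (chi2, df) or
    (0, 0) when the table stays too sparse."""
    table = np.atleast_2d(np.asarray(table, dtype=float))
    while table.shape[1] > 2:
        exp = np.outer(table.sum(1), table.sum(0)) / max(table.sum(), 1)
        if (exp >= MIN_EXPECTED).all():
            break
        table = np.concatenate([table[:, :-2], table[:, -2:].sum(1, keepdims=True)], axis=1)
    table = table[table.sum(axis=1) > 0]
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return 0.0, 0
    exp = np.outer(table.sum(1), table.sum(0)) / table.sum()
    if (exp < MIN_EXPECTED).any():
        return 0.0, 0
    chi2 = float(((table - exp) ** 2 / exp).sum())
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return chi2, df


def release_gof(marray: MArray | np.ndarray) -> GofResult:
    """Pooled TEST2 + TEST3 goodness-of-fit and variance inflation.

    Accepts an MArray (using its retained histories) or a raw history
    matrix. c-hat is floored at 1; an all-sparse dataset yields c-hat = 1
    with a zero-df warning.
    """
    hist = marray.histories if isinstance(marray, MArray) else _history_matrix(marray)
    if hist is None:
        raise ValueError("MArray must retain its source histories for GOF")
    n, T1 = hist.shape
    T = T1 - 1
    rows = []

    seen_before = np.zeros(n, dtype=bool)  # detected at any occasion 1..i-1
    for i in range(1, T):
        at_i = hist[:, i] == 1
        future = hist[:, i + 1:]
        seen_after = future.any(axis=1)

        # TEST3.SR: detected-at-i fish, prior detection vs detected again
        sel = at_i
        if i > 1 and sel.sum():
            tab = np.array(
                [
                    [(sel & seen_before & seen_after).sum(), (sel & seen_before & ~seen_after).sum()],
                    [(sel & ~seen_before & seen_after).sum(), (sel & ~seen_before & ~seen_after).sum()],
                ]
            )
            chi2, df = _pooled_chi2(tab)
            rows.append(("TEST3.SR", i, chi2, df))

        # TEST3.Sm: detected-at-i fish seen again: next detection at i+1 vs later
        sel = at_i & seen_after
        if i > 1 and i + 1 < T1 - 1 and sel.sum():
            nxt = np.argmax(future, axis=1)  # 0 => at occasion i+1
            tab = np.array(
                [
                    [(sel & seen_before & (nxt == 0)).sum(), (sel & seen_before & (nxt > 0)).sum()],
                    [(sel & ~seen_before & (nxt == 0)).sum(), (sel & ~seen_before & (nxt > 0)).sum()],
                ]
            )
            chi2, df = _pooled_chi2(tab)
            rows.append(("TEST3.Sm", i, chi2, df))

        # TEST2.CT: fish detected after i: detected at i vs not, by next time
        sel = seen_after
        if i + 1 < T1 - 1 and sel.sum():
            nxt = np.argmax(future, axis=1)
            tab = np.array(
                [
                    [(sel & at_i & (nxt == 0)).sum(), (sel & at_i & (nxt > 0)).sum()],
                    [(sel & ~at_i & (nxt == 0)).sum(), (sel & ~at_i & (nxt > 0)).sum()],
                ]
            )
            chi2, df = _pooled_chi2(tab)
            rows.append(("TEST2.CT", i, chi2, df))

        seen_before = seen_before | at_i

    comps = pd.DataFrame(rows, columns=["test", "occasion", "chi2", "df"])
    chi2_total = float(comps["chi2"].sum()) if len(comps) else 0.0
    df_total = int(comps["df"].sum()) if len(comps) else 0
    if df_total == 0:
        return GofResult(chi2_total, 0, 1.0, components=comps,
                         warning="zero df: tables too sparse")
    raw = chi2_total / df_total
    return GofResult(chi2_total, df_total, max(raw, 1.0), c_hat_raw=raw, components=comps)


def qaicc(loglik: float, K: int, n_eff: float, c_hat: float = 1.0) -> float:
    """Quasi-likelihood AICc: ``-2 loglik / c_hat + 2K + 2K(K+1)/(n-K-1)``.

    ``n_eff`` follows the released-animals convention unless callers pass
    another. Undefined when ``n_eff <= K + 1``.
    """
    if n_eff <= K + 1:
        raise ValueError(f"QAICc undefined: n_eff={n_eff} <= K+1={K + 1}")
    c_hat = max(c_hat, 1.0)
    return -2.0 * loglik / c_hat + 2.0 * K + 2.0 * K * (K + 1) / (n_eff - K - 1)


def rank_models(
    fits: dict | list,
    c_hat: float = 1.0,
    n_eff: float | None = None,
) -> pd.DataFrame:
    """Rank fitted (or pre-summarized) models by QAICc.

    ``fits`` maps model label -> FitResult, or is a list of
    ``(label, K, qaicc_value)`` triples when QAICc values are supplied
    directly. Unconverged models are excluded (logged in the ``note``
    column semantics: they simply do not appear). Returns a table sorted
    ascending by QAICc with ``delta`` and normalized Akaike ``weight``.
    """
    rows = []
    if isinstance(fits, dict):
        if n_eff is None:
            raise ValueError("n_eff is required when ranking FitResults")
        for label, fr in fits.items():
            if isinstance(fr, FitResult) and not fr.converged:
                continue
            rows.append(
                {
                    "model": label,
                    "K": fr.n_params,
                    "QAICc": qaicc(fr.loglik, fr.n_params, n_eff, c_hat),
                }
            )
    else:
        for label, K, q in fits:
            rows.append({"model": label, "K": K, "QAICc": float(q)})
    if not rows:
        raise ValueError("no converged models to rank")
    table = pd.DataFrame(rows).sort_values("QAICc", kind="stable").reset_index(drop=True)
    table["delta"] = table["QAICc"] - table["QAICc"].iloc[0]
    rel = np.exp(-table["delta"] / 2.0)
    table["weight"] = rel / rel.sum()
    return table


def gof_pvalue(result: GofResult) -> float:
    """Upper-tail chi-square p-value of the pooled GOF statistic."""
    if result.df_total == 0:
        return float("nan")
    return float(stats.chi2.sf(result.chi2_total, result.df_total))
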