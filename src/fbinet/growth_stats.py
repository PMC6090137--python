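"""Growth comparisons: co-culture vs monoculture areas.

Each (focal, partner, medium, day) cell is compared to its monoculture
control (same focal, medium, day) with a two-tailed Welch t-test —
"Student's t-test with unequal variance" — on the raw area scale, and
reduced to a signed significance call at a fixed alpha. No
multiple-testing correction is applied by default, matching the original
screen's per-comparison thresholding; Benjamini-Hochberg can be switched
on for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class WelchResult:
    """Welch two-sample t-test outcome.

    ``degenerate`` flags the zero-variance corner cases where the t
    statistic is not finite-sample meaningful: both samples constant and
    equal (t=0, p=1) or both constant and unequal (p=0).
    """

    t: float
    dof: float
    p: float
    degenerate: bool = False


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> WelchResult:
    """Two-tailed Welch t-test of mean(x) - mean(y).

    t = (mean(x) - mean(y)) / sqrt(s2x/nx + s2y/ny), with
    Welch-Satterthwaite degrees of freedom and a two-sided p from the t
    distribution. Requires at least two values per sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("welch_t_test needs >= 2 values per sample")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    if se2 == 0.0:
        if mx == my:
            return WelchResult(t=0.0, dof=float("nan"), p=1.0, degenerate=True)
        t = float("inf") if mx > my else float("-inf")
        return WelchResult(t=t, dof=float("nan"), p=0.0, degenerate=True)
    t = (mx - my) / np.sqrt(se2)
    dof = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), dof)
    return WelchResult(t=float(t), dof=float(dof), p=float(min(p, 1.0)))


def significance_call(p: float, mean_diff: float, alpha: float = 0.05) -> int:
    """Signed significance call: +1 / -1 if p < alpha (strict) with a
    positive / negative mean difference, else 0."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if p < alpha and mean_diff > 0:
        return 1
    if p < alpha and mean_diff < 0:
        return -1
    return 0


COMPARISON_COLUMNS = [
    "focal",
    "kingdom",
    "partner",
    "medium",
    "day",
    "n_co",
    "n_mono",
    "mean_co",
    "mean_mono",
    "mean_diff",
    "t_statistic",
    "dof",
    "p_value",
    "sign_call",
    "status",
]


def compare_all(
    records: pd.DataFrame,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Compare every co-culture cell to its monoculture control.

    Produces one row per (focal, partner, medium, day), both directions
    of every pair. A cell with no matching control is reported with
    ``status='missing_control'`` rather than dropped. With
    ``bh_correct=True`` p-values are Benjamini-Hochberg adjusted across
    all comparisons before calling significance (off by default).
    """
    mono = records[records["partner"] == ""]
    co = records[records["partner"] != ""]
    mono_groups = {
        key: grp["area"].to_numpy()
        for key, grp in mono.groupby(["focal", "medium", "day"], sort=False)
    }

    rows = []
    for (focal, kingdom, partner, medium, day), grp in co.groupby(
        ["focal", "kingdom", "partner", "medium", "day"], sort=True
    ):
        x = grp["area"].to_numpy()
        y = mono_groups.get((focal, medium, day))
        row = {
            "focal": focal,
            "kingdom": kingdom,
            "partner": partner,
            "medium": medium,
            "day": day,
            "n_co": x.size,
            "n_mono": 0 if y is None else y.size,
            "mean_co": x.mean(),
        }
        if y is None:
            row.update(
                mean_mono=np.nan, mean_diff=np.nan, t_statistic=np.nan,
                dof=np.nan, p_value=np.nan, sign_call=0, status="missing_control",
            )
        else:
            res = welch_t_test(x, y)
            row.update(
                mean_mono=y.mean(),
                mean_diff=x.mean() - y.mean(),
                t_statistic=res.t,
                dof=res.dof,
                p_value=res.p,
                sign_call=0,  # filled below, after optional BH adjustment
                status="degenerate" if res.degenerate else "ok",
            )
        rows.append(row)

    out = pd.DataFrame(rows, columns=COMPARISON_COLUMNS)
    tested = out["p_value"].notna()
    p_eff = out["p_value"].copy()
    if bh_correct and tested.any():
        from statsmodels.stats.multitest import multipletests

        p_eff.loc[tested] = multipletests(
            out.loc[tested, "p_value"], method="fdr_bh"
        )[1]
    out.loc[tested, "sign_call"] = [
        significance_call(p, d, alpha)
        for p, d in zip(p_eff[tested], out.loc[tested, "mean_diff"])
    ]
    return out
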