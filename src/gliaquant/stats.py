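"""The study's statistical layer.

Shapiro-Wilk normality screening (log-only: it never switches tests),
Welch's unequal-variance t test for two-group comparisons, and two-way ANOVA
(diet x injury) for the clearance experiment. Two-sided p values throughout;
the significance convention is p < 0.05. Unbalanced two-way designs use
type-II sums of squares.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

log = logging.getLogger(__name__)

ALPHA = 0.05


@dataclasses.dataclass(frozen=True)
class TestResult:
    statistic: float
    degrees_of_freedom: float | tuple[float, float]
    p_value: float
    test_name: str

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def welch_t(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Welch's t test with Welch-Satterthwaite degrees of freedom."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            # identical constants: no evidence of difference
            return TestResult(0.0, float(len(a) + len(b) - 2), 1.0, "welch_t")
        raise ValueError("both samples have zero variance but differ")
    res = sps.ttest_ind(a, b, equal_var=False)
    return TestResult(
        statistic=float(res.statistic),
        degrees_of_freedom=float(res.df),
        p_value=float(res.pvalue),
        test_name="welch_t",
    )


def shapiro_wilk(sample: Sequence[float]) -> TestResult:
    """Normality screen; results are logged, never used to switch tests."""
    x = np.asarray(sample, dtype=float)
    if not (3 <= len(x) <= 5000):
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    w, p = sps.shapiro(x)
    result = TestResult(float(w), float(len(x)), float(p), "shapiro_wilk")
    if result.p_value < ALPHA:
        log.warning("Shapiro-Wilk rejects normality (W=%.4f, p=%.3g, n=%d)",
                    w, p, len(x))
    return result


def two_way_anova(values: Sequence[float], factor_diet: Sequence[str],
                  factor_injury: Sequence[str]) -> dict[str, TestResult]:
    """Two-way ANOVA with interaction: diet, injury, diet x injury.

    Type-II sums of squares (equivalent to the balanced-design decomposition
    when cells are balanced). Requires >= 2 levels per factor, every cell
    populated, and nonzero residual variance.
    """
    df = pd.DataFrame({
        "value": np.asarray(values, dtype=float),
        "diet": list(factor_diet),
        "injury": list(factor_injury),
    })
    if df["diet"].nunique() < 2 or df["injury"].nunique() < 2:
        raise ValueError("each factor needs >= 2 levels")
    cells = df.groupby(["diet", "injury"], sort=False).size()
    if len(cells) < df["diet"].nunique() * df["injury"].nunique():
        raise ValueError("every diet x injury cell needs >= 1 observation")
    model = smf.ols("value ~ C(diet) * C(injury)", data=df).fit()
    if model.ssr <= np.finfo(float).eps * max(1.0, float(np.abs(df["value"]).max())) ** 2:
        raise ValueError("degenerate data: zero residual variance")
    table = sm.stats.anova_lm(model, typ=2)
    df_resid = float(table.loc["Residual", "df"])
    out: dict[str, TestResult] = {}
    for row, name in (("C(diet)", "diet"), ("C(injury)", "injury"),
                      ("C(diet):C(injury)", "diet:injury")):
        out[name] = TestResult(
            statistic=float(table.loc[row, "F"]),
            degrees_of_freedom=(float(table.loc[row, "df"]), df_resid),
            p_value=float(table.loc[row, "PR(>F)"]),
            test_name=f"two_way_anova[{name}]",
        )
    return out


def compare_groups(table: pd.DataFrame, value_col: str = "value",
                   group_col: str = "group") -> dict[str, TestResult]:
    """Two-group comparison as the study ran it: normality screen + Welch t."""
    groups = list(table[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {groups}")
    a = table[table[group_col] == groups[0]][value_col].to_numpy(dtype=float)
    b = table[table[group_col] == groups[1]][value_col].to_numpy(dtype=float)
    out = {}
    for name, sample in ((groups[0], a), (groups[1], b)):
        if 3 <= len(sample) <= 5000:
            out[f"shapiro[{name}]"] = shapiro_wilk(sample)
    out["welch_t"] = welch_t(a, b)
    return out
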