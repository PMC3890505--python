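"""Reliability diagnostics and inequality inference.

Cronbach's alpha with corrected item-total screening for scale reliability;
one-way ANOVA for deprivation-quintile differences in domain means; logistic
regression for covariate-adjusted odds ratios of vulnerability; Pearson
chi-square for indicator associations.  All analyses delete missing data
pairwise (per analysis, not listwise), so usable n — and hence ANOVA
degrees of freedom — may differ between domains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "ReliabilityResult",
    "AnovaResult",
    "OrResult",
    "ChiSqResult",
    "cronbach_alpha",
    "oneway_anova",
    "adjusted_odds_ratio",
    "chi_square",
]

LOW_ITEM_TOTAL = 0.2


@dataclass
class ReliabilityResult:
    scale: str
    k: int
    n_used: int
    alpha: float
    item_total: dict  # item -> corrected item-total correlation
    low_items: list = field(init=False)

    def __post_init__(self) -> None:
        self.low_items = [
            i for i, r in self.item_total.items() if r < LOW_ITEM_TOTAL
        ]


def cronbach_alpha(score_matrix, scale: str = "scale") -> ReliabilityResult:
    """Internal-consistency reliability of a multi-item scale.

    ``score_matrix`` is pupils x items (DataFrame or 2-D array); rows with
    any missing item are dropped (complete case).  Alpha is
    ``k/(k-1) * (1 - sum(var_i)/var_total)`` with unbiased (n-1) variances.
    Item-total correlations are *corrected*: each item against the sum of
    the remaining items, so an item never correlates with itself; values
    below 0.2 are flagged.
    """
    m = pd.DataFrame(score_matrix).dropna()
    n, k = m.shape
    if k < 2:
        raise ValueError(f"{scale}: alpha requires at least 2 items, got {k}")
    if n < 2:
        raise ValueError(f"{scale}: alpha requires at least 2 complete cases")
    arr = m.to_numpy(dtype=float)
    total = arr.sum(axis=1)
    var_total = total.var(ddof=1)
    if var_total == 0:
        raise ValueError(f"{scale}: zero total-score variance; alpha undefined")
    alpha = k / (k - 1) * (1.0 - arr.var(axis=0, ddof=1).sum() / var_total)

    item_total = {}
    for j, col in enumerate(m.columns):
        rest = total - arr[:, j]
        if arr[:, j].std(ddof=1) == 0 or rest.std(ddof=1) == 0:
            item_total[col] = float("nan")
        else:
            item_total[col] = float(np.corrcoef(arr[:, j], rest)[0, 1])
    return ReliabilityResult(scale, k=k, n_used=n, alpha=float(alpha),
                             item_total=item_total)


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p_value: float
    n_used: int
    group_means: dict


def oneway_anova(values, groups) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA.

    Pupils with a missing value or group label are dropped pairwise, so
    ``df_within = usable_n - n_groups``.  Degenerate inputs (a single group,
    or all values identical) raise ``ValueError``.
    """
    df = pd.DataFrame({"y": np.asarray(values, dtype=float),
                       "g": pd.Series(groups).to_numpy()})
    df = df.dropna()
    levels = sorted(df["g"].unique(), key=str)
    if len(levels) < 2:
        raise ValueError("one-way ANOVA needs at least 2 non-empty groups")
    samples = [df.loc[df["g"] == lv, "y"].to_numpy() for lv in levels]
    n = len(df)
    grand = df["y"].mean()
    ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df_b = len(levels) - 1
    df_w = n - len(levels)
    if ss_within == 0 and ss_between == 0:
        raise ValueError("degenerate ANOVA input: zero variance everywhere")
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(scipy.stats.f.sf(F, df_b, df_w))
    return AnovaResult(
        F=float(F), df_between=df_b, df_within=df_w, p_value=p, n_used=n,
        group_means={str(lv): float(s.mean()) for lv, s in zip(levels, samples)},
    )


@dataclass
class OrResult:
    contrast: str  # e.g. "male vs female"
    odds_ratio: float
    log_or_se: float
    ci_low: float
    ci_high: float
    adjusted_for: tuple
    n_used: int
    estimable: bool = True


def adjusted_odds_ratio(
    outcome,
    exposure,
    reference,
    covariates: pd.DataFrame | dict | None = None,
) -> list:
    """Covariate-adjusted odds ratios from maximum-likelihood logistic fit.

    One OR (exponentiated coefficient, with a Wald 95% CI) per non-reference
    exposure level, all from a single model.  Numeric covariates enter
    as-is; non-numeric covariates are dummy-coded against their first level.
    Rows with any missing value are dropped.  Perfect separation yields
    results flagged non-estimable rather than an exception.
    """
    y = pd.Series(outcome).astype(float)
    x = pd.Series(exposure).astype(str).reset_index(drop=True)
    y = y.reset_index(drop=True)
    data = pd.DataFrame({"_y": y, "_exp": x})
    cov_names: list[str] = []
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        for col in cov.columns:
            if pd.api.types.is_numeric_dtype(cov[col]):
                data[col] = cov[col].astype(float)
                cov_names.append(str(col))
            else:
                dummies = pd.get_dummies(cov[col].astype(str), prefix=str(col),
                                         drop_first=True, dtype=float)
                for dc in dummies.columns:
                    data[dc] = dummies[dc]
                cov_names.append(str(col))
    data = data.dropna()
    if data["_y"].nunique() < 2:
        raise ValueError("outcome must contain both classes")
    levels = sorted(data["_exp"].unique())
    ref = str(reference)
    if ref not in levels:
        raise ValueError(f"reference level {reference!r} absent from exposure")
    contrast_levels = [lv for lv in levels if lv != ref]
    for lv in levels:
        if (data["_exp"] == lv).sum() == 0:  # pragma: no cover - sorted uniques
            raise ValueError(f"empty exposure level {lv!r}")

    design = pd.DataFrame(index=data.index)
    design["const"] = 1.0
    for lv in contrast_levels:
        design[f"exp[{lv}]"] = (data["_exp"] == lv).astype(float)
    for col in data.columns:
        if col not in ("_y", "_exp"):
            design[col] = data[col]

    try:
        fit = sm.Logit(data["_y"].to_numpy(), design.to_numpy()).fit(disp=0)
        params = dict(zip(design.columns, fit.params))
        bse = dict(zip(design.columns, fit.bse))
        estimable = bool(np.all(np.isfinite(fit.params)) and np.all(np.isfinite(fit.bse)))
    except (PerfectSeparationError, np.linalg.LinAlgError):
        params = bse = None
        estimable = False

    out = []
    z = scipy.stats.norm.ppf(0.975)
    for lv in contrast_levels:
        name = f"exp[{lv}]"
        if estimable:
            b, se = params[name], bse[name]
            out.append(OrResult(
                contrast=f"{lv} vs {ref}",
                odds_ratio=float(np.exp(b)),
                log_or_se=float(se),
                ci_low=float(np.exp(b - z * se)),
                ci_high=float(np.exp(b + z * se)),
                adjusted_for=tuple(cov_names),
                n_used=len(data),
            ))
        else:
            out.append(OrResult(
                contrast=f"{lv} vs {ref}",
                odds_ratio=float("nan"), log_or_se=float("nan"),
                ci_low=float("nan"), ci_high=float("nan"),
                adjusted_for=tuple(cov_names), n_used=len(data),
                estimable=False,
            ))
    return out


@dataclass
class ChiSqResult:
    statistic: float
    df: int
    p_value: float
    shape: tuple


def chi_square(table) -> ChiSqResult:
    """Pearson chi-square test of independence on an r x c count table.

    No continuity correction by default (pass the 2x2 through
    ``scipy.stats.chi2_contingency`` with ``correction=False``).  A zero row
    or column margin is reported as an error naming the offending margin.
    """
    t = np.asarray(table, dtype=float)
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    row_sums = t.sum(axis=1)
    col_sums = t.sum(axis=0)
    if np.any(row_sums == 0):
        raise ValueError(f"zero row margin at row {int(np.argmin(row_sums))}")
    if np.any(col_sums == 0):
        raise ValueError(f"zero column margin at column {int(np.argmin(col_sums))}")
    res = scipy.stats.chi2_contingency(t, correction=False)
    return ChiSqResult(statistic=float(res.statistic), df=int(res.dof),
                       p_value=float(res.pvalue), shape=t.shape)
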