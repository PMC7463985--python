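"""Clinical association and survival statistics.

Numerical covariates vs a binary grouping use the Mann-Whitney U test;
covariates with three or more subgroups use Kruskal-Wallis; proportions
of categorical variables use Pearson's uncorrected chi-square (no Yates
continuity correction -- the printed two-decimal p-values of the
association table require the uncorrected statistic).  Overall survival
uses the Kaplan-Meier product-limit estimator with groups split at the
median expression (ties to "high") and the log-rank test.

p-values are reported raw and display-rounded to two decimals with
"0.00" permitted, matching the print convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy import stats as sps

from .expression import mwu_test
from .util import format_p

__all__ = [
    "SurvivalRecord",
    "pearson_chi_square",
    "kruskal_wallis",
    "km_estimate",
    "logrank_test",
    "median_split",
    "associate",
]


@dataclass(frozen=True)
class SurvivalRecord:
    subject: str
    time: float  # months
    event: bool  # death / metastasis observed (False = censored)
    group: str  # "high" / "low"

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("survival time must be non-negative")


def pearson_chi_square(table) -> tuple[float, float]:
    """Uncorrected Pearson chi-square for an r x c contingency table.

    chi2 = sum (O - E)^2 / E with expectations from the margins, p from
    the chi-square distribution with (r-1)(c-1) df.  Low expected counts
    warn rather than fail (small cells occur in the clinical table).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    if obs.sum() < 1:
        raise ValueError("contingency table is empty")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("contingency table has an empty row or column")
    expected = sps.contingency.expected_freq(obs)
    if np.any(expected < 5):
        warnings.warn(
            "chi-square expected count < 5; the asymptotic p-value may be "
            "inaccurate",
            stacklevel=2,
        )
    chi2, p, _, _ = sps.chi2_contingency(obs, correction=False)
    return float(chi2), float(p)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and p (chi-square, k-1 df)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be nonempty")
    if all(np.array_equal(g, groups[0]) for g in groups[1:]) and all(
        np.unique(g).size == 1 for g in groups
    ):
        # all observations identical: no evidence against the null
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def km_estimate(records) -> dict[str, pd.DataFrame]:
    """Kaplan-Meier product-limit curves per group.

    Returns {group: DataFrame(time, survival)} with the step function
    starting at S(0) = 1; right censoring honored.
    """
    recs = list(records)
    if not recs:
        raise ValueError("no survival records")
    curves: dict[str, pd.DataFrame] = {}
    for group in sorted({r.group for r in recs}):
        sub = [r for r in recs if r.group == group]
        kmf = KaplanMeierFitter()
        kmf.fit(
            durations=[r.time for r in sub],
            event_observed=[r.event for r in sub],
            label=group,
        )
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        curves[group] = sf
    return curves


def logrank_test(records) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi2 statistic, p)."""
    recs = list(records)
    groups = sorted({r.group for r in recs})
    if len(groups) != 2:
        raise ValueError(f"log-rank test needs exactly 2 groups, got {groups}")
    a = [r for r in recs if r.group == groups[0]]
    b = [r for r in recs if r.group == groups[1]]
    res = _lifelines_logrank(
        [r.time for r in a],
        [r.time for r in b],
        event_observed_A=[r.event for r in a],
        event_observed_B=[r.event for r in b],
    )
    return float(res.test_statistic), float(res.p_value)


def median_split(values: pd.Series) -> pd.Series:
    """Split samples at the median value: >= median -> "high", else "low"."""
    values = pd.Series(values)
    if len(values) < 2:
        raise ValueError("need at least 2 samples for a median split")
    cutoff = float(np.median(values.to_numpy(dtype=float)))
    return pd.Series(
        np.where(values.to_numpy(dtype=float) >= cutoff, "high", "low"),
        index=values.index,
    )


def associate(
    clinical: pd.DataFrame,
    group_col: str,
    variables: dict[str, str],
) -> pd.DataFrame:
    """Association report of covariates against a grouping column.

    ``variables`` maps column name -> declared type.  A "numeric"
    covariate is compared across the group levels with the Mann-Whitney U
    test (two levels) or Kruskal-Wallis (three or more); a "categorical"
    covariate is cross-tabulated against the grouping and tested with the
    uncorrected Pearson chi-square.  Missing values are dropped per
    variable with the number of non-missing subjects reported; constant
    covariates are skipped with a flag (p = NaN).
    """
    if group_col not in clinical.columns:
        raise ValueError(f"grouping column {group_col!r} not in table")
    levels = sorted(clinical[group_col].dropna().unique())
    if len(levels) < 2:
        raise ValueError(f"grouping needs >= 2 levels, got {levels}")
    rows = []
    for var, vtype in variables.items():
        if var not in clinical.columns:
            raise ValueError(f"variable {var!r} not in table")
        sub = clinical[[var, group_col]].dropna()
        n = len(sub)
        summary: dict[str, object] = {"variable": var, "type": vtype, "n": n}
        if sub[var].nunique() <= 1:
            summary.update(test="skipped_constant", p=np.nan, p_display="")
            rows.append(summary)
            continue
        if vtype == "numeric":
            samples = [
                sub.loc[sub[group_col] == lev, var].to_numpy(dtype=float)
                for lev in levels
            ]
            if len(levels) == 2:
                p = mwu_test(samples[0], samples[1])
                summary["test"] = "mann_whitney"
            else:
                _, p = kruskal_wallis(samples)
                summary["test"] = "kruskal_wallis"
            summary["p"] = p
            for lev, v in zip(levels, samples):
                summary[f"median_{lev}"] = float(np.median(v))
        elif vtype == "categorical":
            table = pd.crosstab(sub[var], sub[group_col])
            chi2, p = pearson_chi_square(table.to_numpy())
            summary.update(test="pearson_chi_square", statistic=chi2, p=p)
        else:
            raise ValueError(
                f"unknown declared type {vtype!r} for variable {var!r} "
                "(expected 'numeric' or 'categorical')"
            )
        summary["p_display"] = format_p(p)
        rows.append(summary)
    return pd.DataFrame(rows)
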