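"""Association and survival statistics for score / variant / clinical tables.

Categorical associations use Fisher's exact test for 2x2 tables and the
chi-square test otherwise; score correlations use Spearman's rank
correlation; survival contrasts use Kaplan-Meier curves with the two-group
log-rank test; the multivariate overall-survival analysis is ordinary
least squares of OS (months) on dummy-coded covariates with per-covariate
partial correlations.  All tests are two-sided; significance is declared
at p <= 0.05 (:data:`ALPHA`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05  # stated significance level (p <= 0.05)

SUBTYPES = ("HRpos_HER2neg", "HRneg_HER2pos", "TNBC")
METASTASIS = ("none", "at_diagnosis", "follow_up")

__all__ = [
    "ALPHA",
    "ClinicalRecord",
    "read_clinical_table",
    "build_cohort_table",
    "association_test",
    "spearman_correlation",
    "km_logrank",
    "multivariate_os",
]


@dataclass(frozen=True)
class ClinicalRecord:
    sample: str
    subtype: str            # HRpos_HER2neg | HRneg_HER2pos | TNBC
    metastasis: str         # none | at_diagnosis | follow_up
    os_months: float        # months from biopsy to death / last contact
    event: str              # "death" | "censored"

    def __post_init__(self) -> None:
        if self.os_months < 0:
            raise ValueError("os_months must be >= 0")
        if self.subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r}")
        if self.metastasis not in METASTASIS:
            raise ValueError(f"unknown metastasis {self.metastasis!r}")
        if self.event not in ("death", "censored"):
            raise ValueError(f"unknown event {self.event!r}")


def read_clinical_table(path) -> pd.DataFrame:
    """Clinical TSV (sample, subtype, metastasis, os_months, event) -> frame."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    required = ("sample", "subtype", "metastasis", "os_months", "event")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for row in df.itertuples(index=False):  # validates values
        ClinicalRecord(
            sample=str(row.sample),
            subtype=row.subtype,
            metastasis=row.metastasis,
            os_months=float(row.os_months),
            event=row.event,
        )
    return df


def build_cohort_table(
    clinical: pd.DataFrame,
    scores: Optional[pd.DataFrame] = None,
    pathway_status: Optional[pd.DataFrame] = None,
    ctlp_samples: Optional[set[str]] = None,
) -> pd.DataFrame:
    """Join clinical, score-label and variant-status records on sample id.

    One row per sample; rows missing any joined block are flagged
    ``incomplete`` rather than dropped.
    """
    table = clinical.copy()
    if scores is not None:
        table = table.merge(scores, on="sample", how="left")
    if pathway_status is not None:
        ps = pathway_status.rename(columns={"HR": "hr_variant", "MMR": "mmr_variant"})
        table = table.merge(ps.reset_index(), on="sample", how="left")
        for col in ("hr_variant", "mmr_variant"):
            table[col] = table[col].map(lambda v: bool(v) if pd.notna(v) else False)
    if ctlp_samples is not None:
        table["ctlp"] = table["sample"].isin(ctlp_samples)
    table["incomplete"] = table.isna().any(axis=1)
    return table


# ---------------------------------------------------------------------------
# categorical association
# ---------------------------------------------------------------------------

def association_test(
    table_or_df: pd.DataFrame,
    row_factor: Optional[str] = None,
    col_factor: Optional[str] = None,
) -> tuple[float, float, pd.DataFrame]:
    """Fisher's exact test (2x2) or chi-square (larger) between two factors.

    Pass either a prebuilt contingency table, or a cohort table plus the
    two factor column names.  Returns (statistic, p, contingency table);
    for Fisher the statistic is the odds ratio (possibly inf).
    """
    if row_factor is not None or col_factor is not None:
        if row_factor is None or col_factor is None:
            raise ValueError("need both row_factor and col_factor")
        table = pd.crosstab(table_or_df[row_factor], table_or_df[col_factor])
    else:
        table = pd.DataFrame(table_or_df)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError(
            f"factor with a single level: contingency table shape {table.shape}"
        )
    arr = table.to_numpy(dtype=float)
    if arr.shape == (2, 2):
        stat, p = sps.fisher_exact(arr, alternative="two-sided")
    else:
        stat, p, _, _ = sps.chi2_contingency(arr)
    return float(stat), float(p), table


def spearman_correlation(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    p comes from the large-sample t approximation with n-2 degrees of
    freedom.  Constant input -> (nan, nan) with a warning, since rank
    correlation is undefined there.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: Spearman correlation undefined")
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def km_logrank(
    table: pd.DataFrame,
    group_factor: str,
    time_col: str = "os_months",
    event_col: str = "event",
) -> tuple[dict[str, pd.DataFrame], float, float]:
    """Kaplan-Meier curves per group plus the two-group log-rank test.

    ``event`` may be the strings "death"/"censored" or 0/1.  Tied event
    times are handled with the standard multi-death (hypergeometric
    variance) correction.  Returns (curves, chi-square statistic, p).
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    df = table[[group_factor, time_col, event_col]].dropna()
    ev = df[event_col]
    if ev.dtype == object:
        observed = (ev == "death").astype(int)
    else:
        observed = ev.astype(int)
    groups = sorted(df[group_factor].unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {groups}")
    curves: dict[str, pd.DataFrame] = {}
    for g in groups:
        mask = df[group_factor] == g
        if mask.sum() == 0:
            raise ValueError(f"group {g!r} has zero subjects")
        kmf = KaplanMeierFitter()
        kmf.fit(df.loc[mask, time_col], observed[mask], label=str(g))
        curves[str(g)] = kmf.survival_function_
    m0 = df[group_factor] == groups[0]
    res = logrank_test(
        df.loc[m0, time_col],
        df.loc[~m0, time_col],
        observed[m0],
        observed[~m0],
    )
    return curves, float(res.test_statistic), float(res.p_value)


def multivariate_os(
    table: pd.DataFrame,
    covariates: Sequence[str] = ("metastasis", "subtype", "hr_variant"),
    time_col: str = "os_months",
) -> pd.DataFrame:
    """OLS of overall survival on dummy-coded covariates.

    Categorical covariates are reference-cell coded (first level dropped).
    Returns one row per design column with the coefficient, its p-value
    and the partial correlation ``r = t / sqrt(t^2 + df_resid)``.
    Collinear designs raise, naming the aliased columns.
    """
    import statsmodels.api as sm

    df = table[[time_col, *covariates]].dropna()
    if len(df) < len(covariates) + 2:
        raise ValueError("not enough complete-case rows")
    X = pd.get_dummies(df[list(covariates)], drop_first=True, dtype=float).astype(float)
    # detect exact collinearity before fitting
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        aliased = []
        cols = list(X.columns)
        for i in range(1, len(cols) + 1):
            if np.linalg.matrix_rank(X.iloc[:, :i].to_numpy()) < i:
                aliased.append(cols[i - 1])
        raise ValueError(f"collinear design; aliased covariates: {aliased}")
    Xc = sm.add_constant(X)
    fit = sm.OLS(df[time_col].astype(float), Xc).fit()
    dfres = fit.df_resid
    rows = []
    for col in X.columns:
        t = fit.tvalues[col]
        rows.append(
            {
                "covariate": col,
                "coef": fit.params[col],
                "p": fit.pvalues[col],
                "partial_r": t / np.sqrt(t**2 + dfres),
            }
        )
    return pd.DataFrame(rows).set_index("covariate")
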