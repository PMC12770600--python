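"""Group-level statistics on timescale metric tables.

The metric table is tidy: one row per (subject, group, outcome, session,
roi, network) with one column per metric.  On top of it this module
provides the study's statistical layer: Welch's unequal-variance t-tests,
Benjamini-Hochberg FDR correction, Spearman rank correlation between
network-level INT orderings (the timescale-hierarchy comparison),
one-way repeated-measures ANOVA across sessions and a two-way
(outcome x network) ANOVA, plus motion QC summaries.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

from .cohort import SubjectScan, framewise_displacement

__all__ = [
    "ContrastResult",
    "HierarchyResult",
    "welch_t",
    "fdr_bh",
    "spearman_hierarchy",
    "rm_anova_oneway",
    "two_way_anova",
    "network_mean_int",
    "subject_means",
    "qc_summary",
]

METRICS = ("int", "int01", "int05", "acw0", "acw01", "acw05", "hurst")


@dataclass
class ContrastResult:
    statistic: float
    df: float
    p_raw: float
    p_adjusted: float
    label: str

    def __post_init__(self) -> None:
        for p in (self.p_raw, self.p_adjusted):
            if np.isfinite(p) and not 0.0 <= p <= 1.0:
                raise ValueError(f"p-value outside [0, 1]: {p}")


@dataclass(frozen=True)
class HierarchyResult:
    order_a: np.ndarray  # ranks of networks in sample A
    order_b: np.ndarray
    rho: float
    p: float
    p_method: str  # "permutation" or "t-approximation"


def welch_t(group_a: np.ndarray, group_b: np.ndarray, label: str = "") -> ContrastResult:
    """Welch's unequal-variance t-test (two-sided) with Satterthwaite df."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("both groups have zero variance")
    res = sps.ttest_ind(a, b, equal_var=False)
    return ContrastResult(
        statistic=float(res.statistic),
        df=float(res.df),
        p_raw=float(res.pvalue),
        p_adjusted=float("nan"),
        label=label,
    )


def fdr_bh(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _spearman_perm_p(ranks_a: np.ndarray, ranks_b: np.ndarray, rho: float) -> float:
    """Exact two-sided permutation p for small n: fraction of permutations of
    one ranking with |rho| >= |observed|."""
    n = ranks_a.size
    perms = np.array(list(itertools.permutations(range(n))))
    b_perm = ranks_b[perms]  # (n!, n)
    a = ranks_a - ranks_a.mean()
    b_c = b_perm - b_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((a**2).sum() * (b_c**2).sum(axis=1))
    rhos = (b_c @ a) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))


def spearman_hierarchy(
    mean_int_a: np.ndarray | pd.Series, mean_int_b: np.ndarray | pd.Series
) -> HierarchyResult:
    """Spearman correlation between two network-level INT orderings.

    Mid-ranks for ties.  The p-value is an exact permutation test when
    n <= 8 networks, the usual t-approximation otherwise (reported in
    ``p_method``).
    """
    a = np.asarray(mean_int_a, dtype=float)
    b = np.asarray(mean_int_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-d vectors of equal length")
    ranks_a = sps.rankdata(a)
    ranks_b = sps.rankdata(b)
    rho = float(sps.spearmanr(a, b).statistic)
    if a.size <= 8:
        p = _spearman_perm_p(ranks_a, ranks_b, rho)
        method = "permutation"
    else:
        p = float(sps.spearmanr(a, b).pvalue)
        method = "t-approximation"
    return HierarchyResult(order_a=ranks_a, order_b=ranks_b, rho=rho, p=p, p_method=method)


def rm_anova_oneway(
    table: pd.DataFrame,
    metric: str = "int",
    subject: str = "subject",
    within: str = "session",
) -> ContrastResult:
    """One-way repeated-measures ANOVA (no sphericity correction).

    Expects one value per (subject, within-level); with k levels and n
    subjects the F statistic has (k-1, (k-1)(n-1)) degrees of freedom.
    Partitioned sums of squares: total = subjects + within-factor + error.
    """
    df = table[[subject, within, metric]].dropna()
    pivot = df.pivot(index=subject, columns=within, values=metric)
    if pivot.isna().any().any():
        missing = [
            f"{s}/{w}"
            for s in pivot.index
            for w in pivot.columns
            if pd.isna(pivot.loc[s, w])
        ]
        raise ValueError(f"unbalanced design; missing cells: {missing}")
    values = pivot.to_numpy()
    n, k = values.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 within levels")
    grand = values.mean()
    ss_factor = n * np.sum((values.mean(axis=0) - grand) ** 2)
    ss_subject = k * np.sum((values.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((values - grand) ** 2)
    ss_error = ss_total - ss_factor - ss_subject
    df_factor = k - 1
    df_error = (k - 1) * (n - 1)
    ms_error = ss_error / df_error
    if ms_error <= 0:
        f_stat = 0.0 if ss_factor <= 1e-12 else float("inf")
    else:
        f_stat = (ss_factor / df_factor) / ms_error
    p = float(sps.f.sf(f_stat, df_factor, df_error)) if np.isfinite(f_stat) else 0.0
    return ContrastResult(
        statistic=float(f_stat),
        df=float(df_factor),
        p_raw=p,
        p_adjusted=float("nan"),
        label=f"rm-anova {metric} across {within} (df {df_factor},{df_error})",
    )


def two_way_anova(
    table: pd.DataFrame,
    metric: str = "int",
    factor_a: str = "outcome",
    factor_b: str = "network",
) -> list[ContrastResult]:
    """Two-way ANOVA (type-II sums of squares): main effects + interaction."""
    df = table[[factor_a, factor_b, metric]].dropna().copy()
    for f in (factor_a, factor_b):
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f} needs >= 2 levels")
    df = df.rename(columns={metric: "_value"})
    model = ols(f"_value ~ C({factor_a}) * C({factor_b})", data=df).fit()
    try:
        aov = anova_lm(model, typ=2)
    except np.linalg.LinAlgError as err:  # pragma: no cover
        raise ValueError(f"rank-deficient design: {err}") from err
    labels = {
        f"C({factor_a})": factor_a,
        f"C({factor_b})": factor_b,
        f"C({factor_a}):C({factor_b})": f"{factor_a} x {factor_b}",
    }
    results = []
    for term, label in labels.items():
        results.append(
            ContrastResult(
                statistic=float(aov.loc[term, "F"]),
                df=float(aov.loc[term, "df"]),
                p_raw=float(aov.loc[term, "PR(>F)"]),
                p_adjusted=float("nan"),
                label=f"two-way anova {metric}: {label}",
            )
        )
    return results


def subject_means(
    table: pd.DataFrame, metric: str = "int", by_network: bool = False
) -> pd.DataFrame:
    """Subject-level means of one metric, per scan (and per network if asked)."""
    keys = ["subject", "group", "outcome", "session"]
    if by_network:
        keys.append("network")
    # dropna=False: control rows carry the "n/a" outcome, which CSV
    # round-trips may surface as NaN
    return table.groupby(keys, as_index=False, observed=True, dropna=False)[
        metric
    ].mean()


def network_mean_int(
    table: pd.DataFrame, group: str, session: int, metric: str = "int"
) -> pd.DataFrame:
    """Per-network group mean +/- sd of subject-level network means."""
    sel = table[(table["group"] == group) & (table["session"] == session)]
    if sel.empty:
        raise ValueError(f"no rows for group={group}, session={session}")
    per_subject = sel.groupby(["network", "subject"], as_index=False, observed=True)[
        metric
    ].mean()
    out = per_subject.groupby("network", observed=True)[metric].agg(["mean", "std"])
    out["std"] = out["std"].fillna(0.0)  # single-subject groups
    return out.reset_index().rename(columns={"mean": f"{metric}_mean", "std": f"{metric}_sd"})


def qc_summary(
    scans: list[SubjectScan],
    max_translation_mm: float = 1.5,
    max_rotation_deg: float = 1.5,
) -> pd.DataFrame:
    """Per-scan head-motion QC: mean/max framewise displacement and
    per-parameter-class exclusion flags (max |translation| and max
    |rotation| against their thresholds)."""
    rows = []
    for scan in scans:
        motion = scan.motion.to_numpy()
        fd = framewise_displacement(motion)
        rows.append(
            {
                "subject": scan.subject_id,
                "session": scan.session,
                "group": scan.group,
                "mean_fd": fd.mean(),
                "max_fd": fd.max(),
                "max_translation_mm": np.abs(motion[:, :3]).max(),
                "max_rotation_deg": np.abs(motion[:, 3:]).max(),
            }
        )
    out = pd.DataFrame(rows)
    out["exclude"] = (out["max_translation_mm"] > max_translation_mm) | (
        out["max_rotation_deg"] > max_rotation_deg
    )
    return out
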