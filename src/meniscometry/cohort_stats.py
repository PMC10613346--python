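"""Group-comparison and reliability statistics for per-knee measurements.

Implements the study-style statistical layer from first principles:

* Mann-Whitney U with an exact rank-sum-enumeration p-value for small
  tie-free samples (combined n <= 16) and a tie-corrected,
  continuity-corrected normal approximation otherwise;
* Pearson chi-square on 2x2 tables with Yates continuity correction (the
  corrected term is floored at zero), alongside the uncorrected statistic;
* ICC(2,1): two-way random effects, absolute agreement, single measures,
  with the F-based 95% confidence interval.

These are intentionally independent of the equivalent scipy/pingouin
routines so the test suite can cross-validate both ways.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateVarianceError, IncompleteGridError
from .volume_io import RatingTable

EXACT_MAX_N = 16  # combined sample size above which the normal approximation kicks in


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _ranksum_counts(n_total: int, n1: int) -> np.ndarray:
    """counts[s] = number of n1-subsets of ranks 1..n_total with rank sum s."""
    max_sum = n_total * (n_total + 1) // 2
    # dp[k][s]: subsets of size k with sum s, over items 1..i
    dp = np.zeros((n1 + 1, max_sum + 1), dtype=np.int64)
    dp[0, 0] = 1
    for item in range(1, n_total + 1):
        for k in range(min(item, n1), 0, -1):
            dp[k, item:] += dp[k - 1, : max_sum + 1 - item]
    return dp[n1]


def _exact_two_sided_p(u1: float, n1: int, n2: int) -> float:
    counts = _ranksum_counts(n1 + n2, n1)
    total = counts.sum()
    offset = n1 * (n1 + 1) // 2  # U1 = ranksum - offset
    u = np.arange(counts.size) - offset
    u_min = min(u1, n1 * n2 - u1)
    p = 2.0 * counts[u <= u_min + 1e-9].sum() / total
    return float(min(p, 1.0))


@dataclass
class MannWhitneyResult:
    u: float
    p: float
    method: str  # 'exact' | 'normal-approximation'


def mann_whitney(x, y) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration p when the combined sample is small (<= 16) and
    tie-free; otherwise a normal approximation with midranks, tie
    correction and a 0.5 continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    combined = np.r_[x, y]
    ranks = sps.rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2
    u_stat = float(min(u1, n1 * n2 - u1))

    has_ties = np.unique(combined).size < combined.size
    if not has_ties and n1 + n2 <= EXACT_MAX_N:
        return MannWhitneyResult(u=u_stat, p=_exact_two_sided_p(u1, n1, n2), method="exact")

    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return MannWhitneyResult(u=u_stat, p=1.0, method="normal-approximation")
    z = max(abs(u1 - n1 * n2 / 2.0) - 0.5, 0.0) / np.sqrt(sigma2)
    p = float(min(2.0 * sps.norm.sf(z), 1.0))
    return MannWhitneyResult(u=u_stat, p=p, method="normal-approximation")


# ---------------------------------------------------------------------------
# Chi-square on 2x2 tables
# ---------------------------------------------------------------------------


def _checked_2x2(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table entries must be non-negative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("all margins must be > 0")
    return t


def chi2_yates(table) -> tuple[float, float]:
    """Pearson chi-square with Yates continuity correction on a 2x2 table.

    The corrected deviation ``|O - E| - 0.5`` is floored at 0, so a table
    already at independence yields stat = 0, p = 1.
    """
    t = _checked_2x2(table)
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    dev = np.maximum(np.abs(t - expected) - 0.5, 0.0)
    stat = float((dev**2 / expected).sum())
    return stat, float(sps.chi2.sf(stat, df=1))


def chi2_pearson(table) -> tuple[float, float]:
    """Uncorrected Pearson chi-square on a 2x2 table (df = 1)."""
    t = _checked_2x2(table)
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    stat = float(((t - expected) ** 2 / expected).sum())
    return stat, float(sps.chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# Intraclass correlation
# ---------------------------------------------------------------------------


@dataclass
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    model: str
    kind: str  # 'inter' | 'intra'

    def __post_init__(self) -> None:
        if not (-1 - 1e-9 <= self.icc <= 1 + 1e-9):
            raise ValueError("icc out of [-1, 1]")
        if not (self.ci_low <= self.icc + 1e-9 and self.icc - 1e-9 <= self.ci_high):
            raise ValueError("CI does not bracket the estimate")


def icc(table: RatingTable, kind: str = "inter", alpha: float = 0.05) -> IccResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    For ``kind='intra'`` the table's rater axis holds repeated sessions of a
    single rater; the algebra is identical, only the label differs.
    """
    if kind not in ("inter", "intra"):
        raise ValueError("kind must be 'inter' or 'intra'")
    vals = np.asarray(table.values, dtype=float)
    if np.isnan(vals).any():
        raise IncompleteGridError("rating grid contains missing values")
    k, n = vals.shape
    if k < 2:
        raise ValueError("need >= 2 raters (inter) or >= 2 sessions (intra)")
    if n < 5:
        raise ValueError("need >= 5 subjects for a meaningful ICC")

    data = vals.T  # subjects x raters
    grand = data.mean()
    subj_means = data.mean(axis=1)
    rater_means = data.mean(axis=0)
    if np.allclose(subj_means, subj_means[0]):
        raise DegenerateVarianceError("zero between-subject variance; ICC undefined")

    ss_subj = k * ((subj_means - grand) ** 2).sum()
    ss_rater = n * ((rater_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_subj - ss_rater
    msr = ss_subj / (n - 1)
    msc = ss_rater / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    icc_val = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    model = "ICC(2,1) two-way random, absolute agreement, single measures"

    if mse <= 1e-300 and msc <= 1e-300:
        # perfect agreement: the F-based interval degenerates
        return IccResult(icc=1.0, ci_low=1.0, ci_high=1.0, model=model, kind=kind)

    # F-based CI (two-way random, absolute agreement, single measures)
    r = icc_val
    a = k * r / (n * (1 - r))
    b = 1 + k * r * (n - 1) / (n * (1 - r))
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    return IccResult(
        icc=float(icc_val),
        ci_low=float(min(lower, icc_val)),
        ci_high=float(max(upper, icc_val)),
        model=model,
        kind=kind,
    )


# ---------------------------------------------------------------------------
# Report layer
# ---------------------------------------------------------------------------


@dataclass
class GroupComparison:
    parameter: str
    group1: str
    group2: str
    n1: int
    n2: int
    mean1: float
    sd1: float
    mean2: float
    sd2: float
    u: float
    p: float
    method: str

    def __post_init__(self) -> None:
        if self.sd1 < 0 or self.sd2 < 0:
            raise ValueError("sd must be >= 0")
        if not (0 < self.p <= 1):
            raise ValueError("p must lie in (0, 1]")


@dataclass
class CategoricalComparison:
    parameter: str
    table: np.ndarray
    stat_yates: float
    p_yates: float
    stat_pearson: float
    p_pearson: float
    note: str = ""


def _describe(sample: np.ndarray) -> tuple[float, float]:
    sample = np.asarray(sample, dtype=float)
    sd = float(sample.std(ddof=1)) if sample.size > 1 else 0.0
    return float(sample.mean()), sd


def _two_group_rows(
    df: pd.DataFrame, group_col: str, params: tuple[str, ...]
) -> list[GroupComparison]:
    groups = sorted(df[group_col].dropna().unique())
    if len(groups) != 2:
        raise ValueError(
            f"need exactly two groups in column {group_col!r}, found {groups!r}"
        )
    g1, g2 = groups
    out = []
    for param in params:
        x = df.loc[df[group_col] == g1, param].astype(float).to_numpy()
        y = df.loc[df[group_col] == g2, param].astype(float).to_numpy()
        mw = mann_whitney(x, y)
        m1, s1 = _describe(x)
        m2, s2 = _describe(y)
        out.append(
            GroupComparison(
                parameter=param, group1=str(g1), group2=str(g2),
                n1=x.size, n2=y.size, mean1=m1, sd1=s1, mean2=m2, sd2=s2,
                u=mw.u, p=mw.p, method=mw.method,
            )
        )
    return out


def compare_groups(
    df: pd.DataFrame,
    group_col: str = "group",
    params: tuple[str, ...] = ("rmt", "pcm", "lm_ratio"),
    categorical: str | None = None,
) -> list[GroupComparison | CategoricalComparison]:
    """Index-by-index two-group comparison (Mann-Whitney), optionally with a
    chi-square comparison of one binary demographic column.

    Row order and group naming do not affect any output.
    """
    results: list[GroupComparison | CategoricalComparison] = list(
        _two_group_rows(df, group_col, params)
    )
    if categorical is not None:
        if categorical not in df.columns:
            raise ValueError(f"categorical column {categorical!r} absent")
        ct = pd.crosstab(df[group_col], df[categorical]).to_numpy()
        stat_y, p_y = chi2_yates(ct)
        stat_p, p_p = chi2_pearson(ct)
        note = ""
        if abs(p_y - p_p) > 0.01:
            note = (
                "continuity-corrected and uncorrected p differ; "
                "report which statistic a cited p-value refers to"
            )
        results.append(
            CategoricalComparison(
                parameter=categorical, table=ct,
                stat_yates=stat_y, p_yates=p_y,
                stat_pearson=stat_p, p_pearson=p_p, note=note,
            )
        )
    return results


def subgroup_comparisons(
    df: pd.DataFrame,
    within_group: str = "DLM",
    params: tuple[str, ...] = ("rmt", "pcm", "lm_ratio"),
) -> dict[str, list[GroupComparison]]:
    """Tear +/- and complete/incomplete splits inside the discoid group."""
    sub = df[df["group"] == within_group]
    out: dict[str, list[GroupComparison]] = {}
    for col in ("tear", "dlm_type"):
        if col not in df.columns:
            raise ValueError(f"subgroup column {col!r} absent")
        usable = sub[sub[col] != "na"]
        if usable[col].nunique() == 2:
            out[col] = _two_group_rows(usable, col, params)
    return out


def render_report(results, subgroups=None) -> str:
    """Human-readable text tables (mean +/- SD per group, U, p)."""
    lines: list[str] = []

    def emit(title: str, rows: list[GroupComparison]) -> None:
        if not rows:
            return
        r0 = rows[0]
        lines.append(title)
        lines.append(
            f"{'parameter':<10} {r0.group1 + ' (n=' + str(r0.n1) + ')':>22} "
            f"{r0.group2 + ' (n=' + str(r0.n2) + ')':>22} {'U':>8} {'p':>10}  method"
        )
        for r in rows:
            lines.append(
                f"{r.parameter:<10} {r.mean1:>12.3f} ± {r.sd1:<6.3f} "
                f"{r.mean2:>13.3f} ± {r.sd2:<6.3f} {r.u:>8.1f} {r.p:>10.4g}  {r.method}"
            )
        lines.append("")

    numeric = [r for r in results if isinstance(r, GroupComparison)]
    emit("Group comparison", numeric)
    for r in results:
        if isinstance(r, CategoricalComparison):
            lines.append(f"{r.parameter} contingency {r.table.tolist()}")
            lines.append(
                f"  chi2 (Yates) = {r.stat_yates:.3f}, p = {r.p_yates:.3f}; "
                f"uncorrected chi2 = {r.stat_pearson:.3f}, p = {r.p_pearson:.3f}"
            )
            if r.note:
                lines.append(f"  note: {r.note}")
            lines.append("")
    for name, rows in (subgroups or {}).items():
        emit(f"Subgroup comparison by {name}", rows)
    return "\n".join(lines)


def comparisons_to_frame(results) -> pd.DataFrame:
    """Flatten GroupComparison rows into a tidy DataFrame for CSV export."""
    rows = []
    for r in results:
        if isinstance(r, GroupComparison):
            rows.append(
                {
                    "parameter": r.parameter,
                    "group1": r.group1, "n1": r.n1, "mean1": r.mean1, "sd1": r.sd1,
                    "group2": r.group2, "n2": r.n2, "mean2": r.mean2, "sd2": r.sd2,
                    "U": r.u, "p": r.p, "method": r.method,
                }
            )
        else:
            rows.append(
                {
                    "parameter": r.parameter,
                    "U": r.stat_yates, "p": r.p_yates,
                    "method": "chi2-yates (uncorrected p=%.4g)" % r.p_pearson,
                }
            )
    return pd.DataFrame(rows)
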