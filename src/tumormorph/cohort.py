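"""Caliper tumor volumes, growth-curve summaries and group statistics.

Subcutaneous xenograft volume from a caliper pair follows the standard
ellipsoid approximation V = a*b^2 / 2 with a the longest and b the shortest
diameter (mm -> mm^3). Group data are summarized as mean +/- SEM per arm and
day. Small-sample comparisons use the exact Mann-Whitney U test (full
enumeration over group labelings); comparisons available only as printed
summaries use a Welch t test computed from means, SEMs and group sizes;
multi-arm comparisons use one-way ANOVA. All p-values are two-sided and no
multiple-testing correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "tumor_volume",
    "add_volumes",
    "summarize",
    "mann_whitney_exact",
    "welch_t_from_summary",
    "anova_oneway",
    "growth_report",
    "GrowthReport",
]

COHORT_COLUMNS = ["group", "animal_id", "day", "length_mm", "width_mm", "weight_g"]


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_two_sided: float
    df: float | None = None


# ---------------------------------------------------------------------------
# Volumes and summaries
# ---------------------------------------------------------------------------

def tumor_volume(a: float, b: float) -> float:
    """Ellipsoid caliper volume a*b^2/2 (mm^3).

    ``a`` is the longest diameter; if a < b the inputs are swapped with a
    warning — a common caliper orientation slip, not a reason to drop the row.
    """
    if a <= 0 or b <= 0:
        raise ValueError(f"caliper diameters must be positive, got ({a}, {b})")
    if a < b:
        warnings.warn(f"length {a} < width {b}; swapping (caliper orientation)")
        a, b = b, a
    return a * b * b / 2.0


def add_volumes(cohort: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of a cohort table with a ``volume_mm3`` column."""
    df = cohort.copy()
    a = df[["length_mm", "width_mm"]].max(axis=1)
    b = df[["length_mm", "width_mm"]].min(axis=1)
    if (df["length_mm"] < df["width_mm"]).any():
        warnings.warn("rows with length < width encountered; swapped for volume")
    if (b <= 0).any():
        raise ValueError("non-positive caliper diameter in cohort table")
    df["volume_mm3"] = a * b * b / 2.0
    return df


def summarize(cohort: pd.DataFrame, value: str = "volume_mm3") -> pd.DataFrame:
    """Per (group, day): n, mean and SEM of ``value``.

    SEM uses the n-1 sample SD and is NaN (undefined) for single-animal
    cells. Volumes are derived from the caliper pairs if absent.
    """
    df = cohort if value in cohort.columns else add_volumes(cohort)
    sub = df.dropna(subset=[value])
    g = sub.groupby(["group", "day"], sort=True)[value]
    out = g.agg(n="count", mean="mean", sem=lambda v: v.sem(ddof=1)).reset_index()
    out["n"] = out["n"].astype(int)
    return out


# ---------------------------------------------------------------------------
# Two-sample and k-sample tests
# ---------------------------------------------------------------------------

def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def mann_whitney_exact(x, y, *, exact_max_n: int = 20) -> TestResult:
    """Two-sided Mann-Whitney U test, exact for small samples.

    For n1 + n2 <= ``exact_max_n`` the null distribution is enumerated over
    all C(n1+n2, n1) group labelings of the pooled midranks (ties handled by
    midranks; enumeration runs over distinguishable labelings). The statistic
    is U = min(U1, U2) and the exact two-sided p-value is the proportion of
    labelings with U <= observed — an exact rational with denominator
    dividing C(n1+n2, n1). Larger samples fall back to the tie-corrected
    normal approximation.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    if n1 + n2 > exact_max_n:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        u = min(float(res.statistic), n1 * n2 - float(res.statistic))
        return TestResult("mann_whitney_exact", u, float(res.pvalue))

    ranks = _midranks(np.concatenate([x, y]))
    r1_obs = float(ranks[:n1].sum())
    u1_obs = r1_obs - n1 * (n1 + 1) / 2.0
    u_obs = min(u1_obs, n1 * n2 - u1_obs)

    hits = 0
    total = comb(n1 + n2, n1)
    # tolerance absorbs float midrank sums; ranks are multiples of 1/2 so
    # any real tie in U is exact in binary floating point anyway
    eps = 1e-9
    for idx in combinations(range(n1 + n2), n1):
        r1 = ranks[list(idx)].sum()
        u1 = r1 - n1 * (n1 + 1) / 2.0
        u = min(u1, n1 * n2 - u1)
        if u <= u_obs + eps:
            hits += 1
    p = Fraction(hits, total)
    return TestResult("mann_whitney_exact", float(u_obs), float(p))


def welch_t_from_summary(
    m1: float,
    sem1: float,
    n1: int,
    m2: float,
    sem2: float,
    n2: int,
    *,
    equal_var: bool = False,
) -> TestResult:
    """Two-sample t test computed from group means, SEMs and sizes.

    Welch by default: t = (m1 - m2) / sqrt(sem1^2 + sem2^2) with
    Welch-Satterthwaite degrees of freedom. ``equal_var=True`` gives the
    pooled (Student) variant with df = n1 + n2 - 2. This is the test
    applicable when only printed summary statistics are available.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sem1 < 0 or sem2 < 0:
        raise ValueError("SEMs must be non-negative")
    if sem1 == 0 and sem2 == 0:
        if m1 == m2:
            name = "student_t" if equal_var else "welch_t_from_summary"
            return TestResult(name, 0.0, 1.0, float(n1 + n2 - 2))
        raise ValueError("zero SEMs with unequal means: degenerate comparison")

    if equal_var:
        s1sq, s2sq = sem1**2 * n1, sem2**2 * n2
        sp2 = ((n1 - 1) * s1sq + (n2 - 1) * s2sq) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = float(n1 + n2 - 2)
        name = "student_t"
    else:
        se = np.sqrt(sem1**2 + sem2**2)
        df = (sem1**2 + sem2**2) ** 2 / (
            sem1**4 / (n1 - 1) + sem2**4 / (n2 - 1)
        )
        name = "welch_t_from_summary"
    t = (m1 - m2) / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TestResult(name, float(t), min(p, 1.0), float(df))


def anova_oneway(groups) -> TestResult:
    """Classical one-way ANOVA F test across >= 2 groups (each n >= 2)."""
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    if all(np.ptp(g) == 0 for g in groups):
        raise ValueError("zero within-group variance everywhere: F undefined")
    f, p = stats.f_oneway(*groups)
    return TestResult("anova_oneway", float(f), float(p))


# ---------------------------------------------------------------------------
# Growth report
# ---------------------------------------------------------------------------

@dataclass
class GrowthReport:
    """Tidy growth-curve statistics.

    per_day : day x arm table (n, mean, sem, p vs control by exact
        Mann-Whitney); ``first_significant_day`` per arm is the earliest day
        with p < alpha.
    final_pairwise : all arm-pair comparisons of final-day volume and (when
        present) weight.
    """

    per_day: pd.DataFrame
    final_pairwise: pd.DataFrame
    first_significant_day: dict[str, int | None]
    control: str
    alpha: float = 0.05


def growth_report(cohort: pd.DataFrame, control: str, alpha: float = 0.05) -> GrowthReport:
    """Compare every treated arm against the control arm over time.

    Per (day, non-control arm): group n/mean/SEM and the exact Mann-Whitney
    p-value against the control volumes of that day (days missing control
    measurements are flagged with a NaN p, not fatal). The final study day
    adds all pairwise arm comparisons for volume and final weight.
    """
    df = add_volumes(cohort)
    arms = sorted(df["group"].unique())
    if control not in arms:
        raise ValueError(f"control group {control!r} not present (arms: {arms})")
    summ = summarize(df).set_index(["group", "day"])

    rows = []
    first_sig: dict[str, int | None] = {a: None for a in arms if a != control}
    for day in sorted(df["day"].unique()):
        ctrl_v = df.loc[(df["group"] == control) & (df["day"] == day), "volume_mm3"]
        for arm in arms:
            if arm == control:
                continue
            v = df.loc[(df["group"] == arm) & (df["day"] == day), "volume_mm3"]
            if v.empty:
                continue
            if ctrl_v.empty:
                p, test = np.nan, "missing_control"
            else:
                res = mann_whitney_exact(v.to_numpy(), ctrl_v.to_numpy())
                p, test = res.p_two_sided, res.test_name
            s = summ.loc[(arm, day)]
            rows.append(
                {
                    "day": int(day),
                    "group": arm,
                    "n": int(s["n"]),
                    "mean_mm3": float(s["mean"]),
                    "sem_mm3": float(s["sem"]) if np.isfinite(s["sem"]) else np.nan,
                    "p_vs_control": p,
                    "test": test,
                }
            )
            if first_sig[arm] is None and np.isfinite(p) and p < alpha:
                first_sig[arm] = int(day)
    per_day = pd.DataFrame(rows, columns=["day", "group", "n", "mean_mm3", "sem_mm3", "p_vs_control", "test"])

    final_day = int(df["day"].max())
    fin = df[df["day"] == final_day]
    pair_rows = []
    for g1, g2 in combinations(arms, 2):
        for metric, col in [("volume_mm3", "volume_mm3"), ("weight_g", "weight_g")]:
            a = fin.loc[fin["group"] == g1, col].dropna()
            b = fin.loc[fin["group"] == g2, col].dropna()
            if a.empty or b.empty:
                continue
            res = mann_whitney_exact(a.to_numpy(), b.to_numpy())
            pair_rows.append(
                {
                    "comparison": f"{g1}_vs_{g2}",
                    "metric": metric,
                    "day": final_day,
                    "p": res.p_two_sided,
                    "test": res.test_name,
                }
            )
    final_pairwise = pd.DataFrame(pair_rows, columns=["comparison", "metric", "day", "p", "test"])
    return GrowthReport(per_day, final_pairwise, first_sig, control, alpha)
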