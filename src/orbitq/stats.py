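"""Cohort statistics: group summaries, mixed ANOVA with laterality,
Dunnett many-to-one post-hoc tests, Pearson correlations, healthy-mean
normalisation and 2-SD outlier-muscle categorisation.

The unit of analysis is a tidy table with one row per patient x eye x
muscle carrying ``volume_mm3``, ``fat_fraction`` and ``t2water_ms`` plus
``group``.  Group comparisons use a two-way mixed ANOVA with the
between-subjects factor *group* and the within-subjects (repeated)
factor *laterality* (left/right eye), followed by Dunnett's test of each
patient group against a reference (healthy) group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, optimize, special, stats as sps

from .core import MUSCLES

__all__ = [
    "group_summary",
    "table2_summary",
    "rm_anova_laterality",
    "dunnett_posthoc",
    "dunnett_critical_value",
    "pearson_with_p",
    "HealthyReference",
    "healthy_reference",
    "normalize_to_healthy",
    "sd_band_counts",
    "age_anova",
    "sex_chi2",
]

METRICS = ("volume_mm3", "fat_fraction", "t2water_ms")


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def group_summary(
    table: pd.DataFrame,
    metric: str,
    pool_eyes: bool = True,
) -> pd.DataFrame:
    """Per-group per-muscle mean and SD of one metric.

    With ``pool_eyes`` (default) the left and right eye each contribute
    an observation; otherwise eyes are averaged within patient first.
    Empty cells are flagged with NaN, and single-observation cells get a
    NaN (undefined) SD.
    """
    if metric not in table.columns:
        raise KeyError(f"metric column {metric!r} not in table")
    df = table
    if not pool_eyes:
        df = (
            table.groupby(["group", "muscle", "patient_id"], as_index=False)[metric]
            .mean()
        )
    g = df.groupby(["group", "muscle"])[metric]
    out = g.agg(mean="mean", sd="std", n="count").reset_index()
    return out


def table2_summary(table: pd.DataFrame, pool_eyes: bool = True) -> pd.DataFrame:
    """Summary-table reproduction: mean +/- SD for all metrics and muscles."""
    pieces = []
    for metric in METRICS:
        s = group_summary(table, metric, pool_eyes=pool_eyes)
        s.insert(0, "metric", metric)
        pieces.append(s)
    return pd.concat(pieces, ignore_index=True)


# ---------------------------------------------------------------------------
# Mixed ANOVA (between: group, within: laterality)
# ---------------------------------------------------------------------------

def _paired_eyes(
    table: pd.DataFrame, metric: str, muscle: str | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    df = table
    if muscle is not None:
        df = df[df["muscle"] == muscle]
    wide = df.pivot_table(
        index=["group", "patient_id"], columns="eye", values=metric
    )
    if not {"L", "R"} <= set(wide.columns):
        raise ValueError("both eyes required for the repeated measure")
    wide = wide.dropna(subset=["L", "R"])  # complete-case
    groups = wide.index.get_level_values("group").to_numpy()
    return wide["L"].to_numpy(float), wide["R"].to_numpy(float), groups


def rm_anova_laterality(
    table: pd.DataFrame,
    metric: str,
    muscle: str | None = None,
    min_group_size: int = 2,
) -> pd.DataFrame:
    """Two-way mixed ANOVA: between factor group, within factor laterality.

    Complete-case: patients missing either eye are dropped; groups with
    fewer than ``min_group_size`` patients are excluded with a warning.
    Returns a table with sums of squares, degrees of freedom, F and p for
    the group, laterality and interaction effects plus both error terms.

    The two-level repeated measure makes the decomposition exact: the
    between-subjects part is a one-way ANOVA on the eye means (times 2)
    and the within part an ANOVA on the left-right differences (halved);
    the five sums of squares partition the total exactly.
    """
    left, right, groups = _paired_eyes(table, metric, muscle)
    names, counts = np.unique(groups, return_counts=True)
    small = names[counts < min_group_size]
    if small.size:
        warnings.warn(
            f"groups excluded with < {min_group_size} patients: {list(small)}",
            stacklevel=2,
        )
        keep = ~np.isin(groups, small)
        left, right, groups = left[keep], right[keep], groups[keep]
        names = names[~np.isin(names, small)]
    if names.size < 2:
        raise ValueError("need at least two groups for the ANOVA")
    return _mixed_anova_arrays(left, right, groups)


def _mixed_anova_arrays(
    left: np.ndarray, right: np.ndarray, groups: np.ndarray
) -> pd.DataFrame:
    """Sums-of-squares mixed ANOVA on per-patient (left, right) pairs."""
    m = (left + right) / 2.0
    d = left - right
    names, inv, counts = np.unique(groups, return_inverse=True, return_counts=True)
    k, n = names.size, m.size

    grand_m = m.mean()
    group_m = np.bincount(inv, weights=m) / counts
    ss_group = 2.0 * float(np.sum(counts * (group_m - grand_m) ** 2))
    ss_subj = 2.0 * float(np.sum((m - group_m[inv]) ** 2))

    grand_d = d.mean()
    group_d = np.bincount(inv, weights=d) / counts
    ss_lat = n * grand_d**2 / 2.0
    ss_inter = float(np.sum(counts * (group_d - grand_d) ** 2)) / 2.0
    ss_werr = float(np.sum((d - group_d[inv]) ** 2)) / 2.0

    df_group, df_subj = k - 1, n - k
    df_lat, df_inter, df_werr = 1, k - 1, n - k

    def f_and_p(ss, dfn, ss_err, dfe):
        if ss_err <= 0:
            if ss <= 0:
                return 0.0, 1.0
            return np.inf, 0.0
        f = (ss / dfn) / (ss_err / dfe)
        return float(f), float(sps.f.sf(f, dfn, dfe))

    f_g, p_g = f_and_p(ss_group, df_group, ss_subj, df_subj)
    f_l, p_l = f_and_p(ss_lat, df_lat, ss_werr, df_werr)
    f_i, p_i = f_and_p(ss_inter, df_inter, ss_werr, df_werr)

    return pd.DataFrame(
        {
            "source": ["group", "subjects(group)", "laterality",
                       "group:laterality", "laterality error"],
            "ss": [ss_group, ss_subj, ss_lat, ss_inter, ss_werr],
            "df": [df_group, df_subj, df_lat, df_inter, df_werr],
            "F": [f_g, np.nan, f_l, f_i, np.nan],
            "p": [p_g, np.nan, p_l, p_i, np.nan],
        }
    )


# ---------------------------------------------------------------------------
# Dunnett
# ---------------------------------------------------------------------------

def dunnett_posthoc(
    table: pd.DataFrame,
    metric: str,
    muscle: str | None = None,
    reference_group: str = "healthy",
    pool_eyes: bool = True,
    seed: int | None = None,
) -> pd.DataFrame:
    """Dunnett many-to-one comparisons of each group against a reference.

    Adjusted p-values come from the multivariate-t distribution of the
    maximum statistic over comparisons, with the error term pooled over
    all groups.  Returns one row per non-reference group with the mean
    difference, statistic and adjusted p.
    """
    df = table if muscle is None else table[table["muscle"] == muscle]
    if not pool_eyes:
        df = (
            df.groupby(["group", "patient_id"], as_index=False)[metric].mean()
        )
    groups = [g for g in df["group"].unique() if g != reference_group]
    control = df.loc[df["group"] == reference_group, metric].dropna().to_numpy()
    if control.size == 0:
        raise ValueError(f"reference group {reference_group!r} is empty")
    if not groups:
        raise ValueError("need at least one non-reference group")
    samples = [
        df.loc[df["group"] == g, metric].dropna().to_numpy() for g in groups
    ]
    rng = np.random.default_rng(seed)
    res = sps.dunnett(*samples, control=control, random_state=rng)
    return pd.DataFrame(
        {
            "group": groups,
            "mean_diff": [s.mean() - control.mean() for s in samples],
            "statistic": res.statistic,
            "p_adjusted": res.pvalue,
        }
    )


def dunnett_critical_value(
    k: int,
    df: int,
    alpha: float = 0.05,
    two_sided: bool = True,
) -> float:
    """Critical value of Dunnett's many-to-one test, balanced design.

    For ``k`` treatment groups compared against a common control with
    equal sample sizes, the comparison statistics share correlation 1/2;
    the critical value c solves ``P(max_i |T_i| <= c) = 1 - alpha``.
    Computed by direct numerical integration over the control variate z
    and the scaled-chi error term s:

        P(c) = E_{z,s}[ (Phi(z + sqrt(2) c s) - Phi(z - sqrt(2) c s))^k ]

    (one-sided: the lower bound is -inf).
    """
    if k < 1 or df < 1:
        raise ValueError("k and df must be >= 1")
    # Gauss-Legendre nodes for z on [-9, 9]
    zs, wz = np.polynomial.legendre.leggauss(160)
    zs, wz = zs * 9.0, wz * 9.0
    phi_z = np.exp(-0.5 * zs**2) / np.sqrt(2 * np.pi)
    # s = sqrt(chi2_df / df): integrate on [0, s_max]
    s_max = 1.0 + 10.0 / np.sqrt(df)
    ss, ws = np.polynomial.legendre.leggauss(160)
    ss = (ss + 1.0) * s_max / 2.0
    ws = ws * s_max / 2.0
    log_norm = (
        np.log(2.0) + 0.5 * df * np.log(df / 2.0) - special.gammaln(df / 2.0)
    )
    f_s = np.exp(log_norm + (df - 1) * np.log(np.maximum(ss, 1e-300))
                 - df * ss**2 / 2.0)

    def coverage(c: float) -> float:
        arg = np.sqrt(2.0) * c * ss  # (s,)
        upper = sps.norm.cdf(zs[None, :] + arg[:, None])
        lower = (
            sps.norm.cdf(zs[None, :] - arg[:, None]) if two_sided else 0.0
        )
        inner = ((upper - lower) ** k * phi_z[None, :]) @ wz
        return float((f_s * inner) @ ws)

    return float(
        optimize.brentq(lambda c: coverage(c) - (1.0 - alpha), 0.5, 10.0)
    )


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

def pearson_with_p(x, y) -> tuple[float, float]:
    """Sample Pearson r with the two-sided t-based p-value.

    Zero-variance input yields (nan, nan) rather than an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Healthy reference, normalisation and 2-SD bands
# ---------------------------------------------------------------------------

@dataclass
class HealthyReference:
    """Per-muscle mean and SD of each metric over healthy controls."""

    mean: pd.DataFrame  # index muscle, columns METRICS
    sd: pd.DataFrame


def healthy_reference(
    table: pd.DataFrame, healthy_group: str = "healthy"
) -> HealthyReference:
    h = table[table["group"] == healthy_group]
    if h.empty:
        raise ValueError(f"no rows for healthy group {healthy_group!r}")
    cols = [m for m in METRICS if m in table.columns]
    g = h.groupby("muscle")[cols]
    return HealthyReference(mean=g.mean(), sd=g.std())


def normalize_to_healthy(
    table: pd.DataFrame,
    reference: HealthyReference,
    metric: str = "volume_mm3",
) -> pd.Series:
    """Metric divided by the healthy mean of the same muscle.

    Corrects for anatomical size differences between muscles so that
    different muscles can be pooled; row order is preserved.
    """
    missing = set(table["muscle"].unique()) - set(reference.mean.index)
    if missing:
        raise ValueError(f"reference missing muscles: {sorted(missing)}")
    ref = reference.mean[metric]
    return table[metric] / table["muscle"].map(ref).astype(float)


def sd_band_counts(
    table: pd.DataFrame,
    reference: HealthyReference,
    metric: str = "volume_mm3",
    n_sd: float = 2.0,
    per_eye: bool = True,
) -> pd.DataFrame:
    """Patients with 0 / 1 / 2+ muscles outside the healthy 2-SD band.

    A muscle (x eye, by default 8 per patient) counts as out-of-band
    when its value falls outside ``healthy mean +/- n_sd SD`` for that
    muscle.  Returns one row per patient with the out-of-band count and
    its category.  Missing muscle rows are skipped with a warning.
    """
    df = table
    if not per_eye:
        df = (
            table.groupby(
                ["group", "patient_id", "muscle"], as_index=False
            )[metric].mean()
        )
    mu = df["muscle"].map(reference.mean[metric]).astype(float)
    sd = df["muscle"].map(reference.sd[metric]).astype(float)
    out_of_band = (df[metric] < mu - n_sd * sd) | (df[metric] > mu + n_sd * sd)

    expected = len(MUSCLES) * (2 if per_eye else 1)
    per_patient = (
        df.assign(out=out_of_band)
        .groupby(["group", "patient_id"])
        .agg(n_out=("out", "sum"), n_obs=("out", "size"))
        .reset_index()
    )
    short = per_patient[per_patient["n_obs"] < expected]
    if not short.empty:
        warnings.warn(
            f"{len(short)} patients with missing muscle rows; "
            "missing muscles skipped",
            stacklevel=2,
        )
    per_patient["category"] = np.select(
        [per_patient["n_out"] == 0, per_patient["n_out"] == 1],
        ["0", "1"],
        default="2+",
    )
    return per_patient


# ---------------------------------------------------------------------------
# Baseline characteristics (standard convenience tests)
# ---------------------------------------------------------------------------

def age_anova(table: pd.DataFrame) -> tuple[float, float]:
    """One-way ANOVA of age across groups (one row per patient)."""
    per_patient = table.groupby(["group", "patient_id"], as_index=False)["age"].first()
    samples = [g["age"].to_numpy() for _, g in per_patient.groupby("group")]
    f, p = sps.f_oneway(*samples)
    return float(f), float(p)


def sex_chi2(table: pd.DataFrame) -> tuple[float, float]:
    """Chi-square test of the sex distribution across groups."""
    per_patient = table.groupby(["group", "patient_id"], as_index=False)["sex"].first()
    counts = pd.crosstab(per_patient["group"], per_patient["sex"])
    chi2, p, _, _ = sps.chi2_contingency(counts)
    return float(chi2), float(p)
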