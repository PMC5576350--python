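"""Cohort-level statistics over per-hip orientation measurements.

The sampling unit is the hip (both hips of a case enter independently;
within-patient correlation between sides is ignored, a documented
limitation).  The analysis pipeline mirrors standard orthopaedic
practice: Kolmogorov–Smirnov normality screening with parameters
estimated from the sample (Lilliefors correction), a rank-based Blom
transformation for measurements that fail it, one-sample t tests of
reference-plane angles against 90°, sex/age subgroup comparisons, and a
one-way ANOVA across the three measurement systems with Fisher's LSD
pairwise contrasts (unadjusted by definition; Bonferroni optional).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "MEASUREMENTS",
    "AGE_BIN_EDGES",
    "AnovaLsdResult",
    "CohortSummary",
    "ks_normality",
    "blom_transform",
    "t_test_vs_90",
    "group_compare",
    "anova_lsd",
    "summarize_cohort",
    "records_from_reports",
    "assign_age_bin",
]

MEASUREMENTS = ("AI", "OI", "RI", "AA", "OA", "RA")

#: Age bins: <30, [30,40), [40,50), ≥50.
AGE_BIN_EDGES = (30.0, 40.0, 50.0)
AGE_BIN_LABELS = ("<30", "[30,40)", "[40,50)", ">=50")


def assign_age_bin(age: float) -> str:
    for edge, label in zip(AGE_BIN_EDGES, AGE_BIN_LABELS):
        if age < edge:
            return label
    return AGE_BIN_LABELS[-1]


def _clean(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    return arr[np.isfinite(arr)]


def ks_normality(values) -> tuple[float, float]:
    """Kolmogorov–Smirnov normality test with estimated parameters.

    The KS statistic is computed against a normal with the sample's own
    mean and SD; the p-value uses the Lilliefors calibration (the naive
    KS p with plugged-in parameters would be grossly conservative).

    Returns (statistic, p).  Requires n ≥ 5.
    """
    arr = _clean(values)
    if len(arr) < 5:
        raise ValueError(f"normality test needs ≥5 values, got {len(arr)}")
    stat, p = lilliefors(arr, dist="norm", pvalmethod="table")
    return float(stat), float(p)


def blom_transform(values) -> np.ndarray:
    """Blom rank-based normal scores: Φ⁻¹((rᵢ − 3/8)/(n + 1/4)).

    Monotone in the input (ties share a midrank and thus a score).  An
    all-tied sample maps to all zeros with a warning.
    """
    arr = np.asarray(values, dtype=float).ravel()
    n = len(arr)
    if n < 2:
        raise ValueError("Blom transform needs n ≥ 2")
    if np.all(arr == arr[0]):
        warnings.warn("all values tied; Blom scores are all zero", stacklevel=2)
        return np.zeros(n)
    ranks = stats.rankdata(arr, method="average")
    return stats.norm.ppf((ranks - 0.375) / (n + 0.25))


def t_test_vs_90(plane_angles) -> tuple[float, float]:
    """One-sample t test of plane angles against 90°.

    Used to judge whether a fitted reference-plane pair is statistically
    perpendicular.  Zero-variance input is an error (the t statistic is
    undefined), not a p-value.
    """
    arr = _clean(plane_angles)
    if len(arr) < 2:
        raise ValueError("t test needs ≥2 values")
    if np.ptp(arr) == 0:
        raise ValueError("zero variance: t statistic vs 90° undefined")
    res = stats.ttest_1samp(arr, popmean=90.0)
    return float(res.statistic), float(res.pvalue)


def group_compare(records: pd.DataFrame, by: str) -> dict[str, dict[str, float]]:
    """Subgroup comparison of each measurement, by sex or by age bin.

    by="sex"
        Two-sample (Welch-free, pooled) t test male vs. female.
    by="age_bin"
        Chi-square on the age-bin × (above/below cohort median) counts —
        the contingency reading of an "age-group chi-square" on a
        continuous angle — plus a one-way ANOVA across bins, reported
        side by side.

    Returns {measurement: {"statistic":…, "p":…, …}}.
    """
    results: dict[str, dict[str, float]] = {}
    if by == "sex":
        for m in MEASUREMENTS:
            groups = [
                _clean(sub[m]) for _, sub in records.groupby("sex") if len(sub) >= 2
            ]
            if len(groups) < 2:
                raise ValueError("sex comparison needs two groups with n ≥ 2")
            t, p = stats.ttest_ind(groups[0], groups[1])
            results[m] = {"statistic": float(t), "p": float(p)}
        return results
    if by == "age_bin":
        bins = records["age_bin"] if "age_bin" in records else records["age"].map(assign_age_bin)
        for m in MEASUREMENTS:
            vals = records[m].to_numpy(dtype=float)
            ok = np.isfinite(vals)
            vals, b = vals[ok], bins[ok]
            median = np.median(vals)
            table = pd.crosstab(b, vals > median)
            if table.shape[1] < 2 or (table.to_numpy().sum(axis=1) == 0).any():
                chi2, chi2_p = float("nan"), float("nan")
            else:
                chi2, chi2_p, _, _ = stats.chi2_contingency(table.to_numpy())
            groups = [vals[b == lbl] for lbl in pd.unique(b)]
            groups = [g for g in groups if len(g) >= 2]
            if len(groups) >= 2:
                f, anova_p = stats.f_oneway(*groups)
            else:
                f, anova_p = float("nan"), float("nan")
            results[m] = {
                "chi2": float(chi2),
                "chi2_p": float(chi2_p),
                "anova_F": float(f),
                "anova_p": float(anova_p),
            }
        return results
    raise ValueError(f"unknown grouping {by!r}; use 'sex' or 'age_bin'")


@dataclass(frozen=True)
class AnovaLsdResult:
    """One-way ANOVA with Fisher's LSD pairwise contrasts.

    ``pairwise`` maps (group_i, group_j) to a dict with the LSD t
    statistic and its unadjusted p (t against the pooled within-group
    mean square on N−k degrees of freedom); ``p_bonferroni`` is included
    when requested — LSD is by definition unadjusted, the correction is
    a modern-practice add-on.
    """

    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    ms_within: float
    pairwise: dict[tuple[str, str], dict[str, float]]


def anova_lsd(
    groups: Mapping[str, Sequence[float]], adjust: str = "none"
) -> AnovaLsdResult:
    """One-way ANOVA over named groups plus LSD pairwise contrasts.

    LSD contrast for groups i, j:
    t = (x̄ᵢ − x̄ⱼ) / sqrt(MS_within (1/nᵢ + 1/nⱼ)), df = N − k.
    """
    if adjust not in ("none", "bonferroni"):
        raise ValueError("adjust must be 'none' or 'bonferroni'")
    cleaned = {name: _clean(vals) for name, vals in groups.items()}
    if len(cleaned) < 2 or any(len(v) < 2 for v in cleaned.values()):
        raise ValueError("ANOVA needs ≥2 groups with n ≥ 2 each")
    names = list(cleaned)
    arrays = [cleaned[n] for n in names]
    n_total = sum(len(a) for a in arrays)
    k = len(arrays)
    df_within = n_total - k
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    ms_within = ss_within / df_within
    if ms_within == 0 and all(a.mean() == arrays[0].mean() for a in arrays):
        # all observations identical: F is 0/0; report F=0, p=1
        f_stat, p_val = 0.0, 1.0
    else:
        f_stat, p_val = stats.f_oneway(*arrays)
    n_pairs = k * (k - 1) // 2
    pairwise: dict[tuple[str, str], dict[str, float]] = {}
    for i, j in combinations(range(k), 2):
        a, b = arrays[i], arrays[j]
        if ms_within == 0:
            t = 0.0 if a.mean() == b.mean() else float("inf")
            p = 1.0 if t == 0.0 else 0.0
        else:
            se = np.sqrt(ms_within * (1 / len(a) + 1 / len(b)))
            t = float((a.mean() - b.mean()) / se)
            p = float(2 * stats.t.sf(abs(t), df_within))
        entry = {"t": t, "p": p}
        if adjust == "bonferroni":
            entry["p_bonferroni"] = min(1.0, p * n_pairs)
        pairwise[(names[i], names[j])] = entry
    return AnovaLsdResult(
        f_statistic=float(f_stat),
        p_value=float(p_val),
        df_between=k - 1,
        df_within=df_within,
        ms_within=float(ms_within),
        pairwise=pairwise,
    )


@dataclass
class CohortSummary:
    """Full cohort analysis: summary table, subgroup tests, system contrasts."""

    table: pd.DataFrame
    n_hips: int
    n_excluded: int
    normality: dict[str, dict[str, float]]
    blom_applied: list[str]
    sex_tests: dict[str, dict[str, float]] | None
    age_tests: dict[str, dict[str, float]] | None
    inclination_anova: AnovaLsdResult | None
    anteversion_anova: AnovaLsdResult | None

    def to_json_dict(self) -> dict:
        def pairs(res: AnovaLsdResult | None) -> dict | None:
            if res is None:
                return None
            return {
                "F": res.f_statistic,
                "p": res.p_value,
                "pairwise": {f"{a}-{b}": v for (a, b), v in res.pairwise.items()},
            }

        return {
            "n_hips": self.n_hips,
            "n_excluded": self.n_excluded,
            "normality": self.normality,
            "blom_applied": self.blom_applied,
            "sex_tests": self.sex_tests,
            "age_tests": self.age_tests,
            "inclination_anova": pairs(self.inclination_anova),
            "anteversion_anova": pairs(self.anteversion_anova),
            "table": self.table.to_dict(orient="index"),
        }


def records_from_reports(reports: Iterable) -> pd.DataFrame:
    """Flatten :class:`~acetorient.angle_measures.CaseReport`s to a records table.

    One row per measured hip with case_id, side, age, sex and the six
    angles; hips with degenerate angles carry NaN and are excluded by
    :func:`summarize_cohort` with a logged count.
    """
    rows = []
    for report, lset in reports:
        for hip in report.hips:
            row = {
                "case_id": report.case_id,
                "side": hip.angles.side,
                "age": lset.age,
                "sex": lset.sex,
            }
            row.update(hip.angles.as_dict())
            rows.append(row)
    return pd.DataFrame(rows)


def summarize_cohort(
    records: pd.DataFrame,
    normality_alpha: float = 0.05,
    lsd_adjust: str = "none",
) -> CohortSummary:
    """Cohort summary: per-measurement mean ± SD, subgroups, and contrasts.

    Pipeline: exclude hips with any non-finite angle (count logged);
    Lilliefors-screen each measurement and Blom-transform those that
    fail before the parametric comparisons (the transformed scores are
    rescaled to the original mean/SD so tabulated values stay in
    degrees); tabulate overall and sex/age-bin subgroup mean ± SD;
    run sex t tests, age-bin chi-square + ANOVA, and the two three-system
    ANOVA+LSD contrasts (AI/OI/RI and AA/OA/RA).
    """
    if len(records) == 0:
        raise ValueError("empty cohort")
    df = records.copy()
    finite = np.isfinite(df[list(MEASUREMENTS)].to_numpy(dtype=float)).all(axis=1)
    n_excluded = int((~finite).sum())
    df = df.loc[finite].reset_index(drop=True)
    if len(df) == 0:
        raise ValueError("no hips with complete, non-degenerate angles")
    if "age_bin" not in df and "age" in df and df["age"].notna().any():
        df["age_bin"] = df["age"].map(
            lambda a: assign_age_bin(a) if pd.notna(a) else pd.NA
        )

    normality: dict[str, dict[str, float]] = {}
    blom_applied: list[str] = []
    analysis = df.copy()
    for m in MEASUREMENTS:
        vals = df[m].to_numpy(dtype=float)
        if len(vals) >= 5 and np.ptp(vals) > 0:
            stat, p = ks_normality(vals)
            normality[m] = {"statistic": stat, "p": p}
            if p < normality_alpha:
                scores = blom_transform(vals)
                analysis[m] = vals.mean() + scores * (vals.std(ddof=1) or 1.0)
                blom_applied.append(m)
        else:
            normality[m] = {"statistic": float("nan"), "p": float("nan")}

    def mean_sd(sub: pd.DataFrame, m: str) -> str:
        v = sub[m].to_numpy(dtype=float)
        if len(v) == 0:
            return ""
        if len(v) == 1:
            return f"{v[0]:.2f} (sd undefined)"
        return f"{v.mean():.2f} ± {v.std(ddof=1):.2f}"

    columns: dict[str, dict[str, str]] = {}
    columns[f"Total (n={len(analysis)})"] = {m: mean_sd(analysis, m) for m in MEASUREMENTS}
    has_sex = "sex" in analysis and analysis["sex"].notna().any()
    if has_sex:
        for sex, sub in analysis.groupby("sex"):
            columns[f"sex={sex} (n={len(sub)})"] = {m: mean_sd(sub, m) for m in MEASUREMENTS}
    has_age = "age_bin" in analysis and analysis["age_bin"].notna().any()
    if has_age:
        for lbl in AGE_BIN_LABELS:
            sub = analysis[analysis["age_bin"] == lbl]
            columns[f"age {lbl} (n={len(sub)})"] = {m: mean_sd(sub, m) for m in MEASUREMENTS}
    table = pd.DataFrame(columns).reindex(list(MEASUREMENTS))

    sex_tests = None
    if has_sex and analysis.groupby("sex").size().ge(2).sum() >= 2:
        sex_tests = group_compare(analysis.dropna(subset=["sex"]), by="sex")
    age_tests = None
    if has_age:
        sub = analysis.dropna(subset=["age_bin"])
        if sub["age_bin"].nunique() >= 2:
            age_tests = group_compare(sub, by="age_bin")

    def try_anova(names: tuple[str, ...]) -> AnovaLsdResult | None:
        try:
            return anova_lsd(
                {m: analysis[m].to_numpy(dtype=float) for m in names},
                adjust=lsd_adjust,
            )
        except ValueError:
            return None  # < 2 hips: contrasts undefined

    incl = try_anova(("AI", "OI", "RI"))
    ante = try_anova(("AA", "OA", "RA"))
    return CohortSummary(
        table=table,
        n_hips=len(analysis),
        n_excluded=n_excluded,
        normality=normality,
        blom_applied=blom_applied,
        sex_tests=sex_tests,
        age_tests=age_tests,
        inclination_anova=incl,
        anteversion_anova=ante,
    )
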