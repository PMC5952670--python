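"""Cohort-level statistics: per-line profiles, group comparisons, and the
migration/recovery-rate correlation.

Group comparisons follow the standard imaging-cohort recipe: a per-group
Shapiro–Wilk normality screen chooses between one-way ANOVA with
Bonferroni-adjusted pairwise t-tests and Kruskal–Wallis with Dunn's
rank-based post-hoc; paired before/after designs use the paired t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simulate import MigrationRecord

__all__ = [
    "CellLineProfile",
    "CorrelationResult",
    "GroupComparison",
    "StatsError",
    "summarize_lines",
    "rank_lines",
    "compare_groups",
    "paired_before_after",
    "dunn_test",
    "correlate_migration",
]

ALPHA = 0.05


class StatsError(ValueError):
    """Raised for undersized or mismatched statistical inputs."""


@dataclass(frozen=True)
class CellLineProfile:
    line: str
    basal_mean: float
    basal_se: float
    response50_mean: float
    response50_se: float
    recovery_rate_mean: float
    recovery_rate_se: float
    n_cells: int
    n_experiments: int


@dataclass(frozen=True)
class CorrelationResult:
    pearson_r: float
    p_value: float
    n: int
    slope: float
    intercept: float


@dataclass
class GroupComparison:
    method: str  # "anova-bonferroni" or "kruskal-dunn"
    statistic: float
    p_value: float
    pairwise: pd.DataFrame  # columns: group1, group2, p_adj, significant
    normality_p: dict

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def _sem(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0


def summarize_lines(records: pd.DataFrame,
                    line_col: str = "cell_line",
                    min_fit_r: float = 0.8,
                    require_converged: bool = True) -> list[CellLineProfile]:
    """Aggregate a per-cell results table into per-line mean ± SE profiles.

    Cells with unconverged fits or fit r below ``min_fit_r`` are excluded
    from the recovery-rate aggregate (they stay in the basal/response
    aggregates, which do not depend on the fit).
    """
    profiles = []
    for line, g in records.groupby(line_col, sort=True):
        if len(g) == 0:
            continue
        gk = g
        if "fit_r" in g.columns:
            ok = g["fit_r"] >= min_fit_r
            if require_converged and "fit_converged" in g.columns:
                ok &= g["fit_converged"].astype(bool)
            gk = g[ok]
        if len(gk) == 0:
            import warnings

            warnings.warn(f"line {line!r}: no accepted recovery fits; skipped")
            continue
        n_exp = g["experiment_id"].nunique() if "experiment_id" in g.columns else 1
        resp = g["delta_r_50"].dropna() if "delta_r_50" in g.columns else pd.Series(dtype=float)
        profiles.append(
            CellLineProfile(
                line=str(line),
                basal_mean=float(g["r_basal"].mean()),
                basal_se=_sem(g["r_basal"].to_numpy()),
                response50_mean=float(resp.mean()) if len(resp) else np.nan,
                response50_se=_sem(resp.to_numpy()) if len(resp) > 1 else 0.0,
                recovery_rate_mean=float(gk["recovery_k_per_min"].mean()),
                recovery_rate_se=_sem(gk["recovery_k_per_min"].to_numpy()),
                n_cells=int(len(g)),
                n_experiments=int(n_exp),
            )
        )
    return profiles


def rank_lines(profiles: list[CellLineProfile],
               by: str = "recovery_rate_mean") -> list[CellLineProfile]:
    """Lines sorted ascending by the chosen metric (lowest to highest)."""
    return sorted(profiles, key=lambda p: getattr(p, by))


def dunn_test(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-based post-hoc test with Bonferroni adjustment.

    z_ij = (R̄_i − R̄_j) / sqrt( (N(N+1)/12 − T) · (1/n_i + 1/n_j) ),
    where T is the tie correction sum(t³ − t)/(12(N−1)).
    """
    names = list(groups)
    values = np.concatenate([np.asarray(groups[g], dtype=float) for g in names])
    labels = np.concatenate([[g] * len(groups[g]) for g in names])
    ranks = stats.rankdata(values)
    n_total = len(values)
    _, counts = np.unique(values, return_counts=True)
    tie_corr = np.sum(counts**3 - counts) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_corr
    mean_ranks = {g: ranks[labels == g].mean() for g in names}
    sizes = {g: int((labels == g).sum()) for g in names}
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / se
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append({"group1": a, "group2": b, "statistic": z, "p_raw": p})
    df = pd.DataFrame(rows)
    df["p_adj"] = np.minimum(df["p_raw"] * len(df), 1.0)
    df["significant"] = df["p_adj"] < ALPHA
    return df


def compare_groups(groups: dict[str, np.ndarray], parametric: str = "auto",
                   ) -> GroupComparison:
    """Omnibus + post-hoc comparison of 2+ groups.

    ``parametric`` is ``"auto"`` (Shapiro–Wilk screen at α=0.05 per group),
    ``"yes"`` (force ANOVA/Bonferroni) or ``"no"`` (force Kruskal/Dunn).
    """
    if len(groups) < 2:
        raise StatsError("need at least 2 groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, v in arrays.items():
        if len(v) < 3:
            raise StatsError(f"group {g!r} has n={len(v)} < 3")
    normality = {g: float(stats.shapiro(v).pvalue) for g, v in arrays.items()}
    if parametric == "auto":
        use_parametric = all(p >= ALPHA for p in normality.values())
    else:
        use_parametric = parametric == "yes"

    names = list(arrays)
    if use_parametric:
        stat, p = stats.f_oneway(*arrays.values())
        rows = []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                a, b = names[i], names[j]
                t, pr = stats.ttest_ind(arrays[a], arrays[b])
                rows.append({"group1": a, "group2": b, "statistic": float(t),
                             "p_raw": float(pr)})
        pw = pd.DataFrame(rows)
        pw["p_adj"] = multipletests(pw["p_raw"], method="bonferroni")[1]
        pw["significant"] = pw["p_adj"] < ALPHA
        method = "anova-bonferroni"
    else:
        stat, p = stats.kruskal(*arrays.values())
        pw = dunn_test(arrays)
        method = "kruskal-dunn"
    return GroupComparison(method=method, statistic=float(stat), p_value=float(p),
                           pairwise=pw, normality_p=normality)


def paired_before_after(before, after) -> tuple[float, float]:
    """Paired t-test for before/after designs; returns (t, p)."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if len(before) != len(after):
        raise StatsError("before/after must be paired (equal length)")
    if len(before) < 3:
        raise StatsError("paired design needs n >= 3")
    t, p = stats.ttest_rel(before, after)
    return float(t), float(p)


def correlate_migration(profiles: list[CellLineProfile] | pd.DataFrame,
                        migration: list[MigrationRecord]) -> CorrelationResult:
    """Pearson correlation between per-line mean recovery rates and
    migration efficiencies, with the least-squares line for plotting."""
    if isinstance(profiles, pd.DataFrame):
        rate_by_line = dict(zip(profiles["line"], profiles["recovery_rate_mean"]))
    else:
        rate_by_line = {p.line: p.recovery_rate_mean for p in profiles}
    eff_by_line = {m.cell_line: m.migration_efficiency for m in migration}
    common = sorted(set(rate_by_line) & set(eff_by_line))
    unmatched = sorted(set(rate_by_line) ^ set(eff_by_line))
    if unmatched:
        raise StatsError(f"unmatched cell lines between profiles and migration: "
                         f"{', '.join(unmatched)}")
    if len(common) < 3:
        raise StatsError(f"correlation needs >= 3 matched lines, got {len(common)}")
    x = np.array([rate_by_line[l] for l in common])
    y = np.array([eff_by_line[l] for l in common])
    r, p = stats.pearsonr(x, y)
    lr = stats.linregress(x, y)
    return CorrelationResult(pearson_r=float(r), p_value=float(p), n=len(common),
                             slope=float(lr.slope), intercept=float(lr.intercept))
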