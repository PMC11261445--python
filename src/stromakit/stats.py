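"""Group comparisons and the Spearman correlation screen.

Covers the statistical layer applied to per-patient, per-region cohort
tables: one-way ANOVA with Tukey's HSD, one-factor repeated-measures
ANOVA over the three stromal regions (each patient contributes all three,
so subject blocking removes between-patient heterogeneity), tie-aware
Spearman rank correlation, and a screen that classifies every pairwise
correlation by the conventional strength bands (|rho| in 0.2-wide bins
from "very weak" to "very strong") and flags as significant only strong
or very strong correlations with p < 0.05.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    DegenerateGroupError,
    InsufficientDataError,
    UndefinedCorrelationError,
)
from .types import REGIONS, STAGES

log = logging.getLogger(__name__)

STRENGTH_LABELS = ("very weak", "weak", "moderate", "strong", "very strong")
STAGE_NUMBER = {st: i + 1 for i, st in enumerate(STAGES)}


def oneway_anova_tukey(groups: dict[str, np.ndarray]) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA plus Tukey HSD pairwise comparisons.

    Returns (F, p, table) where the table has one row per group pair with
    the mean difference and the studentized-range adjusted p-value.
    """
    names = list(groups)
    data = [np.asarray(groups[n], dtype=float) for n in names]
    if len(data) < 2:
        raise DegenerateGroupError("need at least two groups")
    for n, d in zip(names, data):
        if d.size < 2:
            raise DegenerateGroupError(f"group {n!r} needs n >= 2")
    if all(np.ptp(d) == 0 for d in data) and len({d[0] for d in data}) == 1:
        # all observations identical: F = 0 by convention, nothing to compare
        rows = [
            {"pair": (a, b), "mean_diff": 0.0, "p_adj": 1.0}
            for a, b in itertools.combinations(names, 2)
        ]
        return 0.0, 1.0, pd.DataFrame(rows)
    F, p = sps.f_oneway(*data)
    tuk = sps.tukey_hsd(*data)
    rows = []
    for i, j in itertools.combinations(range(len(data)), 2):
        rows.append(
            {
                "pair": (names[i], names[j]),
                "mean_diff": float(np.mean(data[i]) - np.mean(data[j])),
                "p_adj": float(tuk.pvalue[i, j]),
            }
        )
    return float(F), float(p), pd.DataFrame(rows)


@dataclass
class RMAnovaResult:
    f_statistic: float
    p_value: float
    df_condition: int
    df_error: int
    n_subjects: int
    ss_condition: float
    ss_subject: float
    ss_error: float


def rm_anova(
    table: pd.DataFrame,
    subject: str = "patient_id",
    condition: str = "region",
    value: str = "value",
) -> RMAnovaResult:
    """One-factor within-subject (repeated measures) ANOVA.

    Subjects missing any condition are dropped (logged).  The F statistic
    is MS_condition / MS_error after removing the between-subject sum of
    squares, with (k-1) and (k-1)(n-1) degrees of freedom.
    """
    wide = table.pivot_table(index=subject, columns=condition, values=value)
    complete = wide.dropna()
    dropped = len(wide) - len(complete)
    if dropped:
        log.info("rm_anova: dropped %d subjects with incomplete conditions", dropped)
    n, k = complete.shape
    if n < 3:
        raise InsufficientDataError(f"need >= 3 complete subjects, have {n}")
    X = complete.to_numpy(dtype=float)
    grand = X.mean()
    ss_cond = n * float(((X.mean(axis=0) - grand) ** 2).sum())
    ss_subj = k * float(((X.mean(axis=1) - grand) ** 2).sum())
    ss_total = float(((X - grand) ** 2).sum())
    ss_err = ss_total - ss_cond - ss_subj
    df_cond = k - 1
    df_err = (k - 1) * (n - 1)
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err
    if ms_err <= 0:
        f = 0.0 if ms_cond == 0 else float("inf")
        p = 1.0 if ms_cond == 0 else 0.0
    else:
        f = ms_cond / ms_err
        p = float(sps.f.sf(f, df_cond, df_err))
    return RMAnovaResult(
        f_statistic=float(f),
        p_value=float(p),
        df_condition=df_cond,
        df_error=df_err,
        n_subjects=n,
        ss_condition=ss_cond,
        ss_subject=ss_subj,
        ss_error=ss_err,
    )


def spearman(x, y, method: str = "t", n_permutations: int = 10_000, seed: int = 0):
    """Tie-aware Spearman rank correlation.

    rho is the Pearson correlation of mid-ranks; the p-value comes from
    the t approximation with n - 2 degrees of freedom (adequate for the
    cohort sizes this screen is used at).  ``method="permutation"`` gives
    a seeded permutation p-value, preferable at n <= 10.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InsufficientDataError("x and y must be equal-length 1D vectors")
    if x.size < 4:
        raise InsufficientDataError("need n >= 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation of a constant vector is undefined")
    rho, p = sps.spearmanr(x, y)
    rho = float(rho)
    if method == "t":
        return rho, float(p)
    if method == "permutation":
        rng = np.random.default_rng(seed)
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(ry)
            hits += abs(np.corrcoef(rx, perm)[0, 1]) >= obs - 1e-12
        return rho, float((hits + 1) / (n_permutations + 1))
    raise InsufficientDataError(f"unknown method {method!r}")


def classify_strength(rho: float) -> str:
    """Strength label from |rho|: 0.2-wide bins, left-closed/right-open,
    with the final bin closed at 1."""
    a = abs(float(rho))
    if a > 1.0 + 1e-12:
        raise UndefinedCorrelationError(f"|rho| = {a} exceeds 1")
    for threshold, label in zip((0.2, 0.4, 0.6, 0.8), STRENGTH_LABELS):
        if a < threshold:
            return label
    return STRENGTH_LABELS[-1]


@dataclass
class CorrelationReport:
    var_x: str
    var_y: str
    rho: float
    p_value: float
    n: int
    strength: str
    significant: bool


def correlation_screen(
    table: pd.DataFrame,
    region: str = "PeriT",
    variables=("stage", "coll_prt", "pro_prt", "thickness_um", "spacing_um", "vol_fraction"),
    holm: bool = False,
) -> list[CorrelationReport]:
    """All pairwise Spearman correlations among ``variables`` in one region.

    ``stage`` is encoded 1-4.  Each pair gets a strength label; the
    significance rule is |rho| >= 0.6 (strong or very strong) and
    p < 0.05.  No multiplicity correction is applied by default; ``holm``
    adjusts the p-values before applying the rule.
    """
    if region not in REGIONS:
        raise InsufficientDataError(f"unknown region {region!r}")
    sub = table[table["region"] == region]
    wide = sub.pivot_table(index="patient_id", columns="variable", values="value")
    stage_map = (
        table[["patient_id", "stage"]].drop_duplicates().set_index("patient_id")["stage"]
    )
    wide = wide.assign(stage=stage_map.reindex(wide.index).map(STAGE_NUMBER))
    if len(wide) < 4:
        raise InsufficientDataError("need >= 4 patients after filtering")
    pairs = list(itertools.combinations(variables, 2))
    reports = []
    raw = []
    for vx, vy in pairs:
        cols = wide[[vx, vy]].dropna()
        rho, p = spearman(cols[vx].to_numpy(), cols[vy].to_numpy())
        raw.append((vx, vy, rho, p, len(cols)))
    pvals = [r[3] for r in raw]
    if holm and pvals:
        order = np.argsort(pvals)
        m = len(pvals)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * pvals[idx])
            adj[idx] = min(running, 1.0)
        pvals = adj.tolist()
    for (vx, vy, rho, _, n), p in zip(raw, pvals):
        strength = classify_strength(rho)
        significant = strength in ("strong", "very strong") and p < 0.05
        reports.append(CorrelationReport(vx, vy, rho, float(p), n, strength, significant))
    return reports


def reports_to_frame(reports: list[CorrelationReport]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in reports])


def proportion_table(counts: dict[str, int], total: int, decimals: int = 1) -> dict[str, float]:
    """Percentages (rounded to ``decimals``) of category counts over a
    cohort size — the arithmetic behind clinicopathological summary tables."""
    if total <= 0:
        raise DegenerateGroupError("total must be positive")
    return {k: round(100.0 * v / total, decimals) for k, v in counts.items()}
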