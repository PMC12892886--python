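"""Differential expression: geometric-mean fold changes, pairwise t-tests,
Benjamini-Hochberg FDR, DEP calling, volcano tables, and per-protein one-way
ANOVA with Tukey HSD pairwise comparisons.

All tests operate on log2 abundances, consistent with geometric-mean fold
changes and multiplicative noise. Zeros are floored once per matrix at half
the smallest positive value before taking logs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import AbundanceMatrix, RunConfig, SampleSheet
from .errors import ValidationError

Q_EPS = 1e-300  # floor for q in -log10 transforms


# ---------------------------------------------------------------------------
# log2 matrix preparation
# ---------------------------------------------------------------------------


def log2_matrix(matrix: AbundanceMatrix) -> tuple[pd.DataFrame, float]:
    """log2-transform a matrix, flooring zeros at half the min positive value.

    Returns the log2 DataFrame (NaN preserved) and the floor applied (0.0 if
    no zeros were present).
    """
    values = matrix.data.to_numpy(dtype=float)
    positive = values[np.isfinite(values) & (values > 0)]
    if positive.size == 0:
        raise ValidationError("matrix has no positive values")
    floor = 0.0
    if np.any(values[np.isfinite(values)] == 0):
        floor = float(positive.min() / 2.0)
    floored = np.where(np.isfinite(values) & (values == 0), floor, values)
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.log2(floored)
    logs[~np.isfinite(logs)] = np.nan
    return pd.DataFrame(logs, index=matrix.data.index, columns=matrix.data.columns), floor


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def log2_fold_change(group_a, group_b, *, zero_floor: float | None = None) -> float:
    """log2( geomean(A) / geomean(B) ), skipping missing values.

    Zeros are replaced by ``zero_floor`` (required if any zeros are present).
    Returns NaN (untestable) if either group has no usable value.
    """
    out = []
    for values in (group_a, group_b):
        x = np.asarray(values, dtype=float)
        x = x[~np.isnan(x)]
        if zero_floor is not None:
            x = np.where(x == 0, zero_floor, x)
        if x.size == 0 or np.any(x <= 0):
            if np.any(x == 0):
                raise ValidationError("zero values need a zero_floor")
            return float("nan")
        out.append(np.mean(np.log2(x)))
    return float(out[0] - out[1])


def _pooled_t(mean_a, mean_b, var_a, var_b, n_a, n_b):
    """Vectorized equal-variance two-sample t statistic, df, and two-sided p.

    Conventions for zero pooled variance: equal means -> p=1, else p=0.
    Entries with n<2 in either group come back NaN (untestable).
    """
    n_a = np.asarray(n_a, dtype=float)
    n_b = np.asarray(n_b, dtype=float)
    testable = (n_a >= 2) & (n_b >= 2)
    df = n_a + n_b - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        sp2 = ((n_a - 1) * var_a + (n_b - 1) * var_b) / df
        se = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
        t = (mean_a - mean_b) / se
    p = np.full(np.shape(t), np.nan)
    ok = testable & (se > 0)
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    degenerate = testable & (se == 0)
    p[degenerate & (mean_a == mean_b)] = 1.0
    p[degenerate & (mean_a != mean_b)] = 0.0
    t[~testable] = np.nan
    return t, df, p


def _welch_t(mean_a, mean_b, var_a, var_b, n_a, n_b):
    n_a = np.asarray(n_a, dtype=float)
    n_b = np.asarray(n_b, dtype=float)
    testable = (n_a >= 2) & (n_b >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        va = var_a / n_a
        vb = var_b / n_b
        se = np.sqrt(va + vb)
        t = (mean_a - mean_b) / se
        df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    p = np.full(np.shape(t), np.nan)
    ok = testable & (se > 0)
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    degenerate = testable & (se == 0)
    p[degenerate & (mean_a == mean_b)] = 1.0
    p[degenerate & (mean_a != mean_b)] = 0.0
    t[~testable] = np.nan
    return t, df, p


def pairwise_ttest(
    matrix: AbundanceMatrix,
    sheet: SampleSheet,
    contrast: tuple[str, str],
    *,
    equal_var: bool = True,
) -> pd.Series:
    """Per-protein two-sided unpaired t-test p-values on log2 abundances.

    ``contrast`` is (numerator group, denominator group). Proteins with fewer
    than 2 non-missing replicates in either group come back NaN (untestable).
    """
    logs, _ = log2_matrix(matrix)
    stats_ab = _group_moments(logs, sheet, contrast)
    fn = _pooled_t if equal_var else _welch_t
    _, _, p = fn(*stats_ab)
    return pd.Series(p, index=matrix.data.index, name="p_raw")


def _group_moments(logs: pd.DataFrame, sheet: SampleSheet, contrast: tuple[str, str]):
    """nan-aware per-row mean/var/count for both groups of a contrast."""
    moments = []
    for group in contrast:
        cols = [s.sample_id for s in sheet.group_samples(group)]
        if not cols:
            raise ValidationError(f"no samples for group {group!r}")
        block = logs[cols].to_numpy(dtype=float)
        n = np.sum(~np.isnan(block), axis=1)
        mean = np.full(block.shape[0], np.nan)
        var = np.full(block.shape[0], np.nan)
        any_row = n > 0
        if any_row.any():
            mean[any_row] = np.nanmean(block[any_row], axis=1)
        var_row = n > 1
        if var_row.any():
            var[var_row] = np.nanvar(block[var_row], axis=1, ddof=1)
        moments.append((mean, var, n))
    (ma, va, na), (mb, vb, nb) = moments
    return ma, mb, va, vb, na, nb


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``q_(i) = min_{j>=i} p_(j) * m / j`` capped at 1, mapped back to input
    order. NaN entries (untestable) are excluded from m and stay NaN.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if np.any((pv < 0) | (pv > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    out[mask] = q
    return out


# ---------------------------------------------------------------------------
# DEP table
# ---------------------------------------------------------------------------

DEP_COLUMNS = ("protein", "log2fc", "p_raw", "q", "status")


def call_deps(log2fc, q, cfg: RunConfig) -> np.ndarray:
    """Status per protein: up / down / ns / untestable.

    Boundary equality with either cutoff counts as significant.
    """
    log2fc = np.asarray(log2fc, dtype=float)
    q = np.asarray(q, dtype=float)
    status = np.full(log2fc.shape, "ns", dtype=object)
    untestable = np.isnan(log2fc) | np.isnan(q)
    sig = ~untestable & (q <= cfg.q_cutoff)
    status[sig & (log2fc >= cfg.fc_cutoff_log2)] = "up"
    status[sig & (log2fc <= -cfg.fc_cutoff_log2)] = "down"
    status[untestable] = "untestable"
    return status


def dep_table(
    matrix: AbundanceMatrix,
    sheet: SampleSheet,
    contrast: tuple[str, str],
    cfg: RunConfig,
) -> pd.DataFrame:
    """Full DEP table for one contrast (numerator, denominator).

    Columns: protein, log2fc, p_raw, q, status; indexed by protein.
    """
    logs, _ = log2_matrix(matrix)
    ma, mb, va, vb, na, nb = _group_moments(logs, sheet, contrast)
    log2fc = np.where((na >= 1) & (nb >= 1), ma - mb, np.nan)
    fn = _pooled_t if cfg.equal_var else _welch_t
    _, _, p = fn(ma, mb, va, vb, na, nb)
    # a protein is testable only with >=2 replicates per group
    log2fc = np.where(np.isnan(p), np.nan, log2fc)
    q = bh_adjust(p)
    status = call_deps(log2fc, q, cfg)
    df = pd.DataFrame(
        {
            "protein": matrix.data.index,
            "log2fc": log2fc,
            "p_raw": p,
            "q": q,
            "status": status,
        }
    ).set_index("protein", drop=False)
    df.index.name = None
    df.attrs["contrast"] = tuple(contrast)
    return df


def dep_set(dep: pd.DataFrame) -> set[str]:
    """Protein ids called up or down in a DEP table."""
    return set(dep.loc[dep["status"].isin(("up", "down")), "protein"])


def volcano_table(dep: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready rows (protein, log2fc, neg_log10_q, status) for testable proteins."""
    testable = dep[dep["status"] != "untestable"].copy()
    qv = testable["q"].to_numpy(dtype=float)
    testable["neg_log10_q"] = -np.log10(np.maximum(qv, Q_EPS))
    return testable[["protein", "log2fc", "neg_log10_q", "status"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# One-way ANOVA + Tukey HSD
# ---------------------------------------------------------------------------


@dataclass
class AnovaRow:
    protein: str
    F: float
    p_omnibus: float
    tukey_p: dict[tuple[str, str], float]


def anova_tukey(
    matrix: AbundanceMatrix,
    sheet: SampleSheet,
    groups: tuple[str, ...] | list[str] | None = None,
) -> list[AnovaRow]:
    """Per-protein one-way ANOVA on log2 abundances with Tukey HSD pairwise p.

    Tukey-adjusted p-values use the studentized range distribution with the
    ANOVA residual degrees of freedom; unbalanced group sizes use the
    Tukey-Kramer standard error.
    """
    if groups is None:
        groups = tuple(dict.fromkeys(s.group for s in sheet.study_samples()))
    if len(groups) < 2:
        raise ValidationError("ANOVA needs >= 2 groups")
    logs, _ = log2_matrix(matrix)
    cols_by_group = {g: [s.sample_id for s in sheet.group_samples(g)] for g in groups}
    rows: list[AnovaRow] = []
    for protein in matrix.data.index:
        samples = []
        for g in groups:
            vals = logs.loc[protein, cols_by_group[g]].to_numpy(dtype=float)
            samples.append(vals[~np.isnan(vals)])
        if any(len(s) < 2 for s in samples):
            rows.append(AnovaRow(protein, float("nan"), float("nan"), {}))
            continue
        k = len(samples)
        ns = np.array([len(s) for s in samples], dtype=float)
        means = np.array([s.mean() for s in samples])
        n_tot = ns.sum()
        grand = np.concatenate(samples).mean()
        ss_between = float(np.sum(ns * (means - grand) ** 2))
        ss_within = float(sum(((s - s.mean()) ** 2).sum() for s in samples))
        df_b = k - 1
        df_w = int(n_tot) - k
        if ss_within == 0 and ss_between == 0:
            f_stat, p_omni = 0.0, 1.0
            mse = 0.0
        elif ss_within == 0:
            f_stat, p_omni = float("inf"), 0.0
            mse = 0.0
        else:
            mse = ss_within / df_w
            f_stat = (ss_between / df_b) / mse
            p_omni = float(stats.f.sf(f_stat, df_b, df_w))
        tukey: dict[tuple[str, str], float] = {}
        for i in range(k):
            for j in range(i + 1, k):
                if mse == 0:
                    p_pair = 1.0 if means[i] == means[j] else 0.0
                else:
                    se = math.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
                    q_stat = abs(means[i] - means[j]) / se
                    p_pair = float(stats.studentized_range.sf(q_stat, k, df_w))
                tukey[(groups[i], groups[j])] = min(max(p_pair, 0.0), 1.0)
        rows.append(AnovaRow(str(protein), f_stat, p_omni, tukey))
    return rows


__all__ = [
    "AnovaRow",
    "DEP_COLUMNS",
    "Q_EPS",
    "anova_tukey",
    "bh_adjust",
    "call_deps",
    "dep_set",
    "dep_table",
    "log2_fold_change",
    "log2_matrix",
    "pairwise_ttest",
    "volcano_table",
]
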