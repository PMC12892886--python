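"""Normalization and QC: within-plex channel equalization, pooled-bridge
inter-plex scaling, pooled-missing exclusion, peptide-count filtering,
Grubbs single-outlier removal, and razor-rule peptide-to-protein roll-up.

Stage order is enforced through the matrix ``state`` field:
raw -> within_plex_normalized -> bridge_scaled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import AbundanceMatrix, SampleSheet
from .errors import StateError, ValidationError


# ---------------------------------------------------------------------------
# Within-plex normalization
# ---------------------------------------------------------------------------


def normalize_within_plex(matrix: AbundanceMatrix, sheet: SampleSheet) -> AbundanceMatrix:
    """Equalize channel totals within each plex.

    Totals are computed over the plex's shared non-missing rows (rows with a
    value in every channel of the plex); each channel is then scaled so all
    totals equal the plex's mean channel total. Row ratios within a channel
    are untouched.
    """
    if matrix.state != "raw":
        raise StateError(f"normalize_within_plex expects state=raw, got {matrix.state}")
    matrix.check_columns(sheet)
    data = matrix.data.copy()
    for plex in sheet.plex_ids:
        cols = [s.sample_id for s in sheet.samples_in_plex(plex)]
        block = data[cols]
        shared = block.dropna(axis=0, how="any")
        totals = shared.sum(axis=0)
        if (totals == 0).any():
            bad = list(totals.index[totals == 0])
            raise ValidationError(f"plex {plex}: zero channel total for {bad}")
        factors = totals.mean() / totals
        data[cols] = block * factors
    return matrix.with_data(data, state="within_plex_normalized")


# ---------------------------------------------------------------------------
# Bridge scaling
# ---------------------------------------------------------------------------


def bridge_scale(matrix: AbundanceMatrix, sheet: SampleSheet) -> AbundanceMatrix:
    """Per-protein inter-plex scaling via the pooled bridge channels.

    Each plex's columns are multiplied, per protein, by
    ``geomean(pool values across plexes) / pool value in that plex`` so the
    protein's pool values agree across plexes afterwards. Rows with a missing
    or zero pool in any plex must be removed first (see
    :func:`filter_pooled_missing`).
    """
    if matrix.state != "within_plex_normalized":
        raise StateError(
            f"bridge_scale expects state=within_plex_normalized, got {matrix.state}"
        )
    matrix.check_columns(sheet)
    pool_cols = [sheet.pool_sample(p).sample_id for p in sheet.plex_ids]
    pools = matrix.data[pool_cols]
    bad = pools.isna().any(axis=1) | (pools == 0).any(axis=1)
    if bad.any():
        raise ValidationError(
            "missing/zero POOL values for protein(s) "
            f"{list(matrix.data.index[bad][:5])}; run filter_pooled_missing first"
        )
    log_geo = np.log(pools).mean(axis=1)
    geo = np.exp(log_geo)
    data = matrix.data.copy()
    for plex, pool_col in zip(sheet.plex_ids, pool_cols):
        cols = [s.sample_id for s in sheet.samples_in_plex(plex)]
        factor = geo / matrix.data[pool_col]
        data[cols] = data[cols].mul(factor, axis=0)
    return matrix.with_data(data, state="bridge_scaled")


def filter_pooled_missing(
    matrix: AbundanceMatrix, sheet: SampleSheet
) -> tuple[AbundanceMatrix, list[str]]:
    """Drop rows whose pool value is missing or zero in any plex.

    Zero pool intensity is treated as non-detection (missing).
    """
    matrix.check_columns(sheet)
    pool_cols = [sheet.pool_sample(p).sample_id for p in sheet.plex_ids]
    pools = matrix.data[pool_cols]
    bad = pools.isna().any(axis=1) | (pools == 0).any(axis=1)
    excluded = list(matrix.data.index[bad])
    return matrix.with_data(matrix.data.loc[~bad]), excluded


# ---------------------------------------------------------------------------
# Grubbs single-outlier test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GrubbsResult:
    G: float
    G_crit: float
    outlier_index: int | None


def grubbs_critical(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value.

    G_crit = (n-1)/sqrt(n) * sqrt(t^2 / (n-2+t^2)) with t the upper
    alpha/(2n) quantile of Student's t on n-2 degrees of freedom.
    """
    if n < 3:
        raise ValidationError("Grubbs test needs n >= 3")
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))


def grubbs_test(values, alpha: float = 0.05) -> GrubbsResult:
    """Max-studentized-deviate test for a single outlier (two-sided)."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValidationError(f"Grubbs test needs n >= 3, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValidationError("Grubbs test needs finite values")
    sd = x.std(ddof=1)
    g_crit = grubbs_critical(x.size, alpha)
    if sd == 0:
        return GrubbsResult(G=0.0, G_crit=g_crit, outlier_index=None)
    dev = np.abs(x - x.mean()) / sd
    idx = int(np.argmax(dev))
    g = float(dev[idx])
    return GrubbsResult(G=g, G_crit=g_crit, outlier_index=idx if g > g_crit else None)


def apply_grubbs(
    matrix: AbundanceMatrix,
    sheet: SampleSheet,
    alpha: float = 0.05,
) -> tuple[AbundanceMatrix, pd.DataFrame]:
    """Remove at most one outlier per (protein, group) replicate set.

    The test runs on log2 abundances; flagged cells become missing. Groups
    with fewer than 3 non-missing replicates, or zero spread, are skipped.
    Returns the cleaned matrix and a ledger (protein, group, sample, G, G_crit).
    """
    if matrix.state != "bridge_scaled":
        raise StateError(f"apply_grubbs expects state=bridge_scaled, got {matrix.state}")
    matrix.check_columns(sheet)
    data = matrix.data.copy()
    ledger_rows: list[dict] = []
    groups = dict.fromkeys(s.group for s in sheet.study_samples())
    for group in groups:
        cols = [s.sample_id for s in sheet.group_samples(group)]
        block = data[cols].to_numpy(dtype=float)
        with np.errstate(divide="ignore"):
            logs = np.log2(block)
        logs[~np.isfinite(logs)] = np.nan
        n = np.sum(~np.isnan(logs), axis=1)
        ok = n >= 3
        mean = np.zeros((logs.shape[0], 1))
        sd = np.full(logs.shape[0], np.nan)
        if ok.any():
            mean[ok, 0] = np.nanmean(logs[ok], axis=1)
            sd[ok] = np.nanstd(logs[ok], axis=1, ddof=1)
        testable = ok & (sd > 0)
        if not testable.any():
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            dev = np.abs(logs - mean) / sd[:, None]
        g = np.nanmax(np.where(np.isnan(dev), -np.inf, dev), axis=1)
        g_crit = np.full(logs.shape[0], np.inf)
        for nn in np.unique(n[testable]):
            g_crit[testable & (n == nn)] = grubbs_critical(int(nn), alpha)
        flagged = testable & (g > g_crit)
        for ridx in np.flatnonzero(flagged):
            cidx = int(np.nanargmax(np.where(np.isnan(dev[ridx]), -np.inf, dev[ridx])))
            sample = cols[cidx]
            protein = matrix.data.index[ridx]
            data.loc[protein, sample] = np.nan
            ledger_rows.append(
                {
                    "protein": protein,
                    "group": group,
                    "sample": sample,
                    "G": float(g[ridx]),
                    "G_crit": float(g_crit[ridx]),
                }
            )
    ledger = pd.DataFrame(
        ledger_rows, columns=["protein", "group", "sample", "G", "G_crit"]
    )
    if len(ledger):
        ledger = ledger.sort_values(["protein", "group"]).reset_index(drop=True)
    return matrix.with_data(data), ledger


# ---------------------------------------------------------------------------
# Peptide-count filter and roll-up
# ---------------------------------------------------------------------------


def filter_min_peptides(
    matrix: AbundanceMatrix,
    peptide_counts: Mapping[str, int] | pd.Series,
    min_peptides: int = 2,
) -> tuple[AbundanceMatrix, list[str]]:
    """Drop proteins quantified by fewer than ``min_peptides`` peptides."""
    counts = pd.Series(peptide_counts)
    if (counts < 0).any():
        raise ValidationError("peptide counts must be >= 0")
    missing = [r for r in matrix.data.index if r not in counts.index]
    if missing:
        raise ValidationError(f"no peptide count for row(s) {missing[:5]}")
    keep = matrix.data.index[counts[matrix.data.index] >= min_peptides]
    excluded = [r for r in matrix.data.index if r not in set(keep)]
    return matrix.with_data(matrix.data.loc[keep]), excluded


def rollup_proteins(
    matrix: AbundanceMatrix,
    peptide_to_proteins: Mapping[str, frozenset[str] | set[str]],
) -> tuple[AbundanceMatrix, pd.Series]:
    """Sum unique + razor peptide intensities into protein rows.

    Razor rule: a shared peptide is credited to the member protein with the
    most unique peptides; ties break lexicographically by protein id.
    Returns the protein matrix (same state) and per-protein peptide counts.
    """
    if matrix.level != "peptide":
        raise ValidationError("rollup_proteins expects a peptide-level matrix")
    unmapped = [p for p in matrix.data.index if p not in peptide_to_proteins]
    if unmapped:
        raise ValidationError(f"peptide(s) without protein mapping: {unmapped[:5]}")
    unique_counts: dict[str, int] = {}
    for pep in matrix.data.index:
        members = peptide_to_proteins[pep]
        if len(members) == 1:
            (prot,) = tuple(members)
            unique_counts[prot] = unique_counts.get(prot, 0) + 1
    assignment: dict[str, str] = {}
    for pep in matrix.data.index:
        members = sorted(peptide_to_proteins[pep])
        if not members:
            raise ValidationError(f"peptide {pep!r} maps to no protein")
        assignment[pep] = min(members, key=lambda p: (-unique_counts.get(p, 0), p))
    proteins = sorted(set(assignment.values()))
    rows = []
    counts = {}
    for prot in proteins:
        peps = [p for p, a in assignment.items() if a == prot]
        counts[prot] = len(peps)
        block = matrix.data.loc[peps]
        summed = block.sum(axis=0, min_count=1)  # all-missing stays missing
        rows.append(summed)
    out = pd.DataFrame(rows, index=proteins)
    protein_matrix = AbundanceMatrix(data=out, level="protein", state=matrix.state)
    return protein_matrix, pd.Series(counts, name="n_peptides")


__all__ = [
    "GrubbsResult",
    "apply_grubbs",
    "bridge_scale",
    "filter_min_peptides",
    "filter_pooled_missing",
    "grubbs_critical",
    "grubbs_test",
    "normalize_within_plex",
    "rollup_proteins",
]
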