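"""Ground-truthed synthetic studies matching the two-plex multiplex design:
5 groups x 6 replicates split 3+3 across two 16-channel plexes, each plex
carrying one pooled bridge channel.

Signal layers are applied in a fixed, documented order:
group means -> plex shift -> coisolation mixing -> log-normal noise ->
outliers -> missingness. Every layer is reproducible from the seed and the
injected artifacts are ledgered in the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .construct_peptides import DigestSettings, classify_peptides
from .core_io import (
    AbundanceMatrix,
    ConstructSequence,
    POOL_GROUP,
    STUDY_GROUPS,
    SampleMeta,
    SampleSheet,
    TREATMENT_GROUPS,
)
from .errors import ConfigError

DIRECTIONS = ("null", "up", "down")
PROFILES = ("full", "partial", "none", "induced", "n/a")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for the synthetic study generator."""

    n_proteins: int = 1000
    frac_up: float = 0.08
    frac_down: float = 0.02
    effect_log2: float = 2.0
    restoration_profile_probs: Mapping[str, float] = field(
        default_factory=lambda: {"full": 0.8, "partial": 0.1, "none": 0.1}
    )
    frac_treatment_induced: float = 0.0
    noise_cv: float = 0.15
    plex_shift_log2: float = 0.0
    coisolation_rho: float = 0.0
    outlier_rate: float = 0.0
    outlier_factor: float = 10.0
    missing_rate: float = 0.0
    seed: int = 0
    reps_per_group: int = 6
    n_plexes: int = 2
    baseline_log_mean: float = np.log(1e6)
    baseline_log_sigma: float = 0.75

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ConfigError("n_proteins must be >= 1")
        for name in ("frac_up", "frac_down", "frac_treatment_induced",
                     "outlier_rate", "missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.frac_up + self.frac_down > 1.0:
            raise ConfigError("frac_up + frac_down must be <= 1")
        probs = dict(self.restoration_profile_probs)
        if set(probs) != {"full", "partial", "none"}:
            raise ConfigError("restoration_profile_probs needs keys full/partial/none")
        total = sum(probs.values())
        if any(p < 0 for p in probs.values()) or abs(total - 1.0) > 1e-9:
            raise ConfigError("restoration_profile_probs must be nonnegative and sum to 1")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")
        if not (0.0 <= self.coisolation_rho < 1.0):
            raise ConfigError("coisolation_rho must lie in [0, 1)")
        if self.reps_per_group % self.n_plexes != 0:
            raise ConfigError(
                f"{self.reps_per_group} replicates per group cannot be split "
                f"equally across {self.n_plexes} plexes"
            )
        if self.outlier_factor <= 0:
            raise ConfigError("outlier_factor must be > 0")


@dataclass
class GroundTruth:
    """Everything the simulator planted, for downstream validation."""

    direction: pd.Series  # protein -> null|up|down
    profiles: pd.DataFrame  # proteins x treatments -> full|partial|none|induced|n/a
    plex_shift_log2: dict[str, float]
    group_means: pd.DataFrame  # proteins x study groups (pre-artifact truth)
    outlier_cells: list[tuple[str, str]]  # (row_id, sample_id)
    missing_cells: list[tuple[str, str]]
    response_factors: pd.Series | None = None  # peptide sims only

    def to_dict(self) -> dict:
        return {
            "direction": self.direction.to_dict(),
            "profiles": {t: self.profiles[t].to_dict() for t in self.profiles.columns},
            "plex_shift_log2": self.plex_shift_log2,
            "outlier_cells": [list(c) for c in self.outlier_cells],
            "missing_cells": [list(c) for c in self.missing_cells],
            "response_factors": (
                None if self.response_factors is None else self.response_factors.to_dict()
            ),
        }


def make_sample_sheet(cfg: SimulationConfig) -> SampleSheet:
    """Channel layout: per plex, reps_per_group/n_plexes replicates of each
    study group plus one pooled bridge channel."""
    per_plex = cfg.reps_per_group // cfg.n_plexes
    samples: list[SampleMeta] = []
    for plex_idx in range(cfg.n_plexes):
        plex_id = f"plex{plex_idx + 1}"
        channel = 1
        for group in STUDY_GROUPS:
            for r in range(per_plex):
                replicate = plex_idx * per_plex + r + 1
                samples.append(
                    SampleMeta(
                        sample_id=f"{group}_{replicate}",
                        group=group,
                        replicate=replicate,
                        plex_id=plex_id,
                        channel_label=f"ch{channel:02d}",
                    )
                )
                channel += 1
        samples.append(
            SampleMeta(
                sample_id=f"POOL_{plex_idx + 1}",
                group=POOL_GROUP,
                replicate=plex_idx + 1,
                plex_id=plex_id,
                channel_label=f"ch{channel:02d}",
            )
        )
    return SampleSheet(samples)


def _plex_shifts(cfg: SimulationConfig) -> dict[str, float]:
    """Symmetric per-plex log2 shifts (mean zero, span = plex_shift_log2)."""
    if cfg.n_plexes == 1:
        return {"plex1": 0.0}
    span = cfg.plex_shift_log2
    offsets = np.linspace(-span / 2.0, span / 2.0, cfg.n_plexes)
    return {f"plex{i + 1}": float(offsets[i]) for i in range(cfg.n_plexes)}


def _plant_truth(
    cfg: SimulationConfig, rng: np.random.Generator, baseline: np.ndarray, index: pd.Index
) -> tuple[pd.Series, pd.DataFrame, pd.DataFrame]:
    """Directions, per-treatment profiles, and true group-mean matrix."""
    n = cfg.n_proteins
    n_up = int(round(cfg.frac_up * n))
    n_down = int(round(cfg.frac_down * n))
    perm = rng.permutation(n)
    direction = np.full(n, "null", dtype=object)
    direction[perm[:n_up]] = "up"
    direction[perm[n_up : n_up + n_down]] = "down"
    is_dep = direction != "null"

    sign = np.where(direction == "up", 1.0, np.where(direction == "down", -1.0, 0.0))
    wt = baseline
    mdx = baseline * np.power(2.0, sign * cfg.effect_log2)

    null_idx = np.flatnonzero(~is_dep)
    n_induced = min(int(round(cfg.frac_treatment_induced * n)), null_idx.size)
    induced_idx = rng.choice(null_idx, size=n_induced, replace=False) if n_induced else np.array([], dtype=int)
    induced_sign = rng.choice([-1.0, 1.0], size=n_induced)

    profile_names = np.array(["full", "partial", "none"])
    probs = np.array([dict(cfg.restoration_profile_probs)[k] for k in profile_names])

    profiles = pd.DataFrame("n/a", index=index, columns=list(TREATMENT_GROUPS))
    means = {"WT": wt, "mdx_saline": mdx}
    for treatment in TREATMENT_GROUPS:
        assigned = np.full(n, "n/a", dtype=object)
        dep_idx = np.flatnonzero(is_dep)
        if dep_idx.size:
            assigned[dep_idx] = rng.choice(profile_names, size=dep_idx.size, p=probs)
        assigned[induced_idx] = "induced"
        treated = wt.copy()
        treated[assigned == "full"] = wt[assigned == "full"]
        treated[assigned == "none"] = mdx[assigned == "none"]
        mid = assigned == "partial"
        treated[mid] = np.sqrt(wt[mid] * mdx[mid])  # geometric midpoint
        treated[induced_idx] = wt[induced_idx] * np.power(2.0, induced_sign * cfg.effect_log2)
        profiles[treatment] = assigned
        means[treatment] = treated
    group_means = pd.DataFrame(means, index=index)[list(STUDY_GROUPS)]
    return pd.Series(direction, index=index, name="direction"), profiles, group_means


def _expected_matrix(
    group_means: pd.DataFrame, sheet: SampleSheet
) -> pd.DataFrame:
    """Noise-free channel expectations; pools carry the across-group mean."""
    pool_profile = group_means.mean(axis=1)
    cols = {}
    for s in sheet:
        cols[s.sample_id] = pool_profile if s.is_pool else group_means[s.group]
    return pd.DataFrame(cols, index=group_means.index)[sheet.sample_ids]


def _apply_plex_shift(data: pd.DataFrame, sheet: SampleSheet, shifts: Mapping[str, float]) -> pd.DataFrame:
    out = data.copy()
    for plex, shift in shifts.items():
        cols = [s.sample_id for s in sheet.samples_in_plex(plex)]
        out[cols] = out[cols] * (2.0**shift)
    return out


def _apply_coisolation(data: pd.DataFrame, sheet: SampleSheet, rho: float) -> pd.DataFrame:
    if rho == 0:
        return data
    out = data.copy()
    for plex in sheet.plex_ids:
        cols = [s.sample_id for s in sheet.samples_in_plex(plex)]
        block = out[cols]
        row_mean = block.mean(axis=1)
        out[cols] = block.mul(1.0 - rho).add(rho * row_mean, axis=0)
    return out


def _apply_noise(data: pd.DataFrame, cv: float, rng: np.random.Generator) -> pd.DataFrame:
    if cv == 0:
        return data
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    factors = rng.lognormal(mean=0.0, sigma=sigma, size=data.shape)
    return data * factors


def inject_artifacts(
    matrix: AbundanceMatrix,
    sheet: SampleSheet,
    cfg: SimulationConfig,
    seed: int,
) -> tuple[AbundanceMatrix, dict[str, list[tuple[str, str]]]]:
    """Plant single outliers (per protein-group set) and missing cells.

    Outliers multiply one study-sample cell by ``outlier_factor`` with at
    most one outlier per (row, group) replicate set. Missingness hits any
    cell (pools included) independently at ``missing_rate``. Returns the
    modified matrix and a ledger of touched cells.
    """
    rng = np.random.default_rng(seed)
    data = matrix.data.copy()
    outliers: list[tuple[str, str]] = []
    missing: list[tuple[str, str]] = []

    if cfg.outlier_rate > 0:
        groups = list(dict.fromkeys(s.group for s in sheet.study_samples()))
        for group in groups:
            cols = [s.sample_id for s in sheet.group_samples(group)]
            n_rep = len(cols)
            # P(at least one of n_rep cells is an outlier), capped to one hit
            p_any = 1.0 - (1.0 - cfg.outlier_rate) ** n_rep
            hit = rng.random(len(data.index)) < p_any
            which = rng.integers(0, n_rep, size=len(data.index))
            for ridx in np.flatnonzero(hit):
                row = data.index[ridx]
                col = cols[which[ridx]]
                if not np.isnan(data.at[row, col]):
                    data.at[row, col] *= cfg.outlier_factor
                    outliers.append((str(row), col))

    if cfg.missing_rate > 0:
        mask = rng.random(data.shape) < cfg.missing_rate
        for ridx, cidx in zip(*np.nonzero(mask)):
            row, col = data.index[ridx], data.columns[cidx]
            if not np.isnan(data.at[row, col]):
                data.at[row, col] = np.nan
                missing.append((str(row), str(col)))

    out = matrix.with_data(data)
    return out, {"outliers": outliers, "missing": missing}


def simulate_study(
    cfg: SimulationConfig,
) -> tuple[AbundanceMatrix, SampleSheet, GroundTruth]:
    """Generate a protein-level study with planted truth.

    See module docstring for the layer order. Fully deterministic in
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    sheet = make_sample_sheet(cfg)
    index = pd.Index([f"P{i:05d}" for i in range(cfg.n_proteins)], name="protein")
    baseline = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sigma, cfg.n_proteins)
    direction, profiles, group_means = _plant_truth(cfg, rng, baseline, index)
    shifts = _plex_shifts(cfg)

    data = _expected_matrix(group_means, sheet)
    data = _apply_plex_shift(data, sheet, shifts)
    data = _apply_coisolation(data, sheet, cfg.coisolation_rho)
    data = _apply_noise(data, cfg.noise_cv, rng)
    matrix = AbundanceMatrix(data=data, level="protein", state="raw")
    artifact_seed = int(rng.integers(0, 2**31 - 1))
    matrix, ledger = inject_artifacts(matrix, sheet, cfg, artifact_seed)

    truth = GroundTruth(
        direction=direction,
        profiles=profiles,
        plex_shift_log2=shifts,
        group_means=group_means,
        outlier_cells=ledger["outliers"],
        missing_cells=ledger["missing"],
    )
    return matrix, sheet, truth


def simulate_peptide_panel(
    constructs: Sequence[ConstructSequence],
    group_expression: Mapping[str, Mapping[str, float]],
    cfg: SimulationConfig,
    settings: DigestSettings = DigestSettings(),
) -> tuple[AbundanceMatrix, SampleSheet, GroundTruth]:
    """Peptide-level simulation driven by construct copy levels per group.

    A peptide's expected abundance in a sample is
    ``response_factor(peptide) * sum over constructs containing it of the
    sample group's copy level``; response factors are log-normal and recorded
    in the truth. Noise/artifact layers are identical to
    :func:`simulate_study`.
    """
    missing_groups = [g for g in STUDY_GROUPS if g not in group_expression]
    if missing_groups:
        raise ConfigError(f"group_expression missing group(s): {missing_groups}")
    class_map = classify_peptides(constructs, settings)
    peptides = sorted(class_map.membership)
    if not peptides:
        raise ConfigError("digest produced no peptides under these settings")

    rng = np.random.default_rng(cfg.seed)
    sheet = make_sample_sheet(cfg)
    index = pd.Index(peptides, name="peptide")
    rf = pd.Series(
        rng.lognormal(np.log(1e5), 0.5, len(peptides)), index=index, name="response_factor"
    )

    means = {}
    for group in STUDY_GROUPS:
        levels = group_expression[group]
        total = np.array(
            [
                sum(float(levels.get(cid, 0.0)) for cid in class_map.membership[pep])
                for pep in peptides
            ]
        )
        means[group] = rf.to_numpy() * total
    group_means = pd.DataFrame(means, index=index)[list(STUDY_GROUPS)]
    shifts = _plex_shifts(cfg)

    data = _expected_matrix(group_means, sheet)
    data = _apply_plex_shift(data, sheet, shifts)
    data = _apply_coisolation(data, sheet, cfg.coisolation_rho)
    data = _apply_noise(data, cfg.noise_cv, rng)
    matrix = AbundanceMatrix(data=data, level="peptide", state="raw")
    artifact_seed = int(rng.integers(0, 2**31 - 1))
    matrix, ledger = inject_artifacts(matrix, sheet, cfg, artifact_seed)

    n = len(peptides)
    truth = GroundTruth(
        direction=pd.Series("null", index=index, name="direction"),
        profiles=pd.DataFrame("n/a", index=index, columns=list(TREATMENT_GROUPS)),
        plex_shift_log2=shifts,
        group_means=group_means,
        outlier_cells=ledger["outliers"],
        missing_cells=ledger["missing"],
        response_factors=rf,
    )
    return matrix, sheet, truth


__all__ = [
    "DIRECTIONS",
    "PROFILES",
    "GroundTruth",
    "SimulationConfig",
    "inject_artifacts",
    "make_sample_sheet",
    "simulate_peptide_panel",
    "simulate_study",
]
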