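"""Domain types and plain-text I/O: FASTA constructs, wide abundance TSVs,
sample sheets, and JSON run configuration.

Conventions
-----------
* Missing abundance values are ``NaN`` and are never imputed; they propagate.
* The group vocabulary is closed: the five study groups plus ``POOL``.
* FASTA headers for constructs carry ``origin=`` and ``size_class=`` tags, e.g.
  ``>uDys5 origin=transgenic size_class=micro``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import ConfigError, FormatError, SchemaError, StateError, ValidationError

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

ORIGINS = ("endogenous", "transgenic")
SIZE_CLASSES = ("micro", "midi", "full")

#: The five study groups, in canonical order.
STUDY_GROUPS = ("WT", "mdx_saline", "uDys", "midiDys", "fullDys")
TREATMENT_GROUPS = ("uDys", "midiDys", "fullDys")
POOL_GROUP = "POOL"
ALL_GROUPS = STUDY_GROUPS + (POOL_GROUP,)

MATRIX_STATES = ("raw", "within_plex_normalized", "bridge_scaled")

#: The ten pairwise contrasts run in the study, as (numerator, denominator).
DEFAULT_CONTRASTS = (
    ("mdx_saline", "WT"),
    ("uDys", "WT"),
    ("midiDys", "WT"),
    ("fullDys", "WT"),
    ("mdx_saline", "uDys"),
    ("mdx_saline", "midiDys"),
    ("mdx_saline", "fullDys"),
    ("uDys", "midiDys"),
    ("uDys", "fullDys"),
    ("midiDys", "fullDys"),
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConstructSequence:
    """A named amino-acid sequence with origin and size-class tags."""

    id: str
    sequence: str
    origin: str
    size_class: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("construct id must be non-empty")
        if not self.sequence:
            raise ValidationError(f"construct {self.id!r}: sequence is empty")
        for pos, aa in enumerate(self.sequence):
            if aa not in AMINO_ACIDS:
                raise ValidationError(
                    f"construct {self.id!r}: non-amino-acid character "
                    f"{aa!r} at position {pos}"
                )
        if self.origin not in ORIGINS:
            raise ValidationError(
                f"construct {self.id!r}: origin must be one of {ORIGINS}, "
                f"got {self.origin!r}"
            )
        if self.size_class not in SIZE_CLASSES:
            raise ValidationError(
                f"construct {self.id!r}: size_class must be one of "
                f"{SIZE_CLASSES}, got {self.size_class!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SampleMeta:
    """One TMT channel: which sample it carries and where it sits."""

    sample_id: str
    group: str
    replicate: int
    plex_id: str
    channel_label: str

    def __post_init__(self) -> None:
        if self.group not in ALL_GROUPS:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown group {self.group!r} "
                f"(allowed: {', '.join(ALL_GROUPS)})"
            )
        if self.replicate < 1:
            raise ValidationError(
                f"sample {self.sample_id!r}: replicate must be >= 1"
            )

    @property
    def is_pool(self) -> bool:
        return self.group == POOL_GROUP


class SampleSheet:
    """Ordered collection of :class:`SampleMeta` with plex/group helpers."""

    def __init__(self, samples: Sequence[SampleMeta]):
        samples = list(samples)
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate sample_id(s): {dupes}")
        seen_channels = set()
        for s in samples:
            key = (s.plex_id, s.channel_label)
            if key in seen_channels:
                raise ValidationError(
                    f"duplicate (plex_id, channel_label): {key}"
                )
            seen_channels.add(key)
        for plex in sorted({s.plex_id for s in samples}):
            pools = [s for s in samples if s.plex_id == plex and s.is_pool]
            if len(pools) != 1:
                raise ValidationError(
                    f"plex {plex!r} must contain exactly one POOL sample, "
                    f"found {len(pools)}"
                )
        self.samples = samples

    def __iter__(self) -> Iterator[SampleMeta]:
        return iter(self.samples)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def plex_ids(self) -> list[str]:
        out: list[str] = []
        for s in self.samples:
            if s.plex_id not in out:
                out.append(s.plex_id)
        return out

    def samples_in_plex(self, plex_id: str) -> list[SampleMeta]:
        return [s for s in self.samples if s.plex_id == plex_id]

    def pool_sample(self, plex_id: str) -> SampleMeta:
        return next(
            s for s in self.samples if s.plex_id == plex_id and s.is_pool
        )

    def group_samples(self, group: str, *, plex_id: str | None = None) -> list[SampleMeta]:
        return [
            s
            for s in self.samples
            if s.group == group and (plex_id is None or s.plex_id == plex_id)
        ]

    def study_samples(self) -> list[SampleMeta]:
        return [s for s in self.samples if not s.is_pool]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "group": [s.group for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
                "plex_id": [s.plex_id for s in self.samples],
                "channel_label": [s.channel_label for s in self.samples],
                "is_pool": [int(s.is_pool) for s in self.samples],
            }
        )


@dataclass
class AbundanceMatrix:
    """Proteins (or peptides) x channels table of non-negative intensities.

    ``data`` is a float DataFrame indexed by row id with one column per
    sample_id; ``NaN`` marks missing values. ``state`` tracks the
    normalization stage and is enforced by the normalization functions.
    """

    data: pd.DataFrame
    level: str = "protein"
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.level not in ("peptide", "protein"):
            raise ValidationError(f"level must be peptide|protein, got {self.level!r}")
        if self.state not in MATRIX_STATES:
            raise StateError(f"unknown matrix state {self.state!r}")
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate row ids in abundance matrix")
        values = self.data.to_numpy(dtype=float, copy=False)
        if np.any(values[np.isfinite(values)] < 0):
            bad = self.data.lt(0)
            rows = list(self.data.index[bad.any(axis=1)][:5])
            raise ValidationError(f"negative abundance values (rows {rows})")

    @property
    def row_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def with_data(self, data: pd.DataFrame, *, state: str | None = None) -> "AbundanceMatrix":
        return AbundanceMatrix(data=data, level=self.level, state=state or self.state)

    def check_columns(self, sheet: SampleSheet) -> None:
        if list(self.data.columns) != sheet.sample_ids:
            raise SchemaError(
                "matrix columns do not match sample sheet order: "
                f"{list(self.data.columns)} vs {sheet.sample_ids}"
            )


@dataclass(frozen=True)
class RunConfig:
    """Cutoffs and contrast list for a differential-expression run."""

    fc_cutoff_log2: float = 1.0
    q_cutoff: float = 0.05
    grubbs_alpha: float = 0.05
    min_peptides: int = 2
    contrasts: tuple[tuple[str, str], ...] = DEFAULT_CONTRASTS
    seed: int = 0
    equal_var: bool = True

    def __post_init__(self) -> None:
        if self.fc_cutoff_log2 <= 0:
            raise ConfigError("fc_cutoff_log2 must be > 0")
        if not (0.0 < self.q_cutoff < 1.0):
            raise ConfigError("q_cutoff must lie in (0, 1)")
        if not (0.0 < self.grubbs_alpha < 1.0):
            raise ConfigError("grubbs_alpha must lie in (0, 1)")
        if self.min_peptides < 0:
            raise ConfigError("min_peptides must be >= 0")
        for pair in self.contrasts:
            if len(pair) != 2 or pair[0] == pair[1]:
                raise ConfigError(f"bad contrast {pair!r}")
            for g in pair:
                if g not in STUDY_GROUPS:
                    raise ConfigError(f"contrast group {g!r} not a study group")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "contrasts" in raw:
            raw["contrasts"] = tuple(tuple(c) for c in raw["contrasts"])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"bad run config {path}: {exc}") from exc

    def to_dict(self) -> dict:
        return {
            "fc_cutoff_log2": self.fc_cutoff_log2,
            "q_cutoff": self.q_cutoff,
            "grubbs_alpha": self.grubbs_alpha,
            "min_peptides": self.min_peptides,
            "contrasts": [list(c) for c in self.contrasts],
            "seed": self.seed,
            "equal_var": self.equal_var,
        }


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_constructs(path: str | Path) -> list[ConstructSequence]:
    """Read construct sequences from FASTA with tagged headers.

    Header dialect: ``>id origin=<endogenous|transgenic> size_class=<micro|midi|full>``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    constructs: list[ConstructSequence] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        tags = {}
        for token in record.description.split()[1:]:
            if "=" in token:
                key, _, value = token.partition("=")
                tags[key] = value
        for required in ("origin", "size_class"):
            if required not in tags:
                raise FormatError(
                    f"record {record.id!r}: header missing {required}= tag"
                )
        if record.id in seen:
            raise ValidationError(f"duplicate construct id {record.id!r}")
        seen.add(record.id)
        constructs.append(
            ConstructSequence(
                id=record.id,
                sequence=str(record.seq).upper(),
                origin=tags["origin"],
                size_class=tags["size_class"],
            )
        )
    if not constructs:
        raise FormatError(f"no FASTA records found in {path}")
    return constructs


def write_constructs(constructs: Iterable[ConstructSequence], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for c in constructs:
            fh.write(f">{c.id} origin={c.origin} size_class={c.size_class}\n")
            for i in range(0, len(c.sequence), 60):
                fh.write(c.sequence[i : i + 60] + "\n")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a TSV sample sheet (sample_id, group, replicate, plex_id, channel_label)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group", "replicate", "plex_id", "channel_label"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"sample sheet missing column(s): {sorted(missing)}")
    samples = []
    for row in df.itertuples(index=False):
        try:
            replicate = int(row.replicate)
        except (TypeError, ValueError):
            raise ValidationError(
                f"sample {row.sample_id!r}: replicate {row.replicate!r} is not an integer"
            ) from None
        samples.append(
            SampleMeta(
                sample_id=str(row.sample_id),
                group=str(row.group),
                replicate=replicate,
                plex_id=str(row.plex_id),
                channel_label=str(row.channel_label),
            )
        )
    return SampleSheet(samples)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.to_frame().to_csv(path, sep="\t", index=False)


def read_abundance(
    table_path: str | Path,
    sheet_path: str | Path,
    *,
    level: str = "protein",
) -> tuple[AbundanceMatrix, SampleSheet]:
    """Read a wide abundance TSV and its sample sheet.

    The first column holds row ids; the remaining headers must exactly match
    the sheet's sample ids (order-insensitive; columns are reordered to sheet
    order). Empty cells become missing.
    """
    sheet = read_sample_sheet(sheet_path)
    df = pd.read_csv(table_path, sep="\t", index_col=0)
    table_cols = set(df.columns)
    sheet_cols = set(sheet.sample_ids)
    if table_cols != sheet_cols:
        only_table = sorted(table_cols - sheet_cols)
        only_sheet = sorted(sheet_cols - table_cols)
        raise SchemaError(
            "table/sheet sample mismatch: "
            f"table-only={only_table}, sheet-only={only_sheet}"
        )
    df = df[sheet.sample_ids].astype(float)
    df.index = df.index.astype(str)
    df.index.name = None
    matrix = AbundanceMatrix(data=df, level=level, state="raw")
    return matrix, sheet


def write_abundance(matrix: AbundanceMatrix, path: str | Path) -> None:
    out = matrix.data.copy()
    out.index.name = matrix.level
    out.to_csv(path, sep="\t", na_rep="")


def write_table(rows: Sequence[dict], path: str | Path, *, columns: Sequence[str] | None = None) -> None:
    """Write homogeneous dict rows as UTF-8 TSV; missing rendered as empty."""
    if columns is None:
        if not rows:
            raise ValidationError("empty row list needs explicit columns")
        columns = list(rows[0].keys())
    for i, row in enumerate(rows):
        if set(row.keys()) != set(columns):
            raise ValidationError(f"row {i} does not share the common header")
    df = pd.DataFrame(list(rows), columns=list(columns))
    df.to_csv(path, sep="\t", index=False, na_rep="")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


__all__ = [
    "AMINO_ACIDS",
    "ALL_GROUPS",
    "DEFAULT_CONTRASTS",
    "POOL_GROUP",
    "STUDY_GROUPS",
    "TREATMENT_GROUPS",
    "AbundanceMatrix",
    "ConstructSequence",
    "RunConfig",
    "SampleMeta",
    "SampleSheet",
    "read_abundance",
    "read_constructs",
    "read_sample_sheet",
    "read_table",
    "write_abundance",
    "write_constructs",
    "write_sample_sheet",
    "write_table",
]
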