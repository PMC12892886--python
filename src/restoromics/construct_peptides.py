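"""In-silico tryptic digestion and construct-discriminating peptide panels.

Digestion follows the classic trypsin rule — cleave C-terminal to K or R
unless the next residue is P — with a missed-cleavage budget and length
bounds. Peptide membership in a construct is digest-based (the peptide must
appear in that construct's digest under identical settings), so peptides
spanning a deletion junction are specific to the shortened construct.

Panels generalize the three discrimination sets used for dystrophin
constructs (full-length-only, transgenic-shared, large-only) to arbitrary
construct collections via semantic predicates with a fixed precedence that
guarantees disjointness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import AMINO_ACIDS, AbundanceMatrix, ConstructSequence, SampleSheet
from .errors import ConfigError, ValidationError

PANELS = ("PAN", "FULL_ONLY", "TRANSGENIC_SHARED", "LARGE_ONLY", "OTHER")


@dataclass(frozen=True)
class DigestSettings:
    """Protease and filtering parameters for in-silico digestion."""

    protease: str = "trypsin_full"
    max_missed: int = 2
    min_len: int = 6
    max_len: int = 50

    def __post_init__(self) -> None:
        if self.protease != "trypsin_full":
            raise ConfigError(f"unsupported protease {self.protease!r}")
        if self.max_missed < 0:
            raise ConfigError("max_missed must be >= 0")
        if not (1 <= self.min_len <= self.max_len):
            raise ConfigError("need 1 <= min_len <= max_len")


@dataclass(frozen=True)
class DigestPeptide:
    """One digestion product with provenance within its parent sequence."""

    peptide: str
    missed_cleavages: int
    start: int  # 0-based position in the parent sequence


def cleavage_positions(sequence: str) -> list[int]:
    """0-based positions i such that trypsin cuts between i and i+1 (K/R not before P)."""
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def digest(sequence: str, settings: DigestSettings = DigestSettings()) -> list[DigestPeptide]:
    """Fully-specific tryptic digest with missed cleavages and length bounds.

    Returns peptides ordered by (start, length). Raises on empty or invalid
    sequences.
    """
    if not sequence:
        raise ValidationError("cannot digest an empty sequence")
    for pos, aa in enumerate(sequence):
        if aa not in AMINO_ACIDS:
            raise ValidationError(f"non-amino-acid character {aa!r} at position {pos}")
    # fragment boundaries: start indices of fully-cleaved fragments
    cuts = cleavage_positions(sequence)
    starts = [0] + [c + 1 for c in cuts]
    ends = [c + 1 for c in cuts] + [len(sequence)]
    out: list[DigestPeptide] = []
    n_frag = len(starts)
    for i in range(n_frag):
        for m in range(settings.max_missed + 1):
            j = i + m
            if j >= n_frag:
                break
            pep = sequence[starts[i] : ends[j]]
            if settings.min_len <= len(pep) <= settings.max_len:
                out.append(DigestPeptide(pep, m, starts[i]))
    out.sort(key=lambda p: (p.start, len(p.peptide)))
    return out


def digest_set(sequence: str, settings: DigestSettings = DigestSettings()) -> frozenset[str]:
    """Unique peptide sequences of a digest (membership universe)."""
    return frozenset(p.peptide for p in digest(sequence, settings))


@dataclass
class PeptideClassMap:
    """Digest-based membership map and the named discrimination panels."""

    membership: dict[str, frozenset[str]]  # peptide -> construct ids
    panels: dict[str, frozenset[str]]  # panel name -> peptide set
    settings: DigestSettings

    def panel_of(self, peptide: str) -> str:
        for name in PANELS:
            if peptide in self.panels[name]:
                return name
        raise KeyError(peptide)

    @property
    def peptides(self) -> frozenset[str]:
        return frozenset(self.membership)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "peptide": pep,
                "membership": ";".join(sorted(self.membership[pep])),
                "panel": self.panel_of(pep),
            }
            for pep in sorted(self.membership)
        ]
        return pd.DataFrame(rows, columns=["peptide", "membership", "panel"])


def classify_peptides(
    constructs: Sequence[ConstructSequence],
    settings: DigestSettings = DigestSettings(),
) -> PeptideClassMap:
    """Assign every digested peptide to exactly one discrimination panel.

    Panel predicates (checked in precedence order PAN > FULL_ONLY >
    TRANSGENIC_SHARED > LARGE_ONLY > OTHER):

    * PAN — present in every construct's digest
    * FULL_ONLY — in >=1 full-size construct, in no micro/midi construct
    * TRANSGENIC_SHARED — in every transgenic construct, in no endogenous one
    * LARGE_ONLY — in >=1 midi or full construct, in no micro construct
    * OTHER — everything else
    """
    ids = [c.id for c in constructs]
    if len(set(ids)) != len(ids):
        raise ValidationError("construct ids must be unique")
    if not any(c.size_class == "full" for c in constructs):
        raise ConfigError("need at least one construct with size_class=full")

    digests = {c.id: digest_set(c.sequence, settings) for c in constructs}
    by_class = {
        sc: {c.id for c in constructs if c.size_class == sc}
        for sc in ("micro", "midi", "full")
    }
    transgenic = {c.id for c in constructs if c.origin == "transgenic"}
    endogenous = {c.id for c in constructs if c.origin == "endogenous"}
    all_ids = set(ids)

    membership: dict[str, set[str]] = {}
    for cid, peps in digests.items():
        for pep in peps:
            membership.setdefault(pep, set()).add(cid)

    panels: dict[str, set[str]] = {name: set() for name in PANELS}
    for pep, members in membership.items():
        if members == all_ids:
            panels["PAN"].add(pep)
        elif members & by_class["full"] and not members & (by_class["micro"] | by_class["midi"]):
            panels["FULL_ONLY"].add(pep)
        elif transgenic and transgenic <= members and not members & endogenous:
            panels["TRANSGENIC_SHARED"].add(pep)
        elif members & (by_class["midi"] | by_class["full"]) and not members & by_class["micro"]:
            panels["LARGE_ONLY"].add(pep)
        else:
            panels["OTHER"].add(pep)

    return PeptideClassMap(
        membership={p: frozenset(m) for p, m in membership.items()},
        panels={name: frozenset(s) for name, s in panels.items()},
        settings=settings,
    )


@dataclass
class PanelQuant:
    """Per-sample panel abundance plus per-group mean +/- SEM."""

    panel: str
    per_sample: pd.Series  # indexed by sample_id; NaN when all peptides missing
    absent_peptides: list[str]  # panel members with no matrix row
    group_summary: pd.DataFrame | None  # group, n, mean, sem


def quantify_panel(
    matrix: AbundanceMatrix,
    class_map: PeptideClassMap,
    panel: str,
    sheet: SampleSheet | None = None,
) -> PanelQuant:
    """Average a panel's peptide rows per sample (missing values skipped).

    Panel peptides absent from the matrix are reported, never silently
    dropped. With a sample sheet, also summarises mean +/- SEM per group.
    """
    if panel not in PANELS:
        raise ValidationError(f"unknown panel {panel!r}")
    peptides = sorted(class_map.panels[panel])
    if not peptides:
        raise ValidationError(f"panel {panel} is empty")
    present = [p for p in peptides if p in matrix.data.index]
    absent = [p for p in peptides if p not in matrix.data.index]
    if not present:
        raise ValidationError(f"no rows in matrix for panel {panel}")
    per_sample = matrix.data.loc[present].mean(axis=0, skipna=True)

    summary = None
    if sheet is not None:
        rows = []
        for group in dict.fromkeys(s.group for s in sheet.study_samples()):
            cols = [s.sample_id for s in sheet.group_samples(group)]
            vals = per_sample[cols].dropna()
            n = len(vals)
            mean = float(vals.mean()) if n else np.nan
            sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
            rows.append({"group": group, "n": n, "mean": mean, "sem": sem})
        summary = pd.DataFrame(rows, columns=["group", "n", "mean", "sem"])

    return PanelQuant(
        panel=panel,
        per_sample=per_sample,
        absent_peptides=absent,
        group_summary=summary,
    )


__all__ = [
    "PANELS",
    "DigestPeptide",
    "DigestSettings",
    "PanelQuant",
    "PeptideClassMap",
    "classify_peptides",
    "cleavage_positions",
    "digest",
    "digest_set",
    "quantify_panel",
]
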