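"""Therapeutic-evaluation logic: Venn set partitions over DEP lists, the
restoration taxonomy per protein per treatment, summary counts, and the
end-to-end pipeline runner.

A protein that is dysregulated at baseline (treated-vs-WT and mdx-vs-WT
contrasts both DEP-callable) is classified per treatment as:

* restored — baseline DEP, treated-vs-WT not significant
* partial — baseline DEP, treated-vs-WT DEP, treated-vs-mdx DEP
* unrestored — baseline DEP, treated-vs-WT DEP, treated-vs-mdx not DEP
* treatment_induced — baseline not DEP, treated-vs-WT DEP
* unchanged — everything else
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .core_io import (
    AbundanceMatrix,
    RunConfig,
    SampleSheet,
    TREATMENT_GROUPS,
    write_abundance,
)
from .differential_stats import dep_set, dep_table, volcano_table
from .errors import StageError, ValidationError
from .normalization_qc import (
    apply_grubbs,
    bridge_scale,
    filter_min_peptides,
    filter_pooled_missing,
    normalize_within_plex,
)

CATEGORIES = ("restored", "partial", "unrestored", "treatment_induced", "unchanged")


# ---------------------------------------------------------------------------
# Venn partition
# ---------------------------------------------------------------------------


def venn_partition(dep_lists: Mapping[str, set[str]]) -> dict[frozenset[str], set[str]]:
    """Partition the union of DEP lists into power-set regions.

    Keys are frozensets of list names (the region's membership signature);
    every protein lands in exactly one region. Empty regions are omitted.
    """
    names = list(dep_lists)
    universe = set().union(*dep_lists.values()) if dep_lists else set()
    regions: dict[frozenset[str], set[str]] = {}
    for pid in universe:
        signature = frozenset(n for n in names if pid in dep_lists[n])
        regions.setdefault(signature, set()).add(pid)
    return regions


# ---------------------------------------------------------------------------
# Restoration classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RestorationCall:
    protein: str
    treatment: str
    category: str
    status_mdx_vs_wt: str
    status_trt_vs_wt: str
    status_trt_vs_mdx: str


def _is_dep(status: str) -> bool:
    return status in ("up", "down")


def classify_restoration(
    dep_mdx_vs_wt: pd.DataFrame,
    dep_trt_vs_wt: pd.DataFrame,
    dep_trt_vs_mdx: pd.DataFrame,
    treatment: str,
) -> pd.DataFrame:
    """Classify every protein for one treatment from its three DEP statuses.

    The three tables must cover the same protein universe. Returns a frame
    with columns protein, treatment, category and the three statuses.
    """
    universes = [set(t["protein"]) for t in (dep_mdx_vs_wt, dep_trt_vs_wt, dep_trt_vs_mdx)]
    if not (universes[0] == universes[1] == universes[2]):
        missing = sorted((universes[0] | universes[1] | universes[2])
                         - (universes[0] & universes[1] & universes[2]))
        raise ValidationError(f"DEP tables cover different proteins: {missing[:10]}")
    base = dep_mdx_vs_wt.set_index("protein")["status"]
    tw = dep_trt_vs_wt.set_index("protein")["status"]
    tm = dep_trt_vs_mdx.set_index("protein")["status"]
    rows = []
    for pid in dep_mdx_vs_wt["protein"]:
        b, w, m = base[pid], tw[pid], tm[pid]
        if _is_dep(b):
            if not _is_dep(w):
                category = "restored"
            elif _is_dep(m):
                category = "partial"
            else:
                category = "unrestored"
        else:
            category = "treatment_induced" if _is_dep(w) else "unchanged"
        rows.append(
            {
                "protein": pid,
                "treatment": treatment,
                "category": category,
                "status_mdx_vs_wt": b,
                "status_trt_vs_wt": w,
                "status_trt_vs_mdx": m,
            }
        )
    return pd.DataFrame(rows)


def restoration_summary(
    calls: pd.DataFrame, dep_baseline: pd.DataFrame, *, strict: bool = False
) -> dict:
    """Counts per treatment over the baseline DEP set.

    ``restored_inclusive`` (restored + partial) is the headline count;
    ``restored_strict`` counts category restored only. ``strict`` selects
    which of the two the ``headline`` field repeats.
    """
    baseline_deps = dep_set(dep_baseline)
    n_baseline = len(baseline_deps)
    out: dict = {"n_baseline_deps": n_baseline, "treatments": {}}
    for treatment, sub in calls.groupby("treatment"):
        on_base = sub[sub["protein"].isin(baseline_deps)]
        counts = on_base["category"].value_counts().to_dict()
        restored = int(counts.get("restored", 0))
        partial = int(counts.get("partial", 0))
        unrestored = int(counts.get("unrestored", 0))
        induced = int((sub["category"] == "treatment_induced").sum())
        entry = {
            "restored": restored,
            "partial": partial,
            "unrestored": unrestored,
            "restored_strict": restored,
            "restored_inclusive": restored + partial,
            "treatment_induced": induced,
            "headline": restored if strict else restored + partial,
        }
        if restored + partial + unrestored != n_baseline:
            raise ValidationError(
                f"{treatment}: category counts {restored}+{partial}+{unrestored} "
                f"do not sum to {n_baseline} baseline DEPs"
            )
        out["treatments"][str(treatment)] = entry
    return out


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    matrix: AbundanceMatrix
    dep_tables: dict[tuple[str, str], pd.DataFrame]
    calls: pd.DataFrame
    summary: dict
    manifest: dict


def run_pipeline(
    matrix: AbundanceMatrix,
    sheet: SampleSheet,
    cfg: RunConfig,
    *,
    peptide_counts: Mapping[str, int] | None = None,
    strict: bool = False,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """normalize -> pool filter -> bridge -> Grubbs -> DEPs -> restoration.

    Any stage failure is re-raised as :class:`StageError` tagged with the
    stage name. With ``out_dir`` set, writes the normalized matrix, one DEP
    TSV per contrast, restoration calls, summary JSON, and a manifest.
    """

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - tag and re-raise
            raise StageError(name, exc) from exc

    exclusions: dict[str, int] = {}
    m = stage("normalize_within_plex", normalize_within_plex, matrix, sheet)
    m, pool_excluded = stage("filter_pooled_missing", filter_pooled_missing, m, sheet)
    exclusions["pooled_missing"] = len(pool_excluded)
    if peptide_counts is not None:
        m, pep_excluded = stage(
            "filter_min_peptides", filter_min_peptides, m, peptide_counts, cfg.min_peptides
        )
        exclusions["min_peptides"] = len(pep_excluded)
    m = stage("bridge_scale", bridge_scale, m, sheet)
    m, grubbs_ledger = stage("apply_grubbs", apply_grubbs, m, sheet, cfg.grubbs_alpha)
    exclusions["grubbs_cells"] = int(len(grubbs_ledger))

    # DEP tables: configured contrasts plus those restoration needs
    needed = set(tuple(c) for c in cfg.contrasts)
    needed.add(("mdx_saline", "WT"))
    for t in TREATMENT_GROUPS:
        needed.add((t, "WT"))
        needed.add((t, "mdx_saline"))
    deps: dict[tuple[str, str], pd.DataFrame] = {}
    for contrast in sorted(needed):
        deps[contrast] = stage(f"dep:{contrast[0]}_vs_{contrast[1]}", dep_table, m, sheet, contrast, cfg)

    call_frames = []
    for t in TREATMENT_GROUPS:
        call_frames.append(
            stage(
                f"restoration:{t}",
                classify_restoration,
                deps[("mdx_saline", "WT")],
                deps[(t, "WT")],
                deps[(t, "mdx_saline")],
                t,
            )
        )
    calls = pd.concat(call_frames, ignore_index=True)
    summary = stage(
        "restoration_summary", restoration_summary, calls, deps[("mdx_saline", "WT")], strict=strict
    )

    manifest = {
        "version": __version__,
        "config": cfg.to_dict(),
        "strict": strict,
        "n_rows_input": len(matrix.data.index),
        "n_rows_analyzed": len(m.data.index),
        "exclusions": exclusions,
        "contrasts": [f"{a}_vs_{b}" for a, b in sorted(needed)],
    }

    result = PipelineResult(matrix=m, dep_tables=deps, calls=calls, summary=summary, manifest=manifest)
    if out_dir is not None:
        _write_bundle(result, grubbs_ledger, pool_excluded, Path(out_dir))
    return result


def _write_bundle(
    result: PipelineResult,
    grubbs_ledger: pd.DataFrame,
    pool_excluded: Sequence[str],
    out_dir: Path,
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_abundance(result.matrix, out_dir / "normalized_matrix.tsv")
    for (a, b), table in sorted(result.dep_tables.items()):
        table.reset_index(drop=True).to_csv(
            out_dir / f"dep_{a}_vs_{b}.tsv", sep="\t", index=False, na_rep=""
        )
        volcano_table(table).to_csv(
            out_dir / f"volcano_{a}_vs_{b}.tsv", sep="\t", index=False, na_rep=""
        )
    result.calls.to_csv(out_dir / "restoration.tsv", sep="\t", index=False)
    grubbs_ledger.to_csv(out_dir / "grubbs_exclusions.tsv", sep="\t", index=False)
    pd.DataFrame({"protein": list(pool_excluded)}).to_csv(
        out_dir / "pooled_missing_exclusions.tsv", sep="\t", index=False
    )
    with open(out_dir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def bundle_digest(out_dir: str | Path) -> dict[str, str]:
    """SHA-256 of every file in a bundle (determinism checks)."""
    out = {}
    for path in sorted(Path(out_dir).rglob("*")):
        if path.is_file():
            out[str(path.relative_to(out_dir))] = hashlib.sha256(path.read_bytes()).hexdigest()
    return out


__all__ = [
    "CATEGORIES",
    "PipelineResult",
    "RestorationCall",
    "bundle_digest",
    "classify_restoration",
    "restoration_summary",
    "run_pipeline",
    "venn_partition",
]
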