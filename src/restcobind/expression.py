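"""Transcript quantification and knock-down target selection.

Expression is measured either as TSS-tag counts/ppm (promoter-level) or
as mRNA-Seq rpkm (reads per kilobase of transcript per million library
tags).  Fold changes carry a pseudocount of one tag on both sides so
silent genes behave sensibly.  A gene is an explicit Rest target when its
knock-down / control fold change strictly exceeds 2 — a plain threshold,
deliberately without a variance-based differential test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import pandas as pd

from .cobinding import NON_REST_ONLY, CobindClass
from .intervals import PathLike


@dataclass(frozen=True)
class ExpressionRecord:
    """One (gene, condition, measure) quantification."""

    gene_id: str
    condition: str  # e.g. ES, EpiS, ES_ctrl, ES_restKD
    measure: str  # tss_tag_count | tss_ppm | mrna_rpkm
    value: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("expression value must be non-negative")


@dataclass
class TargetCall:
    """Knock-down response of one putative Rest target gene."""

    gene_id: str
    specificity: str  # "unique" (reference-cell-only) | "common"
    cobind: CobindClass
    kd_fold: float
    is_target: bool


def compute_rpkm(tag_count: int, gene_length: int, library_size: int) -> float:
    """rpkm = tags / (kilobases of transcript * millions of library tags)."""
    if gene_length <= 0:
        raise ValueError("gene_length must be positive")
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    if tag_count < 0:
        raise ValueError("tag_count must be non-negative")
    return tag_count / ((gene_length / 1000.0) * (library_size / 1e6))


def fold_change(numerator: float, denominator: float, pseudocount: float = 1.0) -> float:
    """(numerator + p) / (denominator + p); p > 0 keeps 0/0 at 1."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return (numerator + pseudocount) / (denominator + pseudocount)


def select_targets(
    classified_genes: Sequence[Tuple[str, str, CobindClass]],
    ctrl: Mapping[str, float],
    kd: Mapping[str, float],
    threshold: float = 2.0,
    pseudocount: float = 1.0,
) -> List[TargetCall]:
    """Call explicit targets among (gene, specificity, cobind) entries.

    ``ctrl``/``kd`` map gene id -> expression (rpkm).  A gene missing from
    either condition is excluded with a warning.  ``is_target`` is strict:
    fold > threshold.  Raising the threshold never adds targets.
    """
    calls: List[TargetCall] = []
    skipped = []
    for gene_id, specificity, cobind in classified_genes:
        if gene_id not in ctrl or gene_id not in kd:
            skipped.append(gene_id)
            continue
        fold = fold_change(kd[gene_id], ctrl[gene_id], pseudocount)
        calls.append(
            TargetCall(
                gene_id=gene_id,
                specificity=specificity,
                cobind=cobind,
                kd_fold=fold,
                is_target=fold > threshold,
            )
        )
    if skipped:
        warnings.warn(
            f"{len(skipped)} gene(s) missing expression in one condition; "
            f"excluded: {sorted(set(skipped))[:5]}..."
        )
    return calls


def _round_half_up(x: float) -> int:
    import math

    return int(math.floor(x + 0.5))


def target_rate_table(target_calls: Sequence[TargetCall]) -> pd.DataFrame:
    """Per (specificity, cobind) category: total, induced, integer percent.

    Percentages are independent rates (not parts of a whole), rounded half
    up.  Empty categories report percent 0 with ``empty`` flagged.  The
    same gene can legitimately appear in several categories when it is
    associated with sites of different classes, so category totals may
    exceed the number of distinct genes.
    """
    rows = []
    for specificity in ("unique", "common"):
        for cobind in NON_REST_ONLY:
            members = [
                t for t in target_calls
                if t.specificity == specificity and t.cobind == cobind
            ]
            total = len({t.gene_id for t in members})
            induced = len({t.gene_id for t in members if t.is_target})
            pct = _round_half_up(100.0 * induced / total) if total else 0
            rows.append(
                {
                    "specificity": specificity,
                    "cobind": cobind.value,
                    "total": total,
                    "induced": induced,
                    "percent": pct,
                    "empty": total == 0,
                }
            )
    return pd.DataFrame(rows)


def deduplicated_target_counts(
    target_calls: Sequence[TargetCall],
) -> Dict[str, int]:
    """Distinct induced genes per specificity (a gene in several co-binding
    categories counts once), alongside the per-category sums."""
    out: Dict[str, int] = {}
    for specificity in ("unique", "common"):
        genes = {
            t.gene_id for t in target_calls
            if t.specificity == specificity and t.is_target
        }
        out[f"{specificity}_distinct_genes"] = len(genes)
        out[f"{specificity}_category_sum"] = sum(
            1
            for _ in (
                t for t in target_calls
                if t.specificity == specificity and t.is_target
            )
        )
    return out


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def expression_table(records: Iterable[ExpressionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.gene_id, r.condition, r.measure, r.value) for r in records],
        columns=["gene_id", "condition", "measure", "value"],
    )


def write_expression_table(records: Iterable[ExpressionRecord], path: PathLike) -> None:
    expression_table(records).to_csv(path, sep="\t", index=False,
                                     float_format="%.6g")


def write_target_calls(calls: Sequence[TargetCall], path: PathLike) -> None:
    pd.DataFrame(
        [
            (t.gene_id, t.specificity, t.cobind.value, f"{t.kd_fold:.6g}",
             int(t.is_target))
            for t in calls
        ],
        columns=["gene_id", "specificity", "cobind", "kd_fold", "is_target"],
    ).to_csv(path, sep="\t", index=False)
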