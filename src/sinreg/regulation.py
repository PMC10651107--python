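"""Soft/hard regulation classification of direct targets.

Direct targets are binned by |log2FC| (soft: < 2; mid: 2-3 inclusive;
hard: > 3; a log2FC of 2 is a 4-fold change) and by control-cell expression
level (FPKM > 1000 strong; 10-1000 moderate; 1-9.99 low; < 1 silenced).
Hard-regulation candidates are activated direct targets that are silent in
control cells (FPKM <= 1) — genes apparently switched on rather than
fine-tuned.  A TSS-localization score quantifies whether a gene set's
binding profile is concentrated at the TSS or spread across the flanks.
"""

from __future__ import annotations

from typing import Dict, Iterable, Optional

import numpy as np
import pandas as pd

from .metagene import MetageneMatrix, average_profile
from .target_integration import ACTIVATED, DirectTargetTable

__all__ = [
    "LOG2FC_BINS", "EXPRESSION_CATEGORIES",
    "bin_log2fc_value", "bin_log2fc",
    "expression_category", "categorize_expression", "read_fpkm_table",
    "detect_hard_candidates", "tss_localization_score", "candidate_binding_contrast",
]

LOG2FC_BINS = ("lt2", "two_to_three", "gt3")
EXPRESSION_CATEGORIES = ("strong", "moderate", "low", "silenced")


def bin_log2fc_value(log2fc: float) -> str:
    """Bin one |log2FC| value: < 2 -> lt2; [2, 3] -> two_to_three; > 3 -> gt3.

    Boundary values 2 and 3 both fall in the middle bin ("less than 2" and
    "greater than 3" are strict).
    """
    m = abs(float(log2fc))
    if not np.isfinite(m):
        raise ValueError(f"non-finite log2fc {log2fc!r}")
    if m < 2.0:
        return "lt2"
    if m <= 3.0:
        return "two_to_three"
    return "gt3"


def _summary(counts: Dict[str, int], label: str, direction: str) -> dict:
    n = int(sum(counts.values()))
    out = {"label": label, "direction": direction, "n": n, "counts": counts}
    if n == 0:
        out["percentages"] = None
        out["percentages_int"] = None
    else:
        out["percentages"] = {k: round(100.0 * v / n, 1) for k, v in counts.items()}
        out["percentages_int"] = {k: int(round(100.0 * v / n)) for k, v in counts.items()}
    return out


def bin_log2fc(table: DirectTargetTable) -> Dict[str, dict]:
    """Per-direction |log2FC| bin counts and percentages for a target table.

    Returns one summary per direction present (plus directions with zero
    rows reported as empty), each with counts, one-decimal percentages and
    integer-rounded percentages.
    """
    summaries = {}
    for direction in ("repressed", "activated"):
        sub = table.frame[table.frame["direction"] == direction]
        counts = {b: 0 for b in LOG2FC_BINS}
        for v in sub["log2fc"]:
            counts[bin_log2fc_value(v)] += 1
        summaries[direction] = _summary(counts, table.label, direction)
    return summaries


def expression_category(fpkm: float) -> str:
    """FPKM category: > 1000 strong; [10, 1000] moderate; [1, 10) low; < 1 silenced."""
    f = float(fpkm)
    if f < 0 or not np.isfinite(f):
        raise ValueError(f"FPKM must be finite and >= 0, got {fpkm!r}")
    if f > 1000.0:
        return "strong"
    if f >= 10.0:
        return "moderate"
    if f >= 1.0:
        return "low"
    return "silenced"


def read_fpkm_table(path) -> pd.Series:
    """Read a TSV with columns gene_id, fpkm into a Series indexed by gene_id."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "fpkm"):
        if col not in df.columns:
            raise ValueError(f"{path}: FPKM table missing column {col!r}")
    if (df["fpkm"] < 0).any():
        raise ValueError(f"{path}: negative FPKM values")
    return df.set_index("gene_id")["fpkm"]


def categorize_expression(
    fpkm: pd.Series,
    gene_set: Optional[Iterable[str]] = None,
    label: str = "",
) -> tuple[pd.Series, dict]:
    """Expression category per gene plus category counts for a gene set.

    ``fpkm`` maps gene_id -> FPKM.  If ``gene_set`` is given, the counts
    cover only those genes (missing ones are tallied separately); otherwise
    all genes in the table.  Returns (per-gene categories, summary dict).
    """
    if (fpkm < 0).any():
        raise ValueError("negative FPKM values")
    cats = fpkm.map(expression_category)
    if gene_set is None:
        ids = list(fpkm.index)
        missing: list = []
    else:
        ids = [g for g in gene_set if g in cats.index]
        missing = [g for g in gene_set if g not in cats.index]
    counts = {c: 0 for c in EXPRESSION_CATEGORIES}
    for g in ids:
        counts[cats[g]] += 1
    summary = _summary(counts, label, "")
    summary["missing_fpkm"] = len(missing)
    return cats, summary


def detect_hard_candidates(
    table: DirectTargetTable,
    control_fpkm: pd.Series,
    fpkm_ceiling: float = 1.0,
    min_abs_log2fc: float = 3.0,
    other_bound_genes: Optional[set] = None,
    other_regulated_genes: Optional[set] = None,
) -> tuple[list, dict]:
    """Activated direct targets that are silent in control cells.

    Candidates are rows with direction ``activated`` and control FPKM
    <= ``fpkm_ceiling`` (note: the ceiling is inclusive, deliberately
    distinct from the silenced expression category's strict < 1).  The
    summary reports the fraction of candidates exceeding ``min_abs_log2fc``
    in |log2FC| and, when the other isoform's bound/regulated gene sets are
    supplied, the fractions of candidates bound / regulated by it.
    Activated targets without an FPKM entry are excluded and counted.
    """
    activated = table.frame[table.frame["direction"] == ACTIVATED]
    candidates = []
    n_hard = 0
    missing = 0
    for rec in activated.itertuples(index=False):
        if rec.gene_id not in control_fpkm.index:
            missing += 1
            continue
        if control_fpkm[rec.gene_id] <= fpkm_ceiling:
            candidates.append(rec.gene_id)
            if abs(rec.log2fc) > min_abs_log2fc:
                n_hard += 1
    n_act, n_cand = len(activated), len(candidates)
    summary = {
        "label": table.label,
        "n_activated": n_act,
        "n_candidates": n_cand,
        "candidate_pct_of_activated": round(100.0 * n_cand / n_act, 1) if n_act else None,
        "n_above_min_log2fc": n_hard,
        "hard_pct_of_candidates": round(100.0 * n_hard / n_cand, 1) if n_cand else None,
        "missing_fpkm": missing,
        "fpkm_ceiling": fpkm_ceiling,
        "min_abs_log2fc": min_abs_log2fc,
    }
    if other_bound_genes is not None:
        n_bound = sum(g in other_bound_genes for g in candidates)
        summary["n_bound_by_other"] = n_bound
        summary["bound_by_other_pct"] = round(100.0 * n_bound / n_cand, 1) if n_cand else None
    if other_regulated_genes is not None:
        n_reg = sum(g in other_regulated_genes for g in candidates)
        summary["n_regulated_by_other"] = n_reg
        summary["regulated_by_other_pct"] = round(100.0 * n_reg / n_cand, 1) if n_cand else None
    return candidates, summary


def tss_localization_score(matrix: MetageneMatrix, core_bp: int = 250) -> float:
    """Mean signal within +/- ``core_bp`` of the TSS over the mean across the
    full window.  1.0 for a flat profile; >> 1 for a sharp TSS peak.  Returns
    NaN when the full-window mean is zero."""
    prof = average_profile(matrix)["mean"].to_numpy()
    mids = matrix.bin_midpoints
    core = prof[np.abs(mids) <= core_bp]
    overall = prof.mean()
    if overall == 0:
        return float("nan")
    return float(core.mean() / overall)


def candidate_binding_contrast(
    matrix_candidates: MetageneMatrix,
    matrix_all_activated: MetageneMatrix,
    core_bp: int = 250,
) -> dict:
    """Contrast TSS localization of binding between two gene sets.

    Returns the two average profiles and a scalar TSS-localization score per
    set (mean signal within +/- ``core_bp`` of the TSS divided by the mean
    over the full window; higher = more TSS-localized).  The score is this
    package's own quantification of a qualitative profile-shape contrast.
    """
    if (matrix_candidates.flank_bp, matrix_candidates.bin_bp) != (
        matrix_all_activated.flank_bp, matrix_all_activated.bin_bp
    ):
        raise ValueError("matrices must share flank/bin structure")
    return {
        "profile_candidates": average_profile(matrix_candidates),
        "profile_all_activated": average_profile(matrix_all_activated),
        "score_candidates": tss_localization_score(matrix_candidates, core_bp),
        "score_all_activated": tss_localization_score(matrix_all_activated, core_bp),
        "core_bp": core_bp,
    }
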