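"""RNA Pol II promoter-proximal pausing index and group comparison.

The pausing index of a gene is the ratio of mean polymerase signal in a
promoter window around the TSS (default -50 bp to +50 bp) to the mean
signal in the gene body (default +300 bp after the TSS to 100 bp before the
TES), both in transcription orientation.  High values indicate
promoter-proximal pausing.  Genes too short to carry a body window, or with
zero body signal, are excluded (not given infinite indices) and the
exclusions are tallied.

Group differences in pausing are assessed with the Mann-Whitney U test:
exact two-sided p by full enumeration of rank assignments for small
tie-free samples, otherwise a tie-corrected normal approximation with
continuity correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation_io import GeneModel, GenomeAnnotation, oriented_window
from .signal_tracks import SignalTrack, window_mean

__all__ = ["PausingIndexResult", "GroupComparison", "pausing_index",
           "pausing_table", "mann_whitney_u", "compare_pausing"]

STATUS_OK = "ok"
STATUS_SHORT = "excluded_short_gene"
STATUS_ZERO_BODY = "excluded_zero_body"

# exact enumeration is C(n_a + n_b, n_a) assignments; cheap up to n = 12
_EXACT_N_MAX = 12


@dataclass(frozen=True)
class PausingIndexResult:
    gene_id: str
    promoter_mean: Optional[float]
    body_mean: Optional[float]
    pi: Optional[float]
    status: str

    def __post_init__(self) -> None:
        if (self.pi is not None) != (self.status == STATUS_OK):
            raise ValueError("pi must be present exactly when status is ok")


@dataclass(frozen=True)
class GroupComparison:
    """Mann-Whitney U comparison of two samples.

    ``u_statistic`` is the conventional reported U = min(U_a, U_b);
    ``method`` records whether the p-value came from exact enumeration or
    the tie-corrected normal approximation.
    """

    u_statistic: float
    p_two_sided: float
    n_a: int
    n_b: int
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.u_statistic <= self.n_a * self.n_b):
            raise ValueError("U outside [0, n_a * n_b]")
        if not (0.0 <= self.p_two_sided <= 1.0):
            raise ValueError("p outside [0, 1]")


def pausing_index(
    track: SignalTrack,
    gene: GeneModel,
    promoter_up: int = 50,
    promoter_down: int = 50,
    body_start_offset: int = 300,
    body_end_offset: int = 100,
) -> PausingIndexResult:
    """Per-gene pausing index from a signal track.

    Promoter window: oriented offsets ``[-promoter_up, +promoter_down)``
    around the TSS.  Body window: oriented offsets ``[body_start_offset,
    length - body_end_offset)``, i.e. +300 bp after the TSS through 100 bp
    before the TES by default.  Enrichment is the mean per-base signal, so
    the ratio is independent of window lengths.
    """
    if min(promoter_up, promoter_down, body_start_offset, body_end_offset) < 0:
        raise ValueError("window offsets must be >= 0")
    body_lo, body_hi = body_start_offset, gene.length - body_end_offset
    if body_hi <= body_lo:
        return PausingIndexResult(gene.gene_id, None, None, None, STATUS_SHORT)
    p_lo, p_hi = oriented_window(gene.tss, -promoter_up, promoter_down, gene.strand)
    b_lo, b_hi = oriented_window(gene.tss, body_lo, body_hi, gene.strand)
    promoter_mean = window_mean(track, gene.chrom, p_lo, p_hi)
    body_mean = window_mean(track, gene.chrom, b_lo, b_hi)
    if body_mean == 0.0:
        return PausingIndexResult(gene.gene_id, promoter_mean, body_mean, None, STATUS_ZERO_BODY)
    return PausingIndexResult(
        gene.gene_id, promoter_mean, body_mean, promoter_mean / body_mean, STATUS_OK
    )


def pausing_table(track: SignalTrack, annotation: GenomeAnnotation,
                  gene_ids: Optional[Iterable[str]] = None, **window_kwargs) -> pd.DataFrame:
    """Pausing-index results for many genes as a tidy frame."""
    ids = list(gene_ids) if gene_ids is not None else [g.gene_id for g in annotation]
    rows = []
    for gid in ids:
        r = pausing_index(track, annotation[gid], **window_kwargs)
        rows.append(dict(gene_id=r.gene_id, promoter_mean=r.promoter_mean,
                         body_mean=r.body_mean, pi=r.pi, status=r.status))
    return pd.DataFrame(rows, columns=["gene_id", "promoter_mean", "body_mean", "pi", "status"])


def _midranks(pooled: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties given the mean of the ranks they span."""
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(pooled.size, dtype=float)
    sorted_vals = pooled[order]
    i = 0
    while i < pooled.size:
        j = i
        while j + 1 < pooled.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0  # mean of ranks i+1 .. j+1
        i = j + 1
    return ranks


def mann_whitney_u(values_a: Sequence[float], values_b: Sequence[float]) -> GroupComparison:
    """Two-sided Mann-Whitney U test.

    U is computed by the rank-sum identity ``U_a = R_a - n_a (n_a + 1) / 2``
    with midranks for ties.  The two-sided p-value is exact (full
    enumeration of the C(n_a + n_b, n_a) equally likely rank assignments)
    when ``n_a + n_b <= 12`` and there are no ties, and otherwise comes from
    the normal approximation with tie-corrected variance and continuity
    correction.  Reported U is min(U_a, U_b); identical constant samples
    (zero rank variance) give p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("values must be finite")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    r_a = float(ranks[:n_a].sum())
    u_a = r_a - n_a * (n_a + 1) / 2.0
    u_b = n_a * n_b - u_a
    u_min = min(u_a, u_b)

    has_ties = np.unique(pooled).size < pooled.size
    if n_a + n_b <= _EXACT_N_MAX and not has_ties:
        # enumerate every assignment of ranks to group a; count those with a
        # min-U at least as extreme as observed
        all_ranks = range(1, n_a + n_b + 1)
        base = n_a * (n_a + 1) / 2.0
        hits = total = 0
        for combo in combinations(all_ranks, n_a):
            u = sum(combo) - base
            if min(u, n_a * n_b - u) <= u_min:
                hits += 1
            total += 1
        return GroupComparison(u_min, hits / total, n_a, n_b, "exact")

    n = n_a + n_b
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3) - tie_counts).sum())
    var_u = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:
        return GroupComparison(u_min, 1.0, n_a, n_b, "normal_tie_corrected")
    mean_u = n_a * n_b / 2.0
    z = (u_min - mean_u + 0.5) / math.sqrt(var_u)  # continuity correction toward the mean
    p = min(1.0, 2.0 * 0.5 * math.erfc(-z / math.sqrt(2.0)))
    return GroupComparison(u_min, p, n_a, n_b, "normal_tie_corrected")


def compare_pausing(
    track: SignalTrack,
    annotation: GenomeAnnotation,
    group_a: Iterable[str],
    group_b: Iterable[str],
    label_a: str = "repressed",
    label_b: str = "activated",
    check_disjoint: bool = True,
    **window_kwargs,
) -> dict:
    """Pausing-index comparison between two gene groups.

    Computes per-gene pausing for both groups, drops excluded genes from
    the test (tallying them in the report), and runs the Mann-Whitney U
    test on the remaining indices.  The report includes group medians and
    the direction of effect.
    """
    ids_a, ids_b = list(group_a), list(group_b)
    if check_disjoint and set(ids_a) & set(ids_b):
        raise ValueError("gene groups must be disjoint")
    tables = {}
    pis = {}
    excl = {}
    for label, ids in ((label_a, ids_a), (label_b, ids_b)):
        tab = pausing_table(track, annotation, ids, **window_kwargs)
        tables[label] = tab
        ok = tab[tab["status"] == STATUS_OK]
        pis[label] = ok["pi"].to_numpy(dtype=float)
        excl[label] = tab["status"].value_counts().drop(STATUS_OK, errors="ignore").to_dict()
        if pis[label].size == 0:
            raise ValueError(f"group {label!r}: no genes with a computable pausing index "
                             f"(exclusions: {excl[label]})")
    comparison = mann_whitney_u(pis[label_a], pis[label_b])
    med_a, med_b = float(np.median(pis[label_a])), float(np.median(pis[label_b]))
    return {
        "tables": tables,
        "comparison": comparison,
        "median": {label_a: med_a, label_b: med_b},
        "median_difference": med_a - med_b,
        "higher_pausing": label_a if med_a > med_b else (label_b if med_b > med_a else "tie"),
        "excluded": excl,
        "n_tested": {label_a: int(pis[label_a].size), label_b: int(pis[label_b].size)},
    }
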