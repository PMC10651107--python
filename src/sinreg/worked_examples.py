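"""Construct direct-target and FPKM tables from published summary counts.

The original study reports its integration results as counts (how many
direct targets per isoform, how many shared, how many per |log2FC| bin or
expression category).  These builders expand such counts into explicit
tables with synthetic gene identifiers and representative values inside
each bin, so the package's summary operations can recompute the reported
percentages from first principles.  The tables are synthetic stand-ins for
the unpublished per-gene lists: only the counts are real.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .target_integration import ACTIVATED, REPRESSED, DirectTargetTable

__all__ = ["targets_from_bin_counts", "overlap_tables_from_counts", "fpkm_from_category_counts"]

# representative |log2FC| per bin: soft (<2), mid ([2,3]), hard (>3)
_BIN_MAGNITUDES = (1.0, 2.5, 4.0)


def targets_from_bin_counts(
    repressed_bins: Tuple[int, int, int] = (0, 0, 0),
    activated_bins: Tuple[int, int, int] = (0, 0, 0),
    label: str = "",
    prefix: str = "g",
    fdr: float = 0.01,
) -> DirectTargetTable:
    """Direct-target table with the given per-bin counts per direction.

    ``repressed_bins``/``activated_bins`` give counts in the (<2, 2-3, >3)
    |log2FC| bins.  Repressed rows carry positive log2fc and activated rows
    negative, as under a knockdown; the summaries only use |log2FC| and the
    direction label, so the convention is immaterial.
    """
    rows = []
    i = 0
    for direction, bins, sign in ((REPRESSED, repressed_bins, 1.0),
                                  (ACTIVATED, activated_bins, -1.0)):
        for mag, count in zip(_BIN_MAGNITUDES, bins):
            for _ in range(count):
                i += 1
                rows.append(dict(gene_id=f"{prefix}{i:05d}", bound=True, n_peaks=1,
                                 direction=direction, log2fc=sign * mag, fdr=fdr))
    return DirectTargetTable(pd.DataFrame(rows, columns=DirectTargetTable.COLUMNS), label=label)


def overlap_tables_from_counts(
    n_a: int, n_b: int, shared: int,
    label_a: str = "a", label_b: str = "b",
    directions_a: Optional[Tuple[int, int]] = None,
    directions_b: Optional[Tuple[int, int]] = None,
) -> Tuple[DirectTargetTable, DirectTargetTable]:
    """Two direct-target tables with the given sizes and intersection.

    Gene ids are synthetic: the first ``shared`` ids are common to both
    tables.  ``directions_a``/``directions_b`` optionally give
    (repressed, activated) counts per table (defaulting to all repressed).
    """
    if shared > min(n_a, n_b):
        raise ValueError("shared exceeds a table size")

    def build(n: int, offset: int, label: str, directions) -> DirectTargetTable:
        n_rep, n_act = directions if directions is not None else (n, 0)
        if n_rep + n_act != n:
            raise ValueError(f"direction counts for {label!r} must sum to {n}")
        ids = [f"shared{i:05d}" if i < shared else f"{label}{offset + i:05d}"
               for i in range(n)]
        dirs = [REPRESSED] * n_rep + [ACTIVATED] * n_act
        frame = pd.DataFrame({
            "gene_id": ids, "bound": True, "n_peaks": 1, "direction": dirs,
            "log2fc": [1.0 if d == REPRESSED else -1.0 for d in dirs], "fdr": 0.01,
        })
        return DirectTargetTable(frame[DirectTargetTable.COLUMNS], label=label)

    return build(n_a, 0, label_a, directions_a), build(n_b, 100000, label_b, directions_b)


def fpkm_from_category_counts(
    gene_ids: Sequence[str],
    category_counts: Dict[str, int],
) -> pd.Series:
    """FPKM series assigning representative in-category values by count.

    ``category_counts`` maps category name (strong/moderate/low/silenced) to
    the number of genes; counts must sum to ``len(gene_ids)``.  Genes are
    assigned in order.
    """
    representative = {"strong": 2000.0, "moderate": 100.0, "low": 5.0, "silenced": 0.5}
    if sum(category_counts.values()) != len(gene_ids):
        raise ValueError("category counts must sum to the number of genes")
    values = np.concatenate([
        np.full(count, representative[cat]) for cat, count in category_counts.items()
    ]) if gene_ids else np.array([])
    return pd.Series(values, index=list(gene_ids), name="fpkm")
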