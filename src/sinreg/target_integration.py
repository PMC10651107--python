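"""Integrate ChIP peaks with differential expression into direct-target tables.

A *direct target* is a gene that is both bound by the factor (at least one
peak assigned within the strand-aware promoter-to-terminator window) and
significantly differentially expressed when the factor is perturbed.  The
direction of regulation depends on the perturbation polarity: under a
knockdown, a gene that goes *up* when the factor is removed is repressed by
the factor; under overexpression the mapping is inverted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation_io import GenomeAnnotation

log = logging.getLogger(__name__)

__all__ = [
    "Peak",
    "PerturbationConfig",
    "DirectTargetTable",
    "read_peaks",
    "write_narrowpeak",
    "read_de_table",
    "assign_peaks_to_genes",
    "classify_direction",
    "build_direct_targets",
    "overlap_summary",
    "annotate_enhancer_overlap",
]

REPRESSED = "repressed"
ACTIVATED = "activated"
NOT_SIGNIFICANT = "not_significant"

KNOCKDOWN = "knockdown"
OVEREXPRESSION = "overexpression"


@dataclass(frozen=True)
class Peak:
    """A called peak interval (0-based half-open) with optional score/summit."""

    chrom: str
    start: int
    end: int
    score: Optional[float] = None
    summit: Optional[int] = None  # offset from start, in [0, end - start)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak {self.chrom}:{self.start}-{self.end}: start >= end")
        if self.summit is not None and not (0 <= self.summit < self.end - self.start):
            raise ValueError(
                f"peak {self.chrom}:{self.start}-{self.end}: summit {self.summit} out of range"
            )


@dataclass(frozen=True)
class PerturbationConfig:
    """Polarity and significance thresholds for direct-target calling.

    Defaults follow the knockdown analysis: FDR < 0.05 and p < 0.05.  The
    overexpression analysis in the same study used FDR < 0.001.
    """

    polarity: str = KNOCKDOWN
    fdr_threshold: float = 0.05
    p_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.polarity not in (KNOCKDOWN, OVEREXPRESSION):
            raise ValueError(f"polarity must be knockdown or overexpression, got {self.polarity!r}")
        for name in ("fdr_threshold", "p_threshold"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {v}")


@dataclass
class DirectTargetTable:
    """Genes that are peak-bound AND significantly differentially expressed.

    ``frame`` columns: gene_id, bound, n_peaks, direction, log2fc, fdr.
    Every row has ``bound == True`` and a direction of repressed/activated.
    """

    frame: pd.DataFrame
    label: str = ""

    COLUMNS = ["gene_id", "bound", "n_peaks", "direction", "log2fc", "fdr"]

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"direct-target table missing columns: {missing}")
        if len(self.frame):
            if not self.frame["bound"].all():
                raise ValueError("direct-target rows must all be bound")
            bad = ~self.frame["direction"].isin([REPRESSED, ACTIVATED])
            if bad.any():
                raise ValueError("direct-target rows must be repressed or activated")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def gene_ids(self) -> set:
        return set(self.frame["gene_id"])

    def by_direction(self, direction: str) -> "DirectTargetTable":
        return DirectTargetTable(
            self.frame[self.frame["direction"] == direction].reset_index(drop=True),
            label=f"{self.label}:{direction}" if self.label else direction,
        )

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, label: str = "") -> "DirectTargetTable":
        return cls(pd.read_csv(path, sep="\t"), label=label)


def read_peaks(path) -> List[Peak]:
    """Read peaks from BED3+ or ENCODE narrowPeak (10 columns, summit last).

    A narrowPeak summit of -1 (summit not called) maps to ``summit=None``.
    """
    peaks: List[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >= 3 BED columns")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            score = float(f[4]) if len(f) > 4 and f[4] not in (".", "") else None
            summit = None
            if len(f) >= 10:
                s = int(f[9])
                summit = s if s >= 0 else None
            peaks.append(Peak(chrom, start, end, score=score, summit=summit))
    return peaks


def write_narrowpeak(peaks: Sequence[Peak], path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            score = int(p.score) if p.score is not None else 0
            summit = p.summit if p.summit is not None else -1
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\tpeak_{i + 1}\t{score}\t.\t0\t-1\t-1\t{summit}\n"
            )


def read_de_table(path) -> pd.DataFrame:
    """Read a differential-expression TSV with columns gene_id, log2fc, pvalue, fdr."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2fc", "pvalue", "fdr"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: DE table missing columns {sorted(missing)}")
    for col in ("pvalue", "fdr"):
        if ((df[col] < 0) | (df[col] > 1)).any():
            raise ValueError(f"{path}: {col} outside [0, 1]")
    if not np.isfinite(df["log2fc"].to_numpy(dtype=float)).all():
        raise ValueError(f"{path}: non-finite log2fc")
    return df


def _gene_window(gene, upstream_bp: int, past_tes_bp: int) -> tuple[int, int]:
    """Strand-aware assignment window: upstream of the TSS through past the TES."""
    if gene.strand == "+":
        lo, hi = gene.start - upstream_bp, gene.end + past_tes_bp
    else:
        lo, hi = gene.start - past_tes_bp, gene.end + upstream_bp
    return max(0, lo), hi


def assign_peaks_to_genes(
    peaks: Sequence[Peak],
    annotation: GenomeAnnotation,
    upstream_bp: int = 1000,
    past_tes_bp: int = 100,
) -> Dict[str, List[Peak]]:
    """Assign each peak to every gene whose window it overlaps by >= 1 bp.

    The window runs from ``upstream_bp`` upstream of the TSS to
    ``past_tes_bp`` past the TES, oriented in transcription direction: for a
    + strand gene the genomic window is ``[start - upstream_bp, end +
    past_tes_bp)``; for a - strand gene it is ``[start - past_tes_bp, end +
    upstream_bp)``.  A peak may be assigned to multiple (overlapping) genes;
    genes with no assigned peaks are absent from the returned map.  Windows
    extending past the chromosome start are clipped at 0 and logged.
    """
    if upstream_bp < 0 or past_tes_bp < 0:
        raise ValueError("window extensions must be >= 0")
    trees: Dict[str, IntervalTree] = {}
    for gene in annotation:
        lo, hi = _gene_window(gene, upstream_bp, past_tes_bp)
        if lo == 0 and gene.start - (upstream_bp if gene.strand == "+" else past_tes_bp) < 0:
            log.debug("window for %s clipped at chromosome start", gene.gene_id)
        trees.setdefault(gene.chrom, IntervalTree()).addi(lo, hi, gene.gene_id)
    assigned: Dict[str, List[Peak]] = {}
    for peak in peaks:
        tree = trees.get(peak.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(peak.start, peak.end):
            assigned.setdefault(hit.data, []).append(peak)
    return assigned


def classify_direction(log2fc: float, p_value: float, fdr: float, config: PerturbationConfig) -> str:
    """Classify one DE record as repressed / activated / not_significant.

    Under knockdown polarity a significant positive log2fc (gene up when the
    factor is removed) means the factor represses the gene; under
    overexpression the mapping is inverted.  A log2fc of exactly 0 has no
    direction and is not significant.
    """
    if fdr > config.fdr_threshold or p_value > config.p_threshold or log2fc == 0:
        return NOT_SIGNIFICANT
    up = log2fc > 0
    if config.polarity == KNOCKDOWN:
        return REPRESSED if up else ACTIVATED
    return ACTIVATED if up else REPRESSED


def build_direct_targets(
    peaks: Sequence[Peak],
    annotation: GenomeAnnotation,
    de_table: pd.DataFrame,
    config: PerturbationConfig,
    label: str = "",
    upstream_bp: int = 1000,
    past_tes_bp: int = 100,
) -> DirectTargetTable:
    """Intersect bound genes with significant DE records into a direct-target table.

    DE gene_ids not present in the annotation are logged and dropped.  An
    empty intersection yields a valid empty table.
    """
    assigned = assign_peaks_to_genes(peaks, annotation, upstream_bp, past_tes_bp)
    unmatched = [g for g in de_table["gene_id"] if g not in annotation]
    if unmatched:
        log.warning("%d DE gene_ids not in annotation; dropped (e.g. %s)",
                    len(unmatched), unmatched[:3])
    rows = []
    for rec in de_table.itertuples(index=False):
        if rec.gene_id not in annotation or rec.gene_id not in assigned:
            continue
        direction = classify_direction(rec.log2fc, rec.pvalue, rec.fdr, config)
        if direction == NOT_SIGNIFICANT:
            continue
        rows.append(
            dict(gene_id=rec.gene_id, bound=True, n_peaks=len(assigned[rec.gene_id]),
                 direction=direction, log2fc=rec.log2fc, fdr=rec.fdr)
        )
    frame = pd.DataFrame(rows, columns=DirectTargetTable.COLUMNS)
    if not rows:
        log.info("direct-target intersection is empty for %r", label)
    return DirectTargetTable(frame, label=label)


def overlap_summary(table_a: DirectTargetTable, table_b: DirectTargetTable) -> dict:
    """Two-set (Venn) overlap of direct-target tables, keyed by gene_id.

    Returns counts ``only_a``/``only_b``/``shared`` plus, per table, the
    percentage shared and unique — both to one decimal place and rounded to
    integers for display.
    """
    a, b = table_a.gene_ids, table_b.gene_ids
    shared = len(a & b)
    only_a, only_b = len(a) - shared, len(b) - shared

    def pcts(part: int, total: int) -> dict:
        if total == 0:
            return {"pct": None, "pct_int": None}
        pct = 100.0 * part / total
        return {"pct": round(pct, 1), "pct_int": int(round(pct))}

    return {
        "label_a": table_a.label,
        "label_b": table_b.label,
        "n_a": len(a),
        "n_b": len(b),
        "only_a": only_a,
        "only_b": only_b,
        "shared": shared,
        "shared_of_a": pcts(shared, len(a)),
        "shared_of_b": pcts(shared, len(b)),
        "unique_of_a": pcts(only_a, len(a)),
        "unique_of_b": pcts(only_b, len(b)),
    }


def annotate_enhancer_overlap(
    peaks: Sequence[Peak],
    enhancers: Sequence[tuple],
) -> tuple[List[bool], dict]:
    """Flag each peak as enhancer-overlapping (>= 1 bp with any enhancer interval).

    ``enhancers`` are ``(chrom, start, end)`` tuples (BED intervals).  Returns
    the per-peak flags in input order and counts of enhancer / non-enhancer
    peaks.
    """
    trees: Dict[str, IntervalTree] = {}
    for chrom, start, end, *_ in enhancers:
        if start < end:
            trees.setdefault(chrom, IntervalTree()).addi(int(start), int(end))
    flags = []
    for peak in peaks:
        tree = trees.get(peak.chrom)
        flags.append(bool(tree is not None and tree.overlap(peak.start, peak.end)))
    counts = {
        "enhancer_peaks": int(sum(flags)),
        "non_enhancer_peaks": int(len(flags) - sum(flags)),
    }
    return flags, counts
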