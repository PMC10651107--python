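"""Gene annotation parsing and the coordinate conventions used everywhere else.

All coordinates in this package are 0-based half-open (BED convention).
GTF input (1-based inclusive) is shifted on read.  The transcription start
site (TSS) of a minus-strand gene is the *last* base of its interval
(``end - 1``), i.e. the biological 5' end; the transcription end site (TES)
is the opposite boundary.  Every strand-aware window computed downstream
(peak assignment, metagene anchors, pausing windows) derives from these two
anchors.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional

__all__ = [
    "GeneModel",
    "GenomeAnnotation",
    "read_gtf",
    "read_bed",
    "write_bed",
    "oriented_window",
]

_STRANDS = ("+", "-")


@dataclass(frozen=True)
class GeneModel:
    """A strand-aware gene interval with derived TSS/TES anchors.

    Parameters
    ----------
    gene_id : str
        Unique identifier.
    chrom : str
        Chromosome name.
    start, end : int
        0-based half-open interval, ``start < end``.
    strand : str
        ``"+"`` or ``"-"``.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}")
        if self.start < 0:
            raise ValueError(f"gene {self.gene_id}: negative start {self.start}")

    @property
    def tss(self) -> int:
        """0-based position of the transcription start site (5' end)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        """0-based position of the transcription end site (3' end)."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


def oriented_window(anchor: int, offset_start: int, offset_end: int, strand: str) -> tuple[int, int]:
    """Genomic half-open interval for oriented offsets ``[offset_start, offset_end)``.

    Offsets are in transcription direction relative to ``anchor`` (offset 0 is
    the anchor base itself; negative offsets are upstream of it).  For minus
    strand the offsets run leftward in genomic coordinates, so the genomic
    interval is mirrored about the anchor.
    """
    if offset_start >= offset_end:
        raise ValueError(f"empty oriented window [{offset_start}, {offset_end})")
    if strand == "+":
        return anchor + offset_start, anchor + offset_end
    if strand == "-":
        return anchor - offset_end + 1, anchor - offset_start + 1
    raise ValueError(f"strand must be + or -, got {strand!r}")


@dataclass
class GenomeAnnotation:
    """A collection of :class:`GeneModel` keyed by unique ``gene_id``."""

    genes: Dict[str, GeneModel] = field(default_factory=dict)
    chrom_sizes: Optional[Dict[str, int]] = None

    def __post_init__(self) -> None:
        if self.chrom_sizes is not None:
            for g in self.genes.values():
                size = self.chrom_sizes.get(g.chrom)
                if size is not None and g.end > size:
                    raise ValueError(
                        f"gene {g.gene_id} ends at {g.end}, beyond {g.chrom} length {size}"
                    )

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterable[GeneModel]:
        return iter(self.genes.values())

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def add(self, gene: GeneModel) -> None:
        if gene.gene_id in self.genes:
            raise ValueError(f"duplicate gene_id {gene.gene_id!r}")
        self.genes[gene.gene_id] = gene

    def subset(self, gene_ids: Iterable[str]) -> "GenomeAnnotation":
        ids = list(gene_ids)
        missing = [g for g in ids if g not in self.genes]
        if missing:
            raise KeyError(f"unknown gene_ids: {missing}")
        return GenomeAnnotation(
            genes={g: self.genes[g] for g in ids}, chrom_sizes=self.chrom_sizes
        )


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf(path, feature: str = "gene", id_attribute: str = "gene_id") -> GenomeAnnotation:
    """Read a GTF file into a :class:`GenomeAnnotation`.

    Rows whose feature column matches ``feature`` are collected; one
    :class:`GeneModel` is built per unique value of ``id_attribute``,
    spanning the minimum start to maximum end of its rows.  GTF 1-based
    inclusive coordinates are converted to 0-based half-open
    (``start := gtf_start - 1``).

    Raises
    ------
    ValueError
        On malformed lines (with line number) or when rows sharing an id
        disagree on chromosome or strand.
    """
    spans: Dict[str, list] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}: line {lineno}: expected 9 GTF columns, got {len(fields)}")
            chrom, _source, feat, start_s, end_s, _score, strand, _frame, attrs = fields[:9]
            if feat != feature:
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from exc
            attr_map = dict(_GTF_ATTR.findall(attrs))
            if id_attribute not in attr_map:
                raise ValueError(
                    f"{path}: line {lineno}: missing attribute {id_attribute!r}"
                )
            gid = attr_map[id_attribute]
            rec = spans.get(gid)
            if rec is None:
                spans[gid] = [chrom, start1 - 1, end1, strand]
            else:
                if rec[0] != chrom or rec[3] != strand:
                    raise ValueError(
                        f"{path}: line {lineno}: gene {gid!r} has conflicting chrom/strand"
                    )
                rec[1] = min(rec[1], start1 - 1)
                rec[2] = max(rec[2], end1)
    ann = GenomeAnnotation()
    for gid, (chrom, start, end, strand) in spans.items():
        ann.add(GeneModel(gid, chrom, start, end, strand))
    return ann


def read_bed(path) -> GenomeAnnotation:
    """Read a BED6 file (name + strand required) into a :class:`GenomeAnnotation`."""
    ann = GenomeAnnotation()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path}: line {lineno}: BED6 requires 6 columns (strand missing?)"
                )
            chrom, start_s, end_s, name, _score, strand = fields[:6]
            start, end = int(start_s), int(end_s)
            if start >= end:
                raise ValueError(f"{path}: line {lineno}: start >= end ({start} >= {end})")
            ann.add(GeneModel(name, chrom, start, end, strand))
    return ann


def write_bed(annotation: GenomeAnnotation, path) -> None:
    """Write an annotation as BED6 (score column fixed at 0), sorted by position."""
    genes = sorted(annotation, key=lambda g: (g.chrom, g.start, g.end, g.gene_id))
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")
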