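"""Fully labelled synthetic datasets for end-to-end pipeline verification.

The generator emulates the statistical structure the downstream analysis
assumes — promoter-enriched polymerase signal with planted promoter:body
pausing ratios, peaks concentrated at TSSs, differential-expression tables
with planted soft/mid/hard effect-size mixtures under knockdown or
overexpression polarity, and FPKM tables with planted expression
categories — so that every stage (peak assignment, target integration,
metagene profiling, pausing index, regulation binning) can be checked
against ground truth without any external download.

Class labels (direction, effect class, expression category) are planted by
exact stratified counts (largest-remainder apportionment of the configured
weights) rather than independent draws, so the realized label proportions
match the configured ones up to rounding; continuous quantities (gene
lengths, effect sizes, signal levels, FPKM values) are drawn from the
configured distributions.  All randomness flows from one seeded generator:
identical configs give byte-identical on-disk datasets.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .annotation_io import GeneModel, GenomeAnnotation, write_bed
from .signal_tracks import SignalTrack, write_bedgraph
from .target_integration import (
    KNOCKDOWN, OVEREXPRESSION, Peak, write_narrowpeak,
)

__all__ = ["SimulationConfig", "SyntheticDataset", "simulate_annotation",
           "simulate_signal", "simulate_peaks", "simulate_de_and_fpkm",
           "simulate_dataset", "write_dataset", "load_config"]

_CLASS_RANGES = {"soft": (0.3, 1.8), "mid": (2.0, 3.0), "hard": (3.2, 6.0)}
# log-normal medians per expression category; draws are clipped into the
# category's FPKM range so planted labels are always recoverable
_FPKM_MEDIANS = {"silenced": 0.3, "low": 3.0, "moderate": 100.0, "strong": 2000.0}
_FPKM_RANGES = {
    "silenced": (0.0, 0.999),
    "low": (1.0, 9.99),
    "moderate": (10.0, 1000.0),
    "strong": (1000.01, 50000.0),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic dataset; defaults are the study conditions.

    Gene direction labels split 20/20/60 into repressed / activated / null
    (100 genes per regulated group at the default ``n_genes=500``); true
    targets carry planted effect sizes mixed 90/6/4 across soft
    (|log2FC| ~ U(0.3, 1.8)), mid (U(2.0, 3.0)) and hard (U(3.2, 6.0))
    classes.  Planted pausing ratios default to 5.0 for repressed and 1.5
    for activated genes.  Intergenic gaps are wide enough (>= 1.8 kb) that
    TSS-proximal peaks can never fall into a neighbouring gene's
    assignment window, keeping bound/unbound ground truth exact.
    """

    seed: int = 0
    n_genes: int = 500
    chrom: str = "chrSim"
    chrom_length: Optional[int] = None  # None: sized to fit the layout
    gene_length_range: Tuple[int, int] = (1000, 10000)
    gap_range: Tuple[int, int] = (1800, 2600)
    left_margin: int = 5000

    fraction_bound: float = 0.5
    direction_mix: Tuple[float, float, float] = (0.2, 0.2, 0.6)  # repressed, activated, null
    effect_class_weights: Tuple[float, float, float] = (0.9, 0.06, 0.04)  # soft, mid, hard
    polarity: str = KNOCKDOWN

    # significance model: true targets vs nulls
    sig_p_max: float = 0.04
    sig_fdr_max: float = 0.04
    null_p_range: Tuple[float, float] = (0.05, 1.0)

    # signal model
    r_repressed: float = 5.0
    r_activated: float = 1.5
    r_null: float = 1.0
    body_gamma_shape: float = 2.0
    body_gamma_scale: float = 1.0
    background: float = 0.1
    noise: bool = False  # Poisson per-base resampling within gene signal spans

    # peak model
    peak_width_range: Tuple[int, int] = (300, 600)
    peak_center_jitter: int = 200
    decoy_fraction: float = 0.2  # decoy peaks as a fraction of bound genes

    # expression model: silenced, low, moderate, strong
    fpkm_category_weights: Tuple[float, float, float, float] = (0.05, 0.2, 0.7, 0.05)
    fpkm_sigma: float = 0.6

    def __post_init__(self) -> None:
        for name, weights in (("direction_mix", self.direction_mix),
                              ("effect_class_weights", self.effect_class_weights),
                              ("fpkm_category_weights", self.fpkm_category_weights)):
            if abs(sum(weights) - 1.0) > 1e-9 or any(w < 0 for w in weights):
                raise ValueError(f"{name} must be non-negative and sum to 1")
        if not (0.0 <= self.fraction_bound <= 1.0):
            raise ValueError("fraction_bound must be in [0, 1]")
        if self.polarity not in (KNOCKDOWN, OVEREXPRESSION):
            raise ValueError("polarity must be knockdown or overexpression")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    annotation: GenomeAnnotation
    peaks: List[Peak]
    track: SignalTrack
    de_table: pd.DataFrame
    fpkm_table: pd.Series
    ground_truth: pd.DataFrame  # one row per gene, every planted label


def _apportion(weights, n: int) -> List[int]:
    """Largest-remainder apportionment of n items to the given weights."""
    quotas = [w * n for w in weights]
    counts = [int(q) for q in quotas]
    rem = n - sum(counts)
    order = sorted(range(len(weights)), key=lambda i: quotas[i] - int(quotas[i]), reverse=True)
    for i in order[:rem]:
        counts[i] += 1
    return counts


def simulate_annotation(config: SimulationConfig, rng: Optional[np.random.Generator] = None
                        ) -> GenomeAnnotation:
    """Non-overlapping genes on one chromosome with random strands.

    Lengths are uniform in ``gene_length_range``; consecutive genes are
    separated by uniform gaps from ``gap_range``.  Deterministic under the
    config seed.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_genes
    lengths = rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1, n)
    gaps = rng.integers(config.gap_range[0], config.gap_range[1] + 1, n)
    strands = rng.choice(np.array(["+", "-"]), n)
    ann = GenomeAnnotation()
    pos = config.left_margin
    width = len(str(n))
    for i in range(n):
        start, end = int(pos), int(pos + lengths[i])
        ann.add(GeneModel(f"g{i + 1:0{width}d}", config.chrom, start, end, str(strands[i])))
        pos = end + int(gaps[i])
    needed = pos + config.left_margin
    chrom_length = config.chrom_length if config.chrom_length is not None else int(needed)
    if chrom_length < needed:
        raise ValueError(f"chrom_length {chrom_length} too small; layout needs {needed} bp")
    ann.chrom_sizes = {config.chrom: chrom_length}
    return ann


def _plant_labels(config: SimulationConfig, annotation: GenomeAnnotation,
                  rng: np.random.Generator) -> pd.DataFrame:
    """Plant per-gene ground-truth labels: direction, bound, effect class."""
    gene_ids = [g.gene_id for g in annotation]
    n = len(gene_ids)
    n_rep, n_act, n_null = _apportion(config.direction_mix, n)
    directions = np.array(["repressed"] * n_rep + ["activated"] * n_act + ["unregulated"] * n_null)
    rng.shuffle(directions)

    n_bound = int(round(config.fraction_bound * n))
    target_idx = np.nonzero(directions != "unregulated")[0]
    if n_bound < target_idx.size:
        raise ValueError(
            f"fraction_bound ({config.fraction_bound}) binds {n_bound} genes but "
            f"{target_idx.size} genes are planted as regulated; targets must be bound"
        )
    bound = np.zeros(n, dtype=bool)
    bound[target_idx] = True
    null_idx = np.nonzero(directions == "unregulated")[0]
    extra = rng.choice(null_idx, size=n_bound - target_idx.size, replace=False)
    bound[extra] = True

    effect_class = np.array([""] * n, dtype=object)
    for direction in ("repressed", "activated"):
        idx = np.nonzero(directions == direction)[0]
        counts = _apportion(config.effect_class_weights, idx.size)
        classes = np.array(["soft"] * counts[0] + ["mid"] * counts[1] + ["hard"] * counts[2])
        rng.shuffle(classes)
        effect_class[idx] = classes

    ratio = np.full(n, config.r_null)
    ratio[directions == "repressed"] = config.r_repressed
    ratio[directions == "activated"] = config.r_activated
    return pd.DataFrame({
        "gene_id": gene_ids,
        "bound": bound,
        "direction": directions,
        "effect_class": effect_class,
        "pausing_ratio": ratio,
    })


def simulate_signal(config: SimulationConfig, annotation: GenomeAnnotation,
                    ground_truth: pd.DataFrame,
                    rng: Optional[np.random.Generator] = None) -> SignalTrack:
    """Piecewise-constant promoter-enriched signal with planted pausing ratios.

    Per gene with body level ``b`` (Gamma-distributed) and planted ratio
    ``r``: promoter window [TSS-50, TSS+50) at ``r*b``, gene body
    [TSS+300, TES-100) at ``b``, a per-base linear ramp between them, and
    the configured constant background elsewhere.  With ``noise=True``
    every base inside the promoter/ramp/body span is Poisson-resampled
    (the background stays deterministic).  Noise off makes the pausing
    index of every sufficiently long gene exactly ``r``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    ratios = dict(zip(ground_truth["gene_id"], ground_truth["pausing_ratio"]))
    chrom_len = (annotation.chrom_sizes or {}).get(config.chrom)

    starts_parts, ends_parts, values_parts = [], [], []

    def emit_constant(start: int, end: int, value: float) -> None:
        starts_parts.append(np.array([start], dtype=np.int64))
        ends_parts.append(np.array([end], dtype=np.int64))
        values_parts.append(np.array([value], dtype=float))

    def emit_rle(start: int, vals: np.ndarray) -> None:
        """Run-length-encode a per-base vector anchored at ``start``."""
        offsets = np.concatenate([[0], np.nonzero(np.diff(vals) != 0)[0] + 1])
        run_ends = np.concatenate([offsets[1:], [vals.size]])
        starts_parts.append(start + offsets.astype(np.int64))
        ends_parts.append(start + run_ends.astype(np.int64))
        values_parts.append(vals[offsets].astype(float))

    genes = sorted(annotation, key=lambda g: g.start)
    prev_end = 0
    for gene in genes:
        b = float(rng.gamma(config.body_gamma_shape, config.body_gamma_scale))
        b = max(b, 1e-3)  # zero body level would make the planted ratio unrecoverable
        r = float(ratios[gene.gene_id])
        L = gene.length
        # oriented segments: promoter [-50, 50), ramp [50, 300), body [300, L-100)
        prom = np.full(100, r * b)
        ramp_t = np.arange(50, min(300, max(50, L - 100)))
        ramp = r * b + (b - r * b) * (ramp_t - 50) / 250.0
        body_len = max(0, (L - 100) - 300)
        body = np.full(body_len, b)
        oriented = np.concatenate([prom, ramp, body])
        if config.noise:
            oriented = rng.poisson(oriented).astype(float)
        # genomic placement of the oriented span [-50, L-100)
        if gene.strand == "+":
            span_start, span_end = gene.start - 50, gene.start - 50 + oriented.size
            genomic = oriented
        else:
            span_end = gene.end + 50
            span_start = span_end - oriented.size
            genomic = oriented[::-1]
        if span_start > prev_end:
            emit_constant(prev_end, span_start, config.background)
        emit_rle(span_start, genomic)
        prev_end = span_end
    tail_end = chrom_len if chrom_len is not None else prev_end + config.left_margin
    if tail_end > prev_end:
        emit_constant(prev_end, tail_end, config.background)

    return SignalTrack.from_arrays(
        config.chrom,
        np.concatenate(starts_parts),
        np.concatenate(ends_parts),
        np.concatenate(values_parts),
        chrom_sizes=annotation.chrom_sizes,
    )


def simulate_peaks(config: SimulationConfig, annotation: GenomeAnnotation,
                   ground_truth: pd.DataFrame,
                   rng: Optional[np.random.Generator] = None) -> List[Peak]:
    """One TSS-proximal peak per bound gene plus intergenic decoy peaks.

    Bound genes get a peak of width ``peak_width_range`` centred within
    ``peak_center_jitter`` bp of the TSS.  Decoys are placed in intergenic
    gaps with enough clearance from every gene's assignment window, so they
    never create a bound gene.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    bound_ids = set(ground_truth.loc[ground_truth["bound"], "gene_id"])
    peaks: List[Peak] = []
    genes = sorted(annotation, key=lambda g: g.start)
    for gene in genes:
        if gene.gene_id not in bound_ids:
            continue
        width = int(rng.integers(config.peak_width_range[0], config.peak_width_range[1] + 1))
        jitter = int(rng.integers(-config.peak_center_jitter, config.peak_center_jitter + 1))
        center = gene.tss + jitter
        start = max(0, center - width // 2)
        peaks.append(Peak(gene.chrom, start, start + width,
                          score=float(rng.integers(100, 1000)), summit=width // 2))

    # clearance zones: each gene's assignment window (1 kb upstream of TSS
    # through 100 bp past the TES, strand-aware)
    windows = []
    for gene in genes:
        if gene.strand == "+":
            windows.append((gene.start - 1000, gene.end + 100))
        else:
            windows.append((gene.start - 100, gene.end + 1000))
    n_decoys = int(round(config.decoy_fraction * len(bound_ids)))
    gaps = []
    for (_prev_lo, prev_hi), (next_lo, _next_hi) in zip(windows[:-1], windows[1:]):
        if next_lo - prev_hi >= config.peak_width_range[1] + 2:
            gaps.append((prev_hi + 1, next_lo - 1))
    placed = 0
    while placed < n_decoys and gaps:
        gi = int(rng.integers(0, len(gaps)))
        lo, hi = gaps[gi]
        width = int(rng.integers(config.peak_width_range[0], config.peak_width_range[1] + 1))
        if hi - lo < width:
            continue
        start = int(rng.integers(lo, hi - width + 1))
        peaks.append(Peak(config.chrom, start, start + width,
                          score=float(rng.integers(100, 1000)), summit=width // 2))
        placed += 1
    peaks.sort(key=lambda p: (p.chrom, p.start, p.end))
    return peaks


def simulate_de_and_fpkm(config: SimulationConfig, ground_truth: pd.DataFrame,
                         rng: Optional[np.random.Generator] = None
                         ) -> Tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Differential-expression and control-FPKM tables from planted labels.

    Signed log2FC magnitudes are drawn per effect class; the sign follows
    direction and polarity (knockdown: repressed genes go up when the
    factor is removed; overexpression: activated genes go up).  True
    targets get p and FDR below the significance caps, nulls above.  FPKM
    values are log-normal within the planted category's range; hard
    activated genes are forced to control FPKM <= 1 (category silenced),
    making them detectable as hard-regulation candidates.  Returns the DE
    table, the FPKM series, and the ground truth extended with the drawn
    values and the planted hard-candidate flag.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 3)
    gt = ground_truth.copy()
    n = len(gt)

    # FPKM category labels by exact counts, then hard-activated forcing
    cat_names = ("silenced", "low", "moderate", "strong")
    counts = _apportion(config.fpkm_category_weights, n)
    cats = np.concatenate([[c] * k for c, k in zip(cat_names, counts)]).astype(object)
    rng.shuffle(cats)
    hard_act = (gt["direction"] == "activated") & (gt["effect_class"] == "hard")
    cats[np.nonzero(hard_act.to_numpy())[0]] = "silenced"
    fpkm_vals = np.empty(n)
    for i, c in enumerate(cats):
        lo, hi = _FPKM_RANGES[c]
        draw = _FPKM_MEDIANS[c] * float(np.exp(rng.normal(0.0, config.fpkm_sigma)))
        fpkm_vals[i] = min(max(draw, lo), hi)

    # signed log2FC per gene
    up_direction = "repressed" if config.polarity == KNOCKDOWN else "activated"
    log2fc = np.empty(n)
    pvals = np.empty(n)
    fdrs = np.empty(n)
    for i, row in enumerate(gt.itertuples(index=False)):
        if row.direction == "unregulated":
            mag = float(rng.uniform(0.01, 0.3))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            log2fc[i] = sign * mag
            pvals[i] = float(rng.uniform(*config.null_p_range))
            fdrs[i] = float(rng.uniform(*config.null_p_range))
        else:
            lo, hi = _CLASS_RANGES[row.effect_class]
            mag = float(rng.uniform(lo, hi))
            sign = 1.0 if row.direction == up_direction else -1.0
            log2fc[i] = sign * mag
            pvals[i] = float(rng.uniform(0.0, config.sig_p_max))
            fdrs[i] = float(rng.uniform(0.0, config.sig_fdr_max))

    de = pd.DataFrame({"gene_id": gt["gene_id"], "log2fc": log2fc,
                       "pvalue": pvals, "fdr": fdrs})
    fpkm = pd.Series(fpkm_vals, index=gt["gene_id"], name="fpkm")
    gt["expression_category"] = cats
    gt["fpkm"] = fpkm_vals
    gt["log2fc"] = log2fc
    gt["pvalue"] = pvals
    gt["fdr"] = fdrs
    # mirrors the detection rule: activated, bound, silent in control cells
    # (all forced hard-activated genes qualify; so do activated genes whose
    # planted expression category happens to be silenced)
    gt["hard_candidate"] = ((gt["direction"] == "activated") & gt["bound"]
                            & (gt["fpkm"] <= 1.0)).to_numpy()
    return de, fpkm, gt


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a complete labelled dataset from one seeded generator."""
    rng = np.random.default_rng(config.seed)
    annotation = simulate_annotation(config, rng)
    gt = _plant_labels(config, annotation, rng)
    track = simulate_signal(config, annotation, gt, rng)
    peaks = simulate_peaks(config, annotation, gt, rng)
    de, fpkm, gt = simulate_de_and_fpkm(config, gt, rng)
    return SyntheticDataset(config, annotation, peaks, track, de, fpkm, gt)


def write_dataset(dataset: SyntheticDataset, directory) -> Dict[str, str]:
    """Write the dataset as plain-text files re-readable by the package readers.

    Produces genes.bed, peaks.narrowPeak, signal.bedgraph, de.tsv,
    fpkm.tsv, ground_truth.tsv and a manifest.json carrying the config and
    its hash.  Byte-identical for identical configs.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes": directory / "genes.bed",
        "peaks": directory / "peaks.narrowPeak",
        "signal": directory / "signal.bedgraph",
        "de": directory / "de.tsv",
        "fpkm": directory / "fpkm.tsv",
        "ground_truth": directory / "ground_truth.tsv",
        "manifest": directory / "manifest.json",
    }
    write_bed(dataset.annotation, paths["genes"])
    write_narrowpeak(dataset.peaks, paths["peaks"])
    write_bedgraph(dataset.track, paths["signal"])
    dataset.de_table.to_csv(paths["de"], sep="\t", index=False, float_format="%.10g")
    dataset.fpkm_table.rename("fpkm").reset_index().to_csv(
        paths["fpkm"], sep="\t", index=False, float_format="%.10g")
    dataset.ground_truth.to_csv(paths["ground_truth"], sep="\t", index=False,
                                float_format="%.10g")
    manifest = {"config": asdict(dataset.config), "config_hash": dataset.config.config_hash(),
                "n_genes": len(dataset.annotation), "n_peaks": len(dataset.peaks)}
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return {k: str(v) for k, v in paths.items()}


def load_config(path) -> SimulationConfig:
    """Load a SimulationConfig from a YAML file (keys = dataclass fields)."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("gene_length_range", "gap_range", "peak_width_range",
                "direction_mix", "effect_class_weights", "fpkm_category_weights"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return SimulationConfig(**raw)
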