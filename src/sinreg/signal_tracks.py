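"""Genome-wide signal tracks with strand-aware per-base window queries.

A :class:`SignalTrack` is a sparse piecewise-constant coverage map: per
chromosome, sorted non-overlapping ``(start, end, value)`` intervals with
implicit value 0 between them.  It is the container behind the metagene
matrices and the pausing index; the "enrichment value" of a region is
defined throughout as the *mean* per-base signal in that region, which makes
the pausing-index ratio independent of window lengths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Tuple

import numpy as np

log = logging.getLogger(__name__)

__all__ = ["SignalTrack", "read_bedgraph", "write_bedgraph", "window_values", "window_mean"]


@dataclass
class _ChromIntervals:
    starts: np.ndarray  # int64, sorted
    ends: np.ndarray    # int64
    values: np.ndarray  # float64


@dataclass
class SignalTrack:
    """Sparse per-chromosome piecewise-constant signal.

    Uncovered bases have implicit value 0.  Intervals must be sorted and
    non-overlapping within each chromosome; values must be finite.
    """

    chroms: Dict[str, _ChromIntervals] = field(default_factory=dict)
    chrom_sizes: Optional[Dict[str, int]] = None
    clipped_bases: int = 0  # tally of window bases beyond known chromosome bounds

    @classmethod
    def from_intervals(
        cls,
        intervals: Iterable[Tuple[str, int, int, float]],
        chrom_sizes: Optional[Dict[str, int]] = None,
    ) -> "SignalTrack":
        """Build a track from ``(chrom, start, end, value)`` tuples.

        Intervals are sorted per chromosome; any overlap raises ``ValueError``
        naming the offending pair.  Zero-valued intervals are kept (they are
        indistinguishable from gaps at query time).
        """
        per_chrom: Dict[str, list] = {}
        for chrom, start, end, value in intervals:
            if start >= end:
                raise ValueError(f"{chrom}:{start}-{end}: empty or inverted interval")
            if not np.isfinite(value):
                raise ValueError(f"{chrom}:{start}-{end}: non-finite value {value!r}")
            per_chrom.setdefault(chrom, []).append((int(start), int(end), float(value)))
        track = cls(chrom_sizes=chrom_sizes)
        for chrom, ivs in per_chrom.items():
            ivs.sort()
            arr = np.asarray(ivs, dtype=float)
            starts = arr[:, 0].astype(np.int64)
            ends = arr[:, 1].astype(np.int64)
            bad = np.nonzero(starts[1:] < ends[:-1])[0]
            if bad.size:
                i = int(bad[0])
                raise ValueError(
                    f"overlapping intervals on {chrom}: "
                    f"[{starts[i]},{ends[i]}) and [{starts[i + 1]},{ends[i + 1]})"
                )
            track.chroms[chrom] = _ChromIntervals(starts, ends, arr[:, 2])
        return track

    @classmethod
    def from_arrays(
        cls,
        chrom: str,
        starts: np.ndarray,
        ends: np.ndarray,
        values: np.ndarray,
        chrom_sizes: Optional[Dict[str, int]] = None,
    ) -> "SignalTrack":
        """Build a single-chromosome track from parallel coordinate arrays.

        ``starts`` must already be sorted; overlaps and non-finite values
        raise.  Zero-valued intervals are dropped (equivalent to gaps).
        """
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        values = np.asarray(values, dtype=float)
        if not (starts.shape == ends.shape == values.shape):
            raise ValueError("starts/ends/values must have identical shapes")
        if np.any(starts >= ends):
            raise ValueError(f"{chrom}: empty or inverted interval present")
        if starts.size and np.any(np.diff(starts) < 0):
            raise ValueError(f"{chrom}: starts must be sorted")
        if not np.all(np.isfinite(values)):
            raise ValueError(f"{chrom}: non-finite values")
        bad = np.nonzero(starts[1:] < ends[:-1])[0]
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                f"overlapping intervals on {chrom}: "
                f"[{starts[i]},{ends[i]}) and [{starts[i + 1]},{ends[i + 1]})"
            )
        keep = values != 0.0
        track = cls(chrom_sizes=chrom_sizes)
        track.chroms[chrom] = _ChromIntervals(starts[keep], ends[keep], values[keep])
        return track

    @classmethod
    def from_dense(
        cls,
        arrays: Dict[str, np.ndarray],
        chrom_sizes: Optional[Dict[str, int]] = None,
    ) -> "SignalTrack":
        """Build a track from dense per-chromosome arrays via run-length encoding."""
        track = cls(chrom_sizes=chrom_sizes)
        for chrom, arr in arrays.items():
            arr = np.asarray(arr, dtype=float)
            if arr.size == 0:
                continue
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{chrom}: non-finite values in dense signal")
            breaks = np.nonzero(np.diff(arr) != 0)[0] + 1
            starts = np.concatenate(([0], breaks)).astype(np.int64)
            ends = np.concatenate((breaks, [arr.size])).astype(np.int64)
            values = arr[starts]
            keep = values != 0.0
            track.chroms[chrom] = _ChromIntervals(starts[keep], ends[keep], values[keep])
        return track

    def iter_intervals(self) -> Iterable[Tuple[str, int, int, float]]:
        for chrom in sorted(self.chroms):
            ci = self.chroms[chrom]
            for s, e, v in zip(ci.starts, ci.ends, ci.values):
                yield chrom, int(s), int(e), float(v)

    # Query API lives on module-level functions too; methods delegate there.
    def window_values(self, chrom: str, start: int, end: int, strand: str = "+") -> np.ndarray:
        return window_values(self, chrom, start, end, strand)

    def window_mean(self, chrom: str, start: int, end: int) -> float:
        return window_mean(self, chrom, start, end)


def read_bedgraph(path, chrom_sizes: Optional[Dict[str, int]] = None) -> SignalTrack:
    """Read a 4-column bedGraph file; ``track``/comment lines are tolerated.

    Overlapping intervals within a chromosome are rejected with an error
    naming the pair, and non-numeric values raise with the line number.
    """
    intervals = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 bedGraph columns")
            chrom, start_s, end_s, value_s = fields[:4]
            try:
                start, end, value = int(start_s), int(end_s), float(value_s)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-numeric field") from exc
            intervals.append((chrom, start, end, value))
    return SignalTrack.from_intervals(intervals, chrom_sizes=chrom_sizes)


def write_bedgraph(track: SignalTrack, path) -> None:
    """Write a track as 4-column bedGraph (sorted, zero runs omitted)."""
    with open(path, "w") as fh:
        for chrom, s, e, v in track.iter_intervals():
            if v == 0.0:
                continue
            fh.write(f"{chrom}\t{s}\t{e}\t{v!r}\n")


def window_values(track: SignalTrack, chrom: str, start: int, end: int, strand: str = "+") -> np.ndarray:
    """Per-base signal over ``[start, end)``, oriented 5'->3'.

    Uncovered bases yield 0.  Bases beyond known chromosome bounds (when
    ``chrom_sizes`` is set) also yield 0 and are added to the track's
    ``clipped_bases`` tally.  A query on an absent chromosome logs a warning
    and returns zeros.  For ``strand == "-"`` the vector is reversed so index
    0 is the most 5' position of the gene.
    """
    if start >= end:
        raise ValueError(f"empty window [{start}, {end})")
    n = end - start
    out = np.zeros(n, dtype=float)
    if track.chrom_sizes is not None and chrom in track.chrom_sizes:
        size = track.chrom_sizes[chrom]
        clipped = max(0, -start) + max(0, end - size)
        track.clipped_bases += clipped
    ci = track.chroms.get(chrom)
    if ci is None:
        log.warning("window query on absent chromosome %r; returning zeros", chrom)
    elif ci.starts.size:
        # intervals possibly overlapping the window
        lo = int(np.searchsorted(ci.ends, start, side="right"))
        hi = int(np.searchsorted(ci.starts, end, side="left"))
        if hi > lo:
            s_c = np.clip(ci.starts[lo:hi], start, end)
            e_c = np.clip(ci.ends[lo:hi], start, end)
            k = hi - lo
            # interleave covered runs with the zero gaps between/around them
            piece_lens = np.empty(2 * k + 1, dtype=np.int64)
            piece_vals = np.zeros(2 * k + 1, dtype=float)
            piece_lens[0::2] = np.concatenate((s_c, [end])) - np.concatenate(([start], e_c))
            piece_lens[1::2] = e_c - s_c
            piece_vals[1::2] = ci.values[lo:hi]
            out = np.repeat(piece_vals, piece_lens)
    if strand == "-":
        out = out[::-1]
    elif strand != "+":
        raise ValueError(f"strand must be + or -, got {strand!r}")
    return out


def window_mean(track: SignalTrack, chrom: str, start: int, end: int) -> float:
    """Arithmetic mean of per-base signal over ``[start, end)``; the
    "enrichment value" of a region.  Zero-length windows are an error."""
    return float(np.mean(window_values(track, chrom, start, end, "+")))
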