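"""Per-bin read counting and RPM normalization for nascent-transcript reads.

A read is assigned to every bin containing its 5'-most aligned base, so
with the default half-overlapping tiling a read lands in at most two
bins.  Counting is unstranded; strand is carried on intervals but not
consulted beyond locating the 5' base.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GenomicBin, Interval, ParameterError, Tiling


def _five_prime_positions(reads: Sequence[Interval]) -> dict[str, np.ndarray]:
    by_chrom: dict[str, list[int]] = {}
    for r in reads:
        by_chrom.setdefault(r.chrom, []).append(r.five_prime())
    return {c: np.asarray(p, dtype=np.int64) for c, p in by_chrom.items()}


def count_reads(
    bins: Sequence[GenomicBin] | Tiling, reads: Sequence[Interval]
) -> tuple[np.ndarray, int]:
    """Count reads per bin by 5'-base assignment.

    Returns ``(counts, n_rejected)`` where ``n_rejected`` tallies reads
    on chromosomes absent from the tiling (skipped with a warning).
    """
    positions = _five_prime_positions(reads)
    if isinstance(bins, Tiling):
        counts = np.zeros(bins.n_total, dtype=np.int64)
        rejected = 0
        for chrom, pos in positions.items():
            if chrom not in bins.layout:
                rejected += pos.size
                continue
            ids, _ = bins.covering_bins(chrom, pos)
            counts += np.bincount(ids, minlength=bins.n_total)
        if rejected:
            warnings.warn(f"skipped {rejected} reads on unknown chromosomes")
        return counts, rejected

    # generic path: any uniform-width bin list, possibly overlapping
    widths = {b.interval.length for b in bins}
    if len(widths) > 1:
        raise ParameterError("bins must share a common width")
    width = widths.pop() if widths else 0
    starts: dict[str, list[tuple[int, int]]] = {}
    for b in bins:
        starts.setdefault(b.interval.chrom, []).append((b.interval.start, b.index))
    counts = np.zeros(len(bins), dtype=np.int64)
    known = set(starts)
    rejected = 0
    for chrom, pos in positions.items():
        if chrom not in known:
            rejected += pos.size
            continue
        pairs = sorted(starts[chrom])
        s = np.array([p[0] for p in pairs], dtype=np.int64)
        idx = np.array([p[1] for p in pairs], dtype=np.int64)
        lo = np.searchsorted(s, pos - width, side="right")
        hi = np.searchsorted(s, pos, side="right")
        span = hi - lo
        total = int(span.sum())
        if total == 0:
            continue
        base = np.repeat(np.cumsum(span) - span, span)
        flat = np.repeat(lo, span) + (np.arange(total) - base)
        counts += np.bincount(idx[flat], minlength=len(bins))
    if rejected:
        warnings.warn(f"skipped {rejected} reads on unknown chromosomes")
    return counts, rejected


@dataclass
class BinCountMatrix:
    """Bin-by-sample count matrix with per-sample metadata."""

    tiling: Tiling
    samples: list[str]
    genotypes: dict[str, str]
    counts: np.ndarray  # (n_bins, n_samples) int
    library_sizes: np.ndarray  # mapped reads per sample

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.library_sizes = np.asarray(self.library_sizes, dtype=float)
        if self.counts.shape != (self.tiling.n_total, len(self.samples)):
            raise ParameterError("count matrix shape does not match tiling/samples")
        if (self.counts < 0).any():
            raise ParameterError("negative counts")
        if (self.library_sizes <= 0).any():
            raise ParameterError("library sizes must be positive")

    def columns(self, names: Sequence[str]) -> np.ndarray:
        idx = [self.samples.index(n) for n in names]
        return self.counts[:, idx]

    def samples_of(self, genotype: str) -> list[str]:
        return [s for s in self.samples if self.genotypes[s] == genotype]


def build_count_matrix(
    tiling: Tiling,
    sample_reads: Mapping[str, Sequence[Interval]],
    genotypes: Mapping[str, str],
    library_sizes: Mapping[str, float] | None = None,
) -> BinCountMatrix:
    """Count every sample on a shared tiling.

    ``library_sizes`` defaults to the total number of reads in each
    sample's file; pass explicit values to use, e.g., total mapped
    reads from an alignment log.
    """
    samples = list(sample_reads)
    counts = np.zeros((tiling.n_total, len(samples)), dtype=np.int64)
    sizes = np.zeros(len(samples))
    for j, name in enumerate(samples):
        reads = sample_reads[name]
        counts[:, j], _ = count_reads(tiling, reads)
        if library_sizes is not None and name in library_sizes:
            sizes[j] = float(library_sizes[name])
        else:
            sizes[j] = len(reads)
    return BinCountMatrix(tiling, samples, dict(genotypes), counts, sizes)


@dataclass
class BinSignal:
    """Per-bin signal in reads per million mapped reads (RPM)."""

    tiling: Tiling
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.tiling.n_total,):
            raise ParameterError("signal length does not match tiling")
        if (self.values < 0).any():
            raise ParameterError("negative signal values")


def rpm_normalize(counts: np.ndarray, library_size: float, tiling: Tiling | None = None):
    """Scale counts to reads per million mapped reads."""
    if library_size <= 0:
        raise ParameterError("library_size must be positive")
    values = np.asarray(counts, dtype=float) * 1e6 / library_size
    if tiling is None:
        return values
    return BinSignal(tiling, values)


def counts_table(matrix: BinCountMatrix) -> pd.DataFrame:
    df = matrix.tiling.bin_table()
    for j, name in enumerate(matrix.samples):
        df[name] = matrix.counts[:, j]
    return df


def write_bedgraph(signal: BinSignal, path) -> None:
    """bedGraph of a bin signal; overlapping bins are emitted as-is."""
    df = signal.tiling.bin_table()
    with open(path, "w") as fh:
        for chrom, start, end, v in zip(df["chrom"], df["start"], df["end"], signal.values):
            fh.write(f"{chrom}\t{start}\t{end}\t{v:.6g}\n")
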