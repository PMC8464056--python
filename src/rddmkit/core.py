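"""Coordinate conventions, genome tiling and transposable-element end partitioning.

Every coordinate inside the package is 0-based, half-open (the BED
convention): an interval ``[start, end)`` covers ``end - start`` base
pairs.  File formats that use 1-based positions (the Bismark-style
cytosine report) are converted at the parser boundary in
:mod:`rddmkit.io`.

The central spatial primitive is a *sliding-window tiling*: fixed-width
bins of ``bin_size`` bp placed every ``step`` bp along each chromosome.
With the default 100 bp bins and 50 bp step, adjacent bins overlap by
half and every base pair (beyond the first 50) is covered by two bins.
Only full-width bins are produced; a trailing chromosome stub shorter
than ``bin_size`` is not tiled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np

VALID_CONTEXTS = ("CG", "CHG", "CHH")
VALID_STRANDS = ("+", "-", ".")


class ParameterError(ValueError):
    """An argument is outside its documented domain."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths.

    Parameters
    ----------
    chromosomes
        Sequence of ``(name, length)`` pairs.  Names must be unique and
        lengths positive integers.
    """

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        chroms = tuple((str(n), int(l)) for n, l in self.chromosomes)
        object.__setattr__(self, "chromosomes", chroms)
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            raise ParameterError("chromosome names must be unique")
        for name, length in chroms:
            if length < 1:
                raise ParameterError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def __contains__(self, name: object) -> bool:
        return name in self.lengths

    def length_of(self, name: str) -> int:
        try:
            return self.lengths[name]
        except KeyError:
            raise KeyError(f"unknown chromosome {name!r}") from None


@dataclass(frozen=True)
class Interval:
    """A 0-based half-open genomic interval with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ParameterError(f"negative start {self.start}")
        if self.end <= self.start:
            raise ParameterError(f"empty/inverted interval [{self.start}, {self.end})")
        if self.strand not in VALID_STRANDS:
            raise ParameterError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def five_prime(self) -> int:
        """0-based position of the 5'-most base ('-' strand: ``end - 1``)."""
        return self.end - 1 if self.strand == "-" else self.start


@dataclass(frozen=True)
class GenomicBin:
    """One window of a sliding tiling, with its global index."""

    interval: Interval
    index: int


@dataclass(frozen=True)
class TEAnnotation:
    """A transposable element with family and RdDM-category labels."""

    interval: Interval
    family: str = ""
    rddm_class: str = ""

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class CytosineSite:
    """Per-cytosine bisulfite counts.

    ``n_meth`` is the number of reads supporting methylation (#C) and
    ``n_unmeth`` the number supporting non-methylation (#T); the
    methylation level of the site is ``#C / (#C + #T)``.
    """

    chrom: str
    pos: int  # 0-based
    strand: str
    context: str
    n_meth: int
    n_unmeth: int
    trinucleotide: str = ""

    def __post_init__(self) -> None:
        if self.context not in VALID_CONTEXTS:
            raise ParameterError(f"invalid cytosine context {self.context!r}")
        if self.n_meth < 0 or self.n_unmeth < 0:
            raise ParameterError("negative read counts")
        if self.pos < 0:
            raise ParameterError(f"negative position {self.pos}")


def n_bins(length: int, bin_size: int, step: int) -> int:
    """Number of full-width sliding windows fitting in ``length`` bp."""
    if length < bin_size:
        return 0
    return (length - bin_size) // step + 1


class Tiling:
    """A sliding-window tiling of a genome, with vectorized bin lookup.

    Bins are numbered globally: all bins of the first chromosome (in
    layout order, by increasing start) come first, then the second, and
    so on.
    """

    def __init__(self, layout: GenomeLayout, bin_size: int = 100, step: int = 50):
        if bin_size <= 0 or step <= 0:
            raise ParameterError("bin_size and step must be positive")
        if step > bin_size:
            raise ParameterError("step must not exceed bin_size")
        self.layout = layout
        self.bin_size = int(bin_size)
        self.step = int(step)
        self._nbins = {n: n_bins(l, bin_size, step) for n, l in layout.chromosomes}
        offsets: dict[str, int] = {}
        total = 0
        for name, _ in layout.chromosomes:
            offsets[name] = total
            total += self._nbins[name]
        self._offsets = offsets
        self.n_total = total

    def n_bins_of(self, chrom: str) -> int:
        return self._nbins[chrom]

    def offset_of(self, chrom: str) -> int:
        return self._offsets[chrom]

    def bins(self) -> list[GenomicBin]:
        out: list[GenomicBin] = []
        for name, _ in self.layout.chromosomes:
            off = self._offsets[name]
            for j in range(self._nbins[name]):
                s = j * self.step
                out.append(GenomicBin(Interval(name, s, s + self.bin_size), off + j))
        return out

    def bin_table(self):
        """Bin coordinates as a ``pandas.DataFrame`` (chrom, start, end)."""
        import pandas as pd

        chroms: list[str] = []
        starts: list[np.ndarray] = []
        for name, _ in self.layout.chromosomes:
            k = self._nbins[name]
            chroms.extend([name] * k)
            starts.append(np.arange(k, dtype=np.int64) * self.step)
        if starts:
            s = np.concatenate(starts)
        else:  # pragma: no cover - empty layout is rejected upstream
            s = np.array([], dtype=np.int64)
        return pd.DataFrame({"chrom": chroms, "start": s, "end": s + self.bin_size})

    def covering_bins(
        self, chrom: str, positions: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Global bin indices covering each position.

        Returns ``(bin_ids, src_idx)`` flat arrays: position
        ``positions[src_idx[k]]`` falls inside bin ``bin_ids[k]``.  A
        position covered by two overlapping windows contributes two
        entries.  Positions outside every full bin contribute none.
        """
        positions = np.asarray(positions, dtype=np.int64)
        k = self._nbins.get(chrom, 0)
        if k == 0 or positions.size == 0:
            return np.array([], dtype=np.int64), np.array([], dtype=np.int64)
        # window j covers p iff j*step <= p < j*step + bin_size
        j_min = np.maximum(0, (positions - self.bin_size) // self.step + 1)
        j_max = np.minimum(k - 1, positions // self.step)
        span = np.maximum(0, j_max - j_min + 1)
        total = int(span.sum())
        if total == 0:
            return np.array([], dtype=np.int64), np.array([], dtype=np.int64)
        src_idx = np.repeat(np.arange(positions.size), span)
        base = np.repeat(np.cumsum(span) - span, span)
        local = np.repeat(j_min, span) + (np.arange(total) - base)
        return local + self._offsets[chrom], src_idx


def tile_genome(layout: GenomeLayout, bin_size: int = 100, step: int = 50) -> list[GenomicBin]:
    """Tile a genome into fixed-width sliding windows.

    Per chromosome, bins start at 0, ``step``, ``2*step``, ... for as
    long as ``start + bin_size <= length``; ordering is chromosome
    order, then start.

    Examples
    --------
    A 200 bp chromosome at 100/50 yields three bins ``[0,100)``,
    ``[50,150)`` and ``[100,200)``.
    """
    return Tiling(layout, bin_size, step).bins()


class TEEndPartition(NamedTuple):
    five_end: Interval | None
    three_end: Interval | None
    inner: Interval | None


def te_end_partition(te: TEAnnotation | Interval, end_size: int = 150) -> TEEndPartition:
    """Split a TE into its two terminal ``end_size`` bp pieces and the rest.

    The three pieces are disjoint and their union is the TE.  For TEs
    of length <= ``2 * end_size`` the inner piece is empty and the two
    ends are clipped at the midpoint so they never overlap.  The split
    is purely positional (left end / right end); strand is not
    consulted.
    """
    if end_size <= 0:
        raise ParameterError("end_size must be positive")
    iv = te.interval if isinstance(te, TEAnnotation) else te
    mid = (iv.start + iv.end) // 2
    five_stop = min(iv.start + end_size, mid)
    three_start = max(iv.end - end_size, mid)
    five = Interval(iv.chrom, iv.start, five_stop, iv.strand) if five_stop > iv.start else None
    three = Interval(iv.chrom, three_start, iv.end, iv.strand) if iv.end > three_start else None
    inner = None
    if three_start > five_stop:
        inner = Interval(iv.chrom, five_stop, three_start, iv.strand)
    return TEEndPartition(five, three, inner)
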