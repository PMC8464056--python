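"""Readers and writers for the plain-text formats the pipeline consumes.

BED intervals are taken verbatim (already 0-based half-open); the
Bismark-style CX cytosine report is 1-based and converted on input.
All tabular outputs are tab-separated with a header line starting "#".
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import pandas as pd

from .core import (
    VALID_CONTEXTS,
    VALID_STRANDS,
    CytosineSite,
    GenomeLayout,
    Interval,
    TEAnnotation,
)


class BedParseError(ValueError):
    pass


class CxParseError(ValueError):
    pass


def read_chrom_sizes(path: str | os.PathLike) -> GenomeLayout:
    chroms: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise BedParseError(f"{path}:{lineno}: expected 2 columns")
            try:
                chroms.append((fields[0], int(fields[1])))
            except ValueError:
                raise BedParseError(f"{path}:{lineno}: non-integer length {fields[1]!r}") from None
    return GenomeLayout(tuple(chroms))


def write_chrom_sizes(layout: GenomeLayout, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, length in layout.chromosomes:
            fh.write(f"{name}\t{length}\n")


def read_bed(path: str | os.PathLike) -> list[Interval]:
    """Read a BED3/BED6 file into intervals (strand from column 6)."""
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise BedParseError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from None
            if start >= end:
                raise BedParseError(f"{path}:{lineno}: start {start} >= end {end}")
            strand = f[5] if len(f) >= 6 and f[5] in VALID_STRANDS else "."
            try:
                out.append(Interval(f[0], start, end, strand))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from None
    return out


def write_bed(intervals: Iterable[Interval], path: str | os.PathLike,
              names: Sequence[str] | None = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_te_bed(path: str | os.PathLike) -> list[TEAnnotation]:
    """TE annotation BED: family in column 4, RdDM class in column 5."""
    out: list[TEAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise BedParseError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from None
            if start >= end:
                raise BedParseError(f"{path}:{lineno}: start {start} >= end {end}")
            family = f[3] if len(f) >= 4 else ""
            rddm_class = f[4] if len(f) >= 5 else ""
            strand = f[5] if len(f) >= 6 and f[5] in VALID_STRANDS else "."
            out.append(TEAnnotation(Interval(f[0], start, end, strand), family, rddm_class))
    return out


def write_te_bed(tes: Iterable[TEAnnotation], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for te in tes:
            iv = te.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{te.family}\t{te.rddm_class}\t{iv.strand}\n")


def read_cx_report(path: str | os.PathLike) -> list[CytosineSite]:
    """Read a Bismark-style CX cytosine report.

    Columns: chrom, 1-based position, strand, count methylated (#C),
    count unmethylated (#T), context (CG/CHG/CHH), trinucleotide.
    Positions are converted to 0-based.
    """
    out: list[CytosineSite] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise CxParseError(f"{path}:{lineno}: fewer than 6 columns")
            try:
                pos = int(f[1])
                n_meth = int(f[3])
                n_unmeth = int(f[4])
            except ValueError:
                raise CxParseError(f"{path}:{lineno}: non-integer field") from None
            if f[5] not in VALID_CONTEXTS:
                raise CxParseError(f"{path}:{lineno}: unknown context {f[5]!r}")
            if n_meth < 0 or n_unmeth < 0:
                raise CxParseError(f"{path}:{lineno}: negative count")
            tri = f[6] if len(f) >= 7 else ""
            out.append(CytosineSite(f[0], pos - 1, f[2], f[5], n_meth, n_unmeth, tri))
    return out


def write_cx_report(sites: Iterable[CytosineSite], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.pos + 1}\t{s.strand}\t{s.n_meth}\t{s.n_unmeth}"
                f"\t{s.context}\t{s.trinucleotide}\n"
            )


def sites_to_frame(sites: Sequence[CytosineSite]) -> pd.DataFrame:
    """Tabular view of cytosine sites used by the vectorized binning code."""
    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "pos": [s.pos for s in sites],
            "strand": [s.strand for s in sites],
            "context": [s.context for s in sites],
            "n_meth": [s.n_meth for s in sites],
            "n_unmeth": [s.n_unmeth for s in sites],
        }
    )


def write_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a results table as TSV with a '#'-prefixed header line."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False, float_format="%.10g")


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().lstrip("#").rstrip("\n").split("\t")
        return pd.read_csv(fh, sep="\t", names=header)
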