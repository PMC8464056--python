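"""Permutation overlap enrichment and TE-end metaprofiles.

Enrichment compares the number of query intervals overlapping an
annotation (by >= 1 bp) with the distribution of that statistic over
random re-placements of the query intervals.  Each permutation
re-places every interval independently, preserving its length, on a
chromosome chosen with probability proportional to placeable length.
The empirical p uses the plus-one estimator, so the smallest attainable
value at 1000 permutations is 1/1001.

Metaprofiles average a per-base-pair signal around the 5' and 3'
boundaries of long TEs (length above ``min_te_len``), with the 3' side
mirrored so positive offsets always point into the TE; the profile is
reported as a pseudocounted ratio of a numerator and denominator
signal (e.g. wild-type RPM over mutant RPM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GenomeLayout, Interval, ParameterError, TEAnnotation
from .counts import BinSignal


@dataclass
class EnrichmentResult:
    label: str
    n_observed: int
    expected_mean: float
    expected_sd: float
    ratio: float
    empirical_p: float
    direction: str  # "enrichment" or "depletion"
    n_permutations: int


@dataclass
class MetaProfile:
    offsets: np.ndarray  # bp relative to the TE boundary; positive = into the TE
    values: np.ndarray
    n_features: int


class _AnnotationIndex:
    """Merged, per-chromosome sorted intervals for O(log n) overlap queries."""

    def __init__(self, intervals: Sequence[Interval]):
        per: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            per.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, spans in per.items():
            spans.sort()
            merged: list[list[int]] = []
            for s, e in spans:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            arr = np.asarray(merged, dtype=np.int64)
            self._merged[chrom] = (arr[:, 0], arr[:, 1])

    def overlaps(self, chrom: np.ndarray, start: np.ndarray, end: np.ndarray) -> np.ndarray:
        """Boolean mask: does each query interval hit any annotation?"""
        out = np.zeros(start.shape, dtype=bool)
        for c in np.unique(chrom):
            entry = self._merged.get(c)
            if entry is None:
                continue
            starts, ends = entry
            sel = chrom == c
            # first merged interval ending after the query start...
            i = np.searchsorted(ends, start[sel], side="right")
            valid = i < starts.size
            hit = np.zeros(int(sel.sum()), dtype=bool)
            hit[valid] = starts[i[valid]] < end[sel][valid]
            out[sel] = hit
        return out


def _as_index(annotation) -> _AnnotationIndex:
    if isinstance(annotation, _AnnotationIndex):
        return annotation
    return _AnnotationIndex(list(annotation))


def count_overlapping(query: Sequence[Interval], annotation) -> int:
    """Number of query intervals overlapping the annotation by >= 1 bp."""
    idx = _as_index(annotation)
    chrom = np.asarray([q.chrom for q in query])
    start = np.asarray([q.start for q in query], dtype=np.int64)
    end = np.asarray([q.end for q in query], dtype=np.int64)
    return int(idx.overlaps(chrom, start, end).sum())


def permute_intervals(
    query: Sequence[Interval],
    layout: GenomeLayout,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[Interval]:
    """Re-place each interval uniformly at random, preserving its length."""
    if rng is None:
        rng = np.random.default_rng(seed)
    names = layout.names
    lengths = np.asarray([layout.length_of(n) for n in names], dtype=np.int64)
    q_len = np.asarray([q.length for q in query], dtype=np.int64)
    placeable = np.maximum(lengths[:, None] - q_len[None, :] + 1, 0)  # (chrom, query)
    tot = placeable.sum(axis=0)
    if (tot == 0).any():
        raise ParameterError("an interval is longer than every chromosome")
    probs = placeable / tot
    cum = np.cumsum(probs, axis=0)
    u = rng.random(q_len.size)
    chrom_idx = (u[None, :] > cum).sum(axis=0)
    starts = (rng.random(q_len.size) * placeable[chrom_idx, np.arange(q_len.size)]).astype(np.int64)
    return [
        Interval(names[c], int(s), int(s + l))
        for c, s, l in zip(chrom_idx, starts, q_len)
    ]


def _permutation_stats(
    query: Sequence[Interval],
    annotations: Mapping[str, _AnnotationIndex],
    layout: GenomeLayout,
    n_perm: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    names = layout.names
    lengths = np.asarray([layout.length_of(n) for n in names], dtype=np.int64)
    q_len = np.asarray([q.length for q in query], dtype=np.int64)
    placeable = np.maximum(lengths[:, None] - q_len[None, :] + 1, 0)
    tot = placeable.sum(axis=0)
    if (tot == 0).any():
        raise ParameterError("an interval is longer than every chromosome")
    cum = np.cumsum(placeable / tot, axis=0)
    name_arr = np.asarray(names)
    stats = {label: np.empty(n_perm, dtype=np.int64) for label in annotations}
    for k in range(n_perm):
        u = rng.random(q_len.size)
        ci = (u[None, :] > cum).sum(axis=0)
        starts = (rng.random(q_len.size) * placeable[ci, np.arange(q_len.size)]).astype(np.int64)
        chrom = name_arr[ci]
        ends = starts + q_len
        for label, idx in annotations.items():
            stats[label][k] = int(idx.overlaps(chrom, starts, ends).sum())
    return stats


def _result_from_stats(
    label: str, observed: int, perm: np.ndarray
) -> EnrichmentResult:
    n_perm = perm.size
    p_enr = (1 + int((perm >= observed).sum())) / (n_perm + 1)
    p_dep = (1 + int((perm <= observed).sum())) / (n_perm + 1)
    mean = float(perm.mean())
    if mean > 0:
        ratio = observed / mean
    else:
        ratio = 0.0  # degenerate: nothing overlaps under the null
    if p_enr <= p_dep:
        p, direction = p_enr, "enrichment"
    else:
        p, direction = p_dep, "depletion"
    return EnrichmentResult(
        label, observed, mean, float(perm.std(ddof=0)), float(ratio), float(p),
        direction, n_perm,
    )


def overlap_enrichment(
    query: Sequence[Interval],
    annotation,
    layout: GenomeLayout,
    n_perm: int = 1000,
    seed: int | None = None,
    label: str = "annotation",
) -> EnrichmentResult:
    """Permutation test of query/annotation overlap.

    Reports the smaller of the enrichment and depletion tails with its
    direction; the plus-one estimator never returns 0.
    """
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    if not query:
        raise ParameterError("empty query")
    idx = _as_index(annotation)
    observed = count_overlapping(query, idx)
    rng = np.random.default_rng(seed)
    stats = _permutation_stats(query, {label: idx}, layout, n_perm, rng)
    return _result_from_stats(label, observed, stats[label])


def annotate_overlap_classes(
    query: Sequence[Interval],
    annotation_classes: Mapping[str, Sequence[Interval]],
    layout: GenomeLayout,
    n_perm: int = 1000,
    seed: int | None = None,
) -> list[EnrichmentResult]:
    """Enrichment of one query against several annotation classes.

    A single permutation stream is shared: the same random placements
    are scored against every class, so ratios are comparable across
    classes.  Classes with no intervals report observed 0 and ratio 0.
    """
    if not query:
        raise ParameterError("empty query")
    rng = np.random.default_rng(seed)
    indexes = {
        label: _AnnotationIndex(list(ivs)) for label, ivs in annotation_classes.items()
    }
    stats = _permutation_stats(query, indexes, layout, n_perm, rng)
    out = []
    for label, idx in indexes.items():
        observed = count_overlapping(query, idx)
        out.append(_result_from_stats(label, observed, stats[label]))
    return out


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "class": [r.label for r in results],
            "observed": [r.n_observed for r in results],
            "expected_mean": [r.expected_mean for r in results],
            "expected_sd": [r.expected_sd for r in results],
            "ratio": [r.ratio for r in results],
            "p": [r.empirical_p for r in results],
            "direction": [r.direction for r in results],
            "n_permutations": [r.n_permutations for r in results],
        }
    )


def _per_bp_signal(signal: BinSignal) -> dict[str, np.ndarray]:
    """Mean bin value covering each base pair (0 where uncovered)."""
    tiling = signal.tiling
    out: dict[str, np.ndarray] = {}
    df = tiling.bin_table()
    values = signal.values
    pos = 0
    for name, length in tiling.layout.chromosomes:
        k = tiling.n_bins_of(name)
        acc = np.zeros(length + 1)
        cov = np.zeros(length + 1)
        starts = df["start"].to_numpy()[pos : pos + k]
        ends = df["end"].to_numpy()[pos : pos + k]
        vals = values[pos : pos + k]
        np.add.at(acc, starts, vals)
        np.add.at(acc, ends, -vals)
        np.add.at(cov, starts, 1.0)
        np.add.at(cov, ends, -1.0)
        acc = np.cumsum(acc)[:length]
        cov = np.cumsum(cov)[:length]
        with np.errstate(divide="ignore", invalid="ignore"):
            out[name] = np.where(cov > 0, acc / np.maximum(cov, 1e-300), 0.0)
        pos += k
    return out


def te_end_metaprofile(
    signal_num: BinSignal,
    signal_den: BinSignal,
    tes: Sequence[TEAnnotation],
    flank_bp: int = 1000,
    min_te_len: int = 500,
    pseudocount_rpm: float = 0.5,
    resolution: int = 10,
) -> tuple[MetaProfile, MetaProfile]:
    """Average signal ratio around the 5' and 3' boundaries of long TEs.

    Only TEs longer than ``min_te_len`` contribute.  Offsets run from
    ``-flank_bp`` (outside the TE) to ``+flank_bp`` (into the TE) in
    ``resolution``-bp steps; the 3' profile is mirrored so the axis
    direction matches.  The value at each offset is
    ``(mean numerator + pseudocount) / (mean denominator + pseudocount)``
    across contributing TEs.
    """
    if signal_num.tiling is not signal_den.tiling and (
        signal_num.tiling.bin_size != signal_den.tiling.bin_size
        or signal_num.tiling.step != signal_den.tiling.step
        or signal_num.tiling.layout != signal_den.tiling.layout
    ):
        raise ParameterError("numerator and denominator signals use different tilings")
    long_tes = [t for t in tes if t.length > min_te_len]
    offsets = np.arange(-flank_bp, flank_bp)
    n_off = offsets.size
    if not long_tes:
        warnings.warn("no TE longer than min_te_len; empty profile")
        empty = MetaProfile(np.array([], dtype=np.int64), np.array([]), 0)
        return empty, empty
    num_bp = _per_bp_signal(signal_num)
    den_bp = _per_bp_signal(signal_den)
    sums = {end: [np.zeros(n_off), np.zeros(n_off)] for end in ("five", "three")}
    counts = {end: np.zeros(n_off) for end in ("five", "three")}
    for te in long_tes:
        chrom = te.interval.chrom
        if chrom not in num_bp:
            continue
        nv, dv = num_bp[chrom], den_bp[chrom]
        L = nv.size
        for end, pos_arr in (
            ("five", te.interval.start + offsets),
            ("three", te.interval.end - 1 - offsets),
        ):
            valid = (pos_arr >= 0) & (pos_arr < L)
            sums[end][0][valid] += nv[pos_arr[valid]]
            sums[end][1][valid] += dv[pos_arr[valid]]
            counts[end] += valid
    profiles = []
    res_offsets = offsets.reshape(-1, resolution).mean(axis=1)
    for end in ("five", "three"):
        with np.errstate(divide="ignore", invalid="ignore"):
            mean_num = np.where(counts[end] > 0, sums[end][0] / np.maximum(counts[end], 1), np.nan)
            mean_den = np.where(counts[end] > 0, sums[end][1] / np.maximum(counts[end], 1), np.nan)
        # reduce to the reporting resolution before forming the ratio
        mn = np.nanmean(mean_num.reshape(-1, resolution), axis=1)
        md = np.nanmean(mean_den.reshape(-1, resolution), axis=1)
        values = (mn + pseudocount_rpm) / (md + pseudocount_rpm)
        profiles.append(MetaProfile(res_offsets, values, len(long_tes)))
    return profiles[0], profiles[1]


def profile_table(profile: MetaProfile, end_label: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "end": end_label,
            "offset": profile.offsets,
            "value": profile.values,
            "n_features": profile.n_features,
        }
    )
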