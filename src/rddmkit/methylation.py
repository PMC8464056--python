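"""Context-resolved methylation levels and differentially methylated regions.

Levels are the read-count ratio #C / (#C + #T); a cytosine only
qualifies with at least ``min_reads`` sequenced reads (default 5).
Bin levels pool the qualifying counts of all sites of one context
inside the bin (coverage-weighted), not the mean of per-site levels.

DMRs are bins of the sliding tiling where the wild-type-minus-mutant
level difference meets a context-specific minimum (e.g. 0.25 for CHH
loss, 0.55 for CG loss) at a BH FDR below ``max_fdr``; the test is a
two-sided Fisher's exact test on the pooled 2x2 count table.  DMRs are
directional: only hypomethylation in the mutant is called.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .core import CytosineSite, ParameterError, Tiling, VALID_CONTEXTS
from .diff import bh_adjust

__all__ = [
    "CytosineSite",
    "site_level",
    "bin_context_levels",
    "dmr_test",
    "call_dmrs",
]


def site_level(n_meth: int, n_unmeth: int, min_reads: int = 5) -> float | None:
    """Per-site level #C/(#C+#T), or None below the coverage floor."""
    if n_meth < 0 or n_unmeth < 0:
        raise ParameterError("negative counts")
    cov = n_meth + n_unmeth
    if cov < min_reads:
        return None
    return n_meth / cov


def _sites_frame(sites) -> pd.DataFrame:
    if isinstance(sites, pd.DataFrame):
        return sites
    from .io import sites_to_frame

    return sites_to_frame(list(sites))


def bin_context_levels(
    sites,
    tiling: Tiling,
    context: str,
    min_reads: int = 5,
) -> pd.DataFrame:
    """Coverage-weighted methylation level of every bin for one context.

    Sites below the per-cytosine coverage floor are discarded before
    pooling.  Bins without a qualifying site have NaN level.

    Returns a DataFrame aligned with the tiling: columns ``level``,
    ``n_sites``, ``n_meth``, ``n_unmeth``.
    """
    if context not in VALID_CONTEXTS:
        raise ParameterError(f"invalid context {context!r}")
    df = _sites_frame(sites)
    df = df[df["context"] == context]
    cov = df["n_meth"] + df["n_unmeth"]
    df = df[cov >= min_reads]
    meth = np.zeros(tiling.n_total, dtype=np.int64)
    unmeth = np.zeros(tiling.n_total, dtype=np.int64)
    n_sites = np.zeros(tiling.n_total, dtype=np.int64)
    for chrom, grp in df.groupby("chrom", sort=False):
        if chrom not in tiling.layout:
            continue
        ids, src = tiling.covering_bins(chrom, grp["pos"].to_numpy())
        if ids.size == 0:
            continue
        meth += np.bincount(ids, weights=grp["n_meth"].to_numpy()[src],
                            minlength=tiling.n_total).astype(np.int64)
        unmeth += np.bincount(ids, weights=grp["n_unmeth"].to_numpy()[src],
                              minlength=tiling.n_total).astype(np.int64)
        n_sites += np.bincount(ids, minlength=tiling.n_total)
    total = meth + unmeth
    with np.errstate(divide="ignore", invalid="ignore"):
        level = np.where(total > 0, meth / np.maximum(total, 1), np.nan)
    level[n_sites == 0] = np.nan
    out = tiling.bin_table()
    out["level"] = level
    out["n_sites"] = n_sites
    out["n_meth"] = meth
    out["n_unmeth"] = unmeth
    return out


def dmr_test(wt_meth: int, wt_unmeth: int, mut_meth: int, mut_unmeth: int):
    """Two-sided Fisher's exact test on the pooled 2x2 table.

    Returns ``(p, difference)`` with ``difference = level_wt -
    level_mut`` (positive = hypomethylation in the mutant).
    """
    if min(wt_meth, wt_unmeth, mut_meth, mut_unmeth) < 0:
        raise ParameterError("negative counts")
    wt_cov = wt_meth + wt_unmeth
    mut_cov = mut_meth + mut_unmeth
    if wt_cov == 0 or mut_cov == 0:
        raise ParameterError("undefined level: zero coverage")
    _, p = fisher_exact([[wt_meth, wt_unmeth], [mut_meth, mut_unmeth]])
    diff = wt_meth / wt_cov - mut_meth / mut_cov
    return float(p), float(diff)


def call_dmrs(
    wt_sites,
    mut_sites,
    tiling: Tiling,
    context: str,
    min_diff: float,
    max_fdr: float = 0.01,
    min_reads: int = 5,
) -> pd.DataFrame:
    """Call differentially methylated bins for one context.

    Bins with a defined level in both genotypes are tested; BH
    adjustment runs over tested bins only.  A bin is a DMR when
    ``q < max_fdr`` and the wild-type level exceeds the mutant level by
    at least ``min_diff``.

    Returns the full per-bin table (columns ``level_wt``, ``level_mut``,
    ``difference``, ``p``, ``q``, ``is_dmr``, ``tested``).
    """
    if not (0 < min_diff <= 1):
        raise ParameterError("min_diff must lie in (0, 1]")
    wt = bin_context_levels(wt_sites, tiling, context, min_reads)
    mut = bin_context_levels(mut_sites, tiling, context, min_reads)
    tested = wt["level"].notna().to_numpy() & mut["level"].notna().to_numpy()
    n = tiling.n_total
    p = np.ones(n)
    # Fisher p depends only on the 2x2 table; cache repeated tables
    cache: dict[tuple[int, int, int, int], float] = {}
    wm = wt["n_meth"].to_numpy()
    wu = wt["n_unmeth"].to_numpy()
    mm = mut["n_meth"].to_numpy()
    mu = mut["n_unmeth"].to_numpy()
    for i in np.flatnonzero(tested):
        key = (int(wm[i]), int(wu[i]), int(mm[i]), int(mu[i]))
        pv = cache.get(key)
        if pv is None:
            pv, _ = dmr_test(*key)
            cache[key] = pv
        p[i] = pv
    q = bh_adjust(p, tested)
    diff = wt["level"].to_numpy() - mut["level"].to_numpy()
    out = tiling.bin_table()
    out["context"] = context
    out["level_wt"] = wt["level"]
    out["level_mut"] = mut["level"]
    out["difference"] = diff
    out["p"] = np.where(tested, p, np.nan)
    out["q"] = q
    out["tested"] = tested
    out["is_dmr"] = tested & (q < max_fdr) & (diff >= min_diff)
    return out
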