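"""Locus-category logic and group contrasts.

The analysis splits Pol V-transcribed bins by the effect of a mutant on
transcription (reduced vs unchanged) and splits mutant DMRs by whether
the two complementary methylation contexts are still present in the
mutant (both present) or completely absent (neither present).  The two
category systems are then contrasted with Wilcoxon rank-sum tests —
e.g. mutant Pol V signal on "neither present" DMRs against "both
present" DMRs, the package's analogue of the feedback readout.

Presence cutoffs follow the conventional per-context values (5% CHH,
10% CHG, 20% CG); absence means a measured level of exactly 0 in the
mutant while the wild type is above the presence cut.  DMRs meeting
neither rule are explicitly excluded (the categories deliberately do
not partition all DMRs).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .core import ParameterError

PRESENCE_CUTS = {"CHH": 0.05, "CHG": 0.10, "CG": 0.20}

CAT_BOTH = "both_present"
CAT_NEITHER = "neither_present"
CAT_EXCLUDED = "excluded"


def polv_transcribed_bins(diff_wt_vs_polv_null: pd.DataFrame, max_fdr: float = 0.05) -> np.ndarray:
    """Bin indices transcribed by Pol V.

    The contrast must have the wild type as group a and the Pol V null
    (nrpe1) as group b; a bin qualifies when q is below the FDR cut and
    the wild-type adjusted mean exceeds the null mean.
    """
    df = diff_wt_vs_polv_null
    mask = (df["q"] < max_fdr) & (df["mean_a"] > df["mean_b"])
    return np.flatnonzero(mask.fillna(False).to_numpy())


def split_by_mutant_effect(
    transcribed_bins: np.ndarray, mutant_diff: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Intersect transcribed bins with the mutant contrast's statuses.

    Returns ``(reduced, unchanged)`` index arrays; bins in neither
    status are dropped (the categories are non-exhaustive by design).
    """
    if len(mutant_diff) <= (max(transcribed_bins) if len(transcribed_bins) else -1):
        raise ParameterError("mutant contrast computed on a different tiling")
    status = mutant_diff["status"].to_numpy()
    t = np.asarray(transcribed_bins, dtype=np.int64)
    reduced = t[status[t] == "reduced"]
    unchanged = t[status[t] == "unchanged"]
    return reduced, unchanged


def classify_dmr_contexts(
    dmr_bins: np.ndarray,
    dmr_context: str,
    wt_levels: dict[str, pd.DataFrame],
    mut_levels: dict[str, pd.DataFrame],
    presence_cuts: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Categorize DMRs by presence/absence of the complementary contexts.

    ``wt_levels`` / ``mut_levels`` map context -> per-bin level table
    (from :func:`rddmkit.methylation.bin_context_levels`).  For a CHH
    DMR the complementary contexts are CG and CHG; ``both_present``
    needs each above its cut in wild type *and* mutant,
    ``neither_present`` needs both measured as exactly 0 in the mutant
    while present in the wild type.  Anything else — including bins
    with an undefined level in a required context — is excluded, with
    the reason recorded.
    """
    cuts = dict(PRESENCE_CUTS if presence_cuts is None else presence_cuts)
    others = [c for c in ("CG", "CHG", "CHH") if c != dmr_context]
    rows = []
    for b in np.asarray(dmr_bins, dtype=np.int64):
        levels = {}
        undefined = False
        for ctx in others:
            lw = wt_levels[ctx]["level"].iat[b]
            lm = mut_levels[ctx]["level"].iat[b]
            if np.isnan(lw) or np.isnan(lm):
                undefined = True
            levels[ctx] = (lw, lm)
        if undefined:
            cat, reason = CAT_EXCLUDED, "undefined_level"
        elif all(lw > cuts[c] and lm > cuts[c] for c, (lw, lm) in levels.items()):
            cat, reason = CAT_BOTH, ""
        elif all(lm == 0.0 and lw > cuts[c] for c, (lw, lm) in levels.items()):
            cat, reason = CAT_NEITHER, ""
        else:
            cat, reason = CAT_EXCLUDED, "between_absence_and_presence"
        row = {"bin": int(b), "category": cat, "reason": reason}
        for c, (lw, lm) in levels.items():
            row[f"wt_{c}"] = lw
            row[f"mut_{c}"] = lm
        rows.append(row)
    cols = ["bin", "category", "reason"] + [f"{g}_{c}" for c in others for g in ("wt", "mut")]
    return pd.DataFrame(rows, columns=cols)


def _exact_rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact Mann-Whitney p by enumerating all group splits.

    Uses midranks, so ties are handled exactly; feasible for small
    groups (the caller switches at n = 8 per group).
    """
    n, m = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    obs = ranks[:n].sum()
    center = n * (n + m + 1) / 2.0
    dev_obs = abs(obs - center)
    total = 0
    extreme = 0
    for idx in combinations(range(n + m), n):
        total += 1
        if abs(ranks[list(idx)].sum() - center) >= dev_obs - 1e-12:
            extreme += 1
    return extreme / total


def _asymptotic_rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Normal approximation with tie, continuity and kurtosis corrections.

    The rank-sum statistic is light-tailed at small sample sizes
    (negative excess kurtosis), so on top of the usual tie-corrected
    variance and 0.5 continuity correction an Edgeworth term with the
    exact no-ties kurtosis
    ``gamma2 = -(6/5) (m^2 + n^2 + mn + m + n) / (m n (N + 1))``
    is applied; the term is O(1/N) and vanishes for large samples,
    where the value coincides with the standard approximation.
    """
    n, m = a.size, b.size
    N = n + m
    ranks = rankdata(np.concatenate([a, b]))
    s = ranks[:n].sum()
    mu = n * (N + 1) / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (N * (N - 1))
    var = n * m / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return 1.0
    d = abs(s - mu)
    z = max(0.0, d - 0.5) / np.sqrt(var)
    gamma2 = -(6.0 / 5.0) * (m * m + n * n + m * n + m + n) / (m * n * (N + 1))
    tail = norm.sf(z) + norm.pdf(z) * gamma2 / 24.0 * (z**3 - 3 * z)
    return float(min(1.0, max(0.0, 2.0 * tail)))


def compare_groups_wilcoxon(values_a, values_b, exact_max_n: int = 8) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration of all rank splits when both groups have at most
    ``exact_max_n`` observations; otherwise the normal approximation
    with tie, continuity and small-sample kurtosis corrections.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both groups must be non-empty")
    if a.size <= exact_max_n and b.size <= exact_max_n:
        return _exact_rank_sum_p(a, b)
    return _asymptotic_rank_sum_p(a, b)


def category_overlap(set_a, set_b) -> tuple[int, float]:
    """Overlap count and Jaccard index of two bin-identity sets."""
    sa, sb = set(set_a), set(set_b)
    inter = len(sa & sb)
    union = len(sa | sb)
    return inter, (inter / union if union else 0.0)


def category_summary(
    label: str, values: np.ndarray, control_values: np.ndarray | None = None
) -> dict:
    """Group size, quartiles and (optionally) Wilcoxon p vs a control group."""
    values = np.asarray(values, dtype=float)
    q1, med, q3 = (np.percentile(values, [25, 50, 75]) if values.size else (np.nan,) * 3)
    out = {
        "category": label,
        "n_regions": int(values.size),
        "q1": q1,
        "median": med,
        "q3": q3,
        "wilcoxon_p": np.nan,
    }
    if control_values is not None and values.size and len(control_values):
        out["wilcoxon_p"] = compare_groups_wilcoxon(values, control_values)
    return out
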