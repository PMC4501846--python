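"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the library's code paths (and mostly numpy/scipy)
so that agreement between the two routes is meaningful.
"""

from __future__ import annotations

import math
import statistics
from itertools import combinations


def protein_summary(record, channel):
    """Median of a protein's log2 ratios, via statistics.median."""
    values = [math.log2(v) for v in record.ratios(channel).values()]
    if not values:
        return None
    return statistics.median(values)


def background_fit(records, channel, background_fraction=0.90):
    """(median_log2, sd_log2, n_background) by direct sort-and-slice.

    Proteins are ranked by their median-across-replicates summary (stable
    tie-break on protein_id); the lowest floor(f*n) proteins form the
    background set.  The median is taken over the pooled log2 ratios of
    all quantified proteins, the sample SD over the pooled log2 ratios of
    the background set.
    """
    quantified = [
        (protein_summary(r, channel), r.protein_id, r)
        for r in records
        if r.ratios(channel)
    ]
    quantified.sort(key=lambda t: (t[0], t[1]))
    n_background = math.floor(background_fraction * len(quantified))
    pooled_all = [
        math.log2(v) for _, _, r in quantified for v in r.ratios(channel).values()
    ]
    pooled_bg = [
        math.log2(v)
        for _, _, r in quantified[:n_background]
        for v in r.ratios(channel).values()
    ]
    return (
        statistics.median(pooled_all),
        statistics.stdev(pooled_bg),
        n_background,
    )


def call_one_protein(record, cutoff_ml, cutoff_hl, min_replicates, fold_threshold):
    """(enriched_5min, enriched_15min) by exhaustive criterion checking."""
    flags = []
    for channel, cutoff in (("ML", cutoff_ml), ("HL", cutoff_hl)):
        ratios = list(record.ratios(channel).values())
        support = sum(1 for v in ratios if v >= fold_threshold)
        summary = protein_summary(record, channel)
        flags.append(
            support >= min_replicates and summary is not None and summary > cutoff
        )
    return tuple(flags)


def ranksum_distribution(n, m):
    """Exact distribution of the group-a rank sum over all C(n+m, n) splits.

    Returns a dict rank_sum -> count (ranks are 1..n+m, tie-free).
    """
    counts: dict[int, int] = {}
    for subset in combinations(range(1, n + m + 1), n):
        w = sum(subset)
        counts[w] = counts.get(w, 0) + 1
    return counts


def ranksum_two_sided_p(n, m, w_obs):
    """Two-sided exact p for an observed group-a rank sum."""
    dist = ranksum_distribution(n, m)
    total = math.comb(n + m, n)
    p_ge = sum(c for w, c in dist.items() if w >= w_obs) / total
    p_le = sum(c for w, c in dist.items() if w <= w_obs) / total
    return min(1.0, 2.0 * min(p_ge, p_le))


def hypergeom_upper_tail(N, K, n, k):
    """P(X >= k) for X ~ Hypergeom(N, K, n), by direct combinatorial sum."""
    total = math.comb(N, n)
    upper = min(K, n)
    acc = 0
    for j in range(k, upper + 1):
        acc += math.comb(K, j) * math.comb(N - K, n - j)
    return acc / total
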