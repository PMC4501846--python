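"""Regulation calling and temporal dynamics of PTM sites.

Each confident site is summarized per time point by the median of its
linear SILAC ratios across replicates; a site is up-regulated at a time
point when that median is >= 2 (down when <= 0.5, both boundaries
inclusive).  The pair of per-time-point classes, together with the ratio
between the two time points, maps deterministically onto a temporal
dynamics class (early-transient / sustained / late / down-regulated /
unregulated / mixed).  The module also provides the residue-class summary
(Tyr vs Ser/Thr fold changes), a Wilcoxon rank-sum test with exact
enumeration for small tie-free groups, and between-replicate Pearson
correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import ConfigurationError, InsufficientDataError, ValidationError
from .tables_io import CHANNEL_HL, CHANNEL_ML, MOD_PHOSPHO, PtmSiteRecord

CLASS_UP = "up"
CLASS_DOWN = "down"
CLASS_UNCHANGED = "unchanged"
CLASS_MISSING = "missing"

DYN_EARLY_TRANSIENT = "early-transient"
DYN_SUSTAINED = "sustained"
DYN_LATE = "late"
DYN_DOWN = "down-regulated"
DYN_UNREGULATED = "unregulated"
DYN_MIXED = "mixed"

DYNAMICS_CLASSES = (
    DYN_EARLY_TRANSIENT, DYN_SUSTAINED, DYN_LATE, DYN_DOWN, DYN_UNREGULATED, DYN_MIXED,
)

RESIDUE_CLASS_TYR = "Tyr"
RESIDUE_CLASS_ST = "Ser/Thr"


@dataclass(frozen=True)
class RegulationThresholds:
    """Linear fold-change cutoffs for up/down calls (2-fold by default)."""

    up_fold: float = 2.0
    down_fold: float = 0.5

    def __post_init__(self) -> None:
        if not self.up_fold > 1.0 > self.down_fold > 0.0:
            raise ConfigurationError(
                f"need up_fold > 1 > down_fold > 0, got "
                f"({self.up_fold}, {self.down_fold})"
            )


@dataclass(frozen=True)
class RegulationCall:
    """Per-site classification across the two stimulation time points."""

    protein_id: str
    position: int
    residue: str
    modification: str
    class_5min: str
    class_15min: str
    ratio_5min: Optional[float]
    ratio_15min: Optional[float]
    dynamics: str


def median_linear_ratio(site: PtmSiteRecord, channel: str) -> Optional[float]:
    """Median linear ratio across replicates; None when unquantified."""
    ratios = site.ratios(channel)
    if not ratios:
        return None
    return float(np.median(list(ratios.values())))


def _classify_channel(ratio: Optional[float], thresholds: RegulationThresholds) -> str:
    if ratio is None:
        return CLASS_MISSING
    if ratio >= thresholds.up_fold:
        return CLASS_UP
    if ratio <= thresholds.down_fold:
        return CLASS_DOWN
    return CLASS_UNCHANGED


def assign_dynamics_class(
    class_5min: str,
    class_15min: str,
    ratio_5min: Optional[float],
    ratio_15min: Optional[float],
    transient_drop: float = 2.0,
) -> str:
    """Map a per-time-point class pair onto a temporal dynamics label.

    Rules, in precedence order:

    * early-transient — up at 5 min and either no longer up at 15 min or
      dropped by at least ``transient_drop``-fold between the time points;
    * sustained — up at both time points without such a drop;
    * late — up only at 15 min (5 min unchanged or unquantified);
    * down-regulated — down at either time point, up at neither;
    * unregulated — no up or down call at either time point;
    * mixed — anything else (down at 5 min then up at 15 min).
    """
    up5 = class_5min == CLASS_UP
    up15 = class_15min == CLASS_UP
    down5 = class_5min == CLASS_DOWN
    down15 = class_15min == CLASS_DOWN
    if up5:
        if not up15:
            return DYN_EARLY_TRANSIENT
        if ratio_5min is not None and ratio_15min is not None and \
                ratio_5min / ratio_15min >= transient_drop:
            return DYN_EARLY_TRANSIENT
        return DYN_SUSTAINED
    if up15:
        if down5:
            return DYN_MIXED
        return DYN_LATE
    if down5 or down15:
        return DYN_DOWN
    return DYN_UNREGULATED


def classify_regulation(
    site: PtmSiteRecord,
    thresholds: RegulationThresholds = RegulationThresholds(),
    transient_drop: float = 2.0,
) -> RegulationCall:
    """Classify one site per time point and assign its dynamics label."""
    ratio_5 = median_linear_ratio(site, CHANNEL_ML)
    ratio_15 = median_linear_ratio(site, CHANNEL_HL)
    class_5 = _classify_channel(ratio_5, thresholds)
    class_15 = _classify_channel(ratio_15, thresholds)
    dynamics = assign_dynamics_class(class_5, class_15, ratio_5, ratio_15, transient_drop)
    return RegulationCall(
        protein_id=site.protein_id,
        position=site.position,
        residue=site.residue,
        modification=site.modification,
        class_5min=class_5,
        class_15min=class_15,
        ratio_5min=ratio_5,
        ratio_15min=ratio_15,
        dynamics=dynamics,
    )


def classify_sites(
    sites: Sequence[PtmSiteRecord],
    thresholds: RegulationThresholds = RegulationThresholds(),
    transient_drop: float = 2.0,
) -> list[RegulationCall]:
    return [classify_regulation(s, thresholds, transient_drop) for s in sites]


def regulation_counts(calls: Sequence[RegulationCall]) -> dict:
    """Quantified/up/down counts per time point (the overview-table shape)."""
    counts = {}
    for label, cls_attr in (("5min", "class_5min"), ("15min", "class_15min")):
        classes = [getattr(c, cls_attr) for c in calls]
        counts[label] = {
            "n_quantified": sum(cls != CLASS_MISSING for cls in classes),
            "n_up": sum(cls == CLASS_UP for cls in classes),
            "n_down": sum(cls == CLASS_DOWN for cls in classes),
        }
    return counts


def residue_class_summary(
    calls: Sequence[RegulationCall],
    up_only: bool = True,
) -> dict:
    """Mean linear fold change per residue class (Tyr vs Ser/Thr) and time point.

    By default the mean is taken over up-regulated sites only, which is the
    subset the headline "average increase" figures describe; pass
    ``up_only=False`` to average over all quantified sites.  Only phospho
    calls are accepted.
    """
    for call in calls:
        if call.modification != MOD_PHOSPHO:
            raise ValidationError(
                f"residue_class_summary expects phospho calls, got "
                f"{call.modification!r} for {call.protein_id}:{call.position}"
            )
    summary: dict = {}
    for res_class, residues in ((RESIDUE_CLASS_TYR, {"Y"}), (RESIDUE_CLASS_ST, {"S", "T"})):
        summary[res_class] = {}
        class_calls = [c for c in calls if c.residue in residues]
        for label, cls_attr, ratio_attr in (
            ("5min", "class_5min", "ratio_5min"),
            ("15min", "class_15min", "ratio_15min"),
        ):
            quantified = [c for c in class_calls if getattr(c, cls_attr) != CLASS_MISSING]
            ups = [c for c in quantified if getattr(c, cls_attr) == CLASS_UP]
            downs = [c for c in quantified if getattr(c, cls_attr) == CLASS_DOWN]
            pool = ups if up_only else quantified
            ratios = [getattr(c, ratio_attr) for c in pool]
            summary[res_class][label] = {
                "n_sites": len(quantified),
                "n_up": len(ups),
                "n_down": len(downs),
                "mean_fold": float(np.mean(ratios)) if ratios else None,
            }
    return summary


# ---------------------------------------------------------------------------
# rank-sum test


def _mannwhitney_u(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """U statistic of group a (number of (a, b) pairs with a > b, ties 0.5)."""
    u = 0.0
    for a in values_a:
        for b in values_b:
            if a > b:
                u += 1.0
            elif a == b:
                u += 0.5
    return u


def _exact_ranksum_p(values_a: Sequence[float], values_b: Sequence[float],
                     alternative: str) -> tuple[float, float]:
    """Exact p by full enumeration of all C(n+m, n) group assignments.

    The two-sided p is twice the smaller tail probability of the observed U,
    capped at 1.
    """
    n, m = len(values_a), len(values_b)
    pooled = sorted(values_a) + sorted(values_b)
    u_obs = _mannwhitney_u(values_a, values_b)
    total = math.comb(n + m, n)
    count_ge = count_le = 0
    indices = range(n + m)
    for subset in combinations(indices, n):
        chosen = set(subset)
        a_vals = [pooled[i] for i in subset]
        b_vals = [pooled[i] for i in indices if i not in chosen]
        u = _mannwhitney_u(a_vals, b_vals)
        if u >= u_obs - 1e-12:
            count_ge += 1
        if u <= u_obs + 1e-12:
            count_le += 1
    p_greater = count_ge / total
    p_less = count_le / total
    if alternative == "greater":
        return u_obs, p_greater
    if alternative == "less":
        return u_obs, p_less
    return u_obs, min(1.0, 2.0 * min(p_greater, p_less))


def ranksum_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    alternative: str = "two-sided",
    exact_max_n: int = 8,
) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney) test of two independent groups.

    Returns (U statistic of group a, p value).  Uses full enumeration of
    rank assignments when both groups have <= ``exact_max_n`` observations
    and the pooled values are tie-free; otherwise the Normal approximation
    with tie and continuity correction.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ConfigurationError(f"unknown alternative {alternative!r}")
    if len(values_a) == 0 or len(values_b) == 0:
        raise InsufficientDataError("both groups must be non-empty")
    pooled = list(values_a) + list(values_b)
    tie_free = len(set(pooled)) == len(pooled)
    if tie_free and len(values_a) <= exact_max_n and len(values_b) <= exact_max_n:
        return _exact_ranksum_p(values_a, values_b, alternative)
    result = stats.mannwhitneyu(
        values_a, values_b, alternative=alternative,
        method="asymptotic", use_continuity=True,
    )
    return float(result.statistic), float(result.pvalue)


def replicate_correlation(
    records: Sequence,
    channel: str,
    rep_i: int,
    rep_j: int,
) -> float:
    """Pearson correlation of log2 ratios between two replicates.

    Computed over entities quantified in both replicates (complete pairs);
    at least three pairs are required.  Works on protein-group and PTM-site
    records alike since both expose ``ratios(channel)``.
    """
    xs, ys = [], []
    for rec in records:
        ratios = rec.ratios(channel)
        if rep_i in ratios and rep_j in ratios:
            xs.append(math.log2(ratios[rep_i]))
            ys.append(math.log2(ratios[rep_j]))
    if len(xs) < 3:
        raise InsufficientDataError(
            f"need >= 3 complete pairs between replicates {rep_i} and {rep_j}, "
            f"got {len(xs)}"
        )
    r, _ = stats.pearsonr(xs, ys)
    return float(r)
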