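"""Empirical-background calling of receptor-signalosome interactors.

In an affinity-purification SILAC experiment most identified proteins are
nonspecific background binders whose log2 ratios scatter around zero.  The
procedure implemented here models that background empirically, per channel:

1. summarize each protein by the median of its log2 ratios across
   replicates (missing replicates skipped);
2. rank proteins by this summary and treat the 90% with the lowest
   summaries as background binders;
3. pool the individual per-replicate log2 ratios: the median over all
   quantified proteins' ratios and the sample SD over the background
   binders' ratios define the empirical null;
4. enrichment cutoff = median + 2 * SD.

Because the cutoff's SD is an observation-level spread while criterion
(ii) is tested against each protein's median across replicates (a much
tighter statistic), proteins whose enrichment is reproducible across
replicates stand out strongly from proteins with one noisy ratio.

A protein is called a specific interactor when, in at least one channel
(time point), it is BOTH (i) at or above the fold threshold (default
2-fold) in at least ``min_replicates`` replicates of that channel and
(ii) its median log2 ratio exceeds that channel's cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import ConfigurationError, InsufficientDataError
from .tables_io import CHANNEL_HL, CHANNEL_ML, CHANNELS, ProteinGroupRecord


@dataclass(frozen=True)
class BackgroundModel:
    """Empirical-null summary of one SILAC channel.

    ``median_log2`` is the median of the pooled per-replicate log2 ratios
    of all quantified proteins; ``sd_log2`` is the sample SD (n-1
    denominator) of the pooled log2 ratios of the background set (the
    ``background_fraction`` of proteins with the lowest per-protein median
    summaries).  ``n_background`` counts background proteins.
    """

    channel: str
    median_log2: float
    sd_log2: float
    n_background: int
    n_quantified: int
    background_fraction: float = 0.90


@dataclass(frozen=True)
class CutoffSet:
    """Per-channel log2 enrichment cutoffs (median + k * SD)."""

    cutoff_log2_ml: float
    cutoff_log2_hl: float

    def cutoff(self, channel: str) -> float:
        return self.cutoff_log2_ml if channel == CHANNEL_ML else self.cutoff_log2_hl


@dataclass(frozen=True)
class InteractorCall:
    """Per-protein enrichment decision across the two time points."""

    protein_id: str
    enriched_5min: bool
    enriched_15min: bool
    median_log2_ml: Optional[float]
    median_log2_hl: Optional[float]
    replicate_support_5: int
    replicate_support_15: int

    @property
    def is_interactor(self) -> bool:
        return self.enriched_5min or self.enriched_15min


@dataclass(frozen=True)
class VennPartition:
    """Counts of enriched proteins shared between / private to time points."""

    n_both: int
    n_only_t1: int
    n_only_t2: int

    @property
    def n_total(self) -> int:
        return self.n_both + self.n_only_t1 + self.n_only_t2

    def as_dict(self) -> dict:
        return {
            "n_both": self.n_both,
            "n_only_t1": self.n_only_t1,
            "n_only_t2": self.n_only_t2,
            "n_total": self.n_total,
        }


def median_center(records: Sequence[ProteinGroupRecord]) -> list[ProteinGroupRecord]:
    """Divide each channel's ratios by that channel's overall median ratio.

    Optional pre-processing for inputs that were not ratio-normalized
    upstream; off by default in the pipeline.  Centering shifts all log2
    ratios of a channel by a constant, so by scale equivariance it moves
    cutoffs and medians together and leaves the set passing the cutoff
    criterion unchanged; the absolute fold-threshold criterion does see
    the recentered scale, which is the point of normalizing.
    """
    import dataclasses

    centers = {}
    for channel in CHANNELS:
        pooled = [v for rec in records for v in rec.ratios(channel).values()]
        centers[channel] = float(np.median(pooled)) if pooled else 1.0
    out = []
    for rec in records:
        out.append(dataclasses.replace(
            rec,
            ratios_ml={k: v / centers[CHANNEL_ML] for k, v in rec.ratios_ml.items()},
            ratios_hl={k: v / centers[CHANNEL_HL] for k, v in rec.ratios_hl.items()},
        ))
    return out


def median_log2_ratio(record: ProteinGroupRecord, channel: str) -> Optional[float]:
    """Median of a protein's log2 ratios across replicates; None if empty."""
    ratios = record.ratios(channel)
    if not ratios:
        return None
    return float(np.median([math.log2(v) for v in ratios.values()]))


def fit_background_model(
    records: Sequence[ProteinGroupRecord],
    channel: str,
    background_fraction: float = 0.90,
) -> BackgroundModel:
    """Fit the empirical background distribution of one channel.

    Proteins are ordered by their per-protein median summary (stable
    tie-break on protein_id); the lowest floor(background_fraction * n)
    proteins form the background set.  The model's median is taken over
    the pooled per-replicate log2 ratios of all quantified proteins, the
    SD over the pooled ratios of the background set.
    """
    if not 0.0 < background_fraction <= 1.0:
        raise ConfigurationError(
            f"background_fraction must be in (0, 1], got {background_fraction}"
        )
    summaries = []
    for rec in records:
        value = median_log2_ratio(rec, channel)
        if value is not None:
            summaries.append((value, rec.protein_id, rec))
    n = len(summaries)
    if n < 3:
        raise InsufficientDataError(
            f"channel {channel}: need >= 3 quantified proteins, got {n}"
        )
    n_background = math.floor(background_fraction * n)
    if n_background < 2:
        raise InsufficientDataError(
            f"channel {channel}: background set of size {n_background} < 2"
        )
    summaries.sort(key=lambda item: (item[0], item[1]))
    all_ratios = [
        math.log2(v) for _, _, rec in summaries for v in rec.ratios(channel).values()
    ]
    background_ratios = [
        math.log2(v)
        for _, _, rec in summaries[:n_background]
        for v in rec.ratios(channel).values()
    ]
    return BackgroundModel(
        channel=channel,
        median_log2=float(np.median(all_ratios)),
        sd_log2=float(np.std(background_ratios, ddof=1)),
        n_background=n_background,
        n_quantified=n,
        background_fraction=background_fraction,
    )


def derive_cutoffs(
    model_ml: BackgroundModel,
    model_hl: BackgroundModel,
    sd_multiplier: float = 2.0,
) -> CutoffSet:
    """Per-channel cutoff = median + sd_multiplier * SD."""
    if sd_multiplier <= 0:
        raise ConfigurationError(f"sd_multiplier must be > 0, got {sd_multiplier}")
    return CutoffSet(
        cutoff_log2_ml=model_ml.median_log2 + sd_multiplier * model_ml.sd_log2,
        cutoff_log2_hl=model_hl.median_log2 + sd_multiplier * model_hl.sd_log2,
    )


def _replicate_support(record: ProteinGroupRecord, channel: str,
                       fold_threshold: float) -> int:
    return sum(1 for v in record.ratios(channel).values() if v >= fold_threshold)


def call_interactors(
    records: Sequence[ProteinGroupRecord],
    cutoffs: CutoffSet,
    min_replicates: int = 2,
    fold_threshold: float = 2.0,
) -> list[InteractorCall]:
    """Apply both enrichment criteria per channel and emit one call per protein.

    Criterion (i): linear ratio >= fold_threshold in >= min_replicates
    replicates of the same channel (boundary inclusive).  Criterion (ii):
    per-protein median log2 ratio strictly greater than the channel cutoff.
    A channel's enriched flag requires both; a protein is an interactor when
    at least one channel is enriched.
    """
    if min_replicates < 1:
        raise ConfigurationError(f"min_replicates must be >= 1, got {min_replicates}")
    if fold_threshold <= 0:
        raise ConfigurationError(f"fold_threshold must be > 0, got {fold_threshold}")
    if records:
        reps_present: set[int] = set()
        for rec in records:
            reps_present.update(rec.ratios_ml.keys())
            reps_present.update(rec.ratios_hl.keys())
        if min_replicates > len(reps_present):
            raise ConfigurationError(
                f"min_replicates={min_replicates} exceeds the "
                f"{len(reps_present)} replicates present in the data"
            )
    calls = []
    for rec in records:
        med_ml = median_log2_ratio(rec, CHANNEL_ML)
        med_hl = median_log2_ratio(rec, CHANNEL_HL)
        support_5 = _replicate_support(rec, CHANNEL_ML, fold_threshold)
        support_15 = _replicate_support(rec, CHANNEL_HL, fold_threshold)
        enriched_5 = (
            support_5 >= min_replicates
            and med_ml is not None
            and med_ml > cutoffs.cutoff_log2_ml
        )
        enriched_15 = (
            support_15 >= min_replicates
            and med_hl is not None
            and med_hl > cutoffs.cutoff_log2_hl
        )
        calls.append(
            InteractorCall(
                protein_id=rec.protein_id,
                enriched_5min=enriched_5,
                enriched_15min=enriched_15,
                median_log2_ml=med_ml,
                median_log2_hl=med_hl,
                replicate_support_5=support_5,
                replicate_support_15=support_15,
            )
        )
    return calls


def venn_counts(flag_pairs: Iterable[tuple[bool, bool]]) -> VennPartition:
    """Partition (flag_t1, flag_t2) pairs into both / only-t1 / only-t2."""
    n_both = n_only_1 = n_only_2 = 0
    for f1, f2 in flag_pairs:
        if f1 and f2:
            n_both += 1
        elif f1:
            n_only_1 += 1
        elif f2:
            n_only_2 += 1
    return VennPartition(n_both=n_both, n_only_t1=n_only_1, n_only_t2=n_only_2)


def partition_venn(calls: Sequence[InteractorCall]) -> VennPartition:
    """Venn partition of interactors over the 5- and 15-min time points."""
    return venn_counts((c.enriched_5min, c.enriched_15min) for c in calls)
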