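"""Confidence filtering of PTM sites before regulation calling.

High-confidence sites must satisfy all three score filters (boundaries
inclusive): localization probability >= 0.75, identification score >= 40,
posterior error probability <= 0.01.  Di-Gly sites must additionally sit
internally in the identified peptide: trypsin cannot cleave C-terminally of
a di-Gly-modified lysine, so a C-terminal di-Gly lysine is an in-vitro
artifact and is removed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import ContractViolationError, ConfigurationError
from .tables_io import MOD_DIGLY, PtmSiteRecord

REASON_LOCALIZATION = "localization_prob"
REASON_SCORE = "score"
REASON_PEP = "pep"
REASON_CTERM = "peptide_cterm"


@dataclass(frozen=True)
class QualityThresholds:
    """Score filters applied to every PTM site."""

    min_localization_prob: float = 0.75
    min_score: float = 40.0
    max_pep: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_localization_prob <= 1.0:
            raise ConfigurationError(
                f"min_localization_prob must be in [0, 1], got {self.min_localization_prob}"
            )
        if not 0.0 <= self.max_pep <= 1.0:
            raise ConfigurationError(f"max_pep must be in [0, 1], got {self.max_pep}")


@dataclass(frozen=True)
class Rejection:
    """One filtered-out site and the first criterion it failed."""

    protein_id: str
    position: int
    residue: str
    modification: str
    reason: str


def _first_failure(site: PtmSiteRecord, thresholds: QualityThresholds) -> str | None:
    # Criteria checked in a fixed order so the logged reason is deterministic.
    if site.localization_prob < thresholds.min_localization_prob:
        return REASON_LOCALIZATION
    if site.score < thresholds.min_score:
        return REASON_SCORE
    if site.pep > thresholds.max_pep:
        return REASON_PEP
    return None


def filter_confident_sites(
    sites: Sequence[PtmSiteRecord],
    thresholds: QualityThresholds = QualityThresholds(),
) -> tuple[list[PtmSiteRecord], list[Rejection]]:
    """Split sites into (kept, rejected-with-reason) by the score filters.

    Kept iff localization_prob >= min AND score >= min AND pep <= max, all
    boundaries inclusive.  The union of the two outputs is the input, in
    order, with no overlap.
    """
    kept: list[PtmSiteRecord] = []
    rejected: list[Rejection] = []
    for site in sites:
        reason = _first_failure(site, thresholds)
        if reason is None:
            kept.append(site)
        else:
            rejected.append(
                Rejection(site.protein_id, site.position, site.residue,
                          site.modification, reason)
            )
    return kept, rejected


def require_internal_digly(
    sites: Sequence[PtmSiteRecord],
) -> tuple[list[PtmSiteRecord], list[Rejection]]:
    """Drop di-Gly sites whose modified lysine is peptide-C-terminal.

    Only defined for di-Gly records; passing a phospho record is a contract
    violation (the rule has no meaning for phospho peptides).
    """
    kept: list[PtmSiteRecord] = []
    rejected: list[Rejection] = []
    for site in sites:
        if site.modification != MOD_DIGLY:
            raise ContractViolationError(
                f"require_internal_digly got a {site.modification!r} record "
                f"({site.protein_id}:{site.position})"
            )
        if site.is_peptide_cterm:
            rejected.append(
                Rejection(site.protein_id, site.position, site.residue,
                          site.modification, REASON_CTERM)
            )
        else:
            kept.append(site)
    return kept, rejected


def write_rejection_log(rejections: Sequence[Rejection], path: str | Path) -> None:
    """Persist a rejection log as TSV with a ``reason`` column."""
    columns = ["Protein.ID", "Position", "Residue", "Modification", "reason"]
    rows = [
        {
            "Protein.ID": r.protein_id,
            "Position": str(r.position),
            "Residue": r.residue,
            "Modification": r.modification,
            "reason": r.reason,
        }
        for r in rejections
    ]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
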