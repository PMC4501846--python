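"""Protein-level integration across layers and annotation-term enrichment.

Joins the phospho, di-Gly and signalosome layers on protein identifiers to
find proteins co-regulated by phosphorylation and ubiquitylation, and
provides a generic one-sided hypergeometric enrichment test with
Benjamini-Hochberg adjustment over a user-supplied term -> protein
annotation map.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .interactome import InteractorCall
from .regulation import CLASS_UP, RegulationCall


@dataclass(frozen=True)
class CoRegulationRecord:
    """Cross-layer status of one protein with at least one up-regulated site."""

    protein_id: str
    has_up_phospho: bool
    has_up_digly: bool
    in_signalosome: bool
    n_up_phospho_sites: int
    n_up_digly_sites: int

    @property
    def co_regulated(self) -> bool:
        return self.has_up_phospho and self.has_up_digly


@dataclass(frozen=True)
class EnrichmentResult:
    """One annotation term's hypergeometric enrichment in the study set."""

    term: str
    k: int   # study proteins with the term
    K: int   # universe proteins with the term
    n: int   # study size
    N: int   # universe size
    p_value: float
    q_value: float


def _up_site_counts(calls: Iterable[RegulationCall]) -> dict[str, int]:
    """Number of sites up-regulated at any time point, per protein."""
    counts: dict[str, int] = {}
    for call in calls:
        if call.class_5min == CLASS_UP or call.class_15min == CLASS_UP:
            counts[call.protein_id] = counts.get(call.protein_id, 0) + 1
    return counts


def co_regulated_proteins(
    phospho_calls: Sequence[RegulationCall],
    digly_calls: Sequence[RegulationCall],
    interactor_calls: Optional[Sequence[InteractorCall]] = None,
) -> list[CoRegulationRecord]:
    """One record per protein with >= 1 up-regulated site in either PTM layer.

    A protein counts as co-regulated when it carries an up-regulated
    phosphorylation site and an up-regulated di-Gly site, each at any time
    point.  Signalosome membership is annotated when interactor calls are
    supplied.  Output is sorted by protein_id and independent of input
    ordering.
    """
    up_phospho = _up_site_counts(phospho_calls)
    up_digly = _up_site_counts(digly_calls)
    signalosome = {
        c.protein_id for c in (interactor_calls or []) if c.is_interactor
    }
    records = []
    for protein_id in sorted(set(up_phospho) | set(up_digly)):
        n_p = up_phospho.get(protein_id, 0)
        n_d = up_digly.get(protein_id, 0)
        records.append(
            CoRegulationRecord(
                protein_id=protein_id,
                has_up_phospho=n_p > 0,
                has_up_digly=n_d > 0,
                in_signalosome=protein_id in signalosome,
                n_up_phospho_sites=n_p,
                n_up_digly_sites=n_d,
            )
        )
    return records


def hypergeometric_enrichment(
    study_set: Iterable[str],
    annotation_map: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> list[EnrichmentResult]:
    """One-sided hypergeometric upper-tail enrichment per annotation term.

    For a term annotating K of N universe proteins, of which k fall in the
    study set of size n, p = P(X >= k) with X ~ Hypergeom(N, K, n).  Terms
    with k = 0 are skipped; q values are Benjamini-Hochberg over exactly the
    tested terms.  Results are sorted by (p, term).
    """
    universe_set = set(universe)
    study = set(study_set)
    missing = study - universe_set
    if missing:
        raise ValidationError(
            f"study proteins absent from universe: {sorted(missing)[:5]}"
        )
    N = len(universe_set)
    n = len(study)
    tested: list[tuple[str, int, int]] = []
    for term in sorted(annotation_map):
        annotated = set(annotation_map[term]) & universe_set
        k = len(annotated & study)
        if k == 0:
            continue
        tested.append((term, k, len(annotated)))
    if not tested:
        return []
    pvals = [
        float(stats.hypergeom.sf(k - 1, N, K, n)) for _, k, K in tested
    ]
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    results = [
        EnrichmentResult(term=term, k=k, K=K, n=n, N=N,
                         p_value=p, q_value=float(q))
        for (term, k, K), p, q in zip(tested, pvals, qvals)
    ]
    results.sort(key=lambda r: (r.p_value, r.term))
    return results


def read_annotation_map(path: str | Path) -> dict[str, set[str]]:
    """Two-column (term, protein) TSV -> term -> protein-set mapping."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if frame.shape[1] < 2:
        raise ValidationError(f"{path}: annotation file needs two columns")
    term_col, protein_col = frame.columns[:2]
    mapping: dict[str, set[str]] = {}
    for term, protein in zip(frame[term_col], frame[protein_col]):
        mapping.setdefault(term, set()).add(protein)
    return mapping


_COREG_EDGE_COLUMNS = [
    "Protein.ID", "has_up_phospho", "has_up_digly", "in_signalosome",
]
_INTERACTOR_EDGE_COLUMNS = ["Protein.ID", "enriched_5min", "enriched_15min"]


def export_edge_list(records: Sequence, path: str | Path) -> None:
    """Write a node-attribute TSV loadable by standard network tools.

    One row per protein, sorted by protein_id, with boolean attribute
    columns; deterministic and diff-friendly.  Accepts co-regulation
    records and interactor calls (an empty list is written with the
    co-regulation header).
    """
    rows = []
    columns = _COREG_EDGE_COLUMNS
    for rec in records:
        if isinstance(rec, CoRegulationRecord):
            rows.append({
                "Protein.ID": rec.protein_id,
                "has_up_phospho": str(rec.has_up_phospho),
                "has_up_digly": str(rec.has_up_digly),
                "in_signalosome": str(rec.in_signalosome),
            })
        elif isinstance(rec, InteractorCall):
            columns = _INTERACTOR_EDGE_COLUMNS
            rows.append({
                "Protein.ID": rec.protein_id,
                "enriched_5min": str(rec.enriched_5min),
                "enriched_15min": str(rec.enriched_15min),
            })
        else:
            raise ValidationError(f"cannot export records of type {type(rec).__name__}")
    rows.sort(key=lambda r: r["Protein.ID"])
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def read_edge_list(path: str | Path) -> list[dict]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return frame.to_dict(orient="records")


def write_enrichment(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    columns = ["term", "k", "K", "n", "N", "p_value", "q_value"]
    rows = [
        {
            "term": r.term, "k": r.k, "K": r.K, "n": r.n, "N": r.N,
            "p_value": repr(r.p_value), "q_value": repr(r.q_value),
        }
        for r in results
    ]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
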