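"""Shared factories for building toy records in tests."""

from __future__ import annotations

import pytest

from silacsig.tables_io import ProteinGroupRecord, PtmSiteRecord


def make_protein(pid, ml=None, hl=None, gene=None, n_peptides=None):
    return ProteinGroupRecord(
        protein_id=pid,
        gene_name=gene,
        ratios_ml=dict(ml or {}),
        ratios_hl=dict(hl or {}),
        n_peptides=n_peptides,
    )


def make_site(pid="P1", residue="S", position=10, modification="phospho",
              loc=0.99, score=100.0, pep=0.001, cterm=False, ml=None, hl=None):
    return PtmSiteRecord(
        protein_id=pid,
        residue=residue,
        position=position,
        modification=modification,
        localization_prob=loc,
        score=score,
        pep=pep,
        is_peptide_cterm=cterm,
        ratios_ml=dict(ml or {}),
        ratios_hl=dict(hl or {}),
    )


def random_protein_table(rng, max_proteins=100, n_replicates=4):
    """Random replicated pull-down table with missing cells, for oracle tests."""
    n = int(rng.integers(3, max_proteins + 1))
    records = []
    for i in range(n):
        ratios = {"ML": {}, "HL": {}}
        for channel in ("ML", "HL"):
            for rep in range(1, n_replicates + 1):
                if rng.random() < 0.15:
                    continue  # missing cell
                ratios[channel][rep] = float(2.0 ** rng.normal(0.3, 1.2))
        records.append(make_protein(f"P{i:03d}", ml=ratios["ML"], hl=ratios["HL"]))
    return records


@pytest.fixture
def protein_factory():
    return make_protein


@pytest.fixture
def site_factory():
    return make_site
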