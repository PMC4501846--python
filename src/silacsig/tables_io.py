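"""Reading and writing protein-group and PTM-site tables.

The on-disk dialect is a fixed tab-separated layout inspired by MaxQuant
exports: one row per protein group (or modified site), per-replicate SILAC
ratio columns ``Ratio.M.L.rep{k}`` / ``Ratio.H.L.rep{k}``, '.' decimal,
UTF-8.  M/L is the 5-min-stimulated over control channel, H/L the 15-min
channel.  All ratios are stored on the linear scale; log2 transformation is
the business of the statistics modules.

Missing ratio cells ("" or "NaN") become absent entries in the record's
ratio dictionaries — never zero.  A thin ``column_map`` hook allows renaming
columns of real MaxQuant exports into this dialect.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, fields, is_dataclass, asdict
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import FormatError, ValidationError

# Channel identifiers: medium/light = 5 min over control, heavy/light = 15 min.
CHANNEL_ML = "ML"
CHANNEL_HL = "HL"
CHANNELS = (CHANNEL_ML, CHANNEL_HL)

MOD_PHOSPHO = "phospho"
MOD_DIGLY = "diGly"

PROTEIN_ID_COL = "Protein.ID"
GENE_NAME_COL = "Gene.name"
N_PEPTIDES_COL = "N.peptides"
RESIDUE_COL = "Residue"
POSITION_COL = "Position"
MODIFICATION_COL = "Modification"
LOCALIZATION_COL = "Localization.prob"
SCORE_COL = "Score"
PEP_COL = "PEP"
CTERM_COL = "Peptide.Cterm"

_RATIO_RE = re.compile(r"^Ratio\.(M|H)\.L\.rep(\d+)$")

_PHOSPHO_RESIDUES = frozenset("STY")


def ratio_column(channel: str, replicate: int) -> str:
    """Dialect column name for one (channel, replicate) ratio."""
    letter = {"ML": "M", "HL": "H"}[channel]
    return f"Ratio.{letter}.L.rep{replicate}"


@dataclass
class ProteinGroupRecord:
    """One protein group with per-replicate SILAC ratio pairs.

    ``ratios_ml`` and ``ratios_hl`` map replicate index -> linear-scale
    ratio; replicates without a quantified ratio are simply absent.
    """

    protein_id: str
    gene_name: Optional[str] = None
    ratios_ml: dict[int, float] = field(default_factory=dict)
    ratios_hl: dict[int, float] = field(default_factory=dict)
    n_peptides: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValidationError("protein_id must be non-empty")
        for ch, ratios in (("M/L", self.ratios_ml), ("H/L", self.ratios_hl)):
            for rep, value in ratios.items():
                if not value > 0:
                    raise ValidationError(
                        f"protein {self.protein_id}: {ch} ratio in replicate "
                        f"{rep} must be > 0, got {value}"
                    )

    def ratios(self, channel: str) -> dict[int, float]:
        """Replicate -> linear ratio mapping for one channel."""
        if channel == CHANNEL_ML:
            return self.ratios_ml
        if channel == CHANNEL_HL:
            return self.ratios_hl
        raise ValidationError(f"unknown channel {channel!r}")


@dataclass
class PtmSiteRecord:
    """One modified site (phospho or di-Gly) with quality scores and ratios.

    Positions are 1-based on the protein sequence.  ``is_peptide_cterm``
    is meaningful for di-Gly sites only: a di-Gly lysine at the peptide
    C-terminus is a chemical artifact because trypsin cannot cleave after
    a modified lysine.
    """

    protein_id: str
    residue: str
    position: int
    modification: str
    localization_prob: float
    score: float
    pep: float
    is_peptide_cterm: bool = False
    ratios_ml: dict[int, float] = field(default_factory=dict)
    ratios_hl: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValidationError("protein_id must be non-empty")
        if self.modification not in (MOD_PHOSPHO, MOD_DIGLY):
            raise ValidationError(f"unknown modification {self.modification!r}")
        if self.modification == MOD_DIGLY:
            if self.residue != "K":
                raise ValidationError(
                    f"site {self.protein_id}:{self.position}: di-Gly sites "
                    f"must be on K, got {self.residue!r}"
                )
        elif self.residue not in _PHOSPHO_RESIDUES:
            raise ValidationError(
                f"site {self.protein_id}:{self.position}: phospho sites must "
                f"be on S/T/Y, got {self.residue!r}"
            )
        if self.position < 1:
            raise ValidationError(
                f"site {self.protein_id}: position must be >= 1, got {self.position}"
            )
        if not 0.0 <= self.localization_prob <= 1.0:
            raise ValidationError(
                f"site {self.protein_id}:{self.position}: localization_prob "
                f"must be in [0, 1], got {self.localization_prob}"
            )
        if not 0.0 <= self.pep <= 1.0:
            raise ValidationError(
                f"site {self.protein_id}:{self.position}: PEP must be in [0, 1], "
                f"got {self.pep}"
            )
        for ch, ratios in (("M/L", self.ratios_ml), ("H/L", self.ratios_hl)):
            for rep, value in ratios.items():
                if not value > 0:
                    raise ValidationError(
                        f"site {self.protein_id}:{self.position}: {ch} ratio in "
                        f"replicate {rep} must be > 0, got {value}"
                    )

    @property
    def site_key(self) -> tuple[str, int, str, str]:
        return (self.protein_id, self.position, self.residue, self.modification)

    def ratios(self, channel: str) -> dict[int, float]:
        if channel == CHANNEL_ML:
            return self.ratios_ml
        if channel == CHANNEL_HL:
            return self.ratios_hl
        raise ValidationError(f"unknown channel {channel!r}")


# ---------------------------------------------------------------------------
# reading


def _load_frame(path: str | Path, column_map: Optional[Mapping[str, str]]) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if column_map:
        frame = frame.rename(columns=dict(column_map))
    return frame


def _require_columns(frame: pd.DataFrame, required: Sequence[str], path: str | Path) -> None:
    for col in required:
        if col not in frame.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")


def _ratio_columns(frame: pd.DataFrame) -> list[tuple[str, str, int]]:
    """All ratio columns as (column, channel, replicate) triples."""
    found = []
    for col in frame.columns:
        m = _RATIO_RE.match(col)
        if m:
            channel = CHANNEL_ML if m.group(1) == "M" else CHANNEL_HL
            found.append((col, channel, int(m.group(2))))
    return found


def _parse_ratio_cell(raw: str, row: int, col: str, path: str | Path) -> Optional[float]:
    text = raw.strip()
    if text == "" or text.lower() == "nan":
        return None
    try:
        value = float(text)
    except ValueError as exc:
        raise ValidationError(f"{path}: row {row}: column {col!r}: "
                              f"unparsable ratio {raw!r}") from exc
    if not value > 0:
        raise ValidationError(
            f"{path}: row {row}: column {col!r}: ratio must be > 0, got {raw}"
        )
    return value


def read_protein_groups(
    path: str | Path,
    column_map: Optional[Mapping[str, str]] = None,
) -> list[ProteinGroupRecord]:
    """Parse a protein-group table.

    Row order is preserved; missing ratio cells stay missing.  Row numbers
    in error messages are 1-based over the data rows (header excluded).
    """
    frame = _load_frame(path, column_map)
    _require_columns(frame, [PROTEIN_ID_COL], path)
    ratio_cols = _ratio_columns(frame)
    if not ratio_cols:
        raise FormatError(f"{path}: no 'Ratio.M.L.rep*' / 'Ratio.H.L.rep*' columns found")

    records: list[ProteinGroupRecord] = []
    for idx, row in enumerate(frame.itertuples(index=False), start=1):
        row_map = dict(zip(frame.columns, row))
        ratios: dict[str, dict[int, float]] = {CHANNEL_ML: {}, CHANNEL_HL: {}}
        for col, channel, rep in ratio_cols:
            value = _parse_ratio_cell(row_map[col], idx, col, path)
            if value is not None:
                ratios[channel][rep] = value
        gene = row_map.get(GENE_NAME_COL, "").strip() or None
        n_pep_raw = row_map.get(N_PEPTIDES_COL, "").strip()
        try:
            records.append(
                ProteinGroupRecord(
                    protein_id=row_map[PROTEIN_ID_COL].strip(),
                    gene_name=gene,
                    ratios_ml=ratios[CHANNEL_ML],
                    ratios_hl=ratios[CHANNEL_HL],
                    n_peptides=int(n_pep_raw) if n_pep_raw else None,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {idx}: {exc}") from exc
    return records


_TRUE_STRINGS = {"true", "1", "yes"}
_FALSE_STRINGS = {"false", "0", "no", ""}


def _parse_bool(raw: str, row: int, path: str | Path) -> bool:
    text = raw.strip().lower()
    if text in _TRUE_STRINGS:
        return True
    if text in _FALSE_STRINGS:
        return False
    raise ValidationError(f"{path}: row {row}: unparsable boolean {raw!r}")


def read_ptm_sites(
    path: str | Path,
    modification: str,
    column_map: Optional[Mapping[str, str]] = None,
) -> list[PtmSiteRecord]:
    """Parse a PTM-site table for one modification type.

    No confidence filtering happens here — every row is returned; the
    site_quality module decides what is kept.  A ``Modification`` column,
    when present, must agree with the requested modification.
    """
    if modification not in (MOD_PHOSPHO, MOD_DIGLY):
        raise ValidationError(f"unknown modification {modification!r}")
    frame = _load_frame(path, column_map)
    _require_columns(
        frame,
        [PROTEIN_ID_COL, RESIDUE_COL, POSITION_COL, LOCALIZATION_COL, SCORE_COL, PEP_COL],
        path,
    )
    ratio_cols = _ratio_columns(frame)
    if not ratio_cols:
        raise FormatError(f"{path}: no 'Ratio.M.L.rep*' / 'Ratio.H.L.rep*' columns found")

    records: list[PtmSiteRecord] = []
    for idx, row in enumerate(frame.itertuples(index=False), start=1):
        row_map = dict(zip(frame.columns, row))
        declared = row_map.get(MODIFICATION_COL, modification).strip()
        if declared != modification:
            raise ValidationError(
                f"{path}: row {idx}: modification {declared!r} does not match "
                f"requested {modification!r}"
            )
        ratios: dict[str, dict[int, float]] = {CHANNEL_ML: {}, CHANNEL_HL: {}}
        for col, channel, rep in ratio_cols:
            value = _parse_ratio_cell(row_map[col], idx, col, path)
            if value is not None:
                ratios[channel][rep] = value
        try:
            records.append(
                PtmSiteRecord(
                    protein_id=row_map[PROTEIN_ID_COL].strip(),
                    residue=row_map[RESIDUE_COL].strip(),
                    position=int(row_map[POSITION_COL]),
                    modification=modification,
                    localization_prob=float(row_map[LOCALIZATION_COL]),
                    score=float(row_map[SCORE_COL]),
                    pep=float(row_map[PEP_COL]),
                    is_peptide_cterm=_parse_bool(row_map.get(CTERM_COL, ""), idx, path),
                    ratios_ml=ratios[CHANNEL_ML],
                    ratios_hl=ratios[CHANNEL_HL],
                )
            )
        except (ValidationError, ValueError) as exc:
            if isinstance(exc, ValidationError):
                raise ValidationError(f"{path}: row {idx}: {exc}") from exc
            raise ValidationError(f"{path}: row {idx}: malformed field ({exc})") from exc
    return records


# ---------------------------------------------------------------------------
# writing


def _replicate_indices(records: Iterable, channel: str) -> list[int]:
    reps: set[int] = set()
    for rec in records:
        reps.update(rec.ratios(channel).keys())
    return sorted(reps)


def _format_ratio(value: Optional[float]) -> str:
    return "" if value is None else repr(float(value))


def write_protein_groups(records: Sequence[ProteinGroupRecord], path: str | Path) -> None:
    """Write protein groups in the dialect; inverse of read_protein_groups."""
    reps_ml = _replicate_indices(records, CHANNEL_ML)
    reps_hl = _replicate_indices(records, CHANNEL_HL)
    columns = [PROTEIN_ID_COL, GENE_NAME_COL, N_PEPTIDES_COL]
    columns += [ratio_column(CHANNEL_ML, r) for r in reps_ml]
    columns += [ratio_column(CHANNEL_HL, r) for r in reps_hl]
    rows = []
    for rec in records:
        row = {
            PROTEIN_ID_COL: rec.protein_id,
            GENE_NAME_COL: rec.gene_name or "",
            N_PEPTIDES_COL: "" if rec.n_peptides is None else str(rec.n_peptides),
        }
        for r in reps_ml:
            row[ratio_column(CHANNEL_ML, r)] = _format_ratio(rec.ratios_ml.get(r))
        for r in reps_hl:
            row[ratio_column(CHANNEL_HL, r)] = _format_ratio(rec.ratios_hl.get(r))
        rows.append(row)
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def write_ptm_sites(records: Sequence[PtmSiteRecord], path: str | Path) -> None:
    """Write PTM sites in the dialect; inverse of read_ptm_sites."""
    reps_ml = _replicate_indices(records, CHANNEL_ML)
    reps_hl = _replicate_indices(records, CHANNEL_HL)
    columns = [
        PROTEIN_ID_COL, RESIDUE_COL, POSITION_COL, MODIFICATION_COL,
        LOCALIZATION_COL, SCORE_COL, PEP_COL, CTERM_COL,
    ]
    columns += [ratio_column(CHANNEL_ML, r) for r in reps_ml]
    columns += [ratio_column(CHANNEL_HL, r) for r in reps_hl]
    rows = []
    for rec in records:
        row = {
            PROTEIN_ID_COL: rec.protein_id,
            RESIDUE_COL: rec.residue,
            POSITION_COL: str(rec.position),
            MODIFICATION_COL: rec.modification,
            LOCALIZATION_COL: repr(float(rec.localization_prob)),
            SCORE_COL: repr(float(rec.score)),
            PEP_COL: repr(float(rec.pep)),
            CTERM_COL: "True" if rec.is_peptide_cterm else "False",
        }
        for r in reps_ml:
            row[ratio_column(CHANNEL_ML, r)] = _format_ratio(rec.ratios_ml.get(r))
        for r in reps_hl:
            row[ratio_column(CHANNEL_HL, r)] = _format_ratio(rec.ratios_hl.get(r))
        rows.append(row)
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def write_calls(records: Sequence, path: str | Path,
                columns: Optional[Sequence[str]] = None) -> None:
    """Write a list of call dataclasses (or dicts) as a TSV.

    Column order follows the dataclass field order of the first record, or
    the explicit ``columns`` argument (required for an empty list so that a
    header-only file can still be produced).
    """
    rows: list[dict] = []
    for rec in records:
        rows.append(asdict(rec) if is_dataclass(rec) else dict(rec))
    if columns is None:
        if not rows:
            raise ValidationError("columns must be given when the call list is empty")
        first = records[0]
        columns = [f.name for f in fields(first)] if is_dataclass(first) else list(rows[0])
    out_rows = []
    for row in rows:
        out = {}
        for col in columns:
            value = row.get(col)
            out[col] = "" if value is None else str(value)
        out_rows.append(out)
    pd.DataFrame(out_rows, columns=list(columns)).to_csv(path, sep="\t", index=False)


def write_summary(report: Mapping, path: str | Path) -> None:
    """Serialize a summary report as JSON with sorted keys.

    Sorted keys and fixed separators make re-serialization byte-identical,
    which the pipeline's determinism contract relies on.
    """
    text = json.dumps(report, sort_keys=True, indent=2, allow_nan=False)
    Path(path).write_text(text + "\n", encoding="utf-8")


def read_summary(path: str | Path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
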