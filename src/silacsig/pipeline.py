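"""End-to-end pipeline: read tables, call every layer, write a summary report.

The report is plain JSON with sorted keys and no timestamp, so two runs on
identical inputs and config produce byte-identical output.  Every count in
the report can be re-derived from the call TSVs written next to it.
"""

from __future__ import annotations

import dataclasses
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .errors import ConfigurationError
from .integration import co_regulated_proteins, export_edge_list
from .interactome import (
    BackgroundModel,
    InteractorCall,
    call_interactors,
    derive_cutoffs,
    fit_background_model,
    median_center,
    partition_venn,
    venn_counts,
)
from .regulation import (
    CLASS_UP,
    RegulationCall,
    RegulationThresholds,
    classify_sites,
    regulation_counts,
    residue_class_summary,
)
from .site_quality import (
    QualityThresholds,
    filter_confident_sites,
    require_internal_digly,
    write_rejection_log,
)
from .tables_io import (
    CHANNEL_HL,
    CHANNEL_ML,
    MOD_DIGLY,
    MOD_PHOSPHO,
    read_protein_groups,
    read_ptm_sites,
    write_calls,
    write_summary,
)

INTERACTOR_CALL_COLUMNS = [f.name for f in dataclasses.fields(InteractorCall)]
REGULATION_CALL_COLUMNS = [f.name for f in dataclasses.fields(RegulationCall)]


@dataclass
class PipelineConfig:
    """All pipeline inputs, outputs and parameters in one place.

    Any of the three input tables may be omitted; the corresponding layer
    is then skipped.  Defaults reproduce the standard analysis: 90%
    background fraction, median + 2 SD cutoff, 2-fold / two-replicate
    support for interactors, 2-fold up / 0.5-fold down for PTM sites.
    """

    out_dir: Path
    protein_groups: Optional[Path] = None
    phospho_sites: Optional[Path] = None
    digly_sites: Optional[Path] = None
    quality: QualityThresholds = field(default_factory=QualityThresholds)
    regulation: RegulationThresholds = field(default_factory=RegulationThresholds)
    apply_score_filters_to_digly: bool = True
    background_fraction: float = 0.90
    sd_multiplier: float = 2.0
    min_replicates: int = 2
    fold_threshold: float = 2.0
    median_center: bool = False
    transient_drop: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd_multiplier <= 0:
            raise ConfigurationError(
                f"sd_multiplier must be > 0, got {self.sd_multiplier}"
            )
        self.out_dir = Path(self.out_dir)
        for name in ("protein_groups", "phospho_sites", "digly_sites"):
            value = getattr(self, name)
            if value is not None:
                setattr(self, name, Path(value))

    def echo(self) -> dict:
        """JSON-serializable config echo for the report."""
        return {
            "protein_groups": str(self.protein_groups) if self.protein_groups else None,
            "phospho_sites": str(self.phospho_sites) if self.phospho_sites else None,
            "digly_sites": str(self.digly_sites) if self.digly_sites else None,
            "out_dir": str(self.out_dir),
            "quality": dataclasses.asdict(self.quality),
            "regulation": dataclasses.asdict(self.regulation),
            "apply_score_filters_to_digly": self.apply_score_filters_to_digly,
            "background_fraction": self.background_fraction,
            "sd_multiplier": self.sd_multiplier,
            "min_replicates": self.min_replicates,
            "fold_threshold": self.fold_threshold,
            "median_center": self.median_center,
            "transient_drop": self.transient_drop,
            "seed": self.seed,
        }

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Build a config from a sectioned key-value YAML file.

        Recognized sections: ``inputs`` (protein_groups, phospho_sites,
        digly_sites), ``output`` (out_dir), ``quality``, ``regulation``,
        ``interactome``, plus a top-level ``seed``.  Keyword overrides win
        over file values.
        """
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        kwargs: dict = {}
        inputs = raw.get("inputs", {}) or {}
        for key in ("protein_groups", "phospho_sites", "digly_sites"):
            if inputs.get(key):
                kwargs[key] = Path(inputs[key])
        output = raw.get("output", {}) or {}
        if output.get("out_dir"):
            kwargs["out_dir"] = Path(output["out_dir"])
        quality = dict(raw.get("quality", {}) or {})
        if "apply_score_filters_to_digly" in quality:
            kwargs["apply_score_filters_to_digly"] = bool(
                quality.pop("apply_score_filters_to_digly")
            )
        if quality:
            kwargs["quality"] = QualityThresholds(**quality)
        regulation = dict(raw.get("regulation", {}) or {})
        if "transient_drop" in regulation:
            kwargs["transient_drop"] = float(regulation.pop("transient_drop"))
        if regulation:
            kwargs["regulation"] = RegulationThresholds(**regulation)
        interactome = raw.get("interactome", {}) or {}
        for key in ("background_fraction", "sd_multiplier", "fold_threshold"):
            if key in interactome:
                kwargs[key] = float(interactome[key])
        if "min_replicates" in interactome:
            kwargs["min_replicates"] = int(interactome["min_replicates"])
        if "median_center" in interactome:
            kwargs["median_center"] = bool(interactome["median_center"])
        if "seed" in raw:
            kwargs["seed"] = int(raw["seed"])
        kwargs.update(overrides)
        if "out_dir" not in kwargs:
            raise ConfigurationError(f"{path}: output.out_dir is required")
        return cls(**kwargs)


def read_interactor_calls(path: str | Path) -> list[InteractorCall]:
    """Load an interactor-call TSV written by this pipeline."""
    import pandas as pd

    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    calls = []
    for _, row in frame.iterrows():
        calls.append(
            InteractorCall(
                protein_id=row["protein_id"],
                enriched_5min=row["enriched_5min"] == "True",
                enriched_15min=row["enriched_15min"] == "True",
                median_log2_ml=float(row["median_log2_ml"]) if row["median_log2_ml"] else None,
                median_log2_hl=float(row["median_log2_hl"]) if row["median_log2_hl"] else None,
                replicate_support_5=int(row["replicate_support_5"]),
                replicate_support_15=int(row["replicate_support_15"]),
            )
        )
    return calls


def read_regulation_calls(path: str | Path) -> list[RegulationCall]:
    """Load a regulation-call TSV written by this pipeline."""
    import pandas as pd

    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    calls = []
    for _, row in frame.iterrows():
        calls.append(
            RegulationCall(
                protein_id=row["protein_id"],
                position=int(row["position"]),
                residue=row["residue"],
                modification=row["modification"],
                class_5min=row["class_5min"],
                class_15min=row["class_15min"],
                ratio_5min=float(row["ratio_5min"]) if row["ratio_5min"] else None,
                ratio_15min=float(row["ratio_15min"]) if row["ratio_15min"] else None,
                dynamics=row["dynamics"],
            )
        )
    return calls


def _model_dict(model: BackgroundModel) -> dict:
    return {
        "channel": model.channel,
        "median_log2": model.median_log2,
        "sd_log2": model.sd_log2,
        "n_background": model.n_background,
        "n_quantified": model.n_quantified,
        "background_fraction": model.background_fraction,
    }


def _log(message: str) -> None:
    print(f"[silacsig] {message}", file=sys.stderr)


def run_interactome_stage(config: PipelineConfig) -> tuple[dict, list[InteractorCall]]:
    """Background fit, cutoffs, interactor calls and Venn for one table."""
    records = read_protein_groups(config.protein_groups)
    if config.median_center:
        records = median_center(records)
    model_ml = fit_background_model(records, CHANNEL_ML, config.background_fraction)
    model_hl = fit_background_model(records, CHANNEL_HL, config.background_fraction)
    cutoffs = derive_cutoffs(model_ml, model_hl, config.sd_multiplier)
    calls = call_interactors(
        records, cutoffs,
        min_replicates=config.min_replicates,
        fold_threshold=config.fold_threshold,
    )
    venn = partition_venn(calls)
    write_calls(calls, config.out_dir / "interactor_calls.tsv",
                columns=INTERACTOR_CALL_COLUMNS)
    block = {
        "n_quantified": len(records),
        "background_ml": _model_dict(model_ml),
        "background_hl": _model_dict(model_hl),
        "cutoff_log2_ml": cutoffs.cutoff_log2_ml,
        "cutoff_log2_hl": cutoffs.cutoff_log2_hl,
        "venn": venn.as_dict(),
        "n_interactors": venn.n_total,
    }
    return block, calls


def run_ptm_stage(config: PipelineConfig, modification: str
                  ) -> tuple[dict, list[RegulationCall]]:
    """Quality filtering plus regulation calling for one PTM table."""
    path = config.phospho_sites if modification == MOD_PHOSPHO else config.digly_sites
    stem = "phospho" if modification == MOD_PHOSPHO else "digly"
    sites = read_ptm_sites(path, modification)
    rejections = []
    if modification == MOD_PHOSPHO or config.apply_score_filters_to_digly:
        kept, rejected = filter_confident_sites(sites, config.quality)
        rejections.extend(rejected)
    else:
        kept = list(sites)
    if modification == MOD_DIGLY:
        kept, rejected_cterm = require_internal_digly(kept)
        rejections.extend(rejected_cterm)
    write_rejection_log(rejections, config.out_dir / f"{stem}_rejections.tsv")
    calls = classify_sites(kept, config.regulation, config.transient_drop)
    write_calls(calls, config.out_dir / f"{stem}_calls.tsv",
                columns=REGULATION_CALL_COLUMNS)
    venn_up = venn_counts(
        (c.class_5min == CLASS_UP, c.class_15min == CLASS_UP) for c in calls
    )
    block = {
        "n_input": len(sites),
        "n_confident": len(kept),
        "n_rejected": len(rejections),
        "counts": regulation_counts(calls),
        "venn_up_sites": venn_up.as_dict(),
    }
    if modification == MOD_PHOSPHO:
        block["residue_summary"] = residue_class_summary(calls)
    return block, calls


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage with available inputs and write the summary report.

    Stage outputs (call TSVs, rejection logs, co-regulation node table) are
    written into ``out_dir``; the JSON report is written last as
    ``summary.json`` and also returned.
    """
    config.out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "config": config.echo()}

    interactor_calls: list[InteractorCall] = []
    if config.protein_groups is not None:
        _log(f"interactome stage: {config.protein_groups}")
        block, interactor_calls = run_interactome_stage(config)
        report["interactome"] = block

    phospho_calls: list[RegulationCall] = []
    if config.phospho_sites is not None:
        _log(f"phosphoproteome stage: {config.phospho_sites}")
        block, phospho_calls = run_ptm_stage(config, MOD_PHOSPHO)
        report["phospho"] = block

    digly_calls: list[RegulationCall] = []
    if config.digly_sites is not None:
        _log(f"ubiquitylome stage: {config.digly_sites}")
        block, digly_calls = run_ptm_stage(config, MOD_DIGLY)
        report["digly"] = block

    if phospho_calls or digly_calls:
        _log("integration stage")
        coreg = co_regulated_proteins(phospho_calls, digly_calls,
                                      interactor_calls or None)
        export_edge_list(coreg, config.out_dir / "co_regulation.tsv")
        report["integration"] = {
            "n_proteins_with_up_site": len(coreg),
            "n_co_regulated": sum(r.co_regulated for r in coreg),
            "n_co_regulated_in_signalosome": sum(
                r.co_regulated and r.in_signalosome for r in coreg
            ),
        }

    write_summary(report, config.out_dir / "summary.json")
    _log(f"report written: {config.out_dir / 'summary.json'}")
    return report
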