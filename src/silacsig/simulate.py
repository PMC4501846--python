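"""Synthetic SILAC datasets with known ground truth.

The generator emulates a triple-SILAC stimulation time-course: light =
mock-treated control, medium = 5 min and heavy = 15 min of receptor
stimulation, so every protein (or PTM site) carries an M/L and an H/L
ratio per replicate.  Background entities scatter around a log2 ratio of
zero; true interactors / regulated sites are shifted by configurable log2
effects.  Noise is additive Gaussian on the log2 scale (protein-level
effect plus independent replicate noise); missingness is explicit dropout,
never a zero.

Ground-truth labels are drawn before any noise is added and are returned
alongside the tables, which makes every downstream stage testable without
any external download.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .regulation import (
    DYN_DOWN,
    DYN_EARLY_TRANSIENT,
    DYN_LATE,
    DYN_SUSTAINED,
    DYN_UNREGULATED,
)
from .tables_io import MOD_DIGLY, MOD_PHOSPHO, ProteinGroupRecord, PtmSiteRecord


@dataclass(frozen=True)
class SimulationConfig:
    """Design of a simulated signalosome pull-down experiment.

    Defaults mirror the study conditions: ~3,000 quantified proteins in
    four replicate pull-downs, ~5% genuine interactors, a 2-log2 (4-fold)
    mean enrichment at both time points, and 10% missing ratios.
    """

    n_proteins: int = 3000
    frac_interactors: float = 0.05
    effect_log2_5min: float = 2.0
    effect_log2_15min: float = 2.0
    sigma_background: float = 0.5
    sigma_replicate: float = 0.25
    n_replicates: int = 4
    dropout_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ConfigurationError(f"n_proteins must be >= 1, got {self.n_proteins}")
        if not 0.0 <= self.frac_interactors <= 1.0:
            raise ConfigurationError(
                f"frac_interactors must be in [0, 1], got {self.frac_interactors}"
            )
        if self.sigma_background < 0:
            raise ConfigurationError(
                f"sigma_background must be >= 0, got {self.sigma_background}"
            )
        if self.sigma_replicate < 0:
            raise ConfigurationError(
                f"sigma_replicate must be >= 0, got {self.sigma_replicate}"
            )
        if self.n_replicates < 1:
            raise ConfigurationError(
                f"n_replicates must be >= 1, got {self.n_replicates}"
            )
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ConfigurationError(
                f"dropout_prob must be in [0, 1], got {self.dropout_prob}"
            )


@dataclass(frozen=True)
class ProteinTruth:
    """Ground-truth label of one simulated protein."""

    protein_id: str
    is_interactor: bool


# Up-regulation dynamics classes the PTM generator can draw, with their
# mean log2 effects at (5 min, 15 min).  The early-transient default (4.3,
# 1.0) reproduces a ~19.7-fold spike at 5 min decaying to 2-fold at 15 min,
# the hallmark of rapid transient phosphorylation such as IkB-alpha.
DEFAULT_DYNAMICS_MIX: dict[str, float] = {
    DYN_EARLY_TRANSIENT: 0.35,
    DYN_SUSTAINED: 0.35,
    DYN_LATE: 0.20,
    DYN_DOWN: 0.10,
}

DEFAULT_CLASS_EFFECTS: dict[str, tuple[float, float]] = {
    DYN_EARLY_TRANSIENT: (4.3, 1.0),
    DYN_SUSTAINED: (2.0, 2.0),
    DYN_LATE: (0.0, 2.0),
    DYN_DOWN: (-1.5, -1.5),
}


@dataclass(frozen=True)
class PtmSimulationConfig:
    """Design of a simulated phospho + di-Gly site experiment.

    Defaults follow the study scale: ~10,000 phospho sites (4.1% on Tyr)
    and ~6,000 di-Gly sites, quantified in two replicates.  The background
    log2 SD of 0.4 makes the 2-fold regulation cutoff sit near median +
    2.5 SD of unregulated sites, matching the cutoff calibration the
    regulation thresholds assume.
    """

    n_phospho_sites: int = 10000
    n_digly_sites: int = 6000
    frac_tyr: float = 0.041
    frac_regulated: float = 0.20
    dynamics_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DYNAMICS_MIX)
    )
    class_effects_log2: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_EFFECTS)
    )
    sigma_site: float = 0.3
    sigma_background: float = 0.4
    sigma_replicate: float = 0.25
    n_replicates: int = 2
    dropout_prob: float = 0.1
    frac_cterminal_digly: float = 0.05
    frac_low_localization: float = 0.10
    frac_low_score: float = 0.05
    frac_high_pep: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_tyr", "frac_regulated", "dropout_prob",
                     "frac_cterminal_digly", "frac_low_localization",
                     "frac_low_score", "frac_high_pep"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        for name in ("sigma_site", "sigma_background", "sigma_replicate"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_phospho_sites < 0 or self.n_digly_sites < 0:
            raise ConfigurationError("site counts must be >= 0")
        if self.n_replicates < 1:
            raise ConfigurationError(
                f"n_replicates must be >= 1, got {self.n_replicates}"
            )
        if not self.dynamics_mix:
            raise ConfigurationError("dynamics_mix must not be empty")
        weights = list(self.dynamics_mix.values())
        if any(w < 0 for w in weights) or not math.isclose(sum(weights), 1.0,
                                                           abs_tol=1e-9):
            raise ConfigurationError(
                f"dynamics_mix must be a probability distribution, got "
                f"{self.dynamics_mix}"
            )
        for cls in self.dynamics_mix:
            if cls not in self.class_effects_log2:
                raise ConfigurationError(
                    f"dynamics_mix class {cls!r} has no entry in class_effects_log2"
                )


@dataclass(frozen=True)
class SiteTruth:
    """Ground-truth label of one simulated PTM site."""

    protein_id: str
    position: int
    residue: str
    modification: str
    class_5min: str
    class_15min: str
    dynamics: str
    passes_quality: bool


def _protein_id(index: int) -> str:
    return f"P{index:05d}"


def simulate_interactome(
    config: SimulationConfig,
) -> tuple[list[ProteinGroupRecord], list[ProteinTruth]]:
    """Simulate one replicated pull-down protein table plus ground truth.

    Each observed log2 ratio is the protein-level true effect (0 for
    background binders, the configured channel effect for interactors)
    plus independent per-observation noise: experiment-to-experiment
    background-binding variability Normal(0, sigma_background) and
    technical replicate noise Normal(0, sigma_replicate).  Each (protein,
    replicate, channel) cell drops out independently with
    ``dropout_prob``.  Identical config (including seed) reproduces the
    tables bit-for-bit.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    n_interactors = int(round(config.frac_interactors * n))
    interactor_idx = set(
        rng.choice(n, size=n_interactors, replace=False).tolist()
    ) if n_interactors else set()

    noise_sd = math.hypot(config.sigma_background, config.sigma_replicate)
    effects = {"ML": config.effect_log2_5min, "HL": config.effect_log2_15min}
    records: list[ProteinGroupRecord] = []
    truth: list[ProteinTruth] = []
    for i in range(n):
        pid = _protein_id(i + 1)
        is_interactor = i in interactor_idx
        ratios: dict[str, dict[int, float]] = {"ML": {}, "HL": {}}
        for channel in ("ML", "HL"):
            center = effects[channel] if is_interactor else 0.0
            for rep in range(1, config.n_replicates + 1):
                noise = rng.normal(0.0, noise_sd) if noise_sd else 0.0
                value = 2.0 ** (center + noise)
                if rng.random() < config.dropout_prob:
                    continue
                ratios[channel][rep] = value
        records.append(
            ProteinGroupRecord(
                protein_id=pid,
                gene_name=f"G{i + 1}",
                ratios_ml=ratios["ML"],
                ratios_hl=ratios["HL"],
            )
        )
        truth.append(ProteinTruth(protein_id=pid, is_interactor=is_interactor))
    return records, truth


def simulate_null_dataset(
    config: SimulationConfig,
) -> tuple[list[ProteinGroupRecord], list[ProteinTruth]]:
    """Background-only variant of simulate_interactome (zero true effects)."""
    return simulate_interactome(replace(config, frac_interactors=0.0))


def _truth_class(effect: float) -> str:
    # Thresholds on the noiseless site-level effect: +/-1 log2 = 2-fold.
    if effect >= 1.0:
        return "up"
    if effect <= -1.0:
        return "down"
    return "unchanged"


def _draw_quality(rng: np.random.Generator, config: PtmSimulationConfig
                  ) -> tuple[float, float, float, bool]:
    """Draw (localization_prob, score, pep, passes_score_filters)."""
    low_loc = rng.random() < config.frac_low_localization
    low_score = rng.random() < config.frac_low_score
    high_pep = rng.random() < config.frac_high_pep
    loc = rng.uniform(0.10, 0.7499) if low_loc else rng.uniform(0.75, 1.0)
    score = rng.uniform(5.0, 39.9) if low_score else 40.0 + rng.exponential(60.0)
    pep = rng.uniform(0.0101, 0.2) if high_pep else rng.uniform(1e-6, 0.01)
    return loc, score, pep, not (low_loc or low_score or high_pep)


def _simulate_site_table(
    rng: np.random.Generator,
    config: PtmSimulationConfig,
    modification: str,
    n_sites: int,
    protein_pool: int,
) -> tuple[list[PtmSiteRecord], list[SiteTruth]]:
    classes = sorted(config.dynamics_mix)
    weights = np.array([config.dynamics_mix[c] for c in classes])
    weights = weights / weights.sum()

    records: list[PtmSiteRecord] = []
    truth: list[SiteTruth] = []
    used_keys: set[tuple[str, int]] = set()
    for _ in range(n_sites):
        while True:
            pid = _protein_id(int(rng.integers(1, protein_pool + 1)))
            position = int(rng.integers(1, 1000))
            if (pid, position) not in used_keys:
                used_keys.add((pid, position))
                break
        if modification == MOD_DIGLY:
            residue = "K"
        else:
            # Ser:Thr split of non-Tyr sites fixed at 85:15.
            u = rng.random()
            if u < config.frac_tyr:
                residue = "Y"
            elif u < config.frac_tyr + (1 - config.frac_tyr) * 0.85:
                residue = "S"
            else:
                residue = "T"

        regulated = rng.random() < config.frac_regulated
        if regulated:
            # Persistent site-level effect: class mean plus between-site spread.
            cls = classes[int(rng.choice(len(classes), p=weights))]
            mean5, mean15 = config.class_effects_log2[cls]
            effect5 = mean5 + rng.normal(0.0, config.sigma_site)
            effect15 = mean15 + rng.normal(0.0, config.sigma_site)
            obs_sd = config.sigma_replicate
            dynamics = cls
        else:
            # Unregulated sites scatter around zero per observation.
            effect5 = effect15 = 0.0
            obs_sd = math.hypot(config.sigma_background, config.sigma_replicate)
            dynamics = DYN_UNREGULATED

        loc, score, pep, passes_scores = _draw_quality(rng, config)
        is_cterm = (
            modification == MOD_DIGLY
            and rng.random() < config.frac_cterminal_digly
        )
        passes_quality = passes_scores and not is_cterm

        ratios: dict[str, dict[int, float]] = {"ML": {}, "HL": {}}
        for channel, effect in (("ML", effect5), ("HL", effect15)):
            for rep in range(1, config.n_replicates + 1):
                noise = rng.normal(0.0, obs_sd) if obs_sd else 0.0
                value = 2.0 ** (effect + noise)
                if rng.random() < config.dropout_prob:
                    continue
                ratios[channel][rep] = value

        records.append(
            PtmSiteRecord(
                protein_id=pid,
                residue=residue,
                position=position,
                modification=modification,
                localization_prob=loc,
                score=score,
                pep=pep,
                is_peptide_cterm=is_cterm,
                ratios_ml=ratios["ML"],
                ratios_hl=ratios["HL"],
            )
        )
        truth.append(
            SiteTruth(
                protein_id=pid,
                position=position,
                residue=residue,
                modification=modification,
                class_5min=_truth_class(effect5),
                class_15min=_truth_class(effect15),
                dynamics=dynamics,
                passes_quality=passes_quality,
            )
        )
    return records, truth


def simulate_ptm_sites(
    config: PtmSimulationConfig,
) -> tuple[list[PtmSiteRecord], list[PtmSiteRecord], list[SiteTruth]]:
    """Simulate phospho and di-Gly site tables plus a joint truth table.

    Both tables draw protein identifiers from a shared pool so that
    cross-layer co-regulation is exercised.  Truth regulation classes are
    computed from the noiseless site-level effects (up at >= +1 log2, down
    at <= -1 log2); the truth dynamics label is the drawn class.
    """
    rng = np.random.default_rng(config.seed)
    protein_pool = max(1, (config.n_phospho_sites + config.n_digly_sites) // 4)
    phospho, truth_p = _simulate_site_table(
        rng, config, MOD_PHOSPHO, config.n_phospho_sites, protein_pool
    )
    digly, truth_d = _simulate_site_table(
        rng, config, MOD_DIGLY, config.n_digly_sites, protein_pool
    )
    return phospho, digly, truth_p + truth_d


# ---------------------------------------------------------------------------
# truth / config persistence (TSV with ``truth_`` column prefix)


def write_protein_truth(truth: Sequence[ProteinTruth], path: str | Path) -> None:
    rows = [
        {"Protein.ID": t.protein_id, "truth_is_interactor": str(t.is_interactor)}
        for t in truth
    ]
    pd.DataFrame(rows, columns=["Protein.ID", "truth_is_interactor"]).to_csv(
        path, sep="\t", index=False
    )


def read_protein_truth(path: str | Path) -> list[ProteinTruth]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return [
        ProteinTruth(protein_id=row["Protein.ID"],
                     is_interactor=row["truth_is_interactor"] == "True")
        for _, row in frame.iterrows()
    ]


_SITE_TRUTH_COLUMNS = [
    "Protein.ID", "Position", "Residue", "Modification",
    "truth_class_5min", "truth_class_15min", "truth_dynamics",
    "truth_passes_quality",
]


def write_site_truth(truth: Sequence[SiteTruth], path: str | Path) -> None:
    rows = [
        {
            "Protein.ID": t.protein_id,
            "Position": str(t.position),
            "Residue": t.residue,
            "Modification": t.modification,
            "truth_class_5min": t.class_5min,
            "truth_class_15min": t.class_15min,
            "truth_dynamics": t.dynamics,
            "truth_passes_quality": str(t.passes_quality),
        }
        for t in truth
    ]
    pd.DataFrame(rows, columns=_SITE_TRUTH_COLUMNS).to_csv(path, sep="\t", index=False)


def read_site_truth(path: str | Path) -> list[SiteTruth]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return [
        SiteTruth(
            protein_id=row["Protein.ID"],
            position=int(row["Position"]),
            residue=row["Residue"],
            modification=row["Modification"],
            class_5min=row["truth_class_5min"],
            class_15min=row["truth_class_15min"],
            dynamics=row["truth_dynamics"],
            passes_quality=row["truth_passes_quality"] == "True",
        )
        for _, row in frame.iterrows()
    ]


def config_to_flat_dict(config) -> dict:
    """Flat key-value view of a simulation config (for the config echo)."""
    out = {}
    for key, value in asdict(config).items():
        if isinstance(value, dict):
            for sub, sub_value in value.items():
                out[f"{key}.{sub}"] = list(sub_value) if isinstance(sub_value, tuple) else sub_value
        else:
            out[key] = value
    return out
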