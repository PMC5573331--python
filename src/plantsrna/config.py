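"""Run configuration shared by every pipeline stage.

All tunable constants of the analysis live here so that a single YAML file
documents a run: hairpin-window flank length, the 210-nt/10-phase scan
geometry, the hairpin pairing/energy thresholds, the RPTM abundance floor,
the ±0.5·sd biomass grouping factor, and the mismatch budgets for homolog
and target searches.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Pipeline-wide parameters.

    Attributes
    ----------
    flank_len : int
        Nucleotides of flanking sequence taken on each side of a homolog hit
        when building a candidate precursor window (default 150).
    window_len : int
        Phasing scan window in nt; must equal ``phase_len * n_phases``
        (default 210).
    phase_len : int
        Phase register period in nt (default 21, the DCL4 product length).
    n_phases : int
        Number of phase cycles per window, the ``m`` of the hypergeometric
        window statistic (default 10).
    min_paired : int
        Minimum paired nucleotides within the mature-miRNA region for a
        candidate hairpin (default 18).
    max_energy : float
        Folding free-energy threshold in kcal/mol; candidates must fold
        strictly below it (default -40.0).
    rptm_floor : float
        Minimum group-mean abundance in reads per ten million for a miRNA to
        enter differential testing (default 10).
    group_sd_factor : float
        Half-width of the Medium biomass band in units of the TRM standard
        deviation (default 0.5).
    max_homolog_mm : int
        Mismatch budget for the known-mature homolog search (default 2).
    max_target_mm : int
        Mismatch budget for target-site prediction (default 4; sites must
        have strictly fewer mismatches).
    fdr_alpha : float
        BH-adjusted significance level for differential calls (default 0.05).
    p_max : float
        Window P-value threshold for phased-locus calls (default 1e-3).
    score_min : float
        Phase-score threshold for phased-locus calls (default 5.0).
    min_phased_k : int
        Minimum phased unique sRNAs before the phase score is non-zero
        (default 3).
    seed : int
        Seed feeding every source of randomness.
    """

    flank_len: int = 150
    window_len: int = 210
    phase_len: int = 21
    n_phases: int = 10
    min_paired: int = 18
    max_energy: float = -40.0
    rptm_floor: float = 10.0
    group_sd_factor: float = 0.5
    max_homolog_mm: int = 2
    max_target_mm: int = 4
    fdr_alpha: float = 0.05
    p_max: float = 1e-3
    score_min: float = 5.0
    min_phased_k: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_len != self.phase_len * self.n_phases:
            raise ValueError(
                f"window_len ({self.window_len}) must equal phase_len * n_phases "
                f"({self.phase_len} * {self.n_phases})"
            )
        for name in ("flank_len", "window_len", "phase_len", "n_phases",
                     "min_paired"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("max_homolog_mm", "max_target_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 < self.fdr_alpha < 1.0:
            raise ValueError("fdr_alpha must lie in (0, 1)")
        if self.group_sd_factor < 0:
            raise ValueError("group_sd_factor must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
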