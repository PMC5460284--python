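"""Flat pipeline configuration: one YAML file of key: value pairs.

Every stochastic stage takes its seed from the single master ``seed``
key (required — a config without it is rejected, as are unknown keys).
"""

from __future__ import annotations

from dataclasses import dataclass, fields, asdict

import yaml

from .amtdb import MatchParams
from .errors import ConfigurationError
from .simulate import SimulationConfig


@dataclass
class PipelineConfig:
    # simulation
    n_proteins: int = 200
    peptides_min: int = 5
    peptides_max: int = 10
    n_bio_per_group: int = 3
    n_tech_per_bio: int = 1
    n_scans: int = 1000
    mass_error_ppm_sd: float = 2.0
    net_error_sd: float = 0.005
    log2_intensity_mean: float = 20.0
    log2_intensity_sd: float = 2.0
    intensity_noise_sd: float = 0.25
    detection_rate: float = 0.9
    id_rate: float = 0.6
    low_score_rate: float = 0.1
    shared_peptide_rate: float = 0.05
    de_fraction: float = 0.1
    effect_size: float = 1.0
    n_extra_genes: int = 800
    expr_baseline_log2_mean: float = 8.0
    expr_baseline_log2_sd: float = 2.0
    expr_noise_sd: float = 0.25
    # UMC grouping
    umc_mass_tol_ppm: float = 10.0
    umc_max_scan_gap: int = 5
    # AMT DB build / match
    amt_mass_tol_ppm: float = 10.0
    amt_net_tol: float = 0.02
    amt_score_threshold: float = 3.0
    # missing-cell rescue
    rescue_mass_tol_ppm: float = 10.0
    rescue_tech_net_tol: float = 0.01
    rescue_bio_net_tol: float = 0.02
    # differential expression
    n_permutations: int = 1000
    p_cut: float = 0.05
    deg_fc_percentile: float = 95.0
    depeptide_fc_cut: float = 0.58
    dep_min_unique: int = 2
    # master seed (required; no default on purpose)
    seed: int | None = None

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigurationError("config must set an explicit seed")
        self.simulation().validate()
        self.match_params().validate()
        if self.n_permutations < 1:
            raise ConfigurationError("n_permutations must be >= 1")
        if not 0 < self.p_cut < 1:
            raise ConfigurationError("p_cut must be in (0, 1)")
        if not 0 < self.deg_fc_percentile < 100:
            raise ConfigurationError("deg_fc_percentile must be in (0, 100)")
        if self.depeptide_fc_cut < 0:
            raise ConfigurationError("depeptide_fc_cut must be >= 0")
        if self.dep_min_unique < 1:
            raise ConfigurationError("dep_min_unique must be >= 1")

    def simulation(self) -> SimulationConfig:
        return SimulationConfig(
            n_proteins=self.n_proteins,
            peptides_per_protein=(self.peptides_min, self.peptides_max),
            n_bio_per_group=self.n_bio_per_group,
            n_tech_per_bio=self.n_tech_per_bio,
            n_scans=self.n_scans,
            mass_error_ppm_sd=self.mass_error_ppm_sd,
            net_error_sd=self.net_error_sd,
            log2_intensity_mean=self.log2_intensity_mean,
            log2_intensity_sd=self.log2_intensity_sd,
            intensity_noise_sd=self.intensity_noise_sd,
            detection_rate=self.detection_rate,
            id_rate=self.id_rate,
            low_score_rate=self.low_score_rate,
            shared_peptide_rate=self.shared_peptide_rate,
            de_fraction=self.de_fraction,
            effect_size=self.effect_size,
            n_extra_genes=self.n_extra_genes,
            expr_baseline_log2_mean=self.expr_baseline_log2_mean,
            expr_baseline_log2_sd=self.expr_baseline_log2_sd,
            expr_noise_sd=self.expr_noise_sd,
            seed=self.seed,
        )

    def match_params(self) -> MatchParams:
        return MatchParams(
            mass_tol_ppm=self.amt_mass_tol_ppm,
            net_tol=self.amt_net_tol,
            score_threshold=self.amt_score_threshold,
        )

    @classmethod
    def from_dict(cls, data: dict, overrides: dict | None = None) -> "PipelineConfig":
        data = dict(data or {})
        if overrides:
            data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str, overrides: dict | None = None) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"config {path} must be a mapping of key: value")
        return cls.from_dict(data, overrides)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            for key, value in asdict(self).items():
                fh.write(f"{key}: {value}\n")
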