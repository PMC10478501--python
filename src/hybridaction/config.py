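"""Simulation and pipeline configuration objects.

``SimConfig`` fixes the study conditions the synthetic trio panels emulate:
panel sizes matching a diallel-style crossing scheme of inbred accessions,
the planted fractions of additive and (mostly below-MPV) dominant genes, the
log2-scale dominance shift and noise level, treatment and batch structure,
and an upstream rare-allele model whose burden depresses both expression and
hybrid growth advantage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .containers import ConfigurationError

__all__ = ["SimConfig", "SizeModel"]


@dataclass
class SizeModel:
    """Linear model generating rosette areas (mm^2) from expression.

    area = intercept
         + positive_coef * mean(planted positive-cluster genes)
         - negative_coef * mean(planted negative-cluster genes)
         + hybrid_offset * is_hybrid
         - burden_penalty * mean parental rare-allele burden   (hybrids only)
         + Normal(0, noise_sd)
    BTH-treated samples are then scaled by ``bth_factor``.
    """

    intercept: float = 120.0
    positive_coef: float = 8.0
    negative_coef: float = 8.0
    hybrid_offset: float = 30.0
    burden_penalty: float = 0.15
    noise_sd: float = 10.0
    bth_factor: float = 0.6


@dataclass
class SimConfig:
    """Ground-truth generator parameters (all log2 units unless stated)."""

    n_inbreds: int = 60
    n_trios: int = 40
    n_genes: int = 5000
    frac_additive: float = 0.06
    frac_dominant: float = 0.08
    frac_dominant_below: float = 0.92
    dominance_shift: float = 1.0
    noise_sd: float = 0.3
    treatment_effect_sd: float = 1.0
    frac_bth_responsive: float = 0.15
    n_batches: int = 3
    n_plant_batches: int = 4
    n_replicates: int = 3
    accession_sd: float = 0.5          # between-accession expression SD
    baseline_mean: float = 4.0         # mean log2 TPM of gene baselines
    baseline_sd: float = 1.5
    batch_sd: float = 0.2              # library-batch effect SD
    plant_batch_sd: float = 0.15       # plant (growth) batch effect SD
    burden_rate: float = 1.0           # mean rare upstream SNPs per gene
    burden_effect: float = 0.2         # log2 drop per rare allele carried
    n_common_upstream: int = 3         # common SNPs per upstream window
    n_common_genebody: int = 2
    cluster_genes: int = 40            # genes per planted size-linked cluster
    cluster_factor_sd: float = 0.5     # SD of the shared cluster factor
    allow_parent_reuse: bool = True
    treated: bool = True               # generate a BTH arm at all
    size_model: SizeModel = field(default_factory=SizeModel)
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.size_model, dict):
            self.size_model = SizeModel(**self.size_model)
        self.validate()

    def validate(self) -> None:
        for name in ("frac_additive", "frac_dominant", "frac_dominant_below",
                     "frac_bth_responsive"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.frac_additive + self.frac_dominant > 1.0:
            raise ConfigurationError(
                "frac_additive + frac_dominant must be <= 1")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if self.n_inbreds < 3:
            raise ConfigurationError("n_inbreds must be >= 3")
        if self.n_trios < 2:
            raise ConfigurationError("n_trios must be >= 2")
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.burden_rate < 0:
            raise ConfigurationError("burden_rate must be >= 0")
        if self.n_batches < 1 or self.n_plant_batches < 1:
            raise ConfigurationError("batch counts must be >= 1")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if not isinstance(self.seed, int):
            raise ConfigurationError("seed must be an integer")

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
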