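"""Configuration objects for the simulation and the pipeline.

All randomness in the package flows from one master seed. Each sub-generator
derives an independent stream with :func:`substream`, which spawns a child
``numpy.random.Generator`` from ``SeedSequence(master_seed, spawn_key=key)``.
The stream keys are small integer tuples fixed per stage (see ``STREAMS``),
so any stage can be regenerated in isolation and parallel execution cannot
reorder draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import yaml

#: 1000 Genomes phase-1 style panel: 14 populations and their diploid sample
#: sizes (ASW, LWK, YRI, CHB, CHS, JPT, CLM, MXL, PUR, CEU, FIN, GBR, TSI, IBS).
DEFAULT_POPULATIONS = (
    "ASW", "LWK", "YRI", "CHB", "CHS", "JPT", "CLM",
    "MXL", "PUR", "CEU", "FIN", "GBR", "TSI", "IBS",
)
DEFAULT_SAMPLE_SIZES = (59, 79, 86, 97, 100, 89, 60, 58, 55, 54, 93, 87, 98, 14)

#: Named sub-stream keys for seed derivation (counter scheme).
STREAMS = {
    "frequencies": (1,),
    "genotypes": (2,),
    "genes": (3,),
    "evidence": (4,),
    "drug_map": (5,),
    "labels_adr": (6,),
    "enrichment": (7,),
}


def substream(master_seed: int, name: str, *extra: int) -> np.random.Generator:
    """Derive an independent RNG stream from the master seed.

    ``extra`` integers extend the spawn key, e.g. a (drug, pair) index for
    per-cell reproducibility of the resampling null.
    """
    key = STREAMS[name] + tuple(int(e) for e in extra)
    return np.random.default_rng(np.random.SeedSequence(int(master_seed), spawn_key=key))


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass(frozen=True)
class PlantedDrug:
    """A drug whose pathway is enriched for pf-pdGenes of one target pair."""

    drug_id: str
    pair: str
    enrichment_factor: float

    def __post_init__(self) -> None:
        if self.enrichment_factor < 0:
            raise ConfigError("enrichment_factor must be >= 0")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study panel and knowledge tables.

    Defaults reproduce the study conditions: a 14-population panel with the
    printed sample sizes, moderate drift (F = 0.05 is a typical continental
    human value), and evidence-flag rates giving a few percent of genic SNPs
    functional evidence per category.
    """

    populations: Sequence[str] = DEFAULT_POPULATIONS
    sample_sizes: Sequence[int] = DEFAULT_SAMPLE_SIZES
    n_snps: int = 20_000
    divergence: float = 0.05
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    missing_rate: float = 0.0
    n_genes: int = 300
    chrom_length: int = 30_000_000
    chrom: str = "1"
    gene_length_log_mean: float = 9.8   # exp(9.8) ~ 18 kb, human-like median
    gene_length_log_sd: float = 0.8
    nonsyn_fraction: float = 0.6
    promoter_bp: int = 5_500
    evidence_rates: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_EVIDENCE_RATES))
    n_drugs: int = 200
    pathway_size_range: tuple[int, int] = (5, 60)
    n_sources: int = 4
    source_overlap: float = 0.2
    planted_drugs: Sequence[PlantedDrug] = ()
    label_logistic_intercept: float = -2.0
    label_logistic_slope: float = 1.0
    adr_rate_us: float = 20.0
    adr_rate_sg: float = 5.0
    literature_n_cases: int = 11
    seed: int = 0

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    def validate(self) -> "SimulationConfig":
        if len(self.sample_sizes) != len(self.populations):
            raise ConfigError("sample_sizes length must equal number of populations")
        if any(n <= 0 for n in self.sample_sizes):
            raise ConfigError("all sample sizes must be positive")
        if not (0.0 <= self.divergence < 1.0):
            raise ConfigError("divergence F must lie in [0, 1)")
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigError("ancestral_freq_range must be within (0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must lie in [0, 1)")
        for k, r in self.evidence_rates.items():
            if k not in EVIDENCE_CATEGORIES:
                raise ConfigError(f"unknown evidence category: {k}")
            if not (0.0 <= r <= 1.0):
                raise ConfigError(f"rate for {k} outside [0, 1]")
        if min(self.n_snps, self.n_genes, self.n_drugs) <= 0:
            raise ConfigError("counts must be positive")
        if self.pathway_size_range[0] < 1:
            raise ConfigError("pathway sizes must be >= 1")
        return self

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["populations"] = list(self.populations)
        d["sample_sizes"] = [int(n) for n in self.sample_sizes]
        d["planted_drugs"] = [asdict(p) for p in self.planted_drugs]
        d["evidence_rates"] = dict(self.evidence_rates)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "planted_drugs" in d:
            d["planted_drugs"] = [PlantedDrug(**p) for p in d["planted_drugs"]]
        for key in ("ancestral_freq_range", "pathway_size_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d).validate()


#: Evidence categories consumed by the pfSNP decision table.
EVIDENCE_CATEGORIES = (
    "domain_or_functional_region",
    "modification_site",
    "nmd_or_ese_ess",
    "codon_usage_bias",
    "deleterious",
    "tfbs_altering",
    "utr3_conserved",
    "mirna_binding",
    "splice_site",
    "intronic_splice_regulatory",
    "natural_selection_region",
)

DEFAULT_EVIDENCE_RATES = {c: 0.05 for c in EVIDENCE_CATEGORIES}


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (thresholds and stage toggles)."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    out_dir: str = "results/run"
    top_quantile: float = 0.01
    z_threshold: float = 2.58
    n_iter: int = 10_000
    matching: str = "length_decile"   # or "none"
    m_weighting: str = "weighted"     # or "unweighted"
    mode_decimals: int = 1
    top_k_groups: int = 30
    top_k_adr: int = 20
    stages: Sequence[str] = ("simulate", "fst", "annotate", "enrich", "rank", "report")
    seed: int = 0

    def validate(self) -> "RunConfig":
        self.simulation.validate()
        if not (0.0 < self.top_quantile < 1.0):
            raise ConfigError("top_quantile must lie in (0, 1)")
        if self.n_iter < 1:
            raise ConfigError("n_iter must be positive")
        if self.matching not in ("length_decile", "none"):
            raise ConfigError("matching must be 'length_decile' or 'none'")
        if self.m_weighting not in ("weighted", "unweighted"):
            raise ConfigError("m_weighting must be 'weighted' or 'unweighted'")
        unknown = set(self.stages) - {"simulate", "fst", "annotate", "enrich", "rank", "report"}
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        return self
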