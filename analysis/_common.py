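"""Shared study configuration for the numbered analysis drivers.

A two-continent four-population panel with planted enrichment, small enough
to rerun in seconds but large enough that the truth pf-pdGene background per
pair is ~10% of the gene universe.
"""

from pathlib import Path

from popdiff_pgx.config import PlantedDrug, RunConfig, SimulationConfig

OUT = Path(__file__).resolve().parent.parent / "results" / "analysis"
SEED = 20260919


def study_config(stages) -> RunConfig:
    sim = SimulationConfig(
        populations=("CHB", "CEU", "YRI", "JPT"),
        sample_sizes=(97, 54, 86, 89),
        n_snps=20_000, n_genes=150, chrom_length=6_000_000,
        n_drugs=60, pathway_size_range=(10, 40),
        evidence_rates={c: 0.2 for c in SimulationConfig().evidence_rates},
        planted_drugs=tuple(PlantedDrug(f"planted{k}", "CHB-CEU", 6.0)
                            for k in range(3)),
        divergence=0.1, seed=SEED)
    return RunConfig(simulation=sim, out_dir=str(OUT), n_iter=2_000,
                     stages=stages, seed=SEED)
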