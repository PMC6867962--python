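import numpy as np
import pandas as pd
import pytest

from popdiff_pgx.config import RunConfig, SimulationConfig


@pytest.fixture(scope="session")
def two_pop_config():
    """Small two-population panel used across module tests."""
    return SimulationConfig(
        populations=("A", "B"), sample_sizes=(50, 50), n_snps=2_000,
        n_genes=60, chrom_length=5_000_000, n_drugs=30, seed=11,
    )


@pytest.fixture(scope="session")
def small_run_config(tmp_path_factory, two_pop_config):
    out = tmp_path_factory.mktemp("run")
    return RunConfig(simulation=two_pop_config, out_dir=str(out),
                     n_iter=1_000, seed=11)


@pytest.fixture()
def gene_fixture():
    """One + strand and one - strand gene with full feature structure."""
    genes = pd.DataFrame({
        "gene_id": ["gA", "gB"],
        "chrom": ["1", "1"],
        "strand": ["+", "-"],
        "tss": [10_000, 60_000],
        "start": [10_000, 40_000],
        "end": [20_000, 60_000],
        "length": [10_001, 20_001],
    })
    features = pd.DataFrame(
        [
            ("gA", "utr5", 10_000, 10_499),
            ("gA", "exon", 10_500, 12_999),
            ("gA", "intron", 13_000, 16_999),
            ("gA", "exon", 17_000, 18_999),
            ("gA", "utr3", 19_000, 20_000),
            ("gB", "utr3", 40_000, 41_999),
            ("gB", "exon", 42_000, 44_999),
            ("gB", "intron", 45_000, 54_999),
            ("gB", "exon", 55_000, 58_999),
            ("gB", "utr5", 59_000, 60_000),
        ],
        columns=["gene_id", "feature", "start", "end"],
    )
    return genes, features


def make_snps(rows):
    """rows: (snp_id, pos[, consequence]) on chromosome 1."""
    recs = []
    for row in rows:
        snp_id, pos = row[0], row[1]
        cons = row[2] if len(row) > 2 else ""
        recs.append((snp_id, "1", pos, cons))
    return pd.DataFrame(recs, columns=["snp_id", "chrom", "pos", "consequence"])
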