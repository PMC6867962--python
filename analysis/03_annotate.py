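"""Region classification, pfSNP evidence filtering, pdGene/pf-pdGene sets."""

import pandas as pd
from _common import OUT, study_config

from popdiff_pgx.pipeline import run_pipeline

manifest = run_pipeline(study_config(("simulate", "fst", "annotate")))
gene_sets = pd.read_csv(OUT / "gene_sets.tsv", sep="\t")
per_pair = gene_sets.groupby("pair").agg(pd_genes=("gene_id", "nunique"),
                                         pf_pd=("pf_pd", "sum"))
print("pdGenes / pf-pdGenes per population pair:")
print(per_pair.to_string())
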