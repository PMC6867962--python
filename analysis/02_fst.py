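"""Per-SNP pairwise F_ST from the VCF panel and top-1% pdSNP calls."""

import pandas as pd
from _common import OUT, study_config

from popdiff_pgx.pipeline import run_pipeline

manifest = run_pipeline(study_config(("simulate", "fst")))
c = manifest["counts"]
pdsnps = pd.read_csv(OUT / "pdsnps.tsv", sep="\t")
per_pair = pdsnps.groupby("pair").size()
print(f"{c['n_pairs']} population pairs; >= {c['n_eligible_min']} eligible "
      f"SNPs per pair; pdSNP calls per pair:\n{per_pair.to_string()}")
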