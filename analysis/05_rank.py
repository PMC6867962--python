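"""Rank drug classes and disease groups by mode(Z) x significant pairs."""

import pandas as pd
from _common import OUT, study_config

from popdiff_pgx.pipeline import run_pipeline

run_pipeline(study_config(("simulate", "fst", "annotate", "enrich", "rank")))
ranked = pd.read_csv(OUT / "group_ranking.tsv", sep="\t")
top = ranked[ranked["top"]].groupby("kind").head(5)
print("top groups per kind (score = mean over members of mode(Z) x n sig pairs):")
print(top[["kind", "group_id", "group_score", "n_members", "rank"]]
      .to_string(index=False))
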