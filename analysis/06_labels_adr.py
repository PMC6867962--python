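"""PGx label CDFs and t-tests, literature concordance, ADR profiles."""

import json

import pandas as pd
from _common import OUT, study_config

from popdiff_pgx.pipeline import run_pipeline

manifest = run_pipeline(study_config(
    ("simulate", "fst", "annotate", "enrich", "rank", "report")))
ttests = pd.read_csv(OUT / "label_ttests.tsv", sep="\t")
print("significant-pair counts by PGx label tier (pooled two-sided t-test):")
print(ttests.to_string(index=False))
rate = manifest["counts"].get("literature_detection_rate")
if rate is not None:
    print(f"literature concordance: {100 * rate:.1f}% of reported "
          f"(drug, pair) cases detected at Z > 2.58")
prof = pd.read_csv(OUT / "adr_profiles.tsv", sep="\t")
frac = prof["many_pairs"].mean()
print(f"{prof['many_pairs'].sum()}/{len(prof)} top-ADR drugs significant in "
      f">= 10 pairs ({100 * frac:.0f}%)")
print(json.dumps(manifest["counts"], indent=1))
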