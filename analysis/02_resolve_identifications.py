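"""Merge database-search and de novo identifications onto features.

Applies the study's rules: de novo records kept only with ALC% > 80 and
length >= 3; features with an Ig-related database hit at score >= 30 leave
the de novo pool; per feature the database sequence wins at score >= 30,
otherwise the best de novo sequence, otherwise the sub-30 database sequence
flagged low-confidence. Writes results/resolved_idents.csv.
"""
import dataclasses
import pathlib
import sys

import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from rfpep import germline as gl
from rfpep.pipeline import resolve_stage
from rfpep.tables import read_feature_table, read_ident_table

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = ROOT / "cohort"
    if not (cohort / "features.csv").exists():
        sys.exit("run analysis/01_simulate_cohort.py first")
    features = read_feature_table(cohort / "features.csv")
    idents = read_ident_table(cohort / "idents.csv")
    refs = gl.load_default_references()
    germlines = refs["v_genes"] + refs["j_genes"] + refs["constant_regions"]

    resolved, _ = resolve_stage(idents, [f.feature_id for f in features],
                                germlines)
    df = pd.DataFrame([dataclasses.asdict(r) for r in resolved])
    df.to_csv(ROOT / "resolved_idents.csv", index=False)

    by_prov = df.provenance.value_counts()
    print(f"{len(df)} features resolved:")
    for prov, n in by_prov.items():
        print(f"  {prov}: {n}")
    print(f"  low-confidence (database score < 30, no de novo): "
          f"{df.low_confidence.sum()}")
    print(f"table written to {ROOT / 'resolved_idents.csv'}")


if __name__ == "__main__":
    main()
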