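"""Normalize abundances and test each sequenced peptide for differential
abundance between RF(+)/anti-CCP(+) RA and RF(-) disease controls.

Median-reference normalization with 3-MAD log-ratio filtering, then per
peptide: Kruskal-Wallis across the five groups, Dunn post-hoc z for the
contrast, Holm-Sidak adjustment across peptides, and the fold-change call
(up: adj p < 0.05 and FC > 5; down: adj p < 0.05 and FC < 0.2). Writes
results/differential.csv, volcano.csv, z_scores.csv and
normalization_factors.csv.
"""
import pathlib
import sys

import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from rfpep.stats import (differential_analysis, normalize, volcano_table,
                         z_score)
from rfpep.tables import abundance_matrix, read_feature_table, read_sample_meta

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    if not (ROOT / "resolved_idents.csv").exists():
        sys.exit("run analysis/02_resolve_identifications.py first")
    features = read_feature_table(ROOT / "cohort" / "features.csv")
    samples = read_sample_meta(ROOT / "cohort" / "samples.csv")
    resolved = pd.read_csv(ROOT / "resolved_idents.csv")

    matrix = abundance_matrix(features)
    norm, factors = normalize(matrix)
    factors.rename_axis("sample_id").reset_index().to_csv(
        ROOT / "normalization_factors.csv", index=False)

    sequenced = resolved.feature_id[resolved.sequence.notna()].tolist()
    groups = {s.sample_id: s.group for s in samples}
    diff = differential_analysis(norm.loc[sequenced], groups)
    diff.reset_index().to_csv(ROOT / "differential.csv", index=False)
    volcano_table(diff).reset_index().to_csv(ROOT / "volcano.csv", index=False)
    z_score(norm.loc[sequenced]).reset_index().to_csv(
        ROOT / "z_scores.csv", index=False)

    print(f"normalization factors span "
          f"{factors.min():.2f}-{factors.max():.2f} "
          f"(reference sample factor 1.00)")
    print(f"{len(diff)} sequenced peptides tested "
          f"(RF(+)/CCP(+) RA vs RF(-) control):")
    print(diff.call.value_counts().to_string())
    print(f"tables written to {ROOT}")


if __name__ == "__main__":
    main()
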