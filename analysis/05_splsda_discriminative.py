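"""Sparse PLS-DA of the Ig-related peptides and discriminative-peptide
selection.

Cross-validates the sparse model (3 folds x 50 repeats, maximum-distance
rule), records every peptide's selection occurrence, and flags as
discriminative the variable-region peptides with adjusted p < 0.05, FC > 5,
occurrence > 50% and lowest median Z-score in the disease-control group.
Writes results/splsda_occurrence.csv and discriminative_peptides.csv.
"""
import pathlib
import sys

import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from rfpep.splsda import cross_validate, mean_impute, select_discriminative
from rfpep.stats import normalize, z_score
from rfpep.tables import abundance_matrix, read_feature_table, read_sample_meta

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"
SEED = 0
KEEPX = (20, 20)


def main() -> None:
    for req in ("differential.csv", "annotations.csv"):
        if not (ROOT / req).exists():
            sys.exit(f"missing {req}; run the earlier analysis steps first")
    features = read_feature_table(ROOT / "cohort" / "features.csv")
    samples = read_sample_meta(ROOT / "cohort" / "samples.csv")
    resolved = pd.read_csv(ROOT / "resolved_idents.csv")
    annotations = pd.read_csv(ROOT / "annotations.csv")
    diff = pd.read_csv(ROOT / "differential.csv").set_index("feature_id")

    cat_of_seq = dict(zip(annotations.sequence, annotations.category))
    seq_of = dict(zip(resolved.feature_id, resolved.sequence))
    groups = {s.sample_id: s.group for s in samples}
    norm, _ = normalize(abundance_matrix(features))
    ig = [fid for fid, seq in seq_of.items()
          if isinstance(seq, str)
          and cat_of_seq.get(seq) in ("constant", "variable")]

    X = mean_impute(norm.loc[ig]).T
    y = [groups[s] for s in X.index]
    cv = cross_validate(X.to_numpy(), y, list(KEEPX), folds=3, repeats=50,
                        seed=SEED, feature_names=list(X.columns))
    cv.occurrence.rename_axis("feature_id").reset_index().to_csv(
        ROOT / "splsda_occurrence.csv", index=False)

    cat_of_fid = {fid: cat_of_seq.get(seq_of[fid]) for fid in ig}
    zmat = z_score(norm.loc[ig])
    disc = select_discriminative(cv.occurrence, diff.loc[ig], zmat, groups,
                                 cat_of_fid)
    disc["sequence"] = [seq_of[f] for f in disc.index]
    disc.reset_index().to_csv(ROOT / "discriminative_peptides.csv",
                              index=False)

    print(f"sPLS-DA on {len(ig)} Ig-related peptides, keepX={KEEPX}: "
          f"mean CV BER {cv.mean_ber:.3f}")
    print(f"peptides with occurrence > 50%: {(cv.occurrence > 0.5).sum()}")
    flagged = disc[disc.discriminative]
    print(f"discriminative peptides: {len(flagged)}")
    if len(flagged):
        cols = ["sequence", "occurrence", "adj_p", "fc"]
        print(flagged[cols].to_string())
    print(f"tables written to {ROOT}")


if __name__ == "__main__":
    main()
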