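"""Allocate resolved peptides to Ig constant regions and variable-domain
FR/CDR segments.

Constant-region peptides are exact-substring matches against the packaged
heavy-chain constant references (unique vs shared across isotype groups);
the rest are locally aligned to the germline V/J set and accepted as
variable-region when E <= 1 and Smith-Waterman score > 30, with CDR labels
requiring >= 3 aligned CDR residues. Writes results/annotations.csv.
"""
import pathlib
import sys

import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from rfpep import germline as gl
from rfpep.pipeline import annotate_sequences, annotations_frame

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    path = ROOT / "resolved_idents.csv"
    if not path.exists():
        sys.exit("run analysis/02_resolve_identifications.py first")
    resolved = pd.read_csv(path)
    refs = gl.load_default_references()
    germlines = refs["v_genes"] + refs["j_genes"] + refs["constant_regions"]

    db_seqs = resolved.sequence[(resolved.provenance == "database_search")
                                & resolved.sequence.notna()]
    dn_seqs = resolved.sequence[(resolved.provenance == "de_novo")
                                & resolved.sequence.notna()]
    assigns = annotate_sequences(db_seqs.tolist(), germlines)
    assigns.update(annotate_sequences(
        [s for s in dn_seqs if s not in assigns], germlines,
        il_equivalent=True))
    df = annotations_frame(assigns)
    df.to_csv(ROOT / "annotations.csv", index=False)

    print(f"{len(df)} unique sequences annotated:")
    print(df.category.value_counts().to_string())
    const = df[df.category == "constant"]
    print(f"  constant-region: {const.unique_to_isotype.sum()} unique to one "
          f"isotype, {len(const) - const.unique_to_isotype.sum()} shared")
    var = df[df.category == "variable"]
    print("  variable-region labels:")
    print(var.region_label.value_counts().to_string())
    print(f"table written to {ROOT / 'annotations.csv'}")


if __name__ == "__main__":
    main()
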