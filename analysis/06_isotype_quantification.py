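"""Quantify RF isotypes from unique constant-region peptides and call
positivity against the RF(-) disease-control cut-off.

Per sample and isotype group the abundance is the summed normalized
abundance of the peptides unique to that group; the positivity cut-off per
isotype is the highest abundance in the RF(-)/anti-CCP(-) disease-control
group (strictly exceeded = positive). Writes results/isotype_abundance.csv,
isotype_positivity.csv and isotype_tests.csv.
"""
import pathlib
import sys

import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from rfpep import germline as gl
from rfpep.annotate import match_constant_region
from rfpep.isotypes import (isotype_group_tests, positivity_calls,
                            quantify_isotypes)
from rfpep.stats import normalize
from rfpep.tables import abundance_matrix, read_feature_table, read_sample_meta

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    if not (ROOT / "resolved_idents.csv").exists():
        sys.exit("run analysis/02_resolve_identifications.py first")
    features = read_feature_table(ROOT / "cohort" / "features.csv")
    samples = read_sample_meta(ROOT / "cohort" / "samples.csv")
    resolved = pd.read_csv(ROOT / "resolved_idents.csv")
    constants = gl.load_germline_set("constant_regions")

    norm, _ = normalize(abundance_matrix(features))
    groups = {s.sample_id: s.group for s in samples}
    assigns = {row.feature_id: match_constant_region(row.sequence, constants)
               for row in resolved.itertuples()
               if isinstance(row.sequence, str)}
    table, counts = quantify_isotypes(assigns, norm)
    table.rename_axis("isotype").reset_index().to_csv(
        ROOT / "isotype_abundance.csv", index=False)
    calls = positivity_calls(table, groups)
    calls.to_csv(ROOT / "isotype_positivity.csv", index=False)
    tests = isotype_group_tests(table, groups)
    tests.to_csv(ROOT / "isotype_tests.csv", index=False)

    print("unique peptides per isotype:")
    print(counts.to_string())
    print("\npercent positive per group (cut-off = highest RF(-) control):")
    print(calls.pivot(index="isotype", columns="group",
                      values="pct_positive").round(1).to_string())
    contrast = tests[((tests.group_a == "RFposCCPpos_RA")
                      & (tests.group_b == "RFneg_control"))
                     | ((tests.group_a == "RFneg_control")
                        & (tests.group_b == "RFposCCPpos_RA"))]
    print("\nRF(+)/CCP(+) RA vs RF(-) control Dunn p per isotype:")
    print(contrast.set_index("isotype").p.map("{:.2e}".format).to_string())
    print(f"\ntables written to {ROOT}")


if __name__ == "__main__":
    main()
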