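"""Protein-level RF isotype quantification and positivity calling.

Per sample and isotype group, abundance is the sum of normalized abundances
of the peptides *unique* to that group; peptides matching more than one
isotype group contribute nowhere. Positivity is called against a cut-off
derived from a declared reference group: the cut-off per isotype is the
highest abundance observed in the reference group, and a sample is positive
only when it strictly exceeds that value (so no reference sample is ever
positive against its own group's cut-off). Group comparisons reuse the
peptide-level Kruskal–Wallis/Dunn machinery at the protein level; these
protein-level p-values are reported unadjusted.
"""
from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import RegionAssignment
from .stats import dunn_posthoc, kruskal_wallis

logger = logging.getLogger(__name__)


def quantify_isotypes(assignments: Mapping[str, RegionAssignment],
                      matrix: pd.DataFrame,
                      ) -> tuple[pd.DataFrame, pd.Series]:
    """Sum unique constant-region peptide abundances per sample x isotype.

    ``assignments`` maps feature_id -> annotation; ``matrix`` holds
    normalized abundances (features x samples). Returns the isotype x sample
    abundance table and per-isotype unique-peptide counts.
    """
    unique_peps: dict[str, list[str]] = {}
    for fid, a in assignments.items():
        if a.category == "constant" and a.unique_to_isotype and fid in matrix.index:
            unique_peps.setdefault(a.isotype_group, []).append(fid)
    counts = pd.Series({iso: len(v) for iso, v in unique_peps.items()},
                       name="n_unique_peptides", dtype=int)
    rows = {}
    for iso, fids in sorted(unique_peps.items()):
        sub = matrix.loc[fids]
        sums = sub.sum(axis=0, skipna=True)
        # an isotype with no detected peptide in a sample stays missing
        sums[sub.notna().sum(axis=0) == 0] = np.nan
        rows[iso] = sums
    table = pd.DataFrame(rows).T
    if table.empty:
        logger.warning("no isotype has a unique peptide; empty quantification")
    return table, counts


def positivity_calls(isotype_abundance: pd.DataFrame,
                     sample_groups: Mapping[str, str],
                     reference_group: str = "RFneg_control") -> pd.DataFrame:
    """Per-isotype positivity counts/percentages against the highest
    reference-group abundance (strict >)."""
    ref_samples = [s for s in isotype_abundance.columns
                   if sample_groups[s] == reference_group]
    if not ref_samples:
        raise ValueError(f"reference group {reference_group!r} is empty")
    groups = sorted(set(sample_groups.values()))
    rows = []
    for iso, row in isotype_abundance.iterrows():
        cutoff = row[ref_samples].max(skipna=True)
        for g in groups:
            cols = [s for s in isotype_abundance.columns
                    if sample_groups[s] == g]
            vals = row[cols]
            positive = int((vals > cutoff).sum())  # NaN compares False
            rows.append(dict(isotype=iso, group=g, cutoff=cutoff,
                             n_samples=len(cols), n_positive=positive,
                             pct_positive=100.0 * positive / len(cols)
                             if cols else np.nan))
    return pd.DataFrame(rows)


def isotype_group_tests(isotype_abundance: pd.DataFrame,
                        sample_groups: Mapping[str, str]) -> pd.DataFrame:
    """Kruskal–Wallis + Dunn pairwise matrix per isotype (unadjusted)."""
    groups = sorted(set(sample_groups.values()))
    out = []
    for iso, row in isotype_abundance.iterrows():
        per_group = {}
        for g in groups:
            cols = [s for s in isotype_abundance.columns
                    if sample_groups[s] == g]
            vals = row[cols].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            if len(vals):
                per_group[g] = vals
        if len(per_group) < 2:
            continue
        h, kw_p = kruskal_wallis(list(per_group.values()))
        dunn = dunn_posthoc(per_group)
        dunn.insert(0, "isotype", iso)
        dunn["kw_H"] = h
        dunn["kw_p"] = kw_p
        out.append(dunn)
    if not out:
        return pd.DataFrame(columns=["isotype", "group_a", "group_b", "z", "p",
                                     "kw_H", "kw_p"])
    return pd.concat(out, ignore_index=True)
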