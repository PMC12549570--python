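"""Label-free abundance statistics: normalization, Z-scores, Kruskal–Wallis +
Dunn post-hoc testing, Holm–Šídák adjustment, fold-change calling.

Normalization follows the median-reference / MAD-outlier-filtered log-ratio
approach of label-free LC-MS quantification suites: the reference sample is
the one whose total detected abundance is the median across samples, each
sample's scaling factor is the exponential of the mean log-ratio to the
reference over co-detected features after discarding log-ratios more than
3 MAD from their median, and all abundances are divided by their sample's
factor. Missing abundances stay missing throughout: they are excluded from
rank statistics and group means, never imputed as zero.

A peptide is called *up* when the Holm–Šídák-adjusted contrast p-value is
< 0.05 and the fold change exceeds 5, *down* when adjusted p < 0.05 and the
fold change is below 0.2.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

ADJ_P_MAX = 0.05
FC_UP = 5.0
FC_DOWN = 0.2


@dataclass(frozen=True)
class Thresholds:
    adj_p_max: float = ADJ_P_MAX
    fc_up: float = FC_UP
    fc_down: float = FC_DOWN


def normalize(matrix: pd.DataFrame, mad_window: float = 3.0,
              ) -> tuple[pd.DataFrame, pd.Series]:
    """Median-reference normalization with MAD-filtered log-ratios.

    ``matrix`` is features x samples with NaN for missing. Returns the
    normalized matrix and the per-sample scaling factors.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two samples")
    totals = matrix.sum(axis=0, skipna=True)
    ref = (totals - totals.median()).abs().idxmin()
    factors = {}
    ref_col = matrix[ref]
    for sample in matrix.columns:
        col = matrix[sample]
        shared = col.notna() & ref_col.notna() & (col > 0) & (ref_col > 0)
        if not shared.any():
            logger.warning("sample %s shares no detected features with "
                           "reference %s; factor set to 1", sample, ref)
            factors[sample] = 1.0
            continue
        lr = np.log(col[shared] / ref_col[shared])
        med = lr.median()
        mad = (lr - med).abs().median()
        kept = lr[(lr - med).abs() <= mad_window * mad]
        factors[sample] = float(np.exp(kept.mean()))
    factors = pd.Series(factors, name="factor")
    return matrix.div(factors, axis=1), factors


def z_score(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-feature standardization across samples ((x - mean) / sd, ddof=1).

    Features with fewer than two non-missing values become all-missing;
    constant features become all zeros (with a warning).
    """
    out = pd.DataFrame(np.nan, index=matrix.index, columns=matrix.columns)
    n_constant = 0
    for fid, row in matrix.iterrows():
        vals = row.dropna()
        if len(vals) < 2:
            continue
        sd = vals.std(ddof=1)
        if sd == 0:
            out.loc[fid, vals.index] = 0.0
            n_constant += 1
        else:
            out.loc[fid, vals.index] = (vals - vals.mean()) / sd
    if n_constant:
        logger.warning("%d constant features standardized to all-zero Z-scores",
                       n_constant)
    return out


def kruskal_wallis(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and its chi-squared p-value."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    groups = [g[~np.isnan(g)] for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 groups, each with >= 1 value")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def dunn_posthoc(groups: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-based pairwise z statistics and two-sided normal p-values.

    z_ij = (meanrank_i - meanrank_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j))
    with tie correction T = sum(t^3 - t) / (12 (N - 1)).
    """
    clean = {}
    for label, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        v = v[~np.isnan(v)]
        if len(v) == 0:
            logger.warning("group %s empty; excluded from Dunn test", label)
            continue
        clean[label] = v
    labels = list(clean)
    pooled = np.concatenate([clean[c] for c in labels])
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for label in labels:
        k = len(clean[label])
        mean_ranks[label] = ranks[start:start + k].mean()
        start += k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            se = np.sqrt(var_base * (1 / len(clean[a]) + 1 / len(clean[b])))
            z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
            p = 2 * sps.norm.sf(abs(z))
            rows.append(dict(group_a=a, group_b=b, z=float(z), p=float(p)))
    return pd.DataFrame(rows)


def holm_sidak(p_values: Sequence[float]) -> np.ndarray:
    """Holm–Šídák step-down adjusted p-values (input order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p
    with np.errstate(divide="ignore"):  # p == 1 hits log1p(-1) internally
        return multipletests(p, method="holm-sidak")[1]


def fold_change(group_a: np.ndarray, group_b: np.ndarray,
                epsilon: float) -> tuple[float, bool]:
    """Ratio of group means; a zero denominator is replaced by ``epsilon``
    (flagged). Both means zero -> fc 1, flagged."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    mean_a = np.nanmean(a) if np.any(~np.isnan(a)) else np.nan
    mean_b = np.nanmean(b) if np.any(~np.isnan(b)) else np.nan
    if np.isnan(mean_a) or np.isnan(mean_b):
        return np.nan, True
    if mean_a == 0 and mean_b == 0:
        return 1.0, True
    if mean_b == 0:
        return mean_a / epsilon, True
    return float(mean_a / mean_b), False


def differential_analysis(matrix: pd.DataFrame,
                          sample_groups: Mapping[str, str],
                          contrast: tuple[str, str] = ("RFposCCPpos_RA",
                                                       "RFneg_control"),
                          thresholds: Thresholds = Thresholds(),
                          ) -> pd.DataFrame:
    """Per-peptide group statistics for one contrast.

    ``matrix`` holds *normalized* abundances (features x samples). Per
    feature: Kruskal–Wallis across all groups, Dunn z/p for the contrast
    pair, Holm–Šídák adjustment across features, fold change of the contrast
    means, and the up/down/ns call.
    """
    groups = sorted(set(sample_groups.values()))
    cols_by_group = {g: [s for s in matrix.columns if sample_groups[s] == g]
                     for g in groups}
    for g in contrast:
        if g not in cols_by_group or not cols_by_group[g]:
            raise ValueError(f"contrast group {g!r} has no samples")
    pos = matrix.values[matrix.values > 0]
    epsilon = float(pos.min()) if len(pos) else 1.0

    rows = []
    for fid, row in matrix.iterrows():
        per_group = {g: row[cols_by_group[g]].to_numpy(dtype=float)
                     for g in groups}
        usable = {g: v[~np.isnan(v)] for g, v in per_group.items()}
        testable = (sum(len(v) > 0 for v in usable.values()) >= 2
                    and len(usable[contrast[0]]) > 0
                    and len(usable[contrast[1]]) > 0)
        rec = dict(feature_id=fid)
        for g in groups:
            rec[f"mean_{g}"] = (float(np.mean(usable[g]))
                                if len(usable[g]) else np.nan)
        if testable:
            h, kw_p = kruskal_wallis([v for v in usable.values() if len(v)])
            dunn = dunn_posthoc({g: v for g, v in usable.items() if len(v)})
            pair = dunn[((dunn.group_a == contrast[0]) & (dunn.group_b == contrast[1]))
                        | ((dunn.group_a == contrast[1]) & (dunn.group_b == contrast[0]))]
            if len(pair):
                sign = 1.0 if pair.iloc[0].group_a == contrast[0] else -1.0
                rec["dunn_z"] = sign * float(pair.iloc[0].z)
                rec["dunn_p"] = float(pair.iloc[0].p)
            else:
                rec["dunn_z"] = np.nan
                rec["dunn_p"] = np.nan
            rec["kw_H"], rec["kw_p"] = h, kw_p
        else:
            rec.update(kw_H=np.nan, kw_p=np.nan, dunn_z=np.nan, dunn_p=np.nan)
        fc, flagged = fold_change(per_group[contrast[0]], per_group[contrast[1]],
                                  epsilon)
        rec["fc"] = fc
        rec["fc_flagged"] = flagged
        rows.append(rec)
    out = pd.DataFrame(rows).set_index("feature_id")

    adj = np.full(len(out), np.nan)
    mask = out["dunn_p"].notna().to_numpy()
    if mask.any():
        adj[mask] = holm_sidak(out.loc[mask, "dunn_p"].to_numpy())
    out["adj_p"] = adj

    call = np.where(
        (out["adj_p"] < thresholds.adj_p_max) & (out["fc"] > thresholds.fc_up),
        "up",
        np.where((out["adj_p"] < thresholds.adj_p_max)
                 & (out["fc"] < thresholds.fc_down), "down", "ns"))
    call[out["adj_p"].isna().to_numpy() | out["fc"].isna().to_numpy()] = "ns"
    out["call"] = call
    return out


def volcano_table(diff: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready columns log2(fc) and -log10(adj_p) (p floored at the
    smallest positive float, flagged)."""
    tiny = np.finfo(float).tiny
    capped = diff["adj_p"].clip(lower=tiny)
    return pd.DataFrame({
        "log2_fc": np.log2(diff["fc"]),
        "neg_log10_adj_p": -np.log10(capped),
        "p_capped": diff["adj_p"] <= 0,
        "call": diff["call"],
    }, index=diff.index)
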