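"""End-to-end orchestration: simulate -> normalize -> resolve identifications
-> annotate -> differential stats -> sPLS-DA -> isotypes -> feature matching.

Every stage writes a delimited-text table plus per-stage record counts; a
manifest records the configuration hash and seed so a re-run with the same
seed is byte-reproducible. The stages are plain functions over the library
modules, usable independently of :func:`run`.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import germline as gl
from .annotate import Criteria, RegionAssignment, annotate_sequence
from .idents import (exclude_ig_mascot_from_denovo, filter_de_novo,
                     resolve_conflicts)
from .isotypes import isotype_group_tests, positivity_calls, quantify_isotypes
from .matching import match_features
from .simulate import CohortDesign, SimulatedExperiment, simulate_experiment
from .splsda import (cross_validate, mean_impute, select_discriminative,
                     splsda_fit, splsda_tune)
from .stats import (Thresholds, differential_analysis, normalize, volcano_table,
                    z_score)
from .tables import (FeatureRecord, abundance_matrix, features_to_frame,
                     write_results)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables of the analysis, defaults as used throughout the study."""

    design: CohortDesign = field(default_factory=CohortDesign)
    thresholds: Thresholds = field(default_factory=Thresholds)
    criteria: Criteria = field(default_factory=Criteria)
    contrast: tuple[str, str] = ("RFposCCPpos_RA", "RFneg_control")
    reference_group: str = "RFneg_control"
    alc_min: float = 80.0
    mascot_min: float = 30.0
    il_equivalent_de_novo: bool = True
    splsda_tune_model: bool = False
    splsda_h: int = 2
    splsda_keepx: tuple[int, ...] = (20, 20)
    splsda_h_grid: tuple[int, ...] = (2, 3, 4, 5)
    splsda_keepx_grid: tuple[int, ...] = (1, 2, 3, 5, 10, 20, 50)
    splsda_folds: int = 3
    splsda_repeats: int = 50
    occurrence_min: float = 0.5
    mz_tol: float = 0.01
    rt_tol: float = 1.0
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["design"]["group_sizes"] = dict(d["design"]["group_sizes"])
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        design = CohortDesign(**raw.pop("design", {}))
        thresholds = Thresholds(**raw.pop("thresholds", {}))
        criteria = Criteria(**raw.pop("criteria", {}))
        for key in ("contrast", "splsda_keepx", "splsda_h_grid",
                    "splsda_keepx_grid"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(design=design, thresholds=thresholds, criteria=criteria,
                   **raw)


def annotate_sequences(sequences: Sequence[str],
                       germlines: Sequence[gl.GermlineGene],
                       criteria: Criteria = Criteria(),
                       il_equivalent: bool = False,
                       ) -> dict[str, RegionAssignment]:
    """Annotate each unique sequence once (constant precedence inside)."""
    out: dict[str, RegionAssignment] = {}
    for seq in sequences:
        if seq and seq not in out:
            out[seq] = annotate_sequence(seq, germlines, criteria=criteria,
                                         il_equivalent=il_equivalent)
    return out


def annotations_frame(assigns: Mapping[str, RegionAssignment]) -> pd.DataFrame:
    rows = []
    for seq, a in assigns.items():
        rows.append(dict(sequence=seq, category=a.category,
                         isotype_group=a.isotype_group,
                         unique_to_isotype=a.unique_to_isotype,
                         matched_isotypes=";".join(a.matched_isotypes),
                         matched_accessions=";".join(a.matched_accessions),
                         germline_gene=a.germline_gene, sw_score=a.sw_score,
                         e_value=a.e_value, region_label=a.region_label,
                         segments="+".join(a.segments),
                         n_cdr_residues=a.n_cdr_residues))
    return pd.DataFrame(rows)


def resolve_stage(sim_idents, feature_ids, germlines, alc_min: float = 80.0,
                  mascot_min: float = 30.0, il_equivalent: bool = True):
    """Filter, de-duplicate and merge the two identification streams."""
    db = [r for r in sim_idents if r.engine == "database_search"]
    dn = [r for r in sim_idents if r.engine == "de_novo"]
    db_assigns = annotate_sequences([r.sequence for r in db], germlines)
    ig_flags = {s: a.ig_related for s, a in db_assigns.items()}
    dn = filter_de_novo(dn, alc_min=alc_min)
    dn = exclude_ig_mascot_from_denovo(dn, db, ig_flags, score_min=mascot_min)
    resolved = resolve_conflicts(db, dn, feature_ids, ig_flags=ig_flags,
                                 score_min=mascot_min)
    return resolved, db_assigns


def run(config: PipelineConfig, out_dir: str | Path,
        experiment: SimulatedExperiment | None = None) -> dict:
    """Execute every stage in dependency order; returns the result summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    tables: dict[str, pd.DataFrame] = {}

    refs = gl.load_default_references()
    germlines = refs["v_genes"] + refs["j_genes"] + refs["constant_regions"]

    # -- stage 1: cohort ----------------------------------------------------
    sim = experiment or simulate_experiment(config.design)
    sample_groups = {s.sample_id: s.group for s in sim.samples}
    counts["features"] = len(sim.features)
    counts["samples"] = len(sim.samples)
    tables["features"] = features_to_frame(sim.features)
    tables["samples"] = pd.DataFrame(
        [dataclasses.asdict(s) for s in sim.samples])
    tables["ground_truth"] = sim.truth

    # -- stage 2: normalization ---------------------------------------------
    matrix = abundance_matrix(sim.features)
    norm, factors = normalize(matrix)
    tables["normalization_factors"] = factors.rename_axis("sample_id").reset_index()

    # -- stage 3: identification merging ------------------------------------
    feature_ids = [f.feature_id for f in sim.features]
    resolved, db_assigns = resolve_stage(
        sim.idents, feature_ids, germlines, alc_min=config.alc_min,
        mascot_min=config.mascot_min,
        il_equivalent=config.il_equivalent_de_novo)
    tables["resolved_idents"] = pd.DataFrame(
        [dataclasses.asdict(r) for r in resolved])
    counts["identified_features"] = sum(r.sequence is not None for r in resolved)
    counts["de_novo_features"] = sum(r.provenance == "de_novo" for r in resolved)

    # -- stage 4: region annotation ------------------------------------------
    seq_of = {r.feature_id: r.sequence for r in resolved if r.sequence}
    prov_of = {r.feature_id: r.provenance for r in resolved}
    assigns: dict[str, RegionAssignment] = dict(db_assigns)
    dn_seqs = [r.sequence for r in resolved
               if r.provenance == "de_novo" and r.sequence]
    assigns.update(annotate_sequences(
        [s for s in dn_seqs if s not in assigns], germlines,
        criteria=config.criteria,
        il_equivalent=config.il_equivalent_de_novo))
    tables["annotations"] = annotations_frame(assigns)
    cat_of = {fid: assigns[seq].category for fid, seq in seq_of.items()}
    counts["constant_peptides"] = sum(c == "constant" for c in cat_of.values())
    counts["variable_peptides"] = sum(c == "variable" for c in cat_of.values())

    # -- stage 5: differential statistics (sequenced features) ---------------
    sequenced = [fid for fid in feature_ids if fid in seq_of]
    diff = differential_analysis(norm.loc[sequenced], sample_groups,
                                 contrast=config.contrast,
                                 thresholds=config.thresholds)
    zmat = z_score(norm.loc[sequenced])
    tables["differential"] = diff.reset_index()
    tables["volcano"] = volcano_table(diff).reset_index()
    tables["z_scores"] = zmat.reset_index()
    counts["upregulated"] = int((diff["call"] == "up").sum())
    counts["downregulated"] = int((diff["call"] == "down").sum())

    # -- stage 6: sPLS-DA on Ig-related peptides ------------------------------
    ig_fids = [fid for fid in sequenced
               if cat_of.get(fid) in ("constant", "variable")]
    summary: dict = {}
    if len(ig_fids) >= 3:
        X = mean_impute(norm.loc[ig_fids]).T  # samples x peptides
        y = [sample_groups[s] for s in X.index]
        if config.splsda_tune_model:
            tuned = splsda_tune(X.to_numpy(), y, h_grid=config.splsda_h_grid,
                                keepx_grid=config.splsda_keepx_grid,
                                folds=config.splsda_folds,
                                repeats=config.splsda_repeats,
                                seed=config.seed)
            h, keepx = tuned.n_components, tuned.keepx
            tables["splsda_tuning"] = tuned.keepx_table
        else:
            h = config.splsda_h
            keepx = tuple(min(k, len(ig_fids)) for k in config.splsda_keepx[:h])
            while len(keepx) < h:
                keepx = keepx + (keepx[-1],)
        cv = cross_validate(X.to_numpy(), y, keepx, folds=config.splsda_folds,
                            repeats=config.splsda_repeats, seed=config.seed,
                            feature_names=list(X.columns))
        model = splsda_fit(X.to_numpy(), y, keepx,
                           feature_names=list(X.columns))
        tables["splsda_scores"] = pd.DataFrame(
            model.scores, index=X.index,
            columns=[f"comp{i + 1}" for i in range(model.n_components)]
        ).rename_axis("sample_id").reset_index()
        tables["splsda_occurrence"] = (cv.occurrence
                                       .rename_axis("feature_id").reset_index())
        summary["splsda_mean_ber"] = cv.mean_ber
        summary["splsda_keepx"] = list(keepx)

        # -- stage 7: discriminative peptides --------------------------------
        disc = select_discriminative(
            cv.occurrence, diff.loc[ig_fids], zmat.loc[ig_fids],
            sample_groups, cat_of, control_group=config.reference_group,
            adj_p_max=config.thresholds.adj_p_max,
            fc_min=config.thresholds.fc_up,
            occurrence_min=config.occurrence_min)
        disc["sequence"] = [seq_of[f] for f in disc.index]
        tables["discriminative_peptides"] = disc.reset_index()
        counts["discriminative"] = int(disc["discriminative"].sum())

    # -- stage 8: isotype quantification -------------------------------------
    fid_assigns = {fid: assigns[seq] for fid, seq in seq_of.items()}
    iso_table, iso_counts = quantify_isotypes(fid_assigns, norm)
    if not iso_table.empty:
        tables["isotype_abundance"] = iso_table.rename_axis("isotype").reset_index()
        tables["isotype_unique_peptides"] = (iso_counts.rename_axis("isotype")
                                             .reset_index())
        tables["isotype_positivity"] = positivity_calls(
            iso_table, sample_groups, reference_group=config.reference_group)
        tables["isotype_tests"] = isotype_group_tests(iso_table, sample_groups)

    # -- stage 9: cross-experiment feature matching ---------------------------
    rng = np.random.default_rng(config.seed + 1)
    replica = replicate_features(sim.features, rng,
                                 mz_tol=config.mz_tol, rt_tol=config.rt_tol)
    unidentified = [f for f in sim.features
                    if seq_of.get(f.feature_id) is None and f.has_msms]
    matches = match_features(unidentified, replica, mz_tol=config.mz_tol,
                             rt_tol=config.rt_tol)
    tables["feature_matches"] = pd.DataFrame(
        [dataclasses.asdict(m) for m in matches])
    counts["matched_features"] = len(matches)

    written = write_results(out_dir, tables)
    manifest = dict(config_hash=config.config_hash(), seed=config.design.seed,
                    counts=counts, summary=summary,
                    tables=sorted(str(p.name) for p in written.values()))
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True))
    logger.info("pipeline finished: %s", json.dumps(counts, sort_keys=True))
    return manifest


def replicate_features(features: Sequence[FeatureRecord],
                       rng: np.random.Generator, keep_fraction: float = 0.7,
                       mz_tol: float = 0.01, rt_tol: float = 1.0,
                       ) -> list[FeatureRecord]:
    """Emulate the same peptides re-measured in a second experiment: keep a
    fraction of features and jitter m/z and RT within half the matching
    windows."""
    out = []
    for f in features:
        if rng.random() > keep_fraction:
            continue
        out.append(FeatureRecord(
            feature_id=f"B_{f.feature_id}",
            mz=f.mz + float(rng.uniform(-0.5, 0.5)) * mz_tol,
            rt=max(0.0, f.rt + float(rng.uniform(-0.5, 0.5)) * rt_tol),
            charge=f.charge, abundances=dict(f.abundances),
            sequence=f.sequence, has_msms=f.has_msms))
    return out
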