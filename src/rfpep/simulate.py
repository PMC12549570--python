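"""Synthetic RF-enrichment cohort generator.

Emulates the structure of an affinity-enriched RF LC-MS/MS experiment: five
serology-defined groups (27/5/22/28/4 samples), a feature table mixing
background peptides with Ig-derived peptides obtained by in-silico Lys-C +
chymotrypsin digestion of the germline references, multiplicative
group-specific fold-change effects, log-normal within-group noise,
per-sample global scale factors (so normalization is exercised),
abundance-dependent left-censoring to missing, and partial identification
coverage split between database-search (Mascot-like scores) and de novo
(ALC%) records. CDR-variant peptides are produced by point-substituting
residues inside CDR spans of digested V-gene peptides, so they genuinely
fall outside the database and can only be sequenced de novo; de novo
sequences report I as L (isobaric residues).

Effect layout mirrors the study: designated variable-region peptides carry
the fold change in the RF(+) groups, a subset also in RF(−)/CCP(−) RA, and a
"discriminative" subset in every group except the RF(−) disease-control
reference; constant-region peptides are elevated per-isotype in the RF(+)
groups. Everything is driven by one seeded generator: the same seed gives
byte-identical tables.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as pyt_mass

from . import germline as gl
from .annotate import match_constant_region
from .digest import digest
from .tables import GROUP_SIZES, GROUPS, FeatureRecord, IdentRecord, SampleMeta

RF_POS_GROUPS = ("RFposCCPpos_RA", "RFpos_control")
REFERENCE_GROUP = "RFneg_control"


class SimulationConfigError(ValueError):
    pass


@dataclass(frozen=True)
class CohortDesign:
    """Generator parameters; the defaults are the study conditions."""

    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(GROUP_SIZES))
    n_background_peptides: int = 120
    n_ig_peptides: int = 80
    n_upregulated: int = 20
    n_also_rfneg: int = 6
    n_discriminative: int = 8
    n_cdr_variants: int = 10
    fold_change: float = 8.0
    noise_cv: float = 0.3
    missing_rate_low_abundance: float = 0.25
    censor_quantile: float = 0.2
    unidentified_fraction: float = 0.3
    scale_factor_range: tuple[float, float] = (0.5, 2.0)
    isotype_effect_groups: tuple[str, ...] = RF_POS_GROUPS
    effect_groups: tuple[str, ...] = RF_POS_GROUPS
    max_missed_cleavages: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.group_sizes.values()):
            raise SimulationConfigError("group sizes must be >= 0")
        if self.fold_change <= 0:
            raise SimulationConfigError("fold_change must be > 0")
        for p in (self.missing_rate_low_abundance, self.censor_quantile,
                  self.unidentified_fraction):
            if not 0 <= p <= 1:
                raise SimulationConfigError("probabilities must lie in [0, 1]")
        if self.n_upregulated > self.n_ig_peptides:
            raise SimulationConfigError(
                "cannot designate more upregulated peptides than Ig peptides")


@dataclass
class SimulatedExperiment:
    features: list[FeatureRecord]
    idents: list[IdentRecord]
    samples: list[SampleMeta]
    truth: pd.DataFrame
    design: CohortDesign
    scale_factors: pd.Series | None = None


def _digest_pool(genes: Sequence[gl.GermlineGene], design: CohortDesign,
                 min_length: int = 5, max_length: int = 30) -> dict[str, gl.GermlineGene]:
    pool: dict[str, gl.GermlineGene] = {}
    for g in genes:
        for pep in sorted(digest(g.sequence, design.max_missed_cleavages,
                                 min_length=min_length)):
            if len(pep) <= max_length and pep not in pool:
                pool[pep] = g
    return pool


def _variable_region_truth(pep: str, gene: gl.GermlineGene,
                           region_map: gl.RegionMap) -> tuple[str, tuple[int, ...]]:
    start = gene.sequence.find(pep)
    positions = gene.imgt_positions[start:start + len(pep)]
    labels = tuple(dict.fromkeys(region_map.region_of(p) for p in positions))
    return "+".join(labels), positions


def _mutate_cdr(pep: str, positions: Sequence[int], cdr_pos: set[int],
                rng: np.random.Generator) -> str:
    aas = list("ACDEFGHIKMNQRSTV")  # avoid creating/removing cleavage sites is
    # not required; substitutions stay inside the CDR span
    idx = [i for i, p in enumerate(positions) if p in cdr_pos]
    n_mut = int(rng.integers(1, min(3, len(idx)) + 1))
    chosen = rng.choice(idx, size=n_mut, replace=False)
    s = list(pep)
    for i in chosen:
        cur = s[i]
        s[i] = str(rng.choice([a for a in aas if a != cur]))
    return "".join(s)


def _random_peptide(rng: np.random.Generator, constants: Sequence[gl.GermlineGene],
                    length_range: tuple[int, int] = (7, 16)) -> str:
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    while True:
        n = int(rng.integers(*length_range))
        pep = "".join(rng.choice(aas, size=n))
        if all(pep not in c.sequence for c in constants):
            return pep


def simulate_experiment(design: CohortDesign,
                        germlines: Sequence[gl.GermlineGene] | None = None,
                        experiment_id: str = "main") -> SimulatedExperiment:
    """Generate a complete synthetic experiment with ground truth."""
    rng = np.random.default_rng(design.seed)
    if germlines is None:
        refs = gl.load_default_references()
        germlines = refs["v_genes"] + refs["j_genes"] + refs["constant_regions"]
    constants = [g for g in germlines if g.segment == "constant"]
    v_genes = [g for g in germlines if g.segment == "V"]
    if design.n_ig_peptides > 0 and not (constants or v_genes):
        raise SimulationConfigError("empty germline set with n_ig_peptides > 0")
    region_map = gl.default_region_map()
    cdr_pos = region_map.cdr_positions()

    # ---- peptide universe -------------------------------------------------
    const_pool = _digest_pool(constants, design)
    var_pool = _digest_pool(v_genes, design)
    var_pool = {p: g for p, g in var_pool.items() if p not in const_pool}

    n_const = min(design.n_ig_peptides // 2, len(const_pool))
    n_var = min(design.n_ig_peptides - n_const, len(var_pool))
    const_peps = [str(p) for p in rng.choice(sorted(const_pool), size=n_const,
                                             replace=False)]
    var_peps = [str(p) for p in rng.choice(sorted(var_pool), size=n_var,
                                           replace=False)]

    records: list[dict] = []
    for pep in const_peps:
        hit = match_constant_region(pep, constants)
        records.append(dict(sequence=pep, origin="constant",
                            germline=hit.matched_accessions[0],
                            isotype=hit.isotype_group,
                            matched_isotypes=";".join(hit.matched_isotypes),
                            region=None, cdr_mutated=False))
    for pep in var_peps:
        gene = var_pool[pep]
        region, _ = _variable_region_truth(pep, gene, region_map)
        records.append(dict(sequence=pep, origin="variable", germline=gene.name,
                            isotype=None, matched_isotypes="", region=region,
                            cdr_mutated=False))

    # CDR variants: substitute inside CDR spans of CDR-overlapping V peptides
    cdr_candidates = []
    for pep, gene in sorted(var_pool.items()):
        start = gene.sequence.find(pep)
        positions = gene.imgt_positions[start:start + len(pep)]
        if sum(1 for p in positions if p in cdr_pos) >= 3:
            cdr_candidates.append((pep, gene, positions))
    n_cdr = min(design.n_cdr_variants, len(cdr_candidates))
    if n_cdr:
        picked = rng.choice(len(cdr_candidates), size=n_cdr, replace=False)
        for k in picked:
            pep, gene, positions = cdr_candidates[int(k)]
            mutant = _mutate_cdr(pep, positions, cdr_pos, rng)
            region, _ = _variable_region_truth(pep, gene, region_map)
            records.append(dict(sequence=mutant, origin="variable",
                                germline=gene.name, isotype=None,
                                matched_isotypes="", region=region,
                                cdr_mutated=True))

    for _ in range(design.n_background_peptides):
        records.append(dict(sequence=_random_peptide(rng, constants),
                            origin="background", germline=None, isotype=None,
                            matched_isotypes="", region=None, cdr_mutated=False))

    truth = pd.DataFrame(records)
    truth.insert(0, "feature_id",
                 [f"F{i + 1:04d}" for i in range(len(truth))])

    # ---- designated effects ----------------------------------------------
    n_feat = len(truth)
    # designate effects on V-derived peptides long enough to carry variable-
    # region alignment evidence (>= 8 residues)
    var_idx = truth.index[(truth.origin == "variable")
                          & (truth.sequence.str.len() >= 8)].to_numpy()
    # discriminative truth comes from unmutated (database-identifiable) V
    # peptides; CDR variants depend on the stochastic de novo ALC filter
    unmut_idx = truth.index[(truth.origin == "variable") & ~truth.cdr_mutated
                            & (truth.sequence.str.len() >= 8)].to_numpy()
    n_up = min(design.n_upregulated, len(var_idx))
    n_disc = min(design.n_discriminative, n_up, len(unmut_idx))
    disc_idx = rng.choice(unmut_idx, size=n_disc, replace=False)
    rest_pool = np.setdiff1d(var_idx, disc_idx)
    extra = rng.choice(rest_pool, size=min(n_up - n_disc, len(rest_pool)),
                       replace=False)
    up_idx = np.concatenate([disc_idx, extra])
    remaining = extra
    n_also = min(design.n_also_rfneg, len(remaining))
    also_idx = rng.choice(remaining, size=n_also, replace=False) if n_also else []

    effects = pd.DataFrame(1.0, index=truth.index, columns=list(GROUPS))
    fc = design.fold_change
    for i in up_idx:
        effects.loc[i, list(design.effect_groups)] = fc
    for i in also_idx:
        effects.loc[i, "RFnegCCPneg_RA"] = fc
    for i in disc_idx:
        for g in GROUPS:
            if g != REFERENCE_GROUP:
                effects.loc[i, g] = fc
    iso_mask = truth.origin == "constant"
    for i in truth.index[iso_mask]:
        effects.loc[i, list(design.isotype_effect_groups)] = fc

    truth["upregulated"] = truth.index.isin(up_idx)
    truth["also_rfneg"] = truth.index.isin(also_idx)
    truth["discriminative"] = truth.index.isin(disc_idx)
    for g in GROUPS:
        truth[f"effect_{g}"] = effects[g].to_numpy()

    # ---- samples and abundance matrix -------------------------------------
    samples: list[SampleMeta] = []
    counter = 1
    for g in GROUPS:
        for _ in range(int(design.group_sizes.get(g, 0))):
            samples.append(SampleMeta(f"S{counter:03d}", g, experiment_id))
            counter += 1
    sample_ids = [s.sample_id for s in samples]
    group_of = {s.sample_id: s.group for s in samples}

    designated = truth.upregulated | truth.discriminative | iso_mask
    log10_base = np.where(designated,
                          rng.uniform(6.5, 8.0, size=n_feat),
                          rng.uniform(5.0, 8.0, size=n_feat))
    base = 10.0 ** log10_base
    scale = rng.uniform(*design.scale_factor_range, size=len(samples))
    sigma = np.sqrt(np.log1p(design.noise_cv ** 2))
    noise = rng.lognormal(mean=0.0, sigma=sigma, size=(n_feat, len(samples)))
    eff = np.column_stack([effects[group_of[s]].to_numpy() for s in sample_ids])
    abundance = base[:, None] * eff * noise * scale[None, :]

    # abundance-dependent left-censoring
    threshold = np.quantile(abundance, design.censor_quantile)
    censor = ((abundance < threshold)
              & (rng.random(abundance.shape) < design.missing_rate_low_abundance))
    abundance = abundance.astype(object)
    abundance[censor] = None

    # ---- identification coverage ------------------------------------------
    protected = truth.upregulated | truth.discriminative
    unidentified = (rng.random(n_feat) < design.unidentified_fraction) & ~protected
    truth["identified"] = ~unidentified

    idents: list[IdentRecord] = []
    for i, row in truth.iterrows():
        if unidentified[i]:
            continue
        fid = row.feature_id
        if row.cdr_mutated:
            alc = float(rng.uniform(75.0, 99.0))
            idents.append(IdentRecord(fid, row.sequence.replace("I", "L"),
                                      "de_novo", alc=alc))
        else:
            score = float(np.clip(rng.normal(55.0, 18.0), 5.0, 150.0))
            accs = (row.germline,) if row.germline else (f"BG{i:04d}",)
            if row.origin == "constant":
                accs = tuple(match_constant_region(
                    row.sequence, constants).matched_accessions)
            idents.append(IdentRecord(fid, row.sequence, "database_search",
                                      score=score, protein_accessions=accs))
            # parallel de novo read of the same peptide for a fraction
            if rng.random() < 0.3:
                idents.append(IdentRecord(
                    fid, row.sequence.replace("I", "L"), "de_novo",
                    alc=float(rng.uniform(60.0, 99.0))))

    # ---- feature records ---------------------------------------------------
    features: list[FeatureRecord] = []
    for i, row in truth.iterrows():
        charge = int(rng.choice([2, 3, 4]))
        if row.identified or row.origin != "background":
            mz = float(pyt_mass.calculate_mass(sequence=row.sequence,
                                               charge=charge))
        else:
            mz = float(rng.uniform(300.0, 1200.0))
        features.append(FeatureRecord(
            feature_id=row.feature_id, mz=mz, charge=charge,
            rt=float(rng.uniform(5.0, 60.0)),
            abundances={s: abundance[i, j] for j, s in enumerate(sample_ids)},
            sequence=None,
            has_msms=bool(protected[i] or rng.random() < 0.9),
        ))

    scale_factors = pd.Series(scale, index=sample_ids, name="scale")
    return SimulatedExperiment(features, idents, samples, truth, design,
                               scale_factors)
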