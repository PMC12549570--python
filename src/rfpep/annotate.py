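"""Allocation of peptides to Ig constant regions and variable-domain FR/CDR
segments.

Constant-region matching is exact substring search against the heavy-chain
constant reference (optionally with I/L collapsed, since isobaric leucine and
isoleucine cannot be separated by de novo sequencing); a peptide is *unique*
to an isotype when it occurs in exactly one isotype group (duplicate
accessions inside a group count once) and only unique peptides enter
protein-level quantification.

Variable-region assignment aligns the peptide locally (Smith–Waterman,
BLOSUM62, affine gap cost 11 + g) against every germline V/J gene, converts
the aligned germline residues to IMGT unique-numbering positions, and accepts
the best gene when the Karlin–Altschul expectation is <= 1 and the alignment
score is > 30. The assignment is CDR-labelled only when at least three
aligned residues fall inside a CDR span. Constant-region matches take
precedence: a constant-region peptide is never scored against V genes.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .germline import AMINO_ACIDS, GermlineGene, RegionMap, default_region_map

# gapped Karlin-Altschul parameters for BLOSUM62 with gap cost 11 + g
LAMBDA_GAPPED = 0.267
K_GAPPED = 0.041

#: cap on the number of co-optimal tracebacks inspected for tie-breaking
_MAX_TRACEBACKS = 64


@dataclass(frozen=True)
class AlignmentResult:
    score: float
    peptide_span: tuple[int, int] | None   # [start, end) in the peptide
    germline_span: tuple[int, int] | None  # [start, end) in the germline
    n_gaps: int
    aligned_pairs: tuple[tuple[int, int], ...]  # (peptide_idx, germline_idx)


@dataclass(frozen=True)
class Criteria:
    """Acceptance thresholds for variable-region assignment."""

    e_value_max: float = 1.0
    sw_min: float = 30.0
    min_cdr_residues: int = 3


@dataclass(frozen=True)
class RegionAssignment:
    sequence: str
    category: str                      # constant | variable | non_ig
    isotype_group: str | None = None
    unique_to_isotype: bool | None = None
    matched_isotypes: tuple[str, ...] = ()
    matched_accessions: tuple[str, ...] = ()
    germline_gene: str | None = None
    sw_score: float | None = None
    e_value: float | None = None
    aligned_imgt_positions: tuple[int, ...] = ()
    region_label: str | None = None    # FR | CDR | FR+CDR
    segments: tuple[str, ...] = ()
    n_cdr_residues: int = 0
    igblast_ok: bool | None = None
    imgt_ok: bool | None = None

    @property
    def ig_related(self) -> bool:
        return self.category != "non_ig"


@lru_cache(maxsize=8)
def _aligner(gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # affine cost 11 + g: first gapped position -12, each further -1
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def smith_waterman(peptide: str, germline: str, gap_open: int = 11,
                   gap_extend: int = 1) -> AlignmentResult:
    """Optimal local alignment with deterministic tie-breaking.

    Among co-optimal tracebacks, prefers fewer gaps, then the earliest
    germline start, then the earliest peptide start. A non-positive optimal
    score yields the empty alignment with score 0.
    """
    if not peptide or not germline:
        raise ValueError("empty sequence")
    bad = (set(peptide) | set(germline)) - AMINO_ACIDS
    if bad:
        raise ValueError(f"non-amino-acid characters {sorted(bad)!r}")
    aligner = _aligner(gap_open, gap_extend)
    score = float(aligner.score(peptide, germline))
    if score <= 0:
        return AlignmentResult(0.0, None, None, 0, ())
    best = None
    best_key = None
    for i, aln in enumerate(aligner.align(peptide, germline)):
        pairs: list[tuple[int, int]] = []
        n_gaps = 0
        for (p0, p1), (g0, g1) in zip(*aln.aligned):
            pairs.extend(zip(range(p0, p1), range(g0, g1)))
        # gapped columns = span length minus matched columns, on both sequences
        pep_span = (aln.aligned[0][0][0], aln.aligned[0][-1][1])
        germ_span = (aln.aligned[1][0][0], aln.aligned[1][-1][1])
        n_gaps = ((pep_span[1] - pep_span[0] - len(pairs))
                  + (germ_span[1] - germ_span[0] - len(pairs)))
        key = (n_gaps, germ_span[0], pep_span[0])
        if best_key is None or key < best_key:
            best_key = key
            best = AlignmentResult(score, pep_span, germ_span, n_gaps,
                                   tuple(pairs))
        if i + 1 >= _MAX_TRACEBACKS:
            break
    return best


def e_value(score: float, peptide_length: int, database_residue_count: int,
            lam: float = LAMBDA_GAPPED, K: float = K_GAPPED) -> float:
    """Karlin–Altschul expectation E = K * m * n * exp(-lambda * S)."""
    if peptide_length <= 0 or database_residue_count <= 0:
        raise ValueError("lengths must be positive")
    return K * peptide_length * database_residue_count * math.exp(-lam * score)


def collapse_xle(sequence: str) -> str:
    """Collapse isobaric I/L to a single symbol for sequence comparison."""
    return sequence.replace("I", "L")


def match_constant_region(sequence: str, germlines: Iterable[GermlineGene],
                          il_equivalent: bool = False) -> RegionAssignment:
    """Exact substring search of the peptide in each constant-region sequence."""
    seq = collapse_xle(sequence) if il_equivalent else sequence
    isotypes: list[str] = []
    accessions: list[str] = []
    for g in germlines:
        if g.segment != "constant":
            continue
        target = collapse_xle(g.sequence) if il_equivalent else g.sequence
        if seq in target:
            accessions.append(g.name)
            if g.isotype_group not in isotypes:
                isotypes.append(g.isotype_group)
    if not isotypes:
        return RegionAssignment(sequence=sequence, category="non_ig")
    return RegionAssignment(
        sequence=sequence, category="constant",
        isotype_group=isotypes[0] if len(isotypes) == 1 else None,
        unique_to_isotype=len(isotypes) == 1,
        matched_isotypes=tuple(isotypes),
        matched_accessions=tuple(accessions),
    )


def database_residue_count(germlines: Sequence[GermlineGene]) -> int:
    return sum(len(g.sequence) for g in germlines
               if g.segment in ("V", "J"))


def assign_variable_region(sequence: str, germlines: Sequence[GermlineGene],
                           region_map: RegionMap | None = None,
                           criteria: Criteria = Criteria(),
                           il_equivalent: bool = False,
                           db_residues: int | None = None) -> RegionAssignment:
    """Best-germline local alignment with the E-value / score / CDR criteria."""
    region_map = region_map or default_region_map()
    vj = [g for g in germlines if g.segment in ("V", "J")]
    if not vj:
        return RegionAssignment(sequence=sequence, category="non_ig")
    n_db = db_residues if db_residues is not None else database_residue_count(vj)
    query = collapse_xle(sequence) if il_equivalent else sequence

    # score-only scan first; full traceback only for the winning gene
    aligner = _aligner(11, 1)
    best_gene = None
    best_score = -1.0
    for g in sorted(vj, key=lambda g: g.name):
        target = collapse_xle(g.sequence) if il_equivalent else g.sequence
        score = float(aligner.score(query, target))
        if score > best_score:
            best_gene, best_score = g, score
    assert best_gene is not None
    best_aln = smith_waterman(
        query, collapse_xle(best_gene.sequence) if il_equivalent
        else best_gene.sequence)
    ev = e_value(best_aln.score, len(sequence), n_db) if best_aln.score > 0 else (
        e_value(0.0, len(sequence), n_db))

    imgt_positions = tuple(best_gene.imgt_positions[gi]
                           for _, gi in best_aln.aligned_pairs)
    cdr_pos = region_map.cdr_positions()
    n_cdr = sum(1 for p in imgt_positions if p in cdr_pos)
    segments = tuple(dict.fromkeys(region_map.region_of(p)
                                   for p in imgt_positions))

    igblast_ok = ev <= criteria.e_value_max
    imgt_ok = (ev <= criteria.e_value_max and best_aln.score > criteria.sw_min
               and n_cdr >= criteria.min_cdr_residues)
    accepted = ev <= criteria.e_value_max and best_aln.score > criteria.sw_min
    if not accepted:
        return RegionAssignment(sequence=sequence, category="non_ig",
                                germline_gene=best_gene.name,
                                sw_score=best_aln.score, e_value=ev,
                                igblast_ok=igblast_ok, imgt_ok=imgt_ok)
    has_cdr = n_cdr >= criteria.min_cdr_residues
    has_fr = any(s.startswith("FR") for s in segments)
    label = "FR+CDR" if (has_cdr and has_fr) else ("CDR" if has_cdr else "FR")
    return RegionAssignment(
        sequence=sequence, category="variable",
        germline_gene=best_gene.name, sw_score=best_aln.score, e_value=ev,
        aligned_imgt_positions=imgt_positions, region_label=label,
        segments=segments, n_cdr_residues=n_cdr,
        igblast_ok=igblast_ok, imgt_ok=imgt_ok,
    )


def annotate_sequence(sequence: str, germlines: Sequence[GermlineGene],
                      region_map: RegionMap | None = None,
                      criteria: Criteria = Criteria(),
                      il_equivalent: bool = False) -> RegionAssignment:
    """Full per-peptide allocation; constant match takes precedence over
    variable-region scoring."""
    const = match_constant_region(sequence, germlines, il_equivalent=il_equivalent)
    if const.category == "constant":
        return const
    return assign_variable_region(sequence, germlines, region_map=region_map,
                                  criteria=criteria, il_equivalent=il_equivalent)
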