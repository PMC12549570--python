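"""Reconciliation of database-search and de novo identifications.

Per feature, the database-search (Mascot-like) identification wins when its
score is >= 30; below that the de novo (PEAKS-like) identification is used
if one survives the quality filters (ALC% > 80, length >= 3). A sub-30
database hit with no de novo alternative is retained but flagged
low-confidence rather than dropped. Ig-related peptides already identified
by database search with score >= 30 are removed from the de novo candidate
pool (their sequence is settled; de novo would only re-derive it with I/L
ambiguity).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .tables import IdentRecord

MASCOT_PRIORITY_SCORE = 30.0
ALC_MIN = 80.0
MIN_DE_NOVO_LENGTH = 3


@dataclass(frozen=True)
class ResolvedIdent:
    feature_id: str
    sequence: str | None
    provenance: str          # database_search | de_novo | unidentified
    passed_filters: bool
    low_confidence: bool = False
    score: float | None = None
    alc: float | None = None
    ig_related: bool = False


def filter_de_novo(idents: Iterable[IdentRecord], alc_min: float = ALC_MIN,
                   min_length: int = MIN_DE_NOVO_LENGTH) -> list[IdentRecord]:
    """Keep de novo records with ALC% strictly above the cut-off and a
    sequence of at least three residues."""
    return [r for r in idents
            if r.engine == "de_novo" and r.alc > alc_min
            and len(r.sequence) >= min_length]


def exclude_ig_mascot_from_denovo(
        de_novo: Iterable[IdentRecord],
        db_idents: Iterable[IdentRecord],
        ig_flags: Mapping[str, bool],
        score_min: float = MASCOT_PRIORITY_SCORE) -> list[IdentRecord]:
    """Drop de novo candidates for features whose database-search hit is
    Ig-related with score >= ``score_min``.

    ``ig_flags`` maps database-search sequences to their Ig-relatedness (as
    computed by the region annotation on those sequences).
    """
    settled = {r.feature_id for r in db_idents
               if r.engine == "database_search" and r.score >= score_min
               and ig_flags.get(r.sequence, False)}
    return [r for r in de_novo if r.feature_id not in settled]


def _pick_de_novo(candidates: Sequence[IdentRecord]) -> IdentRecord:
    # highest ALC, then longest sequence, then lexicographic
    return sorted(candidates,
                  key=lambda r: (-r.alc, -len(r.sequence), r.sequence))[0]


def resolve_conflicts(db_idents: Sequence[IdentRecord],
                      de_novo_idents: Sequence[IdentRecord],
                      feature_ids: Sequence[str],
                      ig_flags: Mapping[str, bool] | None = None,
                      score_min: float = MASCOT_PRIORITY_SCORE,
                      on_db_ambiguity: str = "best") -> list[ResolvedIdent]:
    """One resolved identification per feature in ``feature_ids``.

    ``on_db_ambiguity``: ``"best"`` keeps the highest-scoring database record
    for a feature, ``"error"`` raises.
    """
    ig_flags = ig_flags or {}
    db_by_feature: dict[str, IdentRecord] = {}
    for r in db_idents:
        if r.engine != "database_search":
            raise ValueError(f"{r.feature_id}: not a database_search record")
        if r.feature_id in db_by_feature:
            if on_db_ambiguity == "error":
                raise ValueError(
                    f"{r.feature_id}: multiple database-search records")
            if r.score > db_by_feature[r.feature_id].score:
                db_by_feature[r.feature_id] = r
        else:
            db_by_feature[r.feature_id] = r

    dn_pool: dict[str, list[IdentRecord]] = {}
    for r in filter_de_novo(de_novo_idents):
        dn_pool.setdefault(r.feature_id, []).append(r)

    resolved = []
    for fid in feature_ids:
        db = db_by_feature.get(fid)
        dn = dn_pool.get(fid)
        if db is not None and db.score >= score_min:
            resolved.append(ResolvedIdent(
                fid, db.sequence, "database_search", True,
                score=db.score, ig_related=ig_flags.get(db.sequence, False)))
        elif dn:
            pick = _pick_de_novo(dn)
            resolved.append(ResolvedIdent(
                fid, pick.sequence, "de_novo", True, alc=pick.alc,
                ig_related=ig_flags.get(pick.sequence, False)))
        elif db is not None:
            resolved.append(ResolvedIdent(
                fid, db.sequence, "database_search", False,
                low_confidence=True, score=db.score,
                ig_related=ig_flags.get(db.sequence, False)))
        else:
            resolved.append(ResolvedIdent(fid, None, "unidentified", False))
    return resolved
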