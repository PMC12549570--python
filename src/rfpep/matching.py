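"""Cross-experiment matching of unidentified LC-MS features.

Two features match when their m/z values differ by strictly less than the
m/z tolerance (default 0.01 Th), their retention times by strictly less than
the RT tolerance (default 1 min), they carry the same charge, and (by
default) both have MS/MS scans. Multi-candidate collisions are resolved by a
greedy one-to-one assignment that always takes the remaining admissible pair
with the smallest |delta m/z|, breaking ties by |delta RT|; this equals the
lexicographically minimal maximal matching and is symmetric under exchanging
the two feature sets.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .tables import FeatureRecord

MZ_TOL = 0.01
RT_TOL = 1.0


@dataclass(frozen=True)
class FeatureMatch:
    feature_id_a: str
    feature_id_b: str
    delta_mz: float
    delta_rt: float
    charge: int


def _admissible(a: FeatureRecord, b: FeatureRecord, mz_tol: float,
                rt_tol: float, require_msms: str) -> bool:
    if a.charge != b.charge:
        return False
    if abs(a.mz - b.mz) >= mz_tol or abs(a.rt - b.rt) >= rt_tol:
        return False
    if require_msms == "both":
        return a.has_msms and b.has_msms
    if require_msms == "either":
        return a.has_msms or b.has_msms
    return True


def match_features(set_a: Sequence[FeatureRecord],
                   set_b: Sequence[FeatureRecord],
                   mz_tol: float = MZ_TOL, rt_tol: float = RT_TOL,
                   require_msms: str = "both") -> list[FeatureMatch]:
    """Greedy nearest-m/z one-to-one matching inside the tolerance windows."""
    candidates = []
    for a in set_a:
        for b in set_b:
            if _admissible(a, b, mz_tol, rt_tol, require_msms):
                dmz = abs(a.mz - b.mz)
                drt = abs(a.rt - b.rt)
                tie = tuple(sorted((a.feature_id, b.feature_id)))
                candidates.append((dmz, drt, tie, a, b))
    candidates.sort(key=lambda c: c[:3])
    used_a: set[str] = set()
    used_b: set[str] = set()
    matches = []
    for dmz, drt, _, a, b in candidates:
        if a.feature_id in used_a or b.feature_id in used_b:
            continue
        used_a.add(a.feature_id)
        used_b.add(b.feature_id)
        matches.append(FeatureMatch(a.feature_id, b.feature_id,
                                    delta_mz=a.mz - b.mz, delta_rt=a.rt - b.rt,
                                    charge=a.charge))
    return matches
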