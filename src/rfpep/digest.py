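"""In-silico sequential Lys-C + chymotrypsin digestion.

Mirrors the bench protocol the cohort generator emulates: Lys-C first
(cleaves C-terminal to K, including K-P bonds), then chymotrypsin (cleaves
C-terminal to F, Y, W or L, blocked when the next residue is proline).
Because Lys-C sites are a subset of no chymotrypsin site, the sequential
digest equals a single pass over the union of both site sets; missed
cleavages count internal sites of either enzyme.
"""
from __future__ import annotations

from .germline import AMINO_ACIDS

CHYMO_RESIDUES = set("FYWL")


class DigestError(ValueError):
    pass


def cleavage_sites(sequence: str) -> list[int]:
    """0-based positions *after* which the combined digest cleaves."""
    sites = []
    n = len(sequence)
    for i, aa in enumerate(sequence[:-1]):
        if aa == "K":
            sites.append(i)
        elif aa in CHYMO_RESIDUES and sequence[i + 1] != "P":
            sites.append(i)
    return sites


def fragments(sequence: str) -> list[str]:
    """Ordered fully-cleaved (0 missed cleavage) fragments; concatenation
    restores the input."""
    _validate(sequence)
    bounds = [-1] + cleavage_sites(sequence) + [len(sequence) - 1]
    return [sequence[a + 1:b + 1] for a, b in zip(bounds, bounds[1:])]


def digest(sequence: str, max_missed_cleavages: int = 0,
           min_length: int = 3) -> set[str]:
    """All digest peptides with 0..``max_missed_cleavages`` internal sites
    and length >= ``min_length``."""
    _validate(sequence)
    frags = fragments(sequence)
    out: set[str] = set()
    for i in range(len(frags)):
        for j in range(i, min(i + max_missed_cleavages + 1, len(frags))):
            pep = "".join(frags[i:j + 1])
            if len(pep) >= min_length:
                out.add(pep)
    return out


def _validate(sequence: str) -> None:
    if not sequence:
        raise DigestError("empty sequence")
    bad = set(sequence) - AMINO_ACIDS
    if bad:
        raise DigestError(f"non-amino-acid characters {sorted(bad)!r}")
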