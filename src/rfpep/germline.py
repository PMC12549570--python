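"""Germline immunoglobulin reference sets and the IMGT region coordinate map.

Variable-domain peptides are interpreted against germline V/J amino-acid
sequences carrying IMGT unique-numbering positions; constant-region peptides
against heavy-chain constant sequences grouped by isotype (IgA1, IgA2,
IgG1-4, IgM). The packaged fixtures (``*_synthetic.fasta``) are synthetic
curated stand-ins for the IMGT/UniProt reference sets: germline-like V/J
sequences and seeded-RNG constant regions with a controlled shared/unique
block structure. Full reference directories in the same FASTA dialect can be
loaded by path.

FASTA header dialect: ``>name|chain|segment[|isotype=GROUP]`` with chain in
{heavy, kappa, lambda} and segment in {V, J, constant}. V sequences carry
IMGT gaps as ``.``; headers without ``|`` fields fall back to inference from
the IMGT-style gene name (IGH/IGK/IGL prefix, V/J letter).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWYX")

CHAINS = ("heavy", "kappa", "lambda")
SEGMENTS = ("V", "J", "constant")
ISOTYPE_GROUPS = ("IgA1", "IgA2", "IgG1", "IgG2", "IgG3", "IgG4", "IgM")

#: built-in fixture names -> packaged file
_FIXTURES = {
    "v_genes": "v_genes_synthetic.fasta",
    "j_genes": "j_genes_synthetic.fasta",
    "constant_regions": "constant_regions_synthetic.fasta",
}

# last IMGT position of the J anchor (end of FR4)
_J_ANCHOR_END = 128


class GermlineValidationError(ValueError):
    """A germline record violates the reference-set contract."""


@dataclass(frozen=True)
class GermlineGene:
    """One germline V/J gene or constant-region entry (amino acids).

    ``sequence`` is ungapped; for V and J segments ``imgt_positions`` gives
    the IMGT unique-numbering position of each residue (strictly increasing).
    Constant segments instead carry an ``isotype_group``.
    """

    name: str
    chain: str
    segment: str
    sequence: str
    imgt_positions: tuple[int, ...] | None = None
    isotype_group: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise GermlineValidationError(f"{self.name}: empty sequence")
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise GermlineValidationError(
                f"{self.name}: non-amino-acid characters {sorted(bad)!r}")
        if self.chain not in CHAINS:
            raise GermlineValidationError(f"{self.name}: unknown chain {self.chain!r}")
        if self.segment not in SEGMENTS:
            raise GermlineValidationError(
                f"{self.name}: unknown segment {self.segment!r}")
        if self.segment in ("V", "J"):
            if self.imgt_positions is None:
                raise GermlineValidationError(
                    f"{self.name}: {self.segment} segment without IMGT positions")
            if len(self.imgt_positions) != len(self.sequence):
                raise GermlineValidationError(
                    f"{self.name}: {len(self.imgt_positions)} IMGT positions for "
                    f"{len(self.sequence)} residues")
            if any(b <= a for a, b in zip(self.imgt_positions,
                                          self.imgt_positions[1:])):
                raise GermlineValidationError(
                    f"{self.name}: IMGT positions not strictly increasing")
        if self.segment == "constant":
            if self.isotype_group is None:
                raise GermlineValidationError(
                    f"{self.name}: constant segment without isotype group")
            if self.isotype_group not in ISOTYPE_GROUPS:
                raise GermlineValidationError(
                    f"{self.name}: unknown isotype group {self.isotype_group!r}")


@dataclass(frozen=True)
class RegionMap:
    """Inclusive IMGT position ranges for the FR/CDR segments of a V domain."""

    boundaries: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(_DEFAULT_BOUNDARIES))

    def region_of(self, position: int) -> str:
        for label, (lo, hi) in self.boundaries.items():
            if lo <= position <= hi:
                return label
        raise KeyError(f"IMGT position {position} outside FR1..FR4")

    def cdr_positions(self) -> set[int]:
        out: set[int] = set()
        for label, (lo, hi) in self.boundaries.items():
            if label.startswith("CDR"):
                out.update(range(lo, hi + 1))
        return out


_DEFAULT_BOUNDARIES = (
    ("FR1", (1, 26)),
    ("CDR1", (27, 38)),
    ("FR2", (39, 55)),
    ("CDR2", (56, 65)),
    ("FR3", (66, 104)),
    ("CDR3", (105, 117)),
    ("FR4", (118, 128)),
)


def default_region_map() -> RegionMap:
    """FR/CDR boundaries of the IMGT unique numbering (FR1 1-26 ... FR4 118-128)."""
    return RegionMap()


def _infer_fields(description: str) -> tuple[str, str, str, str | None]:
    """Parse ``name|chain|segment[|isotype=GROUP]``; fall back to gene-name rules."""
    parts = description.split("|")
    name = parts[0].strip()
    isotype = None
    for p in parts[1:]:
        if p.startswith("isotype="):
            isotype = p.split("=", 1)[1].strip()
    tagged = [p for p in parts[1:] if "=" not in p]
    if len(tagged) >= 2:
        return name, tagged[0].strip(), tagged[1].strip(), isotype
    # bare IMGT-style name, e.g. IGHV3-23*01
    prefix = name[:4].upper()
    chain = {"IGHV": "heavy", "IGHJ": "heavy", "IGKV": "kappa", "IGKJ": "kappa",
             "IGLV": "lambda", "IGLJ": "lambda"}.get(prefix)
    if chain is None:
        raise GermlineValidationError(
            f"cannot infer chain/segment from FASTA header {description!r}")
    segment = "V" if prefix.endswith("V") else "J"
    return name, chain, segment, isotype


def _positions_from_gaps(gapped: str) -> tuple[str, tuple[int, ...]]:
    seq = []
    pos = []
    for i, ch in enumerate(gapped, start=1):
        if ch in ".-":
            continue
        seq.append(ch)
        pos.append(i)
    return "".join(seq), tuple(pos)


def load_germline_set(source: str | Path) -> list[GermlineGene]:
    """Load a germline set from a built-in fixture name or a FASTA path.

    Built-in names: ``v_genes``, ``j_genes``, ``constant_regions``.
    V records must carry IMGT gap characters (``.`` or ``-``) so per-residue
    IMGT positions can be resolved; J records are anchored so that their last
    residue sits at IMGT position 128 (end of FR4).
    """
    if isinstance(source, str) and source in _FIXTURES:
        ref = resources.files("rfpep.data") / _FIXTURES[source]
        with resources.as_file(ref) as path:
            return _load_fasta(path)
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(
            f"{source!r} is neither a built-in fixture {sorted(_FIXTURES)} "
            f"nor an existing FASTA path")
    return _load_fasta(path)


def _load_fasta(path: Path) -> list[GermlineGene]:
    genes: list[GermlineGene] = []
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise GermlineValidationError(f"malformed FASTA {path}: {exc}") from exc
    if not records:
        raise GermlineValidationError(f"{path}: no FASTA records")
    for rec in records:
        name, chain, segment, isotype = _infer_fields(rec.description)
        raw = str(rec.seq).upper()
        if not raw:
            raise GermlineValidationError(f"{name}: empty sequence in {path}")
        if segment == "V":
            if "." not in raw and "-" not in raw:
                raise GermlineValidationError(
                    f"{name}: V segment without IMGT gap characters; cannot "
                    f"resolve IMGT positions")
            seq, positions = _positions_from_gaps(raw)
        elif segment == "J":
            seq = raw.replace(".", "").replace("-", "")
            start = _J_ANCHOR_END - len(seq) + 1
            positions = tuple(range(start, _J_ANCHOR_END + 1))
        else:
            seq, positions = raw, None
        genes.append(GermlineGene(name=name, chain=chain, segment=segment,
                                  sequence=seq, imgt_positions=positions,
                                  isotype_group=isotype))
    return genes


def load_default_references() -> dict[str, list[GermlineGene]]:
    """All three packaged fixture sets, keyed by fixture name."""
    return {name: load_germline_set(name) for name in _FIXTURES}


def constant_groups(genes: Iterable[GermlineGene]) -> dict[str, list[GermlineGene]]:
    """Constant-region genes grouped by isotype (duplicate accessions share one)."""
    out: dict[str, list[GermlineGene]] = {}
    for g in genes:
        if g.segment == "constant":
            out.setdefault(g.isotype_group, []).append(g)
    return out


def v_genes(genes: Iterable[GermlineGene]) -> list[GermlineGene]:
    return [g for g in genes if g.segment == "V"]


def variable_segment_genes(genes: Iterable[GermlineGene]) -> list[GermlineGene]:
    return [g for g in genes if g.segment in ("V", "J")]
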