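"""Tabular I/O for feature quantification, identification and metadata tables.

Canonical dialect: wide delimited text, one row per LC-MS feature with the
metadata columns ``feature_id, mz, charge, rt, has_msms, sequence`` followed
by one abundance column per sample. Missing abundances are empty fields and
stay missing (never coerced to 0). A Progenesis-like export with arbitrary
column names is supported through a :class:`Dialect` mapping.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: the five study groups: RF/anti-CCP serology x disease status
GROUPS = (
    "RFposCCPpos_RA",
    "RFnegCCPpos_RA",
    "RFnegCCPneg_RA",
    "RFneg_control",
    "RFpos_control",
)

#: group sizes of the main cohort design
GROUP_SIZES = {
    "RFposCCPpos_RA": 27,
    "RFnegCCPpos_RA": 5,
    "RFnegCCPneg_RA": 22,
    "RFneg_control": 28,
    "RFpos_control": 4,
}

_META_COLS = ["feature_id", "mz", "charge", "rt", "has_msms", "sequence"]


class TableValidationError(ValueError):
    """A tabular artifact violates its contract."""


@dataclass
class FeatureRecord:
    """One LC-MS feature: physico-chemical coordinates plus per-sample abundances."""

    feature_id: str
    mz: float
    charge: int
    rt: float
    abundances: dict[str, float | None]
    sequence: str | None = None
    has_msms: bool = True

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise TableValidationError(f"{self.feature_id}: mz must be > 0")
        if self.charge == 0:
            raise TableValidationError(f"{self.feature_id}: charge must be nonzero")
        if self.rt < 0:
            raise TableValidationError(f"{self.feature_id}: rt must be >= 0")
        for sample, value in list(self.abundances.items()):
            if value is None:
                continue
            if math.isnan(value):
                self.abundances[sample] = None
            elif value < 0:
                raise TableValidationError(
                    f"{self.feature_id}/{sample}: negative abundance {value}")


@dataclass(frozen=True)
class IdentRecord:
    """One engine-level identification of a feature.

    ``engine`` is ``database_search`` (Mascot-like, carries ``score``) or
    ``de_novo`` (PEAKS-like, carries ``alc`` in percent).
    """

    feature_id: str
    sequence: str
    engine: str
    score: float | None = None
    alc: float | None = None
    protein_accessions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.engine == "database_search":
            if self.score is None or self.alc is not None:
                raise TableValidationError(
                    f"{self.feature_id}: database_search records carry score only")
        elif self.engine == "de_novo":
            if self.alc is None or self.score is not None:
                raise TableValidationError(
                    f"{self.feature_id}: de_novo records carry alc only")
            if not 0 <= self.alc <= 100:
                raise TableValidationError(
                    f"{self.feature_id}: ALC% {self.alc} outside [0, 100]")
        else:
            raise TableValidationError(
                f"{self.feature_id}: unknown engine {self.engine!r}")


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    group: str
    experiment_id: str = "main"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise TableValidationError(
                f"{self.sample_id}: unknown group {self.group!r}")


@dataclass(frozen=True)
class Dialect:
    """Column mapping for a wide feature export.

    ``meta`` maps canonical metadata names to the file's column names (missing
    entries default to the canonical name); ``sample_columns`` lists the
    abundance columns in sample order, or ``None`` to treat every non-metadata
    column as a sample.
    """

    meta: Mapping[str, str] = field(default_factory=dict)
    sample_columns: Sequence[str] | None = None
    sep: str = ","

    def meta_col(self, canonical: str) -> str:
        return dict(self.meta).get(canonical, canonical)


CANONICAL = Dialect()


def read_feature_table(path: str | Path, dialect: Dialect = CANONICAL,
                       ) -> list[FeatureRecord]:
    df = pd.read_csv(path, sep=dialect.sep)
    cols = {c: dialect.meta_col(c) for c in _META_COLS}
    for canonical in ("feature_id", "mz", "charge", "rt"):
        if cols[canonical] not in df.columns:
            raise TableValidationError(
                f"{path}: required column {cols[canonical]!r} missing")
    if dialect.sample_columns is not None:
        samples = list(dialect.sample_columns)
    else:
        known = set(cols.values())
        samples = [c for c in df.columns if c not in known]
    records = []
    for row in df.to_dict("records"):
        abundances: dict[str, float | None] = {}
        for s in samples:
            v = row[s]
            abundances[s] = None if pd.isna(v) else float(v)
        seq = row.get(cols["sequence"])
        has_msms = row.get(cols["has_msms"], True)
        records.append(FeatureRecord(
            feature_id=str(row[cols["feature_id"]]),
            mz=float(row[cols["mz"]]),
            charge=int(row[cols["charge"]]),
            rt=float(row[cols["rt"]]),
            abundances=abundances,
            sequence=None if pd.isna(seq) else str(seq),
            has_msms=bool(has_msms),
        ))
    return records


def features_to_frame(records: Iterable[FeatureRecord]) -> pd.DataFrame:
    """Canonical wide DataFrame (metadata columns then one column per sample)."""
    records = list(records)
    samples: list[str] = []
    for r in records:
        for s in r.abundances:
            if s not in samples:
                samples.append(s)
    rows = []
    for r in records:
        row = dict(feature_id=r.feature_id, mz=r.mz, charge=r.charge, rt=r.rt,
                   has_msms=r.has_msms, sequence=r.sequence)
        for s in samples:
            row[s] = r.abundances.get(s)
        rows.append(row)
    return pd.DataFrame(rows, columns=_META_COLS + samples)


def write_feature_table(path: str | Path, records: Iterable[FeatureRecord]) -> None:
    features_to_frame(records).to_csv(path, index=False)


def read_ident_table(path: str | Path) -> list[IdentRecord]:
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        accs = row.protein_accessions
        accs = () if pd.isna(accs) else tuple(str(accs).split(";"))
        out.append(IdentRecord(
            feature_id=str(row.feature_id),
            sequence=str(row.sequence),
            engine=str(row.engine),
            score=None if pd.isna(row.score) else float(row.score),
            alc=None if pd.isna(row.alc) else float(row.alc),
            protein_accessions=accs,
        ))
    return out


def write_ident_table(path: str | Path, records: Iterable[IdentRecord]) -> None:
    rows = [dict(feature_id=r.feature_id, sequence=r.sequence, engine=r.engine,
                 score=r.score, alc=r.alc,
                 protein_accessions=";".join(r.protein_accessions))
            for r in records]
    pd.DataFrame(rows, columns=["feature_id", "sequence", "engine", "score",
                                "alc", "protein_accessions"]).to_csv(path, index=False)


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path)
    metas = [SampleMeta(str(r.sample_id), str(r.group), str(r.experiment_id))
             for r in df.itertuples(index=False)]
    ids = [m.sample_id for m in metas]
    if len(set(ids)) != len(ids):
        raise TableValidationError(f"{path}: duplicate sample ids")
    return metas


def write_sample_meta(path: str | Path, metas: Iterable[SampleMeta]) -> None:
    pd.DataFrame([dict(sample_id=m.sample_id, group=m.group,
                       experiment_id=m.experiment_id) for m in metas]
                 ).to_csv(path, index=False)


def reconcile(records: Sequence[FeatureRecord], metas: Sequence[SampleMeta]) -> None:
    """Fail if the feature table mentions samples absent from the metadata."""
    known = {m.sample_id for m in metas}
    for r in records:
        unknown = set(r.abundances) - known
        if unknown:
            raise TableValidationError(
                f"{r.feature_id}: samples {sorted(unknown)} not in metadata")


def write_results(out_dir: str | Path, tables: Mapping[str, pd.DataFrame]) -> dict[str, Path]:
    """Write each result DataFrame as ``<name>.csv`` under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, df in tables.items():
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False)
        written[name] = p
    return written


def abundance_matrix(records: Sequence[FeatureRecord]) -> pd.DataFrame:
    """Features x samples abundance matrix (NaN = missing)."""
    df = features_to_frame(records)
    mat = df.drop(columns=_META_COLS[1:]).set_index("feature_id")
    return mat.astype(float)
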