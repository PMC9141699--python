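"""Readers, writers and the standardization transform shared by every stage.

Expression matrices are genes x samples, tab-separated, FPKM-like non-negative
values.  Every downstream statistic assumes rows have been put through
:func:`log_standardize` (z-scores of ``log2(x + 1)``); the ``transform`` flag on
:class:`ExpressionMatrix` guards against applying the transform twice or
feeding raw values to a stage that expects standardized ones.

Gene sets use the MSigDB GMT dialect: one set per line,
``name<TAB>description<TAB>gene<TAB>gene...``.
"""
from __future__ import annotations

import enum
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Transform",
    "ExpressionMatrix",
    "SurvivalTable",
    "GeneSet",
    "GeneSetCollection",
    "TransformStateError",
    "ExpressionFormatError",
    "GmtFormatError",
    "read_expression",
    "write_expression",
    "log_standardize",
    "read_survival",
    "write_survival",
    "read_gmt",
    "write_gmt",
    "write_run_metadata",
]


class Transform(str, enum.Enum):
    """Transform state of an expression matrix."""

    RAW = "raw"
    LOG_STANDARDIZED = "log_standardized"


class TransformStateError(ValueError):
    """A transform was requested on a matrix in the wrong state."""


class ExpressionFormatError(ValueError):
    """An expression file violated the expected TSV dialect."""


class GmtFormatError(ValueError):
    """A GMT line violated the name/description/genes dialect."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples numeric matrix with identifier bookkeeping.

    Parameters
    ----------
    data
        DataFrame indexed by gene id with sample ids as columns.
    transform
        Whether values are raw (non-negative, FPKM-like) or row z-scores of
        ``log2(x + 1)``.
    constant_genes
        Genes whose raw row was constant; after standardization these rows are
        all zero and are excluded from model fitting.
    """

    data: pd.DataFrame
    transform: Transform = Transform.RAW
    constant_genes: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ExpressionFormatError(f"duplicate gene identifiers: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ExpressionFormatError(f"duplicate sample identifiers: {dups[:5]}")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ExpressionFormatError("expression values must be finite")
        if self.transform is Transform.RAW:
            if values.size and values.min() < 0:
                raise ExpressionFormatError("raw expression values must be >= 0")
        else:
            self._check_standardized(values)

    def _check_standardized(self, values: np.ndarray) -> None:
        if values.shape[1] == 0:
            return
        mean = values.mean(axis=1)
        var = values.var(axis=1)
        zero_rows = np.abs(values).max(axis=1) == 0 if values.shape[1] else np.array([])
        bad = ~zero_rows & ((np.abs(mean) > 1e-8) | (np.abs(var - 1.0) > 1e-8))
        if bad.any():
            offenders = self.data.index[bad].tolist()
            raise ExpressionFormatError(
                f"log_standardized rows must have mean 0 / unit variance: {offenders[:5]}"
            )

    @property
    def gene_ids(self) -> list:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        present = [g for g in genes if g in self.data.index]
        return replace(
            self,
            data=self.data.loc[present],
            constant_genes=frozenset(g for g in self.constant_genes if g in present),
        )

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return replace(self, data=self.data.loc[:, list(samples)])


@dataclass(frozen=True)
class SurvivalTable:
    """Per-sample right-censored time-to-event outcome (time in days)."""

    sample_ids: tuple
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "event", np.asarray(self.event, dtype=int))
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers in survival table")
        if len(self.sample_ids) != self.time.shape[0] or len(self.sample_ids) != self.event.shape[0]:
            raise ValueError("sample_ids, time and event must have equal length")
        if self.time.size and (not np.isfinite(self.time).all() or self.time.min() <= 0):
            raise ValueError("survival times must be finite and > 0")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicator must be 0 (censored) or 1 (death)")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, samples: Sequence[str]) -> "SurvivalTable":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [index[s] for s in samples]
        return SurvivalTable(tuple(samples), self.time[idx], self.event[idx])


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: tuple
    category: str = "NA"
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        if len(self.genes) < 1:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} contains duplicate genes")


@dataclass(frozen=True)
class GeneSetCollection:
    sets: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "sets", tuple(self.sets))
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene set names in collection")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list:
        return [s.name for s in self.sets]

    def subset(self, names: Sequence[str]) -> "GeneSetCollection":
        wanted = set(names)
        return GeneSetCollection(tuple(s for s in self.sets if s.name in wanted))


# ---------------------------------------------------------------------------
# expression


def read_expression(path, transform_request: Transform = Transform.RAW) -> ExpressionMatrix:
    """Read a genes-in-rows TSV; first column gene id, header row sample ids.

    Duplicate gene rows are collapsed keeping the row with the highest mean
    (logged).  A non-numeric cell raises naming the offending row and column;
    duplicate sample ids raise a format error.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        dups = sorted({s for s in samples if samples.count(s) > 1})
        raise ExpressionFormatError(f"duplicate sample id(s) in header: {dups}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.columns = samples
    numeric = pd.DataFrame(index=df.index)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna() & (df[col].str.strip().str.lower() != "nan")
        if bad.any():
            gene = df.index[bad.to_numpy()][0]
            raise ExpressionFormatError(
                f"non-numeric expression value at gene {gene!r}, sample {col!r}"
            )
        if converted.isna().any():
            gene = df.index[converted.isna().to_numpy()][0]
            raise ExpressionFormatError(f"missing value at gene {gene!r}, sample {col!r}")
        numeric[col] = converted
    if numeric.index.has_duplicates:
        means = numeric.mean(axis=1)
        order = np.argsort(-means.to_numpy(), kind="stable")
        deduped = numeric.iloc[order]
        n_before = deduped.shape[0]
        deduped = deduped[~deduped.index.duplicated(keep="first")]
        deduped = deduped.loc[[g for g in dict.fromkeys(numeric.index)]]
        logger.info("collapsed %d duplicate gene rows (kept highest mean)", n_before - deduped.shape[0])
        numeric = deduped
    matrix = ExpressionMatrix(numeric, Transform.RAW)
    if transform_request is Transform.LOG_STANDARDIZED:
        matrix = log_standardize(matrix)
    return matrix


def write_expression(matrix: ExpressionMatrix, path) -> None:
    df = matrix.data.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def log_standardize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Row-wise z-scores of ``log2(value + 1)`` with the population-sd convention.

    Constant rows map to all-zero rows and are flagged in ``constant_genes``.
    Applying the transform twice raises :class:`TransformStateError`.
    """
    if matrix.transform is not Transform.RAW:
        raise TransformStateError("matrix is already log-standardized")
    values = np.log2(matrix.values + 1.0)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)  # population sd: divisor n
    constant = sd[:, 0] == 0
    sd[constant] = 1.0
    z = (values - mean) / sd
    z[constant] = 0.0
    data = pd.DataFrame(z, index=matrix.data.index, columns=matrix.data.columns)
    flagged = frozenset(np.asarray(matrix.gene_ids, dtype=object)[constant].tolist())
    if flagged:
        logger.info("flagged %d constant gene rows during standardization", len(flagged))
    return ExpressionMatrix(data, Transform.LOG_STANDARDIZED, flagged)


# ---------------------------------------------------------------------------
# survival


def read_survival(path) -> SurvivalTable:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "time", "event"}
    if not required.issubset(df.columns):
        raise ValueError(f"survival table must have columns {sorted(required)}")
    return SurvivalTable(
        tuple(df["sample_id"].astype(str)),
        df["time"].to_numpy(dtype=float),
        df["event"].to_numpy(dtype=int),
    )


def write_survival(surv: SurvivalTable, path) -> None:
    pd.DataFrame(
        {"sample_id": surv.sample_ids, "time": surv.time, "event": surv.event}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets


def read_gmt(
    path,
    categories: Mapping[str, str] | None = None,
    category_from_name: Callable[[str], str] | None = None,
) -> GeneSetCollection:
    """Read an MSigDB-dialect GMT file.

    Category labels come from an optional companion mapping (set name ->
    category) or from a name-prefix rule; otherwise "NA".  Duplicate genes
    within a set are dropped (logged); a line with fewer than three fields
    raises with its line number.
    """
    sets = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtFormatError(f"line {lineno}: expected >= 3 tab-separated fields")
            name, description = fields[0], fields[1]
            genes = [g for g in fields[2:] if g]
            unique = list(dict.fromkeys(genes))
            if len(unique) != len(genes):
                logger.info("set %s: dropped %d duplicate genes", name, len(genes) - len(unique))
            if categories is not None and name in categories:
                category = categories[name]
            elif category_from_name is not None:
                category = category_from_name(name)
            else:
                category = "NA"
            sets.append(GeneSet(name, tuple(unique), category, description))
    if not sets:
        logger.warning("GMT file %s contained no gene sets", path)
    return GeneSetCollection(tuple(sets))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


# ---------------------------------------------------------------------------
# run metadata sidecar


def write_run_metadata(path, seed=None, config: Mapping | None = None) -> None:
    """JSON sidecar recording package version, seed and a config hash."""
    from gsprog import __version__

    config = dict(config or {})
    digest = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()
    payload = {"version": __version__, "seed": seed, "config": config, "config_sha256": digest}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
        fh.write("\n")
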