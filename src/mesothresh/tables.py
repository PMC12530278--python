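"""Tabular containers and I/O for mesocosm community data.

Conventions
-----------
* Count tables are sample-major: rows are samples, columns are taxa
  (ASVs or phylogenetic-placement "edges").
* On disk, counts are TSV with a header row of taxon ids and the sample id in
  the first column; metadata and environment tables are CSV; result objects
  are JSON.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

TREATMENTS = ("burned", "unburned", "control")
SOURCES = ("water", "daphnia", "mosquito", "sage", "willow")

#: The nine environmental descriptors carried per sample: oxygen saturation,
#: dissolved organic carbon, three DOM fluorescence indices (source,
#: freshness, humification), spectral slope ratio, aromaticity proxy, pH and
#: water temperature.
ENV_VARIABLES = (
    "percent_DO", "DOC", "FI", "BIX", "HIX", "Sr", "SUVA254", "pH",
    "temperature",
)

LOADING_RANGE = (0.0, 400.0)


class ValidationError(ValueError):
    """A table violated one of its declared invariants."""


def _check_unique(ids: Sequence, what: str) -> None:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if list(ids).count(i) > 1})
        raise ValidationError(f"duplicate {what} identifiers: {dupes}")


@dataclass(frozen=True)
class CountTable:
    """Sample x taxon matrix of non-negative integer abundances."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(df.index, "sample")
        _check_unique(df.columns, "taxon")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if np.any(~np.isfinite(arr)):
            raise ValidationError("counts contain non-finite values")
        bad = np.argwhere((arr < 0) | (arr != np.round(arr)))
        if bad.size:
            i, j = bad[0]
            raise ValidationError(
                f"count at sample {df.index[i]!r}, taxon {df.columns[j]!r} "
                f"is {arr[i, j]!r}; counts must be non-negative integers"
            )
        zero = df.index[arr.sum(axis=1) == 0]
        if len(zero):
            raise ValidationError(
                f"sample(s) with no positive counts: {list(zero)}"
            )
        object.__setattr__(self, "data", df.astype(np.int64))

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    def totals(self) -> pd.Series:
        return self.data.sum(axis=1)

    def select_samples(self, ids: Iterable) -> "CountTable":
        return CountTable(self.data.loc[list(ids)])

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CountTable) and self.data.equals(other.data)


def read_count_table(path: str | Path, format_tag: str = "tsv") -> CountTable:
    """Read a count table from disk.

    ``format_tag`` is ``"tsv"`` (header = taxon ids, first column = sample id)
    or ``"biom_json"`` (BIOM 1.0 JSON, dense or sparse).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format_tag == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return CountTable(df)
    if format_tag == "biom_json":
        doc = json.loads(path.read_text())
        # BIOM stores observations (taxa) as rows; transpose to sample-major.
        taxa = [r["id"] for r in doc["rows"]]
        samples = [c["id"] for c in doc["columns"]]
        mat = np.zeros((len(taxa), len(samples)))
        if doc.get("matrix_type") == "sparse":
            for r, c, v in doc["data"]:
                mat[int(r), int(c)] = v
        else:
            mat[:] = np.asarray(doc["data"], dtype=float)
        df = pd.DataFrame(mat.T, index=samples, columns=taxa)
        return CountTable(df)
    raise ValueError(f"unknown format_tag {format_tag!r}; use 'tsv' or 'biom_json'")


def write_count_table(table: CountTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index_label="sample_id")


METADATA_COLUMNS = ("sample_id", "mesocosm_id", "loading_g", "treatment",
                    "day", "source")


def validate_metadata(meta: pd.DataFrame,
                      loading_range: tuple[float, float] = LOADING_RANGE
                      ) -> pd.DataFrame:
    """Validate and normalize a sample metadata frame (indexed by sample_id)."""
    df = meta.copy()
    if "sample_id" in df.columns:
        df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    _check_unique(df.index, "sample")
    missing = [c for c in METADATA_COLUMNS[1:] if c not in df.columns]
    if missing:
        raise ValidationError(f"metadata missing column(s): {missing}")
    lo, hi = loading_range
    load = df["loading_g"].astype(float)
    out = df.index[(load < lo) | (load > hi)]
    if len(out):
        raise ValidationError(
            f"loading_g outside [{lo}, {hi}] for sample(s): {list(out)}")
    bad_t = sorted(set(df["treatment"]) - set(TREATMENTS))
    if bad_t:
        raise ValidationError(f"unknown treatment value(s): {bad_t}")
    bad_s = sorted(set(df["source"]) - set(SOURCES))
    if bad_s:
        raise ValidationError(f"unknown source value(s): {bad_s}")
    df["loading_g"] = load
    df["day"] = df["day"].astype(int)
    return df


def read_metadata(path: str | Path) -> pd.DataFrame:
    return validate_metadata(pd.read_csv(path))


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, index_label="sample_id")


def validate_environment(env: pd.DataFrame, impute: str | None = None
                         ) -> pd.DataFrame:
    """Validate an environment table: exactly the nine variables, no NaN
    unless ``impute='mean'`` was requested explicitly."""
    df = env.copy()
    if "sample_id" in df.columns:
        df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    _check_unique(df.index, "sample")
    missing = [v for v in ENV_VARIABLES if v not in df.columns]
    extra = [c for c in df.columns if c not in ENV_VARIABLES]
    if missing or extra:
        raise ValidationError(
            f"environment table must contain exactly {list(ENV_VARIABLES)}; "
            f"missing={missing}, unexpected={extra}")
    df = df[list(ENV_VARIABLES)].astype(float)
    if df.isna().any().any():
        if impute == "mean":
            df = df.fillna(df.mean())
            warnings.warn("environment table: missing values mean-imputed")
        else:
            cols = list(df.columns[df.isna().any()])
            raise ValidationError(
                f"environment table has missing values in {cols}; "
                "pass impute='mean' to impute explicitly")
    return df


def read_environment(path: str | Path, impute: str | None = None) -> pd.DataFrame:
    return validate_environment(pd.read_csv(path), impute=impute)


def write_environment(env: pd.DataFrame, path: str | Path) -> None:
    env.to_csv(path, index_label="sample_id")


@dataclass(frozen=True)
class AlignedExperiment:
    """Counts, metadata and (optionally) environment in one sample order."""

    counts: CountTable
    metadata: pd.DataFrame
    environment: pd.DataFrame | None = None

    @property
    def sample_ids(self) -> list:
        return self.counts.sample_ids


def join_metadata(table: CountTable, meta: pd.DataFrame,
                  env: pd.DataFrame | None = None) -> AlignedExperiment:
    """Align metadata (and environment) rows to the count table's samples.

    Metadata rows for samples absent from the table are dropped; a count-table
    sample with no metadata row is an error naming the orphans.
    """
    meta = validate_metadata(meta)
    ids = table.sample_ids
    orphans = [s for s in ids if s not in meta.index]
    if orphans:
        raise ValidationError(
            f"count-table sample(s) missing from metadata: {orphans}")
    aligned_env = None
    if env is not None:
        env = validate_environment(env)
        env_orphans = [s for s in ids if s not in env.index]
        if env_orphans:
            raise ValidationError(
                f"count-table sample(s) missing from environment table: "
                f"{env_orphans}")
        aligned_env = env.loc[ids]
    return AlignedExperiment(table, meta.loc[ids], aligned_env)


def write_json(obj, path: str | Path) -> None:
    """Serialize a result object (dataclass/dict/DataFrame mix) to JSON."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="index")
        if isinstance(o, pd.Series):
            return o.to_dict()
        if hasattr(o, "__dataclass_fields__"):
            import dataclasses
            return dataclasses.asdict(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default))
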