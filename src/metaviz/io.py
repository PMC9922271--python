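"""Delimited-text file formats for embeddings, distance matrices, eigenscore
tables and run configuration.

All files are TSV (CSV is auto-detected on read).  Embedding files have a
header ``sample_id<TAB>x<TAB>y`` and one row per sample; matrix files carry
sample ids as both the first row and the first column; eigenscore tables have
samples as rows and candidate names as columns.  Floats are written with
enough digits to round-trip at 1e-12.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .core import AlignmentError, EigenscoreTable, EmbeddingSet, MetaDistance, \
    NormalizedDistanceMatrix

__all__ = [
    "RunConfig",
    "read_embedding",
    "read_embeddings",
    "write_embedding",
    "read_matrix",
    "write_matrix",
    "read_eigenscores",
    "write_eigenscores",
]

_FLOAT_FMT = "%.17g"


def _read_table(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, dtype={0: str})


def read_embedding(path) -> tuple[np.ndarray, np.ndarray]:
    """One embedding file -> (sample_ids, n x 2 coordinates)."""
    df = _read_table(path)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected sample_id plus two coordinate columns")
    ids = df.iloc[:, 0].to_numpy(dtype=object)
    try:
        coords = df.iloc[:, 1:3].astype(float).to_numpy()
    except ValueError as exc:
        for line, row in enumerate(df.itertuples(index=False), start=2):
            try:
                float(row[1]), float(row[2])
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: non-numeric coordinate on line {line}"
                ) from exc
        raise
    return ids, coords


def read_embeddings(paths: Sequence, names: Sequence[str] | None = None) -> EmbeddingSet:
    """Read several embedding files into an aligned EmbeddingSet.

    The first file fixes the canonical sample order; the others may list
    samples in any order but must contain exactly the same ids.
    """
    paths = list(paths)
    if names is None:
        names = [Path(p).stem for p in paths]
    embeddings = {}
    ref_ids = None
    for name, path in zip(names, paths):
        ids, coords = read_embedding(path)
        if ref_ids is None:
            ref_ids = ids
            embeddings[name] = coords
            continue
        missing = sorted(set(ref_ids) - set(ids))
        extra = sorted(set(ids) - set(ref_ids))
        if missing or extra:
            raise AlignmentError(
                f"{path}: sample ids do not match the first file"
                + (f"; missing: {missing}" if missing else "")
                + (f"; extra: {extra}" if extra else "")
            )
        pos = {s: j for j, s in enumerate(ids)}
        embeddings[name] = coords[[pos[s] for s in ref_ids]]
    return EmbeddingSet(embeddings, sample_ids=ref_ids)


def write_embedding(path, sample_ids, coordinates, columns=("x", "y")) -> None:
    df = pd.DataFrame(np.asarray(coordinates), columns=list(columns))
    df.insert(0, "sample_id", np.asarray(sample_ids, dtype=object))
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_matrix(path, matrix) -> None:
    """Write a (meta-)distance matrix with ids on both axes."""
    ids = matrix.sample_ids
    df = pd.DataFrame(matrix.values, index=ids, columns=ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_matrix(path, kind: str = "meta"):
    """Read a matrix file; kind='normalized' validates unit rows, kind='meta'
    accepts any nonnegative square matrix."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    ids = df.index.to_numpy(dtype=object).astype(str)
    values = df.to_numpy(dtype=float)
    if kind == "normalized":
        return NormalizedDistanceMatrix.from_values(values, ids)
    return MetaDistance(values, np.array(ids, dtype=object))


def write_eigenscores(path, table: EigenscoreTable) -> None:
    ids = table.sample_ids if table.sample_ids is not None else np.arange(table.n_samples)
    df = pd.DataFrame(table.values, index=pd.Index(ids, name="sample_id"),
                      columns=table.candidates)
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_eigenscores(path) -> EigenscoreTable:
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    return EigenscoreTable(df.to_numpy(dtype=float), list(df.columns),
                           df.index.to_numpy(dtype=object).astype(str))


@dataclass
class RunConfig:
    """Serializable configuration that re-runs a pipeline to identical
    outputs."""

    structure: str = "mixture"
    n: int = 900
    p: int = 500
    theta: float = 5.0
    seed: int = 0
    weighting: str = "spectral"
    render_method: str = "umap"
    render_params: dict = field(default_factory=dict)
    registry: list | None = None  # list of {name, method, params, seed}
    strict: bool = False
    out_dir: str = "."

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)
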