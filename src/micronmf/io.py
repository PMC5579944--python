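"""Reading and writing count tables, labels, matrices and provenance.

Count tables are delimited text (TSV by default): the first column holds
feature IDs (OTUs or reaction groups), the header row holds sample IDs,
and every cell must parse as a non-negative integer.  Labels come as a
two-column table mapping sample ID to class.  BIOM input is not
supported; convert BIOM tables to TSV first (``biom convert -i table.biom
-o table.tsv --to-tsv``).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ClassPartition, CountMatrix, TypeMatrix, WeightMatrix

__all__ = [
    "read_counts",
    "read_labels",
    "align_labels",
    "write_matrix",
    "write_provenance",
]


def _sep_for(path: Path, fmt: str | None) -> str:
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "tsv"
    if fmt not in ("tsv", "csv"):
        raise ValueError(f"unsupported format {fmt!r} (use 'tsv' or 'csv')")
    return "," if fmt == "csv" else "\t"


def read_counts(path, format: str | None = None) -> CountMatrix:
    """Read a feature-by-sample count table from TSV/CSV."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, format), index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty count table")
    values = df.to_numpy()
    try:
        values = values.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric entries in count table") from exc
    if np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise ValueError(
            f"{path}: negative count at feature {df.index[i]!r}, "
            f"sample {df.columns[j]!r}"
        )
    if not np.allclose(values, np.round(values)):
        i, j = np.argwhere(~np.isclose(values, np.round(values)))[0]
        raise ValueError(
            f"{path}: non-integer count at feature {df.index[i]!r}, "
            f"sample {df.columns[j]!r}"
        )
    return CountMatrix(values, list(df.index.astype(str)), list(df.columns.astype(str)))


def read_labels(path, format: str | None = None) -> pd.Series:
    """Read a sample-to-class table (two columns: sample ID, class)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, format))
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (sample ID, class)")
    series = pd.Series(
        df.iloc[:, 1].astype(str).to_numpy(), index=df.iloc[:, 0].astype(str)
    )
    dup = series.index[series.index.duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicated sample ID(s): {list(dup[:5])}")
    return series


def align_labels(X: CountMatrix, labels: pd.Series) -> ClassPartition:
    """Join labels onto the count matrix's sample order."""
    missing = [s for s in X.sample_ids if s not in labels.index]
    if missing:
        raise ValueError(f"sample(s) missing from labels: {missing[:10]}")
    return ClassPartition(labels.loc[X.sample_ids].to_numpy())


def write_matrix(obj, path, format: str | None = None) -> None:
    """Write a CountMatrix / TypeMatrix / WeightMatrix (or DataFrame) as
    labelled delimited text."""
    path = Path(path)
    if isinstance(obj, (CountMatrix, TypeMatrix, WeightMatrix)):
        df = obj.to_dataframe()
    elif isinstance(obj, pd.DataFrame):
        df = obj
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=_sep_for(path, format))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(out_dir, parameters: dict, seed: int | None,
                     input_paths=()) -> Path:
    """Record inputs (hashes), parameters, seed and package version."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = {
        "package": "micronmf",
        "version": __version__,
        "seed": seed,
        "parameters": parameters,
        "inputs": {str(p): _sha256(Path(p)) for p in input_paths},
    }
    dest = out_dir / "provenance.json"
    with open(dest, "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return dest
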