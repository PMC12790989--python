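"""Readers and writers for the plain-text formats used by the pipeline.

All genomic coordinates are 0-based half-open. Every writer/reader pair
round-trips losslessly; malformed lines fail with the line number.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def _check_coords(df: pd.DataFrame, path, chrom_sizes: dict[str, int] | None = None) -> None:
    bad = df.index[df["start"] > df["end"]]
    if len(bad):
        raise ValueError(f"{path}: start > end at line {int(bad[0]) + 1}")
    if chrom_sizes is not None:
        for rec in df.itertuples(index=True):
            size = chrom_sizes.get(rec.chrom)
            if size is not None and (rec.start < 0 or rec.end > size):
                raise ValueError(f"{path}: coordinates out of bounds at line {rec.Index + 1}")


def read_bed(path, chrom_sizes: dict[str, int] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    df.columns = BED6_COLS[: df.shape[1]]
    try:
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
    except (ValueError, TypeError) as err:
        raise ValueError(f"{path}: non-integer coordinates ({err})") from err
    _check_coords(df, path, chrom_sizes)
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in BED6_COLS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path, chrom_sizes: dict[str, int] | None = None) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"], dtype={"chrom": str},
    )
    if df[["start", "end", "value"]].isna().any().any():
        bad = int(df[["start", "end", "value"]].isna().any(axis=1).idxmax())
        raise ValueError(f"{path}: malformed bedGraph line {bad + 1}")
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    _check_coords(df, path, chrom_sizes)
    return df


def write_bedgraph(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end", "value"]].to_csv(path, sep="\t", header=False, index=False)


def read_tsv(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def write_mtx(df: pd.DataFrame, path) -> None:
    """MatrixMarket (text) matrix with .rows/.cols name sidecars."""
    path = Path(path)
    mat = sparse.csr_matrix(df.to_numpy())
    field = "integer" if np.issubdtype(df.to_numpy().dtype, np.integer) else "real"
    spio.mmwrite(str(path), mat, field=field)
    path.with_suffix(path.suffix + ".rows").write_text("\n".join(map(str, df.index)) + "\n")
    path.with_suffix(path.suffix + ".cols").write_text("\n".join(map(str, df.columns)) + "\n")


def read_mtx(path) -> pd.DataFrame:
    path = Path(path)
    mat = spio.mmread(str(path)).toarray()
    rows = path.with_suffix(path.suffix + ".rows").read_text().splitlines()
    cols = path.with_suffix(path.suffix + ".cols").read_text().splitlines()
    if mat.shape != (len(rows), len(cols)):
        raise ValueError(
            f"{path}: sidecar lengths ({len(rows)}, {len(cols)}) do not match matrix {mat.shape}"
        )
    return pd.DataFrame(mat, index=rows, columns=cols)


def read_guide_library(path) -> pd.DataFrame:
    lib = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"guide_id", "chrom", "start", "end", "is_control"}
    missing = required - set(lib.columns)
    if missing:
        raise ValueError(f"{path}: missing guide library columns {sorted(missing)}")
    lib["is_control"] = lib["is_control"].astype(bool)
    return lib


def sha256sum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
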