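"""Reading and writing count matrices and tables.

Matrices travel as MatrixMarket (``counts.mtx``) with ``genes.tsv`` and
``cells.tsv`` sidecars, or as a single genes×cells TSV; all tabular
outputs are TSV.  ``cells.tsv`` carries ``cell_id``, ``time_point``,
``replicate`` and ``total_reads``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .preprocess import CountMatrix

__all__ = [
    "write_count_matrix",
    "read_count_matrix",
    "write_tsv",
    "read_tsv",
    "write_json",
]


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")
    return path


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path


def write_count_matrix(m: CountMatrix, outdir: str | Path, stem: str = "counts") -> Path:
    """Write a CountMatrix as ``<stem>.mtx`` + ``genes.tsv`` + ``cells.tsv``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat = m.counts.to_numpy()
    if m.normalized:
        sp = sparse.coo_matrix(mat)
    else:
        sp = sparse.coo_matrix(mat.astype(np.int64))
    spio.mmwrite(outdir / f"{stem}.mtx", sp)
    write_tsv(pd.DataFrame({"gene": m.counts.index}), outdir / "genes.tsv")
    cells = m.cell_meta.reset_index().rename(columns={"index": "cell_id"})
    if "cell_id" not in cells.columns:
        cells = cells.rename(columns={cells.columns[0]: "cell_id"})
    write_tsv(cells, outdir / "cells.tsv")
    return outdir / f"{stem}.mtx"


def read_count_matrix(path: str | Path, stem: str = "counts") -> CountMatrix:
    """Read a CountMatrix from a directory (MTX + sidecars) or a single TSV.

    A TSV is genes×cells with gene IDs in the first column; cell metadata
    is then taken from a ``cells.tsv`` next to it if present, otherwise
    cells get placeholder time point/replicate 0.
    """
    path = Path(path)
    if path.is_dir():
        mtx = path / f"{stem}.mtx"
        genes = read_tsv(path / "genes.tsv")["gene"]
        cells = read_tsv(path / "cells.tsv").set_index("cell_id")
        mat = np.asarray(spio.mmread(mtx).todense())
        normalized = not np.issubdtype(mat.dtype, np.integer)
        counts = pd.DataFrame(mat, index=genes, columns=cells.index)
        return CountMatrix(counts=counts, cell_meta=cells, normalized=normalized)
    df = read_tsv(path, index_col=0)
    sidecar = path.parent / "cells.tsv"
    if sidecar.exists():
        cells = read_tsv(sidecar).set_index("cell_id").loc[df.columns]
    else:
        cells = pd.DataFrame(
            {"time_point": 0, "replicate": 0}, index=pd.Index(df.columns, name="cell_id")
        )
    return CountMatrix(counts=df, cell_meta=cells)
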