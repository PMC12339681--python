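"""Reading and writing the pipeline's table and image formats.

Tables are plain CSV with documented column names; count matrices are
MatrixMarket triplets with sidecar gene/well lists; images are multi-page
TIFF (one page per channel: nuclei, IBA1, pHrodo).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import io as spio
from scipy import sparse

__all__ = [
    "write_table",
    "read_table",
    "write_counts_mtx",
    "read_counts_mtx",
    "write_field_tiff",
    "read_field_tiff",
]

_FLOAT_FORMAT = "%.10g"  # fixed formatting keeps outputs byte-reproducible


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_counts_mtx(counts: pd.DataFrame, meta: pd.DataFrame, out_dir: str | Path) -> None:
    """Write a gene x well count matrix as ``counts.mtx`` + ``genes.txt`` +
    ``wells.csv`` (the well metadata table) under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(
        out / "counts.mtx",
        sparse.coo_matrix(counts.to_numpy()),
        comment="",
        field="integer",
    )
    (out / "genes.txt").write_text("\n".join(map(str, counts.index)) + "\n")
    write_table(meta, out / "wells.csv")


def read_counts_mtx(in_dir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    ind = Path(in_dir)
    mat = spio.mmread(ind / "counts.mtx").toarray().astype(np.int64)
    genes = (ind / "genes.txt").read_text().splitlines()
    meta = read_table(ind / "wells.csv")
    counts = pd.DataFrame(mat, index=genes, columns=meta["well"].tolist())
    counts.index.name = "gene"
    return counts, meta


def write_field_tiff(image: np.ndarray, path: str | Path) -> None:
    """Write a (3, H, W) float field image as a 3-page TIFF."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path, np.asarray(image, dtype=np.float32), photometric="minisblack"
    )


def read_field_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)
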