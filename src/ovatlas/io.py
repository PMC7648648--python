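"""Reading and writing the on-disk formats used by the pipeline.

Count matrices travel as 10x Genomics-style Matrix Market triplet
directories (``matrix.mtx`` in genes x cells orientation, ``features.tsv``
or ``genes.tsv``, ``barcodes.tsv``, optionally gzipped).  Ground-truth
labels produced by the simulator are a TSV sidecar.  All tabular outputs
are plain TSV with headers.
"""

from __future__ import annotations

import gzip
import os
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

TRUTH_COLUMNS = ["cell_id", "batch", "tier_path", "is_doublet", "t"]


def _open_maybe_gzip(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _find_variant(outdir: Path, stem: str) -> Path | None:
    """Return the first existing file among ``stem`` and its variants."""
    for name in (stem, stem + ".gz"):
        p = outdir / name
        if p.exists():
            return p
    return None


def write_10x_mtx(adata: ad.AnnData, outdir: str | os.PathLike, *, compress: bool = False) -> Path:
    """Write ``adata`` as a 10x Matrix Market triplet directory.

    The matrix is stored genes x cells with 1-based coordinates, as
    produced by Cell Ranger.  ``features.tsv`` carries gene id, gene name
    and the feature type column.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    suffix = ".gz" if compress else ""

    x = sp.csc_matrix(adata.X).T.astype(np.int64)  # genes x cells
    mtx_path = outdir / ("matrix.mtx" + suffix)
    if compress:
        with gzip.open(mtx_path, "wb") as fh:
            scipy.io.mmwrite(fh, x, field="integer")
    else:
        scipy.io.mmwrite(str(mtx_path), x, field="integer")

    feats = pd.DataFrame(
        {
            "gene_id": adata.var_names,
            "gene_name": adata.var_names,
            "feature_type": "Gene Expression",
        }
    )
    feats.to_csv(outdir / ("features.tsv" + suffix), sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(
        outdir / ("barcodes.tsv" + suffix), sep="\t", header=False, index=False
    )
    return outdir


def read_10x_mtx(indir: str | os.PathLike) -> ad.AnnData:
    """Read a 10x Matrix Market triplet directory into cells x genes AnnData.

    Accepts both the ``features.tsv`` (three-column) and legacy
    ``genes.tsv`` (two-column) dialects, gzipped or plain.
    """
    indir = Path(indir)
    mtx = _find_variant(indir, "matrix.mtx")
    if mtx is None:
        raise FileNotFoundError(f"no matrix.mtx(.gz) under {indir}")
    with _open_maybe_gzip(mtx, "rb") as fh:
        x = scipy.io.mmread(fh)
    x = sp.csr_matrix(x.T)  # cells x genes

    feat_path = _find_variant(indir, "features.tsv") or _find_variant(indir, "genes.tsv")
    if feat_path is None:
        raise FileNotFoundError(f"no features.tsv/genes.tsv under {indir}")
    feats = pd.read_csv(feat_path, sep="\t", header=None)
    gene_ids = feats.iloc[:, 0].astype(str)

    bc_path = _find_variant(indir, "barcodes.tsv")
    if bc_path is None:
        raise FileNotFoundError(f"no barcodes.tsv under {indir}")
    barcodes = pd.read_csv(bc_path, sep="\t", header=None).iloc[:, 0].astype(str)

    if x.shape != (len(barcodes), len(gene_ids)):
        raise ValueError(
            f"matrix shape {x.shape} does not match {len(barcodes)} barcodes x {len(gene_ids)} features"
        )
    adata = ad.AnnData(
        X=x,
        obs=pd.DataFrame(index=pd.Index(barcodes, name="cell_id")),
        var=pd.DataFrame(index=pd.Index(gene_ids, name="gene_id")),
    )
    if feats.shape[1] >= 2:
        adata.var["gene_name"] = feats.iloc[:, 1].astype(str).values
    return adata


def write_truth(adata: ad.AnnData, path: str | os.PathLike) -> Path:
    """Write the simulator's ground-truth sidecar TSV."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "cell_id": adata.obs_names,
            "batch": adata.obs["batch"].astype(str).values,
            "tier_path": adata.obs["tier_path"].astype(str).values,
            "is_doublet": adata.obs["is_doublet"].astype(bool).values,
            "t": adata.obs["t"].values,
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def read_truth(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(TRUTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"truth sidecar missing columns: {sorted(missing)}")
    return df.set_index("cell_id")


def attach_truth(adata: ad.AnnData, truth: pd.DataFrame) -> ad.AnnData:
    """Join a truth sidecar onto ``adata.obs`` by cell id."""
    truth = truth.reindex(adata.obs_names)
    for col in ("batch", "tier_path", "is_doublet", "t"):
        adata.obs[col] = truth[col].values
    adata.obs["is_doublet"] = adata.obs["is_doublet"].fillna(False).astype(bool)
    return adata


def write_embedding(coords: np.ndarray, cell_ids, path: str | os.PathLike) -> Path:
    path = Path(path)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    df = pd.DataFrame(coords, columns=cols)
    df.insert(0, "cell_id", list(cell_ids))
    df.to_csv(path, sep="\t", index=False)
    return path


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | os.PathLike, *, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
    return path
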