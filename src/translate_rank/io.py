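"""Readers and writers for the pipeline's on-disk formats.

Tabular formats are plain TSV/CSV; single-cell matrices use the 10x triplet
dialect (matrix.mtx + barcodes.tsv + features.tsv, 1-based MatrixMarket
indices); gene sets use GMT. All writers emit a ``#`` provenance comment
header recording the tool version and parameters, which every reader here
skips. Gene identifiers are opaque, case-sensitive strings. Write/read
round-trips are lossless on valid files; malformed files raise errors
naming the offending line.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from scipy import io as scio
from scipy import sparse

from . import __version__
from .calcium_quant import TraceSet
from .enrichment import GeneSetCollection
from .polysome_rank import CountMatrix


def _provenance(params: dict | None = None) -> str:
    extra = "" if not params else " " + " ".join(
        f"{k}={v}" for k, v in sorted(params.items()))
    return f"# translate-rank v{__version__}{extra}\n"


def write_table(df: pd.DataFrame, path, params: dict | None = None,
                index: bool = True, sep: str = "\t") -> None:
    """Write a TSV with a provenance comment header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_provenance(params))
        df.to_csv(fh, sep=sep, index=index)


def read_table(path, sep: str = "\t", index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#", index_col=index_col)


# --- counts + design -------------------------------------------------------


def write_count_matrix(cm: CountMatrix, counts_path, design_path) -> None:
    write_table(cm.counts.rename_axis("gene"), counts_path)
    write_table(cm.samples.rename_axis("sample"), design_path)


def read_count_matrix(counts_path, design_path) -> CountMatrix:
    counts = read_table(counts_path)
    if counts.index.duplicated().any():
        dup = counts.index[counts.index.duplicated()][0]
        raise ValueError(f"duplicated gene identifier in counts: {dup!r}")
    arr = counts.to_numpy()
    if not np.allclose(arr, np.rint(arr)):
        raise ValueError("count matrix contains non-integer values")
    counts = counts.astype(np.int64)
    samples = read_table(design_path)
    samples["replicate"] = samples["replicate"].astype(int)
    return CountMatrix(counts=counts, samples=samples)


# --- ranked lists / results ------------------------------------------------


def write_ranked_list(ranked: pd.Series, path, metric_kind: str = "metric",
                      params: dict | None = None) -> None:
    df = ranked.rename(metric_kind).rename_axis("gene").to_frame()
    write_table(df, path, params=params)


def read_ranked_list(path) -> pd.Series:
    df = read_table(path)
    return df.iloc[:, 0]


# --- GMT -------------------------------------------------------------------


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: name <tab> description <tab> gene [<tab> gene ...]."""
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, "
                    "expected at least 3 (name, description, genes)")
            name = fields[0]
            if name in coll:
                raise ValueError(f"{path}:{lineno}: duplicate set {name!r}")
            coll[name] = frozenset(g for g in fields[2:] if g)
    return coll


def write_gmt(coll: GeneSetCollection, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in coll:
            genes = "\t".join(sorted(coll[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


# --- 10x-style MTX triplet -------------------------------------------------


def write_mtx_dir(adata: ad.AnnData, outdir) -> None:
    """Write cells x genes AnnData as matrix.mtx (genes x cells, 1-based),
    barcodes.tsv and features.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X
    if not sparse.issparse(X):
        X = sparse.csr_matrix(X)
    scio.mmwrite(outdir / "matrix.mtx", X.T.astype(np.int64),
                 field="integer")
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", index=False,
                                      header=False)
    pd.Series(adata.var_names).to_csv(outdir / "features.tsv", index=False,
                                      header=False)


def read_mtx_dir(indir) -> ad.AnnData:
    indir = Path(indir)
    mat = scio.mmread(indir / "matrix.mtx").T.tocsr()
    barcodes = pd.read_csv(indir / "barcodes.tsv", header=None)[0].astype(str)
    features = pd.read_csv(indir / "features.tsv", header=None)[0].astype(str)
    if mat.shape != (len(barcodes), len(features)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match barcodes/features "
            f"({len(barcodes)}, {len(features)})")
    return ad.AnnData(X=mat.astype(np.int64),
                      obs=pd.DataFrame(index=barcodes),
                      var=pd.DataFrame(index=features))


# --- calcium traces --------------------------------------------------------


def write_traces(ts: TraceSet, traces_path, schedule_path) -> None:
    write_table(ts.traces.rename_axis("time"), traces_path, sep=",")
    sched = pd.DataFrame(ts.schedule, columns=["label", "time"])
    write_table(sched, schedule_path, sep=",", index=False)


def read_traces(traces_path, schedule_path) -> TraceSet:
    traces = pd.read_csv(traces_path, comment="#", index_col=0)
    traces.index = traces.index.astype(float)
    sched_df = pd.read_csv(schedule_path, comment="#")
    schedule = [(str(r.label), float(r.time)) for r in sched_df.itertuples()]
    return TraceSet(traces=traces, schedule=schedule)


# --- MIDs ------------------------------------------------------------------


def read_mids(path) -> pd.DataFrame:
    """MID CSV: one row per compound, columns compound, m0, m1, ..."""
    df = pd.read_csv(path, comment="#", index_col=0)
    if df.index.duplicated().any():
        raise ValueError("duplicate compound names in MID file")
    return df


def write_mids(df: pd.DataFrame, path, params: dict | None = None) -> None:
    write_table(df.rename_axis("compound"), path, params=params, sep=",")


# --- images ----------------------------------------------------------------


def read_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        return tifffile.imread(path)
    return iio.imread(path)


def write_image(image: np.ndarray, path) -> None:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, image)
    else:
        iio.imwrite(path, image)


def read_mask(path) -> np.ndarray:
    """Single-channel image, nonzero = true."""
    img = read_image(path)
    if img.ndim == 3:
        img = img[..., 0]
    return img > 0


# --- results/JSON ----------------------------------------------------------


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


# --- microarray probe handling --------------------------------------------


def collapse_probes(expression: pd.DataFrame, annotation) -> pd.DataFrame:
    """Collapse a probe x sample matrix to one row per gene symbol.

    Probes with undefined symbols (missing, empty, NaN) or ambiguous
    assignments (multiple genes, e.g. ``"A /// B"``) are dropped; among
    probes sharing a symbol, only the probe with the highest total
    expression across samples is kept.
    """
    ann = pd.Series(annotation)
    symbols = ann.reindex(expression.index)
    defined = symbols.notna() & (symbols.astype(str).str.strip() != "")
    unambiguous = ~symbols.astype(str).str.contains("///", regex=False)
    keep = expression.index[defined & unambiguous]
    if len(keep) == 0:
        raise ValueError("no probe with a defined, unambiguous gene symbol")
    sub = expression.loc[keep]
    sym = symbols.loc[keep].astype(str).str.strip()
    totals = sub.sum(axis=1)
    best = (pd.DataFrame({"symbol": sym, "total": totals})
            .sort_values(["symbol", "total"], ascending=[True, False],
                         kind="stable")
            .drop_duplicates("symbol"))
    out = sub.loc[best.index]
    out.index = best["symbol"].to_numpy()
    out = out.sort_index()
    out.index.name = "gene"
    return out
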