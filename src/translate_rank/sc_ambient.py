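"""Ambient-RNA correction, QC, HVG selection and DE ranking for droplet scRNA-seq.

Droplet libraries contain "soup": cell-free transcripts shared across all
droplets of a sample, mixed into each cell at some contamination fraction
rho. The soup expression profile b_g is estimated from sub-threshold (empty)
barcodes; a global rho is estimated from genes whose cell-level expression
is explainable by the soup alone. Two adjustments are then applied before
subtraction:

* the automatically estimated global fraction is doubled (rho_adj =
  2 * rho_auto), compensating the known tendency of automatic estimators to
  underestimate contamination; and
* rather than one fixed fraction for every cell, each cell's fraction is
  adapted to its library size, rho_c = rho_adj * mean(N) / N_c (capped at
  ``rho_max``), the unique rule that makes the expected number of subtracted
  counts uniform across cells.

Subtraction itself is deterministic: round the expected soup counts
rho_c * N_c * b_g per gene, cap at the observed counts, and redistribute any
per-cell shortfall proportionally to the soup profile over genes that still
have counts. Downstream, cells are QC-filtered on mitochondrial fraction
(<= 10%), library size (>= 800 UMIs) and detected genes (>= 200); highly
variable genes are the top 1000 by within-bin dispersion z-score among genes
with mean normalized expression above 0.01; and condition comparisons are
ranked by RM_adj = -log2FC * log10(p) * X_max, where p comes from a
Wilcoxon rank-sum test and X_max is the larger expressing-cell fraction of
the two groups.

Matrices are :class:`anndata.AnnData` (cells x genes).
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats

from .polysome_rank import ranking_metric, ranked_list


def _dense(adata: ad.AnnData) -> np.ndarray:
    X = adata.X
    if sparse.issparse(X):
        return np.asarray(X.todense(), dtype=float)
    return np.asarray(X, dtype=float)


@dataclass
class SoupModel:
    """Ambient-RNA model: per-gene soup profile and contamination fractions.

    ``profile`` sums to 1 over genes; ``rho_adj`` is the doubled automatic
    estimate used for subtraction.
    """

    profile: pd.Series
    rho_auto: float
    adjust_factor: float = 2.0

    def __post_init__(self) -> None:
        if abs(float(self.profile.sum()) - 1.0) > 1e-9:
            raise ValueError("soup profile must sum to 1")
        if not 0.0 <= self.rho_auto < 1.0:
            raise ValueError("rho_auto must be in [0, 1)")

    @property
    def rho_adj(self) -> float:
        return self.adjust_factor * self.rho_auto


def estimate_soup_profile(raw: ad.AnnData, empty_umi_max: int = 100,
                          cell_quantile: float = 0.10) -> SoupModel:
    """Estimate the soup profile and global contamination from a raw matrix.

    Barcodes with total UMIs <= ``empty_umi_max`` are treated as empty
    droplets containing pure soup; their summed counts define the profile.
    The contamination fraction is estimated on "soup-explainable" genes -
    genes whose pseudo-bulk expression fraction across real cells does not
    exceed their soup fraction, i.e. genes with no evidence of endogenous
    expression. Each cell yields a Poisson MLE of its contamination from
    those genes; rho_auto is a low quantile (``cell_quantile``) of the
    per-cell estimates rather than their mean, because a candidate gene
    genuinely expressed in some cells inflates those cells' estimates and a
    robust lower envelope must not mistake expression for soup. This
    deliberate conservatism makes automatic estimates run low - the
    documented behavior that the downstream factor-of-2 adjustment
    compensates.
    """
    totals = np.asarray(raw.X.sum(axis=1)).ravel()
    empty = totals <= empty_umi_max
    cells = ~empty
    if not np.any(empty):
        raise ValueError(
            "no barcodes at or below empty_umi_max; supply a soup profile "
            "directly via SoupModel")
    soup_counts = np.asarray(raw.X[empty].sum(axis=0)).ravel()
    soup_total = soup_counts.sum()
    if soup_total == 0:
        raise ValueError("empty barcodes contain zero counts")
    profile = pd.Series(soup_counts / soup_total, index=raw.var_names)
    if not np.any(cells):
        raise ValueError("no cell barcodes above empty_umi_max")
    cell_counts = np.asarray(raw.X[cells].sum(axis=0)).ravel()
    cell_total = cell_counts.sum()
    f = cell_counts / cell_total  # pseudo-bulk expression fractions
    b = profile.to_numpy()
    explainable = (b > 0) & (f <= b)
    if not np.any(explainable):
        rho_auto = 0.0
    else:
        # per cell: counts_gc ~ Poisson(rho_c * N_c * b_g) on explainable genes
        X_cells = _dense(raw[cells])
        n_c = X_cells.sum(axis=1)
        b_mass = b[explainable].sum()
        with np.errstate(invalid="ignore", divide="ignore"):
            rho_cells = X_cells[:, explainable].sum(axis=1) / (n_c * b_mass)
        rho_cells = rho_cells[np.isfinite(rho_cells)]
        rho_auto = float(np.quantile(rho_cells, cell_quantile))
        rho_auto = min(max(rho_auto, 0.0), 1.0 - 1e-9)
    return SoupModel(profile=profile, rho_auto=rho_auto)


def correct_ambient(cells: ad.AnnData, soup: SoupModel, rho_max: float = 0.5,
                    max_redistribute: int = 10) -> tuple[ad.AnnData, pd.Series]:
    """Subtract ambient counts with per-cell adapted contamination fractions.

    The target subtracted total is S = rho_adj * mean(N) for every cell;
    rho_c = min(rho_max, S / N_c). Expected soup counts rho_c * N_c * b_g
    are rounded, capped at the observed counts, and any shortfall is
    redistributed proportionally to the soup profile over genes with
    remaining counts (at most ``max_redistribute`` passes). Output counts
    are non-negative integers <= the input.

    Returns the corrected matrix and the per-cell subtracted totals.
    """
    X = _dense(cells)
    n_c = X.sum(axis=1)
    mean_n = n_c.mean()
    if mean_n == 0:
        raise ValueError("mean library size is zero")
    b = soup.profile.reindex(cells.var_names).fillna(0.0).to_numpy()
    target_total = soup.rho_adj * mean_n
    rho_c = np.minimum(rho_max, np.divide(target_total, n_c,
                                          out=np.zeros_like(n_c),
                                          where=n_c > 0))
    out = X.copy()
    removed_totals = np.zeros(len(n_c))
    for c in range(X.shape[0]):
        target = int(round(rho_c[c] * n_c[c]))
        if target <= 0:
            continue
        # largest-remainder apportionment: floor the expected counts, then
        # top up one count per gene in order of fractional remainder, so the
        # per-gene removal tracks e_gc within one count and the per-cell
        # total hits the target exactly when counts suffice
        expected = rho_c[c] * n_c[c] * b
        take = np.minimum(np.floor(expected), out[c])
        out[c] -= take
        removed = int(take.sum())
        shortfall = target - removed
        if shortfall > 0:
            frac = np.where(out[c] > 0, expected - np.floor(expected), -1.0)
            order = np.argsort(-frac)
            top = order[:shortfall][frac[order[:shortfall]] > 0]
            out[c, top] -= 1
            removed += top.size
        for _ in range(max_redistribute):
            shortfall = target - removed
            if shortfall <= 0:
                break
            elig = (out[c] > 0) & (b > 0)
            if not np.any(elig):
                break
            w = b * elig
            alloc = np.floor(shortfall * w / w.sum())
            if alloc.sum() == 0:  # largest-remainder top-up
                frac = shortfall * w / w.sum()
                order = np.argsort(-frac)
                alloc[order[:shortfall]] += 1
            take = np.minimum(alloc, out[c])
            out[c] -= take
            removed += int(take.sum())
        removed_totals[c] = removed
    corrected = ad.AnnData(
        X=sparse.csr_matrix(out.astype(np.int64)),
        obs=cells.obs.copy(), var=cells.var.copy())
    return corrected, pd.Series(removed_totals, index=cells.obs_names,
                                name="subtracted_total")


@dataclass
class CellQC:
    """Per-cell QC metrics and pass/fail flags for each criterion."""

    metrics: pd.DataFrame  # total_umi, n_genes, mito_fraction, pass_* flags

    @property
    def kept(self) -> pd.Index:
        return self.metrics.index[self.metrics["pass"]]


def qc_filter(cells: ad.AnnData, mito_genes, min_umi: int = 800,
              min_genes: int = 200,
              max_mito: float = 0.10) -> tuple[ad.AnnData, CellQC]:
    """Standard droplet QC: keep cells with mito fraction <= 10%, at least
    800 total UMIs and at least 200 detected genes; drop genes expressed in
    no remaining cell. Idempotent."""
    X = _dense(cells)
    totals = X.sum(axis=1)
    n_genes = (X > 0).sum(axis=1)
    mito_mask = cells.var_names.isin(set(mito_genes))
    with np.errstate(invalid="ignore"):
        mito_frac = np.divide(X[:, mito_mask].sum(axis=1), totals,
                              out=np.zeros_like(totals), where=totals > 0)
    metrics = pd.DataFrame({
        "total_umi": totals.astype(int),
        "n_genes": n_genes.astype(int),
        "mito_fraction": mito_frac,
    }, index=cells.obs_names)
    metrics["pass_umi"] = metrics["total_umi"] >= min_umi
    metrics["pass_genes"] = metrics["n_genes"] >= min_genes
    metrics["pass_mito"] = metrics["mito_fraction"] <= max_mito
    metrics["pass"] = (metrics["pass_umi"] & metrics["pass_genes"]
                       & metrics["pass_mito"])
    keep_cells = metrics["pass"].to_numpy()
    if not keep_cells.any():
        import warnings
        warnings.warn("no cell passed QC", RuntimeWarning, stacklevel=2)
    sub = X[keep_cells]
    keep_genes = sub.sum(axis=0) > 0
    filtered = ad.AnnData(
        X=sparse.csr_matrix(sub[:, keep_genes].astype(np.int64)),
        obs=cells.obs.loc[keep_cells].copy(),
        var=cells.var.loc[keep_genes].copy())
    return filtered, CellQC(metrics=metrics)


def _normalize(X: np.ndarray, scale: float | None = None) -> np.ndarray:
    """Per-cell scaling to a common total (default: median library size)."""
    totals = X.sum(axis=1)
    if scale is None:
        scale = float(np.median(totals[totals > 0]))
    factors = np.divide(scale, totals, out=np.zeros_like(totals),
                        where=totals > 0)
    return X * factors[:, None]


def select_hvgs(cells: ad.AnnData, exclusion_lists=(), n: int = 1000,
                min_expr: float = 0.01, n_bins: int = 20) -> list[str]:
    """Highly variable genes by departure from the dispersion-vs-mean trend.

    Counts are size-factor normalized (equal per-cell totals); per-gene
    dispersion = variance/mean; genes are placed in ``n_bins``
    equal-occupancy bins of mean expression and the within-bin z-score of
    dispersion is the departure. Genes in any exclusion list (mitochondrial,
    ribosomal, cell-cycle) or with mean normalized expression <= ``min_expr``
    are never selected. Returns the top ``n`` gene names by departure.
    """
    X = _normalize(_dense(cells))
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1)
    excluded = set()
    for lst in exclusion_lists:
        excluded |= set(lst)
    eligible = (mean > min_expr) & ~cells.var_names.isin(excluded)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, np.nan)
    df = pd.DataFrame({"mean": mean, "disp": disp},
                      index=cells.var_names)[eligible]
    if df.empty:
        import warnings
        warnings.warn("no eligible genes for HVG selection", RuntimeWarning,
                      stacklevel=2)
        return []
    bins = pd.qcut(df["mean"].rank(method="first"),
                   q=min(n_bins, len(df)), labels=False, duplicates="drop")
    z = df.groupby(bins)["disp"].transform(
        lambda d: (d - d.mean()) / d.std(ddof=1) if d.std(ddof=1) > 0
        else d * 0.0)
    df["departure"] = z.fillna(0.0)
    if len(df) < n:
        import warnings
        warnings.warn(f"only {len(df)} eligible genes (< {n}); returning all",
                      RuntimeWarning, stacklevel=2)
    ranked = df.sort_index().sort_values("departure", ascending=False,
                                         kind="stable")
    return list(ranked.index[:n])


def de_rank_adjusted(cells: ad.AnnData, group_a, group_b,
                     scale: float | None = None,
                     eps: float = 1e-9) -> pd.Series:
    """RM_adj-ranked differential expression between two cell groups.

    Per gene: two-sided Wilcoxon rank-sum p on log1p size-factor-normalized
    expression; log2FC = log2((mean_a + eps)/(mean_b + eps)) of normalized
    (de-logged) expression; X_max = larger fraction of expressing cells;
    metric = -log2FC * log10(p) * X_max. Returns a descending ranked Series.
    """
    a_idx = cells.obs_names.get_indexer(pd.Index(group_a))
    b_idx = cells.obs_names.get_indexer(pd.Index(group_b))
    if np.any(a_idx < 0) or np.any(b_idx < 0):
        raise KeyError("unknown cell identifiers in group")
    if set(group_a) & set(group_b):
        raise ValueError("cell groups overlap")
    if len(a_idx) == 0 or len(b_idx) == 0:
        raise ValueError("both groups must be non-empty")
    X = _dense(cells)
    norm = _normalize(X, scale=scale)
    logn = np.log1p(norm)
    la, lb = logn[a_idx], logn[b_idx]
    with np.errstate(invalid="ignore"):
        res = stats.mannwhitneyu(la, lb, axis=0, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    p = np.clip(p, 1e-300, 1.0)
    mean_a = norm[a_idx].mean(axis=0)
    mean_b = norm[b_idx].mean(axis=0)
    log2fc = np.log2((mean_a + eps) / (mean_b + eps))
    frac_a = (X[a_idx] > 0).mean(axis=0)
    frac_b = (X[b_idx] > 0).mean(axis=0)
    x_max = np.maximum(frac_a, frac_b)
    metric = ranking_metric(log2fc, p, x_max)
    return ranked_list(cells.var_names, metric)
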