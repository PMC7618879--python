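"""Differential-translation analysis of paired polysome-profiling counts.

Matched polysomal (>3 ribosomes) and sub-polysomal (<3 ribosomes) RNA-seq
fractions from the same spheroid pellet are modelled per gene with a
negative-binomial GLM (log link)

    log mu = log(sf) + condition + condition:replicate + condition:fraction

with the sub-polysomal fraction as the reference level, so the
condition:fraction coefficient of each condition is the average log2
polysomal/sub-polysomal fold change for that condition, i.e. a per-condition
translation-efficiency estimate that accounts for replicate pairing.
Differences of these coefficients between a reference condition (e.g.
aspartate + scramble shRNA) and another condition measure how a perturbation
shifts translation; they are stabilized by adaptive shrinkage and combined
with their Wald p-values into ranking metrics:

    TRM    = -Delta_log2FC * log10(p)          (translation, shrunken delta)
    RM     = -log2FC * log10(p)                (total RNA)
    RM_adj = -log2FC * log10(p) * X_max        (single cell; see sc_ambient)

Because the design is interaction-only, the full model is block-diagonal
across conditions: each condition block (intercept + replicate + fraction)
is fitted independently, which justifies the independent-SE contrast
formula SE = sqrt(SE_ref^2 + SE_other^2).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

LN2 = math.log(2.0)

SUBPOLYSOMAL = "subpolysomal"
POLYSOMAL = "polysomal"
FRACTIONS = (SUBPOLYSOMAL, POLYSOMAL)

P_FLOOR_DEFAULT = 1e-300


class DesignError(ValueError):
    """Sample metadata does not describe a valid (paired) design."""


@dataclass
class CountMatrix:
    """Integer gene x sample counts plus per-sample metadata.

    ``samples`` is indexed by sample id and carries columns ``condition``,
    ``replicate`` and (for fractionated data) ``fraction``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicated gene identifiers in count matrix")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise DesignError(f"samples missing metadata: {sorted(missing)[:5]}")
        self.samples = self.samples.loc[self.counts.columns]

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def conditions(self) -> list[str]:
        return sorted(self.samples["condition"].unique())

    def n_replicates(self) -> int:
        return int(self.samples.groupby("condition")["replicate"].nunique().max())


def _check_paired(samples: pd.DataFrame) -> None:
    if "fraction" not in samples.columns:
        raise DesignError("paired design requires a 'fraction' column")
    bad = set(samples["fraction"]) - set(FRACTIONS)
    if bad:
        raise DesignError(f"unknown fraction labels: {sorted(bad)}")
    counts = samples.groupby(["condition", "replicate"])["fraction"].agg(
        lambda f: tuple(sorted(f)))
    for key, fracs in counts.items():
        if fracs != tuple(sorted(FRACTIONS)):
            raise DesignError(
                f"condition/replicate {key} lacks exactly one sample per fraction")


def filter_low_expression(cm: CountMatrix, mode: str = "polysome") -> CountMatrix:
    """Drop genes with too many zero counts in any sample group.

    ``polysome`` mode drops a gene when any condition x fraction group has
    zeros in at least ceil(3R/4) of its R replicates (3-of-4 at R=4).
    ``total`` mode pools fractions within each (condition, replicate) and
    drops a gene when any condition has at least ceil(R/2) zero replicates
    (2-of-4 at R=4). Idempotent; the sample set is unchanged.
    """
    counts, samples = cm.counts, cm.samples
    if mode == "polysome":
        if "fraction" not in samples.columns:
            raise DesignError("polysome mode requires fraction metadata")
        groups = samples.groupby(["condition", "fraction"], sort=False)
        frac_num, frac_den = 3, 4
        per_rep = counts
        group_cols = {key: list(idx) for key, idx in groups.groups.items()}
    elif mode == "total":
        # pool fractions (if any) per replicate, then group by condition
        key = list(zip(samples["condition"], samples["replicate"]))
        per_rep = counts.T.groupby(pd.MultiIndex.from_tuples(
            key, names=["condition", "replicate"])).sum().T
        group_cols = {
            cond: [c for c in per_rep.columns if c[0] == cond]
            for cond in samples["condition"].unique()}
        frac_num, frac_den = 1, 2
    else:
        raise ValueError(f"unknown filter mode: {mode!r}")

    keep = pd.Series(True, index=counts.index)
    for key, cols in group_cols.items():
        if not cols:
            raise DesignError(f"empty sample group: {key}")
        r = len(cols)
        threshold = math.ceil(frac_num * r / frac_den)
        n_zero = (per_rep[cols] == 0).sum(axis=1)
        keep &= n_zero < threshold
    return CountMatrix(counts.loc[keep], samples.copy())


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (pseudo-reference = geometric mean)."""
    log_counts = np.log(counts.where(counts > 0))
    log_ref = log_counts.mean(axis=1)
    usable = log_ref.notna() & np.isfinite(log_ref)
    if usable.sum() == 0:
        raise ValueError("no gene has positive counts in all samples")
    ratios = log_counts.loc[usable].sub(log_ref.loc[usable], axis=0)
    sf = np.exp(ratios.median(axis=0))
    if not np.all(np.isfinite(sf)) or np.any(sf <= 0):
        raise ValueError("degenerate size factors")
    return sf


# ---------------------------------------------------------------------------
# Negative-binomial IRLS, vectorized over genes


def _irls_nb(y: np.ndarray, X: np.ndarray, offset: np.ndarray,
             alpha: np.ndarray, max_iter: int = 50,
             tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit ``log mu = X beta + offset`` per gene with NB variance mu+alpha*mu^2.

    y: (G, n) counts; X: (n, p); offset: (n,); alpha: (G,).
    Returns (beta (G, p), se (G, p), converged (G,)) in natural-log units.
    """
    G, n = y.shape
    p = X.shape[1]
    mu = y + 0.5
    eta = np.log(mu) - offset
    beta = np.zeros((G, p))
    converged = np.zeros(G, dtype=bool)
    alpha = alpha[:, None]
    for _ in range(max_iter):
        mu = np.exp(eta + offset)
        W = mu / (1.0 + alpha * mu)
        z = eta + (y - mu) / mu
        XtWX = np.einsum("ni,gn,nj->gij", X, W, X, optimize=True)
        XtWz = np.einsum("ni,gn,gn->gi", X, W, z, optimize=True)
        try:
            new_beta = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        except np.linalg.LinAlgError as exc:  # rank-deficient design
            raise DesignError("rank-deficient design matrix") from exc
        delta = np.max(np.abs(new_beta - beta), axis=1)
        beta = new_beta
        eta = beta @ X.T
        newly = delta < tol
        if np.all(newly):
            converged[:] = True
            break
        converged = newly
    mu = np.exp(beta @ X.T + offset)
    W = mu / (1.0 + alpha * mu)
    XtWX = np.einsum("ni,gn,nj->gij", X, W, X, optimize=True)
    cov = np.linalg.inv(XtWX)
    se = np.sqrt(np.maximum(np.diagonal(cov, axis1=1, axis2=2), 0.0))
    return beta, se, converged


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    if alpha <= 0:
        return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))
    inv = 1.0 / alpha
    return float(np.sum(
        gammaln(y + inv) - gammaln(inv) - gammaln(y + 1)
        + y * np.log(alpha * mu / (1 + alpha * mu))
        - inv * np.log1p(alpha * mu)))


def _moments_dispersion(counts: pd.DataFrame, samples: pd.DataFrame,
                        sf: pd.Series, floor: float) -> np.ndarray:
    """Method-of-moments alpha pooled over condition (x fraction) groups."""
    group_keys = (["condition"]
                  + (["fraction"] if "fraction" in samples.columns else []))
    norm = counts / sf
    num = np.zeros(len(counts))
    den = np.zeros(len(counts))
    for _, idx in samples.groupby(group_keys).groups.items():
        cols = list(idx)
        if len(cols) < 2:
            continue
        sub = norm[cols].to_numpy()
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        df = len(cols) - 1
        num += df * (v - m)
        den += df * m ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(den > 0, num / den, floor)
    return np.clip(alpha, floor, 10.0)


def estimate_dispersions(counts: pd.DataFrame, samples: pd.DataFrame,
                         sf: pd.Series, floor: float = 1e-8,
                         refine: bool = True,
                         design_blocks: list | None = None) -> pd.Series:
    """Per-gene NB dispersion: method-of-moments plus per-gene ML refinement.

    Moments are pooled across all condition x fraction replicate groups of
    normalized counts. The refinement maximizes the Cox-Reid adjusted
    profile likelihood in alpha on a log grid (with quadratic interpolation
    around the maximum), penalizing for the mean parameters of the actual
    fitted design; ``design_blocks`` is a list of (X, sample_columns)
    per independently fitted block and defaults to one intercept-only block
    per condition x fraction group. No dispersion trend or empirical-Bayes
    moderation is applied.
    """
    alpha0 = _moments_dispersion(counts, samples, sf, floor)
    disp = pd.Series(alpha0, index=counts.index)
    if not refine:
        return disp

    if design_blocks is None:
        group_keys = (["condition"]
                      + (["fraction"] if "fraction" in samples.columns else []))
        design_blocks = [(np.ones((len(idx), 1)), list(idx))
                         for _, idx in samples.groupby(group_keys).groups.items()]

    y = counts.to_numpy(dtype=float)
    sf_arr = sf.to_numpy()
    G = len(counts)
    # fitted means per block at the moments dispersion
    mu_hat = np.zeros_like(y)
    for X, cols in design_blocks:
        j = np.array([counts.columns.get_loc(c) for c in cols])
        beta, _, _ = _irls_nb(y[:, j], X, np.log(sf_arr[j]), alpha0,
                              max_iter=25)
        mu_hat[:, j] = np.exp(beta @ X.T + np.log(sf_arr[j]))
    mu_hat = np.maximum(mu_hat, 1e-8)

    grid = np.exp(np.linspace(math.log(max(floor, 1e-4)), math.log(10.0), 41))
    obj = np.empty((grid.size, G))
    inv_all = 1.0 / grid
    for k, a in enumerate(grid):
        inv = inv_all[k]
        ll = np.sum(
            gammaln(y + inv) - gammaln(inv) - gammaln(y + 1)
            + y * np.log(a * mu_hat / (1 + a * mu_hat))
            - inv * np.log1p(a * mu_hat), axis=1)
        adj = np.zeros(G)
        W = mu_hat / (1.0 + a * mu_hat)
        for X, cols in design_blocks:
            j = np.array([counts.columns.get_loc(c) for c in cols])
            XtWX = np.einsum("ni,gn,nj->gij", X, W[:, j], X, optimize=True)
            adj += np.linalg.slogdet(XtWX)[1]
        obj[k] = ll - 0.5 * adj
    best = np.argmax(obj, axis=0)
    log_a = np.log(grid[best])
    # quadratic interpolation on the log-alpha grid where interior
    interior = (best > 0) & (best < grid.size - 1)
    idx = np.flatnonzero(interior)
    b = best[idx]
    f0, f1, f2 = obj[b - 1, idx], obj[b, idx], obj[b + 1, idx]
    h = np.log(grid[1]) - np.log(grid[0])
    denom = f0 - 2 * f1 + f2
    shift = np.where(denom < 0, 0.5 * h * (f0 - f2) / denom, 0.0)
    log_a[idx] += np.clip(shift, -h, h)
    return pd.Series(np.clip(np.exp(log_a), floor, 10.0), index=counts.index)


@dataclass
class EffectTable:
    """Per-gene fraction log2 fold changes and contrasts between conditions.

    ``log2fc``/``se`` are gene x condition frames of the condition:fraction
    coefficient (polysomal vs sub-polysomal, log2 units) and its Wald SE.
    ``contrasts`` maps ``"ref_vs_other"`` to a frame with columns
    ``delta_log2fc``, ``se``, ``pvalue`` and (after shrinkage) ``shrunken``.
    """

    log2fc: pd.DataFrame
    se: pd.DataFrame
    dispersion: pd.Series
    converged: pd.Series
    contrasts: dict[str, pd.DataFrame] = field(default_factory=dict)


def fit_paired_nb(cm: CountMatrix, dispersion: pd.Series | float | None = None,
                  refine_dispersion: bool = True,
                  sample_size_factors: pd.Series | None = None) -> EffectTable:
    """Fit the paired-fraction NB GLM per gene, per condition block.

    Each condition is fitted independently with design
    ``intercept + replicate + fraction`` and log size-factor offsets; the
    fraction coefficient and its Wald SE are returned in log2 units.
    Size factors default to median-of-ratios estimates but can be supplied
    (``sample_size_factors``). All-zero genes (which the expression filter
    should have removed) raise.
    """
    _check_paired(cm.samples)
    counts, samples = cm.counts, cm.samples
    if (counts.sum(axis=1) == 0).any():
        raise ValueError("all-zero gene passed to fit_paired_nb; filter first")
    if sample_size_factors is None:
        sf = size_factors(counts)
    else:
        sf = pd.Series(sample_size_factors, dtype=float).reindex(counts.columns)
        if sf.isna().any() or (sf <= 0).any():
            raise ValueError("supplied size factors must cover all samples "
                             "and be positive")
    conditions_all = sorted(samples["condition"].unique())
    blocks = []
    for cond in conditions_all:
        cols = list(samples.index[samples["condition"] == cond])
        sub = samples.loc[cols]
        reps = sorted(sub["replicate"].unique())
        X = np.column_stack(
            [np.ones(len(cols))]
            + [(sub["replicate"] == r).to_numpy(float) for r in reps[1:]]
            + [(sub["fraction"] == POLYSOMAL).to_numpy(float)])
        blocks.append((X, cols))
    if dispersion is None:
        # dispersion is profiled against condition x fraction group means
        # (24 residual df at R=4) rather than the 20-parameter block design:
        # with only 3 residual df per block a per-gene estimate is far too
        # unstable for Wald inference, and the group-mean profile also
        # absorbs replicate-offset variability, which keeps the Wald
        # intervals honest at small R
        disp = estimate_dispersions(counts, samples, sf,
                                    refine=refine_dispersion)
    elif np.isscalar(dispersion):
        if dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        disp = pd.Series(float(dispersion), index=counts.index)
    else:
        disp = pd.Series(dispersion).reindex(counts.index)

    conditions = conditions_all
    log2fc = pd.DataFrame(index=counts.index, columns=conditions, dtype=float)
    se = pd.DataFrame(index=counts.index, columns=conditions, dtype=float)
    conv = pd.Series(True, index=counts.index)
    for cond, (X, cols) in zip(conditions, blocks):
        y = counts[cols].to_numpy(dtype=float)
        offset = np.log(sf.loc[cols].to_numpy())
        beta, beta_se, ok = _irls_nb(y, X, offset, disp.to_numpy())
        log2fc[cond] = beta[:, -1] / LN2
        se[cond] = beta_se[:, -1] / LN2
        conv &= pd.Series(ok, index=counts.index)
    if (se <= 0).any().any():
        raise ValueError("non-positive coefficient SE")
    return EffectTable(log2fc=log2fc, se=se, dispersion=disp, converged=conv)


def contrast_translation(effects: EffectTable, reference_condition: str,
                         other_condition: str) -> EffectTable:
    """Fill the reference-vs-other translation contrast into ``effects``.

    Delta_log2FC = coef(reference) - coef(other); because condition blocks
    are fitted independently, SE = sqrt(SE_ref^2 + SE_other^2); p is a
    two-sided Wald test of Delta = 0.
    """
    for cond in (reference_condition, other_condition):
        if cond not in effects.log2fc.columns:
            raise KeyError(f"condition not fitted: {cond!r}")
    delta = effects.log2fc[reference_condition] - effects.log2fc[other_condition]
    dse = np.sqrt(effects.se[reference_condition] ** 2
                  + effects.se[other_condition] ** 2)
    z = np.where(dse > 0, delta / dse, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, P_FLOOR_DEFAULT, 1.0)
    name = f"{reference_condition}_vs_{other_condition}"
    effects.contrasts[name] = pd.DataFrame(
        {"delta_log2fc": delta, "se": dse, "pvalue": p}, index=delta.index)
    return effects


# ---------------------------------------------------------------------------
# Adaptive shrinkage


def _shrink_grid(values: np.ndarray, ses: np.ndarray,
                 mult: float = math.sqrt(2.0)) -> np.ndarray:
    lo = max(ses.min() / 10.0, 1e-12)
    hi = 2.0 * np.abs(values).max()
    if hi <= lo:
        return np.array([lo])
    n = int(math.ceil(math.log(hi / lo) / math.log(mult))) + 1
    return lo * mult ** np.arange(n)


def adaptive_shrink(values: np.ndarray, ses: np.ndarray,
                    max_iter: int = 2000, tol: float = 1e-10,
                    return_weights: bool = False):
    """Empirical-Bayes normal-mixture shrinkage of noisy effect estimates.

    Prior: pi0 * delta(0) + sum_k pi_k * Normal(0, sigma_k^2) on a geometric
    sigma grid spanning [SE_min/10, 2*max|value|]; mixture weights fitted by
    EM on the marginal likelihood of the observed (value, SE) pairs; returns
    posterior means. Every component posterior pulls toward zero, so
    |shrunken| <= |raw| for each gene.
    """
    x = np.asarray(values, dtype=float)
    s = np.asarray(ses, dtype=float)
    if x.size == 0:
        raise ValueError("empty input to adaptive_shrink")
    if not np.all(np.isfinite(x)) or np.any(s <= 0) or not np.all(np.isfinite(s)):
        raise ValueError("values must be finite and SEs positive")
    if np.all(x == 0):
        out = np.zeros_like(x)
        return (out, None) if return_weights else out

    sigma = np.concatenate([[0.0], _shrink_grid(x, s)])
    K = sigma.size
    var = s[:, None] ** 2 + sigma[None, :] ** 2  # (G, K)
    log_lik = -0.5 * (np.log(2 * np.pi * var) + x[:, None] ** 2 / var)
    pi = np.full(K, 1.0 / K)
    # mildly favor the null at start, as adaptive shrinkage does
    pi[0] = 0.5
    pi[1:] = 0.5 / (K - 1)
    for _ in range(max_iter):
        log_post = np.log(np.maximum(pi, 1e-300))[None, :] + log_lik
        m = log_post.max(axis=1, keepdims=True)
        post = np.exp(log_post - m)
        post /= post.sum(axis=1, keepdims=True)
        new_pi = post.mean(axis=0)
        if np.max(np.abs(new_pi - pi)) < tol:
            pi = new_pi
            break
        pi = new_pi
    log_post = np.log(np.maximum(pi, 1e-300))[None, :] + log_lik
    m = log_post.max(axis=1, keepdims=True)
    post = np.exp(log_post - m)
    post /= post.sum(axis=1, keepdims=True)
    shrink_factor = sigma[None, :] ** 2 / var
    out = np.sum(post * shrink_factor, axis=1) * x
    return (out, pi) if return_weights else out


def shrink_contrast(effects: EffectTable, contrast: str) -> EffectTable:
    """Apply adaptive shrinkage to a fitted contrast, adding ``shrunken``."""
    tab = effects.contrasts[contrast]
    tab["shrunken"] = adaptive_shrink(tab["delta_log2fc"].to_numpy(),
                                      tab["se"].to_numpy())
    return effects


# ---------------------------------------------------------------------------
# Ranking metrics


def ranking_metric(log2fc, p, weight=1.0, p_floor: float = P_FLOOR_DEFAULT):
    """Signed gene-ranking metric ``-log2fc * log10(p) * weight``.

    Positive for upregulated genes with small p. ``weight`` is 1 for TRM/RM
    and the expressing-cell fraction X_max for RM_adj. Non-positive p-values
    are floored at ``p_floor`` (log10(0) is undefined) with a warning.
    """
    log2fc = np.asarray(log2fc, dtype=float)
    p = np.asarray(p, dtype=float)
    weight = np.asarray(weight, dtype=float)
    if np.any(p > 1):
        raise ValueError("p-values must be <= 1")
    if np.any((weight < 0) | (weight > 1)):
        raise ValueError("weight must be in [0, 1]")
    if np.any(p <= 0):
        warnings.warn(f"p-values <= 0 floored at {p_floor}", RuntimeWarning,
                      stacklevel=2)
        p = np.maximum(p, p_floor)
    out = -log2fc * np.log10(p) * weight
    if out.ndim == 0:
        return float(out)
    return out


def ranked_list(genes: pd.Index | list, metric) -> pd.Series:
    """Metric values indexed by gene, sorted descending with ties broken by
    gene identifier (deterministic order)."""
    s = pd.Series(np.asarray(metric, dtype=float), index=genes, name="metric")
    if not np.all(np.isfinite(s.to_numpy())):
        raise ValueError("ranking metric must be finite")
    order = sorted(s.index, key=lambda g: (-s[g], str(g)))
    return s.loc[order]
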