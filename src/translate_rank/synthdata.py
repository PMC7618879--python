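"""Synthetic inputs with known ground truth for every pipeline stage.

Every generator here is a pure function of its seed and parameters
(bit-reproducible) and emulates the statistical structure its downstream
stage assumes, so that each stage supports a parameter-recovery test:

* :func:`gen_polysome_counts` - negative-binomial counts under the paired
  condition/replicate/fraction design, with stored per-condition fraction
  effects so the true Delta_log2FC between any two conditions is known;
* :func:`gen_sc_soup` - UMI matrices contaminated by a shared ambient
  profile at known per-cell contamination fractions, plus empty droplets;
* :func:`gen_calcium_traces` - fluorescence traces with baseline, noise and
  treatment-locked transients of known amplitude, including designed
  ionomycin non-responders and non-returners;
* :func:`gen_fiber_image` - birefringence-like RGB images with known pixel
  counts per HSB fiber class;
* :func:`gen_mid` (re-exported from :mod:`translate_rank.isotope`) - MIDs
  convolved with natural 13C abundance.

None of these attempt transcriptome-scale realism (no GC/length bias, no
batch effects, no droplet cell calling); they provide exactly the structure
the estimators are meant to recover.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse
from skimage import color

from .calcium_quant import GLYCINE, IONOMYCIN, TraceSet
from .isotope import gen_mid  # noqa: F401  (generator surface)
from .polysome_rank import FRACTIONS, POLYSOMAL, CountMatrix

#: The four spheroid conditions of the polysome-profiling comparison:
#: aspartate-supplemented scramble/Grin2d-kd/Dhps-kd, and no-aspartate scramble.
STUDY_CONDITIONS = ("ASP-shSCR", "ASP-shGRIN2D", "ASP-shDHPS", "NoASP-shSCR")

DEFAULT_SCHEDULE = [(GLYCINE, 30.0), ("aspartate", 90.0), (IONOMYCIN, 150.0)]


# ---------------------------------------------------------------------------
# Paired polysome/sub-polysome counts


@dataclass
class PolysomeTruth:
    """Generative parameters behind a synthetic polysome count matrix."""

    baseline: pd.Series                 # expected sub-polysomal counts
    dispersion: pd.Series               # NB alpha, variance mu + alpha mu^2
    fraction_log2fc: pd.DataFrame       # gene x condition fraction effect
    replicate_log2_offsets: pd.DataFrame  # condition x replicate
    size_factors: pd.Series

    def delta_log2fc(self, reference: str, other: str) -> pd.Series:
        """True translation difference between two conditions."""
        return self.fraction_log2fc[reference] - self.fraction_log2fc[other]


def study_fraction_effects(n_genes: int, conditions=STUDY_CONDITIONS,
                           reference: str = STUDY_CONDITIONS[0],
                           effects=(0.0, 1.5, -1.5),
                           probs=(0.8, 0.1, 0.1), base_mean: float = 0.5,
                           base_sd: float = 0.5, seed: int = 0
                           ) -> tuple[pd.DataFrame, pd.Series]:
    """Fraction-effect matrix where only the reference condition deviates.

    Every condition shares a per-gene base translation effect; the reference
    condition additionally carries a per-gene delta drawn from ``effects``
    with probabilities ``probs``, so the true Delta_log2FC of reference vs
    any other condition equals that delta exactly.

    Returns (gene x condition log2 effects, per-gene true delta).
    """
    rng = np.random.default_rng(seed)
    genes = pd.Index([f"g{i:05d}" for i in range(n_genes)])
    base = rng.normal(base_mean, base_sd, size=n_genes)
    delta = rng.choice(np.asarray(effects, dtype=float), size=n_genes, p=probs)
    eff = pd.DataFrame({c: base.copy() for c in conditions}, index=genes)
    eff[reference] = base + delta
    return eff, pd.Series(delta, index=genes, name="delta_log2fc")


def gen_polysome_counts(n_genes: int, conditions=STUDY_CONDITIONS,
                        n_replicates: int = 4, *, seed: int,
                        baseline=None, dispersion=0.1,
                        fraction_log2fc: pd.DataFrame | None = None,
                        replicate_sd: float = 0.1,
                        size_factors=None, size_factor_sd: float = 0.1,
                        baseline_logmean: float = 5.0,
                        baseline_logsd: float = 1.0
                        ) -> tuple[CountMatrix, PolysomeTruth]:
    """Simulate paired polysomal/sub-polysomal NB counts.

    Expected counts are ``sf * baseline * 2^rep_offset * 2^(effect * poly)``;
    counts are negative-binomial with per-gene dispersion alpha (variance
    mu + alpha mu^2). ``dispersion=0`` is the deterministic noise-free limit
    (counts = round(mu)); negative dispersions or non-positive size factors
    are parameter errors. Same seed, same parameters -> identical output.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    conditions = list(conditions)
    rng = np.random.default_rng(seed)
    genes = pd.Index([f"g{i:05d}" for i in range(n_genes)], name="gene")

    if baseline is None:
        baseline = np.exp(rng.normal(baseline_logmean, baseline_logsd, n_genes))
    baseline = pd.Series(np.asarray(baseline, dtype=float), index=genes)
    if (baseline <= 0).any():
        raise ValueError("baseline abundances must be positive")

    disp = pd.Series(np.broadcast_to(np.asarray(dispersion, dtype=float),
                                     (n_genes,)).copy(), index=genes)
    if (disp < 0).any():
        raise ValueError("dispersions must be >= 0")

    if fraction_log2fc is None:
        fraction_log2fc, _ = study_fraction_effects(
            n_genes, conditions, reference=conditions[0], seed=seed)
    fraction_log2fc = pd.DataFrame(fraction_log2fc)
    fraction_log2fc.index = genes
    if list(fraction_log2fc.columns) != conditions:
        fraction_log2fc = fraction_log2fc[conditions]

    reps = list(range(1, n_replicates + 1))
    rep_off = pd.DataFrame(
        rng.normal(0.0, replicate_sd, size=(len(conditions), n_replicates)),
        index=conditions, columns=reps)

    sample_ids, meta = [], []
    for cond in conditions:
        for rep in reps:
            for frac in FRACTIONS:
                sample_ids.append(f"{cond}_r{rep}_{frac}")
                meta.append((cond, rep, frac))
    samples = pd.DataFrame(meta, index=pd.Index(sample_ids, name="sample"),
                           columns=["condition", "replicate", "fraction"])

    if size_factors is None:
        size_factors = np.exp(rng.normal(0.0, size_factor_sd, len(sample_ids)))
    sf = pd.Series(np.asarray(size_factors, dtype=float), index=sample_ids)
    if (sf <= 0).any():
        raise ValueError("size factors must be positive")

    mu = np.empty((n_genes, len(sample_ids)))
    for j, (cond, rep, frac) in enumerate(meta):
        lfc = fraction_log2fc[cond].to_numpy() if frac == POLYSOMAL else 0.0
        mu[:, j] = (sf.iloc[j] * baseline.to_numpy()
                    * 2.0 ** rep_off.loc[cond, rep] * 2.0 ** lfc)

    alpha = disp.to_numpy()[:, None]
    counts = np.rint(mu)
    noisy = (alpha > 0).ravel()
    if noisy.any():
        size = 1.0 / alpha[noisy]
        p = size / (size + mu[noisy])
        counts[noisy] = rng.negative_binomial(size, p)
    cm = CountMatrix(
        counts=pd.DataFrame(counts.astype(np.int64), index=genes,
                            columns=sample_ids),
        samples=samples)
    truth = PolysomeTruth(baseline=baseline, dispersion=disp,
                          fraction_log2fc=fraction_log2fc,
                          replicate_log2_offsets=rep_off, size_factors=sf)
    return cm, truth


# ---------------------------------------------------------------------------
# Ambient-RNA contaminated UMI matrices


@dataclass
class SoupTruth:
    """Ground truth behind a synthetic soup-contaminated UMI matrix."""

    true_counts: np.ndarray        # cells x genes, uncontaminated
    soup_counts: np.ndarray        # cells x genes, ambient contribution
    profile: pd.Series             # ambient per-gene fractions, sums to 1
    rho: np.ndarray                # per-cell contamination fraction
    cell_names: pd.Index
    gene_names: pd.Index


def gen_sc_soup(n_cells: int, n_genes: int, rho, profile=None, *, seed: int,
                mean_umi: int = 2000, umi_logsd: float = 0.3,
                cell_profile=None, soup_only_frac: float = 0.05,
                soup_only_mass: float = 0.3, n_empty: int = 2000,
                empty_umi_mean: float = 50.0
                ) -> tuple[ad.AnnData, SoupTruth]:
    """Simulate a UMI matrix contaminated by a shared ambient profile.

    Each cell's observed library of size N_c contains Binomial(N_c, rho_c)
    soup molecules drawn multinomially from the ambient profile; the rest
    are endogenous molecules from the cell expression profile, so
    observed = true + soup and the expected soup per cell is rho_c * N_c.
    By default the ambient profile places ``soup_only_mass`` of its mass on
    a block of ambient-specific genes the cells never express (the
    hemoglobin-like transcripts that make ambient contamination estimable
    in real data); the remainder follows the cell profile. ``n_empty``
    empty droplets of pure soup are appended (obs column ``is_cell``).
    """
    rng = np.random.default_rng(seed)
    rho = np.broadcast_to(np.asarray(rho, dtype=float), (n_cells,)).copy()
    if np.any((rho < 0) | (rho >= 1)):
        raise ValueError("rho must satisfy 0 <= rho < 1")
    genes = pd.Index([f"g{i:04d}" for i in range(n_genes)], name="gene")

    n_soup_only = int(round(soup_only_frac * n_genes))
    if cell_profile is None:
        cell_profile = rng.dirichlet(np.full(n_genes, 0.5))
        cell_profile[:n_soup_only] = 0.0
        cell_profile /= cell_profile.sum()
    cell_profile = np.asarray(cell_profile, dtype=float)

    if profile is None:
        profile = (1.0 - soup_only_mass) * cell_profile
        if n_soup_only:
            profile[:n_soup_only] = soup_only_mass / n_soup_only
        profile /= profile.sum()
    profile = np.asarray(profile, dtype=float)
    if abs(profile.sum() - 1.0) > 1e-9 or np.any(profile < 0):
        raise ValueError("soup profile must be non-negative and sum to 1")

    n_c = np.maximum(rng.lognormal(np.log(mean_umi), umi_logsd,
                                   n_cells).astype(int), 50)
    soup_tot = rng.binomial(n_c, rho)
    true = rng.multinomial(n_c - soup_tot, cell_profile)
    soup = rng.multinomial(soup_tot, profile)
    observed = true + soup

    empties = rng.multinomial(
        np.maximum(rng.poisson(empty_umi_mean, n_empty), 1), profile)
    X = np.vstack([observed, empties])
    names = pd.Index([f"cell{i:05d}" for i in range(n_cells)]
                     + [f"empty{i:05d}" for i in range(n_empty)])
    obs = pd.DataFrame({"is_cell": [True] * n_cells + [False] * n_empty},
                       index=names)
    adata = ad.AnnData(X=sparse.csr_matrix(X.astype(np.int64)), obs=obs,
                       var=pd.DataFrame(index=genes))
    truth = SoupTruth(true_counts=true, soup_counts=soup,
                      profile=pd.Series(profile, index=genes), rho=rho,
                      cell_names=names[:n_cells], gene_names=genes)
    return adata, truth


def cells_only(adata: ad.AnnData) -> ad.AnnData:
    """Subset a gen_sc_soup output to real cells (drops empty droplets)."""
    return adata[adata.obs["is_cell"]].copy()


# ---------------------------------------------------------------------------
# Calcium traces


@dataclass
class CalciumTruth:
    """Ground truth for synthetic calcium traces."""

    baseline: np.ndarray            # per-cell F0, > 0
    amplitudes: pd.DataFrame        # cell x treatment, Delta(F/F0) units
    noise_sd: float                 # Gaussian noise s.d. relative to baseline
    non_responders: np.ndarray      # designed ionomycin amplitude 0
    non_returners: np.ndarray       # designed plateau past next addition

    def norm_amplitudes(self) -> pd.DataFrame:
        """True ionomycin-normalized amplitudes (NaN for non-responders)."""
        iono = self.amplitudes[IONOMYCIN]
        return self.amplitudes.div(iono.where(iono > 0), axis=0)


DEFAULT_AMPLITUDES = {GLYCINE: 0.05, "glutamate": 0.1, "aspartate": 0.5,
                      IONOMYCIN: 2.0}


def gen_calcium_traces(n_cells: int, schedule=None, *, seed: int,
                       amplitude_means: dict | None = None,
                       amplitude_cv: float = 0.3,
                       baseline_mean: float = 100.0,
                       baseline_logsd: float = 0.15,
                       noise_sd: float = 0.0, tau: float = 8.0,
                       frac_nonresponder: float = 0.0,
                       frac_nonreturner: float = 0.0,
                       dt: float = 1.0, tail: float = 60.0
                       ) -> tuple[TraceSet, CalciumTruth]:
    """Simulate per-cell fluorescence traces under a treatment schedule.

    Each treatment contributes an instantaneous-rise, exponentially decaying
    transient of known amplitude A (so the window maximum of Delta(F/F0)
    equals A exactly), truncated at the next addition so that responders
    return to baseline; traces are ``baseline * (1 + sum transients)`` plus
    Gaussian noise of s.d. ``noise_sd * baseline``. Designed non-responders
    get ionomycin amplitude 0; designed non-returners hold a plateau through
    subsequent additions. Overlapping treatment windows are impossible by
    schedule validation (strictly increasing times).
    """
    schedule = list(schedule or DEFAULT_SCHEDULE)
    amplitude_means = dict(DEFAULT_AMPLITUDES, **(amplitude_means or {}))
    rng = np.random.default_rng(seed)
    labels = [lab for lab, _ in schedule]
    times = [t for _, t in schedule]
    t_end = times[-1] + tail
    time = np.arange(0.0, t_end + dt / 2, dt)

    baseline = baseline_mean * np.exp(rng.normal(0.0, baseline_logsd, n_cells))
    amp = pd.DataFrame(index=pd.Index([f"cell{i:03d}" for i in range(n_cells)],
                                      name="cell"),
                       columns=labels, dtype=float)
    for lab in labels:
        mean = amplitude_means.get(lab, 0.2)
        scatter = (np.exp(rng.normal(0.0, amplitude_cv, n_cells))
                   if amplitude_cv > 0 else np.ones(n_cells))
        amp[lab] = mean * scatter

    n_nr = int(round(frac_nonresponder * n_cells))
    n_ret = int(round(frac_nonreturner * n_cells))
    flagged = rng.permutation(n_cells)
    non_resp = np.zeros(n_cells, dtype=bool)
    non_resp[flagged[:n_nr]] = True
    non_ret = np.zeros(n_cells, dtype=bool)
    non_ret[flagged[n_nr:n_nr + n_ret]] = True
    amp.loc[non_resp, IONOMYCIN] = 0.0

    # the non-return plateau is attached to the last treatment of interest
    plateau_label = labels[-2] if len(labels) >= 2 else labels[-1]

    data = np.empty((time.size, n_cells))
    for c in range(n_cells):
        signal = np.zeros_like(time)
        for i, (lab, t0) in enumerate(schedule):
            t1 = times[i + 1] if i + 1 < len(times) else np.inf
            a = amp.iloc[c][lab]
            if non_ret[c] and lab == plateau_label:
                signal += np.where(time >= t0, a, 0.0)
            else:
                win = (time >= t0) & (time < t1)
                signal += np.where(win, a * np.exp(-(time - t0) / tau), 0.0)
        trace = baseline[c] * (1.0 + signal)
        if noise_sd > 0:
            trace = trace + rng.normal(0.0, noise_sd * baseline[c], time.size)
        data[:, c] = trace

    traces = pd.DataFrame(data, index=pd.Index(time, name="time"),
                          columns=amp.index)
    ts = TraceSet(traces=traces, schedule=schedule)
    truth = CalciumTruth(baseline=baseline, amplitudes=amp, noise_sd=noise_sd,
                         non_responders=non_resp, non_returners=non_ret)
    return ts, truth


# ---------------------------------------------------------------------------
# Birefringence-like fiber images


@dataclass
class FiberImageTruth:
    """Planted pixel classes of a synthetic birefringence image."""

    class_counts: dict[str, int]
    class_masks: dict[str, np.ndarray]
    tissue_mask: np.ndarray
    exclusion_mask: np.ndarray | None = None


# safe HSB sub-boxes: 2-unit hue margin inside each class box so 8-bit RGB
# round-trips preserve the class; saturation floor keeps hue well-resolved
_CLASS_HSB = {
    "red_orange": ((4, 25), (80, 220), (150, 250)),
    "yellow": ((30, 45), (80, 220), (150, 250)),
    "green": ((50, 138), (80, 220), (150, 250)),
}


def _hsb255_to_rgb8(hsb: np.ndarray) -> np.ndarray:
    rgb = color.hsv2rgb(np.asarray(hsb, dtype=float) / 255.0)
    return np.rint(rgb * 255.0).astype(np.uint8)


def gen_fiber_image(height: int, width: int, class_fractions, *, seed: int,
                    tissue_mask: np.ndarray | None = None
                    ) -> tuple[np.ndarray, FiberImageTruth]:
    """Generate an RGB image with planted fiber-class pixel fractions.

    ``class_fractions`` are the (red_orange, yellow, green) fractions of the
    tissue area; they must sum to at most 1. Fiber pixels get HSB values
    strictly inside the class threshold boxes; remaining tissue pixels are
    dim background (brightness < 140); non-tissue pixels are near-black.
    """
    fractions = np.asarray(class_fractions, dtype=float)
    if fractions.size != 3 or np.any(fractions < 0):
        raise ValueError("class_fractions must be 3 non-negative values")
    if fractions.sum() > 1.0 + 1e-12:
        raise ValueError("class fractions must sum to at most 1")
    rng = np.random.default_rng(seed)
    if tissue_mask is None:
        tissue_mask = np.ones((height, width), dtype=bool)
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    if tissue_mask.shape != (height, width):
        raise ValueError("tissue mask shape mismatch")

    hsb = np.zeros((height, width, 3), dtype=float)
    tissue_idx = np.flatnonzero(tissue_mask.ravel())
    n_tissue = tissue_idx.size
    counts = np.floor(fractions * n_tissue).astype(int)
    order = rng.permutation(n_tissue)
    class_masks, pos = {}, 0
    for name, n in zip(_CLASS_HSB, counts):
        sel = tissue_idx[order[pos:pos + n]]
        pos += n
        mask = np.zeros(height * width, dtype=bool)
        mask[sel] = True
        class_masks[name] = mask.reshape(height, width)
        (h0, h1), (s0, s1), (b0, b1) = _CLASS_HSB[name]
        flat = hsb.reshape(-1, 3)
        flat[sel, 0] = rng.integers(h0, h1 + 1, n)
        flat[sel, 1] = rng.integers(s0, s1 + 1, n)
        flat[sel, 2] = rng.integers(b0, b1 + 1, n)
    # remaining tissue: dim, unsaturated background below the B threshold
    rest = tissue_idx[order[pos:]]
    flat = hsb.reshape(-1, 3)
    flat[rest, 0] = rng.integers(0, 256, rest.size)
    flat[rest, 1] = rng.integers(0, 100, rest.size)
    flat[rest, 2] = rng.integers(20, 120, rest.size)
    # non-tissue: near black
    non_tissue = np.flatnonzero(~tissue_mask.ravel())
    flat[non_tissue, 2] = rng.integers(0, 8, non_tissue.size)

    image = _hsb255_to_rgb8(hsb)
    truth = FiberImageTruth(
        class_counts={k: int(v.sum()) for k, v in class_masks.items()},
        class_masks=class_masks, tissue_mask=tissue_mask)
    return image, truth
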