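"""Natural-abundance correction of carbon mass-isotopomer distributions (MIDs).

A compound with ``n`` carbons measured by GC/LC-MS yields fractional
isotopologue abundances m0..mn. Naturally occurring 13C (about 1.07% of
carbon) inflates heavier isotopologues: a molecule whose tracer-derived label
is M+i is observed at M+j (j >= i) whenever j-i of its n-i unlabeled carbon
positions happen to carry a natural 13C. Correction inverts this binomial
convolution so that the reported distribution reflects tracer-derived label
only; fractional enrichment summarizes it as the labeled fraction of total
carbon.

Only the carbon backbone is corrected here. For derivatized GC-MS fragments
whose Si/H/O isotopes matter, a full user-supplied correction matrix can be
passed to :func:`correct_mid` instead.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import nnls
from scipy.stats import binom

#: Natural abundance of 13C.
NATURAL_13C = 0.0107


def correction_matrix(n_carbons: int, abundance: float = NATURAL_13C) -> np.ndarray:
    """Build the (n+1, n+1) natural-abundance convolution matrix.

    Entry ``(j, i)`` is the probability that a molecule with ``i`` tracer
    carbons is measured as M+j, i.e. ``C(n-i, j-i) a^(j-i) (1-a)^(n-j)``
    for ``j >= i`` and 0 otherwise. Columns sum to 1.

    Parameters
    ----------
    n_carbons
        Number of carbon atoms in the compound backbone (>= 1).
    abundance
        Per-position probability of a natural 13C, in [0, 1).
    """
    if n_carbons < 1:
        raise ValueError("n_carbons must be >= 1")
    if not 0.0 <= abundance < 1.0:
        raise ValueError(f"abundance must be in [0, 1), got {abundance}")
    n = n_carbons
    i = np.arange(n + 1)[None, :]  # true label
    j = np.arange(n + 1)[:, None]  # measured mass shift
    # binom.pmf(k=j-i, n=n-i, p=a); pmf is 0 for k<0 or k>n-i
    mat = binom.pmf(j - i, n - i, abundance)
    return mat


def gen_mid(n_carbons: int, true_mid: np.ndarray,
            natural_abundance: float = NATURAL_13C) -> np.ndarray:
    """Forward model: convolve a tracer-only MID with natural 13C abundance.

    Returns the MID that a mass spectrometer would observe for a compound
    whose tracer-derived distribution is ``true_mid``. Inverse of
    :func:`correct_mid` for noise-free inputs.
    """
    mid = np.asarray(true_mid, dtype=float)
    if mid.shape != (n_carbons + 1,):
        raise ValueError(f"true_mid must have length n_carbons+1={n_carbons + 1}")
    if np.any(mid < 0):
        raise ValueError("true_mid entries must be non-negative")
    if abs(mid.sum() - 1.0) > 1e-6:
        raise ValueError("true_mid must sum to 1")
    return correction_matrix(n_carbons, natural_abundance) @ mid


def correct_mid(measured: np.ndarray, matrix: np.ndarray | None = None,
                abundance: float = NATURAL_13C) -> tuple[np.ndarray, float]:
    """Correct a measured MID for natural isotope abundance.

    Solves ``matrix @ x = measured`` by non-negative least squares (robust to
    measurement noise that would otherwise produce small negative
    abundances), renormalizes ``x`` to sum to 1, and computes the fractional
    carbon enrichment ``sum_i i*x_i / n``.

    Parameters
    ----------
    measured
        Observed m0..mn fractional abundances.
    matrix
        Optional full correction matrix (e.g. including derivatization
        atoms); defaults to the carbon-only matrix at ``abundance``.

    Returns
    -------
    (corrected, enrichment)
        The corrected MID (sums to 1) and the fraction of carbon atoms
        that are tracer-derived 13C, in [0, 1].
    """
    y = np.asarray(measured, dtype=float)
    n = y.size - 1
    if n < 1:
        raise ValueError("measured MID must have at least two entries")
    if not np.any(y > 0):
        raise ValueError("measured MID is all zero")
    if matrix is None:
        matrix = correction_matrix(n, abundance)
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (n + 1, n + 1):
        raise ValueError("correction matrix shape does not match MID length")
    x, _ = nnls(matrix, y)
    total = x.sum()
    if total <= 0:
        raise ValueError("correction produced an all-zero MID")
    x /= total
    enrichment = float(np.dot(np.arange(n + 1), x) / n)
    return x, enrichment
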