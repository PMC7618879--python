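"""Birefringent-collagen quantification and immunofluorescence intensity.

Picrosirius-red stained sections imaged under polarized light show fibrillar
collagen as birefringent fibers whose color tracks fiber thickness:
red-orange = thick/high birefringence (mostly collagen I), yellow = medium
(collagen I/III), green = thin/low (mostly collagen III). Pixels are
classified by Hue-Saturation-Brightness thresholding on the 0-255 scale
(the ImageJ convention, hue circle mapped linearly to 0-255):

    red-orange  H in [2, 27],   S in [0, 255], B in [140, 255]
    yellow      H in [28, 47],  S in [0, 255], B in [140, 255]
    green       H in [48, 140], S in [0, 255], B in [140, 255]

Anything else (in particular brightness below 140) is background. The
relative area of each class is reported as a percentage of the tissue area,
after removing excluded regions (blood vessels, lung rim) that are
endogenously collagen-rich.

For immunofluorescence collagen stains, the total signal intensity is
normalized by the number of DAPI nuclei (counted by Otsu thresholding and
connected components, or supplied directly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import color, filters, measure

LABEL_BACKGROUND = 0
LABEL_RED = 1
LABEL_YELLOW = 2
LABEL_GREEN = 3

CLASS_NAMES = {LABEL_RED: "red_orange", LABEL_YELLOW: "yellow",
               LABEL_GREEN: "green"}


@dataclass(frozen=True)
class HSBThresholds:
    """Inclusive HSB boxes per fiber class on the 0-255 scale."""

    red: tuple = ((2, 27), (0, 255), (140, 255))
    yellow: tuple = ((28, 47), (0, 255), (140, 255))
    green: tuple = ((48, 140), (0, 255), (140, 255))

    def boxes(self):
        return {LABEL_RED: self.red, LABEL_YELLOW: self.yellow,
                LABEL_GREEN: self.green}


DEFAULT_THRESHOLDS = HSBThresholds()


def rgb_to_hsb255(image: np.ndarray) -> np.ndarray:
    """8-bit RGB -> HSB with all three channels on 0-255.

    Hue degrees are mapped linearly: H = round(hue * 255 / 360); saturation
    and brightness likewise scaled from [0, 1] to 0-255 (brightness equals
    the max RGB channel).
    """
    if image.ndim != 3 or image.shape[2] < 3:
        raise ValueError("expected an RGB image (H x W x 3)")
    rgb = np.asarray(image[..., :3], dtype=float) / 255.0
    hsv = color.rgb2hsv(rgb)
    return np.rint(hsv * 255.0).astype(np.int16)


def classify_fibers(image: np.ndarray,
                    thresholds: HSBThresholds = DEFAULT_THRESHOLDS
                    ) -> np.ndarray:
    """Per-pixel fiber-class label map (0 background, 1 red, 2 yellow,
    3 green). A pure per-pixel function of the HSB values."""
    hsb = rgb_to_hsb255(image)
    h, s, b = hsb[..., 0], hsb[..., 1], hsb[..., 2]
    labels = np.zeros(h.shape, dtype=np.uint8)
    for lab, ((h0, h1), (s0, s1), (b0, b1)) in thresholds.boxes().items():
        mask = ((h >= h0) & (h <= h1) & (s >= s0) & (s <= s1)
                & (b >= b0) & (b <= b1))
        labels[mask] = lab
    return labels


def default_tissue_mask(image: np.ndarray, min_brightness: int = 10) -> np.ndarray:
    """Tissue = pixels that are not near-black (brightness >= 10)."""
    b = np.asarray(image[..., :3], dtype=np.int16).max(axis=2)
    return b >= min_brightness


def relative_fiber_area(labels: np.ndarray, tissue_mask: np.ndarray,
                        exclusion_mask: np.ndarray | None = None
                        ) -> pd.DataFrame:
    """Per-class pixel counts and percentages of the effective tissue area.

    The effective region is ``tissue AND NOT exclusion``; excluded pixels
    enter neither numerator nor denominator.
    """
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    if tissue_mask.shape != labels.shape:
        raise ValueError("tissue mask shape does not match label map")
    region = tissue_mask.copy()
    excluded_pixels = 0
    if exclusion_mask is not None:
        exclusion_mask = np.asarray(exclusion_mask, dtype=bool)
        if exclusion_mask.shape != labels.shape:
            raise ValueError("exclusion mask shape does not match label map")
        excluded_pixels = int((tissue_mask & exclusion_mask).sum())
        region &= ~exclusion_mask
    denom = int(region.sum())
    if denom == 0:
        raise ValueError("effective tissue region is empty")
    rows = []
    for lab, name in CLASS_NAMES.items():
        n = int(((labels == lab) & region).sum())
        rows.append((name, n, 100.0 * n / denom))
    out = pd.DataFrame(rows, columns=["class", "pixels", "percent"])
    out.attrs["tissue_pixels"] = denom
    out.attrs["excluded_pixels"] = excluded_pixels
    return out


def count_nuclei(dapi: np.ndarray, min_size: int = 20) -> int:
    """Count nuclei in a DAPI image: Otsu global threshold + connected
    components, discarding objects below ``min_size`` pixels."""
    img = np.asarray(dapi, dtype=float)
    if img.max() == img.min():
        return 0
    thr = filters.threshold_otsu(img)
    lab = measure.label(img > thr)
    sizes = np.bincount(lab.ravel())[1:]
    return int((sizes >= min_size).sum())


def if_intensity_per_nucleus(signal: np.ndarray, nuclei,
                             min_size: int = 20) -> float:
    """Total fluorescence intensity normalized by the nucleus count.

    ``nuclei`` is either an integer count or a DAPI image to segment.
    """
    if isinstance(nuclei, (int, np.integer)):
        count = int(nuclei)
    else:
        count = count_nuclei(np.asarray(nuclei), min_size=min_size)
    if count <= 0:
        raise ValueError("zero nuclei; cannot normalize intensity")
    return float(np.asarray(signal, dtype=float).sum()) / count
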