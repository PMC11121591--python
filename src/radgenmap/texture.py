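"""First- and second-order texture features of masked MRI regions of interest.

An ROI is a 2-D intensity matrix with a same-shape binary mask (the
radiologist-delineated lesion).  Feature extraction proceeds in four steps:

1. min-max normalisation of the masked intensities to [0, 1];
2. uniform quantisation into ``G`` grey levels (default 16);
3. a single grey-level co-occurrence matrix (GLCM) pooled over four
   unit-distance directions (0, 45, 90, 135 degrees), counted symmetrically
   and restricted to pixel pairs that both fall inside the mask;
4. 22 second-order (GLCM) statistics plus 6 first-order (histogram)
   statistics per ROI.

Because of step 1 every feature is invariant to positive affine rescaling of
the raw intensities, so T2-weighted and ADC images can be treated uniformly.

All logarithms are base 2 with the convention ``0 * log 0 = 0``.  Grey levels
are 1-based (1..G), so a constant image has SumAverage = 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RoiImage",
    "Glcm",
    "DegenerateRoiWarning",
    "GLCM_FEATURE_NAMES",
    "HISTOGRAM_FEATURE_NAMES",
    "FEATURE_NAMES",
    "MODALITIES",
    "DEFAULT_LEVELS",
    "DEFAULT_OFFSETS",
    "normalize_roi",
    "quantize",
    "compute_glcm",
    "glcm_features",
    "histogram_features",
    "roi_features",
    "extract_features",
]

MODALITIES = ("T2WI", "ADC")

#: The 22 second-order statistics: the 14 classical co-occurrence features
#: plus 8 common extensions from the MATLAB-era radiomics toolkits.
GLCM_FEATURE_NAMES = (
    "AngularSecondMoment",
    "Contrast",
    "Correlation",
    "SumSquaresVariance",
    "InverseDifferenceMoment",
    "SumAverage",
    "SumVariance",
    "SumEntropy",
    "Entropy",
    "DifferenceVariance",
    "DifferenceEntropy",
    "InfoMeasureCorrelation1",
    "InfoMeasureCorrelation2",
    "MaximalCorrelationCoefficient",
    "Autocorrelation",
    "ClusterShade",
    "ClusterProminence",
    "Dissimilarity",
    "MaximumProbability",
    "InverseDifference",
    "InverseDifferenceNormalized",
    "InverseDifferenceMomentNormalized",
)

#: First-order statistics of the masked, normalised intensities.  Prefixed
#: "Histogram" so the 28-name catalogue has no clash with GLCM Entropy.
HISTOGRAM_FEATURE_NAMES = (
    "HistogramMean",
    "HistogramVariance",
    "HistogramSkewness",
    "HistogramKurtosis",
    "HistogramEnergy",
    "HistogramEntropy",
)

FEATURE_NAMES = GLCM_FEATURE_NAMES + HISTOGRAM_FEATURE_NAMES

DEFAULT_LEVELS = 16
#: (dy, dx) row-major displacements for 0, 45, 90, 135 degrees.
DEFAULT_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))
DEFAULT_HISTOGRAM_BINS = 64


class DegenerateRoiWarning(UserWarning):
    """Raised as a warning when an ROI is degenerate (e.g. constant)."""


@dataclass
class RoiImage:
    """Masked 2-D intensity matrix for one patient and modality."""

    pixels: np.ndarray
    mask: np.ndarray
    modality: str = "T2WI"
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D matrix")
        if self.pixels.shape != self.mask.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} != pixel shape {self.pixels.shape}"
            )
        if int(self.mask.sum()) < 2:
            raise ValueError("mask must select at least 2 pixels")

    @property
    def masked_values(self) -> np.ndarray:
        return self.pixels[self.mask]


@dataclass
class Glcm:
    """Normalised G x G co-occurrence probability matrix with its metadata."""

    p: np.ndarray
    levels: int
    offsets: tuple
    symmetric: bool = True

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (self.levels, self.levels):
            raise ValueError("p must be levels x levels")
        if (self.p < 0).any():
            raise ValueError("co-occurrence probabilities must be non-negative")
        if abs(self.p.sum() - 1.0) > 1e-12:
            raise ValueError("co-occurrence probabilities must sum to 1")


def normalize_roi(image: RoiImage) -> RoiImage:
    """Affinely map the masked intensities so min -> 0 and max -> 1.

    Unmasked pixels are left untouched.  A constant masked region maps to all
    zeros and records a :class:`DegenerateRoiWarning`.  Idempotent on already
    normalised input.
    """
    vals = image.masked_values
    lo, hi = float(vals.min()), float(vals.max())
    out = image.pixels.copy()
    if hi == lo:
        warnings.warn(
            f"degenerate ROI (constant intensity) for patient "
            f"{image.patient_id!r} modality {image.modality!r}",
            DegenerateRoiWarning,
            stacklevel=2,
        )
        out[image.mask] = 0.0
    else:
        out[image.mask] = (vals - lo) / (hi - lo)
    return replace(image, pixels=out)


def quantize(image: RoiImage, levels: int = DEFAULT_LEVELS) -> np.ndarray:
    """Uniformly bin normalised intensities into 1-based integer grey levels.

    [0, 1] is split into ``levels`` equal-width bins; the value 1.0 belongs to
    the top bin.  Returns an integer matrix with 0 outside the mask and
    1..levels inside.
    """
    if levels < 2:
        raise ValueError(f"levels must be >= 2, got {levels}")
    vals = image.masked_values
    if vals.min() < 0 or vals.max() > 1:
        raise ValueError("image must be normalised to [0, 1] before quantisation")
    q = np.zeros(image.pixels.shape, dtype=np.int64)
    inside = np.minimum(np.floor(vals * levels).astype(np.int64), levels - 1) + 1
    q[image.mask] = inside
    return q


def compute_glcm(
    quantized: np.ndarray,
    levels: int = DEFAULT_LEVELS,
    offsets: Sequence[tuple] = DEFAULT_OFFSETS,
    symmetric: bool = True,
) -> Glcm:
    """Pooled-offset grey-level co-occurrence matrix of a quantised ROI.

    ``quantized`` holds 1-based levels inside the mask and 0 outside.  For
    every offset ``(dy, dx)`` each pair of pixels (x, x+offset) with *both*
    ends inside the mask contributes one count at (level(x), level(x+offset));
    with ``symmetric=True`` the mirrored pair is counted too.  Counts are
    pooled over all offsets and normalised to sum to 1.
    """
    q = np.asarray(quantized, dtype=np.int64)
    counts = np.zeros((levels, levels), dtype=np.int64)
    ny, nx = q.shape
    for dy, dx in offsets:
        y0, y1 = max(0, -dy), min(ny, ny - dy)
        x0, x1 = max(0, -dx), min(nx, nx - dx)
        a = q[y0:y1, x0:x1]
        b = q[y0 + dy : y1 + dy, x0 + dx : x1 + dx]
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        ii = a[valid] - 1
        jj = b[valid] - 1
        np.add.at(counts, (ii, jj), 1)
        if symmetric:
            np.add.at(counts, (jj, ii), 1)
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid in-mask pixel pair for any offset in this ROI")
    return Glcm(counts / total, levels=levels, offsets=tuple(map(tuple, offsets)), symmetric=symmetric)


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def glcm_features(glcm: Glcm) -> dict[str, float]:
    """The 22-feature second-order catalogue of a normalised GLCM.

    Degenerate guards: Correlation and MaximalCorrelationCoefficient return 0
    (with a :class:`DegenerateRoiWarning`) when a marginal is concentrated on
    a single level, and the information measures fall back to 0 when the
    marginal entropies vanish.
    """
    p = glcm.p
    g = glcm.levels
    i = np.arange(1, g + 1, dtype=float)
    ii = i[:, None] * np.ones((1, g))
    jj = np.ones((g, 1)) * i[None, :]

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    var_x = float(((i - mu_x) ** 2 * px).sum())
    var_y = float(((i - mu_y) ** 2 * py).sum())

    # diagonal distributions p_{x+y}(k), k = 2..2G and p_{x-y}(k), k = 0..G-1
    k_sum = np.arange(2, 2 * g + 1, dtype=float)
    p_sum = np.zeros(2 * g - 1)
    k_diff = np.arange(0, g, dtype=float)
    p_diff = np.zeros(g)
    sum_idx = (ii + jj - 2).astype(int)
    diff_idx = np.abs(ii - jj).astype(int)
    np.add.at(p_sum, sum_idx.ravel(), p.ravel())
    np.add.at(p_diff, diff_idx.ravel(), p.ravel())

    f: dict[str, float] = {}
    f["AngularSecondMoment"] = float((p**2).sum())
    f["Contrast"] = float(((ii - jj) ** 2 * p).sum())

    sd_xy = np.sqrt(var_x * var_y)
    if sd_xy <= 0:
        warnings.warn(
            "GLCM marginal has zero variance; Correlation set to 0",
            DegenerateRoiWarning,
            stacklevel=2,
        )
        f["Correlation"] = 0.0
    else:
        f["Correlation"] = float(((ii - mu_x) * (jj - mu_y) * p).sum() / sd_xy)

    f["SumSquaresVariance"] = float(((ii - mu_x) ** 2 * p).sum())
    f["InverseDifferenceMoment"] = float((p / (1.0 + (ii - jj) ** 2)).sum())
    sum_avg = float((k_sum * p_sum).sum())
    f["SumAverage"] = sum_avg
    f["SumVariance"] = float(((k_sum - sum_avg) ** 2 * p_sum).sum())
    f["SumEntropy"] = _entropy_bits(p_sum)
    hxy = _entropy_bits(p.ravel())
    f["Entropy"] = hxy
    mu_d = float((k_diff * p_diff).sum())
    f["DifferenceVariance"] = float(((k_diff - mu_d) ** 2 * p_diff).sum())
    f["DifferenceEntropy"] = _entropy_bits(p_diff)

    # information measures of correlation (entropies in bits throughout)
    hx = _entropy_bits(px)
    hy = _entropy_bits(py)
    pxy = px[:, None] * py[None, :]
    nz = (p > 0) & (pxy > 0)
    hxy1 = float(-(p[nz] * np.log2(pxy[nz])).sum())
    nz2 = pxy > 0
    hxy2 = float(-(pxy[nz2] * np.log2(pxy[nz2])).sum())
    denom = max(hx, hy)
    f["InfoMeasureCorrelation1"] = (hxy - hxy1) / denom if denom > 0 else 0.0
    f["InfoMeasureCorrelation2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    f["MaximalCorrelationCoefficient"] = _maximal_correlation(p, px, py)

    f["Autocorrelation"] = float((ii * jj * p).sum())
    f["ClusterShade"] = float(((ii + jj - mu_x - mu_y) ** 3 * p).sum())
    f["ClusterProminence"] = float(((ii + jj - mu_x - mu_y) ** 4 * p).sum())
    f["Dissimilarity"] = float((np.abs(ii - jj) * p).sum())
    f["MaximumProbability"] = float(p.max())
    f["InverseDifference"] = float((p / (1.0 + np.abs(ii - jj))).sum())
    f["InverseDifferenceNormalized"] = float((p / (1.0 + np.abs(ii - jj) / g)).sum())
    f["InverseDifferenceMomentNormalized"] = float((p / (1.0 + ((ii - jj) / g) ** 2)).sum())
    return f


def _maximal_correlation(p: np.ndarray, px: np.ndarray, py: np.ndarray) -> float:
    """Square root of the second-largest eigenvalue of the Q matrix.

    Q(i, j) = sum_k p(i,k) p(j,k) / (px(i) py(k)), restricted to grey levels
    with positive marginal mass.  Fewer than two active levels -> 0.
    """
    active_x = px > 0
    active_y = py > 0
    sub = p[np.ix_(active_x, active_y)]
    if sub.shape[0] < 2 or sub.shape[1] < 2:
        return 0.0
    a = sub / px[active_x][:, None]
    b = sub / py[active_y][None, :]
    q = a @ b.T
    eig = np.linalg.eigvals(q)
    eig = np.sort(np.abs(eig))[::-1]
    second = float(eig[1]) if eig.size > 1 else 0.0
    return float(np.sqrt(np.clip(second, 0.0, 1.0)))


def histogram_features(
    image: RoiImage, bins: int = DEFAULT_HISTOGRAM_BINS
) -> dict[str, float]:
    """First-order statistics of the masked, normalised intensities.

    Moments are population moments computed by direct summation; kurtosis is
    non-excess (normal ~ 3).  Energy and Entropy (base 2) are computed on an
    equal-width histogram over [0, 1] with ``bins`` bins.  A constant region
    yields Skewness = Kurtosis = 0 by convention, with a warning.
    """
    v = image.masked_values
    if v.min() < 0 or v.max() > 1:
        raise ValueError("image must be normalised to [0, 1]")
    mean = float(v.mean())
    var = float(((v - mean) ** 2).mean())
    if var > 0:
        skew = float(((v - mean) ** 3).mean() / var**1.5)
        kurt = float(((v - mean) ** 4).mean() / var**2)
    else:
        warnings.warn(
            "constant masked region; Skewness and Kurtosis set to 0",
            DegenerateRoiWarning,
            stacklevel=2,
        )
        skew = 0.0
        kurt = 0.0
    hist, _ = np.histogram(v, bins=bins, range=(0.0, 1.0))
    ph = hist / hist.sum()
    return {
        "HistogramMean": mean,
        "HistogramVariance": var,
        "HistogramSkewness": skew,
        "HistogramKurtosis": kurt,
        "HistogramEnergy": float((ph**2).sum()),
        "HistogramEntropy": _entropy_bits(ph),
    }


def roi_features(
    image: RoiImage,
    levels: int = DEFAULT_LEVELS,
    offsets: Sequence[tuple] = DEFAULT_OFFSETS,
    symmetric: bool = True,
    histogram_bins: int = DEFAULT_HISTOGRAM_BINS,
) -> dict[str, float]:
    """Full 28-value feature vector (22 GLCM + 6 histogram) for one ROI."""
    norm = normalize_roi(image)
    q = quantize(norm, levels)
    glcm = compute_glcm(q, levels=levels, offsets=offsets, symmetric=symmetric)
    out = glcm_features(glcm)
    out.update(histogram_features(norm, bins=histogram_bins))
    return out


def extract_features(
    images: Iterable[RoiImage],
    levels: int = DEFAULT_LEVELS,
    offsets: Sequence[tuple] = DEFAULT_OFFSETS,
    symmetric: bool = True,
    histogram_bins: int = DEFAULT_HISTOGRAM_BINS,
    long: bool = False,
) -> pd.DataFrame:
    """Feature table for a cohort of ROIs, both modalities per patient.

    Wide format (default): one row per patient, columns suffixed with the
    modality (``SumEntropy_ADC`` etc.), 56 columns total.  ``long=True``
    returns one row per patient per modality with unsuffixed feature columns.
    Patients missing either modality raise an error naming them.
    """
    by_patient: dict[str, dict[str, RoiImage]] = {}
    for img in images:
        by_patient.setdefault(img.patient_id, {})[img.modality] = img
    missing = sorted(
        pid
        for pid, mods in by_patient.items()
        if any(m not in mods for m in MODALITIES)
    )
    if missing:
        raise ValueError(f"patients missing a modality: {missing}")

    rows = []
    for pid in sorted(by_patient):
        for modality in MODALITIES:
            feats = roi_features(
                by_patient[pid][modality],
                levels=levels,
                offsets=offsets,
                symmetric=symmetric,
                histogram_bins=histogram_bins,
            )
            rows.append({"patient_id": pid, "modality": modality, **feats})
    table = pd.DataFrame(rows)
    if long:
        return table.set_index(["patient_id", "modality"])
    wide = table.pivot(index="patient_id", columns="modality")
    wide.columns = [f"{feat}_{mod}" for feat, mod in wide.columns]
    ordered = [f"{feat}_{mod}" for mod in MODALITIES for feat in FEATURE_NAMES]
    return wide[ordered]
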