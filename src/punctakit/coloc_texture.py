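"""Colocalization, compartment ratios and GLCM texture.

Colocalization follows the JACoP conventions: Manders M1 is the fraction of
channel-A signal residing under the channel-B mask (and M2 symmetrically),
and the Pearson correlation is computed over all nucleus pixels by default
(a mask-restricted variant is available, since published analyses differ).

The compartment ratio compares the mean intensity in the nucleus with a
perinuclear ring used as a cytoplasmic proxy, reported as
log2(nuclear / perinuclear).

Texture descriptors come from a gray-level co-occurrence matrix (GLCM)
computed inside an arbitrary nucleus mask: intensities are min-max
quantized per ROI to ``n_levels`` (256 emulates 8-bit conversion),
co-occurrences are counted for pixel pairs at a fixed offset with both
pixels inside the mask, symmetrized and normalized.  Entropy is
-sum p*log(p) (natural log by default; the base is configurable and purely
a constant factor) and the inverse difference moment (IDM) is
sum p_ij / (1 + (i - j)^2).  The GLCM here is computed directly with numpy
because library routines assume rectangular images without mask support;
a unit test cross-checks it against an independent routine on rectangular
regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .segment import NucleusROI

logger = logging.getLogger(__name__)


@dataclass
class ColocResult:
    nucleus_id: int
    m1: Optional[float]
    m2: Optional[float]
    pearson_r: Optional[float]
    overlap_area_um2: float


@dataclass
class CompartmentRatio:
    nucleus_id: int
    nuclear_mfi: float
    perinuclear_mfi: float
    log2_ratio: Optional[float]


@dataclass
class TextureResult:
    nucleus_id: int
    entropy: float
    idm: float
    glcm: np.ndarray
    offset: tuple[int, int]
    n_levels: int
    log_base: str = "e"


def estimate_background(image: np.ndarray, rois: Sequence[NucleusROI]) -> float:
    """Median intensity outside every nucleus and ring (camera background)."""
    image = np.asarray(image, dtype=np.float64)
    outside = np.ones(image.shape, dtype=bool)
    for roi in rois:
        outside &= ~(roi.mask | roi.perinuclear_mask)
    if not outside.any():
        return 0.0
    return float(np.median(image[outside]))


def manders_pearson(
    ch_a: np.ndarray,
    ch_b: np.ndarray,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    roi: NucleusROI,
    pixel_size_um: float,
    pearson_masked: bool = False,
    background_a: float = 0.0,
    background_b: float = 0.0,
) -> ColocResult:
    """Manders M1/M2 and Pearson correlation for one nucleus.

    M1 = sum(A over B-mask) / sum(A over A-mask); M2 symmetric.  Manders
    sums use background-subtracted intensities (clipped at 0) when a
    background estimate is supplied — see :func:`estimate_background` —
    since a constant camera offset otherwise dilutes the coefficients.
    An empty denominator mask yields a null coefficient (logged).  Pearson
    is over all ROI pixels unless ``pearson_masked``, in which case it is
    over the union of the two masks; it is offset-invariant, so no
    subtraction applies.
    """
    ch_a_raw = np.asarray(ch_a, dtype=np.float64)
    ch_b_raw = np.asarray(ch_b, dtype=np.float64)
    ch_a = np.clip(ch_a_raw - background_a, 0.0, None)
    ch_b = np.clip(ch_b_raw - background_b, 0.0, None)
    mask_a = np.asarray(mask_a).astype(bool) & roi.mask
    mask_b = np.asarray(mask_b).astype(bool) & roi.mask

    both = mask_a & mask_b
    denom_a = float(ch_a[mask_a].sum()) if mask_a.any() else 0.0
    denom_b = float(ch_b[mask_b].sum()) if mask_b.any() else 0.0
    m1 = float(ch_a[both].sum() / denom_a) if denom_a > 0 else None
    m2 = float(ch_b[both].sum() / denom_b) if denom_b > 0 else None
    if m1 is None:
        logger.info("nucleus %d: empty A-mask, M1 undefined", roi.nucleus_id)
    if m2 is None:
        logger.info("nucleus %d: empty B-mask, M2 undefined", roi.nucleus_id)

    sel = (mask_a | mask_b) if pearson_masked else roi.mask
    if sel.sum() >= 2 and np.ptp(ch_a_raw[sel]) > 0 and np.ptp(ch_b_raw[sel]) > 0:
        pearson = float(stats.pearsonr(ch_a_raw[sel], ch_b_raw[sel]).statistic)
    else:
        pearson = None

    overlap = float((mask_a & mask_b).sum()) * pixel_size_um**2
    return ColocResult(
        nucleus_id=roi.nucleus_id, m1=m1, m2=m2, pearson_r=pearson, overlap_area_um2=overlap
    )


def compartment_ratio(intensity: np.ndarray, roi: NucleusROI) -> CompartmentRatio:
    """log2(nuclear MFI / perinuclear MFI) for one nucleus."""
    intensity = np.asarray(intensity, dtype=np.float64)
    if not roi.perinuclear_mask.any():
        logger.info("nucleus %d: empty perinuclear ring", roi.nucleus_id)
        return CompartmentRatio(roi.nucleus_id, float(intensity[roi.mask].mean()), 0.0, None)
    nuc = float(intensity[roi.mask].mean())
    peri = float(intensity[roi.perinuclear_mask].mean())
    ratio = None if peri == 0 or nuc <= 0 else float(np.log2(nuc / peri))
    return CompartmentRatio(roi.nucleus_id, nuc, peri, ratio)


def glcm_matrix(
    quantized: np.ndarray,
    mask: np.ndarray,
    offset: tuple[int, int],
    n_levels: int,
) -> np.ndarray:
    """Symmetrized, normalized co-occurrence matrix inside a mask.

    Pairs (p, p + offset) are counted only when both pixels lie inside the
    mask; the transpose is added so the matrix is symmetric, then the whole
    matrix is normalized to sum to 1.
    """
    dr, dc = offset
    h, w = quantized.shape
    src = np.zeros_like(mask, dtype=bool)
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    src[r0:r1, c0:c1] = mask[r0:r1, c0:c1] & np.roll(np.roll(mask, -dr, axis=0), -dc, axis=1)[r0:r1, c0:c1]
    i_vals = quantized[src]
    shifted = np.roll(np.roll(quantized, -dr, axis=0), -dc, axis=1)
    j_vals = shifted[src]
    if i_vals.size == 0:
        raise ValueError("mask too small for any pixel pair at this offset")
    counts = np.zeros((n_levels, n_levels), dtype=np.float64)
    np.add.at(counts, (i_vals, j_vals), 1.0)
    counts = counts + counts.T
    return counts / counts.sum()


def quantize_roi(
    intensity: np.ndarray,
    mask: np.ndarray,
    n_levels: int,
    intensity_range: Optional[tuple[float, float]] = None,
) -> np.ndarray:
    """Rescale masked intensities to integer levels [0, n-1].

    By default the range is the per-ROI min-max (each nucleus is stretched
    to full scale before 8-bit-style conversion); a fixed
    ``intensity_range`` pins the scale instead, making level occupancy — and
    hence entropy — sensitive to the absolute noise amplitude.
    """
    intensity = np.asarray(intensity, dtype=np.float64)
    if intensity_range is None:
        vals = intensity[mask]
        lo, hi = float(vals.min()), float(vals.max())
    else:
        lo, hi = map(float, intensity_range)
        intensity = np.clip(intensity, lo, hi)
    q = np.zeros(intensity.shape, dtype=np.int64)
    if hi > lo:
        scaled = (intensity - lo) / (hi - lo) * n_levels
        q_in = np.clip(scaled.astype(np.int64), 0, n_levels - 1)
        q[mask] = q_in[mask]
    return q


_LOG = {"e": np.log, "2": np.log2, "10": np.log10}


def glcm_texture(
    intensity: np.ndarray,
    roi: NucleusROI,
    offset: tuple[int, int] = (0, 1),
    n_levels: int = 256,
    average_offsets: bool = False,
    log_base: str = "e",
    intensity_range: Optional[tuple[float, float]] = None,
) -> TextureResult:
    """Entropy and inverse difference moment of the per-ROI GLCM.

    With ``average_offsets`` the normalized matrices of the four standard
    directions (0, 45, 90, 135 degrees) at the offset's distance are
    averaged before computing the statistics.  ``intensity_range`` fixes
    the quantization scale instead of the default per-ROI min-max.
    """
    if not roi.mask.any():
        raise ValueError("ROI mask is empty")
    if not 2 <= n_levels <= 256:
        raise ValueError("n_levels must be in [2, 256]")
    log = _LOG[log_base]
    quantized = quantize_roi(intensity, roi.mask, n_levels, intensity_range)

    if average_offsets:
        d = max(abs(offset[0]), abs(offset[1]), 1)
        offsets = [(0, d), (-d, d), (-d, 0), (-d, -d)]
        mats = [glcm_matrix(quantized, roi.mask, off, n_levels) for off in offsets]
        glcm = np.mean(mats, axis=0)
    else:
        glcm = glcm_matrix(quantized, roi.mask, offset, n_levels)

    p = glcm[glcm > 0]
    entropy = float(-(p * log(p)).sum())
    i_idx, j_idx = np.indices(glcm.shape)
    idm = float((glcm / (1.0 + (i_idx - j_idx) ** 2)).sum())
    return TextureResult(
        nucleus_id=roi.nucleus_id,
        entropy=entropy,
        idm=idm,
        glcm=glcm,
        offset=tuple(offset),
        n_levels=n_levels,
        log_base=log_base,
    )


def coloc_to_frame(results: Sequence[ColocResult]) -> pd.DataFrame:
    rows = [
        {
            "nucleus_id": r.nucleus_id,
            "m1": np.nan if r.m1 is None else r.m1,
            "m2": np.nan if r.m2 is None else r.m2,
            "pearson_r": np.nan if r.pearson_r is None else r.pearson_r,
            "overlap_area_um2": r.overlap_area_um2,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=["nucleus_id", "m1", "m2", "pearson_r", "overlap_area_um2"])


def texture_to_frame(results: Sequence[TextureResult]) -> pd.DataFrame:
    rows = [
        {
            "nucleus_id": r.nucleus_id,
            "entropy": r.entropy,
            "idm": r.idm,
            "offset_dr": r.offset[0],
            "offset_dc": r.offset[1],
            "n_levels": r.n_levels,
            "log_base": r.log_base,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["nucleus_id", "entropy", "idm", "offset_dr", "offset_dc", "n_levels", "log_base"],
    )
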