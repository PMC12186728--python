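"""Per-punctum morphometrics and per-nucleus summaries.

Circularity follows the ImageJ convention 4*pi*area/perimeter^2, clamped at
1 (rasterized small shapes can exceed 1 with any discrete perimeter
estimator).  The perimeter is the 4-direction Crofton estimate, which is
close to unbiased for convex blobs.  Intranuclear variability is the sample
standard deviation (coefficient of variation available via flag).  The
area–circularity relationship is an ordinary least squares fit of
log2(circularity) on log2(area), reported with the F-test of zero slope and
the Pearson correlation of the two log2 variables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.measure import perimeter_crofton, regionprops

from .config import ClassifierRules
from .io import LabelMask

logger = logging.getLogger(__name__)


@dataclass
class PunctumRecord:
    """One segmented punctum with shape and intensity descriptors."""

    punctum_id: int
    nucleus_id: int
    area_um2: float
    perimeter_um: float
    circularity: float
    mfi: float
    centroid: tuple[float, float]
    n_lobes_est: int = 1
    extranuclear: bool = False


@dataclass
class NucleusSummary:
    nucleus_id: int
    puncta_count: int
    mean_area: Optional[float] = None
    sd_area: Optional[float] = None
    mean_circularity: Optional[float] = None
    sd_circularity: Optional[float] = None
    mean_mfi: Optional[float] = None
    aggregation_index: Optional[float] = None
    morphology_class: str = "none"


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    pearson_r: float
    f_statistic: float
    p_value: float
    n: int


def estimate_lobes(blob: np.ndarray, min_separation_px: int = 2) -> int:
    """Count convexity-separated lobes of a binary blob.

    Lobes are local maxima of the intra-blob Euclidean distance transform
    separated by at least ``min_separation_px`` — the simplest reproducible
    surrogate for "connected punctate units" in a bouquet-like aggregate.
    """
    blob = np.asarray(blob, dtype=bool)
    if not blob.any():
        return 0
    padded = np.pad(blob, 1)
    dist = ndi.distance_transform_edt(padded)
    peaks = peak_local_max(
        dist, min_distance=min_separation_px, labels=padded, exclude_border=False
    )
    return max(int(len(peaks)), 1)


def measure_puncta(
    mask: LabelMask,
    intensity: np.ndarray,
    pixel_size_um: float,
    assignments: Optional[pd.DataFrame] = None,
) -> list[PunctumRecord]:
    """Measure area, perimeter, circularity, MFI and lobe count per punctum.

    ``assignments`` is the stub table from :func:`segment_puncta`; when
    given, nucleus ids and extranuclear flags are joined by punctum label,
    otherwise every punctum gets nucleus_id 0.
    """
    mask = np.asarray(mask)
    intensity = np.asarray(intensity, dtype=np.float64)
    if mask.shape != intensity.shape:
        raise ValueError("mask and intensity image shapes differ")
    ps = float(pixel_size_um)

    assign: dict[int, tuple[int, bool]] = {}
    if assignments is not None and len(assignments):
        for _, row in assignments.iterrows():
            assign[int(row["punctum_id"])] = (int(row["nucleus_id"]), bool(row["extranuclear"]))

    records: list[PunctumRecord] = []
    for prop in regionprops(mask, intensity_image=intensity):
        blob = prop.image
        perim_px = perimeter_crofton(blob, directions=4)
        area_px = float(prop.area)
        circ = 1.0 if perim_px == 0 else min(1.0, 4.0 * np.pi * area_px / perim_px**2)
        nid, extra = assign.get(prop.label, (0, False))
        records.append(
            PunctumRecord(
                punctum_id=int(prop.label),
                nucleus_id=nid,
                area_um2=area_px * ps * ps,
                perimeter_um=float(perim_px) * ps,
                circularity=float(circ),
                mfi=float(prop.intensity_mean),
                centroid=tuple(prop.centroid),
                n_lobes_est=estimate_lobes(blob),
                extranuclear=extra,
            )
        )
    return records


def summarize_nucleus(
    puncta: Sequence[PunctumRecord],
    profile: Optional[dict] = None,
    rules: Optional[ClassifierRules] = None,
    nucleus_id: Optional[int] = None,
    use_cv: bool = False,
) -> NucleusSummary:
    """Aggregate puncta of one nucleus into counts, means and variability.

    SD fields are the sample standard deviation (ddof=1), or the coefficient
    of variation when ``use_cv``; they are null for fewer than 2 puncta.
    Zero puncta give counts of 0 and null means.  Mixed nucleus ids raise.
    """
    puncta = list(puncta)
    ids = {p.nucleus_id for p in puncta}
    if len(ids) > 1:
        raise ValueError(f"summarize_nucleus got mixed nucleus_ids {sorted(ids)}")
    if nucleus_id is None:
        nucleus_id = ids.pop() if ids else 0

    def _sd(values: np.ndarray) -> Optional[float]:
        if len(values) < 2:
            return None
        sd = float(np.std(values, ddof=1))
        if use_cv:
            m = float(np.mean(values))
            return sd / m if m != 0 else None
        return sd

    summary = NucleusSummary(nucleus_id=int(nucleus_id), puncta_count=len(puncta))
    if puncta:
        areas = np.array([p.area_um2 for p in puncta])
        circs = np.array([p.circularity for p in puncta])
        mfis = np.array([p.mfi for p in puncta])
        summary.mean_area = float(areas.mean())
        summary.sd_area = _sd(areas)
        summary.mean_circularity = float(circs.mean())
        summary.sd_circularity = _sd(circs)
        summary.mean_mfi = float(mfis.mean())
    if profile is not None:
        agg = profile.get("aggregation_index")
        summary.aggregation_index = None if agg is None or np.isnan(agg) else float(agg)
    if rules is not None:
        summary.morphology_class = classify_morphology(puncta, rules)
    elif puncta:
        summary.morphology_class = "punctate" if puncta else "none"
    return summary


def regress_area_circularity(puncta: Sequence[PunctumRecord]) -> RegressionResult:
    """OLS of log2(circularity) on log2(area) across puncta.

    Requires n >= 3 and strictly positive areas and circularities; zero
    variance in log2(area) is an undefined fit.
    """
    puncta = list(puncta)
    if len(puncta) < 3:
        raise ValueError("regression needs at least 3 puncta")
    areas = np.array([p.area_um2 for p in puncta])
    circs = np.array([p.circularity for p in puncta])
    if np.any(areas <= 0) or np.any(circs <= 0):
        raise ValueError("areas and circularities must be > 0 for log2 transform")
    x = np.log2(areas)
    y = np.log2(circs)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in log2(area); fit undefined")

    model = sm.OLS(y, sm.add_constant(x)).fit()
    if np.ptp(y) == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(x, y)[0, 1])
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        pearson_r=r,
        f_statistic=float(model.fvalue),
        p_value=float(model.f_pvalue),
        n=len(puncta),
    )


def classify_morphology(
    puncta: Sequence[PunctumRecord], rules: Optional[ClassifierRules] = None
) -> str:
    """Rule-based punctate/bouquet call for one nucleus.

    "bouquet": any punctum is larger than ``area_thresh_um2`` AND is either
    not circular (< ``circ_thresh``) or has >= ``lobe_thresh`` estimated
    lobes.  "punctate": at least one punctum and none meets the bouquet
    rule.  "none": no puncta.
    """
    rules = rules or ClassifierRules()
    puncta = list(puncta)
    if not puncta:
        return "none"
    for p in puncta:
        if p.area_um2 > rules.area_thresh_um2 and (
            p.circularity < rules.circ_thresh or p.n_lobes_est >= rules.lobe_thresh
        ):
            return "bouquet"
    return "punctate"


def puncta_to_frame(puncta: Sequence[PunctumRecord]) -> pd.DataFrame:
    rows = [
        {
            "punctum_id": p.punctum_id,
            "nucleus_id": p.nucleus_id,
            "area_um2": p.area_um2,
            "perimeter_um": p.perimeter_um,
            "circularity": p.circularity,
            "mfi": p.mfi,
            "centroid_row": p.centroid[0],
            "centroid_col": p.centroid[1],
            "n_lobes_est": p.n_lobes_est,
            "extranuclear": p.extranuclear,
        }
        for p in puncta
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "punctum_id",
            "nucleus_id",
            "area_um2",
            "perimeter_um",
            "circularity",
            "mfi",
            "centroid_row",
            "centroid_col",
            "n_lobes_est",
            "extranuclear",
        ],
    )
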