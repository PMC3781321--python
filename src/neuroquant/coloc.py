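"""Thresholded Mander's colocalization and ROI intensity quantification.

The degree of overlap between a reference channel (e.g. CYFIP1 immunostain)
and one or two partner channels (e.g. eIF4E and NCKAP1) is quantified with
intensity-weighted Mander's coefficients computed over above-threshold pixels.
The *free fraction* is the share of above-threshold reference signal that
overlaps neither partner's support — for a protein partitioning between two
complexes, the pool engaged with neither.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)

__all__ = [
    "ColocResult",
    "RoiQuantification",
    "threshold_channel",
    "manders_coefficients",
    "free_fraction",
    "coloc_report",
    "object_coloc_counts",
    "roi_intensity",
]


@dataclass(frozen=True)
class ColocResult:
    """Mander's coefficients of a reference channel against two partners."""

    M_ref_to_A: float
    M_ref_to_B: float
    free_fraction: float
    thresholds: dict[str, float]


@dataclass(frozen=True)
class RoiQuantification:
    """Mean signal per unit area within one region of interest."""

    roi_id: int
    intensity_per_um2: float
    area_um2: float


ThresholdMethod = Literal["otsu", "fixed", "quantile"]


def threshold_channel(
    img: np.ndarray,
    method: ThresholdMethod = "otsu",
    value: float | None = None,
) -> tuple[np.ndarray, float]:
    """Binarise a channel; returns ``(mask, threshold)``.

    ``mask`` marks pixels *strictly above* the threshold.  Methods:
    ``otsu`` (parameter-free, requires a non-constant image), ``fixed``
    (``value`` is the threshold) and ``quantile`` (``value`` in [0, 1] is the
    quantile below the mask).
    """
    img = np.asarray(img, dtype=float)
    if method == "otsu":
        if np.ptp(img) == 0:
            raise ValueError("Otsu threshold undefined for a constant image")
        t = float(threshold_otsu(img))
    elif method == "fixed":
        if value is None:
            raise ValueError("fixed threshold requires a value")
        t = float(value)
    elif method == "quantile":
        if value is None or not 0 <= value <= 1:
            raise ValueError("quantile threshold requires a value in [0, 1]")
        t = float(np.quantile(img, value))
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return img > t, t


def manders_coefficients(
    ref_img: np.ndarray,
    partner_img: np.ndarray,
    ref_threshold: float,
    partner_threshold: float,
) -> tuple[float, float]:
    """Thresholded Mander's coefficients ``(M1, M2)``.

    ``M1`` is the fraction of above-threshold reference intensity that falls
    on pixels where the partner is above its threshold; ``M2`` swaps the
    roles.  An empty above-threshold set makes the corresponding coefficient
    undefined; it is returned as NaN with a warning.
    """
    ref = np.asarray(ref_img, dtype=float)
    par = np.asarray(partner_img, dtype=float)
    if ref.shape != par.shape:
        raise ValueError("images must have the same shape")
    ref_on = ref > ref_threshold
    par_on = par > partner_threshold

    def _m(signal: np.ndarray, own: np.ndarray, other: np.ndarray) -> float:
        denom = signal[own].sum()
        if denom <= 0:
            warnings.warn(
                "no above-threshold signal; Mander's coefficient undefined",
                RuntimeWarning,
                stacklevel=3,
            )
            return float("nan")
        return float(signal[own & other].sum() / denom)

    return _m(ref, ref_on, par_on), _m(par, par_on, ref_on)


def free_fraction(
    ref_img: np.ndarray,
    partner_a: np.ndarray,
    partner_b: np.ndarray,
    ref_threshold: float,
    a_threshold: float,
    b_threshold: float,
) -> float:
    """Fraction of above-threshold reference signal overlapping neither partner.

    The overlap is taken over the *union* of the two partner supports, so
    signal covered by both partners is not double-counted;
    ``free_fraction + union_overlap == 1`` exactly.
    """
    ref = np.asarray(ref_img, dtype=float)
    a_on = np.asarray(partner_a, dtype=float) > a_threshold
    b_on = np.asarray(partner_b, dtype=float) > b_threshold
    if ref.shape != a_on.shape or ref.shape != b_on.shape:
        raise ValueError("images must have the same shape")
    ref_on = ref > ref_threshold
    denom = ref[ref_on].sum()
    if denom <= 0:
        warnings.warn(
            "no above-threshold reference signal; free fraction undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("nan")
    engaged = ref[ref_on & (a_on | b_on)].sum()
    return float(1.0 - engaged / denom)


def coloc_report(
    ref_img: np.ndarray,
    partner_a: np.ndarray,
    partner_b: np.ndarray,
    method: ThresholdMethod = "otsu",
    value: float | None = None,
) -> ColocResult:
    """Threshold all three channels and report Mander's and free fraction."""
    _, t_ref = threshold_channel(ref_img, method, value)
    _, t_a = threshold_channel(partner_a, method, value)
    _, t_b = threshold_channel(partner_b, method, value)
    m_a, _ = manders_coefficients(ref_img, partner_a, t_ref, t_a)
    m_b, _ = manders_coefficients(ref_img, partner_b, t_ref, t_b)
    free = free_fraction(ref_img, partner_a, partner_b, t_ref, t_a, t_b)
    logger.info(
        "coloc thresholds ref=%.4g A=%.4g B=%.4g; M_A=%.3f M_B=%.3f free=%.3f",
        t_ref, t_a, t_b, m_a, m_b, free,
    )
    return ColocResult(
        M_ref_to_A=m_a,
        M_ref_to_B=m_b,
        free_fraction=free,
        thresholds={"ref": t_ref, "A": t_a, "B": t_b},
    )


def object_coloc_counts(
    ref_img: np.ndarray,
    partner_a: np.ndarray,
    partner_b: np.ndarray,
    ref_threshold: float,
    a_threshold: float,
    b_threshold: float,
) -> dict[str, int]:
    """Object-mode colocalization: count reference puncta by partner overlap.

    Reference puncta are connected components of the thresholded reference
    channel; a punctum colocalizes with a partner if it shares at least one
    pixel with that partner's above-threshold support.  The ``both`` count
    makes the disjoint-complexes assumption checkable.
    """
    ref_on = np.asarray(ref_img, dtype=float) > ref_threshold
    a_on = np.asarray(partner_a, dtype=float) > a_threshold
    b_on = np.asarray(partner_b, dtype=float) > b_threshold
    labels, n = ndimage.label(ref_on)
    counts = {"total": int(n), "A": 0, "B": 0, "both": 0, "free": 0}
    for lab in range(1, n + 1):
        obj = labels == lab
        hit_a = bool((obj & a_on).any())
        hit_b = bool((obj & b_on).any())
        if hit_a and hit_b:
            counts["both"] += 1
        if hit_a:
            counts["A"] += 1
        if hit_b:
            counts["B"] += 1
        if not hit_a and not hit_b:
            counts["free"] += 1
    return counts


def roi_intensity(
    img: np.ndarray,
    roi_masks: list[np.ndarray],
    pixel_size_um: float,
) -> list[RoiQuantification]:
    """Per-ROI total intensity normalised to ROI area (signal per um^2)."""
    img = np.asarray(img, dtype=float)
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    out = []
    for i, m in enumerate(roi_masks):
        m = np.asarray(m, dtype=bool)
        if m.shape != img.shape:
            raise ValueError(f"ROI {i} shape {m.shape} != image shape {img.shape}")
        n_px = int(m.sum())
        if n_px == 0:
            raise ValueError(f"ROI {i} is empty")
        area = n_px * pixel_size_um**2
        out.append(
            RoiQuantification(
                roi_id=i,
                intensity_per_um2=float(img[m].sum() / area),
                area_um2=float(area),
            )
        )
    return out
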