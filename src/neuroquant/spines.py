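"""Dendritic spine morphometry: measurement, classification and population comparison.

Protrusions on a dendritic shaft are described by three lengths, all in
micrometres:

* ``L``   — protrusion length, from the attachment point on the shaft to the tip;
* ``W_H`` — maximal head width;
* ``W_N`` — neck width.

Spines are assigned to four morphological classes by interval rules on these
quantities: stubby (L <= 1), mushroom (1 < L <= 3 and W_H >= 2 W_N), long thin
(1 < L <= 3 and W_H < 2 W_N) and filopodia (3 < L <= 5).  Stubby and mushroom
spines are conventionally called *mature*, long thin and filopodia *immature*.
Protrusions longer than 5 um fall outside the taxonomy and are labelled
``excluded``; they are counted separately and never enter class percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "SpineMeasurement",
    "SpineClass",
    "PopulationSummary",
    "MATURE_CLASSES",
    "IMMATURE_CLASSES",
    "classify_spine",
    "measure_protrusion",
    "summarize_population",
    "compare_class_distributions",
    "compare_length_distributions",
    "pearson_chi2",
    "spine_density",
]

SpineClass = Literal["stubby", "mushroom", "long_thin", "filopodia", "excluded"]

CLASS_NAMES: tuple[str, ...] = ("stubby", "mushroom", "long_thin", "filopodia")
MATURE_CLASSES: frozenset[str] = frozenset({"stubby", "mushroom"})
IMMATURE_CLASSES: frozenset[str] = frozenset({"long_thin", "filopodia"})

#: Maximum protrusion length (um) covered by the four-class taxonomy.
MAX_CLASSIFIED_LENGTH_UM = 5.0


@dataclass(frozen=True)
class SpineMeasurement:
    """Geometry of one dendritic protrusion (lengths in micrometres).

    ``W_H >= W_N`` is *not* enforced: widths are recorded as measured, and a
    thin-necked convention is applied only at classification time.
    """

    L: float
    W_H: float
    W_N: float
    id: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        for name in ("L", "W_H", "W_N"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")


@dataclass(frozen=True)
class PopulationSummary:
    """Per-class tallies of a spine population.

    Percentages are over the four classified morphologies only; ``n_excluded``
    protrusions (L > 5 um) are reported separately.  ``mean_length_um`` and its
    SEM are over the classified spines.
    """

    counts: dict[str, int]
    percentages: dict[str, float]
    mature_percent: float
    immature_percent: float
    mean_length_um: float
    sem_length_um: float
    n_excluded: int
    density_per_um: float | None = None

    @property
    def n_classified(self) -> int:
        return sum(self.counts.values())


def classify_spine(m: SpineMeasurement) -> SpineClass:
    """Assign a spine to one of the four morphological classes.

    The interval boundaries are honoured exactly as stated: ``L <= 1`` is
    stubby regardless of widths; for ``1 < L <= 3`` the head/neck ratio decides
    between mushroom (``W_H >= 2 W_N``) and long thin; ``3 < L <= 5`` is
    filopodia; anything longer is ``excluded``.
    """
    if m.L <= 1.0:
        return "stubby"
    if m.L <= 3.0:
        return "mushroom" if m.W_H >= 2.0 * m.W_N else "long_thin"
    if m.L <= MAX_CLASSIFIED_LENGTH_UM:
        return "filopodia"
    return "excluded"


# ---------------------------------------------------------------------------
# Mask-based measurement
# ---------------------------------------------------------------------------


def _geodesic_distance(mask: np.ndarray, seeds: np.ndarray) -> np.ndarray:
    """Euclidean-weighted geodesic distance inside ``mask`` from ``seeds``.

    Returns an array of +inf outside the mask; distances are in pixels.
    """
    from skimage.graph import MCP_Geometric

    cost = np.where(mask, 1.0, np.inf)
    mcp = MCP_Geometric(cost)
    seed_idx = list(zip(*np.nonzero(seeds & mask)))
    dist, _ = mcp.find_costs(seed_idx)
    return dist


def measure_protrusion(
    mask: np.ndarray,
    base: np.ndarray,
    pixel_size_um: float,
    *,
    head_fraction: float = 0.5,
    id: str = "",
    source: str = "",
) -> SpineMeasurement:
    """Measure L, W_H and W_N of a single protrusion from a binary mask.

    Parameters
    ----------
    mask
        Binary image containing exactly one connected protrusion.
    base
        Binary image marking the attachment segment on the shaft boundary; it
        must intersect ``mask``.
    pixel_size_um
        Physical pixel size.
    head_fraction
        Fraction of the length, measured from the tip, treated as the head
        region (the complement is the neck region).  Default: distal half.

    Notes
    -----
    Length is the maximal geodesic distance (Euclidean step weights) from the
    attachment segment to any mask pixel, plus one pixel for the half-pixel
    caps at either end.  The width profile is built from unit-geodesic-distance
    shells: a one-pixel-thick shell is a cross-section perpendicular to the
    local axis of the protrusion, and its width is taken as the largest
    pairwise distance between its pixel centres plus one pixel.  The maximal
    head width is the widest shell in the distal region, the neck width the
    narrowest shell in the proximal region.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    mask = np.asarray(mask, dtype=bool)
    base = np.asarray(base, dtype=bool)
    if not mask.any():
        raise ValueError("empty protrusion mask")
    n_comp = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))[1]
    if n_comp != 1:
        raise ValueError(f"mask must be a single connected component, found {n_comp}")
    if not (mask & base).any():
        raise ValueError("mask does not touch the base attachment segment")

    # Work on the mask's bounding box: geodesic cost scales with image area.
    rr, cc = np.nonzero(mask)
    r0, r1 = rr.min(), rr.max() + 1
    c0, c1 = cc.min(), cc.max() + 1
    mask = mask[r0:r1, c0:c1]
    base = base[r0:r1, c0:c1]

    dist = _geodesic_distance(mask, base)
    inside = np.isfinite(dist) & mask
    rows, cols = np.nonzero(inside)
    d = dist[rows, cols]
    # +1 px: geodesic distance reaches the pixel *centre* of the farthest
    # pixel; the protrusion extends to its far edge.
    length_px = float(d.max()) + 1.0

    # Width profile from unit-geodesic shells: each shell is a one-pixel-thick
    # cross-section; its width is the chord spanned by its pixel centres
    # (+1 px for the two half-pixel rims).
    shell_index = np.clip(d.astype(int), 0, None)
    n_shells = int(shell_index.max()) + 1
    widths = np.empty(n_shells, dtype=float)
    for s in range(n_shells):
        sel = shell_index == s
        pts = np.column_stack([rows[sel], cols[sel]]).astype(float)
        if pts.shape[0] == 1:
            widths[s] = 1.0
        else:
            diff = pts[:, None, :] - pts[None, :, :]
            widths[s] = float(np.sqrt((diff**2).sum(-1)).max()) + 1.0

    split = length_px * (1.0 - head_fraction)
    shell_pos = np.arange(n_shells) + 0.5
    head_shells = widths[shell_pos >= split]
    neck_shells = widths[shell_pos < split]
    # Degenerate tiny masks: fall back to the full profile.
    if head_shells.size == 0:
        head_shells = widths
    if neck_shells.size == 0:
        neck_shells = widths
    w_h = float(head_shells.max())
    w_n = float(neck_shells.min())

    return SpineMeasurement(
        L=round(length_px * pixel_size_um, 3),
        W_H=round(w_h * pixel_size_um, 3),
        W_N=round(w_n * pixel_size_um, 3),
        id=id,
        source=source,
    )


# ---------------------------------------------------------------------------
# Population summaries and statistics
# ---------------------------------------------------------------------------


def summarize_population(
    ms: Sequence[SpineMeasurement],
    *,
    total_dendrite_length_um: float | None = None,
) -> PopulationSummary:
    """Tally class counts, percentages, mature/immature split and mean length."""
    if len(ms) == 0:
        raise ValueError("cannot summarise an empty spine population")
    labels = [classify_spine(m) for m in ms]
    counts = {c: 0 for c in CLASS_NAMES}
    n_excluded = 0
    lengths = []
    for m, lab in zip(ms, labels):
        if lab == "excluded":
            n_excluded += 1
        else:
            counts[lab] += 1
            lengths.append(m.L)
    n = sum(counts.values())
    if n == 0:
        raise ValueError("all protrusions excluded (L > 5 um); nothing to summarise")
    percentages = {c: 100.0 * counts[c] / n for c in CLASS_NAMES}
    mature = sum(percentages[c] for c in MATURE_CLASSES)
    immature = sum(percentages[c] for c in IMMATURE_CLASSES)
    lengths_arr = np.asarray(lengths, dtype=float)
    mean_l = float(lengths_arr.mean())
    sem_l = float(lengths_arr.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    density = None
    if total_dendrite_length_um is not None:
        if total_dendrite_length_um <= 0:
            raise ValueError("total_dendrite_length_um must be > 0")
        density = (n + n_excluded) / total_dendrite_length_um
    return PopulationSummary(
        counts=counts,
        percentages=percentages,
        mature_percent=mature,
        immature_percent=immature,
        mean_length_um=mean_l,
        sem_length_um=sem_l,
        n_excluded=n_excluded,
        density_per_um=density,
    )


def compare_class_distributions(
    a: PopulationSummary,
    b: PopulationSummary,
    grouping: Literal["four_class", "mature_immature"] = "four_class",
) -> tuple[float, int, float]:
    """Pearson chi-square test comparing two class-count distributions.

    Returns ``(statistic, df, p)``.  With ``grouping="mature_immature"`` the
    four columns are collapsed to the mature/immature dichotomy before
    testing.  No continuity correction is applied (plain sum of
    (O - E)^2 / E).
    """
    if grouping == "four_class":
        table = np.array(
            [[a.counts[c] for c in CLASS_NAMES], [b.counts[c] for c in CLASS_NAMES]],
            dtype=float,
        )
    elif grouping == "mature_immature":
        table = np.array(
            [
                [
                    sum(s.counts[c] for c in MATURE_CLASSES),
                    sum(s.counts[c] for c in IMMATURE_CLASSES),
                ]
                for s in (a, b)
            ],
            dtype=float,
        )
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    return pearson_chi2(table)


def pearson_chi2(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a contingency table.

    Returns ``(statistic, df, p)`` with no continuity correction; rejects
    tables whose margins force a zero expected count.
    """
    table = np.asarray(table, dtype=float)
    expected = stats.contingency.expected_freq(table)
    if np.any(expected <= 0):
        raise ValueError(
            "chi-square test undefined: a row or column total is zero, giving "
            "expected cell counts of 0"
        )
    stat, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), int(df), float(p)


def compare_length_distributions(
    a: Iterable[float], b: Iterable[float]
) -> tuple[float, float, dict[str, np.ndarray]]:
    """Two-sample Kolmogorov-Smirnov test on spine-length samples.

    Returns ``(D, p, curves)`` where ``curves`` holds the pooled grid and the
    two empirical CDFs, ready for cumulative-probability plotting.
    """
    xa = np.sort(np.asarray(list(a), dtype=float))
    xb = np.sort(np.asarray(list(b), dtype=float))
    if xa.size < 2 or xb.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    res = stats.ks_2samp(xa, xb, alternative="two-sided", method="asymp")
    grid = np.unique(np.concatenate([xa, xb]))
    cdf_a = np.searchsorted(xa, grid, side="right") / xa.size
    cdf_b = np.searchsorted(xb, grid, side="right") / xb.size
    curves = {"grid": grid, "cdf_a": cdf_a, "cdf_b": cdf_b}
    return float(res.statistic), float(res.pvalue), curves


def spine_density(
    spine_counts: Sequence[int],
    segment_lengths_um: float | Sequence[float] = 20.0,
) -> float:
    """Spine density in spines/um over one or more dendritic segments.

    ``segment_lengths_um`` may be a scalar (all segments equal, default the
    conventional 20 um sampling window) or one length per segment.
    """
    counts = np.asarray(spine_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("spine counts must be non-negative")
    if np.isscalar(segment_lengths_um):
        lengths = np.full(counts.shape, float(segment_lengths_um))
    else:
        lengths = np.asarray(segment_lengths_um, dtype=float)
        if lengths.shape != counts.shape:
            raise ValueError("one segment length per count required")
    if np.any(lengths <= 0):
        raise ValueError("segment lengths must be > 0")
    total_len = float(lengths.sum())
    if total_len == 0:
        raise ValueError("zero total dendrite length")
    return float(counts.sum() / total_len)
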