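"""Synthetic inputs with known ground truth for every pipeline stage.

Every generator is deterministic given its parameters and seed (independent
substreams are derived from the user seed via ``numpy.random.SeedSequence``),
and emits the ground truth alongside the data, so downstream estimators can
be validated by recovery rather than by eye:

* spine populations drawn from the four morphological classes, and 2D
  rendered dendrites bearing them (maximum-intensity-projection regime:
  Gaussian PSF blur over a binary shape, Poisson photon noise, no camera
  read noise);
* three-channel puncta fields where a controlled fraction of reference
  puncta is colocalized with each of two partner channels;
* two-component exponential FLIM decays with Poisson photon statistics;
* gene association-p-value tables with a controlled fraction of true
  associations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .fret import FlimDecay, efficiency_to_lifetime, photon_fraction_from_molecular
from .images import MultiChannelImage
from .spines import CLASS_NAMES, SpineMeasurement, classify_spine

logger = logging.getLogger(__name__)

__all__ = [
    "SpineRenderParams",
    "ClassGeometryPriors",
    "FlimSimParams",
    "generate_spine_population",
    "render_dendrite_image",
    "protrusion_and_base",
    "generate_puncta_channels",
    "generate_flim_decay",
    "generate_gene_pvalues",
]


@dataclass(frozen=True)
class SpineRenderParams:
    """Rendering regime for synthetic fluorescence images.

    Rates are mean photons per pixel; all sizes in micrometres.
    """

    pixel_size_um: float = 0.1
    psf_sigma_um: float = 0.1
    background_rate: float = 2.0
    peak_rate: float = 200.0
    shaft_width_um: float = 0.5
    image_shape: tuple[int, int] = (128, 512)
    spacing_um: float = 2.0          # centre-to-centre spine spacing
    margin_um: float = 1.0
    min_separation_um: float = 1.0   # between puncta centres

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.psf_sigma_um < 0:
            raise ValueError("psf_sigma_um must be >= 0")
        if self.background_rate < 0 or self.peak_rate < 0:
            raise ValueError("photon rates must be >= 0")
        if self.shaft_width_um <= 0:
            raise ValueError("shaft_width_um must be > 0")


@dataclass(frozen=True)
class ClassGeometryPriors:
    """Per-class sampling ranges (um) for spine geometry.

    Each class's length range must lie inside its defining interval.  Widths
    are parametrised as a neck width plus a head/neck ratio so that the
    class-defining ratio constraints (mushroom >= 2, long thin < 2) are
    honoured by construction; stubby and filopodia carry no width rule, and
    their ranges are chosen to look like their biological counterparts
    (squat wide protrusions; long thin ones).
    """

    stubby_L: tuple[float, float] = (0.4, 1.0)
    stubby_WH: tuple[float, float] = (0.3, 0.6)
    stubby_neck_frac: tuple[float, float] = (0.6, 1.0)   # W_N = frac * W_H
    mushroom_L: tuple[float, float] = (1.0, 3.0)
    mushroom_WN: tuple[float, float] = (0.2, 0.3)
    mushroom_ratio: tuple[float, float] = (2.0, 4.0)
    long_thin_L: tuple[float, float] = (1.0, 3.0)
    long_thin_WN: tuple[float, float] = (0.2, 0.3)
    long_thin_ratio: tuple[float, float] = (1.0, 2.0)
    filopodia_L: tuple[float, float] = (3.0, 5.0)
    filopodia_WN: tuple[float, float] = (0.15, 0.25)
    filopodia_ratio: tuple[float, float] = (1.0, 1.5)

    def __post_init__(self) -> None:
        bounds = {
            "stubby_L": (0.0, 1.0),
            "mushroom_L": (1.0, 3.0),
            "long_thin_L": (1.0, 3.0),
            "filopodia_L": (3.0, 5.0),
        }
        for name, (lo, hi) in bounds.items():
            rng_lo, rng_hi = getattr(self, name)
            if not (lo <= rng_lo < rng_hi <= hi):
                raise ValueError(
                    f"{name}={getattr(self, name)} outside the class-defining "
                    f"interval ({lo}, {hi}]"
                )
        if not (2.0 <= self.mushroom_ratio[0] < self.mushroom_ratio[1]):
            raise ValueError("mushroom head/neck ratio range must start at >= 2")
        if not (1.0 <= self.long_thin_ratio[0] < self.long_thin_ratio[1] <= 2.0):
            raise ValueError("long-thin head/neck ratio range must lie in [1, 2]")


@dataclass(frozen=True)
class FlimSimParams:
    """Two-state FLIM decay simulation.

    ``phi`` is the *molecular* fraction in the compact (FRET-competent)
    state; the fraction of detected photons from that state is
    ``phi * tau_DA / (phi * tau_DA + (1 - phi) * tau_D)`` because a
    molecule's photon yield is proportional to its lifetime (constant
    radiative rate).
    """

    tau_d_ns: float = 2.5
    efficiency: float = 0.5
    phi: float = 0.5
    n_photons: int = 100_000
    n_bins: int = 256
    bin_width_ns: float = 0.1
    seed: int = 0
    fixed_total: bool = False
    irf_sigma_ns: float = 0.0
    background_fraction: float = 0.0   # fraction of photons that are uniform noise

    def __post_init__(self) -> None:
        if not 0 <= self.phi <= 1:
            raise ValueError("phi must be in [0, 1]")
        if not 0 <= self.efficiency < 1:
            raise ValueError("efficiency must be in [0, 1)")
        if self.n_photons <= 0:
            raise ValueError("n_photons must be > 0")
        if self.tau_d_ns <= 0 or self.bin_width_ns <= 0 or self.n_bins < 2:
            raise ValueError("invalid histogram geometry")
        if not 0 <= self.background_fraction < 1:
            raise ValueError("background_fraction must be in [0, 1)")


# ---------------------------------------------------------------------------
# Spine populations
# ---------------------------------------------------------------------------


def _sample_geometry(
    cls: str, priors: ClassGeometryPriors, rng: np.random.Generator
) -> tuple[float, float, float]:
    if cls == "stubby":
        L = rng.uniform(*priors.stubby_L)
        w_h = rng.uniform(*priors.stubby_WH)
        w_n = w_h * rng.uniform(*priors.stubby_neck_frac)
    elif cls == "mushroom":
        L = rng.uniform(*priors.mushroom_L)
        w_n = rng.uniform(*priors.mushroom_WN)
        w_h = w_n * rng.uniform(*priors.mushroom_ratio)
    elif cls == "long_thin":
        L = rng.uniform(*priors.long_thin_L)
        w_n = rng.uniform(*priors.long_thin_WN)
        w_h = w_n * rng.uniform(*priors.long_thin_ratio)
    elif cls == "filopodia":
        L = rng.uniform(*priors.filopodia_L)
        w_n = rng.uniform(*priors.filopodia_WN)
        w_h = w_n * rng.uniform(*priors.filopodia_ratio)
    else:
        raise ValueError(f"unknown spine class {cls!r}")
    return L, w_h, w_n


def generate_spine_population(
    class_probs: dict[str, float],
    n: int,
    priors: ClassGeometryPriors | None = None,
    seed: int = 0,
) -> tuple[list[SpineMeasurement], list[str]]:
    """Draw ``n`` spines with class labels from ``class_probs``.

    Returns ``(measurements, true_labels)``; every measurement classifies
    back to its true label (geometry is resampled in the measure-zero event
    that a uniform draw lands exactly on a class boundary).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    unknown = set(class_probs) - set(CLASS_NAMES)
    if unknown:
        raise ValueError(f"unknown classes {sorted(unknown)}")
    probs = np.array([class_probs.get(c, 0.0) for c in CLASS_NAMES], dtype=float)
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("class probabilities must be >= 0 and sum to 1")
    priors = priors or ClassGeometryPriors()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    labels = rng.choice(len(CLASS_NAMES), size=n, p=probs)
    out: list[SpineMeasurement] = []
    true: list[str] = []
    for i, li in enumerate(labels):
        cls = CLASS_NAMES[li]
        for _ in range(100):
            L, w_h, w_n = _sample_geometry(cls, priors, rng)
            m = SpineMeasurement(L=L, W_H=w_h, W_N=w_n, id=f"spine{i:05d}")
            if classify_spine(m) == cls:
                break
        else:  # pragma: no cover - boundary draws have probability ~0
            raise RuntimeError("could not sample geometry consistent with class")
        out.append(m)
        true.append(cls)
    return out, true


# ---------------------------------------------------------------------------
# Dendrite rendering
# ---------------------------------------------------------------------------


def render_dendrite_image(
    spines: list[SpineMeasurement],
    params: SpineRenderParams | None = None,
    seed: int = 0,
) -> tuple[MultiChannelImage, pd.DataFrame]:
    """Render spines on a straight horizontal shaft, with ground-truth masks.

    Spines attach perpendicular to the shaft, alternating sides, spaced
    ``spacing_um`` apart.  Each protrusion is a neck rectangle (proximal
    half, width ``W_N``) topped by a head rectangle (distal half, width
    ``W_H``); its mask occupies ``round(L / pixel_size)`` rows.  The photon
    image is the binary shape at ``peak_rate``, PSF-blurred, plus
    ``background_rate``, Poisson-sampled.

    Returns the image (ground-truth label mask under ``masks["labels"]``,
    shaft excluded) and a truth table with per-spine geometry, class and
    attachment (base) row.
    """
    params = params or SpineRenderParams()
    px = params.pixel_size_um
    h, w = params.image_shape
    shaft_w = max(1, round(params.shaft_width_um / px))
    shaft_top = h // 2 - shaft_w // 2
    shaft_rows = slice(shaft_top, shaft_top + shaft_w)

    spacing_px = max(1, round(params.spacing_um / px))
    margin_px = max(1, round(params.margin_um / px))
    capacity = (w - 2 * margin_px) // spacing_px + 1
    if len(spines) > capacity:
        raise ValueError(
            f"{len(spines)} spines do not fit: image holds {capacity} at "
            f"{params.spacing_um} um spacing"
        )

    shape = np.zeros((h, w), dtype=bool)
    shape[shaft_rows, :] = True
    labels = np.zeros((h, w), dtype=np.int32)
    rows = []
    for i, m in enumerate(spines):
        n_rows = max(1, round(m.L / px))
        w_n = max(1, round(m.W_N / px))
        w_h = max(1, round(m.W_H / px))
        n_neck = n_rows // 2
        col = margin_px + i * spacing_px
        direction = "up" if i % 2 == 0 else "down"
        half_wn, half_wh = w_n // 2, w_h // 2
        c0 = min(col - half_wn, col - half_wh)
        c1 = max(col - half_wn + w_n, col - half_wh + w_h)
        if c0 < 0 or c1 > w:
            raise ValueError(f"spine {m.id or i} exceeds image width")
        if direction == "up":
            r_base = shaft_top - 1
            r_tip = shaft_top - n_rows
            if r_tip < 0:
                raise ValueError(f"spine {m.id or i} (L={m.L}) exceeds image height")
            neck_rows = slice(r_base - n_neck + 1, r_base + 1)
            head_rows = slice(r_tip, r_base - n_neck + 1)
        else:
            r_base = shaft_top + shaft_w
            r_tip = r_base + n_rows - 1
            if r_tip >= h:
                raise ValueError(f"spine {m.id or i} (L={m.L}) exceeds image height")
            neck_rows = slice(r_base, r_base + n_neck)
            head_rows = slice(r_base + n_neck, r_tip + 1)
        neck_cols = slice(col - half_wn, col - half_wn + w_n)
        head_cols = slice(col - half_wh, col - half_wh + w_h)
        region = np.zeros((h, w), dtype=bool)
        region[neck_rows, neck_cols] = True
        region[head_rows, head_cols] = True
        if (labels[region] != 0).any():
            raise ValueError(
                f"spine {m.id or i} overlaps a previously placed spine; "
                "increase spacing_um"
            )
        labels[region] = i + 1
        shape |= region
        rows.append(
            {
                "label": i + 1,
                "id": m.id,
                "L_um": m.L,
                "WH_um": m.W_H,
                "WN_um": m.W_N,
                "class": classify_spine(m),
                "direction": direction,
                "base_row": r_base,
                "col": col,
                "n_rows_px": n_rows,
            }
        )

    intensity = np.where(shape, params.peak_rate, 0.0)
    if params.psf_sigma_um > 0:
        intensity = ndimage.gaussian_filter(intensity, params.psf_sigma_um / px)
    intensity += params.background_rate
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    photons = rng.poisson(intensity).astype(np.float64)

    img = MultiChannelImage(
        data=photons[None],
        channel_names=["morphology"],
        pixel_size_um=px,
        masks={"labels": labels},
    )
    return img, pd.DataFrame(rows)


def protrusion_and_base(
    img: MultiChannelImage, truth: pd.DataFrame, label: int
) -> tuple[np.ndarray, np.ndarray]:
    """Extract one rendered protrusion's mask and its base attachment segment."""
    labels = img.masks["labels"]
    mask = labels == label
    if not mask.any():
        raise KeyError(f"no protrusion with label {label}")
    row = truth.loc[truth["label"] == label].iloc[0]
    base = np.zeros_like(mask)
    base[int(row["base_row"])] = True
    base &= mask
    return mask, base


# ---------------------------------------------------------------------------
# Puncta fields
# ---------------------------------------------------------------------------


def _dart_throw(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    min_sep_px: float,
    margin_px: int,
    existing: list[tuple[float, float]] | None = None,
    max_tries: int = 20_000,
) -> list[tuple[float, float]]:
    pts: list[tuple[float, float]] = []
    anchors = list(existing or [])
    h, w = shape
    for _ in range(max_tries):
        if len(pts) == n:
            break
        y = rng.uniform(margin_px, h - margin_px)
        x = rng.uniform(margin_px, w - margin_px)
        ok = all(
            (y - py) ** 2 + (x - px_) ** 2 >= min_sep_px**2
            for py, px_ in anchors + pts
        )
        if ok:
            pts.append((y, x))
    if len(pts) < n:
        raise ValueError(
            f"could only place {len(pts)}/{n} puncta at min separation "
            f"{min_sep_px:.1f} px; enlarge the image or reduce density"
        )
    return pts


def _render_spots(
    centers: list[tuple[float, float]],
    shape: tuple[int, int],
    peak: float,
    sigma_px: float,
) -> np.ndarray:
    field_ = np.zeros(shape)
    for y, x in centers:
        field_[int(round(y)), int(round(x))] += 1.0
    if sigma_px > 0:
        field_ = ndimage.gaussian_filter(field_, sigma_px)
        field_ *= peak * 2.0 * np.pi * sigma_px**2
    else:
        field_ *= peak
    return field_


def generate_puncta_channels(
    n_ref: int,
    frac_a: float,
    frac_b: float,
    params: SpineRenderParams | None = None,
    seed: int = 0,
    *,
    extra_frac: float = 0.1,
) -> tuple[MultiChannelImage, pd.DataFrame]:
    """Three-channel puncta field with controlled partner colocalization.

    ``n_ref`` reference puncta are placed with a minimum mutual separation;
    each is independently assigned partner A (prob ``frac_a``), partner B
    (prob ``frac_b``) or neither — the A- and B-bound subsets are disjoint by
    construction.  Partner channels carry a punctum at the centre of each
    bound reference punctum, plus ``extra_frac * n_ref`` independent puncta
    placed away from every reference punctum (partner signal outside the
    reference complexes).

    Returns the image (channels ``ref``, ``A``, ``B``) and a truth table with
    each reference punctum's position and partner status.
    """
    params = params or SpineRenderParams()
    if frac_a < 0 or frac_b < 0 or frac_a + frac_b > 1 + 1e-12:
        raise ValueError("need frac_a, frac_b >= 0 with frac_a + frac_b <= 1")
    if n_ref < 0:
        raise ValueError("n_ref must be >= 0")
    px = params.pixel_size_um
    sigma_px = params.psf_sigma_um / px
    min_sep_px = params.min_separation_um / px
    margin_px = max(3, int(math.ceil(4 * sigma_px)))
    ss = np.random.SeedSequence(seed).spawn(3)
    rng_pos, rng_status, rng_noise = (np.random.default_rng(s) for s in ss)

    ref_pts = _dart_throw(rng_pos, n_ref, params.image_shape, min_sep_px, margin_px)
    status = rng_status.choice(
        ["A", "B", "free"], size=n_ref, p=[frac_a, frac_b, 1.0 - frac_a - frac_b]
    ) if n_ref else np.array([], dtype=str)

    n_extra = int(round(extra_frac * n_ref))
    extra_a = _dart_throw(
        rng_pos, n_extra, params.image_shape, min_sep_px, margin_px, existing=ref_pts
    )
    extra_b = _dart_throw(
        rng_pos, n_extra, params.image_shape, min_sep_px, margin_px,
        existing=ref_pts + extra_a,
    )

    a_pts = [p for p, s in zip(ref_pts, status) if s == "A"] + extra_a
    b_pts = [p for p, s in zip(ref_pts, status) if s == "B"] + extra_b

    channels = []
    for pts in (ref_pts, a_pts, b_pts):
        intensity = _render_spots(pts, params.image_shape, params.peak_rate, sigma_px)
        intensity += params.background_rate
        channels.append(rng_noise.poisson(intensity).astype(np.float64))

    img = MultiChannelImage(
        data=np.stack(channels),
        channel_names=["ref", "A", "B"],
        pixel_size_um=px,
    )
    truth = pd.DataFrame(
        {
            "y": [p[0] for p in ref_pts],
            "x": [p[1] for p in ref_pts],
            "status": status,
        }
    )
    return img, truth


# ---------------------------------------------------------------------------
# FLIM decays
# ---------------------------------------------------------------------------


def generate_flim_decay(p: FlimSimParams) -> FlimDecay:
    """Simulate a donor photon-arrival histogram for the two-state model.

    Photons come from the compact state (lifetime ``tau_D (1 - E)``) with the
    intensity fraction implied by the molecular fraction ``phi``, or from the
    extended state (lifetime ``tau_D``).  Arrival times beyond the histogram
    window are dropped (redrawn in ``fixed_total`` mode so the counts sum
    exactly to ``n_photons``); a window shorter than ``5 tau_D`` is allowed
    but logged as a truncation-bias warning.
    """
    tau_da = efficiency_to_lifetime(p.efficiency, p.tau_d_ns)
    f_photon = photon_fraction_from_molecular(p.phi, tau_da, p.tau_d_ns)
    window = p.n_bins * p.bin_width_ns
    if window < 5 * p.tau_d_ns:
        logger.warning(
            "histogram window %.2f ns < 5 tau_D (%.2f ns): truncation will bias "
            "lifetime estimates", window, 5 * p.tau_d_ns,
        )
    ss = np.random.SeedSequence(p.seed).spawn(2)
    rng_n, rng_t = (np.random.default_rng(s) for s in ss)
    n = p.n_photons if p.fixed_total else int(rng_n.poisson(p.n_photons))

    def _draw(k: int) -> np.ndarray:
        comp_short = rng_t.random(k) < f_photon
        tau = np.where(comp_short, tau_da, p.tau_d_ns)
        t = rng_t.exponential(tau)
        if p.background_fraction > 0:
            is_bg = rng_t.random(k) < p.background_fraction
            t[is_bg] = rng_t.uniform(0.0, window, size=int(is_bg.sum()))
        if p.irf_sigma_ns > 0:
            t = t + rng_t.normal(0.0, p.irf_sigma_ns, size=k)
        return t

    times = _draw(n)
    keep = (times >= 0) & (times < window)
    times = times[keep]
    if p.fixed_total:
        while times.size < n:
            extra = _draw(n - times.size)
            extra = extra[(extra >= 0) & (extra < window)]
            times = np.concatenate([times, extra])

    edges = np.arange(p.n_bins + 1) * p.bin_width_ns
    counts, _ = np.histogram(times, bins=edges)
    return FlimDecay(
        bin_edges_ns=edges,
        counts=counts.astype(np.int64),
        meta={
            "tau_d_ns": p.tau_d_ns,
            "tau_da_ns": tau_da,
            "phi": p.phi,
            "photon_fraction": f_photon,
            "n_photons_requested": p.n_photons,
        },
    )


# ---------------------------------------------------------------------------
# Gene tables
# ---------------------------------------------------------------------------


def generate_gene_pvalues(
    n_genes: int,
    frac_assoc: float,
    effect_z: float = 3.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene table with a controlled fraction of truly associated genes.

    Null genes draw p ~ Uniform(0, 1); each associated gene draws a test
    statistic from Normal(``effect_z``, 1) and reports its upper-tail normal
    p-value.  Columns: ``gene, p_value, is_associated``.
    """
    if not 0 <= frac_assoc <= 1:
        raise ValueError("frac_assoc must be in [0, 1]")
    if effect_z < 0:
        raise ValueError("effect_z must be >= 0")
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    from scipy.stats import norm

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    is_assoc = rng.random(n_genes) < frac_assoc
    p = rng.random(n_genes)
    n_assoc = int(is_assoc.sum())
    if n_assoc:
        z = rng.normal(effect_z, 1.0, size=n_assoc)
        p[is_assoc] = norm.sf(z)
    return pd.DataFrame(
        {
            "gene": [f"GENE{i:05d}" for i in range(n_genes)],
            "p_value": p,
            "is_associated": is_assoc,
        }
    )
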