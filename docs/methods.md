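# Methods

This note records the models behind each module, the conventions chosen
where more than one is defensible, and what the synthetic generators do and
do not emulate.

## Spine morphometry

**Classification.** The four-class taxonomy is applied exactly as printed
on the measurement triple (L, W_H, W_N), with inclusive/exclusive
boundaries as written: L ≤ 1 µm stubby (widths ignored — the rule carries no
width condition for short protrusions); 1 < L ≤ 3 µm split by W_H ≥ 2·W_N
(mushroom) vs W_H < 2·W_N (long thin); 3 < L ≤ 5 µm filopodia. The taxonomy
stops at 5 µm; anything longer is labelled `excluded`, kept out of class
percentages and mean length but reported as a separate count, because
silently dropping such objects would hide data. Mature = stubby + mushroom,
immature = long thin + filopodia.

**Mask measurement.** Length is the maximum geodesic distance (Euclidean
step weights, computed with `skimage.graph.MCP_Geometric`) from the base
attachment segment to any protrusion pixel, plus one pixel for the
half-pixel caps. The width profile comes from one-pixel-thick
geodesic-distance shells: each shell is a cross-section perpendicular to the
local axis, and its width is the largest pairwise distance between its
pixel centres plus one pixel. The head is the distal half of the length and
the neck the proximal half (`head_fraction` is configurable); W_H is the
widest distal shell, W_N the narrowest proximal shell. This convention was
chosen over a medial-axis-radius estimate because skeleton corner branches
near the base systematically corrupt the neck minimum; the shell chord is
exact on straight protrusions of any orientation and errs by at most about
one pixel on curved heads. Where along the spine the neck width is taken is
not fixed by any standard; the proximal-half minimum is the simplest
reproducible choice. Lengths are reported in µm to 3 decimals.

**Statistics.** The χ² statistic is the plain Pearson sum Σ(O−E)²/E with no
continuity correction (scipy `chi2_contingency(correction=False)`); tables
with a zero margin are rejected rather than patched. The two-sample K-S test
uses the asymptotic p-value. Both are cross-checked against brute-force
oracles in the test suite.

## Colocalization

Mander's coefficients are intensity-weighted and thresholded: M(ref→partner)
is the fraction of above-threshold reference intensity lying on pixels where
the partner is above its own threshold. Otsu is the default threshold —
deterministic and parameter-free; fixed-value and quantile thresholds are
available. Costes-style automatic thresholding and randomization testing are
out of scope.

The free fraction is 1 minus the reference mass on the *union* of the two
partner supports, so signal covered by both partners is counted once;
`free_fraction + union_overlap = 1` holds exactly. Treating the two
complexes as disjoint is an assumption of the biology; the object mode
(connected-component puncta, overlap = any shared pixel) reports the
A∩B double-positive count so the assumption can be checked on the data.

ROI quantification is total intensity over ROI area (µm²) — the
normalisation used for per-spine immunosignal readouts.

## FLIM-FRET two-conformation model

Transfer efficiency follows the Förster relation E = 1/(1+(r/R₀)⁶); at
R₀ = 5 nm a compact conformation with termini ~7 nm apart transfers
measurably (E ≈ 0.117) while an extended one at 12.8 nm does not
(E ≈ 0.0035). FRET shortens the donor lifetime, τ_DA = τ_D(1−E).

The decay model is a background-offset biexponential integrated over bins
and renormalised to the acquisition window; fitting maximises the Poisson
likelihood (least squares would mis-weight the sparse tail bins). τ_D is
fixed from a donor-only control to break the amplitude/lifetime degeneracy.
Optimisation uses Nelder–Mead in an unconstrained parametrisation
(log signal, logit fraction, log τ_DA, log background) from 10 Halton
quasi-random starts over (fraction, τ_DA), τ_DA initialised inside
(0, τ_D); relative log-likelihood tolerance 1e-8. Standard errors come from
the numerical observed information at the optimum (delta method).

**Brightness convention (important).** A molecule's expected photon yield is
taken proportional to its lifetime (constant radiative rate). The molecular
fraction φ of compact-state molecules therefore contributes the photon
fraction φτ_DA/(φτ_DA+(1−φ)τ_D), and equals the pre-exponential amplitude
fraction of the biexponential. Fitters in the wild report either
convention; both are returned (`phi_hat`, `photon_fraction`).

τ_D = 2.5 ns is used in simulations as a typical EGFP value — a convention,
not a measured quantity. Mean lifetimes are offered amplitude-weighted
(Σaᵢτᵢ/Σaᵢ) and intensity-weighted (Σaᵢτᵢ²/Σaᵢτᵢ).

## Structure geometry

Coordinates are parsed with biotite (PDB and mmCIF); the highest-occupancy
altloc is kept and waters stripped by default. A float64 copy of the
coordinates is held alongside the container so geometric readouts are exact
to double precision.

Termini distance is the Euclidean Cα–Cα distance between the first and last
resolved residues of a chain (falling back to the nearest resolved residue,
logged, when a terminal Cα is missing), reported in nm.

Shrake–Rupley SASA samples each atom's probe-inflated sphere
(probe 1.4 Å) with a deterministic Fibonacci lattice (default 960 points,
seed-free by construction) and counts points not occluded by any
neighbour's inflated sphere. Van der Waals radii: C 1.70, N 1.55, O 1.52,
S 1.80, P 1.80, H 1.20 Å; unknown elements get 1.70 Å with a warning;
hydrogens participate only if present in the file. The implementation is
cross-checked in tests against an independent latitude/longitude quadrature
oracle and against biotite's own implementation.

Residue burial computes SASA twice — complex and isolated chain — and
reports ΔSASA plus relative accessibilities against the Gly-X-Gly maximal
SASA values of Tien et al. (2013, PLoS ONE 8:e80635).

Hydrophobic runs are maximal stretches of ≥ `min_len` consecutive residues
from the set {A, V, L, I, M, F, W, C} (configurable — there is no single
standard hydrophobicity criterion); `X` is tolerated but never hydrophobic.
Residue numbering follows the supplied annotation (file author numbering),
so positions printed for a construct must be mapped by the caller if the
file numbering is offset from the reference sequence.

## Interactome enrichment

With n genes tested at nominal level α, the expected number of nominal hits
under the uniform null is n·α (36 genes at 0.05 → 1.8). Without a background
table the enrichment p-value is the exact binomial tail P(X ≥ k); with a
genome-wide background table, a one-sided Fisher exact test of
interactome-vs-background × significant-vs-not is added, using the
background's empirical rate — the appropriate test when gene-based p-values
are not uniform genome-wide (polygenic traits). Bonferroni adjustment is
min(1, p·m) with an optional family size m larger than the listed set.
Disease-category percentages are plain tallies over a supplied gene→disease
table, with multi-annotated genes counted once per category.

## Synthetic generators: what they emulate, and what not

All generators derive independent substreams from a single user seed
(`numpy.random.SeedSequence`) and are bitwise reproducible.

**Spine populations** sample per-class geometry uniformly from configurable
ranges chosen to look like their biological counterparts while respecting
the class definitions by construction (e.g. mushroom: L ∈ (1, 3], neck
0.2–0.3 µm, head/neck ratio 2–4; stubby: L ∈ (0.4, 1.0], head 0.3–0.6 µm).
Every generated spine classifies back to its true label.

**Dendrite rendering** is 2D (the z-projection regime of confocal stacks):
spines attach perpendicular to a straight horizontal shaft, alternating
sides at fixed spacing, each drawn as a neck rectangle (proximal half,
width W_N) topped by a head rectangle (distal half, width W_H). The photon
model is Poisson counts over a Gaussian-PSF-blurred binary shape plus a
uniform background; camera read noise is not modelled. Not emulated:
dendrite curvature, 3D structure, tilted or overlapping spines, uneven
staining — so pipeline-recovery results bound performance under ideal
segmentation, not under real tissue imaging.

**Puncta fields** place reference puncta by dart throwing with a minimum
mutual separation (1 µm default), assign partner status multinomially
(A/B/free), stamp partner puncta at bound reference centres, and add 10%
independent partner-only puncta kept away from reference positions. Default
imaging regime: 0.1 µm pixels, PSF σ 0.1 µm, 200 peak and 2 background
photons/pixel — typical confocal immunofluorescence SNR. No reference noise
regime exists for this kind of acquisition, so these defaults are chosen
for testability; at substantially dimmer settings (peak ≈ 50) the thresholded
free-fraction estimator acquires a positive bias of a few points from
threshold noise at punctum rims, which users should keep in mind on dim
data. Chance colocalization is excluded by the separation constraint —
real images include it.

**FLIM decays** draw per-photon state membership at the intensity fraction
implied by φ (brightness ∝ lifetime), exponential arrival times, optional
Gaussian IRF jitter (ideal delta by default — no instrument response is
assumed), and histogram over the window (default 256 × 0.1 ns ≈ 10 τ_D).
Out-of-window photons are dropped (redrawn in fixed-total mode); windows
shorter than 5 τ_D log a truncation warning. Total counts are Poisson
around `n_photons` unless `fixed_total`.

**Gene tables** give null genes p ~ Uniform(0,1) and associated genes the
upper-tail normal p of a draw from Normal(effect_z, 1) — a caricature of a
gene-based GWAS statistic with no linkage structure or gene-size effects.

## Numerical and calibration notes

* Problem sizes in the test suite (100 rendered spines at 0.02 µm pixels,
  20 puncta images, 50 decay fits at 1e5 photons, 2000 null-enrichment
  replicates) are sized to give the estimators' sampling noise a clear
  margin inside the tested tolerances while keeping the suite fast.
* Pixel-size quantization bounds measurement accuracy at ±1 px; the
  measure-then-classify recovery figure (≥95%) counts boundary-adjacent
  flips caused by that quantization as errors.
* The exact binomial test is discrete: at 36 genes its attainable level
  below 0.05 is 0.035, so null-calibration checks of the *rate* of nominal
  rejections use a gene count (351) where the attainable level is ≈ 0.050.
* Degenerate inputs are rejected loudly (zero χ² margins, empty ROI masks,
  constant images under Otsu, sub-minimum decay histograms) rather than
  returning silently defaulted values; undefined Mander's coefficients
  (empty above-threshold reference) are NaN with a warning.
* The two-state fit can in principle drift to τ_DA → τ_D where the fraction
  becomes unidentifiable; multistart initialisation inside (0, τ_D) and the
  fixed donor lifetime make this rare, and non-convergence is flagged on
  the result rather than raised.

## Known limitations

* No automatic spine detection or dendrite tracing: morphometry starts from
  per-protrusion masks (or measurement tables).
* No pixelwise FLIM imaging; one decay per fit.
* No molecular dynamics, docking or energetics; structural claims are
  limited to geometry and accessibility of supplied coordinates.
* Gene-based p-values are consumed, never computed from genotypes.
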