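"""Ground-truth generators: determinism, label consistency, photon bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from neuroquant.fret import FlimDecay, mean_lifetime
from neuroquant.spines import classify_spine
from neuroquant.synthetic import (
    ClassGeometryPriors,
    FlimSimParams,
    SpineRenderParams,
    generate_flim_decay,
    generate_gene_pvalues,
    generate_puncta_channels,
    generate_spine_population,
    protrusion_and_base,
    render_dendrite_image,
)

UNIFORM4 = {c: 0.25 for c in ("stubby", "mushroom", "long_thin", "filopodia")}


class TestSpinePopulation:
    def test_degenerate_distribution(self):
        ms, labels = generate_spine_population({"stubby": 1.0}, 10, seed=1)
        assert len(ms) == 10
        assert all(lab == "stubby" for lab in labels)
        assert all(m.L <= 1.0 for m in ms)

    def test_uniform_counts_within_sampling_bounds(self):
        _, labels = generate_spine_population(UNIFORM4, 4000, seed=3)
        counts = pd.Series(labels).value_counts()
        sigma = np.sqrt(4000 * 0.25 * 0.75)  # ~27.4
        for c in UNIFORM4:
            assert abs(counts[c] - 1000) <= 3 * sigma

    def test_determinism(self):
        a = generate_spine_population(UNIFORM4, 50, seed=9)
        b = generate_spine_population(UNIFORM4, 50, seed=9)
        assert a == b

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            generate_spine_population({"stubby": 0.5, "mushroom": 0.4}, 10)
        with pytest.raises(ValueError):
            generate_spine_population({"weird": 1.0}, 10)

    def test_label_round_trip_large(self):
        # every generated spine classifies back to its true label
        ms, labels = generate_spine_population(UNIFORM4, 10_000, seed=17)
        assert all(classify_spine(m) == lab for m, lab in zip(ms, labels))

    def test_priors_validated(self):
        with pytest.raises(ValueError):
            ClassGeometryPriors(stubby_L=(0.4, 1.5))
        with pytest.raises(ValueError):
            ClassGeometryPriors(mushroom_ratio=(1.5, 4.0))


class TestDendriteRendering:
    def test_single_stubby_axial_extent(self):
        from neuroquant.spines import SpineMeasurement

        spine = SpineMeasurement(L=0.8, W_H=0.5, W_N=0.4, id="s0")
        params = SpineRenderParams(psf_sigma_um=0.0, background_rate=0.0)
        img, truth = render_dendrite_image([spine], params, seed=0)
        labels = img.masks["labels"]
        rows = np.nonzero((labels == 1).any(axis=1))[0]
        extent = rows.max() - rows.min() + 1
        assert abs(extent - 8) <= 1  # 0.8 um at 0.1 um/px

    def test_zero_spines_shaft_only(self):
        img, truth = render_dendrite_image([], SpineRenderParams(), seed=0)
        assert truth.empty
        assert img.masks["labels"].max() == 0
        assert img.channel("morphology").sum() > 0  # shaft photons

    def test_all_zero_rates_give_zero_image(self):
        params = SpineRenderParams(background_rate=0.0, peak_rate=0.0)
        img, _ = render_dendrite_image([], params, seed=0)
        assert img.channel("morphology").sum() == 0

    def test_masks_disjoint(self):
        ms, _ = generate_spine_population(UNIFORM4, 10, seed=5)
        img, truth = render_dendrite_image(ms, SpineRenderParams(image_shape=(160, 512)), seed=5)
        labels = img.masks["labels"]
        # labels partition the spine pixels: counts add up
        assert (labels > 0).sum() == sum((labels == k).sum() for k in truth["label"])

    def test_oversized_spine_rejected(self):
        from neuroquant.spines import SpineMeasurement

        tall = SpineMeasurement(L=5.0, W_H=0.3, W_N=0.2, id="tall")
        with pytest.raises(ValueError, match="tall"):
            render_dendrite_image([tall], SpineRenderParams(image_shape=(40, 128)), seed=0)

    def test_protrusion_and_base_extraction(self):
        from neuroquant.spines import SpineMeasurement, measure_protrusion

        spine = SpineMeasurement(L=1.2, W_H=0.6, W_N=0.3, id="s0")
        params = SpineRenderParams(psf_sigma_um=0.0, background_rate=0.0)
        img, truth = render_dendrite_image([spine], params, seed=0)
        mask, base = protrusion_and_base(img, truth, 1)
        m = measure_protrusion(mask, base, params.pixel_size_um)
        assert m.L == pytest.approx(1.2, abs=0.15)


class TestPunctaChannels:
    def test_full_colocalization_with_a(self):
        params = SpineRenderParams(image_shape=(256, 256))
        img, truth = generate_puncta_channels(40, 1.0, 0.0, params, seed=2)
        assert (truth["status"] == "A").all()
        a = img.channel("A")
        # every reference punctum centre carries strong A signal
        for _, row in truth.iterrows():
            assert a[int(round(row.y)), int(round(row.x))] > 5 * params.background_rate

    def test_truth_fractions_multinomial(self):
        img, truth = generate_puncta_channels(
            300, 0.45, 0.40, SpineRenderParams(image_shape=(512, 512)), seed=4
        )
        free = (truth["status"] == "free").mean()
        sigma = np.sqrt(0.15 * 0.85 / 300)
        assert abs(free - 0.15) <= 4 * sigma

    def test_empty_field(self):
        img, truth = generate_puncta_channels(0, 0.5, 0.3, SpineRenderParams(), seed=0)
        assert truth.empty
        assert img.data.shape[0] == 3

    def test_overcommitted_fractions_rejected(self):
        with pytest.raises(ValueError):
            generate_puncta_channels(10, 0.7, 0.5, seed=0)

    def test_determinism(self):
        a_img, a_truth = generate_puncta_channels(50, 0.5, 0.2, seed=8)
        b_img, b_truth = generate_puncta_channels(50, 0.5, 0.2, seed=8)
        np.testing.assert_array_equal(a_img.data, b_img.data)
        pd.testing.assert_frame_equal(a_truth, b_truth)


def fit_single_exponential(decay: FlimDecay) -> float:
    """Poisson MLE of a single lifetime on a binned decay (test oracle)."""
    edges, counts = decay.bin_edges_ns, decay.counts.astype(float)

    def nll(log_tau):
        tau = np.exp(log_tau)
        cdf = 1.0 - np.exp(-edges / tau)
        mass = np.diff(cdf) / (cdf[-1] - cdf[0])
        mu = counts.sum() * mass
        return float((mu - counts * np.log(mu + 1e-300)).sum())

    res = optimize.minimize_scalar(nll, bounds=(-3, 3), method="bounded")
    return float(np.exp(res.x))


class TestFlimDecay:
    def test_mono_exponential_when_phi_zero(self):
        d = generate_flim_decay(FlimSimParams(phi=0.0, n_photons=100_000, seed=1))
        tau_hat = fit_single_exponential(d)
        assert tau_hat == pytest.approx(2.5, rel=0.02)

    def test_pure_compact_state_lifetime(self):
        # phi = 1, E = 0.5, tau_D = 2.5 -> mono-exponential at 1.25 ns
        d = generate_flim_decay(
            FlimSimParams(phi=1.0, efficiency=0.5, tau_d_ns=2.5, n_photons=100_000, seed=2)
        )
        tau_hat = fit_single_exponential(d)
        assert tau_hat == pytest.approx(1.25, rel=0.02)

    def test_mixture_mean_arrival_time(self):
        # photon-weighted mean arrival of the mixture: sum a_i tau_i^2 / sum a_i tau_i
        p = FlimSimParams(
            phi=0.5, efficiency=0.5, tau_d_ns=2.5, n_photons=100_000,
            n_bins=400, bin_width_ns=0.1, seed=3,
        )
        d = generate_flim_decay(p)
        a = np.array([0.5, 0.5])             # amplitude = molecular fraction
        tau = np.array([1.25, 2.5])
        expected = (a * tau**2).sum() / (a * tau).sum()
        # truncation at 40 ns (16 tau_DA) is negligible; MC error ~ tau/sqrt(N)
        assert mean_lifetime(d) == pytest.approx(expected, rel=0.02)

    def test_photon_bookkeeping(self):
        d = generate_flim_decay(FlimSimParams(n_photons=5000, seed=4))
        assert np.issubdtype(d.counts.dtype, np.integer)
        assert (d.counts >= 0).all()
        # Poisson-total mode: within 5 sigma of the requested count
        assert abs(d.total_counts - 5000) < 5 * np.sqrt(5000)

    def test_fixed_total_mode(self):
        d = generate_flim_decay(FlimSimParams(n_photons=5000, seed=4, fixed_total=True))
        assert d.total_counts == 5000

    def test_high_statistics_lifetime_within_one_percent(self):
        d = generate_flim_decay(FlimSimParams(phi=0.0, n_photons=1_000_000, seed=5))
        assert fit_single_exponential(d) == pytest.approx(2.5, rel=0.01)

    def test_short_window_logs_truncation_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="neuroquant.synthetic"):
            generate_flim_decay(FlimSimParams(n_bins=50, bin_width_ns=0.1, seed=0))
        assert any("truncation" in r.message for r in caplog.records)

    def test_determinism(self):
        a = generate_flim_decay(FlimSimParams(seed=11))
        b = generate_flim_decay(FlimSimParams(seed=11))
        np.testing.assert_array_equal(a.counts, b.counts)


class TestGenePvalues:
    def test_null_significant_count(self):
        df = generate_gene_pvalues(1000, 0.0, seed=1)
        k = (df["p_value"] < 0.05).sum()
        sigma = np.sqrt(1000 * 0.05 * 0.95)  # ~6.9
        assert abs(k - 50) <= 3 * sigma
        assert not df["is_associated"].any()

    def test_strong_association(self):
        df = generate_gene_pvalues(500, 1.0, effect_z=5.0, seed=2)
        # per-gene P(p < 0.05) = P(Z > -3.355) ~ 0.9996
        assert (df["p_value"] < 0.05).mean() > 0.99

    def test_determinism(self):
        a = generate_gene_pvalues(100, 0.3, seed=5)
        b = generate_gene_pvalues(100, 0.3, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            generate_gene_pvalues(10, 1.5)
        with pytest.raises(ValueError):
            generate_gene_pvalues(10, 0.5, effect_z=-1)
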