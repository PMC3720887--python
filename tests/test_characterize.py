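"""Modulation maps, SNR trade-off, axial profiles, contrast, frequency."""

import numpy as np
import pytest
from scipy.optimize import brentq

from simsect import (
    GridFrequency,
    IlluminationPattern,
    NoiseModel,
    Roi,
    SceneSpec,
    axial_profile,
    contrast_ratio,
    estimate_frequency,
    make_pattern_image,
    modulation_map,
    predicted_section_thickness,
    render_axial_series,
    render_triplet,
    section_thickness_from_profile,
    sectioned_image,
    snr_report,
    widefield_image,
)
from simsect.characterize import AxialProfile, section_thickness_subrois
from simsect.simulate import PhaseTriplet, effective_modulation
from tests.conftest import TABLE1_4X


def _unit_scene(shape=(32, 64), f=1.0, d=0.0, mus=0.0):
    return SceneSpec(
        focal_map=np.full(shape, f), background_map=np.full(shape, d),
        mus_prime=mus,
    )


class TestModulationMap:
    def test_noise_free_recovery(self, config, operating_frequency):
        """Programmed m_eff is recovered to 1e-6 and equals the 3-point
        cosine amplitude/mean oracle."""
        scene = _unit_scene()
        pat = IlluminationPattern(m0=0.45, nu=operating_frequency)
        t = render_triplet(scene, pat, config)
        m_eff = effective_modulation(scene, pat, config)
        mmap = modulation_map(t)
        assert mmap.roi_median == pytest.approx(m_eff, abs=1e-6)
        assert np.nanmax(np.abs(mmap.values - m_eff)) <= 1e-6

    def test_zero_modulation(self, config, operating_frequency):
        t = render_triplet(
            _unit_scene(), IlluminationPattern(m0=0.0, nu=operating_frequency),
            config,
        )
        assert modulation_map(t).roi_median == 0.0

    def test_scale_invariance(self, flat_triplet):
        scaled = PhaseTriplet(
            frames=tuple(3.7 * f for f in flat_triplet.frames),
            pattern=flat_triplet.pattern, config=flat_triplet.config,
        )
        assert modulation_map(scaled).roi_median == pytest.approx(
            modulation_map(flat_triplet).roi_median, rel=1e-12
        )

    def test_noisy_recovery_at_snr_30(self, config, operating_frequency):
        """Median m within 3% of truth at per-frame SNR ~ 30."""
        scene = _unit_scene(shape=(120, 120))
        pat = IlluminationPattern(m0=0.45, nu=operating_frequency)
        m_eff = effective_modulation(scene, pat, config)
        # mean frame intensity 0.5 -> photon_scale 1800 gives SNR = 30
        t = render_triplet(scene, pat, config,
                           NoiseModel(photon_scale=1800.0, seed=7))
        assert modulation_map(t).roi_median == pytest.approx(m_eff, rel=0.03)

    def test_background_lowers_measured_m(self, config, pattern):
        """Out-of-focus background dilutes the measured modulation depth."""
        clean = render_triplet(_unit_scene(d=0.0), pattern, config)
        turbid = render_triplet(_unit_scene(d=4.0), pattern, config)
        assert modulation_map(turbid).roi_median < modulation_map(clean).roi_median

    def test_ordering_with_frequency_and_scattering(self, config):
        """Measured median m falls with grid frequency and with turbidity."""
        medians = {}
        for nu in (19.6, 47.7, 101.0):
            for mus in (0.0, 10.0, 20.0):
                pat = IlluminationPattern(
                    m0=0.9, nu=GridFrequency.from_absolute(nu, config))
                t = render_triplet(_unit_scene(mus=mus), pat, config)
                medians[(nu, mus)] = modulation_map(t).roi_median
        for mus in (0.0, 10.0, 20.0):
            assert medians[(19.6, mus)] > medians[(47.7, mus)] > medians[(101.0, mus)]
        for nu in (19.6, 47.7, 101.0):
            assert medians[(nu, 0.0)] > medians[(nu, 10.0)] > medians[(nu, 20.0)]


class TestSnr:
    def test_ratio_decreases_with_modulation(self, config, operating_frequency):
        scene = _unit_scene()
        pat = IlluminationPattern(m0=0.45, nu=operating_frequency)
        t = render_triplet(scene, pat, config, NoiseModel(photon_scale=500, seed=0))
        r1 = snr_report(t, m=0.2).ratio
        r2 = snr_report(t, m=0.4).ratio
        assert r2 < r1

    def test_invalid_modulation_rejected(self, config, pattern, flat_scene):
        t = render_triplet(flat_scene, pattern, config,
                           NoiseModel(photon_scale=500, seed=0))
        with pytest.raises(ValueError):
            snr_report(t, m=0.0)

    def test_matched_modulation_matches_ratio(self, config):
        """Scenes with different turbidity tuned to the same measured m
        report SNR ratios within ~2% — the penalty tracks m alone."""
        nuA = GridFrequency.from_absolute(47.7, config)
        nuB = GridFrequency.from_absolute(24.1, config)
        sceneA = _unit_scene(mus=0.0)
        sceneB = _unit_scene(mus=10.0)
        patA = IlluminationPattern(m0=0.6, nu=nuA)
        mA = modulation_map(render_triplet(sceneA, patA, config)).roi_median

        def mismatch(m0):
            pat = IlluminationPattern(m0=float(m0), nu=nuB)
            return modulation_map(
                render_triplet(sceneB, pat, config)).roi_median - mA

        m0B = brentq(mismatch, 0.01, 1.0, xtol=1e-6)
        patB = IlluminationPattern(m0=m0B, nu=nuB)
        noise = NoiseModel(photon_scale=1800.0, seed=3)
        tA = render_triplet(sceneA, patA, config, noise)
        tB = render_triplet(sceneB, patB, config, noise)
        rA = snr_report(tA).ratio
        rB = snr_report(tB).ratio
        assert abs(rA / rB - 1) <= 0.02

    def test_monte_carlo_oracle(self, config, operating_frequency):
        """Analytic uniform/sectioned SNRs match empirical SNRs over 200
        seeded noise realizations within 5%."""
        scene = _unit_scene(shape=(48, 48))
        pat = IlluminationPattern(m0=0.45, nu=operating_frequency)
        m_eff = effective_modulation(scene, pat, config)
        noise_scale = 1800.0
        wides, sects = [], []
        for i in range(200):
            t = render_triplet(scene, pat, config,
                               NoiseModel(photon_scale=noise_scale, seed=5000 + i))
            wides.append(widefield_image(t).pixels)
            sects.append(sectioned_image(t).pixels)
        wides, sects = np.array(wides), np.array(sects)
        snr_u_mc = wides.mean() / wides.std(axis=0).mean()
        snr_s_mc = sects.mean() / sects.std(axis=0).mean()
        report = snr_report(
            render_triplet(scene, pat, config,
                           NoiseModel(photon_scale=noise_scale, seed=1)),
            m=m_eff,
        )
        assert report.snr_uniform == pytest.approx(snr_u_mc, rel=0.05)
        assert report.snr_sectioned == pytest.approx(snr_s_mc, rel=0.05)
        assert report.ratio == pytest.approx(snr_u_mc / snr_s_mc, rel=0.05)


class TestAxialProfile:
    def test_round_trip_matches_stokseth(self, config, pattern, flat_scene):
        """Noise-free profile reproduces the axial response to 1e-6."""
        from simsect import AxialModel

        zs, series = render_axial_series(
            flat_scene, pattern, config, z_range=(-200, 200), z_step=10
        )
        profile = axial_profile((zs, series))
        model = AxialModel(config=config, frequency=pattern.nu)
        assert np.allclose(profile.intensity, model.response(profile.z), atol=1e-6)

    def test_symmetry(self, config, pattern, flat_scene):
        zs, series = render_axial_series(
            flat_scene, pattern, config, z_range=(-100, 100), z_step=20
        )
        p = axial_profile((zs, series))
        assert np.allclose(p.intensity, p.intensity[::-1], atol=1e-9)

    def test_too_few_positions_rejected(self, config, pattern, flat_scene):
        zs, series = render_axial_series(
            flat_scene, pattern, config, z_range=(0, 30), z_step=10
        )
        with pytest.raises(ValueError, match="5"):
            axial_profile((zs, series))


class TestSectionThickness:
    def test_thinnest_section_from_sampled_profile(self, config):
        """A 10 um-sampled profile at nu_norm = 1 yields 36.6 +/- 0.5 um."""
        from simsect import AxialModel, GridFrequency

        freq = GridFrequency.from_normalized(1.0, config)
        model = AxialModel(config=config, frequency=freq)
        z = np.arange(-100.0, 100.1, 10.0)
        profile = AxialProfile(z=z, intensity=model.response(z))
        assert section_thickness_from_profile(profile) == pytest.approx(36.6, abs=0.5)

    def test_no_crossing_raises(self):
        profile = AxialProfile(z=np.arange(5.0), intensity=np.ones(5))
        with pytest.raises(ValueError, match="50"):
            section_thickness_from_profile(profile)

    def test_sampling_refinement_bound(self, config, pattern, flat_scene):
        """10 um and 1 um sampled scans agree within 1 um."""
        out = {}
        for step in (10.0, 1.0):
            zs, series = render_axial_series(
                flat_scene, pattern, config, z_range=(-160, 160), z_step=step
            )
            out[step] = section_thickness_from_profile(axial_profile((zs, series)))
        assert abs(out[10.0] - out[1.0]) <= 1.0

    @pytest.mark.parametrize("mus_prime", [0.0, 10.0, 20.0])
    def test_matches_theory_at_all_frequencies(self, config, mus_prime):
        """Measured thickness within 2% of the closed form at every
        instrument frequency, independent of scattering level."""
        scene = SceneSpec(
            focal_map=np.full((16, 64), 2.0),
            background_map=np.full((16, 64), 5.0),
            mus_prime=mus_prime,
        )
        for nu in TABLE1_4X:
            freq = GridFrequency.from_absolute(nu, config)
            pat = IlluminationPattern(m0=0.9, nu=freq)
            predicted = predicted_section_thickness(freq, config)
            half_range = min(260.0, 2.2 * predicted)
            zs, series = render_axial_series(
                scene, pat, config, z_range=(-half_range, half_range), z_step=10
            )
            measured = section_thickness_from_profile(axial_profile((zs, series)))
            assert measured == pytest.approx(predicted, rel=0.02)

    def test_subroi_spread_is_small_noise_free(self, config, pattern, flat_scene):
        zs, series = render_axial_series(
            flat_scene, pattern, config, z_range=(-160, 160), z_step=10
        )
        mean, std, values = section_thickness_subrois(
            (zs, series), Roi(0, 16, 0, 64))
        assert len(values) == 8
        assert std <= 1e-6 * mean


class TestContrastRatio:
    def test_uniform_image_is_unity(self):
        img = np.full((40, 40), 3.0)
        report = contrast_ratio(img, [Roi(0, 5, 0, 5)], Roi(20, 30, 20, 30))
        assert report.mean_ratio == pytest.approx(1.0)

    def test_synthetic_spheres_at_10x(self):
        img = np.ones((60, 60))
        targets = [Roi(r, r + 4, c, c + 4) for r, c in ((5, 5), (5, 30), (30, 5))]
        for t in targets:
            img[t.slice()] = 10.0
        report = contrast_ratio(img, targets, Roi(45, 55, 45, 55))
        assert report.mean_ratio == pytest.approx(10.0, abs=1e-6)
        assert report.per_target.shape == (3,)

    def test_zero_background_rejected(self):
        img = np.zeros((20, 20))
        with pytest.raises(ValueError):
            contrast_ratio(img, [Roi(0, 5, 0, 5)], Roi(10, 15, 10, 15))

    def test_sectioning_contrast_gain_on_turbid_spheres(self, config):
        """Sectioned image of bright targets over strong out-of-focus
        background shows a much higher target contrast than widefield."""
        rng = np.random.default_rng(0)
        f = np.full((80, 80), 0.05)
        targets = [Roi(r, r + 6, c, c + 6)
                   for r, c in ((10, 10), (10, 50), (50, 10), (50, 50), (38, 38))]
        for t in targets:
            f[t.slice()] = 1.0
        scene = SceneSpec(focal_map=f,
                          background_map=np.full((80, 80), 6.0), mus_prime=10.0)
        pat = IlluminationPattern(
            m0=1.0, nu=GridFrequency.from_absolute(31.7, config))
        t3 = render_triplet(scene, pat, config)
        bg = Roi(25, 33, 60, 68)
        c_sect = contrast_ratio(sectioned_image(t3).pixels, targets, bg).mean_ratio
        c_wide = contrast_ratio(widefield_image(t3).pixels, targets, bg).mean_ratio
        assert c_sect / c_wide > 5.0  # order-of-magnitude sectioning gain


class TestFrequencyEstimation:
    def test_recovers_pattern_frequency(self, config):
        """A rendered 31.7 mm^-1 grid is read back within 0.2 mm^-1."""
        nu = GridFrequency.from_absolute(31.7, config)
        pat = IlluminationPattern(m0=1.0, nu=nu)
        img = make_pattern_image((32, 512), pat, config, 1)
        est = estimate_frequency(img, config)
        assert not est.flagged
        assert est.frequency.nu_abs == pytest.approx(31.7, abs=0.2)

    def test_flat_image_flagged(self, config):
        est = estimate_frequency(np.full((32, 256), 2.0), config)
        assert est.flagged
        assert est.frequency.nu_abs == 0.0

    @pytest.mark.parametrize("nu_abs", TABLE1_4X)
    def test_table_frequencies_representable_and_recovered(self, config, nu_abs):
        nu = GridFrequency.from_absolute(nu_abs, config)
        img = make_pattern_image(
            (8, 1024), IlluminationPattern(m0=0.8, nu=nu), config, 2)
        est = estimate_frequency(img, config)
        assert est.frequency.nu_abs == pytest.approx(nu_abs, abs=0.4)
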