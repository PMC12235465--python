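"""Azimuthal regrouping against a brute-force oracle, and 1D reductions."""

import numpy as np
import pytest

from npfate.dosimetry import BeamGeometry
from npfate.phantom import ParticleModel, PhantomSpec, form_factor_intensity, render_frame
from npfate.saxs_reduce import (
    Curve1D,
    DetectorFrame,
    EmptyCakeError,
    UndefinedAzimuthError,
    azimuthal_integrate,
    azimuthal_regroup,
    pixel_q_theta,
    q_theta_maps,
    radial_integrate,
    subtract_background,
)


def brute_force_cake(frame, beam, n_q, n_theta):
    """Independent per-pixel double-loop binning oracle."""
    q_map, theta_map = q_theta_maps(beam, frame.counts.shape)
    keep = ~frame.mask & np.isfinite(theta_map)
    q_lo, q_hi = q_map[keep].min(), q_map[keep].max()
    q_edges = np.linspace(q_lo, q_hi, n_q + 1)
    t_edges = np.linspace(-np.pi, np.pi, n_theta + 1)
    sums = np.zeros((n_q, n_theta))
    counts = np.zeros((n_q, n_theta), dtype=int)
    for i in range(frame.counts.shape[0]):
        for j in range(frame.counts.shape[1]):
            if not keep[i, j]:
                continue
            q, t = q_map[i, j], theta_map[i, j]
            qi = min(int(np.searchsorted(q_edges, q, side="right")) - 1, n_q - 1)
            ti = min(int(np.searchsorted(t_edges, t, side="right")) - 1, n_theta - 1)
            if qi < 0 or ti < 0:
                continue
            sums[qi, ti] += frame.counts[i, j]
            counts[qi, ti] += 1
    mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return mean, counts, q_edges, t_edges


class TestPixelQTheta:
    def test_wavelength_from_energy(self, beam):
        """lambda = 12.398 / E: 20.129 keV -> 0.61595 A."""
        assert beam.wavelength_A == pytest.approx(12.398 / 20.129, rel=1e-12)
        assert beam.wavelength_A == pytest.approx(0.61593, abs=1e-5)

    def test_axis_conventions(self):
        beam = BeamGeometry(
            energy_kev=20.0, sample_detector_mm=5000.0, pixel_um=100.0, beam_center=(10.0, 10.0)
        )
        _, theta_x = pixel_q_theta(beam, (10, 15))  # +x axis
        _, theta_y = pixel_q_theta(beam, (15, 10))  # +y axis
        assert theta_x == pytest.approx(0.0, abs=1e-12)
        assert theta_y == pytest.approx(np.pi / 2, abs=1e-12)

    def test_beam_center_has_q_zero_and_undefined_azimuth(self):
        beam = BeamGeometry(
            energy_kev=20.0, sample_detector_mm=5000.0, pixel_um=100.0, beam_center=(10.0, 10.0)
        )
        with pytest.raises(UndefinedAzimuthError):
            pixel_q_theta(beam, (10, 10))
        q_map, theta_map = q_theta_maps(beam, (21, 21))
        assert q_map[10, 10] == 0.0
        assert np.isnan(theta_map[10, 10])

    def test_q_increases_with_radius(self, beam):
        q1, _ = pixel_q_theta(beam, (31.5, 40))
        q2, _ = pixel_q_theta(beam, (31.5, 55))
        assert 0 < q1 < q2


class TestAzimuthalRegroup:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        """Cell-by-cell equality with the per-pixel double-loop oracle over
        random geometries, frames and masks."""
        rng = np.random.default_rng(seed)
        center = tuple(rng.uniform(20, 44, size=2))
        beam = BeamGeometry(
            energy_kev=float(rng.uniform(8, 25)),
            sample_detector_mm=float(rng.uniform(2000, 12000)),
            pixel_um=float(rng.uniform(50, 500)),
            beam_center=center,
        )
        counts = rng.poisson(50.0, size=(64, 64)).astype(float)
        mask = rng.random((64, 64)) < 0.1
        frame = DetectorFrame(counts=counts, mask=mask)
        n_q, n_theta = int(rng.integers(5, 40)), int(rng.integers(4, 48))
        cake = azimuthal_regroup(frame, beam, n_q, n_theta)
        mean, n, q_edges, t_edges = brute_force_cake(frame, beam, n_q, n_theta)
        np.testing.assert_array_equal(cake.pixel_counts, n)
        np.testing.assert_allclose(cake.intensity, mean, rtol=1e-12, equal_nan=True)
        np.testing.assert_allclose(cake.q_edges, q_edges)

    def test_frame_of_ones_gives_cells_of_one(self, beam):
        frame = DetectorFrame(counts=np.ones((64, 64)))
        cake = azimuthal_regroup(frame, beam, 10, 12)
        assert np.all(cake.intensity[cake.valid] == 1.0)

    def test_isotropic_frame_rows_constant(self, isotropic_spec, beam):
        frame = render_frame(isotropic_spec, (0, 0))
        cake = azimuthal_regroup(frame, beam, 12, 16)
        for row in range(12):
            vals = cake.intensity[row][cake.valid[row]]
            if vals.size > 4:
                # cells mix slightly different radii; spread stays small
                assert np.ptp(vals) / vals.mean() < 0.35

    def test_conservation_of_total_counts(self, beam):
        """Sum over cells of mean x pixel_counts equals the total unmasked
        counts exactly (beam-center pixel excluded by construction)."""
        rng = np.random.default_rng(5)
        counts = rng.poisson(30.0, size=(64, 64)).astype(float)
        mask = rng.random((64, 64)) < 0.2
        frame = DetectorFrame(counts=counts, mask=mask)
        cake = azimuthal_regroup(frame, beam, 17, 23)
        _, theta_map = q_theta_maps(beam, counts.shape)
        keep = ~mask & np.isfinite(theta_map)
        total = np.nansum(np.where(cake.valid, cake.intensity * cake.pixel_counts, 0.0))
        assert total == pytest.approx(counts[keep].sum(), rel=1e-12)

    def test_all_masked_raises(self, beam):
        frame = DetectorFrame(counts=np.ones((32, 32)), mask=np.ones((32, 32), dtype=bool))
        with pytest.raises(EmptyCakeError):
            azimuthal_regroup(frame, beam, 5, 5)

    def test_rotation_covariance(self, beam, anisotropic_spec):
        """Rotating the frame by 90 degrees about the beam center shifts the
        azimuthal profile circularly by pi/2 (within interpolation error)."""
        frame = render_frame(anisotropic_spec, (0, 0))
        rotated = DetectorFrame(counts=np.rot90(frame.counts).copy())
        n_theta = 36
        cake_a = azimuthal_regroup(frame, beam, 10, n_theta)
        cake_b = azimuthal_regroup(rotated, beam, 10, n_theta)
        prof_a = azimuthal_integrate(cake_a, 0.002, 0.012).intensity
        prof_b = azimuthal_integrate(cake_b, 0.002, 0.012).intensity
        shift = n_theta // 4  # pi/2 in bins
        np.testing.assert_allclose(np.roll(prof_a, shift), prof_b, rtol=0.02)


class TestIntegrations:
    def test_constant_cake_gives_flat_curve(self, beam):
        frame = DetectorFrame(counts=np.full((64, 64), 7.0))
        cake = azimuthal_regroup(frame, beam, 9, 11)
        curve = radial_integrate(cake)
        valid = np.isfinite(curve.intensity)
        np.testing.assert_allclose(curve.intensity[valid], 7.0, rtol=1e-12)
        profile = azimuthal_integrate(cake, cake.q_edges[0], cake.q_edges[-1])
        np.testing.assert_allclose(profile.intensity, 7.0, rtol=1e-12)

    def test_radial_curve_matches_forward_model(self, isotropic_spec, beam):
        """The regrouped radial curve reproduces the generating form factor
        within 1% wherever enough pixels contribute (resolved-binning regime)."""
        frame = render_frame(isotropic_spec, (0, 0))
        cake = azimuthal_regroup(frame, beam, 40, 36)
        curve = radial_integrate(cake)
        ideal = form_factor_intensity(isotropic_spec.particle, curve.q)
        enough = cake.pixel_counts.sum(axis=1) > 50
        rel = np.abs(curve.intensity - ideal) / ideal
        assert np.nanmax(rel[enough]) < 0.01

    def test_isotropic_azimuthal_profile_flat(self, isotropic_spec, beam):
        frame = render_frame(isotropic_spec, (0, 0))
        cake = azimuthal_regroup(frame, beam, 20, 24)
        profile = azimuthal_integrate(cake, 0.002, 0.012)
        vals = profile.intensity[np.isfinite(profile.intensity)]
        assert np.ptp(vals) / vals.mean() < 0.25  # ring-mixing spread only

    def test_empty_q_window_raises(self, beam):
        frame = DetectorFrame(counts=np.ones((32, 32)))
        cake = azimuthal_regroup(frame, beam, 5, 5)
        with pytest.raises(ValueError):
            azimuthal_integrate(cake, 10.0, 20.0)


class TestSubtractBackground:
    def test_self_subtraction_zeroes(self):
        q = np.linspace(0.001, 0.02, 30)
        c = Curve1D(q=q, intensity=np.exp(-q * 100), sigma=np.full_like(q, 0.01))
        out = subtract_background(c, c, scale=1.0)
        np.testing.assert_allclose(out.intensity, 0.0, atol=1e-15)
        np.testing.assert_allclose(out.sigma, np.sqrt(2) * 0.01)

    def test_scale_zero_is_identity(self):
        q = np.linspace(0.001, 0.02, 30)
        c = Curve1D(q=q, intensity=np.exp(-q * 100))
        b = Curve1D(q=q, intensity=np.ones_like(q))
        out = subtract_background(c, b, scale=0.0)
        np.testing.assert_array_equal(out.intensity, c.intensity)

    def test_recovers_particle_only_curve(self):
        """Particle+solvent minus solvent-only returns the particle term."""
        q = np.linspace(0.001, 0.02, 50)
        particle = 100.0 * np.exp(-(q**2) * 100.0**2 / 3.0)
        solvent = 5.0 + 10.0 * q
        total = Curve1D(q=q, intensity=particle + solvent)
        background = Curve1D(q=q, intensity=solvent)
        out = subtract_background(total, background)
        np.testing.assert_allclose(out.intensity, particle, rtol=1e-12)

    def test_interpolates_onto_sample_grid(self):
        q_s = np.linspace(0.002, 0.018, 40)
        q_b = np.linspace(0.001, 0.02, 25)
        sample = Curve1D(q=q_s, intensity=np.full_like(q_s, 10.0))
        background = Curve1D(q=q_b, intensity=2.0 * q_b)  # linear: interp exact
        out = subtract_background(sample, background)
        np.testing.assert_allclose(out.intensity, 10.0 - 2.0 * q_s, rtol=1e-12)

    def test_disjoint_grids_rejected(self):
        sample = Curve1D(q=np.linspace(0.01, 0.02, 10), intensity=np.ones(10))
        background = Curve1D(q=np.linspace(0.05, 0.06, 10), intensity=np.ones(10))
        with pytest.raises(ValueError):
            subtract_background(sample, background)

    def test_negative_results_retained_with_warning(self):
        q = np.linspace(0.001, 0.02, 10)
        sample = Curve1D(q=q, intensity=np.ones(10))
        background = Curve1D(q=q, intensity=np.full(10, 2.0))
        with pytest.warns(UserWarning, match="negative"):
            out = subtract_background(sample, background)
        assert np.all(out.intensity == -1.0)
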