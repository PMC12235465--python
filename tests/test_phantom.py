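"""Particle models, form factors and phantom rendering."""

import numpy as np
import pytest

from npfate.guinier import guinier_fit
from npfate.phantom import (
    CelluloseBackground,
    InvalidModelError,
    ParticleModel,
    PhantomSpec,
    form_factor_intensity,
    radius_of_gyration,
    render_frame,
    render_timeseries_phantoms,
)
from npfate.saxs_reduce import Curve1D


def make_models():
    return [
        ParticleModel(shape="sphere", radius=50.0),
        ParticleModel(shape="cylinder", length=280.0, cyl_radius=80.0),
        ParticleModel(shape="core_shell_sphere", core_radius=330.0, shell_thickness=120.0),
        ParticleModel(shape="guinier", rg=297.0),
    ]


class TestFormFactor:
    def test_guinier_forward_intensity(self):
        """Forward intensity of the baseline nHAP Guinier model is I0 = 7845."""
        model = ParticleModel(shape="guinier", rg=297.0, concentration=7845.0)
        assert form_factor_intensity(model, np.array([0.0]))[0] == pytest.approx(7845.0)

    def test_sphere_first_minimum(self):
        """|F|^2 of a 50 A sphere has its first zero at q = 4.493/R."""
        model = ParticleModel(shape="sphere", radius=50.0)
        q = np.linspace(0.05, 0.12, 40001)
        i = form_factor_intensity(model, q)
        q_min = q[np.argmin(i)]
        assert q_min == pytest.approx(4.493 / 50.0, rel=1e-3)

    @pytest.mark.parametrize("model", make_models(), ids=lambda m: m.shape)
    def test_zero_concentration_scatters_nothing(self, model):
        from dataclasses import replace

        empty = replace(model, concentration=0.0)
        q = np.linspace(1e-4, 0.05, 50)
        assert np.all(form_factor_intensity(empty, q) == 0.0)

    @pytest.mark.parametrize("model", make_models(), ids=lambda m: m.shape)
    def test_monotone_and_finite_in_guinier_regime(self, model):
        rg = radius_of_gyration(model)
        q = np.linspace(1e-5, 1.0 / rg, 200)
        i = form_factor_intensity(model, q)
        assert np.all(np.isfinite(i))
        assert np.all(np.diff(i) < 0)

    def test_concentration_linearity(self):
        """Doubling concentration doubles the noiseless intensity pointwise."""
        q = np.linspace(1e-4, 0.02, 64)
        m1 = ParticleModel(shape="sphere", radius=50.0, concentration=1.0)
        m2 = ParticleModel(shape="sphere", radius=50.0, concentration=2.0)
        np.testing.assert_allclose(
            form_factor_intensity(m2, q), 2.0 * form_factor_intensity(m1, q), rtol=1e-12
        )

    def test_invalid_dimension_rejected(self):
        with pytest.raises(InvalidModelError):
            ParticleModel(shape="sphere", radius=-5.0)
        with pytest.raises(InvalidModelError):
            ParticleModel(shape="cylinder", length=100.0, cyl_radius=0.0)


class TestRadiusOfGyration:
    def test_sphere_closed_form(self):
        """Rg of a 50 A sphere is sqrt(3/5)*50 = 38.73 A."""
        assert radius_of_gyration(ParticleModel(shape="sphere", radius=50.0)) == pytest.approx(
            38.7298, abs=1e-3
        )

    def test_cylinder_closed_form(self):
        """nHAP rod geometry (L=280 A, R=80 A) gives Rg = 98.66 A."""
        model = ParticleModel(shape="cylinder", length=280.0, cyl_radius=80.0)
        assert radius_of_gyration(model) == pytest.approx(
            np.sqrt(280.0**2 / 12.0 + 80.0**2 / 2.0), rel=1e-12
        )
        assert radius_of_gyration(model) == pytest.approx(98.66, abs=0.01)

    def test_guinier_identity(self):
        assert radius_of_gyration(ParticleModel(shape="guinier", rg=297.0)) == 297.0

    @pytest.mark.parametrize("model", make_models(), ids=lambda m: m.shape)
    def test_guinier_fit_consistency(self, model):
        """A Guinier fit of the noiseless form factor restricted to
        q*Rg <= 1 recovers the closed-form Rg within 2% for every shape."""
        rg = radius_of_gyration(model)
        q = np.linspace(0.05 / rg, 1.0 / rg, 60)
        curve = Curve1D(q=q, intensity=form_factor_intensity(model, q))
        fit = guinier_fit(curve, q_window=(q[0], q[-1]))
        assert fit.rg == pytest.approx(rg, rel=0.02)


class TestRenderFrame:
    def test_isotropic_frame_constant_on_rings(self, isotropic_spec, beam):
        """With no background and no noise, pixels at equal radius from the
        beam center carry equal intensity."""
        frame = render_frame(isotropic_spec, (0, 0))
        from npfate.saxs_reduce import q_theta_maps

        q_map, _ = q_theta_maps(beam, frame.counts.shape)
        r = np.round(np.hypot(*np.mgrid[0:64, 0:64] - np.array([[[31.5]], [[31.5]]])), 6)
        for radius in np.unique(r)[:20]:
            ring = frame.counts[r == radius]
            assert np.ptp(ring) <= 1e-9 * ring.max()

    def test_zero_anisotropy_fraction_rotation_invariant(self, beam):
        """An f=0 background frame is invariant under 90-degree rotation
        about the beam center (exact for a centered square detector)."""
        spec = PhantomSpec(
            beam=beam,
            mesh_shape=(1, 1),
            particle=ParticleModel(shape="guinier", rg=100.0, concentration=0.0),
            concentration_field=np.ones((1, 1)),
            background=CelluloseBackground(amplitude=1e-4, anisotropy_fraction=0.0),
            frame_shape=(64, 64),
        )
        frame = render_frame(spec, (0, 0)).counts
        np.testing.assert_allclose(frame, np.rot90(frame), rtol=1e-10)

    def test_fixed_seed_reproducible(self, beam):
        spec = PhantomSpec(
            beam=beam,
            mesh_shape=(2, 2),
            particle=ParticleModel(shape="guinier", rg=100.0, concentration=100.0),
            concentration_field=np.ones((2, 2)),
            frame_shape=(32, 32),
            noise="poisson",
            seed=42,
        )
        a = render_frame(spec, (1, 0)).counts
        b = render_frame(spec, (1, 0)).counts
        np.testing.assert_array_equal(a, b)

    def test_point_outside_mesh_rejected(self, isotropic_spec):
        with pytest.raises(IndexError):
            render_frame(isotropic_spec, (5, 0))


class TestTimeseriesPhantoms:
    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="unknown mode"):
            render_timeseries_phantoms([0, 1], "sublimation")

    def test_unsorted_days_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            render_timeseries_phantoms([3, 0], "dissolution")

    def test_deterministic_per_seed(self):
        kwargs = dict(
            mesh_shape=(3, 3), frame_shape=(32, 32), volume_shape=(24, 24, 24), map_shape=(24, 24)
        )
        a = render_timeseries_phantoms([0, 1], "dissolution", seed=7, **kwargs)
        b = render_timeseries_phantoms([0, 1], "dissolution", seed=7, **kwargs)
        np.testing.assert_array_equal(a[0].scan.frames, b[0].scan.frames)
        np.testing.assert_array_equal(a[1].volume.gray, b[1].volume.gray)
        np.testing.assert_array_equal(a[1].xrf_mobile.intensity, b[1].xrf_mobile.intensity)

    def test_single_day_gives_insufficient_timepoints_downstream(self):
        from npfate.multimodal import InsufficientTimepointsError, correlate_case

        phs = render_timeseries_phantoms(
            [0],
            "dissolution",
            mesh_shape=(3, 3),
            frame_shape=(32, 32),
            volume_shape=(24, 24, 24),
            map_shape=(24, 24),
        )
        with pytest.raises(InsufficientTimepointsError):
            correlate_case([0], [phs[0].scan.frames[0, 0]], [1.0], [phs[0].xrf_immobile])
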