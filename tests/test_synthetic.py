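"""Generator-level checks: probe trace, substrate field, beads, movies, cohorts."""

import numpy as np
import pytest

from vibracal.imaging import extract_region_timecourses_intensity, partition_regions
from vibracal.mechanics import GridSpec
from vibracal.synthetic import (
    AcquisitionModel,
    CellPhantom,
    EquipmentModel,
    ImageSpec,
    ResponseModel,
    SubstrateFieldModel,
    SyntheticError,
    default_cell_phantom,
    dominant_frequency,
    draw_classes,
    generate_bead_images,
    generate_cohort,
    generate_displacement_field,
    generate_fret_movie,
    generate_probe_trace,
)


class TestProbeTrace:
    def test_default_spectral_peak_is_140_hz(self):
        trace = generate_probe_trace(EquipmentModel())
        bin_hz = 1.0 / EquipmentModel().duration
        assert abs(dominant_frequency(trace) - 140.0) <= bin_hz

    def test_zero_amplitude_gives_zero_trace(self):
        trace = generate_probe_trace(EquipmentModel(amplitude=0.0))
        assert np.all(trace.displacement_um == 0.0)

    def test_undamped_10hz_has_10_upcrossings_per_second(self):
        model = EquipmentModel(
            frequency=10.0, sampling_rate=1000.0, duration=1.0, damping_time=None
        )
        x = generate_probe_trace(model).displacement_um
        up = np.sum((x[:-1] <= 0) & (x[1:] > 0))
        assert up == 10

    def test_damped_energy_decays_across_periods(self):
        model = EquipmentModel(damping_time=0.05, duration=0.2)
        x = generate_probe_trace(model).displacement_um
        per = int(round(model.sampling_rate / model.frequency))
        energies = [
            np.sum(x[i * per : (i + 1) * per] ** 2) for i in range(len(x) // per)
        ]
        assert all(a > b for a, b in zip(energies, energies[1:]))

    def test_deterministic_for_fixed_inputs(self):
        a = generate_probe_trace(EquipmentModel(), seed=3, jitter=0.01)
        b = generate_probe_trace(EquipmentModel(), seed=3, jitter=0.01)
        assert np.array_equal(a.displacement_um, b.displacement_um)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"frequency": 0.0},
            {"amplitude": -1.0},
            {"duration": 0.0},
            {"sampling_rate": 200.0},  # below Nyquist for 140 Hz
            {"damping_time": 0.0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(SyntheticError):
            EquipmentModel(**kwargs)


class TestDisplacementField:
    def test_peak_value_and_location(self, field_model, grid):
        field, _ = generate_displacement_field(field_model, grid)
        mag = field.magnitude
        i, j = np.unravel_index(np.argmax(mag), mag.shape)
        assert mag[i, j] == pytest.approx(field_model.peak_displacement, rel=0.01)
        d = (
            np.hypot(
                grid.x[j] - field_model.probe_position[0],
                grid.y[i] - field_model.probe_position[1],
            )
            - field_model.probe_radius
        )
        assert abs(d - field_model.peak_offset) <= grid.spacing

    def test_zero_peak_gives_zero_field(self, grid):
        model = SubstrateFieldModel(peak_displacement=0.0)
        field, grad = generate_displacement_field(model, grid)
        assert np.all(field.u_x == 0.0) and np.all(field.u_y == 0.0)
        assert all(np.all(g == 0.0) for g in grad.values())

    def test_far_cell_edge_displacement_negligible(self, field_model):
        # the far cell edge sits ~138 µm beyond the probe edge
        x = field_model.probe_position[0]
        y = field_model.probe_position[1] - field_model.probe_radius - 138.0
        u_x, u_y = field_model.displacement(np.array([x]), np.array([y]))
        assert np.hypot(u_x, u_y)[0] < 0.02 * field_model.peak_displacement

    def test_analytic_gradient_matches_central_differences(self, field_model):
        # O(h^2) agreement, checked on the smooth exponential tail
        h = 0.5
        g = GridSpec(origin=(20.0, 100.0), shape=(81, 81), spacing=h)
        field, grad = generate_displacement_field(field_model, g)
        num = np.gradient(field.u_y, h, axis=0, edge_order=2)
        X, Y = g.mesh()
        d = (
            np.hypot(X - field_model.probe_position[0], Y - field_model.probe_position[1])
            - field_model.probe_radius
        )
        sel = d > field_model.peak_offset + 5.0
        sel[[0, -1], :] = False
        err = np.abs(num - grad["duy_dy"])[sel]
        assert err.max() < 5e-4  # second-order truncation at h = 0.5 µm

    def test_coarse_grid_rejected(self, field_model):
        g = GridSpec(origin=(0, 0), shape=(5, 5), spacing=20.0)
        with pytest.raises(SyntheticError, match="coarse"):
            generate_displacement_field(field_model, g)


class TestBeadImages:
    def test_zero_field_images_identical(self, grid):
        model = SubstrateFieldModel(peak_displacement=0.0)
        field, _ = generate_displacement_field(model, grid)
        ref, disp, beads = generate_bead_images(field, seed=0)
        assert np.array_equal(ref, disp)
        assert np.all(beads.displacements == 0.0)

    def test_uniform_translation_ground_truth(self, grid):
        model = SubstrateFieldModel(peak_displacement=0.0)
        field, _ = generate_displacement_field(model, grid)
        field.u_x += 3.0
        _, _, beads = generate_bead_images(field, seed=1)
        assert np.allclose(beads.displacements[:, 0], 3.0)
        assert np.allclose(beads.displacements[:, 1], 0.0)

    def test_fixed_seed_bit_identical(self, field_model, grid):
        field, _ = generate_displacement_field(field_model, grid)
        a = generate_bead_images(field, seed=7, poisson_noise=True)
        b = generate_bead_images(field, seed=7, poisson_noise=True)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_unresolvable_density_warns(self, field_model, grid):
        field, _ = generate_displacement_field(field_model, grid)
        with pytest.warns(UserWarning, match="denser than resolvable"):
            generate_bead_images(field, bead_density=0.2, psf_sigma=2.0, seed=0)


class TestFretMovie:
    def _band_deltas(self, stack, cell, probe):
        part = partition_regions(cell.mask, probe, stack.pixel_size)
        tc = extract_region_timecourses_intensity(stack, part, donor_floor=0.0)
        out = {}
        for name in ("closer", "middle", "farther"):
            r = tc.region(name)
            base = r[: stack.stimulus_frame].mean()
            out[name] = (r[stack.stimulus_frame :].max() - base) / base
        return out

    def test_none_response_noise_off_ratio_constant(self, cell_scene):
        cell, probe, acq = cell_scene
        stack, _ = generate_fret_movie(cell, ResponseModel.for_class("none"), acq)
        resp0 = ResponseModel("none", 0.0)
        stack0, _ = generate_fret_movie(cell, resp0, acq)
        ratio = stack0.acceptor[:, cell.mask] / stack0.donor[:, cell.mask]
        assert np.ptp(ratio, axis=0).max() < 1e-12

    def test_global_phantom_uniform_band_increase(self, cell_scene):
        cell, probe, acq = cell_scene
        stack, _ = generate_fret_movie(cell, ResponseModel.for_class("global"), acq)
        d = self._band_deltas(stack, cell, probe)
        assert d["farther"] / d["closer"] == pytest.approx(1.0, abs=1e-9)

    def test_local_phantom_band_increase_decays(self, cell_scene):
        cell, probe, acq = cell_scene
        stack, _ = generate_fret_movie(cell, ResponseModel.for_class("local"), acq)
        d = self._band_deltas(stack, cell, probe)
        assert d["farther"] / d["closer"] < 0.5
        assert d["closer"] > d["middle"] > d["farther"]

    def test_stimulus_frame_must_precede_end(self, cell_scene):
        cell, probe, acq = cell_scene
        resp = ResponseModel("global", 0.4, stimulus_frame=30)
        with pytest.raises(SyntheticError):
            generate_fret_movie(cell, resp, acq, n_frames=30)

    def test_none_class_amplitude_capped(self):
        with pytest.raises(SyntheticError):
            ResponseModel("none", 0.2)

    def test_phantom_mask_must_be_connected(self):
        mask = np.zeros((20, 20), bool)
        mask[2:5, 2:5] = True
        mask[10:13, 10:13] = True
        with pytest.raises(SyntheticError, match="connected"):
            CellPhantom(mask=mask, centroid=(10.0, 10.0))


class TestCohort:
    def test_degenerate_probabilities_give_single_class(self, cell_scene):
        cell, probe, acq = cell_scene
        movies = list(generate_cohort((1.0, 0.0, 0.0), 5, acq=acq, cell=cell, n_frames=15))
        assert len(movies) == 5
        assert all(t["true_class"] == "global" for _, t in movies)

    def test_empirical_class_fraction_matches_probabilities(self):
        classes = draw_classes((0.8, 0.2, 0.0), 1000, seed=11)
        frac = sum(c == "global" for c in classes) / 1000
        # 99% binomial interval at n=1000 is about +/- 0.033
        assert abs(frac - 0.8) < 0.04

    def test_empty_cohort_rejected(self):
        with pytest.raises(SyntheticError):
            draw_classes((1.0, 0.0, 0.0), 0)

    @pytest.mark.parametrize("p", [(-0.1, 1.1, 0.0), (0.5, 0.2, 0.0)])
    def test_invalid_probabilities_rejected(self, p):
        with pytest.raises(SyntheticError):
            draw_classes(p, 10)

    def test_cohort_reproducible_for_fixed_seed(self, cell_scene):
        cell, probe, acq = cell_scene
        a = next(generate_cohort((0.5, 0.3, 0.2), 2, acq=acq, cell=cell, n_frames=15, seed=5))
        b = next(generate_cohort((0.5, 0.3, 0.2), 2, acq=acq, cell=cell, n_frames=15, seed=5))
        assert np.array_equal(a[0].donor, b[0].donor)
        assert a[1]["true_class"] == b[1]["true_class"]
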