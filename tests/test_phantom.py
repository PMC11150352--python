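"""Phantom construction and acquisition-simulation behavior."""

import dataclasses

import numpy as np
import pytest

from cartimetrics import phantom as ph

FLUID = ph.TISSUE_CLASSES["fluid"]
CART = ph.TISSUE_CLASSES["cartilage"]


class TestBuildPhantom:
    def test_defect_free_band_contains_no_fluid(self, predefect_model):
        band = predefect_model.region_labels > 0
        assert not np.any(predefect_model.labels[band] == FLUID)

    def test_same_seed_is_voxel_identical(self, default_spec):
        a = ph.build_phantom(default_spec)
        b = ph.build_phantom(default_spec)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.proton_density, b.proton_density)

    @pytest.mark.parametrize("diameter", [3.0, 5.0, 8.0])
    def test_defect_gap_matches_nominal_diameter(self, default_spec, default_model, diameter):
        """Fluid gap across the cartilage mid-surface equals the punch size
        to within one voxel (oracle: dense sampling of the label map)."""
        spec = default_spec
        p0, p1 = ph.defect_profile_endpoints(spec, diameter)
        step = 0.05
        length = np.linalg.norm(np.subtract(p1, p0))
        n = int(length / step) + 1
        ts = np.linspace(0.0, 1.0, n)
        pts = np.outer(1 - ts, p0) + np.outer(ts, p1)
        idx = np.round(pts / spec.spacing_mm).astype(int)
        labs = default_model.labels[default_model.mid_slice][idx[:, 0], idx[:, 1]]
        gap_mm = np.count_nonzero(labs == FLUID) * length / (n - 1)
        assert gap_mm == pytest.approx(diameter, abs=spec.spacing_mm)

    def test_defects_ordered_anterior_to_posterior(self, default_spec, default_model):
        mid = default_model.mid_slice
        xs = []
        for d in default_spec.defect_diameters_mm:
            p0, p1 = ph.defect_profile_endpoints(default_spec, d)
            xs.append(0.5 * (p0[1] + p1[1]))
        assert xs == sorted(xs)

    def test_overlapping_defects_raise_naming_diameter(self):
        spec = ph.PhantomSpec(defect_diameters_mm=(8.0, 8.0, 8.0, 8.0, 8.0, 8.0))
        with pytest.raises(ph.DefectPlacementError) as err:
            ph.build_phantom(spec)
        assert err.value.diameter_mm == 8.0

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ph.PhantomSpec(defect_diameters_mm=(0.0,))
        with pytest.raises(ValueError):
            ph.PhantomSpec(spacing_mm=-1.0)
        with pytest.raises(ValueError):
            ph.PhantomSpec(noise_sigma=-1.0)

    def test_maps_share_shape_and_positivity(self, default_model):
        m = default_model
        assert m.t2.shape == m.labels.shape == m.t1rho.shape
        nonbg = m.labels != ph.TISSUE_CLASSES["background"]
        assert np.all(m.t2[nonbg] > 0)
        assert np.all(m.proton_density >= 0)

    def test_regional_t2_override_applied(self, default_spec, predefect_model):
        m = predefect_model
        for name, code in ph.REGION_CLASSES.items():
            if name == "none":
                continue
            sel = (m.region_labels == code) & (m.labels == CART)
            assert np.allclose(m.t2[sel], default_spec.regional_t2[name])


class TestSequenceParams:
    def test_tau_list_must_start_at_zero_and_increase(self):
        with pytest.raises(ValueError):
            ph.SequenceParams("T2prep-PDFS", (10.0, 50.0), (True, True))
        with pytest.raises(ValueError):
            ph.SequenceParams("T2prep-PDFS", (0.0, 50.0, 25.0), (True,) * 3)
        with pytest.raises(ValueError):
            ph.SequenceParams("T2prep-PDFS", (0.0,), (True,))


class TestSimulateStack:
    def test_prep_decay_signal_value(self):
        """PD 1000, T2 50 ms at tau 50 ms gives 1000/e = 367.88."""
        spec = ph.PhantomSpec(
            marrow_texture_amplitude=0.0,
            tissue_table={
                **ph.DEFAULT_TISSUE_TABLE,
                "cartilage": ph.TissueParams(1000.0, 50.0, 50.0),
            },
            regional_t2={"aF": 50.0, "cF": 50.0, "pF": 50.0, "T": 50.0},
            regional_t1rho={"aF": 50.0, "cF": 50.0, "pF": 50.0, "T": 50.0},
            defects_enabled=False,
        )
        model = ph.build_phantom(spec)
        stack = ph.simulate_stack(model, ph.t2prep_params(0.0))
        cart = model.tissue_mask("cartilage")
        assert np.allclose(stack.echo(50.0)[cart], 367.879441, atol=1e-4)
        assert np.allclose(stack.echo(0.0)[cart], 1000.0)

    def test_tau_zero_equals_pd_times_fat_factor(self, default_model):
        stack = ph.simulate_stack(default_model, ph.t2prep_params(0.0))
        fat = default_model.fat
        expected = np.where(fat, default_model.proton_density * 0.05,
                            default_model.proton_density)
        assert np.allclose(stack.echo(0.0), expected)

    def test_t1w_echo_not_fat_suppressed(self, default_model):
        stack = ph.simulate_stack(default_model, ph.spinlock_params(0.0))
        assert np.allclose(stack.echo(0.0), default_model.proton_density)

    def test_signal_strictly_decreases_with_tau(self, default_model):
        stack = ph.simulate_stack(default_model, ph.spinlock_params(0.0))
        tissue = default_model.labels != ph.TISSUE_CLASSES["background"]
        s = [im[tissue] for im in stack.images]
        assert np.all(s[0] > s[1]) and np.all(s[1] > s[2])

    def test_blur_conserves_total_intensity(self, default_model):
        sharp = ph.simulate_stack(default_model, ph.t2prep_params(0.0))
        blurred = ph.simulate_stack(default_model, ph.t2prep_params(0.8))
        a, b = sharp.echo(0.0).sum(), blurred.echo(0.0).sum()
        assert abs(a - b) / a < 1e-3

    def test_background_rician_floor(self):
        """Zero-signal background acquires the Rayleigh mean sigma*sqrt(pi/2)."""
        spec = ph.PhantomSpec(shape=(350, 350), condyle_center_mm=(20.0, 25.0))
        model = ph.build_phantom(spec)
        # far corner is genuine background-free muscle; fabricate PD=0 region
        model.proton_density[:, :, -40:] = 0.0
        stack = ph.simulate_stack(model, ph.t2prep_params(0.0), noise_sigma=10.0, seed=3)
        bg = stack.echo(0.0)[:, :, -40:]
        assert bg.mean() == pytest.approx(10.0 * np.sqrt(np.pi / 2), rel=0.02)

    def test_negative_noise_rejected(self, default_model):
        with pytest.raises(ValueError):
            ph.simulate_stack(default_model, ph.t2prep_params(0.0), noise_sigma=-1.0)


class TestRicianNoise:
    def test_sigma_zero_is_identity(self, rng):
        img = rng.random((20, 20))
        assert np.array_equal(ph.add_rician_noise(img, 0.0, seed=1), img)

    def test_same_seed_reproduces(self, rng):
        img = rng.random((20, 20))
        a = ph.add_rician_noise(img, 2.0, seed=42)
        b = ph.add_rician_noise(img, 2.0, seed=42)
        assert np.array_equal(a, b)

    def test_rayleigh_mean_at_zero_signal(self):
        out = ph.add_rician_noise(np.zeros(10**6), 1.0, seed=0)
        assert out.mean() == pytest.approx(np.sqrt(np.pi / 2), abs=0.01)


def test_stack_round_trip_io(tmp_path, default_model):
    stack = ph.simulate_stack(default_model, ph.spinlock_params(0.2),
                              noise_sigma=5.0, seed=9)
    stack.save(str(tmp_path), prefix="sl")
    loaded = ph.ContrastStack.load(str(tmp_path), prefix="sl")
    assert loaded.taus_ms == stack.taus_ms
    assert loaded.contrast_family == stack.contrast_family
    for a, b in zip(loaded.images, stack.images):
        assert np.allclose(a, b, atol=1e-4)
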