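"""Phasor transform identities, linearity, and phasor-space segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phasorquant import phasor as ph
from phasorquant import pipeline as pl
from phasorquant import synthetic as syn


def _stack_from_traces(traces: np.ndarray) -> ph.DelayStack:
    """(K, N) traces -> a K x N x 1 delay stack on a unit-spaced axis."""
    K = traces.shape[0]
    return ph.DelayStack(intensities=traces[:, :, None], delays=np.arange(K, dtype=float))


class TestTransformIdentities:
    def test_impulse_in_first_frame_maps_to_1_0(self):
        tr = np.zeros((16, 1))
        tr[0, 0] = 1.0
        f = ph.phasor_transform(_stack_from_traces(tr), floor=0.0)
        assert f.g[0, 0] == pytest.approx(1.0, abs=1e-12)
        assert f.s[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_constant_trace_maps_to_origin(self):
        tr = np.full((16, 1), 2.5)
        f = ph.phasor_transform(_stack_from_traces(tr), floor=0.0)
        assert f.g[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert f.s[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_single_bin_spectrum_on_unit_circle(self):
        cube = np.zeros((12, 1, 1))
        k = 5
        cube[k, 0, 0] = 3.0
        stack = ph.SpectralStack(intensities=cube, wavenumbers=np.arange(12, dtype=float))
        f = ph.spectral_phasor_transform(stack, floor=0.0)
        theta = 2 * np.pi * k / 12
        assert f.g[0, 0] == pytest.approx(np.cos(theta), abs=1e-12)
        assert f.s[0, 0] == pytest.approx(np.sin(theta), abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, derandomize=True, max_examples=25)
    def test_nonnegative_trace_inside_unit_disc(self, seed):
        tr = np.random.default_rng(seed).uniform(0, 1, size=(24, 1))
        f = ph.phasor_transform(_stack_from_traces(tr), floor=0.0)
        assert np.hypot(f.g[0, 0], f.s[0, 0]) <= 1 + 1e-12

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            ph.phasor_transform(_stack_from_traces(np.ones((6, 1))))

    def test_harmonic_too_high_rejected(self):
        with pytest.raises(ValueError):
            ph.phasor_transform(_stack_from_traces(np.ones((16, 1))), harmonic=8)


class TestLinearity:
    def test_mixture_is_intensity_weighted_combination(self):
        # oracle: direct summation over the mixed trace, exact by linearity
        rng = np.random.default_rng(7)
        A = rng.uniform(0, 1, 32)
        B = rng.uniform(0, 1, 32)
        alpha = 0.3
        mix = alpha * A + (1 - alpha) * B
        f = ph.phasor_transform(_stack_from_traces(np.stack([A, B, mix], axis=1)), floor=0.0)
        wa, wb = alpha * A.sum(), (1 - alpha) * B.sum()
        g_exp = (wa * f.g[0, 0] + wb * f.g[1, 0]) / (wa + wb)
        s_exp = (wa * f.s[0, 0] + wb * f.s[1, 0]) / (wa + wb)
        assert f.g[2, 0] == pytest.approx(g_exp, abs=1e-12)
        assert f.s[2, 0] == pytest.approx(s_exp, abs=1e-12)

    def test_two_band_mixture_on_segment_between_pure_phasors(self):
        # spectral version: mixture phasor lies on the chord between the
        # pure-band phasors at the intensity-weighted position
        cube = np.zeros((20, 3, 1))
        cube[4, 0, 0] = 1.0  # pure band a
        cube[13, 1, 0] = 1.0  # pure band b
        cube[4, 2, 0] = 0.6
        cube[13, 2, 0] = 0.4
        stack = ph.SpectralStack(intensities=cube, wavenumbers=np.arange(20, dtype=float))
        f = ph.spectral_phasor_transform(stack, floor=0.0)
        g_exp = 0.6 * f.g[0, 0] + 0.4 * f.g[1, 0]
        s_exp = 0.6 * f.s[0, 0] + 0.4 * f.s[1, 0]
        assert f.g[2, 0] == pytest.approx(g_exp, abs=1e-12)
        assert f.s[2, 0] == pytest.approx(s_exp, abs=1e-12)


class TestReferences:
    def test_single_pixel_roi_is_that_pixel(self):
        tr = np.random.default_rng(3).uniform(0.1, 1, size=(16, 4))
        f = ph.phasor_transform(_stack_from_traces(tr), floor=0.0)
        roi = np.zeros(f.g.shape, dtype=bool)
        roi[2, 0] = True
        refs = ph.build_references(f, {"x": roi})
        assert refs.entries[0].g == pytest.approx(f.g[2, 0])
        assert refs.entries[0].s == pytest.approx(f.s[2, 0])

    def test_pure_class_roi_matches_analytic_phasor(self, delays):
        # noise-free pixels of one class all share the analytic class phasor
        p = syn.default_signal_params()["pigment_positive"]
        from phasorquant.signal_models import pump_probe_response

        trace = pump_probe_response(delays, p)
        stack = ph.DelayStack(intensities=np.tile(trace[:, None, None], (1, 3, 3)), delays=delays)
        f = ph.phasor_transform(stack, floor=0.0)
        refs = ph.build_references(f, {"pp": np.ones((3, 3), dtype=bool)})
        assert refs.entries[0].g == pytest.approx(f.g[0, 0], abs=1e-12)
        assert refs.entries[0].s == pytest.approx(f.s[0, 0], abs=1e-12)

    def test_empty_roi_rejected(self):
        f = ph.phasor_transform(_stack_from_traces(np.ones((16, 2)) * 0.5), floor=0.0)
        with pytest.raises(ValueError):
            ph.build_references(f, {"empty": np.zeros(f.g.shape, dtype=bool)})


class TestSegmentation:
    def _field(self, g, s, mask=None):
        g = np.asarray(g, dtype=float)
        total = np.ones_like(g)
        mask = np.ones_like(g, dtype=bool) if mask is None else mask
        return ph.PhasorField(g=g, s=np.asarray(s, dtype=float), total=total,
                              harmonic=1, mask=mask)

    def test_pixel_at_centroid_gets_that_label(self):
        refs = ph.ReferenceSet([ph.ReferenceEntry("a", 0.2, 0.1), ph.ReferenceEntry("b", 0.8, 0.4)])
        f = self._field([[0.2, 0.8]], [[0.1, 0.4]])
        lm = ph.segment_phasor(f, refs)
        names = [lm.legend[v] for v in lm.labels[0]]
        assert names == ["a", "b"]

    def test_equidistant_pixel_takes_lower_index(self):
        refs = ph.ReferenceSet([ph.ReferenceEntry("a", 0.4, 0.0), ph.ReferenceEntry("b", 0.6, 0.0)],
                               max_distance=0.5)
        f = self._field([[0.5]], [[0.0]])
        lm = ph.segment_phasor(f, refs)
        assert lm.legend[lm.labels[0, 0]] == "a"

    def test_far_pixel_labelled_other(self):
        refs = ph.ReferenceSet([ph.ReferenceEntry("a", 0.0, 0.0)], max_distance=0.1)
        f = self._field([[0.9]], [[0.9]])
        lm = ph.segment_phasor(f, refs)
        assert lm.legend[lm.labels[0, 0]] == "other"

    def test_negative_sign_routed_before_gating(self):
        refs = ph.ReferenceSet([ph.ReferenceEntry("a", 0.0, 0.0)])
        f = self._field([[0.0, 0.0]], [[0.0, 0.0]])
        lm = ph.segment_phasor(f, refs, sign_map=np.array([[1.0, -1.0]]))
        assert lm.legend[lm.labels[0, 0]] == "a"
        assert lm.legend[lm.labels[0, 1]] == "pigment_negative"

    def test_polygon_gate_overrides_centroid_distance(self):
        refs = ph.ReferenceSet([
            ph.ReferenceEntry("a", 0.0, 0.0, polygon=((0.4, -0.1), (0.4, 0.1), (0.7, 0.1), (0.7, -0.1))),
            ph.ReferenceEntry("b", 0.5, 0.5),
        ], max_distance=2.0)
        f = self._field([[0.5]], [[0.0]])  # nearer to b's centroid region? inside a's polygon
        lm = ph.segment_phasor(f, refs)
        assert lm.legend[lm.labels[0, 0]] == "a"

    def test_noise_free_scene_matches_truth_everywhere(self, noise_free_scene, noise_free_stack):
        refs = pl.references_from_truth(noise_free_scene, noise_free_stack.delays)
        res = pl.analyze_delay_scene(noise_free_stack, refs,
                                     cell_count=noise_free_scene.cell_count, floor=0.0)
        assert pl.label_accuracy(res["labels"], noise_free_scene) == 1.0

    def test_class_centroids_well_separated(self, noise_free_scene, delays):
        refs = pl.references_from_truth(noise_free_scene, delays)
        by = {e.label: (e.g, e.s) for e in refs.entries}
        (g1, s1), (g2, s2) = by["LD"], by["pigment_positive"]
        assert np.hypot(g1 - g2, s1 - s2) >= 0.2


class TestFloor:
    def test_default_floor_masks_background(self):
        rng = np.random.default_rng(5)
        tr = np.abs(rng.normal(0, 0.01, size=(16, 50)))
        tr[:, 0] += 10.0  # one bright pixel
        f = ph.phasor_transform(_stack_from_traces(tr))
        assert f.mask[0, 0]

    def test_explicit_floor_respected(self):
        tr = np.ones((16, 2))
        tr[:, 1] *= 100.0
        f = ph.phasor_transform(_stack_from_traces(tr), floor=50.0)
        assert not f.mask[0, 0] and f.mask[1, 0]
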