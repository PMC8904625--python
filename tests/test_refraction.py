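"""Static brute-force search and dynamic top-quantile selection."""

import math

import numpy as np
import pandas as pd
import pytest

from retiq import (
    METRIC_NAMES,
    ChromaticModel,
    DynamicRefraction,
    Frame,
    FrameSequence,
    MetricSpec,
    PowerVector,
    SpheroCylinder,
    StaticRefraction,
    ZernikeWavefront,
    build_search_grid,
    dynamic_optimize,
    filter_blinks,
    from_power_vector,
    get_metric,
    iqm_timeseries,
    quantize_prescription,
    residual_wavefront,
    sc_to_zernike,
    static_optimize,
    to_power_vector,
    zernike_to_sc,
)

from .conftest import pure_low_order_wavefront, random_wavefront

FAST_METRICS = (get_metric("entropy"), get_metric("vsx"))


def make_sequence(wavefronts, frame_rate=8.0, blink=None):
    frames = []
    for i, w in enumerate(wavefronts):
        b = blink[i] if blink is not None else False
        frames.append(Frame(time=i / frame_rate, wavefront=None if b else w, blink=b))
    return FrameSequence(frames=tuple(frames), frame_rate=frame_rate)


class TestSearchGrid:
    def test_raw_combination_count(self):
        """13 sphere × 9 cylinder × 9 axis offsets = 1053 raw combinations,
        within the printed upper bound of 1215."""
        grid = build_search_grid(SpheroCylinder(-2.0, -1.0, 90.0))
        assert grid.n_raw == 13 * 9 * 9 == 1053
        assert len(grid) <= 1215

    def test_contains_base(self):
        base = SpheroCylinder(-2.0, -1.0, 90.0)
        assert base in build_search_grid(base).candidates

    def test_deduplication_oracle(self):
        """Candidate count after clamping/wrapping equals an independent
        set-based enumeration of the same ranges."""
        base = SpheroCylinder(-2.0, -1.0, 90.0)
        oracle = set()
        for ds in np.arange(-1.5, 1.51, 0.25):
            for dc in np.arange(-1.0, 1.01, 0.25):
                for da in np.arange(-20.0, 20.01, 5.0):
                    c = min(base.cylinder + dc, 0.0)
                    a = 0.0 if c == 0 else (base.axis + da) % 180.0
                    oracle.add((round(base.sphere + ds, 6), round(c, 6), round(a, 6)))
        assert len(build_search_grid(base)) == len(oracle)

    def test_zero_cylinder_base_clamped(self):
        grid = build_search_grid(SpheroCylinder(1.0, 0.0, 0.0))
        assert all(c.cylinder <= 0 for c in grid.candidates)


class TestResidualWavefront:
    def test_plano_correction_is_identity(self, rng):
        w = random_wavefront(rng)
        res = residual_wavefront(w, SpheroCylinder(0.0))
        assert np.allclose(res.coefficients, w.coefficients)

    def test_own_refraction_cancels_low_order(self, rng):
        w = random_wavefront(rng, hoa_scale=0.08)
        res = residual_wavefront(w, from_power_vector(zernike_to_sc(w)))
        assert np.allclose(res.coefficients[3:6], 0.0, atol=1e-9)
        # high-order terms pass through untouched
        assert np.array_equal(res.coefficients[6:], w.coefficients[6:])

    def test_defocus_worked_example(self):
        w = ZernikeWavefront([0, 0, 0, 0, 1.0 / math.sqrt(3), 0], 4.0)
        res = residual_wavefront(w, SpheroCylinder(-1.0))
        assert res.coefficients[4] == pytest.approx(0.0, abs=1e-12)


class TestQuantization:
    @pytest.mark.parametrize(
        "pv, expected",
        [
            (PowerVector(-1.13, 0.0, 0.0), SpheroCylinder(-1.25, 0.0, 0.0)),
            (PowerVector(0.0, 0.0, 0.0), SpheroCylinder(0.0, 0.0, 0.0)),
        ],
    )
    def test_rounding(self, pv, expected):
        assert quantize_prescription(pv) == expected

    def test_quantized_never_positive_cylinder(self, rng):
        for _ in range(200):
            sc = quantize_prescription(PowerVector(*rng.uniform(-4, 4, 3)))
            assert sc.cylinder <= 0.0
            assert sc.sphere == pytest.approx(round(sc.sphere * 4) / 4)


class TestStaticRefraction:
    def test_recovers_pure_low_order_eye(self, cfg128):
        """An eye whose wavefront is exactly the base prescription is
        recovered within one grid step by every metric."""
        truth = SpheroCylinder(-2.0, -1.0, 60.0)
        pv = to_power_vector(truth)
        w = pure_low_order_wavefront(truth)
        res = StaticRefraction(w, truth, sampling=cfg128).fit(0.05)
        for name in METRIC_NAMES:
            r = res.refraction(name)
            assert abs(r.M - pv.M) <= 0.25, name
            assert abs(r.J0 - pv.J0) <= 0.25, name
            assert abs(r.J45 - pv.J45) <= 0.25, name

    def test_zero_aberration_eye_base_plano(self, cfg128):
        """A perfect eye recovers M = 0 exactly; the astigmatic components of
        the top-5% mean stay within one grid step (the best candidates
        cluster around plano but small-cylinder candidates share the
        near-optimal scores)."""
        w = ZernikeWavefront(np.zeros(15), 4.0)
        res = StaticRefraction(w, SpheroCylinder(0.0), metrics=FAST_METRICS,
                               sampling=cfg128).fit(0.05)
        for spec in FAST_METRICS:
            r = res.refraction(spec.name)
            assert r.M == pytest.approx(0.0, abs=1e-9)
            assert abs(r.J0) <= 0.25 and abs(r.J45) <= 0.25

    def test_top_fraction_one_is_grid_mean(self, cfg128):
        w = pure_low_order_wavefront(SpheroCylinder(-1.0))
        model = StaticRefraction(w, SpheroCylinder(-1.0), metrics=FAST_METRICS,
                                 sampling=cfg128)
        res = model.fit(1.0)
        grid_mean = res.scores[["M", "J0", "J45"]].mean()
        for spec in FAST_METRICS:
            r = res.refraction(spec.name)
            assert r.M == pytest.approx(grid_mean["M"], abs=1e-12)
            assert r.J0 == pytest.approx(grid_mean["J0"], abs=1e-12)

    def test_top_one_matches_exhaustive_argmax(self, cfg128, rng):
        """Selecting exactly one candidate reproduces the argmin/argmax of an
        independent exhaustive scoring loop (deterministic tie-break)."""
        from retiq.metrics import compute_metrics as cm
        from retiq.psf import compute_psf, diffraction_limited_psf

        w = random_wavefront(rng)
        base = quantize_prescription(zernike_to_sc(w))
        grid = build_search_grid(base, sphere_extent=0.5, cylinder_extent=0.25,
                                 axis_extent=10.0)
        model = StaticRefraction(w, base, sampling=cfg128, grid=grid)
        res = model.fit(top_fraction=1.0 / len(grid) / 2)  # forces k = 1
        assert res.n_selected == 1

        dl = diffraction_limited_psf(w.pupil_diameter, w.wavelength, cfg128)
        oracle = {name: [] for name in METRIC_NAMES}
        for cand in grid.candidates:
            vals = cm(compute_psf(residual_wavefront(w, cand), cfg128), dl,
                      model.specs, on_error="nan")
            for name, v in vals.items():
                oracle[name].append(v)
        for spec in model.specs:
            vals = np.array(oracle[spec.name])
            key = vals if spec.minimize else -vals
            key[np.isnan(vals)] = np.inf
            expected = grid.candidates[int(np.argmin(key))]
            chosen = grid.candidates[int(res.selected(spec.name)[0])]
            assert chosen == expected, spec.name

    def test_grid_translation_invariance(self, cfg128):
        """Shifting eye and base by +0.25 D sphere shifts the result by the
        same amount, to within one grid step."""
        base = SpheroCylinder(-1.0, -0.5, 30.0)
        shifted = SpheroCylinder(-0.75, -0.5, 30.0)
        r1 = StaticRefraction(pure_low_order_wavefront(base), base,
                              metrics=FAST_METRICS, sampling=cfg128).fit(0.05)
        r2 = StaticRefraction(pure_low_order_wavefront(shifted), shifted,
                              metrics=FAST_METRICS, sampling=cfg128).fit(0.05)
        for spec in FAST_METRICS:
            dm = r2.refraction(spec.name).M - r1.refraction(spec.name).M
            assert abs(dm - 0.25) <= 0.25

    def test_determinism(self, cfg128, rng):
        w = random_wavefront(rng)
        base = quantize_prescription(zernike_to_sc(w))
        grid = build_search_grid(base, sphere_extent=0.5, cylinder_extent=0.25,
                                 axis_extent=10.0)
        a = StaticRefraction(w, base, metrics=FAST_METRICS, sampling=cfg128, grid=grid).fit()
        b = StaticRefraction(w, base, metrics=FAST_METRICS, sampling=cfg128, grid=grid).fit()
        pd.testing.assert_frame_equal(a.scores, b.scores)
        assert a.refractions == b.refractions


class TestBlinkFiltering:
    def test_no_blinks_identity(self, rng):
        seq = make_sequence([random_wavefront(rng)] * 10)
        assert len(filter_blinks(seq)) == 10

    def test_counts_and_order(self, rng):
        w = random_wavefront(rng)
        blink = [i % 10 == 0 for i in range(80)]
        seq = make_sequence([w] * 80, blink=blink)
        out = filter_blinks(seq)
        assert len(out) == 72
        times = [f.time for f in out]
        assert times == sorted(times)

    def test_idempotent(self, rng):
        w = random_wavefront(rng)
        seq = make_sequence([w] * 20, blink=[i < 2 for i in range(20)])
        once = filter_blinks(seq)
        twice = filter_blinks(once)
        assert [f.time for f in once] == [f.time for f in twice]

    def test_all_blink_errors(self):
        seq = make_sequence([None] * 8, blink=[True] * 8)
        with pytest.raises(ValueError):
            filter_blinks(seq)


class TestDynamicRefraction:
    def test_constant_sequence_returns_quantized_refraction(self, cfg128):
        truth = SpheroCylinder(-1.37 + 0.12, 0.0, 0.0)  # deliberately off-step
        w = pure_low_order_wavefront(truth)
        seq = make_sequence([w] * 16)
        res = DynamicRefraction(seq, metrics=FAST_METRICS, sampling=cfg128).fit(0.2)
        expected = to_power_vector(quantize_prescription(to_power_vector(truth)))
        for spec in FAST_METRICS:
            r = res.refraction(spec.name)
            assert r.M == pytest.approx(expected.M, abs=1e-12)

    def test_two_regime_sequence_prefers_plateau(self, cfg128):
        """60 frames at the true refraction with small HOA, 20 frames 0.75 D
        more myopic with strong added coma: every metric must recover the
        plateau refraction within half a quantization step."""
        truth = SpheroCylinder(-1.5, -0.5, 20.0)
        pv = to_power_vector(truth)
        plateau = pure_low_order_wavefront(truth).with_coefficients({8: 0.03})
        excursion_pv = PowerVector(pv.M - 0.75, pv.J0, pv.J45)
        c = np.zeros(15)
        c[3:6] = sc_to_zernike(excursion_pv, 4.0)
        c[8] = 0.30  # strong coma during the excursion
        excursion = ZernikeWavefront(c, 4.0)
        seq = make_sequence([plateau] * 60 + [excursion] * 20)
        res = DynamicRefraction(seq, sampling=cfg128).fit(0.2)
        assert res.n_selected == 16
        for name in METRIC_NAMES:
            assert abs(res.refraction(name).M - pv.M) <= 0.125, name

    def test_top_fraction_one_is_frame_mean(self, cfg128, rng):
        seq = make_sequence([random_wavefront(rng, lo_scale=0.1) for _ in range(12)])
        res = DynamicRefraction(seq, metrics=FAST_METRICS, sampling=cfg128).fit(1.0)
        mean = res.scores[["M", "J0", "J45"]].mean()
        for spec in FAST_METRICS:
            assert res.refraction(spec.name).M == pytest.approx(mean["M"], abs=1e-12)

    def test_too_few_frames_rejected(self, rng):
        seq = make_sequence([random_wavefront(rng)] * 4)
        with pytest.raises(ValueError):
            DynamicRefraction(seq).fit()

    def test_pupil_guard_rejects_artifact_frames(self, cfg128, rng):
        good = [random_wavefront(rng, lo_scale=0.1) for _ in range(8)]
        tiny = [random_wavefront(rng, lo_scale=0.1, pupil=1.2) for _ in range(3)]
        seq = make_sequence(good + tiny)
        res = DynamicRefraction(seq, metrics=FAST_METRICS, sampling=cfg128).fit(0.5)
        assert res.n_candidates == 8

    def test_determinism(self, cfg128, rng):
        seq = make_sequence([random_wavefront(rng, lo_scale=0.1) for _ in range(10)])
        a = DynamicRefraction(seq, metrics=FAST_METRICS, sampling=cfg128).fit()
        b = DynamicRefraction(seq, metrics=FAST_METRICS, sampling=cfg128).fit()
        pd.testing.assert_frame_equal(a.scores, b.scores)
        assert a.refractions == b.refractions

    def test_fixed_analysis_pupil(self, cfg128, rng):
        """With a fixed analysis diameter all frames are scored on the same
        pupil; smaller-pupil frames are rejected and the recovered refraction
        is unchanged for a pure low-order eye."""
        truth = SpheroCylinder(-1.25, 0.0, 0.0)
        big = [pure_low_order_wavefront(truth, pupil=5.0)] * 8
        small = [pure_low_order_wavefront(truth, pupil=3.0)] * 3
        seq = make_sequence(big + small)
        res = DynamicRefraction(seq, metrics=FAST_METRICS, sampling=cfg128,
                                analysis_pupil=4.0).fit(0.5)
        assert res.n_candidates == 8
        assert (res.scores["pupil"] == 4.0).all()
        for spec in FAST_METRICS:
            assert res.refraction(spec.name).M == pytest.approx(-1.25, abs=1e-9)


class TestTimeseries:
    def test_constant_sequence_constant_columns(self, cfg128):
        w = pure_low_order_wavefront(SpheroCylinder(-1.0))
        ts = iqm_timeseries(make_sequence([w] * 10), get_metric("entropy"),
                            sampling=cfg128)
        assert ts["M"].nunique() == 1
        assert ts["J0"].nunique() == 1

    def test_normalization_and_selection_contract(self, cfg128, rng):
        seq = make_sequence([random_wavefront(rng, lo_scale=0.1) for _ in range(15)])
        ts = iqm_timeseries(seq, get_metric("vsx"), sampling=cfg128)
        assert ts["metric_norm"].min() == 0.0
        assert ts["metric_norm"].max() == 1.0
        assert ts["selected"].sum() == math.ceil(0.2 * 15)


class TestFunctionalWrappers:
    def test_static_optimize_result_fields(self, cfg128):
        w = pure_low_order_wavefront(SpheroCylinder(-1.0))
        out = static_optimize(w, SpheroCylinder(-1.0), get_metric("vsx"),
                              sampling=cfg128)
        assert out.metric_name == "vsx"
        assert out.n_selected == math.ceil(0.05 * out.n_candidates_evaluated)
        assert abs(out.refraction.M + 1.0) <= 0.25

    def test_dynamic_optimize_result_fields(self, cfg128):
        w = pure_low_order_wavefront(SpheroCylinder(-0.75))
        out = dynamic_optimize(make_sequence([w] * 10), get_metric("entropy"),
                               sampling=cfg128)
        assert out.n_candidates_evaluated == 10
        assert out.n_selected == 2
        assert out.refraction.M == pytest.approx(-0.75, abs=1e-9)
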