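"""Curve normalization, Hausdorff distances, random null, pulsation tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulse4d.errors import DegenerateCurveError, InvalidArgumentError
from pulse4d.phantom import generate_pulse_template
from pulse4d.pulsation import (
    PulseWave,
    VolumeCurve,
    classify_curve,
    cohort_pulsation_report,
    generate_random_null,
    hausdorff_distance,
    normalize_mean_one,
    normalize_minmax,
    pulsation_amplitude,
    pulsation_test,
    two_sided_ttest,
)


def brute_force_hausdorff(a, b, value_only=False):
    """Independent double-loop oracle over all point pairs."""
    def pts(v):
        if value_only:
            return [(x,) for x in v]
        n = len(v)
        return [(i / (n - 1), x) for i, x in enumerate(v)]

    A, B = pts(a), pts(b)

    def h(P, Q):
        return max(min(np.hypot(*[p[k] - q[k] for k in range(len(p))])
                       if len(p) == 2 else abs(p[0] - q[0])
                       for q in Q) for p in P)

    return max(h(A, B), h(B, A))


class TestNormalization:
    def test_minmax_example(self):
        c = normalize_minmax(VolumeCurve(values=[2.0, 4.0, 6.0]))
        np.testing.assert_allclose(c.values, [0.0, 0.5, 1.0])
        assert c.normalization == "minmax01"

    def test_minmax_idempotent(self):
        c = normalize_minmax(VolumeCurve(values=[5.0, 1.0, 9.0]))
        np.testing.assert_allclose(normalize_minmax(c).values, c.values)

    def test_constant_curve_degenerate(self):
        with pytest.raises(DegenerateCurveError):
            normalize_minmax(VolumeCurve(values=[5.0, 5.0, 5.0]))

    def test_mean_one_example(self):
        c = normalize_mean_one(VolumeCurve(values=[90.0, 100.0, 110.0]))
        np.testing.assert_allclose(c.values, [0.9, 1.0, 1.1])
        np.testing.assert_allclose(normalize_mean_one(c).values, c.values)

    def test_amplitude_scale_invariant(self):
        raw = VolumeCurve(values=[90.0, 100.0, 110.0])
        assert pulsation_amplitude(raw) == pytest.approx(
            pulsation_amplitude(normalize_mean_one(raw)))

    def test_amplitude_examples(self):
        assert pulsation_amplitude(VolumeCurve(values=[3.0, 3.0, 3.0])) == 1.0
        c = VolumeCurve(values=[1.00, 1.02, 1.04, 1.01])
        assert pulsation_amplitude(c) == pytest.approx(1.04)


class TestHausdorff:
    def test_identity_zero(self):
        v = np.array([0.1, 0.9, 0.4, 0.2])
        assert hausdorff_distance(v, v) == 0.0

    def test_crossing_segments(self):
        # point sets {(0,0),(1,1)} vs {(0,1),(1,0)}: every nearest pair is 1.0
        assert hausdorff_distance([0.0, 1.0], [1.0, 0.0]) == pytest.approx(1.0)

    def test_bounded_by_unit_square_diagonal(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = rng.uniform(0, 1, (2, 10))
            assert hausdorff_distance(a, b) <= np.sqrt(2.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidArgumentError):
            hausdorff_distance([0.0, 1.0], [0.0, 0.5, 1.0])

    @pytest.mark.parametrize("value_only", [False, True])
    def test_matches_brute_force_oracle(self, value_only):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(2, 12)
            a, b = rng.uniform(0, 1, (2, n))
            assert hausdorff_distance(a, b, value_only) == pytest.approx(
                brute_force_hausdorff(a, b, value_only), abs=1e-12)

    @settings(deadline=None, max_examples=60)
    @given(st.integers(0, 2**20))
    def test_pseudometric_properties(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c = rng.uniform(0, 1, (3, 8))
        dab = hausdorff_distance(a, b)
        assert dab >= 0
        assert dab == pytest.approx(hausdorff_distance(b, a), abs=1e-12)
        assert dab <= hausdorff_distance(a, c) + hausdorff_distance(c, b) + 1e-12


class TestRandomNull:
    def test_monte_carlo_moments(self):
        pulse = generate_pulse_template(10)
        null = generate_random_null(10_000, 10, 1234, pulse)
        draws = null.curves.ravel()            # 1e5 clipped Gaussian draws
        assert abs(draws.mean() - 0.5) < 0.01
        assert 0.186 <= draws.std(ddof=1) <= 0.20   # clipping shrinks the SD
        assert null.n_curves == 10_000

    def test_seeded_determinism(self):
        pulse = generate_pulse_template(10)
        n1 = generate_random_null(20, 10, 7, pulse)
        n2 = generate_random_null(20, 10, 7, pulse)
        np.testing.assert_array_equal(n1.curves, n2.curves)
        np.testing.assert_array_equal(n1.distances, n2.distances)

    def test_single_curve_allowed(self):
        pulse = generate_pulse_template(10)
        null = generate_random_null(1, 10, 0, pulse)
        assert null.distances.shape == (1,)

    def test_renormalized_null_spans_unit_interval(self):
        pulse = generate_pulse_template(10)
        null = generate_random_null(50, 10, 3, pulse, renorm=True)
        np.testing.assert_allclose(null.curves.min(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(null.curves.max(axis=1), 1.0, atol=1e-12)


class TestWelch:
    def test_identical_samples(self):
        res = two_sided_ttest([1.0, 1.0, 1.0], [1.0, 1.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_five_sigma_shift_tiny_p(self):
        rng = np.random.default_rng(99)
        a = rng.normal(0.0, 1.0, 14)
        b = rng.normal(5.0, 1.0, 14)
        res = two_sided_ttest(a, b)
        assert res.p < 1e-6

    def test_order_symmetric(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 2, 12)
        assert two_sided_ttest(a, b).p == pytest.approx(two_sided_ttest(b, a).p)

    def test_pulsation_test_reports_group_means(self):
        pulse = generate_pulse_template(10)
        null = generate_random_null(14, 10, 11, pulse)
        res = pulsation_test([0.1, 0.12, 0.11], null)
        assert res.mean_a == pytest.approx(0.11)
        assert res.mean_b == pytest.approx(null.distances.mean())


class TestClassification:
    def test_constant_curve_is_flat(self):
        pulse = generate_pulse_template(10)
        null = generate_random_null(100, 10, 2, pulse)
        c = VolumeCurve(values=np.full(10, 7.0))
        assert classify_curve(c, pulse, null) == "flat"

    def test_pulse_wave_itself_is_pulsatile(self):
        pulse = generate_pulse_template(10)
        null = generate_random_null(100, 10, 2, pulse)
        c = VolumeCurve(values=pulse.values, normalization="minmax01")
        assert classify_curve(c, pulse, null) == "pulsatile"

    def test_random_curves_classified_random(self):
        pulse = generate_pulse_template(10)
        null = generate_random_null(1000, 10, 2, pulse)
        rng = np.random.default_rng(8)
        draws = np.clip(rng.normal(0.5, 0.2, (200, 10)), 0, 1) + 1.0
        labels = [classify_curve(VolumeCurve(values=d), pulse, null)
                  for d in draws]
        frac_random = np.mean([lab == "random" for lab in labels])
        assert frac_random >= 0.90       # percentile rule passes ~5% as pulsatile

    def test_cohort_report_structure(self):
        pulse = generate_pulse_template(10)
        null = generate_random_null(14, 10, 4, pulse)
        curves = [VolumeCurve(values=1.0 + 0.05 * pulse.values, label="a"),
                  VolumeCurve(values=np.linspace(1, 1.1, 10), label="b")]
        rep = cohort_pulsation_report(curves, pulse, null)
        assert rep.labels == ["a", "b"]
        assert rep.distances.shape == (2,)
        assert 0.0 <= rep.p <= 1.0
        assert len(rep.classes) == 2
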