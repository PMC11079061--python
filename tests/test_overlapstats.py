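"""Overlap coefficient estimators, estimator selection and categorization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dielniche.circkde import fit_density
from dielniche.overlapstats import (
    Estimator, OverlapCategory, OverlapEstimate, categorize_overlap, delta1,
    delta4, delta_from_samples, estimate_overlap, overlap_area,
    select_estimator,
)
from dielniche.synthetic import ARCHETYPES, _mix, analytic_overlap, mixture_pdf, sample_mixture

TWO_PI = 2 * math.pi


class TestDelta1:
    def test_identical_samples_give_unity(self, rng):
        x = rng.vonmises(1.0, 3.0, 400) % TWO_PI
        k = fit_density(x, 0.8)
        assert delta1(k, k) == pytest.approx(1.0, abs=1e-9)

    def test_near_disjoint_densities(self):
        a = _mix((1.0, 0.0, 20.0))
        b = _mix((1.0, math.pi, 20.0))
        assert overlap_area(lambda t: mixture_pdf(t, a),
                            lambda t: mixture_pdf(t, b)) < 0.01

    def test_default_grid_matches_quadrature_oracle(self):
        """128-point grid integral vs the 8192-point oracle on true densities."""
        a = _mix((1.0, 0.0, 2.0))
        b = _mix((1.0, math.pi / 2, 2.0))
        coarse = overlap_area(lambda t: mixture_pdf(t, a),
                              lambda t: mixture_pdf(t, b), grid_n=128)
        assert coarse == pytest.approx(analytic_overlap(a, b), abs=1e-3)

    def test_grid_floor(self, rng):
        x = rng.vonmises(0, 2, 100) % TWO_PI
        k = fit_density(x, 0.8)
        with pytest.raises(ValueError):
            delta1(k, k, grid_n=32)


class TestDelta4:
    def test_identical_samples_give_exactly_one(self, rng):
        x = rng.vonmises(1.0, 3.0, 300) % TWO_PI
        k = fit_density(x)
        assert delta4(x, x, k, k) == 1.0

    def test_same_distribution_envelope(self):
        """Two independent samples from one distribution stay near Delta = 1."""
        for seed in range(20):
            r = np.random.default_rng(seed)
            x1 = r.vonmises(0.0, 2.0, 5000) % TWO_PI
            x2 = r.vonmises(0.0, 2.0, 5000) % TWO_PI
            d, _ = delta_from_samples(x1, x2, Estimator.DELTA4)
            assert 0.95 <= d <= 1.0

    def test_matches_quadrature_oracle(self, rng):
        a = _mix((1.0, 0.0, 2.0))
        b = _mix((1.0, math.pi, 2.0))
        x1 = sample_mixture(5000, a, rng)
        x2 = sample_mixture(5000, b, rng)
        d, _ = delta_from_samples(x1, x2, Estimator.DELTA4)
        assert d == pytest.approx(analytic_overlap(a, b), abs=0.03)

    def test_empty_sample_rejected(self, rng):
        x = rng.vonmises(0, 2, 50) % TWO_PI
        k = fit_density(x)
        with pytest.raises(ValueError):
            delta4(x, np.empty(0), k, k)


class TestSelection:
    @pytest.mark.parametrize(
        "n1, n2, expected",
        [
            (794, 2588, Estimator.DELTA4),
            (30, 40, Estimator.DELTA1),
            (50, 400, Estimator.DELTA1),   # 50 is not "> 50"
            (51, 51, Estimator.DELTA4),
            (40, 2000, Estimator.DELTA1),  # smaller sample governs
        ],
    )
    def test_rule(self, n1, n2, expected):
        assert select_estimator(n1, n2) is expected

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            select_estimator(0, 10)


class TestCategorization:
    @pytest.mark.parametrize(
        "delta, category",
        [
            (0.25, OverlapCategory.LOW),
            (0.49999, OverlapCategory.LOW),
            (0.50, OverlapCategory.MEDIUM),
            (0.80, OverlapCategory.MEDIUM),
            (0.81, OverlapCategory.HIGH),
            (1.0, OverlapCategory.HIGH),
        ],
    )
    def test_thresholds(self, delta, category):
        assert categorize_overlap(delta) is category

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            categorize_overlap(1.2)
        with pytest.raises(ValueError):
            OverlapEstimate(1.2, Estimator.DELTA1, 10, 10)


class TestEstimateOverlap:
    def test_identical_samples(self, rng):
        x = rng.vonmises(0.5, 3.0, 200) % TWO_PI
        est = estimate_overlap(x, x)
        assert est.delta == pytest.approx(1.0, abs=1e-9)
        assert est.category is OverlapCategory.HIGH

    def test_archetype_recovery(self, rng):
        """Crepuscular vs nocturnal overlap recovered near its analytic value."""
        crep, noct = ARCHETYPES["crepuscular"], ARCHETYPES["nocturnal"]
        x1 = sample_mixture(500, crep, rng)
        x2 = sample_mixture(500, noct, rng)
        est = estimate_overlap(x1, x2)
        assert est.delta == pytest.approx(analytic_overlap(crep, noct), abs=0.05)

    @given(
        seed=st.integers(min_value=0, max_value=10_000),
        n1=st.integers(min_value=15, max_value=120),
        n2=st.integers(min_value=15, max_value=120),
        kappa=st.floats(min_value=0.3, max_value=8.0),
        mu=st.floats(min_value=0.0, max_value=TWO_PI),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_range_and_symmetry(self, seed, n1, n2, kappa, mu):
        """Delta always lands in [0, 1] and is exactly symmetric."""
        import warnings

        r = np.random.default_rng(seed)
        x1 = r.vonmises(mu, kappa, n1) % TWO_PI
        x2 = r.vonmises(0.0, 1.0, n2) % TWO_PI
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # small-sample instability note
            a = estimate_overlap(x1, x2)
            b = estimate_overlap(x2, x1)
        assert 0.0 <= a.delta <= 1.0
        assert a.delta == b.delta
        assert a.estimator is b.estimator

    def test_null_mean_close_to_one(self):
        """Mean Delta over same-distribution pairs (n=100) exceeds 0.85."""
        deltas = []
        for seed in range(200):
            r = np.random.default_rng(seed)
            x1 = r.vonmises(0.0, 2.0, 100) % TWO_PI
            x2 = r.vonmises(0.0, 2.0, 100) % TWO_PI
            d, _ = delta_from_samples(x1, x2)
            deltas.append(d)
            assert d <= 1.0
        assert np.mean(deltas) > 0.85
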