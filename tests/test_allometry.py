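"""SMA fitting, confidence intervals, and the ornament classifiers.

The published coefficient table for this study system (five populations,
head crest / dorsal fin / ventral fin control) is used as a worked example:
applying the CI-overlap classifier to the printed intervals must reproduce
the published flag pattern exactly.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from divergekit.allometry import (
    BELOW_THRESHOLD,
    INDISTINGUISHABLE_FROM_CONTROL,
    SEXUALLY_SELECTED,
    AllometryFit,
    ci_overlap,
    classify_ornament,
    elevation_ci_bootstrap,
    sex_dimorphism_elevation,
    slope_ci,
    sma_fit,
)

# Published allometric exponents b (95% CI) per population:
# {population: {(trait, sex): (b, lo, hi)}}
PUBLISHED_EXPONENTS = {
    "Pago": {
        ("crest", "M"): (2.50, 1.96, 3.03),
        ("dorsal", "M"): (1.82, 1.63, 2.01),
        ("ventral", "M"): (1.25, 1.07, 1.43),
        ("dorsal", "F"): (1.43, 1.19, 1.67),
        ("ventral", "F"): (1.23, 1.04, 1.43),
    },
    "Taga'chang": {
        ("crest", "M"): (2.24, 1.86, 2.62),
        ("dorsal", "M"): (1.53, 1.39, 1.67),
        ("ventral", "M"): (1.22, 1.08, 1.36),
        ("dorsal", "F"): (1.32, 1.19, 1.46),
        ("ventral", "F"): (1.12, 0.97, 1.27),
    },
    "Talofofo": {
        ("crest", "M"): (2.03, 1.50, 2.57),
        ("dorsal", "M"): (1.59, 1.37, 1.81),
        ("ventral", "M"): (1.49, 1.18, 1.81),
        ("dorsal", "F"): (1.49, 1.38, 1.60),
        ("ventral", "F"): (1.31, 1.10, 1.51),
    },
    "Umatac": {
        ("crest", "M"): (2.62, 2.14, 3.10),
        ("dorsal", "M"): (1.61, 1.39, 1.84),
        ("ventral", "M"): (1.25, 1.04, 1.46),
        ("dorsal", "F"): (1.47, 1.27, 1.68),
        ("ventral", "F"): (1.22, 0.99, 1.46),
    },
    "Adelup": {
        ("crest", "M"): (2.14, 1.74, 2.55),
        ("dorsal", "M"): (1.71, 1.57, 1.85),
        ("ventral", "M"): (1.33, 1.16, 1.51),
        ("dorsal", "F"): (1.42, 1.20, 1.65),
        ("ventral", "F"): (1.27, 1.02, 1.52),
    },
}


def _fit(trait, pop, sex, b, lo, hi, a=0.0, a_lo=None, a_hi=None):
    return AllometryFit(
        trait=trait, population=pop, sex=sex, n=25,
        elevation_a=a, exponent_b=b, r=0.9, grand_mean_x=4.0,
        a_ci=(a_lo, a_hi) if a_lo is not None else None, b_ci=(lo, hi))


def published_classifications():
    out = {}
    for pop, entries in PUBLISHED_EXPONENTS.items():
        for sex in ("M", "F"):
            control = _fit("ventral", pop, sex,
                           *entries[("ventral", sex)])
            for trait in ("crest", "dorsal"):
                if (trait, sex) not in entries:
                    continue
                fit = _fit(trait, pop, sex, *entries[(trait, sex)])
                out[(pop, trait, sex)] = classify_ornament(fit, control)
    return out


class TestSmaFit:
    def test_perfect_line(self):
        fit = sma_fit([0, 1, 2, 3], [0, 2, 4, 6], grand_mean_x=1.5)
        assert fit.exponent_b == pytest.approx(2.0)
        assert fit.r == pytest.approx(1.0)
        assert fit.elevation_a == pytest.approx(3.0)

    def test_negative_slope(self):
        x = np.arange(5.0)
        fit = sma_fit(x, -x)
        assert fit.exponent_b == pytest.approx(-1.0)
        assert fit.r == pytest.approx(-1.0)

    def test_sma_equals_ols_over_abs_r(self):
        """b_SMA = b_OLS / |r| on arbitrary data (1000 random draws)."""
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(1000):
            x = rng.normal(0, rng.uniform(0.5, 3), 50)
            y = rng.uniform(-2, 2) * x + rng.normal(0, 1, 50)
            fit = sma_fit(x, y)
            b_ols = np.polyfit(x, y, 1)[0]
            worst = max(worst, abs(fit.exponent_b - b_ols / abs(fit.r)))
        assert worst < 1e-10

    def test_swap_xy_inverts_slope(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=40)
        y = 1.7 * x + rng.normal(0, 0.5, 40)
        b_xy = sma_fit(x, y).exponent_b
        b_yx = sma_fit(y, x).exponent_b
        assert b_xy == pytest.approx(1.0 / b_yx, rel=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            sma_fit([1, 1, 1], [0, 1, 2])
        with pytest.raises(ValueError, match="n >= 3"):
            sma_fit([0, 1], [0, 1])


class TestSlopeCI:
    def test_perfect_correlation_collapses(self):
        assert slope_ci(2.0, 1.0, 30) == (2.0, 2.0)

    def test_interval_contains_estimate(self):
        lo, hi = slope_ci(2.0, 0.8, 30)
        assert lo < 2.0 < hi

    def test_coverage_93_to_97_percent(self):
        """Nominal 95% slope CI covers the population SMA slope in 93-97%
        of 1000 replicates at n = 30."""
        rng = np.random.default_rng(11)
        true_b = np.sqrt(2.0 ** 2 + 1.0)  # population sd(y)/sd(x)
        hits = 0
        for _ in range(1000):
            x = rng.normal(0, 1, 30)
            y = 2.0 * x + rng.normal(0, 1, 30)
            lo, hi = sma_fit(x, y).b_ci
            hits += lo <= true_b <= hi
        assert 930 <= hits <= 970

    def test_bootstrap_slope_ci_agrees_with_analytic(self):
        """Percentile-bootstrap slope CI matches the analytic formula within
        10% of the interval width on one seeded n = 50 sample."""
        rng = np.random.default_rng(99)
        x = rng.normal(0, 1, 50)
        y = 2.0 * x + rng.normal(0, 0.8, 50)
        fit = sma_fit(x, y)
        lo_a, hi_a = fit.b_ci
        boots = []
        brng = np.random.default_rng(100)
        for _ in range(2000):
            idx = brng.integers(0, 50, 50)
            xb, yb = x[idx], y[idx]
            r = np.corrcoef(xb, yb)[0, 1]
            boots.append(np.sign(r) * yb.std(ddof=1) / xb.std(ddof=1))
        lo_b, hi_b = np.quantile(boots, [0.025, 0.975])
        width = hi_a - lo_a
        assert abs(lo_b - lo_a) < 0.1 * width
        assert abs(hi_b - hi_a) < 0.1 * width


class TestClassifiers:
    def test_ci_overlap_pago_crest_vs_control(self):
        assert not ci_overlap((1.96, 3.03), (1.07, 1.43))

    def test_ci_overlap_talofofo_crest_vs_control(self):
        assert ci_overlap((1.50, 2.57), (1.18, 1.81))

    def test_identical_intervals_overlap(self):
        assert ci_overlap((1.0, 2.0), (1.0, 2.0))

    def test_published_flag_pattern_reproduced_exactly(self):
        """Male head crest flagged in 4/5 populations (all but Talofofo),
        male dorsal fin in Pago, Taga'chang and Adelup only, and no female
        dorsal fin — the published pattern."""
        cls = published_classifications()
        crest_flagged = {p for (p, t, s), c in cls.items()
                        if t == "crest" and c == SEXUALLY_SELECTED}
        dorsal_m = {p for (p, t, s), c in cls.items()
                    if t == "dorsal" and s == "M" and c == SEXUALLY_SELECTED}
        dorsal_f = {p for (p, t, s), c in cls.items()
                    if t == "dorsal" and s == "F" and c == SEXUALLY_SELECTED}
        assert crest_flagged == {"Pago", "Taga'chang", "Umatac", "Adelup"}
        assert dorsal_m == {"Pago", "Taga'chang", "Adelup"}
        assert dorsal_f == set()

    def test_umatac_dorsal_indistinguishable_from_control(self):
        cls = published_classifications()
        assert cls[("Umatac", "dorsal", "M")] == INDISTINGUISHABLE_FROM_CONTROL

    def test_below_threshold_overrides_ci_separation(self):
        fit = _fit("dorsal", "P", "M", 1.2, 1.1, 1.3)
        control = _fit("ventral", "P", "M", 0.5, 0.4, 0.6)
        assert classify_ornament(fit, control) == BELOW_THRESHOLD

    def test_mismatched_population_rejected(self):
        fit = _fit("crest", "P", "M", 2.0, 1.8, 2.2)
        control = _fit("ventral", "Q", "M", 1.2, 1.0, 1.4)
        with pytest.raises(ValueError):
            classify_ornament(fit, control)


class TestSexDimorphism:
    def test_pago_dorsal_elevation_is_male_biased(self):
        m = _fit("dorsal", "Pago", "M", 1.82, 1.63, 2.01,
                 a=2.70, a_lo=2.67, a_hi=2.73)
        f = _fit("dorsal", "Pago", "F", 1.43, 1.19, 1.67,
                 a=2.45, a_lo=2.41, a_hi=2.49)
        assert sex_dimorphism_elevation(m, f) == "male-biased"

    def test_identical_fits_indistinguishable(self):
        m = _fit("dorsal", "P", "M", 1.8, 1.6, 2.0, a=2.5, a_lo=2.4, a_hi=2.6)
        f = _fit("dorsal", "P", "F", 1.8, 1.6, 2.0, a=2.5, a_lo=2.4, a_hi=2.6)
        assert sex_dimorphism_elevation(m, f) == "indistinguishable"

    def test_equal_true_elevations_rarely_called_dimorphic(self):
        """Specificity: with equal true elevations the call should be
        'indistinguishable' in at least 90% of replicates."""
        rng = np.random.default_rng(21)
        calls = 0
        reps = 200
        for _ in range(reps):
            x1 = rng.normal(4.0, 0.15, 30)
            x2 = rng.normal(4.0, 0.15, 30)
            y1 = 1.0 + 2.0 * (x1 - 4.0) + rng.normal(0, 0.05, 30)
            y2 = 1.0 + 2.0 * (x2 - 4.0) + rng.normal(0, 0.05, 30)
            fm = sma_fit(x1, y1, 4.0, trait="t", population="p", sex="M",
                         n_bootstrap=200, rng=rng)
            ff = sma_fit(x2, y2, 4.0, trait="t", population="p", sex="F",
                         n_bootstrap=200, rng=rng)
            calls += sex_dimorphism_elevation(fm, ff) == "indistinguishable"
        assert calls >= 0.90 * reps


@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
@settings(max_examples=25, derandomize=True, deadline=None)
def test_zero_noise_recovery_to_ten_digits(seed):
    """With no noise the SMA fit returns the generating (a, b) to at least
    10 significant digits."""
    rng = np.random.default_rng(seed)
    a, b = rng.uniform(0.5, 3.0), rng.uniform(1.0, 3.0)
    x = rng.normal(4.0, 0.2, 30)
    y = a + b * (x - 4.0)
    fit = sma_fit(x, y, grand_mean_x=4.0)
    assert fit.exponent_b == pytest.approx(b, rel=1e-10)
    assert fit.elevation_a == pytest.approx(a, rel=1e-10)
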