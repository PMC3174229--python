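import numpy as np
import pytest
from scipy import stats

from pathrise.core_data import FloraTable
from pathrise.introduction_dynamics import (
    CumulativeCurve,
    FiellerEstimate,
    build_cumulative,
    compare_inclusion,
    deletion_test,
    fit_inclusion_glm,
    fit_loess_with_span_selection,
    fit_sequential_polynomial,
    loess_fit,
)

from conftest import make_record


def curve_from_times(t, pathway="x", origin=1800):
    years = np.sort(origin + np.ceil(np.asarray(t)).astype(int))
    grid = np.arange(years[0], years[-1] + 1)
    cum = np.searchsorted(years, grid, side="right").astype(float)
    return CumulativeCurve(pathway=pathway, years=grid, cumulative=cum)


class TestBuildCumulative:
    def test_counting(self):
        recs = [make_record(i, {"escape"}, year=y) for i, y in enumerate([1850, 1850, 1900])]
        t = FloraTable(records=recs)
        c = build_cumulative(t, "escape")
        assert c.years[0] == 1850 and c.years[-1] == 1900
        assert c.cumulative[0] == 2
        assert all(c.cumulative[:-1] == 2)
        assert c.cumulative[-1] == 3

    def test_sqrt_transform(self):
        recs = [make_record(i, {"escape"}, year=y) for i, y in enumerate([1850, 1850, 1900])]
        c = build_cumulative(FloraTable(records=recs), "escape", transform="sqrt")
        assert c.cumulative[0] == pytest.approx(np.sqrt(2))
        assert c.n_species == 3

    def test_final_count_equals_tally(self, small_synthetic):
        dated = sum(
            1 for r in small_synthetic
            if "escape" in r.pathways and r.first_record_year is not None
        )
        c = build_cumulative(small_synthetic, "escape")
        assert c.cumulative[-1] == dated

    def test_insufficient_data(self):
        t = FloraTable(records=[make_record(1, {"release"}, year=1900)])
        with pytest.raises(ValueError, match="dated"):
            build_cumulative(t, "release")


class TestSequentialPolynomial:
    @pytest.mark.parametrize("degree", [1, 2])
    def test_exact_polynomial_recovered(self, degree):
        x = np.arange(1850, 1950)
        y = 3.0 + 0.1 * (x - 1900) + (0.002 * (x - 1900) ** 2 if degree == 2 else 0)
        c = CumulativeCurve("x", x, y)
        assert fit_sequential_polynomial(c).degree == degree

    def test_noisy_cubic_matches_partial_f_oracle(self):
        rng = np.random.default_rng(3)
        x = np.arange(100, dtype=float)
        xs = (x - x.mean()) / x.std()
        y = 5 + xs + 0.5 * xs**2 + 0.8 * xs**3 + rng.normal(0, 0.05, len(x))
        c = CumulativeCurve("x", x, y)
        fit = fit_sequential_polynomial(c)

        # oracle: fit all degrees, apply partial-F tests sequentially
        def rss(d):
            X = np.vander(xs, d + 1, increasing=True)
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            return float(np.sum((y - X @ coef) ** 2))

        degree = 1
        for d in range(2, 7):
            f = (rss(d - 1) - rss(d)) / (rss(d) / (len(x) - d - 1))
            if stats.f.sf(f, 1, len(x) - d - 1) >= 0.05:
                break
            degree = d
        assert fit.degree == degree == 3


class TestLoess:
    def make_linear_curve(self, n=60):
        x = np.arange(1850, 1850 + n, dtype=float)
        y = 1.0 + 0.25 * (x - 1850)
        return CumulativeCurve("x", x, y)

    @pytest.mark.parametrize("span", [0.15, 0.4, 1.0])
    def test_exact_on_linear_signal(self, span):
        c = self.make_linear_curve()
        fit = loess_fit(c, span)
        assert np.allclose(fit.fitted, c.cumulative, atol=1e-8)

    def test_span_one_equals_global_regression(self):
        rng = np.random.default_rng(0)
        x = np.arange(1850, 1950, dtype=float)
        y = 2 + 0.1 * x + rng.normal(0, 1, len(x))
        c = CumulativeCurve("x", x, y)
        fit = loess_fit(c, 1.0)
        beta = np.polyfit(x, y, 1)
        assert np.allclose(fit.fitted, np.polyval(beta, x), atol=1e-8)
        assert fit.enp == pytest.approx(2.0, abs=1e-6)

    def test_enp_decreases_with_span(self):
        rng = np.random.default_rng(1)
        x = np.arange(1800, 1950, dtype=float)
        y = np.cumsum(rng.uniform(0, 1, len(x)))
        c = CumulativeCurve("x", x, y)
        enps = [loess_fit(c, s).enp for s in (0.1, 0.2, 0.4, 0.7, 1.0)]
        assert all(a > b for a, b in zip(enps, enps[1:]))

    def test_span_selection_on_abrupt_acceleration(self):
        """A curve with a sharp late acceleration: LOESS beats the best
        polynomial in the deletion test, mirroring the model choice made for
        real introduction curves."""
        rng = np.random.default_rng(5)
        x = np.arange(1800, 2000, dtype=float)
        base = 0.05 * (x - 1800)
        kick = np.where(x >= 1960, 0.8 * (x - 1960), 0.0)
        y = np.sqrt(1 + base + kick) + rng.normal(0, 0.02, len(x))
        c = CumulativeCurve("x", x, y, transform="sqrt")
        lo = fit_loess_with_span_selection(c, start_span=0.08, step=0.02)
        poly = fit_sequential_polynomial(c)
        f, dfn, dfd, p = deletion_test(poly, lo)
        assert lo.enp > poly.enp
        assert p < 0.05

    def test_too_small_start_span_raises(self):
        c = self.make_linear_curve(n=20)
        with pytest.raises(ValueError):
            fit_loess_with_span_selection(c, start_span=0.01)


class TestFieller:
    def test_exact_logistic_identity(self):
        """Cumulative proportions exactly on logit(F) = a + b t give
        t50 = -a/b exactly."""
        a, b = -14.5, 0.1
        t = np.arange(50, 251)
        F = 1 / (1 + np.exp(-(a + b * t)))
        n = 600
        cum = np.round(F / F[-1] * n)  # monotone, ends at n
        cum = np.maximum.accumulate(cum)
        curve = CumulativeCurve("x", t + 1800, cum)
        est = fit_inclusion_glm(curve, 1800, likelihood="cumulative")
        assert est.t50 == pytest.approx(-a / b, rel=0.02)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(2)
        t = rng.logistic(150, 14, 500)
        t = t[(t > 0) & (t < 200)]
        c1 = curve_from_times(t)
        c2 = curve_from_times(t + 30)
        e1 = fit_inclusion_glm(c1, 1800)
        e2 = fit_inclusion_glm(c2, 1800)
        assert e2.t50 - e1.t50 == pytest.approx(30.0, abs=1e-4)
        assert e2.ci_low - e1.ci_low == pytest.approx(30.0, abs=1e-3)

    def test_fieller_agrees_with_parametric_bootstrap(self):
        """The Fieller CI endpoints match a parametric-bootstrap percentile
        CI to within 10% of the CI width."""
        rng = np.random.default_rng(8)
        t = rng.logistic(150, 14, 3000)
        t = t[(t > 0) & (t < 200)][:600]
        est = fit_inclusion_glm(curve_from_times(t), 1800)
        a, b = est.glm_coefficients
        boot = []
        for rep in range(400):
            r = np.random.default_rng(10_000 + rep)
            tb = r.logistic(-a / b, 1 / b, 3000)
            tb = tb[(tb > 0) & (tb < 200)][:600]
            boot.append(fit_inclusion_glm(curve_from_times(tb), 1800).t50)
        lo, hi = np.percentile(boot, [2.5, 97.5])
        width = est.ci_high - est.ci_low
        assert est.ci_low == pytest.approx(lo, abs=0.1 * width)
        assert est.ci_high == pytest.approx(hi, abs=0.1 * width)
        assert est.ci_low <= 150 <= est.ci_high

    def test_negative_slope_rejected(self):
        c = CumulativeCurve("x", np.arange(1900, 1950), np.linspace(50, 12, 50))
        with pytest.raises(ValueError):
            fit_inclusion_glm(c, 1800, likelihood="cumulative")


class TestCompareInclusion:
    def make(self, p, lo, hi):
        return FiellerEstimate(
            pathway=p, t50=(lo + hi) / 2, ci_low=lo, ci_high=hi,
            glm_coefficients=(0, 1), vcov=np.eye(2),
        )

    def test_overlapping_not_different(self):
        # the published release vs escape intervals overlap
        table = compare_inclusion(
            [self.make("release", 141.2, 148.5), self.make("escape", 146.0, 147.6)]
        )
        assert not table.loc["release", "escape"]

    def test_disjoint_different_and_symmetric(self):
        # the published stowaway vs contaminant intervals are disjoint
        table = compare_inclusion(
            [self.make("stowaway", 162.5, 165.2), self.make("contaminant", 172.1, 173.6)]
        )
        assert table.loc["stowaway", "contaminant"]
        assert table.loc["contaminant", "stowaway"]

    def test_identical_not_different(self):
        table = compare_inclusion(
            [self.make("a", 10, 20), self.make("b", 10, 20)]
        )
        assert not table.loc["a", "b"]
        assert not table.loc["a", "a"]
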