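"""Univariable MR estimators against independent oracles and invariants."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_harmonized
from mrmediate.errors import (
    DegenerateInstrumentError,
    GridCoverageError,
    InsufficientInstrumentsError,
)
from mrmediate.univariable import (
    contamination_mixture,
    instrument_strength,
    ivw,
    mr_egger,
    ratio_estimates,
    wald_ratio,
    weighted_median,
)


def simulated(rng, k=20, theta=0.5, intercept=0.0):
    bx = rng.normal(0.1, 0.05, k)
    sx = rng.uniform(0.005, 0.02, k)
    sy = rng.uniform(0.005, 0.02, k)
    by = intercept + theta * bx + rng.normal(0, sy)
    return make_harmonized(bx, sx, by, sy)


class TestWaldRatio:
    @pytest.mark.parametrize(
        "bx,by,sy,theta,se",
        [(0.1, 0.05, 0.01, 0.5, 0.1), (-0.1, 0.05, 0.01, -0.5, 0.1), (0.2, 0.0, 0.02, 0.0, 0.1)],
    )
    def test_arithmetic(self, bx, by, sy, theta, se):
        est = wald_ratio(bx, by, sy)
        assert est.theta == pytest.approx(theta)
        assert est.se == pytest.approx(se)

    def test_zero_bx_raises(self):
        with pytest.raises(DegenerateInstrumentError):
            wald_ratio(0.0, 0.1, 0.01)


class TestIVW:
    def test_single_variant_equals_wald(self):
        data = make_harmonized([0.1], [0.01], [0.05], [0.01])
        est = ivw(data)
        wald = wald_ratio(0.1, 0.05, 0.01)
        assert est.theta == pytest.approx(wald.theta)
        assert est.se == pytest.approx(wald.se)

    def test_exact_collinear_data(self):
        data = make_harmonized([0.1, 0.2], [0.01, 0.01], [0.05, 0.10], [0.01, 0.01])
        est = ivw(data)
        assert est.theta == pytest.approx(0.5)
        assert est.Q == pytest.approx(0.0, abs=1e-20)

    def test_matches_wls_oracle(self, rng):
        data = simulated(rng)
        fit = sm.WLS(data.by, data.bx, weights=1 / data.sy**2).fit()
        assert ivw(data).theta == pytest.approx(fit.params[0], abs=1e-10)

    def test_fixed_vs_multiplicative_se(self, rng):
        data = simulated(rng, theta=0.3)
        fe = ivw(data, "fixed")
        re = ivw(data, "multiplicative")
        assert re.se >= fe.se
        assert re.theta == fe.theta

    def test_all_zero_bx_raises(self):
        data = make_harmonized([0.0, 0.0], [0.01, 0.01], [0.0, 0.0], [0.01, 0.01])
        with pytest.raises(DegenerateInstrumentError):
            ivw(data)


class TestEgger:
    def test_exact_linear_data(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        by = 0.02 + 0.5 * bx
        data = make_harmonized(bx, 0.01, by, 0.01)
        est = mr_egger(data)
        assert est.intercept == pytest.approx(0.02, abs=1e-12)
        assert est.theta == pytest.approx(0.5, abs=1e-12)

    def test_null_outcome(self):
        data = make_harmonized([0.1, 0.2, 0.3], 0.01, [0.0, 0.0, 0.0], 0.01)
        est = mr_egger(data)
        assert est.theta == pytest.approx(0.0, abs=1e-12)
        assert est.intercept == pytest.approx(0.0, abs=1e-12)

    def test_matches_wls_oracle(self, rng):
        data = simulated(rng, intercept=0.01)
        flip = np.where(data.bx[:, 0] < 0, -1.0, 1.0)
        X = sm.add_constant(data.bx[:, 0] * flip)
        fit = sm.WLS(data.by * flip, X, weights=1 / data.sy**2).fit()
        est = mr_egger(data)
        assert est.intercept == pytest.approx(fit.params[0], abs=1e-10)
        assert est.theta == pytest.approx(fit.params[1], abs=1e-10)

    def test_too_few_variants(self):
        data = make_harmonized([0.1, 0.2], 0.01, [0.05, 0.1], 0.01)
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(data)


class TestWeightedMedian:
    def test_middle_order_statistic(self):
        # equal weights: ratios 0.1/0.5/0.9 -> 0.5
        bx = np.ones(3)
        by = np.array([0.1, 0.5, 0.9])
        data = make_harmonized(bx, 0.01, by, 0.01)
        est = weighted_median(data, n_boot=50, seed=0)
        assert est.theta == pytest.approx(0.5)

    def test_degenerate_identical_ratios(self):
        bx = np.array([0.1, 0.2, 0.4])
        by = 0.3 * bx
        data = make_harmonized(bx, 1e-8, by, 1e-8)
        est = weighted_median(data, n_boot=100, seed=1)
        assert est.theta == pytest.approx(0.3)
        assert est.se < 1e-6

    def test_matches_interpolated_definition(self, rng):
        for _ in range(5):
            data = simulated(rng, k=5)
            r, s = ratio_estimates(data)
            w = 1 / s**2
            order = np.argsort(r)
            p = (np.cumsum(w[order]) - 0.5 * w[order]) / np.sum(w)
            expected = float(np.interp(0.5, p, r[order]))
            est = weighted_median(data, n_boot=10, seed=0)
            assert est.theta == pytest.approx(expected, abs=1e-12)


class TestContaminationMixture:
    def test_consensus(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        by = 0.4 * bx
        data = make_harmonized(bx, 0.001, by, 0.002)
        est = contamination_mixture(data)
        assert est.theta == pytest.approx(0.4, abs=1e-3)
        assert set(est.valid_set) == set(data.variant_ids)

    def test_two_clusters_flag_multimodal(self):
        bx = np.ones(8) * 0.2
        by = np.concatenate([np.zeros(4), 0.2 * np.ones(4)])  # ratios 0 and 1
        data = make_harmonized(bx, 0.001, by, 0.002)
        est = contamination_mixture(data)
        assert est.multimodal

    def test_grid_must_span_ratios(self):
        data = make_harmonized([0.1, 0.2], 0.01, [0.05, 0.2], 0.01)
        with pytest.raises(GridCoverageError):
            contamination_mixture(data, grid=np.linspace(0, 0.1, 11))

    def test_matches_exhaustive_assignment_search(self, rng):
        import itertools

        for _ in range(3):
            k = 8
            bx = rng.normal(0.15, 0.05, k)
            bx[np.abs(bx) < 0.02] = 0.05
            by = rng.normal(0.05, 0.05, k)
            data = make_harmonized(bx, 0.01, by, rng.uniform(0.005, 0.02, k))
            est = contamination_mixture(data)
            r, s = ratio_estimates(data)
            psi = est.psi
            center = float(np.mean(r))
            span = max(float(np.std(r)), float(np.max(s)), 1e-6)
            grid = np.linspace(center - 6 * span, center + 6 * span, 10001)
            diff = r[None, :] - grid[:, None]
            V = (-0.5 * (np.log(2 * np.pi * s**2) + diff**2 / s**2)).T
            I = (
                -0.5
                * (np.log(2 * np.pi * (s**2 + psi**2)) + diff**2 / (s**2 + psi**2))
            ).T
            A = np.array(list(itertools.product([0, 1], repeat=k)), dtype=float)
            L = A @ V + (1 - A) @ I
            best = np.unravel_index(np.argmax(L), L.shape)
            assert est.theta == pytest.approx(grid[best[1]], abs=1e-12)


class TestInstrumentStrength:
    def test_arithmetic(self):
        data = make_harmonized([0.1, 0.02], [0.01, 0.01], [0.0, 0.0], [0.01, 0.01])
        rec = instrument_strength(data)
        assert rec.f_stats[0] == pytest.approx(100)
        assert rec.f_stats[1] == pytest.approx(4)
        assert rec.mean_f == pytest.approx(52)
        assert rec.min_f == pytest.approx(4)

    def test_scaling_law(self, rng):
        data = simulated(rng, k=10)
        base = instrument_strength(data)
        scaled = make_harmonized(
            data.bx[:, 0], data.sx[:, 0] * np.sqrt(2), data.by, data.sy
        )
        np.testing.assert_allclose(
            instrument_strength(scaled).f_stats, base.f_stats / 2
        )


@given(c=st.floats(min_value=0.5, max_value=3.0))
def test_scale_equivariance(c):
    """Multiplying all bx, sx by c divides every estimate by c."""
    rng = np.random.default_rng(11)
    data = simulated(rng, k=10, theta=0.4)
    scaled = make_harmonized(data.bx[:, 0] * c, data.sx[:, 0] * c, data.by, data.sy)
    assert ivw(scaled).theta == pytest.approx(ivw(data).theta / c, rel=1e-9)
    assert mr_egger(scaled).theta == pytest.approx(mr_egger(data).theta / c, rel=1e-9)
    assert weighted_median(scaled, n_boot=10, seed=0).theta == pytest.approx(
        weighted_median(data, n_boot=10, seed=0).theta / c, rel=1e-9
    )
    assert contamination_mixture(scaled).theta == pytest.approx(
        contamination_mixture(data).theta / c, rel=1e-3
    )


def test_orientation_invariance(rng):
    """Jointly negating any variant's (bx, by) leaves estimates unchanged."""
    data = simulated(rng, k=12, theta=0.3)
    flip = rng.choice([-1.0, 1.0], size=12)
    flipped = make_harmonized(
        data.bx[:, 0] * flip, data.sx[:, 0], data.by * flip, data.sy
    )
    assert ivw(flipped).theta == pytest.approx(ivw(data).theta, rel=1e-12)
    assert mr_egger(flipped).theta == pytest.approx(mr_egger(data).theta, rel=1e-12)
    assert weighted_median(flipped, n_boot=10, seed=0).theta == pytest.approx(
        weighted_median(data, n_boot=10, seed=0).theta, rel=1e-12
    )
    assert contamination_mixture(flipped).theta == pytest.approx(
        contamination_mixture(data).theta, rel=1e-9
    )
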