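import numpy as np
import pytest
from scipy import stats as sps

import transpec as tp
from transpec.exceptions import ValidationError
from transpec.thresholds import (
    DensityCurve,
    estimate_density,
    find_inflection_points,
    select_lip,
    select_rip,
)

from .conftest import make_probs


def smoothed_density_oracle(pdf, bandwidth, grid_size=512, fine=8192):
    """Boundary-reflected kernel smoothing of an analytic density on [0, 1].

    Independent of the KDE implementation: bins the analytic pdf on a fine
    grid and convolves each bin's mass with the Gaussian kernel (plus its
    reflections), giving the curve the KDE estimates as n -> infinity.
    """
    edges = np.linspace(0.0, 1.0, fine + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    mass = pdf(mids) * np.diff(edges)
    mass /= mass.sum()
    grid = np.linspace(0.0, 1.0, grid_size)
    delta = grid[:, None] - mids[None, :]
    refl0 = grid[:, None] + mids[None, :]
    refl1 = (2.0 - grid[:, None]) - mids[None, :]
    k = (
        sps.norm.pdf(delta, scale=bandwidth)
        + sps.norm.pdf(refl0, scale=bandwidth)
        + sps.norm.pdf(refl1, scale=bandwidth)
    )
    return DensityCurve(grid=grid, density=k @ mass, bandwidth=bandwidth)


class TestProbabilities:
    def test_direct_count_with_threshold_inclusive(self):
        expr = tp.ExpressionMatrix(
            [[0.6, 0.4, 0.5, 0.0, 1.0, 1.0]], ["t1"], [f"s{i}" for i in range(6)]
        )
        samples = tp.SampleTable.from_records(
            [f"s{i}" for i in range(6)], ["A"] * 4 + ["B"] * 2, [8] * 6
        )
        probs = tp.compute_probabilities(expr, samples, 0.5)
        # 0.5 counts as expressed (>=, not >)
        assert probs.p[0, 0] == pytest.approx(2 / 4)
        assert probs.p[0, 1] == pytest.approx(1.0)

    @pytest.mark.parametrize("values,expected", [([0.0] * 4, 0.0), ([0.7] * 4, 1.0)])
    def test_extremes(self, values, expected):
        expr = tp.ExpressionMatrix([values + [1.0]], ["t1"], [f"s{i}" for i in range(5)])
        samples = tp.SampleTable.from_records(
            [f"s{i}" for i in range(5)], ["A"] * 4 + ["B"], [8] * 5
        )
        probs = tp.compute_probabilities(expr, samples)
        assert probs.p[0, 0] == expected

    def test_monotone_in_tpm_threshold(self):
        rng = np.random.default_rng(0)
        expr = tp.ExpressionMatrix(
            rng.lognormal(0, 1.5, (30, 40)),
            [f"t{j}" for j in range(30)],
            [f"s{i}" for i in range(40)],
        )
        samples = tp.SampleTable.from_records(
            [f"s{i}" for i in range(40)], ["A"] * 20 + ["B"] * 20, [8] * 40
        )
        prev = tp.compute_probabilities(expr, samples, 0.1).p
        for thr in (0.5, 1.0, 5.0):
            cur = tp.compute_probabilities(expr, samples, thr).p
            assert (cur <= prev + 1e-12).all()
            prev = cur

    def test_invariant_under_sample_permutation_within_tissue(self):
        rng = np.random.default_rng(1)
        expr = tp.ExpressionMatrix(
            rng.lognormal(0, 1, (10, 20)),
            [f"t{j}" for j in range(10)],
            [f"s{i}" for i in range(20)],
        )
        ids = [f"s{i}" for i in range(20)]
        samples = tp.SampleTable.from_records(ids, ["A"] * 10 + ["B"] * 10, [8] * 20)
        perm = ids[3:10] + ids[:3] + ids[13:] + ids[10:13]
        samples_perm = tp.SampleTable.from_records(
            perm, ["A"] * 10 + ["B"] * 10, [8] * 20
        )
        p1 = tp.compute_probabilities(expr, samples).p
        p2 = tp.compute_probabilities(expr, samples_perm).p
        assert np.array_equal(p1, p2)

    def test_single_tissue_rejected(self, tiny_expr):
        samples = tp.SampleTable.from_records(
            ["s1", "s2", "s3", "s4"], ["A"] * 4, [8] * 4
        )
        with pytest.raises(ValidationError, match=">= 2 tissues"):
            tp.compute_probabilities(tiny_expr, samples)


class TestDensity:
    def test_integrates_to_one(self):
        rng = np.random.default_rng(2)
        for a, b in [(0.3, 0.3), (2, 5), (1, 1)]:
            curve = estimate_density(rng.beta(a, b, 2000))
            assert np.trapezoid(curve.density, curve.grid) == pytest.approx(1.0, abs=0.02)

    def test_bimodal_beta_has_interior_minimum(self):
        rng = np.random.default_rng(3)
        curve = estimate_density(rng.beta(0.3, 0.3, 10_000))
        d = curve.density
        interior = (curve.grid > 0.3) & (curve.grid < 0.7)
        # local minimum strictly inside (0.3, 0.7): density rises on both sides
        i_min = np.argmin(np.where(interior, d, np.inf))
        assert 0.3 < curve.grid[i_min] < 0.7
        assert d[i_min] < d[curve.grid < 0.1].max()
        assert d[i_min] < d[curve.grid > 0.9].max()

    def test_constant_vector_is_degenerate(self):
        with pytest.raises(ValidationError, match="degenerate"):
            estimate_density(np.full(200, 0.5))

    def test_too_few_values_advises(self):
        with pytest.raises(ValidationError, match="fixed bandwidth"):
            estimate_density(np.linspace(0, 1, 50))

    def test_fixed_bandwidth_allows_small_n(self):
        curve = estimate_density(
            np.linspace(0.2, 0.8, 20), bandwidth_rule="fixed", bandwidth=0.1
        )
        assert curve.bandwidth == 0.1


class TestInflectionPoints:
    def test_truncated_normal_inflects_at_mu_pm_sigma(self):
        rng = np.random.default_rng(4)
        draws = rng.normal(0.5, 0.1, 60_000)
        draws = draws[(draws >= 0) & (draws <= 1)]
        curve = estimate_density(draws)
        ips = find_inflection_points(curve)
        # KDE convolution widens sigma to sqrt(0.1^2 + h^2); still within 0.02
        assert min(abs(x - 0.4) for x in ips) < 0.02
        assert min(abs(x - 0.6) for x in ips) < 0.02

    def test_linear_segment_has_no_inflection(self):
        grid = np.linspace(0, 1, 512)
        density = 2.0 - 2.0 * grid  # strictly linear, integrates to 1
        curve = DensityCurve(grid=grid, density=density, bandwidth=0.1)
        assert find_inflection_points(curve) == []

    def test_u_shaped_beta_has_flank_inflections(self):
        rng = np.random.default_rng(5)
        curve = estimate_density(rng.beta(0.3, 0.3, 20_000))
        ips = find_inflection_points(curve)
        assert len(ips) >= 2
        assert any(x < 0.5 for x in ips) and any(x > 0.5 for x in ips)

    @pytest.mark.parametrize(
        "pdf",
        [
            lambda x: sps.beta.pdf(x, 0.3, 0.3),
            lambda x: sps.norm.pdf(x, 0.5, 0.1),
        ],
        ids=["beta(0.3,0.3)", "normal(0.5,0.1)"],
    )
    def test_kde_inflections_match_smoothed_analytic_density(self, pdf):
        rng = np.random.default_rng(6)
        if pdf(np.array([0.5]))[0] > 2:  # normal case: denser at centre
            draws = rng.normal(0.5, 0.1, 80_000)
            draws = draws[(draws >= 0) & (draws <= 1)]
        else:
            draws = rng.beta(0.3, 0.3, 80_000)
        curve = estimate_density(draws)
        oracle = smoothed_density_oracle(pdf, curve.bandwidth)
        got = np.array(find_inflection_points(curve))
        want = np.array(find_inflection_points(oracle))
        assert len(want) > 0
        # every expected inflection is recovered within grid + MC resolution
        for w in want:
            assert np.min(np.abs(got - w)) < 0.02


class TestCutoffSelection:
    @pytest.mark.parametrize(
        "ips,expected,fallback",
        [
            ((0.2, 0.8, 0.95), 0.8, False),
            ((0.76, 0.88), 0.88, False),  # rightmost wins
            ((0.2, 0.95), 0.75, True),
            ((0.75, 0.9), 0.9, False),  # window closed on both ends
        ],
    )
    def test_select_rip(self, ips, expected, fallback):
        rip, fb = select_rip(ips, (0.75, 0.9))
        assert rip == pytest.approx(expected)
        assert fb is fallback

    @pytest.mark.parametrize(
        "ips,expected,fallback",
        [
            ((0.12, 0.2, 0.8), 0.2, False),
            ((0.8,), 0.25, True),
            ((0.07,), 0.07, False),
        ],
    )
    def test_select_lip(self, ips, expected, fallback):
        lip, fb = select_lip(ips, (0.05, 0.25))
        assert lip == pytest.approx(expected)
        assert fb is fallback

    def test_window_bounds_validated(self):
        with pytest.raises(ValidationError):
            select_rip([0.8], (0.3, 0.9))
        with pytest.raises(ValidationError):
            select_lip([0.1], (0.1, 0.6))


class TestTissueThresholds:
    def test_planted_u_shape_lands_in_windows(self, small_corpus):
        expr, samples, _ = small_corpus
        kept, expr2, _ = tp.filter_samples(samples, expr)
        probs = tp.compute_probabilities(expr2, kept)
        thr = tp.compute_tissue_thresholds(probs)
        assert ((thr["rip"] >= 0.75) & (thr["rip"] <= 0.9)).all()
        assert ((thr["lip"] >= 0.05) & (thr["lip"] <= 0.25)).all()
        assert not thr["rip_fallback"].any()
        assert not thr["lip_fallback"].any()
        assert (thr["lip"] < thr["rip"]).all()
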