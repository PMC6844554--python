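"""Statistical operations against hand-computed and enumeration oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipidhca.errors import ConstantInputError, InvalidParameterError
from lipidhca.fourpl import FourPLParams, true_response
from lipidhca.stats import (
    ddct,
    dunn_posttest,
    fit_4pl,
    kruskal_wallis,
    large_droplet_fraction,
    mann_whitney,
    normalize_to_vehicle,
    spearman,
    stratify_high_low,
)
from lipidhca.synthetic import generate_ct_table

G123 = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]


class TestKruskalWallis:
    def test_hand_computed_h(self):
        # ranks 1..9, mean ranks 2/5/8: H = 12/90 * 3*(4+25+64) - 30 = 7.2
        res = kruskal_wallis(G123)
        assert res.statistic == pytest.approx(7.2)

    def test_invariant_to_within_group_order(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(size=10) for _ in range(3)]
        h1 = kruskal_wallis(groups).statistic
        shuffled = [rng.permutation(g) for g in groups]
        assert kruskal_wallis(shuffled).statistic == pytest.approx(h1)

    def test_all_identical_values(self):
        res = kruskal_wallis([[5, 5], [5, 5, 5]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_needs_two_groups(self):
        with pytest.raises(InvalidParameterError):
            kruskal_wallis([[1, 2, 3]])

    def test_null_type_one_error_rate(self):
        """Rejection rate at alpha = 0.05 across 2000 null simulations."""
        rng = np.random.default_rng(2024)
        rejections = 0
        n_sim = 2000
        for _ in range(n_sim):
            groups = rng.normal(size=(3, 30))
            if kruskal_wallis(list(groups)).p_value < 0.05:
                rejections += 1
        assert 0.04 <= rejections / n_sim <= 0.06

    def test_two_group_p_ordering_matches_mann_whitney(self):
        """With two groups, KW and the rank-sum test order datasets identically."""
        rng = np.random.default_rng(7)
        results = []
        for _ in range(15):
            a = rng.normal(0, 1, 12)
            b = rng.normal(rng.uniform(0, 1.5), 1, 12)
            results.append(
                (kruskal_wallis([a, b]).p_value, mann_whitney(a, b).p_value)
            )
        for i in range(len(results)):
            for j in range(len(results)):
                pk_i, pm_i = results[i]
                pk_j, pm_j = results[j]
                if pk_i < pk_j:
                    assert pm_i <= pm_j


class TestDunn:
    def test_identical_groups_all_adjusted_one(self):
        table = dunn_posttest([[3, 3, 3], [3, 3, 3], [3, 3, 3]])
        assert (table["p_adj"] == 1.0).all()

    def test_hand_computed_z_pair_1_3(self):
        # mean ranks 2 and 8, var base N(N+1)/12 = 7.5 (no ties)
        table = dunn_posttest(G123)
        pair = table[(table["group_i"] == 0) & (table["group_j"] == 2)]
        assert abs(pair["z"].iloc[0]) == pytest.approx(6.0 / math.sqrt(7.5 * (2 / 3)))

    def test_adjusted_at_least_unadjusted(self):
        rng = np.random.default_rng(1)
        table = dunn_posttest([rng.normal(size=8) for _ in range(4)])
        assert (table["p_adj"] >= table["p"] - 1e-15).all()
        holm = dunn_posttest([rng.normal(size=8) for _ in range(4)], adjust="holm")
        assert (holm["p_adj"] >= holm["p"] - 1e-15).all()


class TestMannWhitney:
    def test_complete_separation(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        # exact two-sided p: 2 / C(6,3) = 0.1
        assert res.p_value == pytest.approx(0.1)
        assert res.extra["method"] == "exact"

    def test_identical_samples(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(4.5)  # n^2 / 2
        assert res.p_value == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(InvalidParameterError):
            mann_whitney([], [1.0])


class TestSpearman:
    def test_monotone_extremes(self):
        x = np.arange(10.0)
        assert spearman(x, np.exp(x)).statistic == pytest.approx(1.0)
        assert spearman(x, -(x**3)).statistic == pytest.approx(-1.0)

    def test_hand_computed_half(self):
        assert spearman([1, 2, 3], [1, 3, 2]).statistic == pytest.approx(0.5)

    def test_constant_vector_rejected(self):
        with pytest.raises(ConstantInputError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=4, max_size=30, unique=True))
    def test_invariant_to_monotone_transform(self, xs):
        rng = np.random.default_rng(0)
        y = rng.normal(size=len(xs))
        if np.unique(y).size < 2:
            return
        x = np.asarray(xs)
        r1 = spearman(x, y).statistic
        r2 = spearman(x + x**3, y).statistic  # strictly increasing map
        assert r1 == pytest.approx(r2)


class TestFit4PL:
    @pytest.mark.parametrize("mode,params", [
        ("stimulation", FourPLParams(2.0, 40.0, 0.8, 1.3, "stimulation")),
        ("inhibition", FourPLParams(0.3, 1.0, 9.0, 0.9, "inhibition")),
    ])
    def test_noiseless_recovery_exact(self, mode, params):
        dose = np.array([0.01, 0.1, 1.0, 10.0, 100.0, 1000.0])
        resp = true_response(dose, params)
        fit = fit_4pl(dose, resp, mode)
        assert fit.converged and not fit.degenerate
        assert fit.params.c50 == pytest.approx(params.c50, rel=1e-6)
        assert fit.params.hill == pytest.approx(params.hill, rel=1e-6)
        assert fit.params.bottom == pytest.approx(params.bottom, rel=1e-6, abs=1e-8)
        assert fit.params.top == pytest.approx(params.top, rel=1e-6)

    def test_scale_equivariance(self):
        params = FourPLParams(1.0, 10.0, 2.0, 1.0, "stimulation")
        dose = np.array([0.0, 0.1, 1.0, 10.0, 100.0])
        resp = true_response(dose, params)
        c = 7.3
        f1 = fit_4pl(dose, resp, "stimulation")
        f2 = fit_4pl(dose * c, resp, "stimulation")
        assert f2.params.c50 == pytest.approx(c * f1.params.c50, rel=1e-6)

    def test_vehicle_placeholder_insensitive(self):
        """A 10x change of the zero-dose placeholder moves EC50 < 5%."""
        params = FourPLParams(1.0, 10.0, 0.5, 1.0, "stimulation")
        dose = np.array([0.0, 0.05, 0.5, 5.0, 50.0])
        rng = np.random.default_rng(3)
        resp = true_response(dose, params) * rng.normal(1.0, 0.02, dose.size)
        c_a = fit_4pl(dose, resp, "stimulation", vehicle_divisor=100.0).params.c50
        c_b = fit_4pl(dose, resp, "stimulation", vehicle_divisor=1000.0).params.c50
        assert abs(c_a - c_b) / c_b < 0.05

    def test_constant_response_degenerate(self):
        fit = fit_4pl([0.0, 0.1, 1.0, 10.0], [5.0, 5.0, 5.0, 5.0], "stimulation")
        assert fit.degenerate and not fit.converged

    def test_too_few_doses_rejected(self):
        with pytest.raises(InvalidParameterError):
            fit_4pl([0.0, 1.0, 1.0], [1.0, 2.0, 2.0], "stimulation")


class TestNormalization:
    def test_fold_and_zscore_definitions(self):
        vehicle = [90.0, 100.0, 110.0]  # mean 100, sd 10
        assert normalize_to_vehicle([100.0], vehicle, "fold")[0] == pytest.approx(1.0)
        assert normalize_to_vehicle([120.0], vehicle, "zscore")[0] == pytest.approx(2.0)
        assert normalize_to_vehicle([100.0], vehicle, "zscore")[0] == pytest.approx(0.0)

    def test_vehicle_fold_self_mean_one(self):
        rng = np.random.default_rng(0)
        v = rng.lognormal(1, 0.5, 500)
        assert normalize_to_vehicle(v, v, "fold").mean() == pytest.approx(1.0)

    def test_errors(self):
        with pytest.raises(InvalidParameterError):
            normalize_to_vehicle([1.0], [], "fold")
        with pytest.raises(InvalidParameterError):
            normalize_to_vehicle([1.0], [0.0, 0.0], "fold")
        with pytest.raises(InvalidParameterError):
            normalize_to_vehicle([1.0], [5.0, 5.0], "zscore")


class TestLargeDroplets:
    def test_identical_samples_fold_one(self):
        rng = np.random.default_rng(0)
        v = rng.lognormal(3, 0.7, 2000)
        res = large_droplet_fraction(v, v)
        assert res.fold_enrichment == pytest.approx(1.0)

    def test_normal_tail_is_2sd(self):
        rng = np.random.default_rng(1)
        v = rng.normal(50, 5, 200_000)
        res = large_droplet_fraction(v, v)
        assert res.frac_vehicle == pytest.approx(0.0228, abs=0.003)

    def test_lognormal_area_scaling_matches_closed_form(self):
        """Simulator defaults: log-normal areas, 1.6x scale -> >3-fold tail."""
        from scipy.stats import norm

        meanlog_r, sdlog_r, scale = math.log(2.5), 0.35, 1.6
        m = math.log(math.pi) + 2 * meanlog_r  # area log-mean
        s = 2 * sdlog_r
        mean_a = math.exp(m + s**2 / 2)
        sd_a = mean_a * math.sqrt(math.exp(s**2) - 1)
        thr = mean_a + 2 * sd_a
        frac_v = norm.sf((math.log(thr) - m) / s)
        frac_t = norm.sf((math.log(thr) - m - math.log(scale)) / s)
        assert frac_t / frac_v > 3.0  # the closed-form oracle itself

        rng = np.random.default_rng(2)
        v = math.pi * rng.lognormal(meanlog_r, sdlog_r, 60_000) ** 2
        t = math.pi * (rng.lognormal(meanlog_r, sdlog_r, 60_000) * math.sqrt(scale)) ** 2
        res = large_droplet_fraction(v, t)
        assert res.frac_vehicle == pytest.approx(frac_v, abs=0.005)
        assert res.fold_enrichment == pytest.approx(frac_t / frac_v, rel=0.1)
        assert res.fold_enrichment > 3.0

    def test_empty_vehicle_tail_flagged(self):
        res = large_droplet_fraction([1.0, 1.1, 0.9], [100.0])
        assert res.frac_vehicle == 0.0 and res.fold_enrichment is None


class TestStratification:
    def test_all_at_means_all_low(self):
        t = stratify_high_low([5.0] * 10, [2.0] * 10, (5.0, 2.0))
        assert t.pct.loc["low_a", "low_b"] == pytest.approx(100.0)

    def test_independent_symmetric_quadrants(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 20_000)
        b = rng.normal(0, 1, 20_000)
        t = stratify_high_low(a, b, (0.0, 0.0))
        assert np.allclose(t.pct.to_numpy(), 25.0, atol=1.5)

    def test_quadrants_sum_to_100(self):
        rng = np.random.default_rng(4)
        t = stratify_high_low(rng.normal(size=57), rng.normal(size=57), (0.1, -0.2))
        assert t.pct.to_numpy().sum() == pytest.approx(100.0, abs=0.1)


def _fixed_ct_table(target_shift: float) -> pd.DataFrame:
    """Noise-free Ct table with a constant normalizer."""
    rows = []
    for group, shift in (("vehicle", 0.0), ("treated", target_shift)):
        for rep in range(1, 4):
            sample = f"{group}_{rep}"
            rows.append(dict(sample=sample, group=group, gene="ACTB", replicate=rep, ct=15.0))
            rows.append(
                dict(sample=sample, group=group, gene="SREBF1", replicate=rep, ct=24.0 - shift)
            )
    return pd.DataFrame(rows)


class TestDdct:
    def test_identical_groups_fold_one(self):
        res = ddct(_fixed_ct_table(0.0))
        assert np.allclose(res.per_gene["fold"], 1.0)

    def test_exact_one_cycle_fold_two(self):
        res = ddct(_fixed_ct_table(1.0))
        assert np.allclose(res.per_gene["fold"], 2.0)

    def test_missing_normalizer_rejected(self):
        table = generate_ct_table(3, 1.0, 0.1, 7)
        broken = table[~((table["sample"] == "treated_2") & (table["gene"] == "ACTB"))]
        with pytest.raises(InvalidParameterError):
            ddct(broken)
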