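import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

import mnasemap as m
from mnasemap.calling import Nucleosome, NucleosomeMap


def _map(summits, label="m", occupancy=None, fuzziness=None):
    occupancy = occupancy or [1.0] * len(summits)
    fuzziness = fuzziness or [30.0] * len(summits)
    return NucleosomeMap(
        label,
        [Nucleosome("chrI", int(s), float(o), float(f))
         for s, o, f in zip(summits, occupancy, fuzziness)],
    )


class TestMatchNucleosomes:
    def test_identical_maps_self_match(self):
        a = _map([100, 300, 500])
        pairs, ua, ub = m.match_nucleosomes(a, _map([100, 300, 500]))
        assert len(pairs) == 3 and not ua and not ub
        assert all(p.summit_offset == 0 and p.delta_occupancy == 0 for p in pairs)

    def test_uniform_shift_reported_in_offsets(self):
        pairs, _, _ = m.match_nucleosomes(_map([100, 300, 500]),
                                          _map([130, 330, 530]))
        assert [p.summit_offset for p in pairs] == [30, 30, 30]

    def test_far_summits_stay_unmatched(self):
        pairs, ua, ub = m.match_nucleosomes(_map([100, 500]), _map([100, 400]))
        assert len(pairs) == 1
        assert [n.summit for n in ua] == [500]
        assert [n.summit for n in ub] == [400]

    def test_one_to_one_greedy_by_distance(self):
        # two a-summits compete for one b-summit: the closer one wins
        pairs, ua, _ = m.match_nucleosomes(_map([100, 160]), _map([140]))
        assert len(pairs) == 1 and pairs[0].a.summit == 160
        assert [n.summit for n in ua] == [100]

    def test_occupancy_scaling_separates_from_fuzziness(self):
        # only occupancy perturbed in the second condition: matched pairs
        # show negative mean delta-occupancy, |delta fuzziness| ~ 0
        rng = np.random.default_rng(11)
        summits = np.sort(rng.choice(np.arange(200, 50_000, 10), 150,
                                     replace=False))
        occ = rng.uniform(0.5, 2.0, 150)
        fz = rng.uniform(25, 45, 150)
        a = _map(summits, "wt", occ.tolist(), fz.tolist())
        b = _map(summits, "mut", (0.7 * occ).tolist(), fz.tolist())
        pairs, _, _ = m.match_nucleosomes(a, b)
        d_occ = np.mean([p.delta_occupancy for p in pairs])
        d_fz = np.mean(np.abs([p.delta_fuzziness for p in pairs]))
        assert d_occ < 0 and d_fz < 2.0


class TestSignedLogpCurve:
    def test_equal_inputs_give_zero(self):
        out = m.signed_logp_curve([1.0, 2.0], [1.0, 2.0])
        assert np.all(out == 0.0)

    def test_positive_difference_plots_positive(self):
        out = m.signed_logp_curve([30.0], [10.0])
        # P(X >= 30 | lambda = 10) = 2.51e-7 by direct pmf summation
        expected = -math.log10(m.poisson_sf(30, 10.0))
        assert out[0] == pytest.approx(expected)
        assert out[0] == pytest.approx(6.6, abs=0.1)

    def test_negative_difference_mirrors(self):
        out = m.signed_logp_curve([10.0], [30.0])
        assert out[0] == pytest.approx(math.log10(m.poisson_sf(30, 10.0)))

    def test_antisymmetric_under_swap(self):
        rng = np.random.default_rng(12)
        a, b = rng.uniform(0, 40, 50), rng.uniform(0, 40, 50)
        np.testing.assert_allclose(m.signed_logp_curve(a, b),
                                   -m.signed_logp_curve(b, a))

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        raw=st.lists(st.floats(0, 100), min_size=1, max_size=20),
        corrected=st.lists(st.floats(0, 100), min_size=1, max_size=20),
    )
    def test_antisymmetry_property(self, raw, corrected):
        n = min(len(raw), len(corrected))
        a, b = np.asarray(raw[:n]), np.asarray(corrected[:n])
        np.testing.assert_allclose(m.signed_logp_curve(a, b),
                                   -m.signed_logp_curve(b, a), atol=1e-12)


class TestDensity2D:
    def test_single_point_max_at_its_cell(self):
        d = m.density2d([(3.0, 7.0)])
        i, j = np.unravel_index(np.argmax(d.grid), d.grid.shape)
        # single point sits in the centre of the padded range
        assert abs(i - 50) <= 1 and abs(j - 50) <= 1
        assert d.grid.shape == (100, 100)

    def test_identical_points_superpose(self):
        one = m.density2d([(1.0, 2.0)])
        ten = m.density2d([(1.0, 2.0)] * 10)
        assert ten.grid.max() == pytest.approx(10 * one.grid.max(), abs=1e-6)

    def test_two_separated_clusters_equal_maxima(self):
        rng = np.random.default_rng(13)
        c1 = rng.normal((0, 0), 0.5, (300, 2))
        c2 = rng.normal((30, 30), 0.5, (300, 2))
        d = m.density2d(np.vstack([c1, c2]))
        half = d.grid[:50, :50].max(), d.grid[50:, 50:].max()
        assert abs(half[0] - half[1]) / max(half) < 0.05

    def test_total_mass_translation_invariant(self):
        rng = np.random.default_rng(14)
        pts = rng.normal(0, 2, (100, 2))
        d0 = m.density2d(pts)
        d1 = m.density2d(pts + 1234.5)
        assert d1.grid.sum() == pytest.approx(d0.grid.sum(), rel=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            m.density2d([])


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, p = m.pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        x = np.arange(10.0)
        r, _ = m.pearson(x, -x)
        assert r == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        r, _ = m.pearson([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8)

    def test_zero_variance_undefined(self):
        r, p = m.pearson([1, 1, 1], [1, 2, 3])
        assert math.isnan(r) and math.isnan(p)


# --- brute-force oracles for the category tests ---------------------------

def _ecdf_distance(x, y):
    allv = np.sort(np.concatenate([x, y]))
    fx = np.searchsorted(np.sort(x), allv, "right") / len(x)
    fy = np.searchsorted(np.sort(y), allv, "right") / len(y)
    return np.max(np.abs(fx - fy))


def oracle_ks(a, b):
    pooled = np.concatenate([a, b])
    d_obs = _ecdf_distance(a, b)
    cnt = tot = 0
    for comb in itertools.combinations(range(len(pooled)), len(a)):
        mask = np.zeros(len(pooled), bool)
        mask[list(comb)] = True
        if _ecdf_distance(pooled[mask], pooled[~mask]) >= d_obs - 1e-12:
            cnt += 1
        tot += 1
    return cnt / tot


def oracle_mwu(a, b):
    def u_stat(x, y):
        return sum(np.sum(xi > y) + 0.5 * np.sum(xi == y) for xi in x)

    pooled = np.concatenate([a, b])
    u_obs = u_stat(a, b)
    us = np.array([
        u_stat(pooled[list(comb)],
               pooled[[i for i in range(len(pooled)) if i not in comb]])
        for comb in itertools.combinations(range(len(pooled)), len(a))
    ])
    p_ge = np.mean(us >= u_obs - 1e-12)
    p_le = np.mean(us <= u_obs + 1e-12)
    return min(1.0, 2 * min(p_ge, p_le))


def oracle_t(a, b):
    n1, n2 = len(a), len(b)
    sp2 = ((n1 - 1) * np.var(a, ddof=1) + (n2 - 1) * np.var(b, ddof=1)) / (
        n1 + n2 - 2
    )
    t = (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    df = n1 + n2 - 2

    def pdf(x):
        return math.exp(
            math.lgamma((df + 1) / 2) - math.lgamma(df / 2)
            - 0.5 * math.log(df * math.pi)
            - (df + 1) / 2 * math.log1p(x * x / df)
        )

    tail, _ = integrate.quad(pdf, abs(t), math.inf)
    return t, 2 * tail


def oracle_hypergeom(population, successes, draws, observed):
    total = math.comb(population, draws)
    return sum(
        math.comb(successes, k) * math.comb(population - successes, draws - k)
        for k in range(observed, min(successes, draws) + 1)
    ) / total


def oracle_fisher(table):
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(k):
        return (math.comb(r1, k) * math.comb(r2, c1 - k)) / math.comb(n, c1)

    p_obs = prob(a)
    return sum(
        prob(k)
        for k in range(max(0, c1 - r2), min(r1, c1) + 1)
        if prob(k) <= p_obs * (1 + 1e-9)
    )


class TestCategoryTests:
    def test_ks_identical_samples(self):
        d, p = m.ks_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0 and p == 1.0

    def test_hypergeometric_worked_example(self):
        # population 10, 5 successes, 4 draws, observing all 4
        p = m.hypergeom_enrichment(10, 5, 4, 4)
        assert p == pytest.approx(5 / 210, abs=1e-12)

    def test_fisher_diagonal_table(self):
        _, p = m.fisher_exact_test([[5, 0], [0, 5]])
        assert p == pytest.approx(2 / 252, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            m.ks_test([], [1.0])

    @pytest.mark.parametrize("trial", range(20))
    def test_all_five_tests_match_enumeration_oracles(self, trial):
        rng = np.random.default_rng(100 + trial)
        a = rng.normal(0, 1, int(rng.integers(4, 7)))
        b = rng.normal(rng.uniform(-1, 1), 1, int(rng.integers(4, 7)))

        _, p_ks = m.ks_test(a, b)
        assert p_ks == pytest.approx(oracle_ks(a, b), abs=1e-9)

        _, p_u = m.mannwhitney_test(a, b)
        assert p_u == pytest.approx(oracle_mwu(a, b), abs=1e-9)

        t, p_t = m.t_test(a, b)
        t_o, p_o = oracle_t(a, b)
        assert t == pytest.approx(t_o, abs=1e-9)
        assert p_t == pytest.approx(p_o, abs=1e-9)

        population = int(rng.integers(8, 20))
        successes = int(rng.integers(1, population))
        draws = int(rng.integers(1, population))
        observed = int(rng.integers(0, min(successes, draws) + 1))
        assert m.hypergeom_enrichment(
            population, successes, draws, observed
        ) == pytest.approx(oracle_hypergeom(population, successes, draws,
                                            observed), abs=1e-9)

        table = rng.integers(0, 10, (2, 2))
        _, p_f = m.fisher_exact_test(table)
        assert p_f == pytest.approx(oracle_fisher(table.tolist()), abs=1e-9)

    def test_batch_report_shape(self):
        df = m.category_tests(
            {
                "fuzziness_shift": ("ks", [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]),
                "tata_enrichment": ("hypergeom", 10, 5, 4, 4),
            }
        )
        assert set(df.columns) == {"label", "test", "statistic", "p_value"}
        assert len(df) == 2
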