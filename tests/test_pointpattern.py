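import numpy as np
import pytest
from scipy import stats

from forestdiv import (
    PlotWindow,
    PointPattern,
    annulus_pair_counts,
    envelope_test,
    interspecific_associations,
    intraspecific_association,
    intraspecific_batch,
    classify_small_tree_patterns,
    pcf_bivariate,
    pcf_univariate,
    simulate_csr,
    thomas_pcf,
    toroidal_shift,
)
from forestdiv.pointpattern import InsufficientStems
from forestdiv.synthetic import simulate_thomas

from conftest import make_census

WIN = PlotWindow()


def brute_annulus_counts(xy, edges, xy2=None):
    """Exhaustive double-loop pair counting (the estimator oracle)."""
    counts = np.zeros(len(edges) - 1, dtype=int)
    if xy2 is None:
        for i in range(len(xy)):
            for j in range(i + 1, len(xy)):
                d = float(np.hypot(*(xy[i] - xy[j])))
                for b in range(len(edges) - 1):
                    if edges[b] <= d < edges[b + 1]:
                        counts[b] += 1
    else:
        for p in xy:
            for q in xy2:
                d = float(np.hypot(*(p - q)))
                for b in range(len(edges) - 1):
                    if edges[b] <= d < edges[b + 1]:
                        counts[b] += 1
    return counts


class TestPcfUnivariate:
    def test_annulus_counts_match_brute_force(self):
        rng = np.random.default_rng(11)
        edges = np.arange(0, 11.0, 1.0)
        for n in (5, 17, 30):
            xy = rng.random((n, 2)) * 100
            pat = PointPattern(xy, WIN)
            assert (annulus_pair_counts(pat, edges) ==
                    brute_annulus_counts(xy, edges)).all()

    def test_csr_pcf_is_near_one(self):
        pat = simulate_csr(500, WIN, seed=1)
        est = pcf_univariate(pat)
        sel = (est.r >= 5) & (est.r <= 20)
        assert est.g[sel].mean() == pytest.approx(1.0, abs=0.1)
        assert (est.g >= 0).all()

    def test_thomas_pcf_matches_closed_form(self):
        # kappa = 20/ha, sigma = 3 m, mu = 10 offspring/parent
        kappa, sigma = 0.002, 3.0
        r = np.array([2.0])
        g_hat = [
            pcf_univariate(simulate_thomas(kappa, sigma, 10.0, WIN, seed=100 + s),
                           r_grid=r).g[0]
            for s in range(20)
        ]
        g_true = thomas_pcf(2.0, kappa, sigma)
        assert g_true > 1
        assert abs(np.mean(g_hat) - g_true) / g_true < 0.15

    def test_requires_two_points_and_sane_rmax(self):
        with pytest.raises(ValueError):
            pcf_univariate(PointPattern(np.array([[1.0, 1.0]]), WIN))
        with pytest.raises(ValueError, match="quarter"):
            pcf_univariate(simulate_csr(50, WIN, seed=0),
                           r_grid=np.array([10.0, 30.0]))


class TestPcfBivariate:
    def test_independent_csr_cross_pcf_near_one(self):
        p1 = simulate_csr(300, WIN, seed=2)
        p2 = simulate_csr(300, WIN, seed=3)
        est = pcf_bivariate(p1, p2)
        sel = (est.r >= 5) & (est.r <= 20)
        assert est.g[sel].mean() == pytest.approx(1.0, abs=0.1)

    def test_forced_colocation_blows_up_at_small_r(self):
        p1 = simulate_csr(200, PlotWindow(100, 100), seed=4)
        shifted = np.clip(p1.points + 0.1, 0, 100)
        p2 = PointPattern(shifted, WIN)
        est = pcf_bivariate(p1, p2, r_grid=np.array([0.25, 0.5, 10.0]))
        assert est.g[0] > 10
        assert est.g[2] == pytest.approx(1.0, abs=0.3)

    def test_cross_counts_match_brute_force(self):
        rng = np.random.default_rng(5)
        xy1, xy2 = rng.random((12, 2)) * 100, rng.random((9, 2)) * 100
        edges = np.arange(0, 26.0, 2.0)
        got = annulus_pair_counts(PointPattern(xy1, WIN), edges,
                                  PointPattern(xy2, WIN))
        assert (got == brute_annulus_counts(xy1, edges, xy2)).all()

    def test_symmetry_in_arguments(self):
        p1 = simulate_thomas(0.002, 3.0, 10.0, WIN, seed=6)
        p2 = simulate_csr(150, WIN, seed=7)
        h = 1.0
        g12 = pcf_bivariate(p1, p2, bandwidth=h).g
        g21 = pcf_bivariate(p2, p1, bandwidth=h).g
        assert g12 == pytest.approx(g21, rel=1e-9)


class TestSimulateCsr:
    def test_deterministic_and_empty(self):
        assert simulate_csr(0, WIN, seed=1).n == 0
        a = simulate_csr(50, WIN, seed=42).points
        b = simulate_csr(50, WIN, seed=42).points
        assert (a == b).all()

    def test_uniform_over_subplot_grid(self):
        # chi-square GOF on the 100-cell grid, alpha = 0.01
        rejected = 0
        for seed in range(100):
            pat = simulate_csr(500, WIN, seed=seed)
            idx = WIN.subplot_index(pat.points[:, 0], pat.points[:, 1])
            obs = np.bincount(idx, minlength=WIN.n_subplots)
            p = stats.chisquare(obs).pvalue
            rejected += p < 0.01
        assert rejected <= 2


class TestEnvelope:
    def test_null_data_called_within_almost_everywhere(self):
        r = np.arange(1.0, 21.0, 1.0)
        fracs = []
        for seed in range(3):
            pat = simulate_csr(100, WIN, seed=seed)
            env = envelope_test(pat, nsim=999, k=5, r_grid=r, seed=1000 + seed)
            fracs.append((env.calls == "within").mean())
        assert np.mean(fracs) >= 0.95

    def test_band_ordering_and_call_consistency(self):
        pat = simulate_thomas(0.002, 2.0, 10.0, WIN, seed=8)
        env = envelope_test(pat, nsim=99, k=3, seed=9)
        assert (env.lower <= env.upper).all()
        above = env.observed > env.upper
        below = env.observed < env.lower
        assert ((env.calls == "above") == above).all()
        assert ((env.calls == "below") == below).all()

    def test_nsim_too_small_for_rank(self):
        with pytest.raises(ValueError):
            envelope_test(simulate_csr(20, WIN, seed=0), nsim=5, k=5)

    def test_toroidal_shift_preserves_structure(self):
        pat = simulate_thomas(0.002, 2.0, 10.0, WIN, seed=10)
        shifted = toroidal_shift(pat, np.random.default_rng(3))
        assert shifted.n == pat.n
        assert WIN.contains(shifted.points[:, 0], shifted.points[:, 1]).all()


def _two_species_census(xy_a, xy_b, dbh=5.0):
    rows = [("A", "Ga", "F1", x, y, dbh) for x, y in xy_a]
    rows += [("B", "Gb", "F2", x, y, dbh) for x, y in xy_b]
    return make_census(rows)


class TestBatchClassifiers:
    def test_low_abundance_species_excluded(self):
        rng = np.random.default_rng(0)
        census = _two_species_census(rng.random((30, 2)) * 100,
                                     rng.random((5, 2)) * 100)
        res = classify_small_tree_patterns(census, min_abundance=10,
                                           nsim=39, k=1, seed=1)
        assert res.n_analyzed == 1
        assert "B" in res.skipped

    def test_csr_community_rarely_called_clustered(self):
        rng = np.random.default_rng(1)
        rows = []
        for s in range(12):
            for x, y in rng.random((25, 2)) * 100:
                rows.append((f"S{s:02d}", f"G{s}", f"F{s}", x, y, 5.0))
        res = classify_small_tree_patterns(make_census(rows), nsim=199, k=1, seed=2)
        assert res.proportion.mean() < 0.15

    def test_clustered_community_detected_at_small_scales(self):
        rows = []
        for s in range(8):
            pat = simulate_thomas(0.0015, 2.0, 10.0, WIN, seed=50 + s)
            for x, y in pat.points:
                rows.append((f"S{s:02d}", f"G{s}", f"F{s}", x, y, 5.0))
        res = classify_small_tree_patterns(make_census(rows), nsim=199, k=1, seed=3)
        small_bin = res.proportion[1]  # 2.5-5 m
        large_bin = res.proportion[4]  # 15-20 m
        assert small_bin >= 0.75
        assert large_bin < small_bin

    def test_pair_denominator_is_n_choose_2(self, synthetic_census):
        census, _, _ = synthetic_census
        ab = census.abundances()
        thr = int(np.sort(ab)[-4])  # ensures >= 4 qualifying species
        res = interspecific_associations(census, min_abundance=thr,
                                         nsim=39, k=1, seed=4)
        n_dom = int((ab >= thr).sum())
        assert res.n_analyzed == n_dom * (n_dom - 1) // 2

    def test_segregated_halves_called_negative(self):
        rng = np.random.default_rng(2)
        a = rng.random((60, 2)) * [50, 100]
        b = rng.random((60, 2)) * [50, 100] + [50, 0]
        census = _two_species_census(a, b)
        res = interspecific_associations(census, min_abundance=10,
                                         nsim=199, k=1, seed=5)
        assert res.detail[("A", "B")].any()

    def test_independent_csr_pair_near_nominal(self):
        rng = np.random.default_rng(3)
        negs = []
        for rep in range(20):
            census = _two_species_census(rng.random((80, 2)) * 100,
                                         rng.random((80, 2)) * 100)
            res = interspecific_associations(census, min_abundance=10,
                                             nsim=199, k=1, seed=600 + rep)
            negs.append(res.detail[("A", "B")])
        # per-bin false-negative-association rate stays near the 0.5% one-sided level
        assert np.mean(negs) < 0.08


class TestIntraspecific:
    def _census_large_small(self, small_xy, large_xy):
        rows = [("A", "G", "F", x, y, 5.0) for x, y in small_xy]
        rows += [("A", "G", "F", x, y, 30.0) for x, y in large_xy]
        return make_census(rows)

    def test_recruits_clustered_on_adults_called_positive(self):
        rng = np.random.default_rng(4)
        adults = rng.random((15, 2)) * 80 + 10
        recruits = np.repeat(adults, 8, axis=0) + rng.normal(0, 2.0, (120, 2))
        recruits = recruits[(recruits >= 0).all(1) & (recruits <= 100).all(1)]
        census = self._census_large_small(recruits, adults)
        env = intraspecific_association(census, "A", nsim=199, k=1,
                                        r_grid=np.arange(0.5, 10.5, 0.5), seed=6)
        assert (env.calls[env.r <= 5] == "above").any()

    def test_independent_recruits_mostly_within(self):
        rng = np.random.default_rng(5)
        census = self._census_large_small(rng.random((100, 2)) * 100,
                                          rng.random((12, 2)) * 100)
        env = intraspecific_association(census, "A", nsim=199, k=1, seed=7)
        assert (env.calls == "within").mean() > 0.8

    def test_species_without_large_trees_skipped_in_batch(self):
        rng = np.random.default_rng(6)
        census = self._census_large_small(rng.random((30, 2)) * 100, [])
        with pytest.raises(InsufficientStems):
            intraspecific_association(census, "A")
        results, skipped = intraspecific_batch(census, nsim=39, k=1, seed=8)
        assert results == {} and "A" in skipped
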