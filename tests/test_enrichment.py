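import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import wallenius_enumerate
from lenrich.de_testing import call_de
from lenrich.enrichment import (
    ContingencyCounts,
    category_odds,
    hypergeometric_pvalues,
    sampling_pvalues,
    wallenius_pvalues,
)
from lenrich.enrichment import test_categories as run_category_tests
from lenrich.errors import ConfigurationError, ValidationError
from lenrich.pwf import fit_pwf
from lenrich.synthetic import SimulationConfig, generate_dataset


class TestContingencyCounts:
    def test_valid(self):
        ContingencyCounts(N=10, K=5, n=5, k=3)

    @pytest.mark.parametrize(
        "N,K,n,k",
        [(10, 11, 5, 3), (10, 5, 11, 3), (10, 5, 5, 6), (10, 9, 9, 7)],
    )
    def test_invalid(self, N, K, n, k):
        with pytest.raises(ValidationError):
            ContingencyCounts(N=N, K=K, n=n, k=k)


class TestHypergeometric:
    def test_all_overlap(self):
        p_over, _ = hypergeometric_pvalues(ContingencyCounts(10, 5, 5, 5))
        assert p_over == pytest.approx(1 / 252, rel=1e-12)

    def test_half_tail(self):
        p_over, _ = hypergeometric_pvalues(ContingencyCounts(10, 5, 5, 3))
        assert p_over == pytest.approx(0.5, rel=1e-12)

    def test_k_zero_whole_support(self):
        p_over, _ = hypergeometric_pvalues(ContingencyCounts(50, 10, 20, 0))
        assert p_over == 1.0

    @given(
        N=st.integers(2, 40),
        data=st.data(),
    )
    @settings(max_examples=60, deadline=None)
    def test_tails_share_observed_point(self, N, data):
        K = data.draw(st.integers(1, N - 1))
        n = data.draw(st.integers(1, N - 1))
        k = data.draw(st.integers(max(0, K + n - N), min(K, n)))
        p_over, p_under = hypergeometric_pvalues(ContingencyCounts(N, K, n, k))
        assert p_over + p_under >= 1.0 - 1e-12


class TestCategoryOdds:
    def test_stated_formula(self):
        assert category_odds([0.2, 0.4], [0.1, 0.1, 0.1]) == pytest.approx(3.0)

    def test_equal_weights_unity(self):
        assert category_odds([0.3, 0.3], [0.3] * 5) == pytest.approx(1.0)

    def test_empty_complement_rejected(self):
        with pytest.raises(ValidationError):
            category_odds([0.2], [])

    def test_out_of_range_weight_rejected(self):
        with pytest.raises(ValidationError):
            category_odds([0.0], [0.1])


class TestWallenius:
    def test_central_reduction(self):
        c = ContingencyCounts(100, 20, 30, 9)
        assert wallenius_pvalues(c, 1.0) == hypergeometric_pvalues(c)

    def test_five_gene_urn(self):
        # exhaustive enumeration: P(X=2) = (4/7)*(2/5) ... = 8/35
        p_over, _ = wallenius_pvalues(ContingencyCounts(5, 2, 2, 2), 2.0)
        assert p_over == pytest.approx(8 / 35, abs=1e-9)

    def test_k_zero_whole_support(self):
        p_over, _ = wallenius_pvalues(ContingencyCounts(5, 2, 2, 0), 2.0)
        assert p_over == 1.0

    def test_bad_odds_rejected(self):
        with pytest.raises(ValidationError):
            wallenius_pvalues(ContingencyCounts(5, 2, 2, 1), 0.0)

    @pytest.mark.parametrize("omega", [0.25, 1.0, 4.0])
    @pytest.mark.parametrize("N", [4, 6, 8])
    def test_oracle_equivalence_small_urns(self, N, omega):
        for K in range(1, N):
            for n in range(1, N + 1):
                pmf = wallenius_enumerate(N, K, n, omega)
                for k in range(max(0, K + n - N), min(K, n) + 1):
                    p_over, p_under = wallenius_pvalues(
                        ContingencyCounts(N, K, n, k), omega
                    )
                    assert p_over == pytest.approx(pmf[k:].sum(), abs=1e-6)
                    assert p_under == pytest.approx(pmf[: k + 1].sum(), abs=1e-6)

    def test_degenerate_category_equals_universe(self):
        p_over, p_under = wallenius_pvalues(ContingencyCounts(5, 5, 3, 3), 2.0)
        assert p_over == 1.0 and p_under == 1.0


class TestSampling:
    def test_uniform_weights_match_hypergeometric(self):
        from scipy.stats import hypergeom

        N, K, n_de, k = 50, 10, 10, 5
        members = np.zeros(N, dtype=bool)
        members[:K] = True
        reps = 20_000
        p_over, _, _ = sampling_pvalues(
            np.full(N, 0.5), members, n_de, k, reps=reps, seed=9
        )
        truth = hypergeom.sf(k - 1, N, K, n_de)
        se = np.sqrt(truth * (1 - truth) / reps)
        assert abs(p_over - truth) < 3 * se

    def test_estimator_floor(self):
        members = np.zeros(20, dtype=bool)
        members[:3] = True
        reps = 50
        p_over, _, _ = sampling_pvalues(
            np.full(20, 0.1), members, 4, 4, reps=reps, seed=1
        )
        assert p_over >= 1 / (reps + 1)

    def test_impossible_k_gives_floor(self):
        members = np.zeros(10, dtype=bool)
        members[0] = True
        reps = 100
        p_over, _, _ = sampling_pvalues(
            np.full(10, 0.2), members, 2, 2, reps=reps, seed=3
        )
        assert p_over == pytest.approx(1 / (reps + 1))

    def test_seed_determinism(self):
        members = np.zeros(30, dtype=bool)
        members[:8] = True
        w = np.linspace(0.05, 0.5, 30)
        a = sampling_pvalues(w, members, 6, 3, reps=500, seed=42)
        b = sampling_pvalues(w, members, 6, 3, reps=500, seed=42)
        assert a[0] == b[0] and a[1] == b[1]
        np.testing.assert_array_equal(a[2], b[2])

    def test_zero_weight_rejected(self):
        members = np.zeros(5, dtype=bool)
        members[0] = True
        with pytest.raises(ValidationError):
            sampling_pvalues(np.array([0.0, 0.1, 0.1, 0.1, 0.1]), members, 2, 1)

    def test_n_de_bounds_rejected(self):
        members = np.zeros(5, dtype=bool)
        with pytest.raises(ValidationError):
            sampling_pvalues(np.full(5, 0.1), members, 5, 1)

    def test_matches_wallenius_law(self):
        # the exponential-race draw follows Wallenius' distribution: compare
        # replicate counts on a tiny urn against the enumeration oracle
        N, K, n_de, omega = 6, 2, 3, 4.0
        members = np.zeros(N, dtype=bool)
        members[:K] = True
        w = np.where(members, 0.4 * omega, 0.4)
        reps = 40_000
        _, _, hist = sampling_pvalues(w, members, n_de, 1, reps=reps, seed=5)
        emp = hist / reps
        pmf = wallenius_enumerate(N, K, n_de, omega)
        np.testing.assert_allclose(emp[: pmf.size], pmf, atol=0.01)


@pytest.fixture(scope="module")
def dataset():
    cfg = SimulationConfig(
        n_genes=1500,
        n_categories=40,
        de_fraction=0.1,
        fold_change=5.0,
        lib_sizes=(400_000, 400_000),
        seed=21,
    )
    table, cmap, _truth = generate_dataset(cfg)
    call_de(table, fdr_threshold=1e-4)
    pwf = fit_pwf(table.lengths, table.frame["de_flag"].to_numpy())
    table.frame["pwf_weight"] = pwf.evaluate(table.lengths)
    return table, cmap


class TestTestCategories:
    def test_equal_weights_reduce_to_hypergeometric(self, dataset):
        table, cmap = dataset
        table = table.restrict(table.gene_ids)  # copy
        call_de(table, fdr_threshold=1e-4)
        table.frame["pwf_weight"] = 0.25
        rw = run_category_tests(table, cmap, method="wallenius")
        rh = run_category_tests(table, cmap, method="hypergeometric")
        byh = {r.category_id: r for r in rh}
        for r in rw:
            assert r.p_over == pytest.approx(byh[r.category_id].p_over, abs=1e-9)
            assert r.p_under == pytest.approx(byh[r.category_id].p_under, abs=1e-9)

    def test_one_result_per_category(self, dataset):
        table, cmap = dataset
        res = run_category_tests(table, cmap, method="wallenius")
        assert len(res) == cmap.n_categories
        assert {r.category_id for r in res} == set(cmap.categories)

    def test_ranking_and_fdr(self, dataset):
        table, cmap = dataset
        res = run_category_tests(table, cmap, method="wallenius")
        ps = [r.p_over for r in res]
        assert ps == sorted(ps)
        assert [r.rank for r in res] == list(range(1, len(res) + 1))
        assert all(r.fdr_over >= r.p_over - 1e-15 for r in res)

    def test_sampling_determinism(self, dataset):
        table, cmap = dataset
        a = run_category_tests(table, cmap, method="sampling", reps=400, seed=5)
        b = run_category_tests(table, cmap, method="sampling", reps=400, seed=5)
        assert [(r.category_id, r.p_over) for r in a] == [
            (r.category_id, r.p_over) for r in b
        ]

    def test_missing_weights_configuration_error(self, dataset):
        table, cmap = dataset
        bare = table.restrict(table.gene_ids)
        bare.frame.drop(columns=["pwf_weight"], inplace=True)
        call_de(bare, fdr_threshold=1e-4)
        with pytest.raises(ConfigurationError):
            run_category_tests(bare, cmap, method="wallenius")

    def test_missing_flags_configuration_error(self, dataset):
        table, cmap = dataset
        bare = table.restrict(table.gene_ids)
        bare.frame.drop(
            columns=[c for c in ("de_pvalue", "de_qvalue", "de_flag") if c in bare.frame],
            inplace=True,
        )
        with pytest.raises(ConfigurationError):
            run_category_tests(bare, cmap, method="hypergeometric")

    def test_planted_enrichment_ranks_first_all_methods(self):
        cfg = SimulationConfig(
            n_genes=2000,
            n_categories=50,
            de_fraction=0.1,
            fold_change=5.0,
            length_bias_strength=0.5,
            category_size_range=(20, 150),
            enriched_categories={"C00010": 10.0},
            lib_sizes=(500_000, 500_000),
            seed=77,
        )
        table, cmap, _ = generate_dataset(cfg)
        call_de(table, fdr_threshold=1e-4)
        pwf = fit_pwf(table.lengths, table.frame["de_flag"].to_numpy())
        table.frame["pwf_weight"] = pwf.evaluate(table.lengths)
        for method in ("hypergeometric", "wallenius", "sampling"):
            res = run_category_tests(table, cmap, method=method, reps=2000, seed=1)
            assert res[0].category_id == "C00010", method
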