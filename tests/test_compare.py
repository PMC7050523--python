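"""Region counting, NB exact test, dispersion estimation and BH correction."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tnxpress.compare import (
    RegionCountTable,
    bh_adjust,
    compare_condition,
    count_regions,
    estimate_dispersion,
    log_cpm,
    nb_exact_test,
)
from tnxpress.formats import GeneModel, InsertionProfile


def single_site_profile(pos, fwd=0, rev=0, length=1000):
    f = np.zeros(length, dtype=int)
    r = np.zeros(length, dtype=int)
    f[pos] = fwd
    r[pos] = rev
    return InsertionProfile("x", f, r)


class TestCountRegions:
    def test_site_before_plus_gene_lands_in_upstream_forward(self):
        prof = single_site_profile(50, fwd=3)
        gene = GeneModel("g", "g", 100, 400, "+")
        df = count_regions(prof, [gene])
        assert df.loc[("g", "upstream", "forward"), "reads"] == 3
        assert df.loc[("g", "upstream", "forward"), "sites"] == 1
        assert df.loc[("g", "gene", "combined"), "reads"] == 0
        assert df.loc[("g", "downstream", "combined"), "reads"] == 0

    def test_strand_flip_moves_site_to_downstream(self):
        prof = single_site_profile(50, fwd=3)
        gene = GeneModel("g", "g", 100, 400, "-")
        df = count_regions(prof, [gene])
        assert df.loc[("g", "downstream", "forward"), "reads"] == 3
        assert df.loc[("g", "upstream", "forward"), "reads"] == 0

    def test_window_clamped_at_replicon_start(self):
        prof = single_site_profile(5, rev=2)
        gene = GeneModel("g", "g", 20, 300, "+")
        df = count_regions(prof, [gene])  # upstream window is [0, 20)
        assert df.loc[("g", "upstream", "reverse"), "reads"] == 2
        far = single_site_profile(700, rev=2)
        assert count_regions(far, [gene]).loc[("g", "upstream", "reverse"), "reads"] == 0

    def test_combined_is_sum_of_channels(self, screen):
        df = count_regions(screen.control, screen.genes)
        wide = df["reads"].unstack("channel")
        np.testing.assert_array_equal(wide["combined"], wide["forward"] + wide["reverse"])

    def test_nonpositive_window_rejected(self):
        with pytest.raises(ValueError):
            count_regions(single_site_profile(0), [GeneModel("g", "g", 0, 10, "+")], window=0)


class TestLogCpm:
    def test_closed_form_values(self):
        assert log_cpm(256, 10**6, prior=0.0) == pytest.approx(8.0)
        # prior also damps the library size, so the value sits within
        # ~1e-6 relative of log2(0.5 CPM)
        assert log_cpm(0, 10**6, prior=0.5) == pytest.approx(np.log2(0.5), abs=1e-4)

    def test_scale_invariance_for_large_counts(self):
        a = log_cpm(10_000, 10**6)
        b = log_cpm(20_000, 2 * 10**6)
        assert abs(a - b) < 1e-4

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            log_cpm(1, 0)


def enumeration_oracle(a: int, b: int, phi: float) -> float:
    """Independent brute-force conditional exact test via scipy distributions."""
    t = a + b
    if t == 0:
        return 1.0
    x = np.arange(t + 1)
    mu = t / 2
    if phi == 0:
        pmf = stats.poisson.pmf(x, mu) * stats.poisson.pmf(t - x, mu)
    else:
        r = 1.0 / phi
        p = r / (r + mu)
        pmf = stats.nbinom.pmf(x, r, p) * stats.nbinom.pmf(t - x, r, p)
    pmf = pmf / pmf.sum()
    return float(pmf[pmf <= pmf[a] * (1 + 1e-8)].sum())


class TestNbExactTest:
    def test_empty_total_gives_p_one(self):
        assert nb_exact_test(0, 0, 0.5) == 1.0

    def test_poisson_limit_equals_conditional_binomial(self):
        # (10, 0) under phi=0: two-sided conditional Binomial(10, 1/2)
        assert nb_exact_test(10, 0, 0.0) == pytest.approx(2 * 0.5**10, abs=1e-12)
        assert nb_exact_test(10, 0, 0.0) == pytest.approx(0.001953125, abs=1e-12)

    @pytest.mark.parametrize("a,b", [(3, 9), (0, 7), (12, 12), (25, 10), (1, 0)])
    def test_poisson_limit_matches_scipy_binomtest(self, a, b):
        expected = stats.binomtest(a, a + b, 0.5).pvalue
        assert nb_exact_test(a, b, 0.0) == pytest.approx(expected, rel=1e-9)

    def test_modal_split_gives_p_one(self):
        assert nb_exact_test(5, 5, 0.0) == 1.0

    @pytest.mark.parametrize("phi", [0.0, 0.05, 0.2, 1.0])
    @pytest.mark.parametrize("t", [1, 2, 7, 30, 101, 200])
    def test_matches_enumeration_oracle(self, phi, t):
        for a in range(t + 1):
            assert nb_exact_test(a, t - a, phi) == pytest.approx(
                enumeration_oracle(a, t - a, phi), abs=1e-10
            )

    def test_symmetric_in_groups(self):
        assert nb_exact_test(17, 4, 0.3) == nb_exact_test(4, 17, 0.3)

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            nb_exact_test(1, 2, -0.1)


def _table_from_counts(counts: np.ndarray) -> RegionCountTable:
    rows, n = counts.shape
    idx = pd.MultiIndex.from_tuples(
        [(f"g{i}", "gene", "combined") for i in range(rows)],
        names=["gene_id", "region", "channel"],
    )
    reads = pd.DataFrame(counts, index=idx, columns=[f"s{j}" for j in range(n)])
    libs = {f"s{j}": int(reads[f"s{j}"].sum()) for j in range(n)}
    return RegionCountTable(reads=reads, sites=reads.copy(), library_sizes=libs)


class TestEstimateDispersion:
    @pytest.mark.parametrize("phi_true,tol", [(0.0, 0.01), (0.2, 0.05)])
    def test_recovers_known_dispersion(self, phi_true, tol):
        rng = np.random.default_rng(42)
        mu = 100
        if phi_true == 0:
            counts = rng.poisson(mu, size=(2000, 4))
        else:
            r = 1 / phi_true
            counts = rng.negative_binomial(r, r / (r + mu), size=(2000, 4))
        table = _table_from_counts(counts)
        est = estimate_dispersion(table, ["s0", "s1"], ["s2", "s3"])
        assert est == pytest.approx(phi_true, abs=tol)

    def test_unreplicated_groups_fall_back_to_default_with_warning(self):
        table = _table_from_counts(np.array([[10, 12]]))
        with pytest.warns(UserWarning, match="falling back"):
            est = estimate_dispersion(table, ["s0"], ["s1"], default=0.1)
        assert est == 0.1


class TestBhAdjust:
    def test_step_up_formula_by_hand(self):
        q = bh_adjust(np.array([0.01, 0.02, 0.04]))
        np.testing.assert_allclose(q, [0.03, 0.03, 0.04], atol=1e-15)

    def test_single_p_and_ties(self):
        assert bh_adjust(np.array([0.3]))[0] == 0.3
        np.testing.assert_allclose(bh_adjust(np.full(5, 0.2)), np.full(5, 0.2))

    def test_matches_statsmodels_and_dominates_p(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        for _ in range(20):
            p = rng.uniform(1e-8, 1.0, size=rng.integers(1, 200))
            q = bh_adjust(p)
            _, q_ref, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(q, q_ref, atol=1e-12)
            assert (q >= p).all()

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=60), st.randoms())
    def test_permutation_equivariance(self, p_list, rnd):
        p = np.array(p_list)
        perm = np.arange(p.size)
        rnd.shuffle(perm)
        q = bh_adjust(p)
        q_perm = bh_adjust(p[perm])
        np.testing.assert_allclose(q_perm, q[perm], atol=1e-15)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.0, 0.5]))
        with pytest.raises(ValueError):
            bh_adjust(np.array([1.1]))


class TestCompareCondition:
    def test_swapping_groups_negates_logfc_and_preserves_p(self, screen):
        fwd = compare_condition(
            screen.table, ["control_1", "control_2"], ["treated_1", "treated_2"]
        )
        rev = compare_condition(
            screen.table, ["treated_1", "treated_2"], ["control_1", "control_2"]
        )
        np.testing.assert_allclose(rev["logFC"], -fwd["logFC"], atol=1e-12)
        np.testing.assert_allclose(rev["p_value"], fwd["p_value"], atol=1e-12)

    def test_deterministic_given_inputs(self, screen):
        a = compare_condition(screen.table, ["control_1", "control_2"], ["null_1", "null_2"])
        pd.testing.assert_frame_equal(a, screen.records_null)

    def test_null_condition_significant_fraction_below_alpha(self, screen):
        assert screen.records_null["significant"].mean() <= 0.05

    def test_designed_knockouts_enriched_in_gene_row(self, screen):
        rec = screen.records_treated
        hits = 0
        for gid in screen.ko_genes:
            row = rec[
                (rec["gene_id"] == gid) & (rec["region"] == "gene") & (rec["channel"] == "combined")
            ].iloc[0]
            if row["significant"] and row["direction"] == "enriched":
                hits += 1
        assert hits >= len(screen.ko_genes) - 2

    def test_zero_library_size_rejected(self):
        counts = np.array([[0, 0], [0, 0]])
        table = _table_from_counts(counts)
        with pytest.raises(ValueError, match="library size"):
            compare_condition(table, ["s0"], ["s1"])
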