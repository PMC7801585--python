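"""Expression classification, specialization and enrichment statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from venomlgt.expression_class import (
    bh_fdr,
    bonferroni,
    classify_expressed,
    classify_high,
    exclusive_concurrence,
    hypergeom_tail,
    n99_threshold,
    specialization_index,
    specific_gene_enrichment,
)
from venomlgt.formats_io import ExpressionMatrix


def _matrix(values, genes=None, samples=None, vg="VG"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or ([f"s{i}" for i in range(values.shape[1] - 1)] + [vg])
    meta = {s: "stage" for s in samples}
    meta[samples[-1]] = "venom_gland"
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples),
                            meta)


class TestN99:
    def test_cumulative_hand_example(self):
        # sorted desc: 97, 1, 1, 1; cumsums 97, 98, 99 -> third gene, TPM 1
        assert n99_threshold([97, 1, 1, 1]) == 1.0

    def test_single_gene(self):
        assert n99_threshold([100]) == 100.0

    def test_permutation_invariance(self):
        assert n99_threshold([1, 97, 1, 1]) == n99_threshold([97, 1, 1, 1])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            n99_threshold([0, 0, 0])

    def test_percentile_mode(self):
        vals = list(range(1, 101))
        assert n99_threshold(vals, mode="percentile") == pytest.approx(
            np.percentile(vals, 99))


class TestClassifyExpressed:
    def test_strictly_above_threshold(self):
        m = _matrix([[97], [1], [1], [1]], samples=["VG"])
        calls = classify_expressed(m)
        assert calls.expressed["VG"] == {"g0"}

    def test_uniform_vector_gives_empty(self):
        m = _matrix([[1], [1], [1], [1]], samples=["VG"])
        calls = classify_expressed(m)
        assert calls.thresholds["VG"] == 1.0
        assert calls.expressed["VG"] == set()

    def test_zero_gene_does_not_change_calls(self):
        m1 = _matrix([[97], [1], [1], [1]], samples=["VG"])
        m2 = _matrix([[97], [1], [1], [1], [0]], samples=["VG"])
        assert (classify_expressed(m1).expressed["VG"]
                == classify_expressed(m2).expressed["VG"])


class TestClassifyHigh:
    def _big_matrix(self, seed=0, n=200):
        rng = np.random.default_rng(seed)
        vals = rng.lognormal(2.0, 1.5, size=(n, 2))
        return _matrix(vals, samples=["s1", "VG"])

    def test_gene_at_mean_not_high(self):
        # expressed genes with one clear outlier; a gene at the log-mean of
        # the expressed population has upper-tail p = 0.5
        m = self._big_matrix()
        calls = classify_high(m)
        for s in ("s1", "VG"):
            expr = sorted(calls.expressed[s])
            logv = np.log2(m.values.loc[expr, s] + 1)
            mean = logv.mean()
            nearest = (logv - mean).abs().idxmin()
            assert nearest not in calls.high[s]

    def test_high_set_within_expressed(self):
        calls = classify_high(self._big_matrix())
        for s, hi in calls.high.items():
            assert hi <= calls.expressed[s]

    def test_alpha_monotonicity(self):
        m = self._big_matrix()
        strict = classify_high(m, alpha_stage=0.001, alpha_vg=0.001)
        loose = classify_high(m, alpha_stage=0.05, alpha_vg=0.05)
        for s in strict.high:
            assert strict.high[s] <= loose.high[s]

    def test_vg_uses_looser_alpha(self):
        m = self._big_matrix()
        calls = classify_high(m)
        assert calls.alpha["VG"] == 0.05 and calls.alpha["s1"] == 0.01

    def test_upper_tail_calibration(self):
        # the count of highly expressed genes should be near alpha * n
        # for normal log-TPM (z-test calibration)
        rng = np.random.default_rng(1)
        vals = np.exp2(rng.normal(8, 2, size=(4000, 2))) - 1
        m = _matrix(vals, samples=["s1", "VG"])
        calls = classify_high(m, alpha_stage=0.05, alpha_vg=0.05)
        n_expr = len(calls.expressed["s1"])
        frac = len(calls.high["s1"]) / n_expr
        assert 0.02 < frac < 0.09


class TestSpecialization:
    def test_target_only_gives_one(self):
        m = _matrix([[0, 0, 10]], samples=["s1", "s2", "VG"])
        prof = specialization_index(m, "VG")
        assert prof.index["g0"] == 1.0

    def test_uniform_over_ten_samples(self):
        m = _matrix([[5] * 10],
                    samples=[f"s{i}" for i in range(9)] + ["VG"])
        assert specialization_index(m, "VG").index["g0"] == pytest.approx(0.1)

    def test_zero_row_defined_as_zero(self):
        m = _matrix([[0, 0], [1, 1]], samples=["s1", "VG"])
        assert specialization_index(m, "VG").index["g0"] == 0.0

    def test_tau_mode_bounds(self):
        m = _matrix([[0, 0, 10], [3, 3, 3], [1, 0, 9]],
                    samples=["s1", "s2", "VG"])
        prof = specialization_index(m, "VG", mode="tau")
        assert prof.index["g0"] == pytest.approx(1.0)
        assert prof.index["g1"] == pytest.approx(0.0)
        assert 0.0 <= prof.index["g2"] <= 1.0


class TestExclusiveConcurrence:
    def _calls(self):
        rows = [[100, 100, 1, 1],
                [100, 100, 100, 1],
                [1, 1, 1, 1]] + [[1, 1, 1, 1]] * 20  # low background
        m = _matrix(rows, samples=["P3", "AF", "L1", "VG"])
        return classify_expressed(m)

    def test_exact_subset_true(self):
        conc = exclusive_concurrence(self._calls(), {"P3", "AF"},
                                     ["P3", "AF", "L1"])
        assert conc["g0"] is True

    def test_superset_false(self):
        conc = exclusive_concurrence(self._calls(), {"P3", "AF"},
                                     ["P3", "AF", "L1"])
        assert conc["g1"] is False

    def test_unexpressed_gene_false(self):
        conc = exclusive_concurrence(self._calls(), {"P3", "AF"},
                                     ["P3", "AF", "L1"])
        assert conc.get("g2", False) is False

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            exclusive_concurrence(self._calls(), set(), ["P3", "AF"])


def brute_force_hypergeom(N, K, n, k, tail):
    """Oracle: enumerate all C(N, n) draws from a labeled population."""
    pop = [1] * K + [0] * (N - K)
    total = hits = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        x = sum(pop[i] for i in draw)
        if (tail == "upper" and x >= k) or (tail == "lower" and x <= k):
            hits += 1
    return hits / total if total else 1.0


class TestHypergeom:
    def test_enumerated_example(self):
        # N=4, K=2, n=2: draws with both successes = 1 of C(4,2)=6
        assert hypergeom_tail(4, 2, 2, 2, "upper") == pytest.approx(1 / 6)

    def test_k_zero_upper_is_one(self):
        assert hypergeom_tail(50, 10, 5, 0, "upper") == 1.0

    def test_tail_identity(self):
        N, K, n, k = 20, 8, 6, 3
        pmf = (hypergeom_tail(N, K, n, k, "upper")
               + hypergeom_tail(N, K, n, k, "lower") - 1.0)
        from scipy.stats import hypergeom as hg
        assert pmf == pytest.approx(hg.pmf(k, N, K, n))

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            hypergeom_tail(4, 5, 2, 1)
        with pytest.raises(ValueError):
            hypergeom_tail(4, 2, 2, 3)

    @given(st.integers(2, 9), st.data())
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_matches_enumeration(self, N, data):
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        k = data.draw(st.integers(max(0, n - (N - K)), min(K, n)))
        tail = data.draw(st.sampled_from(["upper", "lower"]))
        assert hypergeom_tail(N, K, n, k, tail) == pytest.approx(
            brute_force_hypergeom(N, K, n, k, tail), abs=1e-12)


class TestCorrections:
    def test_bonferroni_scales(self):
        assert bonferroni([0.001] + [1.0] * 9)[0] == pytest.approx(0.01)

    def test_single_p_unchanged(self):
        assert bonferroni([0.3]) == [pytest.approx(0.3)]
        assert bh_fdr([0.3]) == [pytest.approx(0.3)]

    def test_bh_step_up_by_hand(self):
        # 0.01*3/1=0.03, 0.02*3/2=0.03, 0.03*3/3=0.03
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03] * 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([1.2])
        with pytest.raises(ValueError):
            bh_fdr([-0.1])

    def test_adjusted_at_least_raw(self):
        p = [0.2, 0.01, 0.6, 0.03]
        assert all(a >= r for a, r in zip(bonferroni(p), p))
        assert all(a >= r for a, r in zip(bh_fdr(p), p))


class TestEnrichment:
    def _calls_with(self, high):
        from venomlgt.expression_class import ExpressionCalls
        return ExpressionCalls(thresholds={"s": 1.0},
                               expressed={"s": set(high) | {"gx"}},
                               high={"s": set(high)})

    def test_no_high_genes_p_one(self):
        universe = [f"g{i}" for i in range(100)]
        res = specific_gene_enrichment(self._calls_with([]), universe[:10],
                                       universe)
        assert res.table.loc["s", "p"] == 1.0

    def test_delegates_to_hypergeom(self):
        universe = [f"g{i}" for i in range(20)]
        high = universe[:4]       # all high genes specific
        res = specific_gene_enrichment(self._calls_with(high), universe[:5],
                                       universe)
        row = res.table.loc["s"]
        assert row["p"] == pytest.approx(hypergeom_tail(20, 5, 4, 4, "upper"))

    def test_planted_overrepresentation_significant(self):
        # K/N = 0.1, k/n = 0.5 at n = 50, N = 1000
        universe = [f"g{i}" for i in range(1000)]
        spec = universe[:100]
        high = universe[:25] + universe[100:125]
        res = specific_gene_enrichment(self._calls_with(high), spec, universe)
        assert res.table.loc["s", "p_bonferroni"] < 0.005
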