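"""Rate estimation (NG86, K2P), saturation filter, pathway scan,
percentile ranks and macro-synteny calling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from venomlgt import _codon
from venomlgt.formats_io import GeneOrderMap, OrthologTable
from venomlgt.molevol import (
    CodonPairAlignment,
    RateEstimate,
    call_macro_synteny,
    filter_saturated,
    k2p,
    ng86,
    pathway_scan,
    percentile_rank,
)
from venomlgt.synthetic_data import simulate_cds


class TestCodonPairAlignment:
    def test_rejects_unequal_lengths(self):
        with pytest.raises(ValueError, match="unequal"):
            CodonPairAlignment("ATGAAA", "ATG")

    def test_rejects_internal_stop(self):
        with pytest.raises(ValueError, match="stop"):
            CodonPairAlignment("ATGTAA", "ATGAAA")

    def test_rejects_gaps(self):
        with pytest.raises(ValueError, match="gap"):
            CodonPairAlignment("ATG-AA", "ATGCAA")


def brute_site_fractions(codon):
    """Oracle: classify all 9 single-nucleotide changes directly."""
    out = []
    for pos in range(3):
        syn = non = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if _codon.is_stop(alt):
                continue
            if _codon.translate(alt) == _codon.translate(codon):
                syn += 1
            else:
                non += 1
        out.append(syn / (syn + non) if (syn + non) else 0.0)
    return tuple(out)


class TestNg86:
    def test_identical_sequences(self):
        est = ng86(CodonPairAlignment("ATGAAA", "ATGAAA"))
        assert est.Sd == est.Nd == 0
        assert est.dS == est.dN == 0.0
        assert est.ds_zero

    def test_synonymous_third_position(self):
        # Phe TTT -> Phe TTC
        est = ng86(CodonPairAlignment("ATGTTT", "ATGTTC"))
        assert est.Nd == 0 and est.Sd == 1
        assert est.dN == 0.0 and est.dS > 0
        assert est.omega == 0.0

    def test_nonsynonymous_third_position(self):
        # Phe TTT -> Leu TTA: nonsynonymous despite position 3
        est = ng86(CodonPairAlignment("ATGTTT", "ATGTTA"))
        assert est.Sd == 0 and est.Nd == 1
        assert est.dN > 0 and est.ds_zero
        assert math.isnan(est.omega)

    def test_site_fractions_match_enumeration(self):
        for codon in _codon.SENSE_CODONS:
            assert _codon.codon_site_fractions(codon) == pytest.approx(
                brute_site_fractions(codon))

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_sites_sum_to_length(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 40))
        a = simulate_cds(n, 0.4, rng)
        b = simulate_cds(n, 0.4, rng)
        est = ng86(CodonPairAlignment(a, b))
        assert est.S + est.N == pytest.approx(3 * n)

    def test_path_counts_avoid_stops(self):
        # TGT (Cys) <-> TGC via 1 change; TAT <-> TGG must average over
        # orderings that avoid TAG/TGA stops
        sd, nd = _codon.codon_path_counts("TAT", "TGG")
        assert sd + nd == pytest.approx(2.0)

    def test_saturation_sentinel(self):
        # maximally divergent short pair drives p toward/above 3/4
        est = ng86(CodonPairAlignment("ATGCGT", "ATGGCA"))
        assert est.dN >= 0 or math.isinf(est.dN)


class TestK2p:
    def test_identical_zero(self):
        assert k2p("ACGTACGT", "ACGTACGT") == 0.0

    def test_closed_form_example(self):
        # 100 sites: 10 transitions, 5 transversions -> P=0.1, Q=0.05
        a = "A" * 100
        b = "G" * 10 + "C" * 5 + "A" * 85
        expected = -0.5 * math.log(1 - 0.2 - 0.05) - 0.25 * math.log(1 - 0.1)
        assert k2p(a, b) == pytest.approx(expected, abs=1e-12)
        assert k2p(a, b) == pytest.approx(0.1702, abs=1e-4)

    @given(st.integers(0, 40), st.integers(0, 40))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_matches_closed_form(self, ts, tv):
        n = 200
        if 2 * (ts / n) + tv / n >= 1 or 2 * tv / n >= 1:
            return
        a = "A" * n
        b = "G" * ts + "C" * tv + "A" * (n - ts - tv)
        P, Q = ts / n, tv / n
        expected = (-0.5 * math.log(1 - 2 * P - Q)
                    - 0.25 * math.log(1 - 2 * Q))
        assert k2p(a, b) == pytest.approx(expected, abs=1e-12)

    def test_symmetric(self):
        a, b = "ACGTTGCA", "GCGTTACA"
        assert k2p(a, b) == k2p(b, a)

    def test_ambiguity_sites_excluded(self):
        assert k2p("ANGT", "AAGT") == 0.0

    def test_saturated_sentinel(self):
        assert math.isinf(k2p("ACACACAC", "GTGTGTGT"))

    def test_refuses_protein_sequences(self):
        with pytest.raises(ValueError, match="nucleotide"):
            k2p("MELK", "MELK")


def _estimate(pair_id, dS):
    return RateEstimate(pair_id, 100, 200, 10, 10, 0.1, 0.05, dS,
                        dS / 2, 0.5, False, dS > 2)


class TestFilterSaturated:
    def test_above_bound_removed(self):
        assert filter_saturated([_estimate("a", 2.5)]) == []

    def test_at_bound_retained(self):
        assert len(filter_saturated([_estimate("a", 2.0)])) == 1

    def test_empty(self):
        assert filter_saturated([]) == []

    def test_undefined_removed(self):
        assert filter_saturated([_estimate("a", math.inf)]) == []


def _pathway_estimates(omegas_by_pathway):
    ests, pmap = [], {}
    i = 0
    for pw, omegas in omegas_by_pathway.items():
        pmap[pw] = []
        for om in omegas:
            pid = f"g{i}"
            i += 1
            ests.append(RateEstimate(pid, 100, 200, 5, 5, 0.05, 0.025,
                                     0.3, om * 0.3, om, False, False))
            pmap[pw].append(pid)
    return ests, pmap


class TestPathwayScan:
    def test_uniform_omegas_nothing_elevated(self):
        ests, pmap = _pathway_estimates(
            {f"p{k}": [0.2] * 4 for k in range(5)})
        scan = pathway_scan(ests, pmap)
        assert scan.elevated() == []
        assert (scan.table["z"] == 0).all()

    def test_median_definition(self):
        ests, pmap = _pathway_estimates({"p0": [0.1, 0.2, 0.9],
                                         "p1": [0.1, 0.1, 0.1]})
        scan = pathway_scan(ests, pmap)
        assert scan.table.loc["p0", "median_omega"] == pytest.approx(0.2)

    def test_min_genes_excludes_small_pathways(self):
        ests, pmap = _pathway_estimates({"p0": [0.1, 0.2, 0.3],
                                         "p1": [0.1, 0.4, 0.2],
                                         "tiny": [0.9, 0.9]})
        scan = pathway_scan(ests, pmap, min_genes=3)
        assert "tiny" not in scan.table.index

    def test_conserved_class(self):
        ests, pmap = _pathway_estimates({"p0": [0.0, 0.01, 0.01],
                                         "p1": [0.3, 0.3, 0.3],
                                         "p2": [0.25, 0.3, 0.35]})
        scan = pathway_scan(ests, pmap, conserved_eps=0.02)
        assert scan.table.loc["p0", "class_"] == "conserved"

    def test_fewer_than_two_pathways_rejected(self):
        ests, pmap = _pathway_estimates({"p0": [0.1, 0.2, 0.3]})
        with pytest.raises(ValueError):
            pathway_scan(ests, pmap)


class TestPercentileRank:
    def test_above_999_of_1000(self):
        ref = list(range(1000))
        assert percentile_rank(998.5, ref) == 99.9

    def test_below_all(self):
        assert percentile_rank(-1, [1, 2, 3]) == 0.0

    def test_ties_excluded(self):
        assert percentile_rank(2, [1, 2, 2, 3]) == 25.0

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            percentile_rank(1, [])


def _orders(a_genes, b_genes):
    return GeneOrderMap({"A": {"scA": [(g, "+") for g in a_genes]},
                         "B": {"scB": [(g, "+") for g in b_genes]}})


def _table(n):
    return OrthologTable("A", "B", {f"a{i}": f"b{i}" for i in range(n)})


def brute_force_synteny(gmap, table, min_block, max_gap):
    """Oracle: enumerate every candidate run over the ortholog sub-order
    and keep maximal valid ones, then assign longest-first."""
    sp_a, sp_b = table.species_a, table.species_b
    pos_b = {}
    for sc, genes in gmap.orders[sp_b].items():
        for i, (g, _s) in enumerate(genes):
            pos_b[g] = (sc, i)
    all_runs = []
    for sc_a, genes in sorted(gmap.orders[sp_a].items()):
        entries = []
        for idx, (g, _s) in enumerate(genes):
            if g in table.pairs:
                entries.append((idx, g) + pos_b[table.pairs[g]])
        n = len(entries)

        def valid(i, j, d):
            for k in range(i, j - 1):
                a1, _, sc1, b1 = entries[k]
                a2, _, sc2, b2 = entries[k + 1]
                if sc1 != sc2 or a2 - a1 - 1 > max_gap:
                    return False
                step = (b2 - b1) * d
                if step < 1 or step - 1 > max_gap:
                    return False
            return True

        for d, orient in ((1, "same"), (-1, "inverted")):
            for i in range(n):
                for j in range(i + 2, n + 1):
                    if not valid(i, j, d):
                        continue
                    if (i > 0 and valid(i - 1, j, d)) or \
                       (j < n and valid(i, j + 1, d)):
                        continue  # not maximal
                    all_runs.append((sc_a, tuple(e[1] for e in entries[i:j]),
                                     orient))
    all_runs = [r for r in all_runs if len(r[1]) >= min_block]
    used, blocks = set(), []
    for sc_a, genes, orient in sorted(all_runs,
                                      key=lambda r: (-len(r[1]), r[0], r[1])):
        free = [g for g in genes if g not in used]
        # longest contiguous unused run
        best, cur = [], []
        for g in genes:
            if g in used:
                best, cur = max(best, cur, key=len), []
            else:
                cur.append(g)
        best = max(best, cur, key=len)
        if len(best) >= min_block:
            used.update(best)
            blocks.append((sc_a, tuple(best), orient))
    return sorted(blocks)


class TestMacroSynteny:
    def test_perfect_collinearity(self):
        gmap = _orders([f"a{i}" for i in range(5)],
                       [f"b{i}" for i in range(5)])
        blocks = call_macro_synteny(gmap, _table(5))
        assert len(blocks) == 1
        assert blocks[0].n_genes == 5
        assert blocks[0].orientation == "same"

    def test_b_side_gap_limit(self):
        # B positions 1,2,3,10,11: max_gap=1 cuts after the third gene
        b_genes = (["b0", "b1", "b2"] + [f"x{i}" for i in range(6)]
                   + ["b3", "b4"])
        gmap = _orders([f"a{i}" for i in range(5)], b_genes)
        blocks = call_macro_synteny(gmap, _table(5), min_block=3, max_gap=1)
        assert len(blocks) == 1
        assert blocks[0].genes_a == ("a0", "a1", "a2")

    def test_inversion_detected(self):
        gmap = _orders([f"a{i}" for i in range(4)],
                       [f"b{i}" for i in range(3, -1, -1)])
        blocks = call_macro_synteny(gmap, _table(4))
        assert len(blocks) == 1 and blocks[0].orientation == "inverted"

    def test_missing_gene_in_orders_rejected(self):
        gmap = _orders(["a0", "a1", "a2"], ["b0", "b1"])
        with pytest.raises(ValueError, match="not in orders"):
            call_macro_synteny(gmap, _table(3))

    @given(st.integers(0, 5000))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_matches_brute_force_small_orders(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        a_genes = [f"a{i}" for i in range(n)]
        # random B arrangement with occasional fillers
        b_genes = [f"b{i}" for i in rng.permutation(n)]
        for fi in range(int(rng.integers(0, 3))):
            b_genes.insert(int(rng.integers(len(b_genes) + 1)), f"x{fi}")
        gmap = _orders(a_genes, b_genes)
        table = _table(n)
        got = sorted((b.scaffold_a, b.genes_a, b.orientation)
                     for b in call_macro_synteny(gmap, table,
                                                 min_block=3, max_gap=1))
        expected = brute_force_synteny(gmap, table, 3, 1)
        assert got == expected
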