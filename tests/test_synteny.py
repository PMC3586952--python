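"""Synteny detectors against brute-force rule evaluation, the paralog-pair
correction, normalization and the Kruskal-Wallis comparison."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from phyloscan import simgen, synteny
from phyloscan.geneorder import GeneOrderGenome
from phyloscan.synteny import SyntenicPair


# --------------------------------------------------------------- oracles
# Deliberately naive re-statements of the detection rules, evaluated over
# every gene pair; the detectors must agree exactly.

def relaxed_oracle(query, target, max_q=3, max_t=4, window=7):
    tfam = {}
    for c, g in target.genes():
        tfam.setdefault(g.family_id, []).append((c, g))
    found = set()
    for contig, genes in query.contigs.items():
        for a in genes:
            for b in genes:
                if b.index <= a.index or b.index - a.index - 1 > max_q:
                    continue
                between = [g for g in genes if a.index < g.index < b.index]
                for ca, ta in tfam.get(a.family_id, []):
                    for cb, tb in tfam.get(b.family_id, []):
                        if ca != cb or ta.index == tb.index:
                            continue
                        if abs(ta.index - tb.index) - 1 > max_t:
                            continue
                        ok = True
                        for g in between:
                            hits = tfam.get(g.family_id, [])
                            if not hits:
                                continue
                            if not any(c == ca and
                                       (abs(h.index - ta.index) <= window or
                                        abs(h.index - tb.index) <= window)
                                       for c, h in hits):
                                ok = False
                                break
                        if ok:
                            lo, hi = sorted((ta, tb), key=lambda g: g.index)
                            found.add((a.gene_id, b.gene_id,
                                       lo.gene_id, hi.gene_id))
    return found


def strict_oracle(query, target, mode, max_gap=3):
    ttok = {}
    for c, g in target.genes():
        if g.ortholog_id is not None:
            ttok[g.ortholog_id] = (c, g)
    omap = {}
    for c, g in query.genes():
        if g.ortholog_id is not None and g.ortholog_id in ttok:
            omap[g.gene_id] = ttok[g.ortholog_id]
    found = set()
    for contig, genes in query.contigs.items():
        for a in genes:
            for b in genes:
                if b.index <= a.index or b.index - a.index - 1 > max_gap:
                    continue
                if a.strand != b.strand:
                    continue
                if a.gene_id not in omap or b.gene_id not in omap:
                    continue
                (ca, ta), (cb, tb) = omap[a.gene_id], omap[b.gene_id]
                if ca != cb or abs(ta.index - tb.index) - 1 > max_gap:
                    continue
                if ta.strand != tb.strand:
                    continue
                lo, hi = sorted((ta.index, tb.index))
                ok = True
                for g in genes:
                    if not a.index < g.index < b.index:
                        continue
                    if g.gene_id not in omap:
                        continue
                    cg, tg = omap[g.gene_id]
                    if mode == "literal":
                        ok = False
                    elif cg != ca or not lo < tg.index < hi:
                        ok = False
                if ok:
                    pair = sorted((ta, tb), key=lambda g: g.index)
                    found.add((a.gene_id, b.gene_id,
                               pair[0].gene_id, pair[1].gene_id))
    return found


def _as_set(pairs):
    return {(p.query_pair[0], p.query_pair[1],
             p.target_pair[0], p.target_pair[1]) for p in pairs}


def _random_genome_pair(seed):
    sp, _ = simgen.generate_species_tree(2, seed=seed)
    genomes, _ = simgen.evolve_gene_orders(sp, 60, 1.0, 0.8, 0.8, seed=seed)
    a, b = genomes.values()
    return a, b


class TestDetectorsAgainstOracle:
    @pytest.mark.parametrize("seed", range(6))
    def test_relaxed_matches_brute_force(self, seed):
        q, t = _random_genome_pair(seed)
        assert _as_set(synteny.find_relaxed_pairs(q, t)) == \
            relaxed_oracle(q, t)

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("mode", ["literal", "interval_consistent"])
    def test_strict_matches_brute_force(self, seed, mode):
        q, t = _random_genome_pair(seed + 50)
        got = _as_set(synteny.find_strict_pairs(q, t, intervening_mode=mode))
        assert got == strict_oracle(q, t, mode)


class TestRuleEdges:
    def test_colinear_identical_genomes_relaxed_count(self, colinear_genome):
        # gaps 0..3 between 10 genes: 9 + 8 + 7 + 6 = 30 pairs
        a, b = colinear_genome("A", 10), colinear_genome("B", 10)
        assert len(synteny.find_relaxed_pairs(a, b)) == 30

    def test_query_gap_of_four_never_reported(self, colinear_genome):
        a, b = colinear_genome("A", 10), colinear_genome("B", 10)
        pairs = synteny.find_relaxed_pairs(a, b)
        gaps = [int(p.query_pair[1][3:]) - int(p.query_pair[0][3:]) - 1
                for p in pairs]
        assert max(gaps) <= 3

    def test_target_separation_of_five_not_reported(self, colinear_genome):
        from phyloscan.geneorder import Gene
        a = colinear_genome("A", 2)
        # target: homologs of F0, F1 separated by 5 intervening genes
        genes = ([Gene("B_g0", 0, "+", "F0", "L0")]
                 + [Gene(f"B_gx{i}", i, "+", f"X{i}", None)
                    for i in range(1, 6)]
                 + [Gene("B_g1", 6, "+", "F1", "L1")])
        b = GeneOrderGenome("B", {"c1": genes})
        assert synteny.find_relaxed_pairs(a, b) == []
        assert synteny.find_strict_pairs(a, b) == []

    def test_strict_literal_keeps_only_adjacencies(self, colinear_genome):
        a, b = colinear_genome("A", 10), colinear_genome("B", 10)
        literal = synteny.find_strict_pairs(a, b, intervening_mode="literal")
        assert len(literal) == 9
        interval = synteny.find_strict_pairs(
            a, b, intervening_mode="interval_consistent")
        assert len(interval) == 30

    def test_opposite_strand_query_pair_excluded(self, colinear_genome):
        a = colinear_genome("A", 10)
        flipped = colinear_genome("A", 10)
        from phyloscan.geneorder import Gene
        genes = [Gene(g.gene_id, g.index, "-" if g.index % 2 else "+",
                      g.family_id, g.ortholog_id)
                 for g in flipped.contigs["c1"]]
        mixed = GeneOrderGenome("Q", {"c1": genes})
        b = colinear_genome("B", 10)
        assert synteny.find_strict_pairs(mixed, b) == []


class TestCollapse:
    def test_tandem_duplicated_target_counted_once(self, colinear_genome):
        a = colinear_genome("A", 12)
        b = colinear_genome("B", 12)
        dup = simgen.tandem_duplicate(b, "c1", 4, 2, token_prefix="D1")
        dup = simgen.tandem_duplicate(dup, "c1", 4, 2, token_prefix="D2")
        raw = synteny.find_relaxed_pairs(a, dup)
        corrected = synteny.collapse_paralogous_pairs(raw)
        by_key = {}
        for p in raw:
            by_key.setdefault((p.query_pair, p.family_pair), []).append(p)
        assert any(len(v) >= 3 for v in by_key.values())
        assert len(corrected) == len(by_key)

    def test_no_duplicates_is_identity(self, colinear_genome):
        a, b = colinear_genome("A", 10), colinear_genome("B", 10)
        pairs = synteny.find_relaxed_pairs(a, b)
        assert synteny.collapse_paralogous_pairs(pairs) == pairs

    def test_corrected_never_exceeds_raw(self):
        for seed in range(5):
            q, t = _random_genome_pair(seed + 100)
            raw = synteny.find_relaxed_pairs(q, t)
            corrected = synteny.collapse_paralogous_pairs(raw)
            assert len(corrected) <= len(raw)

    @given(st.lists(st.tuples(st.integers(0, 5), st.integers(0, 5),
                              st.integers(0, 3), st.integers(0, 3),
                              st.integers(0, 9)), max_size=40))
    @settings(derandomize=True, max_examples=60)
    def test_collapse_properties_on_arbitrary_pair_lists(self, raw_tuples):
        """Correction is idempotent, never grows the list, and leaves exactly
        one pair per (query pair, family pair) group."""
        pairs = [SyntenicPair((f"q{a}", f"q{b}"), (f"t{k}", f"t{k + 1}"),
                              "relaxed", tuple(sorted((f"F{fa}", f"F{fb}"))))
                 for a, b, fa, fb, k in raw_tuples]
        collapsed = synteny.collapse_paralogous_pairs(pairs)
        assert len(collapsed) <= len(pairs)
        assert synteny.collapse_paralogous_pairs(collapsed) == collapsed
        keys = {(tuple(sorted(p.query_pair)), p.family_pair)
                for p in pairs}
        assert len(collapsed) == len(keys)


class TestNormalization:
    @pytest.mark.parametrize("count,shared,expected",
                             [(5, 1000, 5.0), (0, 7, 0.0), (30, 10, 3000.0)])
    def test_pairs_per_thousand(self, count, shared, expected):
        assert synteny.normalize_pair_count(count, shared) == expected

    def test_zero_shared_rejected(self):
        with pytest.raises(ValueError):
            synteny.normalize_pair_count(3, 0)

    def test_compare_genomes_invariants(self):
        q, t = _random_genome_pair(7)
        res = synteny.compare_genomes(q, t, "relaxed")
        assert res.corrected_count <= res.raw_count
        assert res.normalized_raw == pytest.approx(
            1000 * res.raw_count / res.shared_homologs)


class TestKruskalWallis:
    def test_all_equal_observations(self):
        h, p = synteny.compare_groups_kw({"a": [2.0, 2.0], "b": [2.0, 2.0]})
        assert h == 0.0 and p == 1.0

    def test_hand_computed_h(self):
        groups = {"g1": [1, 2, 3], "g2": [4, 5, 6], "g3": [7, 8, 9]}
        # H = 12/(N(N+1)) * sum n_i (rbar_i - rbar)^2 with no ties
        n = 9
        rank_sums = {"g1": 1 + 2 + 3, "g2": 4 + 5 + 6, "g3": 7 + 8 + 9}
        expected = (12.0 / (n * (n + 1))
                    * sum(rs ** 2 / 3 for rs in rank_sums.values())
                    - 3 * (n + 1))
        h, p = synteny.compare_groups_kw(groups)
        assert h == pytest.approx(expected)
        assert p == pytest.approx(1 - stats.chi2.cdf(expected, df=2))

    def test_null_p_values_roughly_uniform(self, rng):
        pvals = []
        for _ in range(400):
            pooled = rng.normal(size=12)
            groups = {"a": pooled[:4], "b": pooled[4:8], "c": pooled[8:]}
            pvals.append(synteny.compare_groups_kw(
                {k: list(v) for k, v in groups.items()})[1])
        ks = stats.kstest(pvals, "uniform").pvalue
        assert ks > 0.001

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            synteny.compare_groups_kw({"only": [1.0, 2.0]})
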