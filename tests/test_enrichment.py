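"""Hypergeometric over-representation and IUPAC motif enrichment."""

import itertools
from fractions import Fraction

import numpy as np
import pytest

from nearzero import (
    GeneSetCollection,
    Motif,
    hypergeometric_enrichment,
    hypergeometric_pvalue,
    motif_enrichment_factor,
    overlap_with_reference,
    scan_motif,
)
from nearzero.simulate import generate_promoters

IUPAC_TEST = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def _naive_scan(seq: str, pattern: str) -> int:
    """Brute-force window scan oracle for IUPAC matching (one strand)."""
    hits = 0
    for i in range(len(seq) - len(pattern) + 1):
        if all(seq[i + j] in IUPAC_TEST[c] for j, c in enumerate(pattern)):
            hits += 1
    return hits


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


class TestHypergeometric:
    def test_worked_example(self):
        # N=10, K=5, n=4, k=4: p = C(5,4)*C(5,0)/C(10,4) = 5/210
        assert hypergeometric_pvalue(4, 10, 5, 4) == pytest.approx(5 / 210, rel=1e-12)

    def test_zero_overlap_tail_is_one(self):
        assert hypergeometric_pvalue(0, 100, 10, 5) == 1.0

    def test_matches_exhaustive_enumeration(self):
        # exact rational comparison against enumerating all C(N, n) draws
        for N in (5, 8, 11, 12):
            universe = list(range(N))
            for K in (1, N // 2, N - 1):
                annotated = set(universe[:K])
                for n in (1, N // 2, N - 1):
                    total = 0
                    at_least = {}
                    for draw in itertools.combinations(universe, n):
                        total += 1
                        overlap = len(annotated & set(draw))
                        at_least[overlap] = at_least.get(overlap, 0) + 1
                    for k in range(0, min(n, K) + 1):
                        count = sum(v for kk, v in at_least.items() if kk >= k)
                        exact = Fraction(count, total)
                        assert hypergeometric_pvalue(k, N, K, n) == pytest.approx(
                            float(exact), rel=1e-10
                        )

    def test_enrichment_table_and_bonferroni(self):
        universe = [f"g{i}" for i in range(100)]
        coll = GeneSetCollection(
            sets={"setA": universe[:10], "setB": universe[50:60]},
            universe=universe,
        )
        res = hypergeometric_enrichment(universe[:10], coll, p_threshold=1e-6)
        row_a = res[res.set_name == "setA"].iloc[0]
        assert row_a.k == 10 and row_a.ef == pytest.approx(10.0)
        assert (res.p_bonf >= res.p - 1e-15).all()

    def test_no_enrichment_gives_unit_ef(self):
        universe = [f"g{i}" for i in range(100)]
        # cluster of 20 holding exactly its proportional share (4) of a 20-gene set
        members = universe[:4] + universe[50:66]
        coll = GeneSetCollection(sets={"s": universe[:20]}, universe=universe)
        res = hypergeometric_enrichment(members, coll)
        assert res.iloc[0].ef == pytest.approx(1.0)

    def test_cluster_outside_universe_rejected(self):
        coll = GeneSetCollection(sets={"s": ["a"]}, universe=["a", "b"])
        with pytest.raises(ValueError, match="ghost"):
            hypergeometric_enrichment(["a", "ghost"], coll)

    def test_empty_set_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="orphan"):
            coll = GeneSetCollection(
                sets={"orphan": ["zzz"], "ok": ["a"]}, universe=["a", "b"]
            )
        assert list(coll.sets) == ["ok"]


class TestReferenceOverlap:
    def test_planted_concentration_detected(self, rng):
        universe = [f"g{i}" for i in range(4000)]
        clusters = {
            1: universe[:400],
            2: universe[400:800],
            3: universe[800:1200],
        }
        # 300-gene reference, 80% concentrated in cluster 1
        reference = list(rng.choice(universe[:400], 240, replace=False)) + list(
            rng.choice(universe[1200:], 60, replace=False)
        )
        res = overlap_with_reference(clusters, reference, universe)
        by = res.set_index("cluster")
        assert by.loc[1, "significant"] and by.loc[1, "p"] < 1e-6
        assert not by.loc[2, "significant"] and by.loc[2, "label"] == "NS"
        assert not by.loc[3, "significant"]

    def test_reference_equal_to_universe_is_flat(self):
        universe = [f"g{i}" for i in range(50)]
        res = overlap_with_reference({1: universe[:10]}, universe, universe)
        assert res.iloc[0].ef == pytest.approx(1.0)

    def test_disjoint_reference_gives_p_one(self):
        universe = [f"g{i}" for i in range(50)]
        res = overlap_with_reference({1: universe[:10]}, universe[40:], universe)
        assert res.iloc[0].k == 0 and res.iloc[0].p == 1.0

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            overlap_with_reference({1: ["a"]}, ["zzz"], ["a", "b"])


class TestMotifScan:
    def test_degenerate_position_matches_both_bases(self):
        motif = Motif("TCGTTYAG", scan_both_strands=False)
        hits = scan_motif(
            {"a": "TCGTTCAG", "b": "TCGTTTAG", "c": "TCGTTAAG"}, motif
        )
        assert bool(hits.loc["a", "hit"]) and bool(hits.loc["b", "hit"])
        assert not hits.loc["c", "hit"]

    def test_reverse_complement_strand(self):
        motif = Motif("TCGTTYAG", scan_both_strands=True)
        hits = scan_motif({"p": "AACTGAACGATT"}, motif)  # contains revcomp(TCGTTCAG)
        assert bool(hits.loc["p", "hit"])
        one_strand = scan_motif({"p": "AACTGAACGATT"}, Motif("TCGTTYAG", scan_both_strands=False))
        assert not one_strand.loc["p", "hit"]

    def test_n_in_sequence_never_matches(self):
        motif = Motif("TCGTTYAG", scan_both_strands=False)
        hits = scan_motif({"p": "TCGTTNAG"}, motif)
        assert not hits.loc["p", "hit"]

    def test_invalid_motif_character_rejected(self):
        with pytest.raises(ValueError):
            Motif("TCGTT0AG")

    def test_counts_match_bruteforce_window_oracle(self):
        motif = Motif("TCGTTYAG", scan_both_strands=True)
        prom = generate_promoters(
            [f"g{i}" for i in range(50)], length=800, p_background=0.5,
            p_planted=0.5, seed=5,
        )
        hits = scan_motif(prom, motif)
        for gid, seq in prom.items():
            expected = _naive_scan(seq, motif.pattern) + _naive_scan(
                _revcomp(seq), motif.pattern
            )
            assert hits.loc[gid, "n_hits"] == expected


class TestMotifEnrichmentFactor:
    def test_ratio_arithmetic_matches_reported_magnitude(self):
        # cluster hit fraction 0.38 vs universe 0.10 -> EF = 3.8
        universe = [f"g{i}" for i in range(1000)]
        cluster = universe[:100]
        hit = {g: False for g in universe}
        for g in cluster[:38]:
            hit[g] = True
        for g in universe[100:162]:
            hit[g] = True  # 38 + 62 = 100 hits universe-wide
        res = motif_enrichment_factor(cluster, hit, universe)
        assert res["ef"] == pytest.approx(3.8, rel=1e-12)

    def test_cluster_equal_to_universe_is_unit(self):
        universe = [f"g{i}" for i in range(40)]
        hit = {g: i % 3 == 0 for i, g in enumerate(universe)}
        res = motif_enrichment_factor(universe, hit, universe)
        assert res["ef"] == pytest.approx(1.0)

    def test_nested_clusters_with_same_hit_fraction_share_ef(self):
        universe = [f"g{i}" for i in range(100)]
        hit = {g: False for g in universe}
        for g in universe[:10] + universe[20:25]:
            hit[g] = True
        inner = universe[:4] + universe[40:44]  # 4/8 hits
        outer = universe[:8] + universe[40:48]  # 8/16 hits
        ef_inner = motif_enrichment_factor(inner, hit, universe)["ef"]
        ef_outer = motif_enrichment_factor(outer, hit, universe)["ef"]
        assert ef_inner == pytest.approx(ef_outer)

    def test_hitless_universe_flagged(self):
        universe = ["a", "b", "c"]
        res = motif_enrichment_factor(["a"], {g: False for g in universe}, universe)
        assert res["degenerate"] and np.isnan(res["ef"])

    def test_planted_motif_recovers_target_ef(self):
        # hit rates: 40% in a 200-gene cluster vs 10% across the
        # 2000-gene universe -> EF 4.0, overwhelming significance
        genes = [f"g{i}" for i in range(2000)]
        cluster = genes[:200]
        p_bg = (0.10 * 2000 - 0.40 * 200) / 1800
        prom = generate_promoters(
            genes, p_background=p_bg, p_planted=0.40,
            planted_genes=cluster, seed=9, exact=True,
        )
        hits = scan_motif(prom, Motif("TCGTTYAG"))
        res = motif_enrichment_factor(cluster, hits, genes)
        assert abs(res["ef"] - 4.0) / 4.0 <= 0.20
        assert res["p"] < 1e-6


def test_gmt_round_trip(tmp_path):
    universe = ["a", "b", "c", "d"]
    coll = GeneSetCollection(sets={"s1": ["a", "b"], "s2": ["c"]}, universe=universe)
    path = tmp_path / "sets.gmt"
    coll.to_gmt(path)
    loaded = GeneSetCollection.from_gmt(path, universe)
    assert loaded.sets == coll.sets
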