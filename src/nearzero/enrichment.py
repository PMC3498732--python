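"""Gene-set over-representation and promoter motif enrichment.

Over-representation of an annotation set (functional category, TF-target
list, or an external reference signature) within a gene cluster is
scored with the hypergeometric upper tail: drawing ``n`` cluster genes
from a universe of ``N`` analyzable genes of which ``K`` carry the
annotation,

    p = P(X >= k),  X ~ Hypergeometric(N, K, n)

together with the enrichment factor EF = (k/n) / (K/N), the ratio of the
annotation's frequency in the cluster to its frequency in the universe.
The universe is the set of genes that survived preprocessing, not the
whole genome.

Promoter motifs are written in the IUPAC degenerate alphabet (e.g.
TCGTTYAG, Y = C or T) and matched exactly against upstream sequences on
one or both strands; an ``N`` in the sequence never matches.  The motif
enrichment factor is the hit-fraction ratio cluster/universe with the
same hypergeometric tail on hit counts.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy.stats import hypergeom

__all__ = [
    "IUPAC",
    "Motif",
    "GeneSetCollection",
    "hypergeometric_pvalue",
    "hypergeometric_enrichment",
    "overlap_with_reference",
    "scan_motif",
    "motif_enrichment_factor",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class Motif:
    """IUPAC promoter motif, scanned exactly (no mismatches)."""

    pattern: str
    scan_both_strands: bool = True
    promoter_length: int = 800

    def __post_init__(self) -> None:
        bad = [c for c in self.pattern.upper() if c not in IUPAC]
        if bad:
            raise ValueError(f"invalid IUPAC character(s) in motif: {bad}")
        object.__setattr__(self, "pattern", self.pattern.upper())

    def regex(self) -> re.Pattern:
        # lookahead so overlapping matches are all counted
        body = "".join(
            c if len(IUPAC[c]) == 1 else f"[{IUPAC[c]}]" for c in self.pattern
        )
        return re.compile(f"(?={body})")

    def expansions(self) -> list[str]:
        """All concrete sequences the degenerate pattern stands for."""
        seqs = [""]
        for c in self.pattern:
            seqs = [s + b for s in seqs for b in IUPAC[c]]
        return seqs


@dataclass
class GeneSetCollection:
    """Named gene sets over a common analyzable universe.

    On construction every set is restricted to the universe; sets that
    become empty are dropped with a warning.
    """

    sets: dict = field(default_factory=dict)
    universe: frozenset = frozenset()

    def __post_init__(self) -> None:
        self.universe = frozenset(self.universe)
        restricted = {}
        for name, members in self.sets.items():
            kept = frozenset(members) & self.universe
            if not kept:
                warnings.warn(f"gene set {name!r} is empty after restriction; dropped", stacklevel=2)
                continue
            restricted[name] = kept
        self.sets = restricted

    def __len__(self) -> int:
        return len(self.sets)

    @classmethod
    def from_gmt(cls, path, universe: Iterable) -> "GeneSetCollection":
        sets = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                sets[parts[0]] = frozenset(g for g in parts[2:] if g)
        return cls(sets=sets, universe=frozenset(universe))

    def to_gmt(self, path, description: str = "na") -> None:
        with open(path, "w") as fh:
            for name in sorted(self.sets):
                members = "\t".join(sorted(self.sets[name]))
                fh.write(f"{name}\t{description}\t{members}\n")


def hypergeometric_pvalue(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    Evaluated via the survival function (log-space internally), stable up
    to genome-sized universes.
    """
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def _check_universe(genes: Iterable, universe: frozenset, what: str) -> frozenset:
    genes = frozenset(genes)
    outside = genes - universe
    if outside:
        raise ValueError(f"{what} gene(s) outside the universe: {sorted(outside)[:10]}")
    return genes


def hypergeometric_enrichment(
    cluster: Iterable,
    collection: GeneSetCollection,
    p_threshold: float = 1e-6,
) -> pd.DataFrame:
    """Over-representation of every set of the collection in one cluster.

    Returns one row per set: overlap ``k``, cluster size ``n``, set size
    ``K``, universe size ``N``, raw ``p``, Bonferroni-adjusted ``p_bonf``
    (within this collection), ``ef`` and the significance flag on raw p.
    """
    cluster_set = _check_universe(cluster, collection.universe, "cluster")
    N = len(collection.universe)
    n = len(cluster_set)
    m = len(collection.sets)
    rows = []
    for name in sorted(collection.sets):
        members = collection.sets[name]
        K = len(members)
        k = len(cluster_set & members)
        p = hypergeometric_pvalue(k, N, K, n)
        ef = (k / n) / (K / N) if n > 0 else np.nan
        rows.append(
            {
                "set_name": name,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p": p,
                "p_bonf": min(1.0, m * p),
                "ef": ef,
                "significant": p < p_threshold,
            }
        )
    return pd.DataFrame(rows)


def overlap_with_reference(
    clusters: Mapping,
    reference: Iterable,
    universe: Iterable,
    p_threshold: float = 1e-6,
) -> pd.DataFrame:
    """Per-cluster over-representation of an external reference gene set.

    ``clusters`` maps cluster id -> member gene ids.  The reference is
    restricted to the universe first; clusters not reaching the p-value
    cut-off are labelled NS.
    """
    universe = frozenset(universe)
    ref = frozenset(reference) & universe
    if not ref:
        raise ValueError("reference set is empty after restriction to the universe")
    N, K = len(universe), len(ref)
    rows = []
    for cid in sorted(clusters):
        cluster_set = _check_universe(clusters[cid], universe, f"cluster {cid}")
        n = len(cluster_set)
        k = len(cluster_set & ref)
        p = hypergeometric_pvalue(k, N, K, n)
        ef = (k / n) / (K / N) if n > 0 else np.nan
        rows.append(
            {
                "cluster": cid,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p": p,
                "ef": ef,
                "significant": p < p_threshold,
                "label": f"{p:.2E}" if p < p_threshold else "NS",
            }
        )
    return pd.DataFrame(rows)


def scan_motif(promoters: Mapping, motif: Motif) -> pd.DataFrame:
    """Exact IUPAC match of a motif against promoter sequences.

    A promoter is a hit iff the motif occurs at least once on the given
    strand, or on either strand when ``scan_both_strands``.  Overlapping
    occurrences are all counted; ``N`` bases in the sequence never match.
    Returns a DataFrame indexed by promoter id with ``hit`` and
    ``n_hits`` columns.
    """
    rx = motif.regex()
    ids, hits, counts = [], [], []
    for pid, seq in promoters.items():
        s = str(seq).upper()
        c = len(rx.findall(s))
        if motif.scan_both_strands:
            c += len(rx.findall(str(Seq(s).reverse_complement())))
        ids.append(pid)
        counts.append(c)
        hits.append(c > 0)
    return pd.DataFrame({"hit": hits, "n_hits": counts}, index=pd.Index(ids, name="gene_id"))


def motif_enrichment_factor(
    cluster: Iterable,
    hits: Mapping | pd.DataFrame | pd.Series,
    universe: Iterable,
) -> dict:
    """Motif enrichment factor of a cluster vs the analyzed universe.

    EF = (hit fraction in cluster) / (hit fraction in universe); the
    significance is the hypergeometric upper tail of the cluster hit
    count given the universe hit count.  A universe without any hit
    yields an undefined (NaN) EF, flagged ``degenerate``.
    """
    if isinstance(hits, pd.DataFrame):
        hit_map = hits["hit"]
    elif isinstance(hits, pd.Series):
        hit_map = hits
    else:
        hit_map = pd.Series(dict(hits))
    universe = frozenset(universe)
    cluster_set = _check_universe(cluster, universe, "cluster")
    missing = universe - frozenset(hit_map.index)
    if missing:
        raise ValueError(f"hit flags missing for universe gene(s): {sorted(missing)[:10]}")
    N, n = len(universe), len(cluster_set)
    K = int(sum(bool(hit_map[g]) for g in universe))
    k = int(sum(bool(hit_map[g]) for g in cluster_set))
    if K == 0:
        return {
            "k": k, "n": n, "K": K, "N": N,
            "ef": float("nan"), "p": 1.0, "degenerate": True,
        }
    ef = (k / n) / (K / N)
    return {
        "k": k, "n": n, "K": K, "N": N,
        "ef": ef, "p": hypergeometric_pvalue(k, N, K, n), "degenerate": False,
    }
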