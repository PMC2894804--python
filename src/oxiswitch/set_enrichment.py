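"""Over-representation analysis of trajectory clusters against gene sets.

Gene-set collections (GO terms, keywords, pathways, cis-regulatory motif
target sets) are supplied as GMT files.  For a cluster of n genes from a
universe of N, a set of K members overlapping the cluster in k genes is
scored by the hypergeometric upper tail P(X >= k) (Fisher mode) or by the
conservative EASE variant P(X >= k) computed with k - 1 (one overlapping
gene discounted).  Raw p-values are corrected by Bonferroni or
Benjamini-Hochberg; enriched terms can be grouped into functional annotation
groups by Cohen's-kappa similarity of their gene memberships, each group
scored by the geometric mean of its members' Benjamini-corrected p-values
(significant at <= 0.05).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneSetCollection",
    "FunctionalGroup",
    "parse_gmt",
    "ora_pvalue",
    "fold_enrichment",
    "correct",
    "enrich",
    "functional_groups",
    "motif_enrichment",
]


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a background universe."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str]
    universe: frozenset[str]

    def __len__(self) -> int:
        return len(self.sets)

    @classmethod
    def from_dict(
        cls, sets: dict[str, set[str]], universe: set[str] | None = None
    ) -> "GeneSetCollection":
        """Build a collection from plain dicts (identifiers uppercased)."""
        if universe is None:
            universe = set().union(*sets.values()) if sets else set()
        uni = frozenset(g.upper() for g in universe)
        cleaned = {}
        for name, members in sets.items():
            inter = frozenset(g.upper() for g in members) & uni
            if inter:
                cleaned[name] = inter
        return cls(sets=cleaned, descriptions={n: "" for n in cleaned}, universe=uni)


@dataclass(frozen=True)
class FunctionalGroup:
    """Group of similarly-annotated terms scored by geometric-mean Benjamini p."""

    terms: tuple[str, ...]
    score: float

    @property
    def significant(self) -> bool:
        return self.score <= 0.05


def parse_gmt(path, universe: set[str] | None = None) -> GeneSetCollection:
    """Read a GMT file: name <TAB> description <TAB> member...

    Identifiers are uppercased and deduplicated; sets are intersected with
    the universe (default: the union of all members).  Empty post-filter
    sets are dropped.
    """
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    raw: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line {lineno}: expected >= 3 fields")
        name, desc, *members = parts
        raw[name] = [m.upper() for m in members if m]
        descriptions[name] = desc
    if universe is None:
        universe = set().union(*raw.values()) if raw else set()
    uni = frozenset(g.upper() for g in universe)
    for name, members in raw.items():
        inter = frozenset(members) & uni
        if inter:
            sets[name] = inter
    return GeneSetCollection(
        sets=sets,
        descriptions={n: descriptions[n] for n in sets},
        universe=uni,
    )


def ora_pvalue(k: int, n: int, K: int, N: int, mode: str = "fisher") -> float:
    """Hypergeometric upper-tail P(X >= k); EASE mode discounts one overlap gene.

    k = overlap, n = cluster size, K = set size in the universe, N = universe
    size.  ``mode='ease'`` computes the tail at k - 1 (DAVID's conservative
    EASE score); k = 0 (or k = 1 under EASE) gives p = 1.
    """
    if not (0 <= k <= min(n, K)) or n > N or K > N:
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    if mode not in ("fisher", "ease"):
        raise ValueError(f"unknown mode {mode!r}")
    kk = k - 1 if mode == "ease" else k
    if kk <= 0:
        return 1.0
    return float(stats.hypergeom.sf(kk - 1, N, K, n))


def fold_enrichment(k: int, n: int, K: int, N: int) -> float:
    """Observed over expected overlap: (k/n) / (K/N)."""
    if n <= 0 or K <= 0 or N <= 0:
        raise ValueError("cluster, set and universe sizes must be positive")
    return (k / n) / (K / N)


def correct(p: np.ndarray, method: str = "benjamini") -> np.ndarray:
    """Multiple-testing correction over the tested collection.

    ``bonferroni``: min(1, m*p).  ``benjamini``: BH step-up.  Both are
    monotone in the raw p-values.
    """
    p = np.asarray(p, dtype=float)
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    if method == "benjamini":
        from .differential_expression import bh_adjust

        return bh_adjust(p)
    raise ValueError(f"unknown correction {method!r}")


def enrich(
    cluster_genes, collection: GeneSetCollection, mode: str = "ease"
) -> pd.DataFrame:
    """Score every set of the collection against one cluster.

    Returns a DataFrame sorted by raw p with columns: set, description, n,
    K, k, fold_enrichment, p, p_bonferroni, p_benjamini.  The cluster is
    intersected with the universe first; a low overlap triggers a warning.
    """
    import warnings

    cluster = frozenset(str(g).upper() for g in cluster_genes)
    in_universe = cluster & collection.universe
    if cluster and len(in_universe) < 0.5 * len(cluster):
        warnings.warn(
            f"only {len(in_universe)}/{len(cluster)} cluster genes are in the "
            "collection universe; check identifier namespaces",
            stacklevel=2,
        )
    n = len(in_universe)
    N = len(collection.universe)
    rows = []
    for name, members in collection.sets.items():
        K = len(members)
        k = len(in_universe & members)
        rows.append(
            {
                "set": name,
                "description": collection.descriptions.get(name, ""),
                "n": n,
                "K": K,
                "k": k,
                "fold_enrichment": fold_enrichment(k, n, K, N) if n else 0.0,
                "p": ora_pvalue(k, n, K, N, mode=mode) if n else 1.0,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_bonferroni"] = correct(out["p"].to_numpy(), "bonferroni")
        out["p_benjamini"] = correct(out["p"].to_numpy(), "benjamini")
        out = out.sort_values("p", kind="mergesort").reset_index(drop=True)
    return out


def _cohen_kappa(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's kappa between two binary membership vectors."""
    n = a.size
    po = np.mean(a == b)
    pa, pb = a.mean(), b.mean()
    pe = pa * pb + (1 - pa) * (1 - pb)
    if pe == 1.0:
        return 1.0
    return (po - pe) / (1 - pe)


def functional_groups(
    enrichment: pd.DataFrame,
    memberships: dict[str, set[str]],
    cluster_genes,
    kappa_threshold: float = 0.5,
    seed_size: int = 3,
    alpha: float = 0.05,
) -> list[FunctionalGroup]:
    """Group Benjamini-significant terms by gene-membership similarity.

    Terms significant at ``alpha`` (Benjamini) seed groups greedily, in
    p-value order: a seed collects every other significant term whose
    Cohen's kappa with it (over the cluster genes) meets the threshold.
    Groups sharing a majority of members are merged; terms may belong to
    several groups.  Each group is scored by the geometric mean of its
    members' Benjamini-corrected p-values.
    """
    sig = enrichment[enrichment["p_benjamini"] <= alpha]
    if sig.empty:
        return []
    genes = sorted(str(g).upper() for g in cluster_genes)
    idx = {g: i for i, g in enumerate(genes)}
    vectors = {}
    for term in sig["set"]:
        v = np.zeros(len(genes), dtype=bool)
        for g in memberships.get(term, ()):
            gi = idx.get(str(g).upper())
            if gi is not None:
                v[gi] = True
        vectors[term] = v

    terms = list(sig["set"])
    benj = dict(zip(sig["set"], sig["p_benjamini"]))
    raw_groups: list[set[str]] = []
    for seed in terms:  # already in ascending p order
        group = {
            other
            for other in terms
            if other == seed
            or _cohen_kappa(vectors[seed], vectors[other]) >= kappa_threshold
        }
        if len(group) >= min(seed_size, len(terms)):
            raw_groups.append(group)

    merged: list[set[str]] = []
    for g in raw_groups:
        for m in merged:
            if len(g & m) > 0.5 * min(len(g), len(m)):
                m |= g
                break
        else:
            merged.append(set(g))

    if not merged:  # every term isolated: report singletons
        merged = [{t} for t in terms]

    groups = []
    for m in merged:
        score = float(np.exp(np.mean([math.log(max(benj[t], 1e-300)) for t in m])))
        groups.append(FunctionalGroup(terms=tuple(sorted(m)), score=score))
    groups.sort(key=lambda g: g.score)
    return groups


def motif_enrichment(
    cluster_genes, motifs: GeneSetCollection, alpha: float = 0.05
) -> pd.DataFrame:
    """Bonferroni-filtered motif over-representation (Fisher mode).

    Scores every motif target set, applies Bonferroni over the collection,
    and reports sets with corrected p < ``alpha`` sorted ascending.
    """
    res = enrich(cluster_genes, motifs, mode="fisher")
    if res.empty:
        return res
    keep = res[res["p_bonferroni"] < alpha]
    return keep.sort_values("p_bonferroni", kind="mergesort").reset_index(drop=True)
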