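"""Gene-set enrichment: hypergeometric over-representation and preranked GSEA.

Two classic statistics, implemented from their published definitions:

* Over-representation: for a query set drawn from a finite universe (here the
  290-gene endogenous panel by default), the upper-tail hypergeometric
  probability of seeing at least the observed overlap with each term set,
  BH-adjusted across terms.

* Preranked GSEA: a weighted Kolmogorov-Smirnov running sum over a ranked
  gene list.  Walking down the ranking, hits increment the sum by
  |score|^w / sum_hits |score|^w and misses decrement by 1/(N - N_hits); the
  enrichment score ES is the signed maximum deviation from zero.  With
  w = 0 this is the classic KS statistic.  Significance comes from gene-label
  permutations (random same-size sets drawn from the ranked genes), and
  NES = ES / mean(|permuted ES| of the same sign).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .deconv_de import bh_adjust

logger = logging.getLogger("hclsig")


class EnrichmentError(ValueError):
    pass


@dataclass
class GeneSetCollection:
    """Named gene sets (symbols uppercased on load)."""

    sets: dict[str, frozenset[str]]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.sets:
            raise EnrichmentError("gene set collection is empty")
        self.sets = {t: frozenset(g.upper() for g in gs) for t, gs in self.sets.items()}


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: term <tab> description <tab> gene1 <tab> gene2 ..."""
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise EnrichmentError(f"{path}:{ln}: GMT line needs term, description, >=1 gene")
        term = parts[0]
        genes = frozenset(g.strip().upper() for g in parts[2:] if g.strip())
        if not genes:
            raise EnrichmentError(f"{path}:{ln}: term {term!r} has no genes")
        sets[term] = genes
    return GeneSetCollection(sets=sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path,
              description: str = "na") -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for term in sorted(collection.sets):
            genes = "\t".join(sorted(collection.sets[term]))
            fh.write(f"{term}\t{description}\t{genes}\n")
    return path


def hypergeometric_enrich(
    query: set[str] | Sequence[str],
    collection: GeneSetCollection,
    universe: set[str] | Sequence[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of ``query`` in each term.

    Term genes outside the universe are intersected away first; p values are
    BH-adjusted across terms.  The effect column is a Haldane-corrected odds
    ratio of the 2x2 overlap table.
    """
    universe = {g.upper() for g in universe}
    query = {g.upper() for g in query}
    if not query:
        raise EnrichmentError("query gene set is empty")
    stray = query - universe
    if stray:
        raise EnrichmentError(f"query gene(s) outside universe: {sorted(stray)[:5]}")
    m = len(universe)
    n = len(query)
    rows = []
    for term, genes in collection.sets.items():
        term_genes = genes & universe
        k_total = len(term_genes)
        overlap = query & term_genes
        k = len(overlap)
        # P(X >= k), X ~ Hypergeom(M=m, n=k_total, N=n)
        p = float(stats.hypergeom.sf(k - 1, m, k_total, n)) if k_total else 1.0
        a, b_ = k, k_total - k
        c, d = n - k, m - k_total - (n - k)
        odds = ((a + 0.5) * (d + 0.5)) / ((b_ + 0.5) * (c + 0.5))
        rows.append({
            "term": term,
            "overlap_count": k,
            "term_size": k_total,
            "overlap_genes": ",".join(sorted(overlap)),
            "p_raw": min(p, 1.0),
            "effect": odds,
        })
    out = pd.DataFrame(rows).set_index("term")
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    return out.sort_values("p_raw")


# ---------------------------------------------------------------------------
# Preranked GSEA
# ---------------------------------------------------------------------------


def _running_sum(scores: np.ndarray, hit_mask: np.ndarray, weight: float) -> np.ndarray:
    """Weighted KS running sum over the ranked list."""
    n = scores.size
    n_hits = int(hit_mask.sum())
    if n_hits == 0 or n_hits == n:
        raise EnrichmentError("term must hit a strict subset of the ranked list")
    w = np.abs(scores) ** weight
    hit_w = np.where(hit_mask, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        # all hit scores are zero under weight > 0: fall back to equal steps
        hit_w = hit_mask.astype(float)
        denom = hit_w.sum()
    steps = hit_w / denom - (~hit_mask) / (n - n_hits)
    return np.cumsum(steps)


def _es(scores: np.ndarray, hit_mask: np.ndarray, weight: float) -> float:
    walk = _running_sum(scores, hit_mask, weight)
    return float(walk[np.argmax(np.abs(walk))])


@dataclass
class GseaResult:
    term: str
    es: float
    nes: float
    p_value: float
    n_permutations: int
    seed: int
    overlap_count: int
    running_sum: np.ndarray = field(repr=False)


def gsea_preranked(
    ranked: Mapping[str, float] | pd.Series,
    term: set[str] | Sequence[str],
    weight_exponent: float = 1.0,
    n_permutations: int = 1000,
    seed: int = 0,
    term_name: str = "term",
) -> GseaResult:
    """Enrichment score and permutation p for one term on a ranked list.

    ``ranked`` maps gene -> score, ordered by decreasing score (re-sorted
    here; ties keep their stable input order).  The permutation null draws
    random same-size gene sets from the ranked genes ("gene-label"
    permutation), which matches the preranked use case where no sample-level
    phenotypes exist.  p uses the add-one convention
    (1 + #{same-sign |perm ES| >= |ES|}) / (1 + #same-sign perms).
    """
    if isinstance(ranked, pd.Series):
        genes = [str(g).upper() for g in ranked.index]
        scores = ranked.to_numpy(dtype=float)
    else:
        genes = [str(g).upper() for g in ranked.keys()]
        scores = np.asarray(list(ranked.values()), dtype=float)
    if len(set(genes)) != len(genes):
        raise EnrichmentError("ranked list contains duplicate genes")
    order = np.argsort(-scores, kind="stable")
    genes = [genes[i] for i in order]
    scores = scores[order]
    term_set = {g.upper() for g in term}
    hit_mask = np.array([g in term_set for g in genes])
    if not hit_mask.any():
        raise EnrichmentError(f"term {term_name!r} shares no genes with the ranked list")

    walk = _running_sum(scores, hit_mask, weight_exponent)
    es = float(walk[np.argmax(np.abs(walk))])

    rng = np.random.default_rng(seed)
    n_hits = int(hit_mask.sum())
    perm_es = np.empty(n_permutations)
    idx = np.arange(len(genes))
    for i in range(n_permutations):
        mask = np.zeros(len(genes), dtype=bool)
        mask[rng.choice(idx, size=n_hits, replace=False)] = True
        perm_es[i] = _es(scores, mask, weight_exponent)
    same_sign = perm_es >= 0 if es >= 0 else perm_es <= 0
    pool = np.abs(perm_es[same_sign])
    p = (1.0 + float(np.sum(pool >= abs(es)))) / (1.0 + pool.size)
    nes = es / pool.mean() if pool.size and pool.mean() > 0 else float("nan")
    return GseaResult(
        term=term_name, es=es, nes=float(nes), p_value=float(p),
        n_permutations=n_permutations, seed=seed,
        overlap_count=n_hits, running_sum=walk,
    )
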