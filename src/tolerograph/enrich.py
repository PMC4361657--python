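"""Gene-set analytics: weighted Kolmogorov-Smirnov enrichment (GSEA) for
cell-lineage sets and hypergeometric over-representation analysis.

GSEA asks whether the members of a set (for example, genes specific to
CD56+ NK cells) concentrate near the top or bottom of a gene list ranked
by a two-group signal-to-noise score. The enrichment score is the signed
maximal deviation of a weighted running sum; significance and
normalization come from phenotype or gene-set permutations. ORA tests a
discrete gene list for overlap with each set by the hypergeometric upper
tail, with Benjamini-Hochberg control across sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import DataError, DirectionalGeneList, ExpressionMatrix


class GeneSetCollection(dict):
    """Mapping set name -> set of gene/probe identifiers."""

    def __init__(self, sets: Dict[str, Iterable[str]]):
        cleaned = {}
        for name, members in sets.items():
            members = set(members)
            if not members:
                raise DataError(f"gene set {name!r} is empty")
            cleaned[name] = members
        super().__init__(cleaned)

    def restrict(self, universe: Set[str]) -> "GeneSetCollection":
        kept = {n: m & universe for n, m in self.items() if m & universe}
        return GeneSetCollection(kept) if kept else GeneSetCollection.__new__(GeneSetCollection)


def rank_genes(x: ExpressionMatrix, labels: Sequence[int],
               sigma_floor: float = 0.2) -> List[Tuple[str, float]]:
    """Rank genes by the signal-to-noise score (mu_A - mu_B)/(sd_A + sd_B).

    Each group standard deviation is floored at max(0.2*|mean|,
    sigma_floor * 0.2) per the classic GSEA convention, preventing
    low-variance genes from dominating. Descending score order with
    lexicographic tie-break on gene id.
    """
    labels = np.asarray(labels)
    mask_a = labels == 1
    mask_b = labels == 0
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise DataError("each group needs >= 2 samples")

    def floored(vals: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        mu = vals.mean(axis=1)
        sd = vals.std(axis=1, ddof=1)
        sd = np.maximum(sd, np.maximum(0.2 * np.abs(mu), sigma_floor * 0.2))
        return mu, sd

    mu_a, sd_a = floored(x.values[:, mask_a])
    mu_b, sd_b = floored(x.values[:, mask_b])
    score = (mu_a - mu_b) / (sd_a + sd_b)
    order = sorted(range(x.n_probes), key=lambda i: (-score[i], x.probe_ids[i]))
    return [(x.probe_ids[i], float(score[i])) for i in order]


def enrichment_score(ranked: Sequence[Tuple[str, float]], gene_set: Set[str],
                     weight: float = 1.0) -> Tuple[float, np.ndarray, int]:
    """Weighted-KS enrichment score over a ranked gene list.

    Hits increment the running sum by |score|^weight normalized by the
    total hit weight; misses decrement by 1/(N - N_H). Returns the
    signed maximal deviation, the running sum, and the index where the
    extremum is attained.
    """
    n = len(ranked)
    hits = np.array([g in gene_set for g, _ in ranked])
    n_hit = int(hits.sum())
    if n_hit == 0:
        raise DataError("gene set does not intersect the ranked universe")
    if n_hit == n:
        raise DataError("gene set equals the ranked universe")
    w = np.abs(np.array([sc for _, sc in ranked])) ** weight
    hit_w = np.where(hits, w, 0.0)
    total = hit_w.sum()
    if total == 0:
        hit_w = hits.astype(float)   # all-zero scores: unweighted KS
        total = hit_w.sum()
    step = np.where(hits, hit_w / total, -1.0 / (n - n_hit))
    running = np.cumsum(step)
    peak = int(np.argmax(np.abs(running)))
    return float(running[peak]), running, peak


@dataclass
class GseaResult:
    table: pd.DataFrame   # columns: set, size, es, nes, p_value, fdr_q

    def row(self, name: str) -> pd.Series:
        return self.table.set_index("set").loc[name]


def gsea_test(x: ExpressionMatrix, labels: Sequence[int],
              sets: GeneSetCollection, n_perm: int = 1000,
              perm_type: str = "phenotype", weight: float = 1.0,
              seed: int = 0) -> GseaResult:
    """GSEA with permutation-based NES, p-values and FDR.

    ``perm_type`` is ``phenotype`` (shuffle sample labels and re-rank;
    requires >= 7 samples, else auto-switches to ``gene_set``) or
    ``gene_set`` (draw random sets of the same size from the universe).
    NES = ES / mean(|permuted ES| of the same sign); p = fraction of
    same-sign permuted ES at least as extreme; FDR by the standard
    NES-ratio estimator, clipped to [0, 1].
    """
    labels = np.asarray(labels)
    if perm_type not in ("phenotype", "gene_set"):
        raise DataError(f"unknown perm_type {perm_type!r}")
    if perm_type == "phenotype" and len(labels) < 7:
        import warnings
        warnings.warn("fewer than 7 samples: switching to gene_set permutation")
        perm_type = "gene_set"
    rng = np.random.default_rng(seed)
    ranked = rank_genes(x, labels)
    universe = [g for g, _ in ranked]
    names = sorted(sets)
    restricted = {n: sets[n] & set(universe) for n in names}
    restricted = {n: m for n, m in restricted.items() if m and len(m) < len(universe)}
    names = sorted(restricted)
    if not names:
        raise DataError("no gene set intersects the ranked universe")

    obs_es = {n: enrichment_score(ranked, restricted[n], weight)[0] for n in names}

    perm_es = {n: np.empty(n_perm) for n in names}
    if perm_type == "phenotype":
        for b in range(n_perm):
            perm_labels = labels[rng.permutation(len(labels))]
            pranked = rank_genes(x, perm_labels)
            for n in names:
                perm_es[n][b] = enrichment_score(pranked, restricted[n], weight)[0]
    else:
        for n in names:
            size = len(restricted[n])
            for b in range(n_perm):
                idx = rng.choice(len(universe), size=size, replace=False)
                rand_set = {universe[i] for i in idx}
                perm_es[n][b] = enrichment_score(ranked, rand_set, weight)[0]

    def normalize(es: float, null: np.ndarray) -> float:
        same = null[null >= 0] if es >= 0 else null[null < 0]
        denom = np.mean(np.abs(same)) if same.size else np.mean(np.abs(null))
        return es / denom if denom > 0 else 0.0

    rows = []
    all_nes_null: List[np.ndarray] = []
    nes_obs = {}
    for n in names:
        null = perm_es[n]
        nes_obs[n] = normalize(obs_es[n], null)
        nes_null = np.array([normalize(e, null) for e in null])
        all_nes_null.append(nes_null)
    pooled_null = np.concatenate(all_nes_null)
    obs_vals = np.array([nes_obs[n] for n in names])

    for n, nes_null in zip(names, all_nes_null):
        es = obs_es[n]
        null = perm_es[n]
        same = null[null >= 0] if es >= 0 else null[null < 0]
        if same.size:
            p = float((np.abs(same) >= abs(es)).sum() + 1) / (same.size + 1)
        else:
            p = 1.0 / (null.size + 1)
        nes = nes_obs[n]
        # FDR: fraction of null NES at least as extreme (same sign), over
        # the fraction of observed NES at least as extreme
        if nes >= 0:
            num_null = float(np.mean(pooled_null >= nes)) if pooled_null.size else 0.0
            pos = pooled_null[pooled_null >= 0]
            num = float(np.mean(pos >= nes)) if pos.size else 0.0
            den_obs = obs_vals[obs_vals >= 0]
            den = float(np.mean(den_obs >= nes)) if den_obs.size else 1.0
        else:
            neg = pooled_null[pooled_null < 0]
            num = float(np.mean(neg <= nes)) if neg.size else 0.0
            den_obs = obs_vals[obs_vals < 0]
            den = float(np.mean(den_obs <= nes)) if den_obs.size else 1.0
        fdr = min(max(num / den if den > 0 else 0.0, 0.0), 1.0)
        rows.append({"set": n, "size": len(restricted[n]), "es": es,
                     "nes": nes, "p_value": p, "fdr_q": fdr})
    return GseaResult(pd.DataFrame(rows))


@dataclass
class OraResult:
    table: pd.DataFrame   # set, k_overlap, set_size, list_size, universe_size,
                          # p_hypergeom, fdr_q, ratio

    def significant(self, fdr_alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table.fdr_q <= fdr_alpha]


def ora_test(gene_list, sets: GeneSetCollection, universe: Set[str],
             fdr_alpha: float = 0.05) -> OraResult:
    """Hypergeometric over-representation of a gene list in each set.

    p = P(X >= k) for overlap k drawn from a universe of size M with
    set size K and list size N; Benjamini-Hochberg q-values across sets.
    Results are sorted by ascending p.
    """
    if isinstance(gene_list, DirectionalGeneList):
        ids = gene_list.ids()
    else:
        ids = set(gene_list)
    universe = set(universe)
    if not ids <= universe:
        raise DataError("gene list must be a subset of the universe")
    M, N = len(universe), len(ids)
    rows = []
    for name in sorted(sets):
        members = sets[name] & universe
        if not members:
            continue
        K = len(members)
        k = len(members & ids)
        p = float(stats.hypergeom.sf(k - 1, M, K, N))
        rows.append({"set": name, "k_overlap": k, "set_size": K,
                     "list_size": N, "universe_size": M,
                     "p_hypergeom": min(p, 1.0), "ratio": f"{k}/{K}"})
    table = pd.DataFrame(rows)
    if len(table):
        table["fdr_q"] = multipletests(table.p_hypergeom, method="fdr_bh")[1]
        table = table.sort_values("p_hypergeom", kind="stable").reset_index(drop=True)
    else:
        table["fdr_q"] = []
    return OraResult(table)
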