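"""Pre-ranked gene-set enrichment and word-cloud term scoring.

Genes ordered by a signed ranking metric (TRM/RM/RM_adj, see
:mod:`translate_rank.polysome_rank`) are tested against a gene-set
collection with the classic weighted Kolmogorov-Smirnov enrichment score
(weight exponent 1): walking down the list, set members increment a running
sum by |metric| / sum(|metric| over members), non-members decrement it by
1/(N - N_hits); the ES is the running-sum value of maximal absolute
deviation from zero. Significance comes from gene-label permutations of the
metric; NES normalizes each ES by the mean |null ES| of the same sign, and
BH adjustment is applied across all tested sets.

Term scoring summarizes an NES-ranked list of gene sets as a word cloud:
set names are split on underscores into terms, each occurrence is scored
100/RP where RP is the set's rank percentile rounded *up* to a multiple of
0.1% (so scores span 1-1000), and a term's overall score is the mean of its
per-set scores. Stop terms (prepositions, conjunctions, generic words) are
removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

#: Terms removed before building the word cloud: prepositions, conjunctions
#: and generic vocabulary that carries no pathway meaning.
DEFAULT_STOP_TERMS = frozenset({
    "WITH", "VIA", "THROUGH", "OF", "IN", "TO", "BY", "FROM", "FOR", "ON",
    "AND", "OR", "NOT",
    "GENE", "GENES", "PATHWAY", "PATHWAYS", "REGULATION", "TARGET",
    "TARGETS", "PROCESS", "UP", "DN",
})


class GeneSetCollection(dict):
    """Named gene sets (name -> frozenset of gene identifiers)."""

    @classmethod
    def from_sets(cls, sets: dict) -> "GeneSetCollection":
        coll = cls()
        for name, genes in sets.items():
            if name in coll:
                raise ValueError(f"duplicate gene-set name: {name!r}")
            coll[name] = frozenset(genes)
        return coll

    def filtered(self, genes_present, min_size: int = 3,
                 max_size: int = 1500) -> "GeneSetCollection":
        """Keep sets whose overlap with ``genes_present`` is in [min, max]."""
        universe = set(genes_present)
        out = GeneSetCollection()
        for name, members in self.items():
            eff = len(members & universe)
            if min_size <= eff <= max_size:
                out[name] = self[name]
        return out


def _sorted_metric(ranked: pd.Series) -> pd.Series:
    order = sorted(ranked.index, key=lambda g: (-ranked[g], str(g)))
    return ranked.loc[order]


def enrichment_score(ranked: pd.Series, gene_set) -> tuple[float, np.ndarray, list]:
    """Weighted-KS enrichment score of one gene set.

    Parameters
    ----------
    ranked
        Metric values indexed by gene; sorted internally (descending metric,
        ties broken by gene identifier).
    gene_set
        Iterable of gene identifiers; must overlap the ranked list.

    Returns
    -------
    (es, running_sum, leading_edge)
        ES in [-1, 1], the full running-sum vector (one value per gene
        position), and the leading-edge gene list.
    """
    s = _sorted_metric(ranked)
    genes = s.index
    hits = genes.isin(set(gene_set)).astype(bool)
    n_hits = int(hits.sum())
    n = len(genes)
    if n_hits == 0:
        raise ValueError("gene set has zero overlap with the ranked list")
    w = np.abs(s.to_numpy())
    hit_w = np.where(hits, w, 0.0)
    total = hit_w.sum()
    if total == 0:  # all-hit metrics are zero: uniform increments
        hit_w = hits.astype(float)
        total = float(n_hits)
    step = hit_w / total
    if n_hits < n:
        step = step - (~hits) / (n - n_hits)
    running = np.cumsum(step)
    idx = int(np.argmax(np.abs(running)))
    es = float(np.clip(running[idx], -1.0, 1.0))
    if es >= 0:
        leading = [g for g, h in zip(genes[: idx + 1], hits[: idx + 1]) if h]
    else:
        leading = [g for g, h in zip(genes[idx:], hits[idx:]) if h]
    return es, running, leading


def _es_for_positions(pos: np.ndarray, absw: np.ndarray, n: int) -> np.ndarray:
    """Vectorized ES for many hit-position sets.

    pos: (B, k) integer positions into the sorted metric (any order);
    absw: |metric| sorted descending. Running sum is piecewise linear and
    extreme only adjacent to hits, so only 2k candidates per row matter.
    """
    B, k = pos.shape
    if k >= n:
        return np.ones(B)
    pos = np.sort(pos, axis=1)
    w = absw[pos]
    totals = w.sum(axis=1, keepdims=True)
    uniform = totals == 0
    if np.any(uniform):
        w = np.where(uniform, 1.0, w)
        totals = np.where(uniform, float(k), totals)
    cum = np.cumsum(w, axis=1) / totals
    j = np.arange(k)[None, :]
    miss = (pos - j) / (n - k)
    after = cum - miss          # running sum at each hit
    before = after - w / totals  # running sum just before each hit
    cand = np.concatenate([after, before], axis=1)
    idx = np.argmax(np.abs(cand), axis=1)
    return cand[np.arange(B), idx]


def _null_es(absw: np.ndarray, size: int, n_perm: int, rng: np.random.Generator,
             chunk: int = 2000) -> np.ndarray:
    """Gene-label permutation null: ES of ``n_perm`` random size-k sets."""
    n = absw.size
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        r = rng.random((b, n))
        pos = np.argpartition(r, size - 1, axis=1)[:, :size]
        out[done:done + b] = _es_for_positions(pos, absw, n)
        done += b
    return out


def preranked_gsea(ranked: pd.Series, collection: GeneSetCollection,
                   n_perm: int = 10000, seed: int = 0, min_size: int = 3,
                   max_size: int = 1500) -> pd.DataFrame:
    """Permutation pre-ranked GSEA over a gene-set collection.

    Only sets with 3-1500 members present in the ranked list are tested.
    Nominal p = (1 + #{same-sign null |ES| >= |ES|}) / (1 + #same-sign null);
    NES = ES / mean |same-sign null ES|; FDR by BH over all tested sets.
    Null distributions are cached per set size (a gene-label permutation
    null depends only on the set size). Deterministic given ``seed``.

    Returns a DataFrame indexed by set name with columns ``es``, ``nes``,
    ``pval``, ``fdr``, ``size``, ``leading_edge``; sets skipped for zero
    overlap are listed in ``result.attrs['skipped']``.
    """
    if len(collection) == 0:
        raise ValueError("empty gene-set collection")
    if n_perm < 100:
        import warnings
        warnings.warn(f"n_perm={n_perm} is very low; p-values will be coarse",
                      RuntimeWarning, stacklevel=2)
    s = _sorted_metric(ranked)
    universe = set(s.index)
    absw = np.abs(s.to_numpy())
    rng = np.random.default_rng(seed)
    rows, skipped = [], {}
    null_cache: dict[int, np.ndarray] = {}
    for name in sorted(collection):
        members = collection[name] & universe
        eff = len(members)
        if eff == 0:
            skipped[name] = "zero overlap with ranked list"
            continue
        if not (min_size <= eff <= max_size):
            skipped[name] = f"effective size {eff} outside [{min_size}, {max_size}]"
            continue
        es, _, leading = enrichment_score(s, members)
        if eff not in null_cache:
            null_cache[eff] = _null_es(absw, eff, n_perm, rng)
        null = null_cache[eff]
        same = null[np.sign(null) == np.sign(es)] if es != 0 else null
        if same.size == 0:
            nes, p = np.nan, 1.0
        else:
            nes = es / np.mean(np.abs(same))
            p = (1 + np.sum(np.abs(same) >= abs(es))) / (1 + same.size)
        rows.append((name, es, nes, p, eff, ",".join(map(str, leading))))
    if not rows:
        raise ValueError("no gene set passed the size filter")
    res = pd.DataFrame(rows, columns=["set", "es", "nes", "pval", "size",
                                      "leading_edge"]).set_index("set")
    res["fdr"] = multipletests(res["pval"], method="fdr_bh")[1]
    res = res[["es", "nes", "pval", "fdr", "size", "leading_edge"]]
    res.attrs["skipped"] = skipped
    return res


def rank_sets_by_nes(result: pd.DataFrame, positive_only: bool = False) -> list[str]:
    """Gene-set names ordered by NES descending (ties by name)."""
    res = result.dropna(subset=["nes"])
    if positive_only:
        res = res[res["nes"] > 0]
    return sorted(res.index, key=lambda s: (-res.loc[s, "nes"], s))


def ranking_percentile(rank: int, total: int) -> float:
    """Rank percentile rounded up to the next multiple of 0.1%.

    ``rank`` is 1-based. Exact integer arithmetic: RP in tenths of a percent
    is ceil(1000 * rank / total)."""
    if not 1 <= rank <= total:
        raise ValueError("rank must be in [1, total]")
    tenths = -((-1000 * rank) // total)  # ceil division
    return tenths / 10.0


@dataclass
class TermScoreTable:
    """Word-cloud term scores: ``table`` has one row per term (term, score,
    n_sets); ``details`` one row per (term, set) occurrence."""

    table: pd.DataFrame
    details: pd.DataFrame


def term_scores(ranked_sets, stop_terms=DEFAULT_STOP_TERMS,
                top_n: int = 100) -> TermScoreTable:
    """Score individual name terms of an ordered gene-set ranking.

    ``ranked_sets`` is an ordered sequence of set names, best first. Names
    are split on underscores and case-folded to upper case; each term is
    counted once per set. Per-set score = 100/RP with RP the set's rank
    percentile rounded up to 0.1% multiples (range 1-1000); a term's overall
    score is the mean over all sets containing it. The ``top_n`` terms by
    overall score are returned, stop terms removed.
    """
    names = list(ranked_sets)
    if not names:
        raise ValueError("empty gene-set ranking")
    total = len(names)
    stop = {t.upper() for t in stop_terms}
    detail_rows = []
    for rank, name in enumerate(names, start=1):
        rp = ranking_percentile(rank, total)
        score = 100.0 / rp
        terms = {t.upper() for t in str(name).split("_") if t}
        for term in sorted(terms - stop):
            detail_rows.append((term, name, rank, rp, score))
    details = pd.DataFrame(
        detail_rows, columns=["term", "set", "rank", "rp", "score"])
    agg = details.groupby("term")["score"].agg(["mean", "size"])
    agg.columns = ["score", "n_sets"]
    agg = agg.sort_index().sort_values("score", ascending=False,
                                       kind="stable").head(top_n)
    return TermScoreTable(table=agg.reset_index(), details=details)
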