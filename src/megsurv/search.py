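"""Discovery of mutually exclusive gene sets from a binary alteration matrix.

The engine has three stages, mirroring the structure of the exclusivity
analysis it implements:

1. **Multiple-path (beam) search** — score every gene pair with the
   likelihood-ratio test, then grow the most significant sets one gene at a
   time, keeping a beam of candidates per size; record the minimum nominal
   p-value per size ``k`` (``p_k``).
2. **Global-null-hypothesis (GNH) permutation test** — re-run the search on
   matrices whose columns are independently shuffled across patients
   (marginal frequencies preserved, co-occurrence destroyed) to convert the
   per-size minima into adjusted significances ``Q_k``; the overall
   statistic is ``theta = min_k Q_k``.
3. **Model selection** — grow each significant seed set while the nominal
   p-value of the best one-gene expansion stays below a permutation
   calibrated threshold ``p0`` chosen to keep the false-expansion rate
   under a target (5% by default).

Because the LRT depends on a candidate set only through its pattern counts,
scores are memoised on those counts; permutation replicates of the same
matrix hit the cache heavily.
"""

from __future__ import annotations

import itertools
import logging
import zlib
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .batchfit import batch_lrt_approx, pattern_counts
from .core import EPS, _fit_alternative_agg, _loglik_agg, _lrt_from_loglik
from .io import AlterationMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SearchResult",
    "GnhResult",
    "MegsCollection",
    "ScoreCache",
    "multipath_search",
    "gnh_test",
    "calibrate_p0",
    "model_selection",
    "build_network",
    "coverage",
]


@dataclass
class ScoredSet:
    genes: tuple[str, ...]
    statistic: float
    p_value: float

    def sort_key(self):
        # p-value first, deterministic lexicographic tie-break on labels
        return (self.p_value, -self.statistic, self.genes)


@dataclass
class SearchResult:
    """Beams of best gene sets per size with the per-size minimum p-values."""

    best_sets: dict[int, list[ScoredSet]]
    p_min: dict[int, float]


@dataclass
class GnhResult:
    """Permutation-adjusted per-size significances and the overall statistic."""

    q_values: dict[int, float]
    theta: float
    global_p: float
    n_perm: int
    p_min_obs: dict[int, float]
    perm_p_min: dict[int, np.ndarray] = field(repr=False, default=None)


@dataclass
class MegsCollection:
    """Significant mutually exclusive gene sets after model selection."""

    sets: list[dict]          # each: genes, p_value, coverage
    p0_by_size: dict[int, float]
    alpha: float


class ScoreCache:
    """Memoise LRT scores on bit-packed pattern counts.

    The mixture likelihood of a candidate set is a function of the counts of
    the 2^m possible mutation patterns only, so two submatrices with equal
    pattern counts share a score.  Within-column permutation replicates of
    one matrix produce heavily overlapping count keys.
    """

    def __init__(self, n_starts: int = 2, max_size: int = 2_000_000):
        self.n_starts = n_starts
        self.max_size = max_size
        self._store: dict = {}
        self.hits = 0
        self.misses = 0

    def score_columns(self, cols: np.ndarray) -> tuple[float, float]:
        """(S, p) for the LRT on an N x m column slice."""
        m = cols.shape[1]
        packed = cols @ (1 << np.arange(m))
        counts = np.bincount(packed, minlength=2 ** m)
        key = counts.tobytes()
        cached = self._store.get(key)
        if cached is not None:
            self.hits += 1
            return cached
        self.misses += 1
        result = self._score_counts(counts, m)
        if len(self._store) < self.max_size:
            self._store[key] = result
        return result

    def _score_counts(self, counts: np.ndarray, m: int) -> tuple[float, float]:
        nz = np.flatnonzero(counts)
        U = ((nz[:, None] >> np.arange(m)) & 1).astype(float)
        w = counts[nz].astype(float)
        N = w.sum()
        pi0 = np.clip((w @ U) / N, EPS, 1.0 - EPS)
        ll_null = _loglik_agg(U, w, 0.0, pi0)
        ll_alt, _, _ = _fit_alternative_agg(U, w, pi0, ll_null, self.n_starts)
        return _lrt_from_loglik(ll_alt, ll_null)


def _usable_features(values: np.ndarray, labels: list[str], min_count: int):
    counts = values.sum(axis=0)
    keep = np.flatnonzero(counts >= min_count)
    dropped = [labels[j] for j in range(len(labels)) if counts[j] < min_count]
    if dropped:
        logger.info("excluding %d features mutated in < %d patients",
                    len(dropped), min_count)
    return keep, dropped


def _score_level(values: np.ndarray, gene_sets: list[tuple[str, ...]],
                 idx_of: dict[str, int], cache: ScoreCache,
                 n_refine: int) -> list[ScoredSet]:
    """Exactly-scored top of a candidate level, ranked by the batch fit.

    All candidates are scored by the vectorized approximate fit; the
    ``n_refine`` most promising are re-fitted exactly and returned sorted.
    Small levels are refined in full, which makes the search identical to
    an all-exact evaluation there.
    """
    if len(gene_sets) <= n_refine:
        chosen = range(len(gene_sets))
    else:
        sets_idx = np.array([[idx_of[g] for g in gs] for gs in gene_sets])
        counts = pattern_counts(values, sets_idx)
        _, p_approx = batch_lrt_approx(counts)
        chosen = np.argsort(p_approx, kind="stable")[:n_refine]
    out = []
    for i in chosen:
        gs = gene_sets[i]
        S, p = cache.score_columns(values[:, [idx_of[g] for g in gs]])
        out.append(ScoredSet(gs, S, p))
    out.sort(key=ScoredSet.sort_key)
    return out


def _refine_count(beam_width: int) -> int:
    # refine enough beyond the beam that approximate-ranking jitter cannot
    # push a true beam member out
    return max(2 * beam_width, beam_width + 10)


def _search_values(values: np.ndarray, labels: list[str], K: int,
                   beam_width: int, cache: ScoreCache,
                   min_count: int = 2) -> SearchResult:
    keep, _ = _usable_features(values, labels, min_count)
    if len(keep) < 2:
        raise ValueError("fewer than 2 usable features for search")
    idx_of = {labels[j]: j for j in keep}
    names = sorted(idx_of)
    n_refine = _refine_count(beam_width)

    best: dict[int, list[ScoredSet]] = {}
    p_min: dict[int, float] = {}

    pairs = list(itertools.combinations(names, 2))
    level = _score_level(values, pairs, idx_of, cache, n_refine)
    best[2] = level[:beam_width]
    p_min[2] = level[0].p_value

    for k in range(3, K + 1):
        if len(names) < k:
            break
        seen: set[tuple[str, ...]] = set()
        for member in best[k - 1]:
            for g in names:
                if g not in member.genes:
                    seen.add(tuple(sorted(member.genes + (g,))))
        if not seen:
            break
        level = _score_level(values, sorted(seen), idx_of, cache, n_refine)
        best[k] = level[:beam_width]
        p_min[k] = level[0].p_value
    return SearchResult(best_sets=best, p_min=p_min)


def multipath_search(matrix: AlterationMatrix, K: int = 5,
                     beam_width: int = 20, cache: ScoreCache | None = None,
                     min_count: int = 2) -> SearchResult:
    """Beam search for the most exclusive gene sets of each size 2..K.

    Size 2 scores all pairs exhaustively; each subsequent level extends
    every beam member with every absent gene, deduplicates, and keeps the
    ``beam_width`` most significant sets.  ``p_min[k]`` is the smallest
    nominal LRT p-value observed at size ``k``.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if beam_width < 1:
        raise ValueError("beam_width must be >= 1")
    if matrix.n_features < 2:
        raise ValueError("need at least 2 features")
    cache = cache or ScoreCache()
    return _search_values(matrix.values, matrix.feature_labels, K,
                          beam_width, cache, min_count)


def _permute_columns(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = np.empty_like(values)
    N = values.shape[0]
    for j in range(values.shape[1]):
        out[:, j] = values[rng.permutation(N), j]
    return out


def gnh_test(matrix: AlterationMatrix, K: int = 5, beam_width: int = 20,
             n_perm: int = 200, seed: int | None = None,
             cache: ScoreCache | None = None, min_count: int = 2) -> GnhResult:
    """Global-null permutation test: does the matrix contain any MEGS?

    Each replicate independently shuffles every column across patients and
    re-runs the beam search; ``Q_k`` is the add-one permutation p-value of
    the observed ``p_min[k]``, ``theta = min_k Q_k``, and the global p-value
    compares observed theta with each replicate's theta computed
    leave-one-out against the remaining replicates.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if seed is None:
        raise ValueError("a seed is required for the permutation test")
    rng = np.random.default_rng(seed)
    cache = cache or ScoreCache()

    obs = _search_values(matrix.values, matrix.feature_labels, K, beam_width,
                         cache, min_count)
    sizes = sorted(obs.p_min)
    perm_p_min = {k: np.empty(n_perm) for k in sizes}
    for r in range(n_perm):
        shuffled = _permute_columns(matrix.values, rng)
        res = _search_values(shuffled, matrix.feature_labels, K, beam_width,
                             cache, min_count)
        for k in sizes:
            perm_p_min[k][r] = res.p_min.get(k, 1.0)

    q = {k: (1 + int((perm_p_min[k] <= obs.p_min[k]).sum())) / (n_perm + 1)
         for k in sizes}
    theta = min(q.values())

    # leave-one-out theta for each replicate against the other replicates
    theta_perm = np.empty(n_perm)
    for r in range(n_perm):
        qs = []
        for k in sizes:
            others = np.delete(perm_p_min[k], r)
            qs.append((1 + int((others <= perm_p_min[k][r]).sum())) / n_perm)
        theta_perm[r] = min(qs)
    global_p = (1 + int((theta_perm <= theta).sum())) / (n_perm + 1)

    return GnhResult(q_values=q, theta=theta, global_p=global_p,
                     n_perm=n_perm, p_min_obs=dict(obs.p_min),
                     perm_p_min=perm_p_min)


def calibrate_p0(matrix: AlterationMatrix, base_set: list[str],
                 n_perm: int = 200, fpr_target: float = 0.05,
                 seed: int | None = None,
                 cache: ScoreCache | None = None) -> float:
    """Permutation-calibrated expansion threshold p0 for one base set.

    Under the null that no remaining gene is exclusive with ``base_set``,
    each replicate shuffles every candidate column independently, scores
    every one-gene expansion of the base set, and records the minimum
    nominal p.  ``p0`` is the ``fpr_target`` quantile (lower order
    statistic) of those minima, so expanding whenever the best expansion's
    p falls below ``p0`` has false-positive rate <= ``fpr_target``.
    """
    if not 0.0 < fpr_target <= 1.0:
        raise ValueError("fpr_target must lie in (0, 1]")
    if fpr_target == 1.0:
        return 1.0
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if seed is None:
        raise ValueError("a seed is required for calibration")
    rng = np.random.default_rng(seed)
    cache = cache or ScoreCache()

    base_idx = [matrix.feature_labels.index(g) for g in base_set]
    cand_idx = [j for j in range(matrix.n_features) if j not in base_idx]
    if not cand_idx:
        raise ValueError("no candidate genes outside the base set")
    base_cols = matrix.values[:, base_idx]
    N = matrix.n_patients
    nc = len(cand_idx)

    # Build every (permutation, candidate) expansion column at once and
    # rank them with the batch fit; only each replicate's best one or two
    # expansions are re-fitted exactly to take the minimum.
    stacked = np.empty((N, n_perm * nc + len(base_idx)), dtype=matrix.values.dtype)
    stacked[:, :len(base_idx)] = base_cols
    col = len(base_idx)
    for r in range(n_perm):
        perm = rng.permutation(N)
        for j in cand_idx:
            stacked[:, col] = matrix.values[perm, j]
            col += 1
    b_idx = list(range(len(base_idx)))
    sets_idx = np.array([b_idx + [len(base_idx) + t] for t in range(n_perm * nc)])
    counts = pattern_counts(stacked, sets_idx)
    _, p_approx = batch_lrt_approx(counts)
    p_approx = p_approx.reshape(n_perm, nc)

    minima = np.empty(n_perm)
    top2 = np.argsort(p_approx, axis=1, kind="stable")[:, :2]
    for r in range(n_perm):
        best = 1.0
        for j in top2[r]:
            cols = np.column_stack([base_cols,
                                    stacked[:, len(base_idx) + r * nc + j]])
            _, p = cache.score_columns(cols)
            best = min(best, p)
        minima[r] = best
    order = np.sort(minima)
    # k-th smallest with k = floor(fpr_target * n_perm): at most a
    # fpr_target fraction of null minima fall strictly below it
    k = int(np.floor(fpr_target * n_perm))
    if k < 1:
        return float(order[0]) * 0.5
    return float(order[k - 1])


def _base_seed(master_seed: int, base: tuple[str, ...]) -> int:
    """Deterministic calibration seed per base set, independent of visit order."""
    h = zlib.crc32("|".join(base).encode())
    return int((master_seed * 2654435761 + h) % (2 ** 31))


def _expand_set(matrix: AlterationMatrix, genes: tuple[str, ...], K: int,
                n_perm: int, fpr_target: float, master_seed: int,
                cache: ScoreCache, min_count: int,
                p0_cache: dict) -> tuple[tuple[str, ...], float]:
    """Grow one seed set while the best expansion beats its calibrated p0."""
    keep, _ = _usable_features(matrix.values, matrix.feature_labels, min_count)
    usable = {matrix.feature_labels[j] for j in keep}
    current = tuple(sorted(genes))
    idx_of = {g: j for j, g in enumerate(matrix.feature_labels)}
    _, current_p = cache.score_columns(
        matrix.values[:, [idx_of[g] for g in current]])
    while len(current) < K:
        cands = sorted(usable - set(current))
        if not cands:
            break
        level = [tuple(sorted(current + (g,))) for g in cands]
        scored = _score_level(matrix.values, level, idx_of, cache,
                              n_refine=min(len(level), 8))
        best = scored[0]
        if current not in p0_cache:
            p0_cache[current] = calibrate_p0(
                matrix, list(current), n_perm=n_perm, fpr_target=fpr_target,
                seed=_base_seed(master_seed, current), cache=cache)
        if best.p_value < p0_cache[current]:
            current, current_p = best.genes, best.p_value
        else:
            break
    return current, current_p


def model_selection(matrix: AlterationMatrix, search: SearchResult,
                    gnh: GnhResult, alpha: float = 0.05, K: int = 5,
                    n_perm: int = 200, fpr_target: float = 0.05,
                    seed: int | None = None,
                    cache: ScoreCache | None = None,
                    min_count: int = 2,
                    max_seeds_per_size: int = 10) -> MegsCollection:
    """Expand every significant seed set into a final MEGS collection.

    Seeds are beam members at sizes whose adjusted significance clears
    ``Q_k < alpha`` and whose own nominal p is at most the permutation
    threshold for their size; each seed grows one gene at a time while the
    best expansion's nominal p stays below the calibrated ``p0`` for the
    current base.  The returned sets are deduplicated (unordered).
    """
    if seed is None:
        raise ValueError("a seed is required for model selection")
    cache = cache or ScoreCache()

    sig_sizes = [k for k, qk in gnh.q_values.items() if qk < alpha]
    results: dict[tuple[str, ...], float] = {}
    p0_by_size: dict[int, float] = {}
    p0_cache: dict = {}
    expanded: dict[tuple[str, ...], tuple[tuple[str, ...], float]] = {}
    for k in sig_sizes:
        # admit beam members whose nominal p beats the alpha-quantile of the
        # permutation distribution of p_min at this size
        thresh = float(np.quantile(gnh.perm_p_min[k], alpha)) \
            if gnh.perm_p_min is not None else alpha
        p0_by_size[k] = thresh
        for member in search.best_sets.get(k, [])[:max_seeds_per_size]:
            if member.p_value > thresh:
                continue
            start = tuple(sorted(member.genes))
            if start not in expanded:
                expanded[start] = _expand_set(matrix, start, K, n_perm,
                                              fpr_target, seed, cache,
                                              min_count, p0_cache)
            final, final_p = expanded[start]
            if final not in results or final_p < results[final]:
                results[final] = final_p

    # Backward validation: a set of size >= 3 is kept only if its nominal p
    # beats the calibrated expansion threshold of every leave-one-gene-out
    # base.  A set that entered through a contaminated seed (true set plus
    # one passenger) fails the check against the true set as base, while
    # every member of a genuine MEGS survives it.
    idx_of = {g: j for j, g in enumerate(matrix.feature_labels)}
    kept = []
    for genes in sorted(results, key=lambda g: (len(g), g)):
        if len(genes) >= 3:
            _, p_final = cache.score_columns(
                matrix.values[:, [idx_of[g] for g in genes]])
            ok = True
            # test the most significant base first: if the set rode in on a
            # contaminated seed, that base is the one whose p0 it cannot beat
            bases = sorted(
                (tuple(x for x in genes if x != g) for g in genes),
                key=lambda b: cache.score_columns(
                    matrix.values[:, [idx_of[x] for x in b]])[1])
            for base in bases:
                if base not in p0_cache:
                    p0_cache[base] = calibrate_p0(
                        matrix, list(base), n_perm=n_perm,
                        fpr_target=fpr_target,
                        seed=_base_seed(seed, base), cache=cache)
                if p_final >= p0_cache[base]:
                    ok = False
                    break
            if not ok:
                continue
        kept.append(genes)

    sets = [{"genes": list(g), "p_value": results[g],
             "coverage": coverage(matrix, list(g))}
            for g in sorted(kept, key=lambda g: (results[g], g))]
    return MegsCollection(sets=sets, p0_by_size=p0_by_size, alpha=alpha)


def build_network(collection: MegsCollection) -> nx.Graph:
    """Summarise a MEGS collection as a weighted exclusivity network.

    Vertex weight counts the sets containing the gene; edge weight counts
    the sets containing both endpoints.  Genes in no set are absent.
    """
    G = nx.Graph()
    for entry in collection.sets:
        genes = entry["genes"]
        for g in genes:
            if G.has_node(g):
                G.nodes[g]["weight"] += 1
            else:
                G.add_node(g, weight=1)
        for a, b in itertools.combinations(sorted(genes), 2):
            if G.has_edge(a, b):
                G[a][b]["weight"] += 1
            else:
                G.add_edge(a, b, weight=1)
    return G


def coverage(matrix: AlterationMatrix, gene_set: list[str]) -> float:
    """Fraction of patients carrying at least one alteration of the set."""
    cols = matrix.columns(gene_set)
    return float((cols.max(axis=1) > 0).mean())
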