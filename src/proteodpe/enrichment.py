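"""Preranked gene-set enrichment, over-representation, and gene-set
de-redundancy.

The enrichment score (ES) is the classic weighted running sum: walking down
the ranked list, in-set genes add |r_i|^w normalized by the in-set total
and out-of-set genes subtract 1/(N - N_set); ES is the maximum deviation
from zero. Significance comes from gene-label permutation (random sets of
the same size) with add-one correction and adaptive doubling of the
permutation count until the exceedance count is resolved or a cap is
reached — an approximation of multilevel p-value refinement that restores
small-p resolution without the exact split algorithm. NES divides ES by
the mean magnitude of same-sign permutation scores. The leading edge is
the in-set prefix (suffix, for negative ES) up to the running-sum
extremum.

Redundant gene-set collections (e.g. the full GO ontologies) are reduced by
iteratively merging the pair of sets with the highest Cohen's kappa
agreement over a gene universe until no pair exceeds the threshold
(default 0.4).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneSetCollection

log = logging.getLogger("proteodpe")

__all__ = [
    "EnrichmentResult",
    "KappaClustering",
    "rank_statistic",
    "enrichment_score",
    "gsea_preranked",
    "leading_edge_frequency",
    "ora_hypergeometric",
    "cohens_kappa",
    "kappa_simplify",
]

PERMUTATION_CAP = 2**17
MIN_EXCEEDANCES = 10


def rank_statistic(
    dpe: pd.DataFrame, mode: str = "t_stat"
) -> pd.DataFrame:
    """Build the descending ranked list for preranked enrichment.

    ``mode`` chooses the signed statistic: ``t_stat`` (the moderated t) or
    ``signed_logp`` (sign(logFC) * -log10 p). Duplicate gene symbols
    collapse to the row with maximal |statistic|; ties in the statistic
    break by accession so the order is stable across runs.
    """
    if dpe["contrast"].nunique() > 1:
        raise ValueError("rank_statistic expects a single contrast")
    if mode == "t_stat":
        stat = dpe["t"].to_numpy(dtype=float)
    elif mode == "signed_logp":
        stat = np.sign(dpe["logFC"].to_numpy()) * (
            -np.log10(np.clip(dpe["p_value"].to_numpy(), 1e-300, None))
        )
    else:
        raise ValueError(f"unknown rank mode {mode!r}")
    table = dpe.assign(stat=stat)
    dup = table["gene_symbol"].duplicated(keep=False)
    if dup.any():
        log.info("collapsing %d duplicate gene symbols to max |stat|",
                 int(dup.sum()))
        table = (
            table.assign(_abs=table["stat"].abs())
            .sort_values(["_abs", "accession"], ascending=[False, True],
                         kind="mergesort")
            .drop_duplicates("gene_symbol", keep="first")
            .drop(columns="_abs")
        )
    table = table.sort_values(
        ["stat", "accession"], ascending=[False, True], kind="mergesort"
    )
    return table[["gene_symbol", "accession", "stat"]].reset_index(drop=True)


def enrichment_score(
    stats_ranked: np.ndarray, hit_positions: np.ndarray, weight_exp: float = 1.0
) -> tuple[float, int]:
    """ES of one gene set given 0-based hit positions in the ranked list.

    Returns (ES, extremum hit index into the sorted hit positions).
    """
    N = stats_ranked.size
    k = hit_positions.size
    if k == 0 or k >= N:
        raise ValueError("set must be a proper non-empty subset of the universe")
    pos = np.sort(hit_positions)
    w = np.abs(stats_ranked[pos]) ** weight_exp
    total = w.sum()
    if total == 0:
        w = np.ones(k)
        total = float(k)
    hitcum = np.cumsum(w) / total
    miss = 1.0 / (N - k)
    i = np.arange(k)
    after = hitcum - (pos - i) * miss
    before = (hitcum - w / total) - (pos - i) * miss
    i_max = int(np.argmax(after))
    i_min = int(np.argmin(before))
    if after[i_max] >= -before[i_min]:
        return float(after[i_max]), i_max
    return float(before[i_min]), i_min


def _perm_es(
    stats_ranked: np.ndarray, k: int, n: int, rng: np.random.Generator,
    weight_exp: float,
) -> np.ndarray:
    """ES for ``n`` random same-size gene-label permutations (vectorized)."""
    N = stats_ranked.size
    W = np.abs(stats_ranked) ** weight_exp
    pos = np.argsort(rng.random((n, N)), axis=1)[:, :k]
    pos.sort(axis=1)
    w = W[pos]
    totals = w.sum(axis=1, keepdims=True)
    zero = totals[:, 0] == 0
    if zero.any():
        w[zero] = 1.0
        totals[zero] = k
    hitcum = np.cumsum(w, axis=1) / totals
    miss = 1.0 / (N - k)
    i = np.arange(k)[None, :]
    after = hitcum - (pos - i) * miss
    before = (hitcum - w / totals) - (pos - i) * miss
    pos_max = after.max(axis=1)
    neg_min = before.min(axis=1)
    return np.where(pos_max >= -neg_min, pos_max, neg_min)


def gsea_preranked(
    ranked: pd.DataFrame,
    sets: GeneSetCollection,
    weight_exp: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 10,
    max_size: int = 500,
) -> pd.DataFrame:
    """Preranked GSEA over a gene-set collection.

    ``ranked`` is the output of :func:`rank_statistic`. Sets are
    intersected with the ranked universe and filtered to
    [``min_size``, ``max_size``]. p-values are two-sided on |ES| by
    gene-label permutation with add-one correction (minimum attainable p is
    1/(n+1)); the permutation count doubles adaptively until the exceedance
    count is resolved or the cap is hit. Adjusted p is BH across tested
    sets.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    genes = ranked["gene_symbol"].to_numpy()
    stats_r = ranked["stat"].to_numpy(dtype=float)
    index = {g: i for i, g in enumerate(genes)}
    N = genes.size
    rng = np.random.default_rng(seed)
    rows = []
    perm_cache: dict[int, np.ndarray] = {}
    for name in sorted(sets):
        members = sets[name]
        pos = np.array(sorted(index[g] for g in members if g in index))
        k = pos.size
        if k == 0:
            log.info("set %s has empty intersection with the universe; skipped",
                     name)
            continue
        if k < min_size or k > max_size or k >= N:
            log.debug("set %s size %d outside [%d, %d]; skipped",
                      name, k, min_size, min(max_size, N - 1))
            continue
        es, ext_idx = enrichment_score(stats_r, pos, weight_exp)
        # adaptive permutation: grow until the exceedance count is resolved
        perms = perm_cache.get(k)
        if perms is None:
            perms = _perm_es(stats_r, k, n_perm, rng, weight_exp)
        while True:
            count = int((np.abs(perms) >= abs(es)).sum())
            if count >= MIN_EXCEEDANCES or perms.size >= PERMUTATION_CAP:
                break
            extra = _perm_es(stats_r, k, perms.size, rng, weight_exp)
            perms = np.concatenate([perms, extra])
        perm_cache[k] = perms
        p = (1.0 + count) / (1.0 + perms.size)
        same_sign = perms[np.sign(perms) == np.sign(es)] if es != 0 else perms
        nes = es / np.abs(same_sign).mean() if same_sign.size else np.nan
        spos = np.sort(pos)
        if es >= 0:
            lead = spos[: ext_idx + 1]
        else:
            lead = spos[ext_idx:]
        rows.append(
            {
                "set_name": name,
                "size": k,
                "ES": es,
                "NES": nes,
                "p_value": p,
                "leading_edge": ";".join(genes[lead]),
                "n_perm_used": perms.size,
            }
        )
    table = pd.DataFrame(rows)
    if not table.empty:
        from .dpe import adjust_bh

        table["adj_p_value"] = adjust_bh(table["p_value"].to_numpy())
    return table


@dataclass
class EnrichmentResult:
    """Enrichment table plus the ranked list it was computed from."""

    table: pd.DataFrame
    ranked: pd.DataFrame


def leading_edge_frequency(
    enr: pd.DataFrame, alpha: float = 0.05, min_count: int = 0
) -> pd.Series:
    """Count, per gene, the significant sets whose leading edge contains it.

    Returns genes with count strictly greater than ``min_count``, sorted by
    descending count then gene name.
    """
    sig = enr[enr["adj_p_value"] < alpha]
    counts: dict[str, int] = {}
    for edge in sig["leading_edge"]:
        for g in str(edge).split(";"):
            if g:
                counts[g] = counts.get(g, 0) + 1
    series = pd.Series(counts, dtype=int, name="n_leading_edges")
    series = series[series > min_count]
    series = series.sort_index(kind="mergesort")
    return series.sort_values(ascending=False, kind="mergesort")


def ora_hypergeometric(
    hits: list[str], background: list[str], sets: GeneSetCollection
) -> pd.DataFrame:
    """Hypergeometric over-representation of a hit list against gene sets.

    The background is the measured (pre-filtered) protein universe; every
    hit must belong to it. Per set, the upper-tail probability of drawing
    at least the observed overlap; BH across sets.
    """
    bg = set(background)
    stray = [h for h in hits if h not in bg]
    if stray:
        raise ValueError(f"hits not in background: {sorted(stray)}")
    hit_set = set(hits)
    N, n = len(bg), len(hit_set)
    rows = []
    for name in sorted(sets):
        K = len(sets[name] & bg)
        if K == 0:
            continue
        k = len(sets[name] & hit_set)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set_name": name, "overlap": k, "set_in_background": K,
                     "p_value": p})
    table = pd.DataFrame(rows)
    if not table.empty:
        from .dpe import adjust_bh

        table["adj_p_value"] = adjust_bh(table["p_value"].to_numpy())
    return table


def cohens_kappa(a: np.ndarray, b: np.ndarray) -> float:
    """Chance-corrected agreement of two binary membership vectors."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    n = a.size
    po = float((a == b).sum()) / n
    p_yes = (a.sum() / n) * (b.sum() / n)
    p_no = ((n - a.sum()) / n) * ((n - b.sum()) / n)
    pe = p_yes + p_no
    if 1.0 - pe < 1e-12:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1.0 - pe)


@dataclass
class KappaClustering:
    """Result of iterative kappa merging of redundant gene sets."""

    clusters: list  # list of lists of original set names
    representatives: list  # one original set name per cluster
    max_residual_kappa: float
    merged_sets: GeneSetCollection = None

    def __post_init__(self) -> None:
        flat = [name for cl in self.clusters for name in cl]
        if len(flat) != len(set(flat)):
            raise ValueError("clusters must partition the input sets")


def kappa_simplify(
    sets: GeneSetCollection, universe: list[str], kappa_max: float = 0.4
) -> KappaClustering:
    """Merge gene sets until no pair agrees with Cohen's kappa > threshold.

    Sets are binary membership vectors over ``universe``. The pair with
    maximal kappa merges (union membership, cluster labels concatenated)
    while that kappa strictly exceeds ``kappa_max``; each merge reduces the
    set count by one, so termination is guaranteed. The representative of a
    cluster is its largest original member set (ties break
    lexicographically).
    """
    if len(universe) == 0:
        raise ValueError("empty universe")
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    uni = pd.Index(sorted(set(universe)))
    names = sorted(sets)
    M = np.zeros((len(names), len(uni)), dtype=bool)
    for i, name in enumerate(names):
        M[i] = uni.isin(sorted(sets[name]))
    clusters: list[list[str]] = [[n] for n in names]
    orig_sizes = {n: int(M[i].sum()) for i, n in enumerate(names)}

    def pairwise_kappa(mat: np.ndarray) -> np.ndarray:
        m, n = mat.shape
        f = mat.astype(float)
        n11 = f @ f.T
        s = f.sum(axis=1)
        n10 = s[:, None] - n11
        n01 = s[None, :] - n11
        n00 = n - n11 - n10 - n01
        po = (n11 + n00) / n
        pe = (s[:, None] / n) * (s[None, :] / n) + (
            (n - s[:, None]) / n
        ) * ((n - s[None, :]) / n)
        with np.errstate(invalid="ignore", divide="ignore"):
            kap = (po - pe) / (1.0 - pe)
        kap = np.where(1.0 - pe < 1e-12, np.where(po >= 1.0, 1.0, 0.0), kap)
        np.fill_diagonal(kap, -np.inf)
        return kap

    while M.shape[0] > 1:
        kap = pairwise_kappa(M)
        i, j = np.unravel_index(np.argmax(kap), kap.shape)
        if kap[i, j] <= kappa_max:
            break
        a, b = min(i, j), max(i, j)
        M[a] = M[a] | M[b]
        clusters[a] = clusters[a] + clusters[b]
        M = np.delete(M, b, axis=0)
        del clusters[b]

    residual = float(np.max(pairwise_kappa(M))) if M.shape[0] > 1 else -np.inf
    reps = []
    merged = {}
    for ci, cl in enumerate(clusters):
        rep = sorted(cl, key=lambda n: (-orig_sizes[n], n))[0]
        reps.append(rep)
        merged["|".join(sorted(cl))] = sorted(uni[M[ci]])
    return KappaClustering(
        clusters=[sorted(cl) for cl in clusters],
        representatives=reps,
        max_residual_kappa=residual,
        merged_sets=GeneSetCollection(merged, source=sets.source),
    )
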