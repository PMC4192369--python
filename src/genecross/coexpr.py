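"""Coexpression guilt-by-association and a minimal eQTL scan.

The guilt-by-association chain: (1) keep only the probes of a focal gene
that are mutually concordant (pairwise Pearson r >= 0.5 at p <= 0.05), so
probes that do not track the transcript are excluded; (2) for each
concordant probe, rank every other probe on the array by correlation and
take the top K; (3) intersect the per-probe top-K lists and map surviving
probes to genes; (4) score the intersection against chance with a
permutation test of random K-subsets, and score the overlap of two gene
lists from different resources against a common gene universe with both a
permutation and an exact hypergeometric tail.

The eQTL scan maps an expression trait across the marker map with a
max-statistic permutation threshold and classifies the peak as cis
(colocalized with the gene) or trans (significant elsewhere).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synth import marker_pvalues

log = logging.getLogger(__name__)

__all__ = [
    "OverlapTest",
    "EqtlScanResult",
    "probe_concordance",
    "top_k_correlates",
    "intersect_lists",
    "intersection_sizes",
    "multi_list_overlap_p",
    "two_set_overlap_p",
    "eqtl_scan",
]


@dataclass
class OverlapTest:
    set_sizes: tuple[int, ...]
    universe: int
    observed: int
    n_perm: int
    p_emp: float
    seed: int
    exact_p: float | None = None


@dataclass
class EqtlScanResult:
    marker_p: pd.DataFrame
    peak_marker: str
    peak_p: float
    threshold: float
    classification: str  # cis | trans | none
    cis_window_bp: int
    n_perm: int = 0
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Probe concordance

def _pearson_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Pearson r via the t-transform with n-2 df."""
    r = np.clip(r, -0.9999999999, 0.9999999999)
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def probe_concordance(
    expr: pd.DataFrame,
    probes: pd.DataFrame,
    gene_id: str,
    r_min: float = 0.5,
    p_max: float = 0.05,
):
    """Mutually concordant probe set of a gene, plus the pairwise table.

    Builds the graph whose edges are probe pairs with Pearson r >= ``r_min``
    and correlation-test p <= ``p_max``, then greedily grows a clique from
    the highest-degree probe (ties by probe id), at each step adding the
    highest-degree probe adjacent to every member. Returns
    ``(probe_ids, pair_table, flag)`` where ``pair_table`` holds every
    pair's r and p and ``flag`` is ``"untestable"`` for single-probe genes,
    ``"singleton"`` when no pair passes, else ``"ok"``.
    """
    ids = probes.loc[probes["gene_id"] == gene_id, "probe_id"].tolist()
    if not ids:
        raise ValueError(f"gene {gene_id!r} has no probes")
    if len(ids) == 1:
        return ids, pd.DataFrame(columns=["probe_a", "probe_b", "r", "p"]), "untestable"

    x = expr.loc[ids].to_numpy(dtype=float)
    n = x.shape[1]
    r = np.corrcoef(x)
    p = _pearson_p(r, n)
    iu, ju = np.triu_indices(len(ids), k=1)
    pair_table = pd.DataFrame(
        {
            "probe_a": [ids[i] for i in iu],
            "probe_b": [ids[j] for j in ju],
            "r": r[iu, ju],
            "p": p[iu, ju],
        }
    )

    adj = (r >= r_min) & (p <= p_max)
    np.fill_diagonal(adj, False)
    degree = adj.sum(axis=1)
    if degree.max() == 0:
        # no concordant pair: report the lexicographically first probe alone
        return [sorted(ids)[0]], pair_table, "singleton"

    order = sorted(range(len(ids)), key=lambda i: (-degree[i], ids[i]))
    clique = [order[0]]
    for cand in order[1:]:
        if all(adj[cand, m] for m in clique):
            clique.append(cand)
    members = sorted(ids[i] for i in clique)
    return members, pair_table, "ok"


# ---------------------------------------------------------------------------
# Top-K correlate lists

def top_k_correlates(
    expr: pd.DataFrame, probe_id: str, k: int = 20_000, absolute: bool = False
) -> list[str]:
    """The ``k`` probes most correlated with the focal probe.

    Ranked by signed Pearson r descending (or |r| with ``absolute=True``),
    ties broken by probe id; the focal probe itself and zero-variance
    probes are excluded (the latter logged).
    """
    mat = expr.to_numpy(dtype=float)
    ids = expr.index.to_numpy()
    sd = mat.std(axis=1)
    dead = sd == 0
    if dead.any():
        log.warning("excluding %d zero-variance probe(s) from ranking", int(dead.sum()))
    focal_pos = np.flatnonzero(ids == probe_id)
    if focal_pos.size == 0:
        raise ValueError(f"probe {probe_id!r} not in matrix")
    keep = ~dead
    keep[focal_pos[0]] = False
    if k > keep.sum():
        raise ValueError(f"k={k} exceeds the {int(keep.sum())} rankable probes")

    f = mat[focal_pos[0]]
    fz = (f - f.mean()) / f.std()
    sub = mat[keep]
    sz = (sub - sub.mean(axis=1, keepdims=True)) / sub.std(axis=1, keepdims=True)
    r = sz @ fz / len(fz)
    score = np.abs(r) if absolute else r
    sub_ids = ids[keep]
    order = np.lexsort((sub_ids, -score))
    return sub_ids[order[:k]].tolist()


def intersect_lists(lists: list[list[str]], probes: pd.DataFrame | None = None):
    """Exact intersection of >= 2 probe lists, optionally mapped to genes.

    Returns ``(common_probes, genes)``; ``genes`` deduplicates multiple
    probes of one gene and is None when no annotation is given.
    """
    if len(lists) < 2:
        raise ValueError("need at least two lists")
    common = set(lists[0])
    for lst in lists[1:]:
        common &= set(lst)
    common = sorted(common)
    genes = None
    if probes is not None:
        gmap = probes.set_index("probe_id")["gene_id"]
        genes = sorted(set(gmap.loc[[p for p in common if p in gmap.index]]))
    return common, genes


# ---------------------------------------------------------------------------
# Overlap permutation tests

def intersection_sizes(
    n_lists: int, k: int, N: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Simulated intersection sizes of ``n_lists`` random k-subsets of [N].

    Sequential conditional draws: I1 = k, then I_{j+1} ~
    Hypergeom(N, I_j, k) — the size of a fresh random k-subset's overlap
    with the running intersection. Distribution-identical to sampling the
    subsets explicitly, at O(n_lists) per replicate.
    """
    inter = np.full(n_perm, k, dtype=np.int64)
    for _ in range(n_lists - 1):
        live = inter > 0
        draw = np.zeros_like(inter)
        if live.any():
            draw[live] = rng.hypergeometric(inter[live], N - inter[live], k)
        inter = draw
    return inter


def multi_list_overlap_p(
    n_lists: int,
    k: int,
    N: int,
    observed: int,
    n_perm: int = 1_000_000,
    seed: int = 0,
    plus_one: bool = True,
) -> OverlapTest:
    """How often do ``n_lists`` random k-subsets of [N] share >= ``observed``?

    The intersection size of sequential random subsets is simulated by
    conditional hypergeometric draws — I1 = k, then
    I_{j+1} ~ Hypergeom(N, I_j, k) — which has exactly the distribution of
    intersecting explicitly sampled subsets, at O(n_lists) cost per
    replicate.
    """
    if k > N:
        raise ValueError("k must be <= N")
    if observed > k:
        raise ValueError("observed must be <= k")
    rng = np.random.default_rng(seed)
    inter = intersection_sizes(n_lists, k, N, n_perm, rng)
    exceed = int(np.count_nonzero(inter >= observed))
    p = (exceed + 1) / (n_perm + 1) if plus_one else max(exceed / n_perm, 0.0)
    p = p if p > 0 else 1.0 / (n_perm + 1)
    return OverlapTest((k,) * n_lists, N, observed, n_perm, float(p), seed)


def two_set_overlap_p(
    nA: int,
    nB: int,
    N: int,
    observed: int,
    n_perm: int = 1_000_000,
    seed: int = 0,
    plus_one: bool = True,
) -> OverlapTest:
    """Significance of the overlap of two gene sets in a common universe.

    Permutation p (random nA- and nB-subsets of [N], one hypergeometric
    draw per replicate) plus the exact upper tail
    P(X >= observed), X ~ Hypergeom(N, nA, nB).
    """
    if nA > N or nB > N:
        raise ValueError("set sizes must be <= N")
    if observed > min(nA, nB):
        raise ValueError("observed overlap cannot exceed the smaller set")
    rng = np.random.default_rng(seed)
    draws = rng.hypergeometric(nA, N - nA, nB, size=n_perm)
    exceed = int(np.count_nonzero(draws >= observed))
    p = (exceed + 1) / (n_perm + 1) if plus_one else exceed / n_perm
    p = p if p > 0 else 1.0 / (n_perm + 1)
    exact = float(stats.hypergeom.sf(observed - 1, N, nA, nB))
    return OverlapTest((nA, nB), N, observed, n_perm, float(p), seed, exact_p=exact)


# ---------------------------------------------------------------------------
# eQTL scan

def eqtl_scan(
    expr_trait: np.ndarray,
    genotypes: np.ndarray,
    markers: pd.DataFrame,
    gene_location: tuple[str, int],
    cis_window_bp: int = 10_000_000,
    n_perm: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
) -> EqtlScanResult:
    """Map an expression trait across the genome and classify the peak.

    Per-marker association is the Welch two-group comparison of the trait
    by marker genotype. The genome-wide threshold is the ``alpha`` quantile
    of the minimum p-value over ``n_perm`` strain-label permutations
    (max-statistic control of the familywise error rate). The peak is
    ``cis`` when significant and within ``cis_window_bp`` of the gene on
    its chromosome, ``trans`` when significant elsewhere, ``none``
    otherwise.
    """
    expr_trait = np.asarray(expr_trait, dtype=float)
    p = marker_pvalues(genotypes, expr_trait)
    tab = markers[["chrom", "pos_bp", "marker_id"]].copy()
    tab["p"] = p

    rng = np.random.default_rng(seed)
    null_min = np.empty(n_perm)
    for i in range(n_perm):
        null_min[i] = marker_pvalues(genotypes, rng.permutation(expr_trait)).min()
    threshold = float(np.quantile(null_min, alpha))

    peak_idx = int(np.argmin(p))
    peak = tab.iloc[peak_idx]
    gene_chrom, gene_pos = gene_location
    if peak["p"] > threshold:
        cls = "none"
    elif peak["chrom"] == gene_chrom and abs(int(peak["pos_bp"]) - int(gene_pos)) <= cis_window_bp:
        cls = "cis"
    else:
        cls = "trans"
    return EqtlScanResult(
        marker_p=tab,
        peak_marker=str(peak["marker_id"]),
        peak_p=float(peak["p"]),
        threshold=threshold,
        classification=cls,
        cis_window_bp=cis_window_bp,
        n_perm=n_perm,
    )
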