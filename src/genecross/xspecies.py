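"""Cross-species concordance: are mouse-significant genes associated in human?

Three complementary tests, all operating on the homology-joined table of
per-gene p-values:

* genomic-control lambda of the mouse-significant genes' human p-values,
  with a permutation null built from random gene sets of the same size
  (lambda > 1 would indicate collective inflation of human significance);
* the rank-rank hypergeometric overlap (RRHO) test, a threshold-free scan
  of the overlap between the tops of the two ranked lists over a grid of
  rank-threshold pairs, familywise-corrected by a max-statistic
  permutation;
* Bonferroni-corrected single-gene lookup: a mouse-significant gene is a
  cross-species hit if its human p-value clears alpha divided by the
  number of mouse-significant genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "LambdaResult",
    "RRHOResult",
    "join_homologs",
    "genomic_lambda",
    "lambda_perm_test",
    "rrho_test",
    "bonferroni_overlap",
    "qq_table",
]

# median of the 1-df chi-squared distribution
CHI2_1DF_MEDIAN = float(stats.chi2.isf(0.5, df=1))


@dataclass
class LambdaResult:
    lambda_obs: float
    n_set: int
    n_perm: int
    p_perm: float
    seed: int


@dataclass
class RRHOResult:
    step: int
    logp_map: np.ndarray
    max_logp: float
    p_fwer: float
    n_perm: int
    seed: int


def join_homologs(
    human: pd.DataFrame, mouse: pd.DataFrame, homology: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Join human and mouse gene p-values through the homology map.

    Duplicate mappings (a human or mouse gene appearing in several pairs)
    are resolved by keeping the pair with the smallest human p-value; the
    discarded pairs are logged. Returns the joined table
    (``human_gene_id, mouse_gene_id, p_human, p_mouse``) and a stats dict
    with ``n_human_total, n_mapped, coverage``.
    """
    j = homology.merge(
        human[["gene_id", "p"]].rename(columns={"gene_id": "human_gene_id", "p": "p_human"}),
        on="human_gene_id",
    ).merge(
        mouse[["gene_id", "p"]].rename(columns={"gene_id": "mouse_gene_id", "p": "p_mouse"}),
        on="mouse_gene_id",
    )
    before = len(j)
    j = j.sort_values(["p_human", "human_gene_id"], kind="stable")
    j = j.drop_duplicates("human_gene_id").drop_duplicates("mouse_gene_id")
    if len(j) < before:
        log.warning("dropped %d duplicate homology pair(s), kept smallest human p", before - len(j))
    if j.empty:
        raise ValueError("homology join produced no rows")
    n_total = human["gene_id"].nunique()
    info = {
        "n_human_total": int(n_total),
        "n_mapped": int(len(j)),
        "coverage": len(j) / n_total,
    }
    return j.reset_index(drop=True), info


def genomic_lambda(p_values) -> float:
    """Genomic-control inflation factor (median convention).

    lambda = median(Q(p_i)) / Q(0.5) with Q the upper-tail 1-df chi-squared
    quantile; lambda = 1 for a uniform p-value sample, > 1 under inflation.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value input")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return float(np.median(stats.chi2.isf(p, df=1)) / CHI2_1DF_MEDIAN)


def lambda_perm_test(
    joined: pd.DataFrame,
    test_set: list[str],
    n_perm: int = 100_000,
    seed: int = 0,
    strict: bool = True,
    plus_one: bool = False,
    set_column: str = "mouse_gene_id",
    p_column: str = "p_human",
) -> LambdaResult:
    """Permutation p-value for the lambda of a gene set's human p-values.

    The observed lambda uses the human p-values of ``test_set`` (ids in
    ``set_column`` of the joined table). Each permutation draws the same
    number of genes uniformly without replacement from the whole joined
    table and recomputes lambda. ``strict=True`` counts permutations with
    lambda strictly greater than observed and divides by ``n_perm``;
    ``plus_one`` switches to the (r+1)/(n+1) estimator.
    """
    test_set = list(test_set)
    if len(test_set) < 2:
        raise ValueError("test_set must contain >= 2 genes")
    in_table = set(joined[set_column])
    missing = [g for g in test_set if g not in in_table]
    if missing:
        raise ValueError(f"test_set genes absent from joined table: {missing[:5]}")

    p_all = joined[p_column].to_numpy(dtype=float)
    chi_all = stats.chi2.isf(p_all, df=1)
    mask = joined[set_column].isin(test_set).to_numpy()
    lam_obs = float(np.median(chi_all[mask]) / CHI2_1DF_MEDIAN)

    rng = np.random.default_rng(seed)
    k = len(test_set)
    m = chi_all.size
    exceed = 0
    done = 0
    batch = max(1, 2_000_000 // m)  # uniform k-subsets via random-key argpartition
    while done < n_perm:
        b = min(batch, n_perm - done)
        keys = rng.random((b, m))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        lams = np.median(chi_all[idx], axis=1) / CHI2_1DF_MEDIAN
        exceed += int((lams > lam_obs).sum()) if strict else int((lams >= lam_obs).sum())
        done += b
    p_perm = (exceed + 1) / (n_perm + 1) if plus_one else exceed / n_perm
    p_perm = max(p_perm, 1.0 / (n_perm + 1))  # keep in (0, 1]
    return LambdaResult(lam_obs, k, n_perm, float(p_perm), seed)


def _rrho_max_logp(rank_b_of_a_sorted: np.ndarray, n: int, step: int):
    """max -log10 hypergeometric upper-tail p over the rank-threshold grid.

    ``rank_b_of_a_sorted``: for genes sorted by list-A rank, their 0-based
    rank in list B. Overlap counts at every (i*step, j*step) cell come from
    a 2-D histogram of the (A-rank, B-rank) pairs, cumulated over both axes.
    """
    edges = np.arange(0, n + step, step, dtype=float)
    a_rank = np.arange(n)
    hist, _, _ = np.histogram2d(a_rank, rank_b_of_a_sorted, bins=(edges, edges))
    overlap = hist.cumsum(axis=0).cumsum(axis=1)  # overlap[i,j] = |topA(i+1)s ∩ topB(j+1)s|
    ii = np.minimum(edges[1:], n)
    kk = overlap
    na = ii[:, None]
    nb = ii[None, :]
    # P(X >= k), X ~ Hypergeom(N=n, K=na, n=nb)
    logp = -np.log10(np.clip(stats.hypergeom.sf(kk - 1, n, na, nb), 1e-320, None))
    return logp, float(logp.max())


def rrho_test(
    scores_a: pd.Series,
    scores_b: pd.Series,
    step: int | None = None,
    n_perm: int = 200,
    seed: int = 0,
) -> RRHOResult:
    """Rank-rank hypergeometric overlap test of two per-gene score lists.

    Both inputs are indexed by gene id over the same universe and ranked
    ascending (small p = strong). The familywise-corrected p-value is the
    fraction of permutations (random shufflings of list B's ranks, list A
    held fixed) whose maximal -log10 hypergeometric overlap p meets or
    exceeds the observed one.
    """
    if set(scores_a.index) != set(scores_b.index):
        raise ValueError("score lists must share one gene universe")
    if scores_a.isna().any() or scores_b.isna().any():
        raise ValueError("missing values in score lists")
    n = len(scores_a)
    if step is None:
        step = max(1, n // 100)
    if step >= n:
        raise ValueError("step must be smaller than the universe size")

    rank_a = scores_a.rank(method="first").astype(int) - 1
    rank_b = scores_b.reindex(scores_a.index).rank(method="first").astype(int) - 1
    order = np.argsort(rank_a.to_numpy())
    b_of_a = rank_b.to_numpy()[order]

    logp_map, max_obs = _rrho_max_logp(b_of_a, n, step)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        _, mx = _rrho_max_logp(rng.permutation(n), n, step)
        exceed += mx >= max_obs
    p_fwer = (exceed + 1) / (n_perm + 1)
    return RRHOResult(step, logp_map, max_obs, p_fwer, n_perm, seed)


def bonferroni_overlap(
    mouse_sig: list[str],
    human: pd.DataFrame,
    alpha: float = 0.05,
    gene_column: str = "gene_id",
    p_column: str = "p",
) -> tuple[list[str], float]:
    """Cross-species hits among ``mouse_sig`` at the Bonferroni threshold.

    threshold = alpha / |mouse_sig|; hits are the genes of ``mouse_sig``
    present in the human table with p <= threshold, sorted by p.
    """
    if not mouse_sig:
        raise ValueError("mouse_sig must be non-empty")
    threshold = alpha / len(mouse_sig)
    sub = human[human[gene_column].isin(mouse_sig)]
    hit = sub.loc[sub[p_column] <= threshold].sort_values([p_column, gene_column], kind="stable")
    return hit[gene_column].tolist(), threshold


def qq_table(p_values) -> pd.DataFrame:
    """Expected vs observed -log10 p quantiles for a QQ plot."""
    p = np.sort(np.asarray(p_values, dtype=float))
    n = p.size
    expected = (np.arange(1, n + 1) - 0.5) / n
    return pd.DataFrame(
        {"expected_neglog10": -np.log10(expected), "observed_neglog10": -np.log10(p)}
    )
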