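"""Gene-level p-values from a marker-level QTL scan by positional interpolation.

A single-marker QTL scan yields one p-value per genotyped marker. To
compare with gene-based human results, each gene is assigned an estimated
p-value by linear interpolation on the raw p scale between the two markers
flanking the gene's start position: a gene halfway between markers with
p = 0.02 and p = 0.04 gets p = 0.03. Genes outside the marker range are
clamped to the nearest marker (extrapolation could leave (0, 1]).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["interpolate_gene_p", "select_significant"]


def _check_markers(markers: pd.DataFrame) -> None:
    for chrom, grp in markers.groupby("chrom", sort=False):
        pos = grp["pos_bp"].to_numpy()
        if not (np.diff(pos) > 0).all():
            raise ValueError(f"marker positions not strictly increasing on {chrom}")


def interpolate_gene_p(markers: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Interpolate per-gene p-values from the marker map.

    Parameters
    ----------
    markers : DataFrame with columns ``chrom, pos_bp, marker_id, p``,
        sorted by (chrom, pos_bp) within chromosome.
    genes : DataFrame with columns ``gene_id, chrom, start_bp, end_bp``.
        The gene's start position is the interpolation anchor.

    Returns
    -------
    DataFrame with columns ``gene_id, chrom, anchor_bp, p, method`` where
    ``method`` is one of ``interpolated``, ``at-marker``, ``clamped-left``,
    ``clamped-right``.

    Raises
    ------
    ValueError if a gene's chromosome has no markers.
    """
    markers = markers.sort_values(["chrom", "pos_bp"], kind="stable")
    _check_markers(markers)
    by_chrom = {c: g for c, g in markers.groupby("chrom", sort=False)}

    missing = set(genes["chrom"]) - set(by_chrom)
    if missing:
        raise ValueError(f"no markers on chromosome(s): {sorted(missing)}")

    out = []
    for chrom, grp in genes.groupby("chrom", sort=False):
        mk = by_chrom[chrom]
        pos = mk["pos_bp"].to_numpy(dtype=float)
        pv = mk["p"].to_numpy(dtype=float)
        x = grp["start_bp"].to_numpy(dtype=float)
        if len(pos) < 2:
            log.warning("chromosome %s has <2 markers; clamping all genes to it", chrom)
        # np.interp is linear between knots and clamps at the ends,
        # exactly the interpolation rule used here
        p = np.interp(x, pos, pv)
        method = np.where(
            np.isin(x, pos),
            "at-marker",
            np.where(x < pos[0], "clamped-left",
                     np.where(x > pos[-1], "clamped-right", "interpolated")),
        )
        out.append(
            pd.DataFrame(
                {
                    "gene_id": grp["gene_id"].to_numpy(),
                    "chrom": chrom,
                    "anchor_bp": grp["start_bp"].to_numpy(),
                    "p": p,
                    "method": method,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def select_significant(table: pd.DataFrame, alpha: float = 0.05) -> list[str]:
    """Genes with p <= alpha, sorted by p ascending (ties by gene id)."""
    if table.empty:
        raise ValueError("empty gene p-value table")
    hit = table.loc[table["p"] <= alpha, ["gene_id", "p"]]
    hit = hit.sort_values(["p", "gene_id"], kind="stable")
    return hit["gene_id"].tolist()
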