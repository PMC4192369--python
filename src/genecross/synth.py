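"""Seeded synthetic data with the statistical structure the pipeline assumes.

Emulates, at desk scale, the three substrates of a cross-species gene
prioritization study:

* a biparental recombinant-inbred (RI) mouse cross with a planted QTL —
  two-allele homozygous genotypes with Markov recombination along each
  chromosome and a quantitative phenotype driven by one marker;
* human GWAS summary statistics with block-structured linkage
  disequilibrium (LD) and a planted causal gene, plus the genotype panel
  from which SNP-SNP correlation can be recomputed;
* an exon-array-like expression matrix (probes x strains) with a planted
  coexpression module and, for a focal gene, a mixture of concordant and
  non-concordant probes.

All generators are deterministic given their spec and seed, and return a
truth record sufficient to score recovery downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "CrossSimSpec",
    "GwasSimSpec",
    "ExprSimSpec",
    "gen_genes",
    "gen_cross",
    "gen_gwas",
    "gen_homology",
    "gen_expression",
    "marker_pvalues",
]


# ---------------------------------------------------------------------------
# Specs

@dataclass
class CrossSimSpec:
    """Parameters of the simulated RI cross.

    ``n_strains`` defaults to 37 (an RI panel of 35 lines plus the two
    parental strains). Genotypes are coded 0/1: RI lines are fully inbred,
    so only the two homozygous states occur. ``qtl_effect`` is the mean
    phenotype difference between genotype groups in units of ``noise_sd``
    when ``noise_sd`` is 1.
    """

    n_strains: int = 37
    n_chrom: int = 5
    markers_per_chrom: int = 30
    recomb_prob: float = 0.2
    qtl_marker: int = 0
    qtl_effect: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0
    genes_per_chrom: int = 12
    marker_spacing_bp: int = 500_000
    gene_length_bp: int = 20_000
    marker_stat: str = "nominal"  # or "genomewide"
    n_perm_gw: int = 500

    def __post_init__(self) -> None:
        if self.n_strains < 3:
            raise ValueError("n_strains must be >= 3")
        if not 0.0 <= self.recomb_prob <= 0.5:
            raise ValueError("recomb_prob must be in [0, 0.5]")
        n_markers = self.n_chrom * self.markers_per_chrom
        if not 0 <= self.qtl_marker < n_markers:
            raise ValueError(f"qtl_marker {self.qtl_marker} out of range [0, {n_markers})")
        if self.marker_stat not in ("nominal", "genomewide"):
            raise ValueError("marker_stat must be 'nominal' or 'genomewide'")


@dataclass
class GwasSimSpec:
    """Parameters of the simulated GWAS summary statistics.

    LD is blockwise-exchangeable: dosage correlation ``within_block_r``
    between any two SNPs in a block, zero between blocks. The phenotype is
    driven by one SNP inside ``causal_gene`` with slope ``causal_beta`` on
    the standardized dosage.
    """

    n_individuals: int = 1000
    n_blocks: int = 12
    snps_per_block: int = 10
    within_block_r: float = 0.7
    causal_gene: str | None = None
    causal_beta: float = 0.0
    maf_range: tuple[float, float] = (0.1, 0.5)
    seed: int = 0
    window_bp: int = 50_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.within_block_r < 1.0:
            raise ValueError("within_block_r must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")


@dataclass
class ExprSimSpec:
    """Parameters of the simulated exon-array expression matrix.

    Probes of genes in ``module_genes`` load on one shared latent factor
    with loading sqrt(``module_r``), so any two module probes correlate at
    ``module_r`` in expectation. The focal gene (lexicographically first
    module gene) additionally receives ``n_noise_probes`` probes of
    independent noise, emulating intron/UTR probes that do not track the
    gene's expression.
    """

    n_strains: int = 70
    n_genes: int = 200
    probes_per_gene: int | tuple[int, int] = (2, 4)
    module_genes: frozenset[str] = field(default_factory=frozenset)
    module_r: float = 0.85
    n_noise_probes: int = 11
    focal_probes: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.module_r < 1.0:
            raise ValueError("module_r must be in [0, 1)")
        lo, hi = self._probe_range()
        if lo < 1:
            raise ValueError("probes_per_gene must be >= 1")
        if self.n_strains < 4:
            raise ValueError("n_strains must be >= 4 (correlation p-values degenerate below)")

    def _probe_range(self) -> tuple[int, int]:
        if isinstance(self.probes_per_gene, int):
            return self.probes_per_gene, self.probes_per_gene
        lo, hi = self.probes_per_gene
        return int(lo), int(hi)


# ---------------------------------------------------------------------------
# Gene tables

def gen_genes(
    n_genes: int,
    n_chrom: int,
    span_bp: int,
    gene_length_bp: int = 20_000,
    prefix: str = "G",
    chrom_prefix: str = "chr",
) -> pd.DataFrame:
    """Evenly place ``n_genes`` non-overlapping genes across ``n_chrom`` chromosomes.

    Coordinates are 1-based inclusive. Returns columns
    ``gene_id, chrom, start_bp, end_bp``.
    """
    per = int(np.ceil(n_genes / n_chrom))
    rows = []
    i = 0
    for c in range(1, n_chrom + 1):
        for j in range(per):
            if i >= n_genes:
                break
            start = 1 + int(round((j + 0.5) * span_bp / per))
            rows.append(
                {
                    "gene_id": f"{prefix}{i:04d}",
                    "chrom": f"{chrom_prefix}{c}",
                    "start_bp": start,
                    "end_bp": start + gene_length_bp - 1,
                }
            )
            i += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# RI cross

def marker_pvalues(genotypes: np.ndarray, phenotype: np.ndarray) -> np.ndarray:
    """Per-marker Welch two-group p-values of ``phenotype`` split by genotype.

    Vectorized across markers. Monomorphic markers (or a genotype group of
    fewer than 2 strains, where the within-group variance is undefined)
    get p = 1 with a logged warning: such markers carry no mapping
    information.
    """
    g = np.asarray(genotypes, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    n = y.size
    n1 = g.sum(axis=0)
    n0 = n - n1
    testable = (n0 >= 2) & (n1 >= 2)
    if not testable.all():
        log.warning(
            "%d marker(s) monomorphic or near-monomorphic; p-value recorded as 1",
            int((~testable).sum()),
        )
    p = np.ones(g.shape[1])
    if not testable.any():
        return p
    with np.errstate(divide="ignore", invalid="ignore"):
        s1 = y @ g
        q1 = (y * y) @ g
        m1 = s1 / n1
        m0 = (y.sum() - s1) / n0
        v1 = (q1 - n1 * m1 * m1) / (n1 - 1)
        v0 = ((y * y).sum() - q1 - n0 * m0 * m0) / (n0 - 1)
        se2 = v0 / n0 + v1 / n1
        t = (m0 - m1) / np.sqrt(se2)
        df = se2 * se2 / ((v0 / n0) ** 2 / (n0 - 1) + (v1 / n1) ** 2 / (n1 - 1))
    idx = np.flatnonzero(testable & (se2 > 0))
    p[idx] = 2.0 * stats.t.sf(np.abs(t[idx]), df=df[idx])
    return p


def gen_cross(spec: CrossSimSpec):
    """Simulate an RI cross and its single-marker QTL scan.

    Returns ``(markers, genes, genotypes, phenotype, truth)`` where
    ``markers`` has columns ``chrom, pos_bp, marker_id, p`` (the marker map
    with per-marker scan p-values), ``genes`` is a mouse gene table,
    ``genotypes`` is strains x markers in {0, 1}, and ``truth`` records the
    planted marker and the gene nearest to it.
    """
    rng = np.random.default_rng(spec.seed)
    n_m = spec.n_chrom * spec.markers_per_chrom

    geno = np.empty((spec.n_strains, n_m), dtype=np.int8)
    for c in range(spec.n_chrom):
        sl = slice(c * spec.markers_per_chrom, (c + 1) * spec.markers_per_chrom)
        block = np.empty((spec.n_strains, spec.markers_per_chrom), dtype=np.int8)
        block[:, 0] = rng.random(spec.n_strains) < 0.5
        # Markov chain along the chromosome: flip with prob recomb_prob
        flips = rng.random((spec.n_strains, spec.markers_per_chrom - 1)) < spec.recomb_prob
        for k in range(1, spec.markers_per_chrom):
            block[:, k] = block[:, k - 1] ^ flips[:, k - 1]
        geno[:, sl] = block

    g_qtl = geno[:, spec.qtl_marker].astype(float)
    phenotype = spec.qtl_effect * g_qtl + spec.noise_sd * rng.standard_normal(spec.n_strains)

    p = marker_pvalues(geno, phenotype)
    if spec.marker_stat == "genomewide":
        # family-wise (max-statistic) adjustment, as interval-mapping scans
        # report: adjusted p_j = share of phenotype permutations whose
        # genome-wide minimum nominal p is <= nominal p_j
        null_min = np.empty(spec.n_perm_gw)
        for i in range(spec.n_perm_gw):
            null_min[i] = marker_pvalues(geno, rng.permutation(phenotype)).min()
        p = (np.searchsorted(np.sort(null_min), p, side="right") + 1) / (spec.n_perm_gw + 1)
    chroms = np.repeat(
        [f"chr{c}" for c in range(1, spec.n_chrom + 1)], spec.markers_per_chrom
    )
    pos = np.tile(
        (np.arange(spec.markers_per_chrom) + 1) * spec.marker_spacing_bp, spec.n_chrom
    )
    markers = pd.DataFrame(
        {
            "chrom": chroms,
            "pos_bp": pos,
            "marker_id": [f"{c}_mk{i % spec.markers_per_chrom:03d}" for i, c in enumerate(chroms)],
            "p": p,
        }
    )

    span = (spec.markers_per_chrom + 1) * spec.marker_spacing_bp
    genes = gen_genes(
        spec.genes_per_chrom * spec.n_chrom,
        spec.n_chrom,
        span,
        gene_length_bp=spec.gene_length_bp,
        prefix="MG",
    )

    qtl_chrom = markers["chrom"].iloc[spec.qtl_marker]
    qtl_pos = int(markers["pos_bp"].iloc[spec.qtl_marker])
    same = genes[genes["chrom"] == qtl_chrom]
    nearest = same.iloc[(same["start_bp"] - qtl_pos).abs().argmin()]
    truth = {
        "qtl_marker": int(spec.qtl_marker),
        "qtl_marker_id": markers["marker_id"].iloc[spec.qtl_marker],
        "qtl_chrom": qtl_chrom,
        "qtl_pos_bp": qtl_pos,
        "qtl_effect": float(spec.qtl_effect),
        "nearest_gene": nearest["gene_id"],
    }
    return markers, genes, geno, phenotype, truth


# ---------------------------------------------------------------------------
# GWAS summary statistics

def gen_gwas(spec: GwasSimSpec, genes: pd.DataFrame):
    """Simulate LD-blocked genotypes, a phenotype, and single-SNP p-values.

    Within a block every haplotype allele copies a block-ancestral allele
    with probability sqrt(r) and is otherwise an independent Bernoulli(maf)
    draw, which gives pairwise dosage correlation r within the block and
    zero between blocks. Returns ``(snps, panel, truth)``: the summary
    table (``snp_id, chrom, pos_bp, p``), the individuals x SNP dosage
    panel (DataFrame, columns = SNP ids), and the truth record.
    """
    rng = np.random.default_rng(spec.seed)
    n_snps = spec.n_blocks * spec.snps_per_block

    # each LD block sits on one gene (cycling through the gene table), its
    # SNPs spread over the gene body +/- half the assignment window, so
    # gene-level SNP coverage is guaranteed once n_blocks >= n_genes
    gsort = genes.sort_values(["chrom", "start_bp"], kind="stable").reset_index(drop=True)
    snp_chrom, snp_pos = [], []
    for b in range(spec.n_blocks):
        grow = gsort.iloc[b % len(gsort)]
        lo_bp = max(1, int(grow["start_bp"]) - spec.window_bp // 2)
        hi_bp = int(grow["end_bp"]) + spec.window_bp // 2
        pos = np.linspace(lo_bp, hi_bp, spec.snps_per_block).round().astype(int)
        snp_chrom.extend([grow["chrom"]] * spec.snps_per_block)
        snp_pos.extend(pos.tolist())
    snp_pos = np.asarray(snp_pos)
    snp_ids = np.array([f"rs{i:05d}" for i in range(n_snps)])

    s = np.sqrt(spec.within_block_r)
    dosage = np.empty((spec.n_individuals, n_snps), dtype=np.int8)
    lo, hi = spec.maf_range
    for b in range(spec.n_blocks):
        sl = slice(b * spec.snps_per_block, (b + 1) * spec.snps_per_block)
        f = rng.uniform(lo, hi)
        # two haplotypes per individual, each with a block-ancestral allele
        anc = rng.random((spec.n_individuals, 2)) < f
        own = rng.random((spec.n_individuals, 2, spec.snps_per_block)) < f
        copy = rng.random((spec.n_individuals, 2, spec.snps_per_block)) < s
        hap = np.where(copy, anc[:, :, None], own)
        dosage[:, sl] = hap.sum(axis=1)

    # drop monomorphic SNPs (no association information, break correlation)
    poly = dosage.std(axis=0) > 0
    if not poly.all():
        log.warning("dropping %d monomorphic SNP(s)", int((~poly).sum()))
    dosage, snp_ids = dosage[:, poly], snp_ids[poly]
    snp_chrom = [c for c, keep in zip(snp_chrom, poly) if keep]
    snp_pos = snp_pos[poly]

    causal_snp = None
    y = rng.standard_normal(spec.n_individuals)
    if spec.causal_gene is not None:
        grow = genes.loc[genes["gene_id"] == spec.causal_gene]
        if grow.empty:
            raise ValueError(f"causal gene {spec.causal_gene!r} not in gene table")
        grow = grow.iloc[0]
        inside = (
            (np.asarray(snp_chrom) == grow["chrom"])
            & (snp_pos >= grow["start_bp"] - spec.window_bp)
            & (snp_pos <= grow["end_bp"] + spec.window_bp)
        )
        idx = np.flatnonzero(inside)
        if idx.size == 0:
            raise ValueError(
                f"no SNPs within +/-{spec.window_bp} bp of causal gene {spec.causal_gene!r}"
            )
        causal_idx = int(idx[idx.size // 2])
        causal_snp = str(snp_ids[causal_idx])
        g = dosage[:, causal_idx].astype(float)
        y = spec.causal_beta * (g - g.mean()) / g.std() + rng.standard_normal(spec.n_individuals)

    # single-SNP regression p via the correlation t-statistic
    x = dosage.astype(float)
    x = (x - x.mean(axis=0)) / x.std(axis=0)
    r = (x * ((y - y.mean()) / y.std())[:, None]).mean(axis=0)
    n = spec.n_individuals
    t = r * np.sqrt((n - 2) / np.clip(1.0 - r * r, 1e-12, None))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)

    snps = pd.DataFrame({"snp_id": snp_ids, "chrom": snp_chrom, "pos_bp": snp_pos, "p": p})
    panel = pd.DataFrame(dosage, columns=snp_ids)
    truth = {
        "causal_gene": spec.causal_gene,
        "causal_snp": causal_snp,
        "causal_beta": float(spec.causal_beta),
    }
    return snps, panel, truth


# ---------------------------------------------------------------------------
# Homology

def gen_homology(
    genes_h: pd.DataFrame,
    genes_m: pd.DataFrame,
    coverage: float = 0.883,
    seed: int = 0,
    include: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """A one-to-one human-to-mouse homology map over a random gene subset.

    ``coverage`` is the fraction of human genes with a mouse homologue
    (default 0.883, the coverage typical of curated homology databases for
    a genome-wide human set). ``include`` forces specific
    (human_gene, mouse_gene) pairs into the map, e.g. a planted causal
    pair. Returns columns ``human_gene_id, mouse_gene_id``.
    """
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must be in (0, 1]")
    rng = np.random.default_rng(seed)
    h_ids = list(genes_h["gene_id"])
    m_ids = list(genes_m["gene_id"])
    n_pairs = int(round(coverage * len(h_ids)))

    forced = list(include or [])
    used_h = {h for h, _ in forced}
    used_m = {m for _, m in forced}
    pool_h = [g for g in h_ids if g not in used_h]
    pool_m = [g for g in m_ids if g not in used_m]
    n_extra = max(0, min(n_pairs - len(forced), len(pool_h), len(pool_m)))
    pick_h = rng.choice(len(pool_h), size=n_extra, replace=False)
    pick_m = rng.permutation(len(pool_m))[:n_extra]
    pairs = forced + [(pool_h[i], pool_m[j]) for i, j in zip(sorted(pick_h), pick_m)]
    return pd.DataFrame(pairs, columns=["human_gene_id", "mouse_gene_id"])


# ---------------------------------------------------------------------------
# Expression matrix

_CONC_CLASSES = ["exon", "exon", "exon", "exon", "utr5", "utr3"]


def gen_expression(
    spec: ExprSimSpec,
    gene_ids: list[str] | None = None,
    focal: str | None = None,
    module_factor: np.ndarray | None = None,
):
    """Simulate a probes x strains expression matrix with a planted module.

    Returns ``(expr, probes)``: a DataFrame indexed by probe id with strain
    columns (each probe standardized across strains), and the probe
    annotation table (``probe_id, gene_id, target_class``). The focal gene
    (first module gene sorted, unless given explicitly) gets
    ``focal_probes`` concordant probes plus ``n_noise_probes`` independent
    noise probes, emulating an exon array where only the exon/UTR probes
    track the transcript. ``module_factor`` replaces the latent module
    expression (standardized internally); passing a genotype-derived vector
    plants an eQTL for every module gene.
    """
    rng = np.random.default_rng(spec.seed)
    if gene_ids is None:
        gene_ids = [f"G{i:04d}" for i in range(spec.n_genes)]
    if len(gene_ids) != spec.n_genes:
        raise ValueError("gene_ids length must equal n_genes")
    module = sorted(spec.module_genes)
    unknown = set(module) - set(gene_ids)
    if unknown:
        raise ValueError(f"module genes not in gene universe: {sorted(unknown)}")
    if focal is None:
        focal = module[0] if module else None
    elif focal not in spec.module_genes:
        raise ValueError("focal gene must be a module gene")

    if module_factor is None:
        f_mod = rng.standard_normal(spec.n_strains)
    else:
        f_mod = np.asarray(module_factor, dtype=float)
        if f_mod.size != spec.n_strains:
            raise ValueError("module_factor length must equal n_strains")
        f_mod = (f_mod - f_mod.mean()) / max(f_mod.std(), 1e-12)
    lo, hi = spec._probe_range()
    load = np.sqrt(spec.module_r)

    rows, ann = [], []
    k = 0
    for g in gene_ids:
        in_module = g in spec.module_genes
        n_conc = spec.focal_probes if g == focal else int(rng.integers(lo, hi + 1))
        for j in range(n_conc):
            eps = rng.standard_normal(spec.n_strains)
            x = load * f_mod + np.sqrt(1.0 - spec.module_r) * eps if in_module else eps
            cls = _CONC_CLASSES[j % len(_CONC_CLASSES)]
            rows.append(x)
            ann.append((f"pb{k:06d}", g, cls))
            k += 1
        if g == focal:
            for _ in range(spec.n_noise_probes):
                rows.append(rng.standard_normal(spec.n_strains))
                ann.append((f"pb{k:06d}", g, "intron"))
                k += 1

    mat = np.asarray(rows)
    mat = (mat - mat.mean(axis=1, keepdims=True)) / mat.std(axis=1, keepdims=True)
    probes = pd.DataFrame(ann, columns=["probe_id", "gene_id", "target_class"])
    expr = pd.DataFrame(mat, index=probes["probe_id"].to_numpy(),
                        columns=[f"strain{s:03d}" for s in range(spec.n_strains)])
    expr.index.name = "probe_id"
    return expr, probes
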