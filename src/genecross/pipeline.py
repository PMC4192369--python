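"""End-to-end orchestration: simulate -> mouse -> human -> cross-species -> coexpression.

Every stage reads its inputs from files written by the previous stage and
writes its own outputs before the next stage starts, so a run can be
restarted at any stage boundary. All randomness flows from one global seed
through named per-stage substreams (see :mod:`genecross._rng`), so a stage
re-run in isolation reproduces exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, coexpr, human_assoc, io, mouse_qtl, synth, xspecies
from ._rng import spawn_seed, substream

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    ``mode`` is ``simulate`` (write synthetic inputs only), ``analyze``
    (inputs must already exist in ``outdir``) or ``full``. ``shared_signal``
    plants the SAME gene as the mouse QTL driver, the human causal gene and
    the coexpression focal gene; with ``False`` every planted effect is
    kept but no cross-species correspondence exists (the null pipeline).
    """

    outdir: str = "run"
    seed: int = 0
    mode: str = "full"
    shared_signal: bool = True

    # simulation scale
    cross: dict = field(default_factory=dict)       # CrossSimSpec overrides
    gwas: dict = field(default_factory=dict)        # GwasSimSpec overrides
    expr: dict = field(default_factory=dict)        # ExprSimSpec overrides
    homology_coverage: float = 0.883
    module_size: int = 8
    external_list_size: int = 20

    # analysis parameters
    alpha: float = 0.05
    window_bp: int = 50_000
    gene_sims: int = 2_000
    lambda_perms: int = 10_000
    rrho_perms: int = 200
    overlap_perms: int = 100_000
    top_k: int = 40
    r_min: float = 0.5
    p_max: float = 0.05
    cis_window_bp: int = 10_000_000
    eqtl_perms: int = 200

    def path(self, name: str) -> Path:
        return Path(self.outdir) / name


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML config file; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return RunConfig(**raw)


# ---------------------------------------------------------------------------
# Stages

def stage_simulate(cfg: RunConfig) -> dict:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)

    cross_kwargs = dict(cfg.cross)
    # interval-mapping scans report genome-wide significance; gene selection
    # at alpha then stays specific to the planted QTL's chromosome. The
    # tighter linkage emulates a dense RI marker map, where the significant
    # region spans several genes.
    cross_kwargs.setdefault("marker_stat", "genomewide")
    cross_kwargs.setdefault("recomb_prob", 0.05)
    cross_spec = synth.CrossSimSpec(seed=spawn_seed(cfg.seed, "cross"), **cross_kwargs)
    if "qtl_marker" not in cfg.cross:
        # plant the QTL mid-chromosome-1 so it sits among genes
        cross_spec.qtl_marker = cross_spec.markers_per_chrom // 2
    markers, genes_m, geno, pheno, cross_truth = synth.gen_cross(cross_spec)
    planted_mouse = cross_truth["nearest_gene"]

    genes_h = synth.gen_genes(
        len(genes_m),
        cross_spec.n_chrom,
        (cross_spec.markers_per_chrom + 1) * cross_spec.marker_spacing_bp,
        gene_length_bp=cross_spec.gene_length_bp,
        prefix="HG",
    )

    rng = substream(cfg.seed, "plant")
    if cfg.shared_signal:
        # the human causal gene is the homologue of the planted mouse gene
        planted_human = genes_h["gene_id"].iloc[
            int(genes_m.index[genes_m["gene_id"] == planted_mouse][0])
        ]
        include = [(planted_human, planted_mouse)]
    else:
        planted_human = str(rng.choice(genes_h["gene_id"].to_numpy()))
        include = None

    gwas_kwargs = dict(cfg.gwas)
    gwas_kwargs.setdefault("n_blocks", len(genes_h))  # one LD block per gene
    gwas_spec = synth.GwasSimSpec(
        seed=spawn_seed(cfg.seed, "gwas"), causal_gene=planted_human, **gwas_kwargs
    )
    snps, panel, gwas_truth = synth.gen_gwas(gwas_spec, genes_h)

    homology = synth.gen_homology(
        genes_h, genes_m, coverage=cfg.homology_coverage,
        seed=spawn_seed(cfg.seed, "homology"), include=include,
    )

    # coexpression module around the planted mouse gene (shared runs) or a
    # random gene (null runs)
    all_m = list(genes_m["gene_id"])
    focal = planted_mouse if cfg.shared_signal else str(rng.choice(all_m))
    others = [g for g in all_m if g != focal]
    module = sorted([focal] + list(rng.choice(others, size=cfg.module_size - 1, replace=False)))
    expr_kwargs = dict(cfg.expr)
    expr_kwargs.setdefault("n_strains", cross_spec.n_strains)
    expr_spec = synth.ExprSimSpec(
        n_genes=len(all_m),
        module_genes=frozenset(module),
        seed=spawn_seed(cfg.seed, "expr"),
        **expr_kwargs,
    )
    # drive the module factor by the planted QTL genotype -> cis-eQTL at
    # the QTL marker for every module gene, in particular the focal one
    g_qtl = geno[:, cross_truth["qtl_marker"]].astype(float)
    expr, probes = synth.gen_expression(
        expr_spec, gene_ids=all_m, focal=focal, module_factor=g_qtl
    )

    # external coexpression resource: module genes plus random extras
    extra = [g for g in all_m if g not in set(module)]
    n_extra = max(0, cfg.external_list_size - len(module))
    external = sorted(set(module) | set(rng.choice(extra, size=n_extra, replace=False)))

    io.write_table(markers, out / "markers.tsv")
    io.write_table(genes_m, out / "genes_mouse.tsv")
    io.write_table(genes_h, out / "genes_human.tsv")
    io.write_table(pd.DataFrame(geno, columns=markers["marker_id"]), out / "geno_mouse.tsv")
    io.write_table(pd.DataFrame({"strain": range(len(pheno)), "phenotype": pheno}),
                   out / "phenotype.tsv")
    io.write_table(snps, out / "snps.tsv")
    io.write_table(panel, out / "panel.tsv")
    io.write_table(homology, out / "homology.tsv")
    io.write_table(expr, out / "expr.tsv", index=True)
    io.write_table(probes, out / "probes.tsv")
    (out / "external_genes.txt").write_text("\n".join(external) + "\n")
    truth = {
        "cross": cross_truth,
        "gwas": gwas_truth,
        "planted_mouse_gene": planted_mouse,
        "planted_human_gene": planted_human,
        "shared_signal": cfg.shared_signal,
        "module_genes": module,
        "focal_gene": focal,
        "external_list": external,
    }
    io.write_json(truth, out / "truth.json")
    return {
        "n_markers": len(markers),
        "n_genes_mouse": len(genes_m),
        "n_genes_human": len(genes_h),
        "n_snps": len(snps),
        "n_probes": len(probes),
        "planted_mouse_gene": planted_mouse,
        "planted_human_gene": planted_human,
    }


def stage_mouse(cfg: RunConfig) -> dict:
    markers = io.read_table(cfg.path("markers.tsv"), "markers")
    genes = io.read_table(cfg.path("genes_mouse.tsv"), "genes")
    table = mouse_qtl.interpolate_gene_p(markers, genes)
    io.write_table(table, cfg.path("gene_p_mouse.tsv"))
    sig = mouse_qtl.select_significant(table, alpha=cfg.alpha)
    return {"n_genes": len(table), "n_significant": len(sig), "significant": sig}


def stage_human(cfg: RunConfig) -> dict:
    snps = io.read_table(cfg.path("snps.tsv"), "snps")
    genes = io.read_table(cfg.path("genes_human.tsv"), "genes")
    panel = pd.read_csv(cfg.path("panel.tsv"), sep="\t")
    table = human_assoc.gene_based_scan(
        snps, genes, panel, window_bp=cfg.window_bp, n_sims=cfg.gene_sims,
        seed=spawn_seed(cfg.seed, "human_assoc"),
    )
    io.write_table(table, cfg.path("gene_p_human.tsv"))
    tested = table.dropna(subset=["p_emp"])
    return {"n_genes": len(table), "n_tested": int(len(tested))}


def stage_xspecies(cfg: RunConfig) -> dict:
    mouse = io.read_table(cfg.path("gene_p_mouse.tsv"), "gene_p")
    human = io.read_table(cfg.path("gene_p_human.tsv"), "gene_p_human")
    homology = io.read_table(cfg.path("homology.tsv"), "homology")
    human_p = human.dropna(subset=["p_emp"]).rename(columns={"p_emp": "p"})

    joined, join_info = xspecies.join_homologs(human_p, mouse, homology)
    mouse_sig = mouse_qtl.select_significant(mouse, alpha=cfg.alpha)
    mapped_sig = [g for g in mouse_sig if g in set(joined["mouse_gene_id"])]

    report: dict = {"join": join_info, "n_mouse_significant": len(mouse_sig),
                    "n_mapped_significant": len(mapped_sig)}
    if len(mapped_sig) >= 2:
        lam = xspecies.lambda_perm_test(
            joined, mapped_sig, n_perm=cfg.lambda_perms,
            seed=spawn_seed(cfg.seed, "lambda"),
        )
        report["lambda_obs"] = lam.lambda_obs
        report["lambda_p_perm"] = lam.p_perm
        qq = xspecies.qq_table(joined.loc[joined["mouse_gene_id"].isin(mapped_sig), "p_human"])
        io.write_table(qq, cfg.path("qq_table.tsv"))

    scores_a = joined.set_index("mouse_gene_id")["p_mouse"]
    scores_b = joined.set_index("mouse_gene_id")["p_human"]
    rr = xspecies.rrho_test(scores_a, scores_b, n_perm=cfg.rrho_perms,
                            seed=spawn_seed(cfg.seed, "rrho"))
    report["rrho_max_logp"] = rr.max_logp
    report["rrho_p_fwer"] = rr.p_fwer

    if mapped_sig:
        htab = joined.rename(columns={"mouse_gene_id": "gene_id", "p_human": "p"})
        hits, threshold = xspecies.bonferroni_overlap(mapped_sig, htab, alpha=cfg.alpha)
        h_of_m = joined.set_index("mouse_gene_id")["human_gene_id"]
        report["bonferroni_threshold"] = threshold
        report["hits"] = [{"mouse_gene": g, "human_gene": h_of_m[g]} for g in hits]
    io.write_json(report, cfg.path("xspecies_report.json"))
    return report


def stage_coexpr(cfg: RunConfig) -> dict:
    expr = io.read_table(cfg.path("expr.tsv"), "expr")
    probes = io.read_table(cfg.path("probes.tsv"), "probes")
    markers = io.read_table(cfg.path("markers.tsv"), "markers")
    genes_m = io.read_table(cfg.path("genes_mouse.tsv"), "genes")
    geno = pd.read_csv(cfg.path("geno_mouse.tsv"), sep="\t").to_numpy()
    with open(cfg.path("truth.json")) as fh:
        truth = json.load(fh)
    focal = truth["focal_gene"]
    external = truth["external_list"]

    conc, pair_table, flag = coexpr.probe_concordance(
        expr, probes, focal, r_min=cfg.r_min, p_max=cfg.p_max
    )
    io.write_table(pair_table, cfg.path("probe_pairs.tsv"))

    n_probes = len(expr)
    k = min(cfg.top_k, n_probes - 1)
    lists = [coexpr.top_k_correlates(expr, pb, k=k) for pb in conc]
    report: dict = {"focal_gene": focal, "concordant_probes": conc, "concordance_flag": flag,
                    "top_k": k, "n_probes": n_probes}
    if len(lists) >= 2:
        common, common_genes = coexpr.intersect_lists(lists, probes)
        ov = coexpr.multi_list_overlap_p(
            len(lists), k, n_probes, len(common), n_perm=cfg.overlap_perms,
            seed=spawn_seed(cfg.seed, "multi_overlap"),
        )
        report["n_common_probes"] = len(common)
        report["n_common_genes"] = len(common_genes)
        report["multi_list_p"] = ov.p_emp
        io.write_gmt(
            {"coexpressed_with_focal": (f"genes coexpressed with {focal}", common_genes)},
            cfg.path("coexpr_sets.gmt"),
        )
        universe = probes["gene_id"].nunique()
        observed = len(set(external) & set(common_genes))
        two = coexpr.two_set_overlap_p(
            len(external), len(common_genes), universe, observed,
            n_perm=cfg.overlap_perms, seed=spawn_seed(cfg.seed, "two_overlap"),
        )
        report["external_overlap"] = {
            "nA": len(external), "nB": len(common_genes), "universe": universe,
            "observed": observed, "p_emp": two.p_emp, "exact_p": two.exact_p,
        }

    # eQTL of the focal gene's expression (mean of concordant probes)
    trait = expr.loc[conc].mean(axis=0).to_numpy()
    grow = genes_m.set_index("gene_id").loc[focal]
    scan = coexpr.eqtl_scan(
        trait, geno, markers, (grow["chrom"], int(grow["start_bp"])),
        cis_window_bp=cfg.cis_window_bp, n_perm=cfg.eqtl_perms,
        seed=spawn_seed(cfg.seed, "eqtl"),
    )
    io.write_table(scan.marker_p, cfg.path("eqtl_scan.tsv"))
    report["eqtl"] = {
        "peak_marker": scan.peak_marker,
        "peak_p": scan.peak_p,
        "threshold": scan.threshold,
        "classification": scan.classification,
    }
    io.write_json(report, cfg.path("coexpr_report.json"))
    return report


_STAGES = [
    ("simulate", stage_simulate),
    ("mouse", stage_mouse),
    ("human", stage_human),
    ("xspecies", stage_xspecies),
    ("coexpr", stage_coexpr),
]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages in order; halt on error with a partial report."""
    if cfg.mode not in ("simulate", "analyze", "full"):
        raise ValueError(f"unknown mode {cfg.mode!r}")
    todo = [s for s in _STAGES
            if (cfg.mode != "simulate" or s[0] == "simulate")
            and (cfg.mode != "analyze" or s[0] != "simulate")]
    report: dict = {
        "version": __version__,
        "config": dataclasses.asdict(cfg),
        "stages": {},
        "wall_clock_s": {},
    }
    for name, fn in todo:
        t0 = time.perf_counter()
        try:
            report["stages"][name] = fn(cfg)
        except Exception as e:  # halt with partial report
            report["stages"][name] = {"error": f"{type(e).__name__}: {e}"}
            report["halted_at"] = name
            log.error("stage %s failed: %s", name, e)
            break
        finally:
            report["wall_clock_s"][name] = round(time.perf_counter() - t0, 3)
    io.write_json(report, cfg.path("run_report.json"))
    return report
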