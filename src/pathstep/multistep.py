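"""Single-step and multistep (pathway-then-gene) testing procedures.

The single-step procedure applies a gene-based set test genome-wide at
a genome-wide alpha.  The multistep procedure first tests each pathway
(the union of its genes' variants, one very large set) at the pathway
alpha; only inside pathways flagged significant does it then test each
member gene, at either 0.05 / (genes in the pathway) (conventional) or
a flat 0.05 (liberal).  A gene is *jointly* significant when both its
pathway and the gene itself pass.  Both procedures share one null-model
fit per phenotype replicate — every test is a score test against the
identical null.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .lmm import FamilialLMMResults
from .settests import (BURDEN_DEFAULT_WEIGHTS, VC_DEFAULT_WEIGHTS)

__all__ = ["AlphaConfig", "MultistepResult", "run_single_step",
           "run_multistep", "METHODS"]

METHODS = ("VC", "Burden")


@dataclass(frozen=True)
class AlphaConfig:
    """Alpha schedule for the two procedures.

    conventional: 1e-6 single-step gene tests, 5e-4 pathway tests,
    0.05 / (genes in pathway) for within-pathway gene tests.
    liberal: 5e-3 single-step, 0.05 pathway, flat 0.05 gene tests.
    """

    mode: str
    single_step_gene_alpha: float
    pathway_alpha: float
    gene_rule: str                      # bonferroni_within_pathway | fixed
    gene_alpha: float = 0.05

    def __post_init__(self):
        for a in (self.single_step_gene_alpha, self.pathway_alpha,
                  self.gene_alpha):
            if not (0.0 < a < 1.0):
                raise ValueError("alphas must lie in (0, 1)")
        if self.gene_rule not in ("bonferroni_within_pathway", "fixed"):
            raise ValueError(f"unknown gene rule {self.gene_rule!r}")

    @classmethod
    def conventional(cls) -> "AlphaConfig":
        return cls("conventional", 1e-6, 5e-4, "bonferroni_within_pathway")

    @classmethod
    def liberal(cls) -> "AlphaConfig":
        return cls("liberal", 5e-3, 0.05, "fixed")

    def within_pathway_threshold(self, n_genes: int) -> float:
        if self.gene_rule == "bonferroni_within_pathway":
            return self.gene_alpha / n_genes
        return self.gene_alpha


@dataclass
class MultistepResult:
    """Step-1 pathway table plus step-2 gene table (flagged pathways only)."""

    pathway_table: pd.DataFrame
    gene_table: pd.DataFrame
    pathway_method: str
    gene_method: str

    @property
    def tag(self) -> str:
        return f"{self.pathway_method}-{self.gene_method}"


def _run_set(fit: FamilialLMMResults, genotypes, variant_ids, method,
             set_id, ids=None):
    G = genotypes.columns(variant_ids)
    mafs = genotypes.sample_mafs(variant_ids)
    gm_ids = genotypes.ids if ids is None else ids
    if method == "VC":
        return fit.vc_test(G, mafs=mafs, weights=VC_DEFAULT_WEIGHTS,
                           set_id=set_id, ids=gm_ids)
    if method == "Burden":
        return fit.burden_test(G, mafs=mafs, weights=BURDEN_DEFAULT_WEIGHTS,
                               set_id=set_id, ids=gm_ids)
    raise ValueError(f"unknown method {method!r}")


def run_single_step(gene_sets, fit: FamilialLMMResults, genotypes,
                    method: str, alpha_cfg: AlphaConfig) -> pd.DataFrame:
    """Gene-based tests genome-wide at the single-step alpha.

    Untestable genes (all variants monomorphic) are reported with
    ``untestable=True`` and are never significant.
    """
    rows = []
    for gs in gene_sets:
        r = _run_set(fit, genotypes, list(gs.variant_ids), method,
                     gs.gene_id)
        rows.append({
            "set_id": gs.gene_id, "method": method,
            "n_variants": r.n_variants_tested, "Q": r.statistic,
            "p": r.p_value, "pvalue_method": r.pvalue_method,
            "untestable": r.untestable,
            "significant": (not r.untestable
                            and r.p_value < alpha_cfg.single_step_gene_alpha),
        })
    return pd.DataFrame(rows)


def run_multistep(pathways, gene_sets, fit: FamilialLMMResults, genotypes,
                  pathway_method: str, gene_method: str,
                  alpha_cfg: AlphaConfig,
                  force_step2: bool = False) -> MultistepResult:
    """Pathway tests, then gene tests inside significant pathways.

    ``force_step2`` computes gene tests in every pathway for
    diagnostics; joint significance still requires the pathway flag.
    Genes listed in no supplied pathway are excluded (the caller is
    warned through the gene table simply not containing them).
    """
    genes_by_id = {g.gene_id: g for g in gene_sets}
    prow, grow = [], []
    for pw in pathways:
        r = _run_set(fit, genotypes, list(pw.variant_ids), pathway_method,
                     pw.pathway_id)
        pw_sig = not r.untestable and r.p_value < alpha_cfg.pathway_alpha
        prow.append({
            "pathway_id": pw.pathway_id, "method": pathway_method,
            "n_genes": len(pw.gene_ids), "n_variants": r.n_variants_tested,
            "Q": r.statistic, "p": r.p_value,
            "pvalue_method": r.pvalue_method, "untestable": r.untestable,
            "significant": pw_sig,
        })
        if not (pw_sig or force_step2):
            continue
        thr = alpha_cfg.within_pathway_threshold(len(pw.gene_ids))
        for gid in pw.gene_ids:
            gs = genes_by_id.get(gid)
            if gs is None:
                continue
            g = _run_set(fit, genotypes, list(gs.variant_ids), gene_method,
                         gid)
            g_sig = not g.untestable and g.p_value < thr
            grow.append({
                "gene_id": gid, "pathway_id": pw.pathway_id,
                "method": gene_method, "n_variants": g.n_variants_tested,
                "Q": g.statistic, "p": g.p_value,
                "pvalue_method": g.pvalue_method, "untestable": g.untestable,
                "gene_significant": g_sig,
                "pathway_significant": pw_sig,
                "joint_significant": bool(pw_sig and g_sig),
            })
    gene_cols = ["gene_id", "pathway_id", "method", "n_variants", "Q", "p",
                 "pvalue_method", "untestable", "gene_significant",
                 "pathway_significant", "joint_significant"]
    return MultistepResult(
        pathway_table=pd.DataFrame(prow),
        gene_table=(pd.DataFrame(grow, columns=gene_cols)),
        pathway_method=pathway_method, gene_method=gene_method)
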