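"""Empirical power and type-I error across phenotype replicates.

Power of a unit (gene or pathway) under a method is the proportion of
phenotype replicates in which it is significant; for the multistep
procedure the *joint* event (pathway and gene both significant) is the
primary definition, with the pathway-only proportion reported
separately.  Type-I error uses the identical machinery on the null
trait.  Exact Clopper-Pearson intervals accompany every proportion
because typical replicate counts (200) leave wide uncertainty.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from .cohort import (CohortConfig, GenotypeMatrix, simulate_null_trait,
                     simulate_phenotypes)
from .kinship import KinshipMatrix, compute_kinship
from .lmm import FamilialLMM
from .multistep import AlphaConfig, run_multistep, run_single_step
from .phenotypes import prepare_analysis_table

__all__ = ["clopper_pearson", "estimate_power", "estimate_type1",
           "compare_methods", "ReplicateStudy"]

DEFAULT_COVARIATES = ["sex", "mean_age", "ever_smoked"]


def clopper_pearson(k: int, n: int, level: float = 0.95):
    """Exact binomial confidence interval for a proportion."""
    a = 1.0 - level
    lo = 0.0 if k == 0 else float(beta_dist.ppf(a / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(beta_dist.isf(a / 2, k + 1, n - k))
    return lo, hi


def _summarize(df_long: pd.DataFrame, level: float) -> pd.DataFrame:
    alphas = df_long.groupby(["unit_id", "method"])["alpha_tag"].nunique() \
        if "alpha_tag" in df_long.columns else None
    if alphas is not None and (alphas > 1).any():
        raise ValueError("mixed alpha configurations across replicates")
    g = df_long.groupby(["unit_id", "method"], sort=True)["significant"]
    out = g.agg(n_replicates="count", n_significant="sum").reset_index()
    out["proportion"] = out["n_significant"] / out["n_replicates"]
    ci = [clopper_pearson(int(k), int(n), level)
          for k, n in zip(out["n_significant"], out["n_replicates"])]
    out["ci_low"] = [c[0] for c in ci]
    out["ci_high"] = [c[1] for c in ci]
    return out


def estimate_power(df_long: pd.DataFrame, causal_units=None,
                   level: float = 0.95) -> pd.DataFrame:
    """Per-unit empirical power table from long replicate results.

    ``df_long`` needs columns (replicate, unit_id, method, significant)
    — one row per unit per replicate.  When ``causal_units`` is given,
    only those units are kept (power is defined for causal units).
    """
    df = df_long
    if causal_units is not None:
        df = df[df["unit_id"].isin(set(causal_units))]
    return _summarize(df, level)


def estimate_type1(df_long: pd.DataFrame, level: float = 0.95):
    """Per-unit rejection rates on the null trait, plus the mean/SD
    summary of per-unit rates.

    Returns ``(table, summary)`` with summary keys "mean" and "sd".
    """
    table = _summarize(df_long, level)
    by_method = {}
    for method, sub in table.groupby("method"):
        by_method[method] = {"mean": float(sub["proportion"].mean()),
                             "sd": float(sub["proportion"].std(ddof=0))}
    return table, by_method


def compare_methods(single_table: pd.DataFrame,
                    multi_table: pd.DataFrame):
    """Per-gene single-step vs multistep power comparison.

    Both inputs are power tables from :func:`estimate_power` (one
    method each).  Genes present in only one table are excluded with a
    warning.  Returns ``(per_gene, aggregate)`` where aggregate holds
    the fraction of genes whose multistep power is at least the
    single-step power and the mean power gain.
    """
    import warnings

    s = single_table.set_index("unit_id")["proportion"]
    m = multi_table.set_index("unit_id")["proportion"]
    common = s.index.intersection(m.index)
    only = set(s.index).symmetric_difference(m.index)
    if only:
        warnings.warn(f"excluding {len(only)} unit(s) present in only one "
                      "table", stacklevel=2)
    per_gene = pd.DataFrame({
        "unit_id": common,
        "single_step_power": s.loc[common].to_numpy(),
        "multistep_power": m.loc[common].to_numpy(),
    })
    per_gene["difference"] = (per_gene["multistep_power"]
                              - per_gene["single_step_power"])
    aggregate = {
        "n_genes": int(len(per_gene)),
        "fraction_multistep_ge_single":
            float((per_gene["difference"] >= 0).mean()) if len(per_gene)
            else float("nan"),
        "mean_power_gain": float(per_gene["difference"].mean())
            if len(per_gene) else float("nan"),
    }
    return per_gene, aggregate


# ----------------------------------------------------------------------


class ReplicateStudy:
    """Runs the full pipeline over many phenotype replicates.

    Genotypes, pedigree, kinship and sets are fixed; each replicate
    simulates a phenotype (or the null trait), collapses it, refits the
    null model and applies the requested single-step methods and
    multistep method pairs.  The kinship eigendecomposition is computed
    once and shared by every fit.
    """

    def __init__(self, ped, genotypes: GenotypeMatrix, catalog,
                 gene_sets, pathways, config: CohortConfig,
                 alpha_cfg: AlphaConfig,
                 single_methods=("VC", "Burden"),
                 multistep_pairs=(("VC", "VC"), ("VC", "Burden"),
                                  ("Burden", "VC"), ("Burden", "Burden")),
                 covariates=None,
                 kin: KinshipMatrix | None = None):
        self.ped = ped
        self.genotypes = genotypes
        self.catalog = catalog
        self.gene_sets = list(gene_sets)
        self.pathways = list(pathways)
        self.config = config
        self.alpha_cfg = alpha_cfg
        self.single_methods = list(single_methods)
        self.multistep_pairs = [tuple(p) for p in multistep_pairs]
        self.covariates = (list(covariates) if covariates is not None
                           else list(DEFAULT_COVARIATES))
        self.kin = kin if kin is not None else compute_kinship(ped)

    # -- single replicate ----------------------------------------------

    def _fit_replicate(self, replicate: int, null_trait: bool):
        if null_trait:
            exams = simulate_null_trait(self.ped, self.config, replicate,
                                        kin=self.kin)
        else:
            exams = simulate_phenotypes(self.ped, self.genotypes,
                                        self.catalog, self.config,
                                        replicate, kin=self.kin)
        coll = prepare_analysis_table(exams)
        model = FamilialLMM.from_dataframe(coll, "mean_MAP",
                                           self.covariates, self.kin)
        return model.fit()

    def run_replicate(self, replicate: int, null_trait: bool = False):
        """All requested procedures on one replicate; returns long rows."""
        fit = self._fit_replicate(replicate, null_trait)
        rows = []
        for method in self.single_methods:
            tab = run_single_step(self.gene_sets, fit, self.genotypes,
                                  method, self.alpha_cfg)
            for r in tab.itertuples(index=False):
                rows.append((replicate, r.set_id, f"single:{method}",
                             bool(r.significant), r.p))
        pathway_methods_seen = set()
        for pm, gm in self.multistep_pairs:
            res = run_multistep(self.pathways, self.gene_sets, fit,
                                self.genotypes, pm, gm, self.alpha_cfg)
            tag = f"multi:{pm}-{gm}"
            if pm not in pathway_methods_seen:
                pathway_methods_seen.add(pm)
                for r in res.pathway_table.itertuples(index=False):
                    rows.append((replicate, r.pathway_id, f"pathway:{pm}",
                                 bool(r.significant), r.p))
            for r in res.gene_table.itertuples(index=False):
                rows.append((replicate, r.gene_id, tag,
                             bool(r.joint_significant), r.p))
            # genes in unflagged pathways: joint event did not occur
            tested = set(res.gene_table["gene_id"])
            for pw in self.pathways:
                for gid in pw.gene_ids:
                    if gid not in tested:
                        rows.append((replicate, gid, tag, False, np.nan))
        return rows

    # -- many replicates -----------------------------------------------

    def run(self, n_replicates: int | None = None, null_trait: bool = False,
            first_replicate: int = 0) -> pd.DataFrame:
        """Long table (replicate, unit_id, method, significant, p)."""
        n = n_replicates or self.config.n_replicates
        rows = []
        for rep in range(first_replicate, first_replicate + n):
            rows.extend(self.run_replicate(rep, null_trait=null_trait))
        df = pd.DataFrame(rows, columns=["replicate", "unit_id", "method",
                                         "significant", "p"])
        df["alpha_tag"] = self.alpha_cfg.mode
        return df

    # -- convenience ---------------------------------------------------

    @property
    def causal_genes(self) -> list[str]:
        return [g.gene_id for g in self.gene_sets if g.causal]

    @property
    def causal_pathways(self) -> list[str]:
        return [p.pathway_id for p in self.pathways if p.n_causal_genes > 0]
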