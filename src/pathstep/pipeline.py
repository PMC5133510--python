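"""End-to-end pipeline: simulate -> prep -> kinship -> fit -> test ->
evaluate, with a reproducibility manifest.

Every stage failure aborts with the stage name; rerunning with the same
configuration reproduces all numeric outputs bit-identically (all
randomness flows from the configured seeds).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import (CohortConfig, drop_genotypes, simulate_catalog,
                     simulate_pedigrees)
from .evaluation import ReplicateStudy, compare_methods, estimate_power, \
    estimate_type1
from .io import dump_yaml, sha256_of, write_vcf
from .kinship import compute_kinship
from .multistep import AlphaConfig
from .sets import PathwayDesign, build_gene_sets, build_synthetic_pathways, \
    write_gmt

__all__ = ["RunConfig", "StageError", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    alpha_mode: str = "liberal"              # liberal | conventional
    pathway_seed: int = 7
    n_replicates: int | None = None          # default: cohort.n_replicates
    n_null_replicates: int | None = None
    single_methods: tuple = ("VC", "Burden")
    multistep_pairs: tuple = (("VC", "VC"), ("VC", "Burden"),
                              ("Burden", "VC"), ("Burden", "Burden"))
    pathway_strata: list | None = None       # None -> auto-sized design

    def alpha_config(self) -> AlphaConfig:
        return (AlphaConfig.liberal() if self.alpha_mode == "liberal"
                else AlphaConfig.conventional())

    def to_dict(self) -> dict:
        return {
            "cohort": self.cohort.to_dict(),
            "alpha_mode": self.alpha_mode,
            "pathway_seed": self.pathway_seed,
            "n_replicates": self.n_replicates,
            "n_null_replicates": self.n_null_replicates,
            "single_methods": list(self.single_methods),
            "multistep_pairs": [list(p) for p in self.multistep_pairs],
            "pathway_strata": self.pathway_strata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d:
            d["cohort"] = CohortConfig.from_dict(d["cohort"])
        if "multistep_pairs" in d:
            d["multistep_pairs"] = tuple(tuple(p)
                                         for p in d["multistep_pairs"])
        if "single_methods" in d:
            d["single_methods"] = tuple(d["single_methods"])
        return cls(**d)


def _auto_design(gene_sets, strata) -> PathwayDesign:
    if strata is not None:
        return PathwayDesign(strata=[tuple(s) for s in strata])
    # scale a single stratum to the available causal genes: pathways of
    # 5 genes with 40% causal, as many as the causal pool allows
    n_causal = sum(1 for g in gene_sets if g.causal)
    n_non = sum(1 for g in gene_sets if not g.causal)
    n_pw = max(1, min(n_causal // 2, n_non // 3))
    return PathwayDesign(strata=[(5, 40, n_pw)])


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Run every stage and write outputs + manifest under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def stage(name, fn):
        try:
            return fn()
        except Exception as e:
            raise StageError(f"stage {name!r} failed: {e}") from e

    seed = config.cohort.seed

    def _simulate():
        ped = simulate_pedigrees(config.cohort)
        catalog = simulate_catalog(config.cohort)
        gm = drop_genotypes(ped, catalog, seed=seed)
        ped.to_fam(out / "pedigree.fam", header_comment=f"seed {seed}")
        catalog.write_tsv(out / "catalog.tsv", seed=seed)
        write_vcf(gm, catalog, out / "genotypes.vcf", seed=seed)
        gm.write_tsv(out / "genotypes.tsv", seed=seed)
        written.extend([out / "pedigree.fam", out / "catalog.tsv",
                        out / "genotypes.vcf", out / "genotypes.tsv"])
        return ped, catalog, gm

    ped, catalog, gm = stage("simulate", _simulate)

    def _kinship():
        kin = compute_kinship(ped)
        kin.write_tsv(out / "kinship.tsv", fmt="long")
        written.append(out / "kinship.tsv")
        return kin

    kin = stage("kinship", _kinship)

    def _sets():
        gene_sets = build_gene_sets(catalog)
        design = _auto_design(gene_sets, config.pathway_strata)
        pathways = build_synthetic_pathways(gene_sets, design,
                                            config.pathway_seed)
        write_gmt(gene_sets, out / "genes.gmt")
        write_gmt(pathways, out / "pathways.gmt")
        written.extend([out / "genes.gmt", out / "pathways.gmt"])
        return gene_sets, pathways

    gene_sets, pathways = stage("sets", _sets)

    alpha_cfg = config.alpha_config()
    study = ReplicateStudy(ped, gm, catalog, gene_sets, pathways,
                           config.cohort, alpha_cfg,
                           single_methods=config.single_methods,
                           multistep_pairs=config.multistep_pairs, kin=kin)

    n_rep = config.n_replicates or config.cohort.n_replicates
    n_null = config.n_null_replicates or n_rep

    def _test():
        long = study.run(n_rep)
        long.to_csv(out / "results_long.tsv", sep="\t", index=False)
        written.append(out / "results_long.tsv")
        return long

    long = stage("test", _test)

    def _null():
        nl = study.run(n_null, null_trait=True)
        nl.to_csv(out / "results_null_long.tsv", sep="\t", index=False)
        written.append(out / "results_null_long.tsv")
        return nl

    null_long = stage("null", _null)

    def _evaluate():
        causal = set(study.causal_genes) | set(study.causal_pathways)
        power = estimate_power(long, causal_units=causal)
        power.to_csv(out / "power_by_unit.tsv", sep="\t", index=False)
        t1_table, t1_summary = estimate_type1(null_long)
        t1_table.to_csv(out / "type1_by_unit.tsv", sep="\t", index=False)
        comps = []
        for pm, gmth in config.multistep_pairs:
            single = power[power["method"] == f"single:{gmth}"]
            multi = power[power["method"] == f"multi:{pm}-{gmth}"]
            if single.empty or multi.empty:
                continue
            per_gene, agg = compare_methods(single, multi)
            per_gene.insert(0, "comparison", f"{pm}-{gmth} vs {gmth}")
            comps.append((per_gene, {"comparison": f"{pm}-{gmth} vs {gmth}",
                                     **agg}))
        if comps:
            pd.concat([c[0] for c in comps]).to_csv(
                out / "comparison.tsv", sep="\t", index=False)
            written.append(out / "comparison.tsv")
        written.extend([out / "power_by_unit.tsv",
                        out / "type1_by_unit.tsv"])
        return {"type1_summary": t1_summary,
                "comparisons": [c[1] for c in comps]}

    summary = stage("evaluate", _evaluate)

    manifest = {
        "pathstep_version": __version__,
        "config": config.to_dict(),
        "alpha": {"mode": alpha_cfg.mode,
                  "single_step_gene_alpha": alpha_cfg.single_step_gene_alpha,
                  "pathway_alpha": alpha_cfg.pathway_alpha,
                  "gene_rule": alpha_cfg.gene_rule,
                  "gene_alpha": alpha_cfg.gene_alpha},
        "summary": summary,
        "checksums": {p.name: sha256_of(p) for p in written},
    }
    dump_yaml(manifest, out / "manifest.yaml")
    return out
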