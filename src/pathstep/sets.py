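"""Gene-level variant sets and synthetic pathway assembly.

Genes are variant sets defined by the annotation (one gene per
variant); pathways are mutually exclusive sets of genes built by
sampling without replacement from the gene pool, stratified by pathway
size and by the percentage of member genes that are causal.  A
pathway's variant set is the union of its member genes' variants, so a
single-stage pathway test treats the pathway as one very large variant
set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GeneSet", "PathwayDesign", "PathwaySet", "build_gene_sets",
           "build_synthetic_pathways", "read_gmt", "write_gmt"]


@dataclass(frozen=True)
class GeneSet:
    gene_id: str
    variant_ids: tuple
    causal: bool | None = None        # simulation truth when known

    def __post_init__(self):
        if not self.variant_ids:
            raise ValueError(f"gene set {self.gene_id!r} is empty")
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError(f"duplicate variants in gene {self.gene_id!r}")


@dataclass(frozen=True)
class PathwaySet:
    pathway_id: str
    gene_ids: tuple
    variant_ids: tuple
    n_causal_genes: int


@dataclass
class PathwayDesign:
    """Strata of (pathway size, percent causal, how many pathways).

    ``percent_causal * n_genes / 100`` must be an integer for every
    stratum.  Leftover genes are placed into non-causal filler
    pathways of ``filler_size`` genes.
    """

    strata: list = field(default_factory=list)   # (n_genes, pct, n_pathways)
    filler_size: int = 10

    def __post_init__(self):
        for n_genes, pct, n_pw in self.strata:
            if n_pw < 0:
                raise ValueError("stratum pathway count must be >= 0")
            k = pct * n_genes / 100.0
            if abs(k - round(k)) > 1e-9:
                raise ValueError(
                    f"stratum ({n_genes}, {pct}%): causal count "
                    f"{k} is not an integer")

    @classmethod
    def reference_design(cls) -> "PathwayDesign":
        """The size {5, 10} x percent-causal {20, 40, 60, 100} grid with
        15/11/10/5 pathways per cell — 82 causal-containing pathways."""
        strata = []
        for size in (5, 10):
            for pct, n_pw in zip((20, 40, 60, 100), (15, 11, 10, 5)):
                strata.append((size, pct, n_pw))
        return cls(strata=strata)

    def n_causal_genes_needed(self) -> int:
        return sum(n_pw * int(round(pct * ng / 100.0))
                   for ng, pct, n_pw in self.strata)

    def n_noncausal_genes_needed(self) -> int:
        return sum(n_pw * (ng - int(round(pct * ng / 100.0)))
                   for ng, pct, n_pw in self.strata)

    def n_pathways(self) -> int:
        return sum(n_pw for _, _, n_pw in self.strata)


def build_gene_sets(catalog) -> list[GeneSet]:
    """One GeneSet per distinct gene in a variant catalog/annotation.

    Accepts a VariantCatalog or a DataFrame with at least
    (variant_id, gene_id); causal flags come from ``effect_beta`` when
    present.  Variants with an empty gene label are excluded with a
    warning; duplicate variant ids are an error.
    """
    df = catalog.frame if hasattr(catalog, "frame") else pd.DataFrame(catalog)
    if df["variant_id"].duplicated().any():
        dup = df.loc[df["variant_id"].duplicated(), "variant_id"].tolist()
        raise ValueError(f"duplicate variant ids {dup[:5]}")
    gene = df["gene_id"].astype("string")
    blank = gene.isna() | (gene.str.strip() == "")
    if blank.any():
        warnings.warn(f"excluding {int(blank.sum())} variant(s) with empty "
                      "gene label", stacklevel=2)
        df = df[~blank]
    has_truth = "effect_beta" in df.columns
    out = []
    for gid, sub in df.groupby("gene_id", sort=True):
        causal = bool((sub["effect_beta"] != 0).any()) if has_truth else None
        out.append(GeneSet(str(gid), tuple(sub["variant_id"]), causal))
    return out


def build_synthetic_pathways(genes: list[GeneSet], design: PathwayDesign,
                             seed: int) -> list[PathwaySet]:
    """Assemble mutually exclusive pathways by stratified sampling.

    Causal and non-causal genes are drawn without replacement (globally
    across strata) so every pathway's realized causal-gene count equals
    its stratum's target exactly.  Remaining genes become filler
    pathways with no causal genes; leftover causal genes are discarded
    with a warning rather than diluted into fillers.
    """
    by_id = {g.gene_id: g for g in genes}
    causal_pool = sorted(g.gene_id for g in genes if g.causal)
    noncausal_pool = sorted(g.gene_id for g in genes if not g.causal)
    need_c = design.n_causal_genes_needed()
    need_n = design.n_noncausal_genes_needed()
    if len(causal_pool) < need_c:
        raise ValueError(f"design needs {need_c} causal genes but only "
                         f"{len(causal_pool)} available "
                         f"(deficit {need_c - len(causal_pool)})")
    if len(noncausal_pool) < need_n:
        raise ValueError(f"design needs {need_n} non-causal genes but only "
                         f"{len(noncausal_pool)} available "
                         f"(deficit {need_n - len(noncausal_pool)})")
    rng = np.random.default_rng([seed, 77])
    rng.shuffle(causal_pool)
    rng.shuffle(noncausal_pool)

    pathways = []
    ci = ni = 0
    k = 0
    for n_genes, pct, n_pw in design.strata:
        n_causal = int(round(pct * n_genes / 100.0))
        for _ in range(n_pw):
            k += 1
            gids = (causal_pool[ci:ci + n_causal]
                    + noncausal_pool[ni:ni + n_genes - n_causal])
            ci += n_causal
            ni += n_genes - n_causal
            pathways.append(_make_pathway(f"PW{k:04d}", gids, by_id,
                                          n_causal))
    leftover_causal = causal_pool[ci:]
    if leftover_causal:
        warnings.warn(f"{len(leftover_causal)} causal gene(s) not placed in "
                      "any stratum pathway; excluded from pathways",
                      stacklevel=2)
    rest = noncausal_pool[ni:]
    for start in range(0, len(rest), design.filler_size):
        chunk = rest[start:start + design.filler_size]
        if not chunk:
            break
        k += 1
        pathways.append(_make_pathway(f"PW{k:04d}", chunk, by_id, 0))
    return pathways


def _make_pathway(pid, gids, by_id, n_causal) -> PathwaySet:
    variants = []
    for gid in gids:
        variants.extend(by_id[gid].variant_ids)
    if len(set(variants)) != len(variants):
        raise ValueError(f"pathway {pid}: duplicate variants across genes")
    return PathwaySet(pid, tuple(gids), tuple(variants), n_causal)


# ----------------------------------------------------------------------
# GMT I/O


def write_gmt(sets, path, description: str = "") -> None:
    """Write gene sets or pathways in GMT (id, description, members)."""
    with open(path, "w") as fh:
        for s in sets:
            if isinstance(s, PathwaySet):
                sid, members = s.pathway_id, s.gene_ids
                desc = description or f"n_causal={s.n_causal_genes}"
            else:
                sid, members = s.gene_id, s.variant_ids
                desc = description or (f"causal={int(bool(s.causal))}"
                                       if s.causal is not None else "na")
            fh.write("\t".join([sid, desc, *members]) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file into {set_id: member list}."""
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out[parts[0]] = parts[2:]
    return out
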