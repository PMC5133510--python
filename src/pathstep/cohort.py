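"""Synthetic family cohorts for power and type-I-error studies.

Emulates the structure of a multigenerational sequencing study: large
pedigrees, rare and common variants gene-dropped down the families,
longitudinal blood-pressure phenotypes over three exams with age, sex,
smoking and antihypertensive-medication covariates, a polygenic
familial component with covariance ``sigma2_poly * 2 Phi``, a null
trait carrying no genetic effects, and replicate phenotype simulations
over fixed genotypes.

Randomness is organised as one stream per (purpose, replicate) pair:
pedigree structure, the variant catalog, genotypes, and covariates are
functions of the cohort seed alone, so phenotype replicates share them,
while each phenotype replicate draws its own polygenic and residual
noise.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .kinship import KinshipMatrix, compute_kinship
from .pedigree import Individual, Pedigree

__all__ = ["CohortConfig", "VariantCatalog", "GenotypeMatrix",
           "simulate_pedigrees", "simulate_catalog", "drop_genotypes",
           "simulate_phenotypes", "simulate_null_trait",
           "expected_family_size", "ConfigError"]


class ConfigError(ValueError):
    """Invalid cohort configuration."""


@dataclass
class CohortConfig:
    """Knobs of the synthetic cohort generator.

    Defaults describe the reference study conditions used throughout
    the test-bed: 24 families of three generations with sibships of 3
    (17 members each, n = 408), ~30 genes with a mixture of rare and
    common variants, a fifth of genes causal, and variance components
    giving the collapsed trait a heritability near 0.4.
    """

    seed: int = 2016
    # pedigree template
    n_families: int = 24
    n_generations: int = 3
    sibship_kind: str = "fixed"          # "fixed" | "poisson" (min 1)
    sibship_size: float = 3
    # variant catalog
    n_genes: int = 30
    variants_per_gene_min: int = 4
    variants_per_gene_max: int = 16
    rare_fraction: float = 0.8
    rare_maf_range: tuple = (0.002, 0.02)
    common_maf_range: tuple = (0.05, 0.5)
    causal_gene_fraction: float = 0.2
    causal_variant_fraction: float = 0.5
    effect_scale: float = 1.0            # |beta| = scale * |log10 maf|
    effect_sign_pos_fraction: float = 0.8
    # variance components (mmHg^2, on the MAP scale)
    polygenic_variance: float = 30.0
    residual_variance: float = 36.0      # person-level, shared over exams
    exam_noise_variance: float = 12.0    # exam-level, shared SBP/DBP
    trait_noise_variance: float = 4.0    # exam-level, per trait
    # longitudinal / covariate structure
    exam_count: int = 3
    exam_spacing_years: float = 5.0
    top_generation_age: float = 70.0
    generation_gap_years: float = 25.0
    sbp_intercept: float = 115.0
    dbp_intercept: float = 75.0
    age_center: float = 45.0
    age_slope_sbp: float = 0.4
    age_slope_dbp: float = 0.25
    male_effect_sbp: float = 4.0
    male_effect_dbp: float = 2.0
    smoke_effect_sbp: float = 5.0
    smoke_effect_dbp: float = 3.0
    smoking_start_prob: float = 0.25
    smoking_persistence: float = 0.9
    # medication rule: treated iff untreated SBP/DBP exceed 140/90; the
    # recorded values are reduced by (10, 5) so the standard +10/+5
    # adjustment inverts treatment exactly
    hypertension_sbp: float = 140.0
    hypertension_dbp: float = 90.0
    treatment_effect_sbp: float = 10.0
    treatment_effect_dbp: float = 5.0
    # replicate design
    n_replicates: int = 200
    genotype_missing_rate: float = 0.0

    def validate(self) -> "CohortConfig":
        if self.n_generations < 1:
            raise ConfigError("pedigree template needs >= 1 generation")
        if self.n_families < 1:
            raise ConfigError("need >= 1 family")
        if min(self.polygenic_variance, self.residual_variance,
               self.exam_noise_variance, self.trait_noise_variance) < 0:
            raise ConfigError("variances must be non-negative")
        if self.exam_count < 1:
            raise ConfigError("exam_count must be >= 1")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if self.sibship_kind not in ("fixed", "poisson"):
            raise ConfigError(f"unknown sibship kind {self.sibship_kind!r}")
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rare_maf_range"] = list(self.rare_maf_range)
        d["common_maf_range"] = list(self.common_maf_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        for k in ("rare_maf_range", "common_maf_range"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d).validate()


# ----------------------------------------------------------------------
# variant catalog


class VariantCatalog:
    """Variant table: id, chromosome, position, gene, founder MAF, beta.

    A gene is causal iff it contains at least one variant with a
    non-zero effect.  Positions are strictly increasing within each
    chromosome and every variant belongs to exactly one gene.
    """

    REQUIRED = ["variant_id", "chrom", "pos", "gene_id",
                "founder_maf", "effect_beta"]

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in frame.columns]
        if missing:
            raise ValueError(f"catalog lacks columns {missing}")
        df = frame[self.REQUIRED].copy()
        df["chrom"] = df["chrom"].astype(str)
        if df["variant_id"].duplicated().any():
            dup = df.loc[df["variant_id"].duplicated(), "variant_id"].tolist()
            raise ValueError(f"duplicate variant ids {dup[:5]}")
        maf = df["founder_maf"].to_numpy(dtype=float)
        if np.any(maf <= 0) or np.any(maf > 0.5):
            raise ValueError("founder MAFs must lie in (0, 0.5]")
        for chrom, sub in df.groupby("chrom"):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on "
                                 f"chromosome {chrom}")
        self.frame = df.reset_index(drop=True)

    @property
    def variant_ids(self) -> list[str]:
        return self.frame["variant_id"].tolist()

    @property
    def mafs(self) -> np.ndarray:
        return self.frame["founder_maf"].to_numpy(dtype=float)

    @property
    def betas(self) -> np.ndarray:
        return self.frame["effect_beta"].to_numpy(dtype=float)

    @property
    def causal_genes(self) -> list[str]:
        f = self.frame
        return sorted(f.loc[f["effect_beta"] != 0, "gene_id"].unique())

    def null_copy(self) -> "VariantCatalog":
        df = self.frame.copy()
        df["effect_beta"] = 0.0
        return VariantCatalog(df)

    def write_tsv(self, path, seed=None) -> None:
        with open(path, "w") as fh:
            if seed is not None:
                fh.write(f"# generating_seed: {seed}\n")
            self.frame.to_csv(fh, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "VariantCatalog":
        return cls(pd.read_csv(path, sep="\t", comment="#"))


# ----------------------------------------------------------------------
# genotypes


@dataclass
class GenotypeMatrix:
    """Alternate-allele counts, individuals x variants; NaN = missing."""

    ids: list
    variant_ids: list
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.ids), len(self.variant_ids)):
            raise ValueError("counts shape does not match ids/variants")
        self._vidx = {v: j for j, v in enumerate(self.variant_ids)}
        self._iidx = {i: k for k, i in enumerate(self.ids)}

    def columns(self, variant_ids) -> np.ndarray:
        try:
            idx = [self._vidx[v] for v in variant_ids]
        except KeyError as e:
            raise KeyError(f"unknown variant {e}") from e
        return self.counts[:, idx]

    def align(self, ids) -> "GenotypeMatrix":
        idx = [self._iidx[i] for i in ids]
        return GenotypeMatrix(list(ids), self.variant_ids, self.counts[idx])

    def sample_mafs(self, variant_ids=None) -> np.ndarray:
        G = (self.counts if variant_ids is None
             else self.columns(variant_ids))
        freq = np.nanmean(G, axis=0) / 2.0
        return np.clip(np.minimum(freq, 1.0 - freq), 1e-8, 0.5)

    def write_tsv(self, path, seed=None) -> None:
        with open(path, "w") as fh:
            if seed is not None:
                fh.write(f"# generating_seed: {seed}\n")
            pd.DataFrame(self.counts, index=self.ids,
                         columns=self.variant_ids).to_csv(fh, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        return cls([str(i) for i in df.index],
                   [str(c) for c in df.columns], df.to_numpy(dtype=float))


# ----------------------------------------------------------------------
# pedigree simulation


def expected_family_size(config: CohortConfig) -> int:
    """Members per family for a fixed-sibship template (closed form)."""
    if config.sibship_kind != "fixed":
        raise ConfigError("closed-form size only defined for fixed sibships")
    s = int(config.sibship_size)
    total, couples = 2, 1
    for g in range(2, config.n_generations + 1):
        children = couples * s
        total += children
        if g < config.n_generations:
            total += children          # married-in spouses
            couples = children
    return total


def simulate_pedigrees(config: CohortConfig) -> Pedigree:
    """Multigenerational pedigrees per the template; seed-deterministic.

    Each family starts from a founder couple; every child in a
    non-final generation marries an unrelated founder spouse and the
    couple has a sibship of children.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 11])
    members: list[Individual] = []
    for f in range(config.n_families):
        fid = f"F{f + 1:03d}"
        counter = [0]

        def new_id():
            counter[0] += 1
            return f"{fid}_I{counter[0]:03d}"

        pa, ma = new_id(), new_id()
        members.append(Individual(pa, fid, None, None, "male"))
        members.append(Individual(ma, fid, None, None, "female"))
        couples = [(pa, ma)]
        for g in range(2, config.n_generations + 1):
            next_couples = []
            for father, mother in couples:
                if config.sibship_kind == "fixed":
                    s = int(config.sibship_size)
                else:
                    s = max(1, int(rng.poisson(config.sibship_size)))
                for _ in range(s):
                    child = new_id()
                    child_sex = "male" if rng.random() < 0.5 else "female"
                    members.append(Individual(child, fid, father, mother,
                                              child_sex))
                    if g < config.n_generations:
                        spouse = new_id()
                        spouse_sex = ("female" if child_sex == "male"
                                      else "male")
                        members.append(Individual(spouse, fid, None, None,
                                                  spouse_sex))
                        if child_sex == "male":
                            next_couples.append((child, spouse))
                        else:
                            next_couples.append((spouse, child))
            couples = next_couples
    return Pedigree.build([(m.iid, m.fid, m.father, m.mother,
                            "1" if m.sex == "male" else "2")
                           for m in members])


def _generation_depth(ped: Pedigree) -> np.ndarray:
    """Generation index per individual (0 = top).

    Descendants get max(parent depth) + 1; married-in founders adopt
    their children's generation minus one so ages line up.
    """
    depth = np.zeros(ped.n)
    idx = ped._index
    for i, m in enumerate(ped.members):
        if not m.is_founder:
            depth[i] = max(depth[idx[m.father]], depth[idx[m.mother]]) + 1
    for i, m in enumerate(ped.members):
        if m.is_founder:
            kids = [k for k, c in enumerate(ped.members)
                    if c.father == m.iid or c.mother == m.iid]
            if kids:
                depth[i] = max(min(depth[k] for k in kids) - 1, 0)
    return depth


# ----------------------------------------------------------------------
# variant catalog simulation


def simulate_catalog(config: CohortConfig) -> VariantCatalog:
    """Draw a variant catalog per the configured architecture."""
    config.validate()
    rng = np.random.default_rng([config.seed, 22])
    chroms = [f"{c}" for c in range(1, 23, 2)]   # odd autosomes
    rows = []
    n_causal_genes = int(round(config.causal_gene_fraction * config.n_genes))
    causal_genes = set(rng.choice(config.n_genes, size=n_causal_genes,
                                  replace=False).tolist())
    pos_per_chrom = {c: 0 for c in chroms}
    vcount = 0
    for g in range(config.n_genes):
        gene = f"GENE{g + 1:04d}"
        chrom = chroms[g % len(chroms)]
        m = rng.integers(config.variants_per_gene_min,
                         config.variants_per_gene_max + 1)
        causal_flags = np.zeros(m, dtype=bool)
        if g in causal_genes:
            causal_flags = rng.random(m) < config.causal_variant_fraction
            if not causal_flags.any():
                causal_flags[rng.integers(m)] = True
        for j in range(m):
            vcount += 1
            if rng.random() < config.rare_fraction:
                lo, hi = config.rare_maf_range
                maf = 10 ** rng.uniform(np.log10(lo), np.log10(hi))
            else:
                lo, hi = config.common_maf_range
                maf = rng.uniform(lo, hi)
            pos_per_chrom[chrom] += int(rng.integers(500, 5000))
            beta = 0.0
            if causal_flags[j]:
                sign = (1.0 if rng.random() <
                        config.effect_sign_pos_fraction else -1.0)
                beta = sign * config.effect_scale * abs(np.log10(maf))
            rows.append((f"var{vcount:05d}", chrom, pos_per_chrom[chrom],
                         gene, maf, beta))
    return VariantCatalog(pd.DataFrame(
        rows, columns=VariantCatalog.REQUIRED))


# ----------------------------------------------------------------------
# gene drop


def drop_genotypes(ped: Pedigree, catalog: VariantCatalog,
                   seed: int | None = None) -> GenotypeMatrix:
    """Gene-drop genotypes down the pedigree (no linkage, no LD).

    Founders draw counts ~ Binomial(2, maf); each non-founder receives
    one allele per parent, transmitted with probability count/2 —
    exactly Mendelian for unlinked biallelic variants.
    """
    mafs = catalog.mafs
    rng = np.random.default_rng([seed if seed is not None else 0, 33])
    m = mafs.size
    counts = np.zeros((ped.n, m))
    idx = ped._index
    for i, memb in enumerate(ped.members):
        if memb.is_founder:
            counts[i] = rng.binomial(2, mafs)
        else:
            cf = counts[idx[memb.father]]
            cm = counts[idx[memb.mother]]
            counts[i] = (rng.binomial(1, cf / 2.0)
                         + rng.binomial(1, cm / 2.0))
    return GenotypeMatrix(ped.ids, catalog.variant_ids, counts)


def mask_genotypes(gm: GenotypeMatrix, rate: float,
                   seed: int = 0) -> GenotypeMatrix:
    """Randomly set a fraction of genotype calls to missing."""
    if rate <= 0:
        return gm
    rng = np.random.default_rng([seed, 44])
    counts = gm.counts.copy()
    counts[rng.random(counts.shape) < rate] = np.nan
    return GenotypeMatrix(gm.ids, gm.variant_ids, counts)


# ----------------------------------------------------------------------
# phenotype simulation


def simulate_phenotypes(ped: Pedigree, genotypes: GenotypeMatrix | None,
                        catalog: VariantCatalog | None,
                        config: CohortConfig, replicate_seed: int,
                        kin: KinshipMatrix | None = None) -> pd.DataFrame:
    """One longitudinal phenotype replicate for fixed genotypes.

    Underlying SBP and DBP at each exam are intercept + age/sex/smoking
    terms + the variant genetic value + a polygenic deviate
    ``u ~ N(0, sigma2_poly 2Phi)`` + a person-level residual + exam
    noise.  Individuals whose untreated pressures exceed the
    hypertension thresholds at an exam are medicated there, and their
    RECORDED pressures are reduced by the treatment effect.

    Covariates (age, sex, smoking) depend only on the cohort seed, so
    all replicates share them; the polygenic and residual draws are
    functions of ``replicate_seed``.  Pass ``genotypes=None`` (or a
    catalog with all-zero betas) for a purely polygenic trait.
    """
    config.validate()
    if kin is None:
        kin = compute_kinship(ped)
    elif kin.ids != ped.ids:
        kin = kin.reindex(ped.ids)
    n, t = ped.n, config.exam_count

    # --- covariates: fixed across replicates ---
    cov_rng = np.random.default_rng([config.seed, 55])
    depth = _generation_depth(ped)
    base_age = (config.top_generation_age
                - config.generation_gap_years * depth
                + cov_rng.uniform(-4.0, 4.0, size=n))
    ages = base_age[:, None] + config.exam_spacing_years * np.arange(t)[None, :]
    male = np.array([m.sex == "male" for m in ped.members], dtype=float)
    smoke = np.zeros((n, t))
    smoke[:, 0] = cov_rng.random(n) < config.smoking_start_prob
    for k in range(1, t):
        stay = cov_rng.random(n) < config.smoking_persistence
        start = cov_rng.random(n) < (1.0 - config.smoking_persistence) * \
            config.smoking_start_prob
        smoke[:, k] = np.where(smoke[:, k - 1] == 1, stay, start)

    # --- genetic value ---
    gv = np.zeros(n)
    if genotypes is not None and catalog is not None:
        betas = catalog.betas
        nz = betas != 0
        if nz.any():
            vids = [v for v, keep in zip(catalog.variant_ids, nz) if keep]
            G = genotypes.align(ped.ids).columns(vids)
            G = np.where(np.isnan(G), np.nanmean(G, axis=0), G)
            gv = G @ betas[nz]

    # --- replicate-specific draws ---
    rep_rng = np.random.default_rng([config.seed, 66, int(replicate_seed)])
    u = np.sqrt(config.polygenic_variance) * \
        (kin.chol2() @ rep_rng.standard_normal(n))
    e_person = np.sqrt(config.residual_variance) * rep_rng.standard_normal(n)
    eps_shared = np.sqrt(config.exam_noise_variance) * \
        rep_rng.standard_normal((n, t))
    eps_sbp = np.sqrt(config.trait_noise_variance) * \
        rep_rng.standard_normal((n, t))
    eps_dbp = np.sqrt(config.trait_noise_variance) * \
        rep_rng.standard_normal((n, t))

    common = (gv + u + e_person)[:, None] + eps_shared
    age_c = ages - config.age_center
    sbp = (config.sbp_intercept + config.age_slope_sbp * age_c
           + config.male_effect_sbp * male[:, None]
           + config.smoke_effect_sbp * smoke + common + eps_sbp)
    dbp = (config.dbp_intercept + config.age_slope_dbp * age_c
           + config.male_effect_dbp * male[:, None]
           + config.smoke_effect_dbp * smoke + common + eps_dbp)

    med = ((sbp >= config.hypertension_sbp)
           | (dbp >= config.hypertension_dbp)).astype(float)
    sbp_rec = sbp - config.treatment_effect_sbp * med
    dbp_rec = dbp - config.treatment_effect_dbp * med

    ids = np.repeat(ped.ids, t)
    return pd.DataFrame({
        "individual_id": ids,
        "exam": np.tile(np.arange(1, t + 1), n),
        "age": ages.ravel(),
        "sex": np.repeat(male, t).astype(int),
        "smoke": smoke.ravel().astype(int),
        "med": med.ravel().astype(int),
        "SBP": sbp_rec.ravel(),
        "DBP": dbp_rec.ravel(),
    })


def simulate_null_trait(ped: Pedigree, config: CohortConfig,
                        replicate_seed: int,
                        kin: KinshipMatrix | None = None) -> pd.DataFrame:
    """Phenotype replicate with every variant effect forced to zero.

    Identical generator (polygenic and covariate structure retained);
    the collapsed MAP of this table is the null trait used for
    empirical type-I-error estimation.
    """
    return simulate_phenotypes(ped, None, None, config, replicate_seed,
                               kin=kin)
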