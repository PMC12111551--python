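"""Seeded generators for every input the screen consumes.

The generator emulates the statistical structure the analysis assumes:

* **LD-structured genotypes** — per block, a latent Gaussian AR(1) chain is
  thresholded into haplotype alleles at MAF quantiles; the latent
  correlation of each adjacent pair is calibrated (bivariate-normal CDF +
  root finding) so that the *realized* adjacent genotype correlation
  equals ``block_rho``, decaying approximately as ``block_rho**distance``
  within a block and vanishing across blocks. SNPs in strong LD share a
  block-level base frequency with small jitter, as high-LD variants must.
* **Paired case-control summary statistics** — per-SNP marginal log-odds
  effects are induced by planted causal effects through the empirical
  within-block LD, with standard errors from the case-control asymptotic
  formula ``se = 1/sqrt(2 * n_eff * p(1-p))``, ``n_eff = 4/(1/cases +
  1/controls)``. The default "analytic" mode samples
  ``beta_hat ~ Normal(beta_marginal, se^2)`` directly; an opt-in
  "phenotype" mode simulates binary outcomes under a logistic model and
  fits per-SNP logistic regressions.
* **Expression matrices** — one latent immune-infiltration factor per
  cohort drives marker genes and a chosen set of target genes with a
  common loading; all rows are Z-scored across samples.
* **Gene annotations, gene sets and eQTL records** for the downstream
  annotation and alignment steps.

Identical configuration and seed give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import ConfigError, PipelineError

EFFECT_CLASSES = ("null", "opposite", "concordant", "heterogeneous",
                  "a_only", "b_only")

# ordered non-palindromic allele pairs (effect, other)
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class PlantedEffect:
    """A causal SNP with per-trait log-odds effects.

    ``effect_class`` labels the planted pattern: ``opposite`` effects have
    discordant signs (the screen's target), ``concordant`` the same sign,
    ``heterogeneous`` opposite signs of very unequal magnitude (tripping
    Cochran's Q), ``a_only``/``b_only`` act on one trait, ``null`` on
    neither.
    """

    snp_index: int
    effect_class: str
    beta_a: float = 0.0
    beta_b: float = 0.0

    def __post_init__(self):
        if self.effect_class not in EFFECT_CLASSES:
            raise ConfigError(f"unknown effect class {self.effect_class!r}")
        prod = self.beta_a * self.beta_b
        if self.effect_class == "null" and (self.beta_a != 0 or self.beta_b != 0):
            raise ConfigError("null effect must have beta_a = beta_b = 0")
        if self.effect_class == "opposite" and not prod < 0:
            raise ConfigError("opposite effect requires beta_a * beta_b < 0")
        if self.effect_class == "concordant" and not prod > 0:
            raise ConfigError("concordant effect requires beta_a * beta_b > 0")
        if self.effect_class == "heterogeneous" and not prod < 0:
            raise ConfigError("heterogeneous effect requires opposite signs")
        if self.effect_class == "a_only" and (self.beta_a == 0 or self.beta_b != 0):
            raise ConfigError("a_only effect requires beta_a != 0, beta_b = 0")
        if self.effect_class == "b_only" and (self.beta_b == 0 or self.beta_a != 0):
            raise ConfigError("b_only effect requires beta_b != 0, beta_a = 0")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with case-control sample sizes
    defaulting to 50k/50k per trait (the scale of the large source GWAS)
    and four expression cohorts of 500 tumors each."""

    seed: int = 0
    n_snps: int = 400
    n_blocks: int = 50
    block_rho: float = 0.9
    maf_range: tuple = (0.15, 0.45)
    n_individuals: int = 2000
    n_cases_a: int = 50_000
    n_controls_a: int = 50_000
    n_cases_b: int = 50_000
    n_controls_b: int = 50_000
    planted_effects: list = field(default_factory=list)
    chrom_length: int = 150_000_000
    chrom: str = "1"
    n_genes: int = 200
    n_samples_expr: int = 500
    n_cohorts: int = 4
    infiltration_loading: float = 0.9
    info_range: tuple = (0.85, 1.0)
    maf_block_jitter: float = 0.02
    allele_perturb_rate: float = 0.0

    def __post_init__(self):
        counts = dict(n_snps=self.n_snps, n_blocks=self.n_blocks,
                      n_individuals=self.n_individuals,
                      n_cases_a=self.n_cases_a, n_controls_a=self.n_controls_a,
                      n_cases_b=self.n_cases_b, n_controls_b=self.n_controls_b,
                      chrom_length=self.chrom_length, n_genes=self.n_genes,
                      n_samples_expr=self.n_samples_expr,
                      n_cohorts=self.n_cohorts)
        for name, v in counts.items():
            if v <= 0:
                raise ConfigError(f"{name} must be positive, got {v}")
        if not 0 <= self.block_rho < 1:
            raise ConfigError("block_rho must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must lie within (0, 0.5]")
        if not 0 <= self.infiltration_loading <= 1:
            raise ConfigError("infiltration_loading must be in [0, 1]")
        if self.n_blocks > self.n_snps:
            raise ConfigError("n_blocks cannot exceed n_snps")
        for eff in self.planted_effects:
            if not 0 <= eff.snp_index < self.n_snps:
                raise ConfigError(f"planted snp_index {eff.snp_index} out of range")
        if not 0 <= self.allele_perturb_rate <= 1:
            raise ConfigError("allele_perturb_rate must be in [0, 1]")


def block_assignments(config: SimulationConfig) -> np.ndarray:
    """Block id for each SNP (contiguous, near-equal block sizes)."""
    return np.array_split(np.arange(config.n_snps), config.n_blocks), \
        np.repeat(np.arange(config.n_blocks),
                  [len(b) for b in np.array_split(np.arange(config.n_snps),
                                                  config.n_blocks)])


def plant_effects(config: SimulationConfig, n_opposite: int = 0,
                  n_concordant: int = 0, n_heterogeneous: int = 0,
                  beta: float = 0.15, het_ratio: float = 6.0) -> list:
    """Place one causal SNP (the middle of a block) per planted locus.

    Blocks are consumed in order: opposite loci first, then concordant,
    then heterogeneous (whose trait-B magnitude is ``het_ratio`` times
    larger, with opposite sign). Remaining blocks stay null.
    """
    blocks, _ = block_assignments(config)
    need = n_opposite + n_concordant + n_heterogeneous
    if need > len(blocks):
        raise ConfigError("more planted loci than LD blocks")
    effects = []
    for i in range(n_opposite):
        idx = int(blocks[i][len(blocks[i]) // 2])
        effects.append(PlantedEffect(idx, "opposite", beta, -beta))
    for i in range(n_opposite, n_opposite + n_concordant):
        idx = int(blocks[i][len(blocks[i]) // 2])
        effects.append(PlantedEffect(idx, "concordant", beta, beta))
    for i in range(n_opposite + n_concordant, need):
        idx = int(blocks[i][len(blocks[i]) // 2])
        effects.append(PlantedEffect(idx, "heterogeneous", beta,
                                     -beta * het_ratio))
    return effects


_latent_cache: dict = {}


def _bvn_cdf(t1: float, t2: float, r: float) -> float:
    return float(stats.multivariate_normal.cdf(
        [t1, t2], mean=[0.0, 0.0], cov=[[1.0, r], [r, 1.0]],
        allow_singular=True))


def _latent_adjacent_rho(maf_i: float, maf_j: float, target: float) -> float:
    """Latent Gaussian correlation giving allele correlation ``target``
    after thresholding at the two MAF quantiles. Capped where the target
    exceeds what the frequency pair allows."""
    if target <= 0:
        return 0.0
    key = (round(maf_i, 4), round(maf_j, 4), round(target, 4))
    if key in _latent_cache:
        return _latent_cache[key]
    t1, t2 = stats.norm.ppf(maf_i), stats.norm.ppf(maf_j)
    denom = np.sqrt(maf_i * (1 - maf_i) * maf_j * (1 - maf_j))

    def allele_corr(r):
        return (_bvn_cdf(t1, t2, r) - maf_i * maf_j) / denom

    hi = 0.999999
    if allele_corr(hi) <= target:
        out = hi
    else:
        out = float(optimize.brentq(lambda r: allele_corr(r) - target,
                                    0.0, hi, xtol=1e-6))
    _latent_cache[key] = out
    return out


def simulate_ld_genotypes(config: SimulationConfig
                          ) -> tuple[np.ndarray, pd.DataFrame]:
    """Simulate a dosage matrix (individuals x SNPs) with block LD plus the
    SNP map (rsid, chromosome, position, alleles, configured MAF).

    Dosages are 0/1/2 counts of the effect allele from two independent
    haplotypes. Positions are strictly increasing, blocks occupy disjoint
    windows spaced far enough apart that inter-block loci do not merge
    during clumping.
    """
    rng = np.random.default_rng([config.seed, 1])
    blocks, block_of = block_assignments(config)
    n = config.n_individuals

    # block-level base MAF with small per-SNP jitter
    lo, hi = config.maf_range
    base = rng.uniform(lo, hi, size=config.n_blocks)
    jitter = rng.uniform(-config.maf_block_jitter, config.maf_block_jitter,
                         size=config.n_snps)
    maf = np.clip(base[block_of] + jitter, max(lo, 0.01), hi)

    # positions: disjoint per-block windows
    region = config.chrom_length // config.n_blocks
    positions = np.empty(config.n_snps, dtype=np.int64)
    for b, idx in enumerate(blocks):
        window = min(100_000, max(region // 2, len(idx) + 1))
        offs = np.sort(rng.choice(window, size=len(idx), replace=False))
        positions[idx] = b * region + 1 + offs

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=config.n_snps)
    effect_alleles = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    other_alleles = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])

    genotypes = np.empty((n, config.n_snps), dtype=np.int8)
    thresholds = stats.norm.ppf(maf)
    for idx in blocks:
        m = len(idx)
        latent = np.empty((2 * n, m))
        latent[:, 0] = rng.standard_normal(2 * n)
        for j in range(1, m):
            r = _latent_adjacent_rho(maf[idx[j - 1]], maf[idx[j]],
                                     config.block_rho)
            latent[:, j] = (r * latent[:, j - 1]
                            + np.sqrt(1 - r * r) * rng.standard_normal(2 * n))
        hap = latent < thresholds[idx]
        genotypes[:, idx] = (hap[:n].astype(np.int8) + hap[n:].astype(np.int8))

    snp_map = pd.DataFrame({
        "rsid": [f"rs{i + 1:06d}" for i in range(config.n_snps)],
        "chrom": config.chrom,
        "pos": positions,
        "effect_allele": effect_alleles,
        "other_allele": other_alleles,
        "maf": maf,
        "block": block_of,
    })
    return genotypes, snp_map


def _marginal_betas(genotypes: np.ndarray, block_of: np.ndarray,
                    effects: list, which: str) -> np.ndarray:
    """Per-SNP marginal log-odds effects induced through within-block LD."""
    beta = np.zeros(genotypes.shape[1])
    sd = genotypes.std(axis=0)
    for eff in effects:
        b = getattr(eff, f"beta_{which}")
        if b == 0:
            continue
        c = eff.snp_index
        if sd[c] == 0:
            raise PipelineError(
                f"planted effect on monomorphic SNP index {c}")
        same = np.flatnonzero(block_of == block_of[c])
        gc = genotypes[:, c].astype(float)
        for j in same:
            if sd[j] == 0:
                continue
            r = np.corrcoef(genotypes[:, j].astype(float), gc)[0, 1]
            beta[j] += r * (sd[c] / sd[j]) * b
    return beta


def effective_sample_size(n_cases: int, n_controls: int) -> float:
    return 4.0 / (1.0 / n_cases + 1.0 / n_controls)


def analytic_se(eaf: np.ndarray, n_cases: int, n_controls: int) -> np.ndarray:
    """Asymptotic log-OR standard error for a case-control GWAS."""
    n_eff = effective_sample_size(n_cases, n_controls)
    return 1.0 / np.sqrt(2.0 * n_eff * eaf * (1.0 - eaf))


def simulate_pair_sumstats(genotypes: np.ndarray, snp_map: pd.DataFrame,
                           config: SimulationConfig, mode: str = "analytic"
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the two trait summary-statistic tables (cancer-like A,
    autoimmune-like B) from independent cohorts.

    In the default ``analytic`` mode each estimate is drawn
    ``Normal(beta_marginal, se^2)`` with the asymptotic case-control
    standard error — distributionally exact under large-sample theory and
    fast at any cohort size. ``mode="phenotype"`` instead simulates binary
    phenotypes under a logistic model for explicitly generated cohorts and
    fits per-SNP logistic regressions (slower; intended for end-to-end
    realism checks at small sample sizes).

    Raises
    ------
    PipelineError
        A planted effect falls on a monomorphic SNP.
    """
    if mode not in ("analytic", "phenotype"):
        raise ConfigError(f"unknown generation mode {mode!r}")
    rng = np.random.default_rng([config.seed, 2])
    block_of = snp_map["block"].to_numpy()
    eaf = genotypes.mean(axis=0) / 2.0
    poly = (eaf > 0) & (eaf < 1)
    for eff in config.planted_effects:
        if not poly[eff.snp_index]:
            raise PipelineError(
                f"planted effect on monomorphic SNP index {eff.snp_index}")

    tables = []
    for which, (n_cases, n_controls) in (
            ("a", (config.n_cases_a, config.n_controls_a)),
            ("b", (config.n_cases_b, config.n_controls_b))):
        beta_true = _marginal_betas(genotypes, block_of,
                                    config.planted_effects, which)
        se = np.where(poly, analytic_se(np.clip(eaf, 1e-6, 1 - 1e-6),
                                        n_cases, n_controls), np.nan)
        if mode == "analytic":
            beta_hat = beta_true + se * rng.standard_normal(len(se))
        else:
            beta_hat, se = _phenotype_mode_estimates(
                config, which, n_cases, n_controls, rng)
        p = 2.0 * stats.norm.sf(np.abs(beta_hat / se))
        info = rng.uniform(*config.info_range, size=len(se))
        df = pd.DataFrame({
            "rsid": snp_map["rsid"], "chrom": snp_map["chrom"],
            "pos": snp_map["pos"],
            "effect_allele": snp_map["effect_allele"],
            "other_allele": snp_map["other_allele"],
            "eaf": eaf, "info": info, "beta": beta_hat, "se": se, "p": p,
        })
        df = df[poly].reset_index(drop=True)
        df.attrs["sign_flipped"] = False
        tables.append(df)

    df_a, df_b = tables
    if config.allele_perturb_rate > 0:
        df_b = _perturb_alleles(df_b, config.allele_perturb_rate, rng)
    return df_a, df_b


def _phenotype_mode_estimates(config, which, n_cases, n_controls, rng):
    """Simulate an explicit cohort for one trait under a logistic model and
    fit per-SNP logistic regressions (Newton iterations vectorized across
    SNPs). Trait cohorts are generated independently of each other and of
    the LD reference panel."""
    n_total = n_cases + n_controls
    cohort_cfg = SimulationConfig(
        seed=config.seed + (7 if which == "a" else 11),
        n_snps=config.n_snps, n_blocks=config.n_blocks,
        block_rho=config.block_rho, maf_range=config.maf_range,
        n_individuals=n_total, planted_effects=config.planted_effects,
        chrom_length=config.chrom_length, maf_block_jitter=config.maf_block_jitter)
    g, _ = simulate_ld_genotypes(cohort_cfg)
    g = g.astype(float)
    case_frac = n_cases / n_total
    # intercept chosen so the expected case fraction matches the design
    eta0 = np.log(case_frac / (1 - case_frac))
    lin = eta0 + (g - g.mean(axis=0)) @ _causal_vector(config, g.shape[1], which)
    y = (rng.random(n_total) < 1.0 / (1.0 + np.exp(-lin))).astype(float)

    a = np.full(g.shape[1], eta0)
    b = np.zeros(g.shape[1])
    for _ in range(12):
        eta = a + b * g
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        r = y[:, None] - mu
        saa = w.sum(axis=0)
        sab = (w * g).sum(axis=0)
        sbb = (w * g * g).sum(axis=0)
        ga = r.sum(axis=0)
        gb = (r * g).sum(axis=0)
        det = saa * sbb - sab * sab
        det = np.where(det <= 0, np.nan, det)
        a += (sbb * ga - sab * gb) / det
        b += (saa * gb - sab * ga) / det
    eta = a + b * g
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1 - mu)
    saa = w.sum(axis=0)
    sab = (w * g).sum(axis=0)
    sbb = (w * g * g).sum(axis=0)
    var_b = saa / np.maximum(saa * sbb - sab * sab, 1e-12)
    return b, np.sqrt(var_b)


def _causal_vector(config, n_snps, which):
    v = np.zeros(n_snps)
    for eff in config.planted_effects:
        v[eff.snp_index] += getattr(eff, f"beta_{which}")
    return v


def _perturb_alleles(df: pd.DataFrame, rate: float, rng) -> pd.DataFrame:
    """Swap effect/other alleles or strand-complement a random subset of
    trait-B rows so that harmonization has real work to do. The encoded
    association is unchanged."""
    df = df.copy()
    chosen = np.flatnonzero(rng.random(len(df)) < rate)
    swap = chosen[: len(chosen) // 2]
    flip = chosen[len(chosen) // 2:]
    ea = df["effect_allele"].to_numpy(copy=True)
    oa = df["other_allele"].to_numpy(copy=True)
    ea[swap], oa[swap] = oa[swap].copy(), ea[swap].copy()
    df.loc[df.index[swap], "beta"] = -df.loc[df.index[swap], "beta"]
    df.loc[df.index[swap], "eaf"] = 1 - df.loc[df.index[swap], "eaf"]
    for i in flip:
        ea[i] = _COMPLEMENT[ea[i]]
        oa[i] = _COMPLEMENT[oa[i]]
    df["effect_allele"] = ea
    df["other_allele"] = oa
    df.attrs["sign_flipped"] = False
    return df


def simulate_expression(config: SimulationConfig, driven_genes,
                        marker_genes, gene_universe=None) -> dict:
    """Per-cohort Z-scored expression with one latent infiltration factor.

    Marker genes and driven genes load on the cohort's factor with
    ``config.infiltration_loading``; all other genes are independent
    noise. Every returned row has mean 0 and SD 1 across samples.

    Returns ``{cohort label: genes x samples DataFrame}``.
    """
    lam = config.infiltration_loading
    if not 0 <= lam <= 1:
        raise ConfigError("infiltration_loading must be in [0, 1]")
    driven = {str(g).upper() for g in driven_genes}
    markers = {str(g).upper() for g in marker_genes}
    if gene_universe is None:
        filler = [f"GENE{i + 1:04d}" for i in range(config.n_genes)]
        gene_universe = sorted(driven | markers) + \
            [g for g in filler if g not in driven | markers]
        gene_universe = gene_universe[:max(config.n_genes, len(driven | markers))]
    universe = [str(g).upper() for g in gene_universe]
    if not (driven | markers) <= set(universe):
        raise ConfigError("driven and marker genes must lie in the gene universe")

    loaded = np.array([g in driven or g in markers for g in universe])
    out = {}
    for c in range(config.n_cohorts):
        rng = np.random.default_rng([config.seed, 3, c])
        n = config.n_samples_expr
        factor = rng.standard_normal(n)
        noise = rng.standard_normal((len(universe), n))
        x = np.where(loaded[:, None],
                     lam * factor[None, :] + np.sqrt(1 - lam * lam) * noise,
                     noise)
        x = x - x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        x = x / sd
        out[f"cohort{c + 1}"] = pd.DataFrame(
            x, index=universe,
            columns=[f"s{c + 1}_{i + 1:04d}" for i in range(n)])
    return out


def simulate_gene_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Gene intervals tiled along the chromosome (1-based inclusive)."""
    rng = np.random.default_rng([config.seed, 5])
    spacing = config.chrom_length // config.n_genes
    starts = (np.arange(config.n_genes) * spacing + 1
              + rng.integers(0, max(spacing // 4, 2), size=config.n_genes))
    lengths = rng.integers(5_000, 100_000, size=config.n_genes)
    return pd.DataFrame({
        "chrom": config.chrom,
        "start": starts,
        "end": np.minimum(starts + lengths, config.chrom_length),
        "strand": rng.choice(["+", "-"], size=config.n_genes),
        "gene_id": [f"ENSG{i + 1:08d}" for i in range(config.n_genes)],
        "symbol": [f"GENE{i + 1:04d}" for i in range(config.n_genes)],
    })


def simulate_gene_sets(symbols, immune_symbols, seed: int = 0,
                       n_pathways_per_db: int = 20, set_size: int = 15,
                       databases=("reactome", "kegg")) -> tuple:
    """An immune gene list plus GMT-style pathway collections.

    Half of each database's pathways get immune-flavoured names and are
    enriched for ``immune_symbols``; the rest draw uniformly from the
    universe. Returns ``(immune GeneSet, list of pathway GeneSets)``.
    """
    from .annotate import GeneSet

    rng = np.random.default_rng([seed, 6])
    symbols = [str(s).upper() for s in symbols]
    immune = [str(s).upper() for s in immune_symbols]
    immune_set = GeneSet(name="immport_like_immune_list",
                         description="curated immune-related genes",
                         members=frozenset(immune), database="immune_list")
    pathways = []
    for db in databases:
        for i in range(n_pathways_per_db):
            if i < n_pathways_per_db // 2 and immune:
                n_imm = min(set_size // 2, len(immune))
                members = list(rng.choice(immune, size=n_imm, replace=False))
                members += list(rng.choice(symbols, size=set_size - n_imm,
                                           replace=False))
                name = f"{db}_cytokine_signaling_{i + 1}"
            else:
                members = list(rng.choice(symbols, size=min(set_size, len(symbols)),
                                          replace=False))
                name = f"{db}_metabolic_process_{i + 1}"
            pathways.append(GeneSet(name=name, description=db,
                                    members=frozenset(members), database=db))
    return immune_set, pathways


def simulate_eqtl_records(leads: pd.DataFrame, direction_by_rsid: dict,
                          seed: int = 0) -> pd.DataFrame:
    """eQTL records for lead SNPs with planted expression directions.

    ``leads`` needs ``lead_rsid``, ``nearest_gene``, ``effect_allele``,
    ``other_allele``; ``direction_by_rsid`` maps rsid -> +1/-1, the sign
    of the expression effect of the *effect* allele.
    """
    rng = np.random.default_rng([seed, 4])
    rows = []
    for _, lead in leads.iterrows():
        rsid = str(lead["lead_rsid"])
        sign = direction_by_rsid.get(rsid)
        if sign is None:
            continue
        z = float(sign) * rng.uniform(5.0, 15.0)
        rows.append({"rsid": rsid, "gene": lead["nearest_gene"],
                     "effect_allele": lead["effect_allele"],
                     "other_allele": lead["other_allele"],
                     "z": z, "p": 2.0 * stats.norm.sf(abs(z))})
    return pd.DataFrame(rows)
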