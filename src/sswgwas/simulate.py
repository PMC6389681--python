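"""Synthetic populations with the structure the single-step analysis assumes.

Emulates a dairy-cattle study design: a cow population descended from a
small number of sire families (19 by default), genotyped with biallelic
SNPs of a realistic founder allele-frequency spectrum, with phenotypes
driven by farm/lactation/parity fixed effects, a few large-effect QTL
regions (a DGAT1-like window absorbing ~25 % of the additive variance by
default) and a pedigree-structured polygenic remainder.  Genotypes are
produced by gene dropping — random Mendelian transmission of founder
alleles down the pedigree — so every trio is Mendelian-consistent by
construction.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import MISSING_CALL, GenotypeSet, Pedigree, PhenotypeTable, UNKNOWN_PARENT
from .kinship import a_matrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_pedigree",
    "simulate_genotypes",
    "plant_qc_failures",
    "simulate_phenotypes",
    "subset_animals",
    "simulate_dataset",
    "cow_ids",
]


@dataclass
class SimConfig:
    """Study-design parameters for the generator.

    Defaults mirror the emulated field design: 614 cows in 19 sire
    families across 19 farms, trait scale of the most abundant casein
    fraction (mean 35.45, SD 17.46 wt/wt %), one dominant QTL region
    absorbing 25 % of the additive variance plus two minor ones, and a
    moderate heritability of 0.3 (milk protein composition heritabilities
    span roughly 0.05-0.8; 0.3 sits in the well-identified middle).
    SNP count and chromosome number are desk-scale stand-ins for a dense
    panel.
    """

    seed: int = 1
    n_sires: int = 19
    n_dams: int = 300
    n_generations: int = 1
    n_cows: int = 614
    n_snps: int = 2000
    n_chromosomes: int = 5
    maf_low: float = 0.05
    maf_high: float = 0.5
    n_qtl: int = 3
    qtl_variance_fractions: tuple[float, ...] = (0.25, 0.05, 0.05)
    h2_target: float = 0.3
    trait_name: str = "alpha_s1_casein"
    trait_mean: float = 35.45
    trait_sd: float = 17.46
    n_farms: int = 19
    n_lactations: int = 3
    n_parities: int = 3
    farm_sd: float = 0.5  # fixed-effect SDs in phenotypic-SD units
    lactation_sd: float = 0.2
    parity_sd: float = 0.2
    n_records_per_cow: int = 1  # lactation records per phenotyped cow
    phenotype_generations: int = 1  # most-recent generations carrying records
    missing_rate: float = 0.0
    n_genotyped: int = 598
    plant_callrate_fail: int = 0
    plant_maf_fail: int = 0
    plant_hwe_fail: int = 0
    hidden_qtl: bool = False
    ld_block_size: int = 1  # 1 = independent loci; >1 = founder haplotype blocks

    def __post_init__(self) -> None:
        if not (0.0 <= self.h2_target < 1.0):
            raise ValueError("h2_target must be in [0, 1)")
        if sum(self.qtl_variance_fractions[: self.n_qtl]) > 1.0:
            raise ValueError("QTL variance fractions must sum to <= 1")
        if not (0.0 < self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if self.n_records_per_cow < 1:
            raise ValueError("n_records_per_cow must be >= 1")
        if not (1 <= self.phenotype_generations <= max(self.n_generations, 1)):
            raise ValueError("phenotype_generations must be in [1, n_generations]")


@dataclass
class SimTruth:
    """Ground truth recorded alongside a simulated dataset."""

    true_bv: pd.Series  # per pedigree animal, final trait scale
    qtl_marker_indices: np.ndarray  # genome-order indices into the panel
    qtl_effects: np.ndarray  # allele-substitution effects, final scale
    sigma2_a: float  # realized additive variance among cows
    sigma2_e: float  # realized residual variance among cows
    realized_h2: float
    fixed_effects: dict = field(default_factory=dict)


def _generation_prefix(g: int) -> str:
    return f"G{g}"


def simulate_pedigree(cfg: SimConfig) -> Pedigree:
    """Sire-family pedigree: founder sires and dams, then each generation
    of offspring sired by one of the ``n_sires`` founder sires with a dam
    drawn from the previous generation's females."""
    rng = np.random.default_rng(cfg.seed)
    sires = [f"SIRE{i + 1:03d}" for i in range(cfg.n_sires)]
    dams = [f"DAM{i + 1:04d}" for i in range(cfg.n_dams)]
    records = [(a, UNKNOWN_PARENT, UNKNOWN_PARENT) for a in sires + dams]

    females = dams
    for gen in range(1, cfg.n_generations + 1):
        size = cfg.n_cows if gen == cfg.n_generations else max(cfg.n_dams, cfg.n_cows)
        offspring = []
        for i in range(size):
            animal = f"{_generation_prefix(gen)}_{i + 1:05d}"
            sire = sires[rng.integers(cfg.n_sires)]
            dam = females[rng.integers(len(females))]
            records.append((animal, sire, dam))
            offspring.append(animal)
        females = offspring
    return Pedigree(tuple(records))


def cow_ids(ped: Pedigree, cfg: SimConfig) -> list[str]:
    """Final-generation cow ids, or the founder dams when no offspring
    generation was simulated."""
    if cfg.n_generations == 0:
        return [a for a in ped.animal_ids if a.startswith("DAM")]
    prefix = _generation_prefix(cfg.n_generations) + "_"
    return [a for a in ped.animal_ids if a.startswith(prefix)]


def phenotyped_ids(ped: Pedigree, cfg: SimConfig) -> list[str]:
    """Ids of the cows carrying phenotype records: the most recent
    ``phenotype_generations`` generations (founder dams when none)."""
    if cfg.n_generations == 0:
        return [a for a in ped.animal_ids if a.startswith("DAM")]
    gens = range(cfg.n_generations - cfg.phenotype_generations + 1, cfg.n_generations + 1)
    prefixes = tuple(_generation_prefix(g) + "_" for g in gens)
    return [a for a in ped.animal_ids if a.startswith(prefixes)]


def _founder_frequencies(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    return rng.uniform(cfg.maf_low, cfg.maf_high, size=cfg.n_snps)


def _marker_map(cfg: SimConfig) -> pd.DataFrame:
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_snps // cfg.n_chromosomes)
    per_chrom[: cfg.n_snps % cfg.n_chromosomes] += 1
    rows = []
    snp = 0
    for c in range(cfg.n_chromosomes):
        for j in range(per_chrom[c]):
            snp += 1
            rows.append((f"snp{snp:06d}", str(c + 1), 10_000 * (j + 1)))
    return pd.DataFrame(rows, columns=["snp_id", "chromosome", "position_bp"])


def simulate_genotypes(ped: Pedigree, cfg: SimConfig) -> GenotypeSet:
    """Gene-drop genotypes for every pedigree animal.

    Founder haplotype alleles are Bernoulli(p_i) with p_i uniform on
    [maf_low, maf_high]; each non-founder inherits one allele per parent,
    drawn independently per locus (or per haplotype block when
    ``ld_block_size`` > 1, which preserves founder linkage within
    blocks).  Optional random missingness is applied afterwards.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    p = _founder_frequencies(cfg, rng)
    n = ped.n_animals
    m = cfg.n_snps
    par = ped.parent_indices()

    hap = np.empty((2, n, m), dtype=np.int8)
    n_blocks = -(-m // cfg.ld_block_size)
    block_of = np.repeat(np.arange(n_blocks), cfg.ld_block_size)[:m]
    # LD mode: founder haplotypes are drawn from a small per-run pool so
    # loci within a block are correlated; blocks transmit without
    # recombination
    pool = None
    if cfg.ld_block_size > 1:
        pool = (rng.random((_POOL_SIZE, m)) < p).astype(np.int8)

    for i in range(n):
        for h, parent in enumerate(par[i]):
            if parent < 0:
                if pool is None:
                    hap[h, i] = rng.random(m) < p
                else:
                    choice = rng.integers(_POOL_SIZE, size=n_blocks)[block_of]
                    hap[h, i] = pool[choice, np.arange(m)]
            else:
                which = rng.integers(2, size=n_blocks)[block_of]
                hap[h, i] = np.where(which == 0, hap[0, parent], hap[1, parent])
    calls = (hap[0] + hap[1]).astype(np.int16)

    if cfg.missing_rate > 0:
        mask = rng.random(calls.shape) < cfg.missing_rate
        calls[mask] = MISSING_CALL

    return GenotypeSet(animal_ids=list(ped.animal_ids), markers=_marker_map(cfg), calls=calls)


_POOL_SIZE = 16


def plant_qc_failures(
    g: GenotypeSet,
    seed: int,
    n_callrate: int = 0,
    n_maf: int = 0,
    n_hwe: int = 0,
) -> tuple[GenotypeSet, dict[str, list[str]]]:
    """Overwrite disjoint random SNPs so they fail exactly one QC filter.

    Call-rate failures get ~80 % missing calls; MAF failures are made
    monomorphic; HWE failures get an extreme heterozygote deficit
    (half 0, half 2) while keeping MAF at 0.5.  Returns the modified
    panel and the planted SNP ids per filter.
    """
    total = n_callrate + n_maf + n_hwe
    if total > g.n_markers:
        raise ValueError("more planted failures than SNPs")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(g.n_markers, size=total, replace=False)
    cr_idx = chosen[:n_callrate]
    maf_idx = chosen[n_callrate:n_callrate + n_maf]
    hwe_idx = chosen[n_callrate + n_maf:]

    calls = g.calls.copy()
    n = g.n_animals
    for j in cr_idx:
        mask = rng.random(n) < 0.8
        mask[rng.integers(n)] = True  # guarantee at least one missing
        calls[mask, j] = MISSING_CALL
    for j in maf_idx:
        calls[:, j] = 2
    half = n // 2
    for j in hwe_idx:
        order = rng.permutation(n)
        calls[order[:half], j] = 0
        calls[order[half:], j] = 2

    snp_ids = g.markers["snp_id"]
    planted = {
        "callrate": snp_ids.iloc[cr_idx].tolist(),
        "maf": snp_ids.iloc[maf_idx].tolist(),
        "hwe": snp_ids.iloc[hwe_idx].tolist(),
    }
    out = GenotypeSet(animal_ids=list(g.animal_ids), markers=g.markers.copy(), calls=calls)
    return out, planted


def simulate_phenotypes(
    ped: Pedigree, g: GenotypeSet, cfg: SimConfig
) -> tuple[PhenotypeTable, SimTruth]:
    """Phenotypes for the final-generation cows under y = Xb + Wa + e.

    Breeding values are the sum of QTL contributions (QTL drawn among
    panel SNPs with effects sized to the target variance fractions) and a
    pedigree-covariant polygenic remainder; var(a)/var(a+e) targets
    ``h2_target`` among the cows.  Farm/lactation/parity level effects
    are normal with the configured SDs, and the final phenotypes are
    affinely mapped to the configured trait mean and SD.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    cows = phenotyped_ids(ped, cfg)
    if not cows:
        raise ValueError("no phenotyped cows in pedigree")
    cow_pos = ped.index_of(cows)
    n_cows = len(cows)
    n_rec = cfg.n_records_per_cow
    n_obs = n_cows * n_rec

    sigma2_a = cfg.h2_target
    sigma2_e = 1.0 - cfg.h2_target

    # QTL component over all pedigree animals
    fractions = np.asarray(cfg.qtl_variance_fractions[: cfg.n_qtl], dtype=float)
    qtl_idx = np.array([], dtype=np.intp)
    qtl_eff = np.array([])
    bv = np.zeros(ped.n_animals)
    if cfg.h2_target > 0 and cfg.n_qtl > 0:
        freqs = g.calls.astype(float).mean(axis=0) / 2.0
        eligible = np.flatnonzero((freqs > 0.15) & (freqs < 0.85))
        if eligible.size < cfg.n_qtl:
            raise ValueError("not enough polymorphic SNPs to place QTL")
        qtl_idx = np.sort(rng.choice(eligible, size=cfg.n_qtl, replace=False))
        het = 2.0 * freqs[qtl_idx] * (1.0 - freqs[qtl_idx])
        qtl_eff = np.sqrt(fractions * sigma2_a / het) * rng.choice([-1.0, 1.0], cfg.n_qtl)
        centered = g.calls[:, qtl_idx].astype(float) - 2.0 * freqs[qtl_idx]
        bv += centered @ qtl_eff

    # polygenic remainder with pedigree covariance
    poly_frac = 1.0 - fractions.sum() if cfg.n_qtl > 0 else 1.0
    if cfg.h2_target > 0 and poly_frac > 0:
        A = a_matrix(ped).values
        L = np.linalg.cholesky(A + 1e-10 * np.eye(ped.n_animals))
        bv += np.sqrt(poly_frac * sigma2_a) * (L @ rng.standard_normal(ped.n_animals))

    e = rng.standard_normal(n_obs) * np.sqrt(sigma2_e)
    if cfg.h2_target == 0:
        bv[:] = 0.0
        e = rng.standard_normal(n_obs)

    farm_eff = rng.standard_normal(cfg.n_farms) * cfg.farm_sd
    lact_eff = rng.standard_normal(cfg.n_lactations) * cfg.lactation_sd
    par_eff = rng.standard_normal(cfg.n_parities) * cfg.parity_sd
    # one farm per cow; with repeated records the lactation number follows
    # the record index, otherwise cows are sampled at random lactations;
    # parity is random per record so the two factors are not confounded
    farm = np.repeat(rng.integers(cfg.n_farms, size=n_cows), n_rec)
    if n_rec > 1:
        lact = np.tile(np.arange(n_rec) % cfg.n_lactations, n_cows)
    else:
        lact = rng.integers(cfg.n_lactations, size=n_obs)
    parity = rng.integers(cfg.n_parities, size=n_obs)

    obs_pos = np.repeat(cow_pos, n_rec)
    y_raw = bv[obs_pos] + e + farm_eff[farm] + lact_eff[lact] + par_eff[parity]
    sd_raw = float(np.std(y_raw, ddof=1)) or 1.0
    scale = cfg.trait_sd / sd_raw
    y = cfg.trait_mean + (y_raw - float(np.mean(y_raw))) * scale

    a_cows = bv[cow_pos] * scale
    e_scaled = e * scale
    s2a = float(np.var(a_cows, ddof=1))
    s2e = float(np.var(e_scaled, ddof=1))

    table = PhenotypeTable(pd.DataFrame({
        "animal_id": np.repeat(cows, n_rec),
        "trait_name": cfg.trait_name,
        "value": y,
        "farm": [f"farm{f + 1:02d}" for f in farm],
        "lactation": [f"lact{v + 1}" for v in lact],
        "parity": [f"par{v + 1}" for v in parity],
    }))
    truth = SimTruth(
        true_bv=pd.Series(bv * scale, index=ped.animal_ids),
        qtl_marker_indices=qtl_idx,
        qtl_effects=qtl_eff * scale,
        sigma2_a=s2a,
        sigma2_e=s2e,
        realized_h2=s2a / (s2a + s2e) if (s2a + s2e) > 0 else 0.0,
        fixed_effects={"farm": farm_eff * scale, "lactation": lact_eff * scale,
                       "parity": par_eff * scale},
    )
    return table, truth


def subset_animals(g: GenotypeSet, ids) -> GenotypeSet:
    """Restrict a panel to the given animals, preserving their order."""
    lookup = {a: i for i, a in enumerate(g.animal_ids)}
    idx = [lookup[a] for a in ids]
    return GenotypeSet(animal_ids=list(ids), markers=g.markers.copy(), calls=g.calls[idx].copy())


def simulate_dataset(cfg: SimConfig) -> dict:
    """Full synthetic dataset: pedigree, analysis genotype panel,
    phenotypes and ground truth.

    The analysis panel covers ``n_genotyped`` randomly chosen cows (every
    cow when n_genotyped exceeds the cow count); planted QC failures are
    injected into it, and hidden-QTL mode drops the causal SNPs from the
    panel while leaving their phenotypic contribution in place.
    """
    ped = simulate_pedigree(cfg)
    g_full = simulate_genotypes(ped, cfg)
    pheno, truth = simulate_phenotypes(ped, g_full, cfg)

    cows = cow_ids(ped, cfg)
    rng = np.random.default_rng(cfg.seed + 3)
    if cfg.n_genotyped < len(cows):
        chosen = sorted(rng.choice(len(cows), size=cfg.n_genotyped, replace=False))
        genotyped = [cows[i] for i in chosen]
    else:
        genotyped = list(cows)
    panel = subset_animals(g_full, genotyped)

    if cfg.hidden_qtl and truth.qtl_marker_indices.size:
        keep = np.setdiff1d(np.arange(panel.n_markers), truth.qtl_marker_indices)
        panel = GenotypeSet(
            animal_ids=panel.animal_ids,
            markers=panel.markers.loc[keep].reset_index(drop=True),
            calls=panel.calls[:, keep].copy(),
        )

    planted = {"callrate": [], "maf": [], "hwe": []}
    if cfg.plant_callrate_fail or cfg.plant_maf_fail or cfg.plant_hwe_fail:
        panel, planted = plant_qc_failures(
            panel, cfg.seed + 4, cfg.plant_callrate_fail, cfg.plant_maf_fail, cfg.plant_hwe_fail
        )

    return {
        "pedigree": ped,
        "genotypes_all": g_full,
        "panel": panel,
        "phenotypes": pheno,
        "truth": truth,
        "genotyped_ids": genotyped,
        "planted_qc": planted,
    }
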