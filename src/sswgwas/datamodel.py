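"""Core domain types shared by every stage of the single-step GWAS pipeline.

The pipeline operates on three primary inputs — a pedigree, an
additively-coded genotype panel with a marker map, and a phenotype table
with fixed-effect factors — plus a run configuration holding every
threshold and sampler setting.  All containers are thin, validated
wrappers around numpy arrays / pandas frames so downstream linear algebra
can work on plain arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

__all__ = [
    "UNKNOWN_PARENT",
    "MISSING_CALL",
    "Pedigree",
    "GenotypeSet",
    "PhenotypeTable",
    "RunConfig",
    "RelationshipMatrix",
    "VarianceComponents",
]

#: sentinel for an unknown sire/dam in pedigree records
UNKNOWN_PARENT = "0"

#: integer sentinel for a missing genotype call (additive codes are 0/1/2)
MISSING_CALL = -1


@dataclass(frozen=True)
class Pedigree:
    """Topologically ordered pedigree (parents always precede offspring).

    Each record is ``(animal_id, sire_id, dam_id)``; unknown parents are
    stored as :data:`UNKNOWN_PARENT`.  The ordering invariant is what makes
    the tabular relationship-matrix recursions valid, so it is enforced at
    construction time.
    """

    records: tuple[tuple[str, str, str], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for animal, sire, dam in self.records:
            if animal in seen:
                raise ValueError(f"duplicate animal id {animal!r} in pedigree")
            for parent in (sire, dam):
                if parent != UNKNOWN_PARENT and parent not in seen:
                    raise ValueError(
                        f"pedigree not topologically ordered: parent {parent!r} "
                        f"of {animal!r} not declared earlier"
                    )
            seen.add(animal)

    @property
    def animal_ids(self) -> list[str]:
        return [rec[0] for rec in self.records]

    @property
    def n_animals(self) -> int:
        return len(self.records)

    def index_of(self, ids) -> np.ndarray:
        """Positions of ``ids`` in pedigree order (error on unknown id)."""
        lookup = {a: i for i, a in enumerate(self.animal_ids)}
        try:
            return np.array([lookup[a] for a in ids], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"animal id {exc.args[0]!r} not in pedigree") from None

    def parent_indices(self) -> np.ndarray:
        """(n, 2) array of sire/dam positions, -1 for unknown."""
        lookup = {a: i for i, a in enumerate(self.animal_ids)}
        out = np.full((self.n_animals, 2), -1, dtype=np.intp)
        for i, (_, sire, dam) in enumerate(self.records):
            if sire != UNKNOWN_PARENT:
                out[i, 0] = lookup[sire]
            if dam != UNKNOWN_PARENT:
                out[i, 1] = lookup[dam]
        return out


@dataclass
class GenotypeSet:
    """Animals x markers additive genotype panel with its marker map.

    ``calls`` holds 0/1/2 copies of the second (counted) allele, with
    :data:`MISSING_CALL` for no-calls.  Markers are kept sorted by
    (chromosome, position, snp_id); chromosomes are ordered by first
    appearance in the map rather than by numeric value, so non-numeric
    labels (X, contigs) are handled uniformly.
    """

    animal_ids: list[str]
    markers: pd.DataFrame  # columns: snp_id, chromosome, position_bp
    calls: np.ndarray  # int8/int16, shape (n_animals, n_markers)

    def __post_init__(self) -> None:
        self.markers = self.markers.reset_index(drop=True)
        if self.calls.shape != (len(self.animal_ids), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.animal_ids)} animals x {len(self.markers)} markers"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING_CALL))
        if bad.any():
            ai, mi = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype code {self.calls[ai, mi]} at "
                f"(animal {self.animal_ids[ai]!r}, snp {self.markers['snp_id'].iloc[mi]!r})"
            )
        self._sort_markers()

    def _sort_markers(self) -> None:
        chrom_rank = {c: r for r, c in enumerate(pd.unique(self.markers["chromosome"]))}
        order = self.markers.assign(
            _cr=self.markers["chromosome"].map(chrom_rank)
        ).sort_values(["_cr", "position_bp", "snp_id"], kind="stable").index.to_numpy()
        self.markers = self.markers.iloc[order].reset_index(drop=True)
        self.calls = np.ascontiguousarray(self.calls[:, order])

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def has_missing(self) -> bool:
        return bool((self.calls == MISSING_CALL).any())

    def chromosomes(self) -> list:
        """Chromosome labels in map order of first appearance."""
        return list(pd.unique(self.markers["chromosome"]))


@dataclass
class PhenotypeTable:
    """Long-format phenotype records with fixed-effect factor levels.

    One row per (animal, trait) observation; ``farm``, ``lactation`` and
    ``parity`` are categorical labels entering the model as fixed effects.
    """

    data: pd.DataFrame

    REQUIRED = ("animal_id", "trait_name", "value", "farm", "lactation", "parity")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns {missing}")
        self.data = self.data.reset_index(drop=True)

    def traits(self) -> list[str]:
        return sorted(self.data["trait_name"].unique())

    def for_trait(self, trait: str) -> pd.DataFrame:
        sub = self.data[self.data["trait_name"] == trait]
        if sub.empty:
            raise KeyError(f"trait {trait!r} not present in phenotype table")
        return sub.reset_index(drop=True)

    def validate_against(self, ped: Pedigree) -> None:
        known = set(ped.animal_ids)
        unknown = set(self.data["animal_id"]) - known
        if unknown:
            raise ValueError(
                f"phenotyped animals absent from pedigree: {sorted(unknown)[:5]}"
            )


@dataclass
class RunConfig:
    """All tunable thresholds and sampler settings for one pipeline run.

    Defaults follow the study design this pipeline reimplements: strict
    call-rate/MAF/HWE exclusion thresholds of 0.90 / 0.05 / 1e-6, 5-SNP
    windows with a 0.5 % variance-explained cutoff, one re-weighting
    iteration, and a Bonferroni genome-wide level of 0.01/N.  The Gibbs
    chain defaults to a desk-scale 10,000/1,000 (the full-scale analogue
    is 100,000 rounds with 9,000 burn-in).
    """

    call_rate_min: float = 0.90
    maf_min: float = 0.05
    hwe_p_min: float = 1e-6
    tau: float = 0.05  # weight of A22 blended into the tuned G
    window_size: int = 5
    window_step: int = 1
    ve_threshold: float = 0.5  # % of genetic variance, inclusive
    chain_length: int = 10_000
    burn_in: int = 1_000
    thin: int = 10
    seed: int = 1
    reweight_iterations: int = 1
    pvalue_mode: str = "as-printed"  # or "empirical"
    bonferroni_alpha: float = 0.01

    def __post_init__(self) -> None:
        if not (0.0 <= self.call_rate_min <= 1.0):
            raise ValueError("call_rate_min must be in [0, 1]")
        if not (0.0 <= self.maf_min <= 0.5):
            raise ValueError("maf_min must be in [0, 0.5]")
        if not (0.0 <= self.hwe_p_min <= 1.0):
            raise ValueError("hwe_p_min must be in [0, 1]")
        if not (0.0 <= self.tau <= 1.0):
            raise ValueError("tau must be in [0, 1]")
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if self.window_step < 1:
            raise ValueError("window_step must be >= 1")
        if self.burn_in >= self.chain_length:
            raise ValueError("burn_in must be < chain_length")
        if self.reweight_iterations < 0:
            raise ValueError("reweight_iterations must be >= 0")
        if self.pvalue_mode not in ("as-printed", "empirical"):
            raise ValueError("pvalue_mode must be 'as-printed' or 'empirical'")
        if not (0.0 < self.bonferroni_alpha < 1.0):
            raise ValueError("bonferroni_alpha must be in (0, 1)")


@dataclass
class RelationshipMatrix:
    """Symmetric relationship matrix (pedigree A, A22, or genomic G) with
    the animal ordering its rows refer to."""

    animal_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.animal_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("relationship matrix is not symmetric")
        # enforce exact symmetry so downstream factorizations are stable
        self.values = (self.values + self.values.T) / 2.0


@dataclass(frozen=True)
class VarianceComponents:
    """Additive-genetic and residual variances of the animal model."""

    sigma2_a: float
    sigma2_e: float

    def __post_init__(self) -> None:
        if self.sigma2_a <= 0 or self.sigma2_e <= 0:
            raise ValueError("variance components must be strictly positive")

    @property
    def ratio(self) -> float:
        """Mixed-model shrinkage ratio k = sigma2_e / sigma2_a."""
        return self.sigma2_e / self.sigma2_a

    @property
    def h2(self) -> float:
        return self.sigma2_a / (self.sigma2_a + self.sigma2_e)
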