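"""Genotype quality control and genomic relationship machinery.

Covers the genomic side of single-step GBLUP: SNP filtering (call rate,
MAF, Hardy-Weinberg), current-population allele frequencies, the
(optionally marker-weighted) genomic relationship matrix
G* = Z diag(d) Z' * lambda with lambda = 1 / sum 2 p_i (1 - p_i),
two-moment compatibility tuning of G against the pedigree block A22,
blending, and assembly of the single-step inverse
H^-1 = A^-1 + [0 0; 0 G_w^-1 - A22^-1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datamodel import MISSING_CALL, GenotypeSet, RelationshipMatrix, RunConfig

__all__ = [
    "QcReport",
    "MarkerWeights",
    "HInverse",
    "hwe_pvalue",
    "qc_filter",
    "allele_freq",
    "lambda_norm",
    "centered_z",
    "g_matrix",
    "tune_and_blend",
    "h_inverse",
]


@dataclass
class QcReport:
    """Per-filter accounting of SNP removals.

    Each removed SNP is attributed to the first filter it fails, testing
    in the order call-rate -> MAF -> HWE, so the counts always sum to
    n_input - n_retained regardless of overlapping failures.
    """

    n_input: int
    n_removed_callrate: int
    n_removed_maf: int
    n_removed_hwe: int
    n_retained: int
    removed_callrate_ids: list = field(default_factory=list)
    removed_maf_ids: list = field(default_factory=list)
    removed_hwe_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        total = self.n_removed_callrate + self.n_removed_maf + self.n_removed_hwe
        if self.n_input != self.n_retained + total:
            raise ValueError("QC counts do not sum to n_input")


@dataclass
class MarkerWeights:
    """Diagonal of the marker-weight matrix D (nonnegative, at least one
    positive entry)."""

    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.ndim != 1:
            raise ValueError("weights must be a vector")
        if (self.d < 0).any() or not (self.d > 0).any():
            raise ValueError("weights must be nonnegative with at least one positive entry")

    @classmethod
    def identity(cls, n_markers: int) -> "MarkerWeights":
        return cls(np.ones(n_markers))


@dataclass
class HInverse:
    """Single-step H^-1 over all pedigree animals.

    Equals A^-1 outside the genotyped block; inside it carries the
    G_w^-1 - A22^-1 correction.  Metadata records the blend weight tau
    and the compatibility-tuning coefficients (a, b).
    """

    animal_ids: list
    values: np.ndarray
    genotyped_ids: list
    tau: float
    tuning_a: float
    tuning_b: float


def hwe_pvalue(n0: int, n1: int, n2: int) -> float:
    """Hardy-Weinberg goodness-of-fit P-value from genotype counts.

    1-df chi-square against expected counts at the sample allele
    frequency, no continuity correction.  Monomorphic samples return 1
    (no evidence against equilibrium).
    """
    n = n0 + n1 + n2
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    p = (n1 + 2 * n2) / (2 * n)
    if p == 0.0 or p == 1.0:
        return 1.0
    expected = np.array([n * (1 - p) ** 2, n * 2 * p * (1 - p), n * p**2])
    observed = np.array([n0, n1, n2], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def _snp_counts(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP (n0, n1, n2, n_missing) over animals."""
    n0 = (calls == 0).sum(axis=0)
    n1 = (calls == 1).sum(axis=0)
    n2 = (calls == 2).sum(axis=0)
    nm = (calls == MISSING_CALL).sum(axis=0)
    return n0, n1, n2, nm


def qc_filter(g: GenotypeSet, cfg: RunConfig | None = None) -> tuple[GenotypeSet, QcReport]:
    """Apply call-rate, MAF and HWE filters; impute residual missing calls.

    Exclusion is by strict inequality (a SNP exactly at a threshold is
    retained); each removed SNP is attributed to the first filter it
    fails in the order call-rate -> MAF -> HWE.  Missing calls on
    retained SNPs are imputed to the SNP mean rounded to the nearest
    integer code, so post-QC panels contain no missing data.
    """
    cfg = cfg or RunConfig()
    n0, n1, n2, nm = _snp_counts(g.calls)
    n_animals = g.n_animals
    n_typed = n0 + n1 + n2

    call_rate = n_typed / n_animals
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_typed > 0, (n1 + 2 * n2) / (2 * np.maximum(n_typed, 1)), 0.0)
    maf = np.minimum(p, 1 - p)

    fail_cr = call_rate < cfg.call_rate_min
    fail_maf = ~fail_cr & (maf < cfg.maf_min)
    need_hwe = ~fail_cr & ~fail_maf
    hwe_p = np.ones(g.n_markers)
    for j in np.flatnonzero(need_hwe):
        hwe_p[j] = hwe_pvalue(int(n0[j]), int(n1[j]), int(n2[j]))
    fail_hwe = need_hwe & (hwe_p < cfg.hwe_p_min)

    keep = ~(fail_cr | fail_maf | fail_hwe)
    if not keep.any():
        raise ValueError("quality control removed every SNP")

    snp_ids = g.markers["snp_id"]
    report = QcReport(
        n_input=g.n_markers,
        n_removed_callrate=int(fail_cr.sum()),
        n_removed_maf=int(fail_maf.sum()),
        n_removed_hwe=int(fail_hwe.sum()),
        n_retained=int(keep.sum()),
        removed_callrate_ids=snp_ids[fail_cr].tolist(),
        removed_maf_ids=snp_ids[fail_maf].tolist(),
        removed_hwe_ids=snp_ids[fail_hwe].tolist(),
    )

    calls = g.calls[:, keep].astype(np.int16).copy()
    # mean-impute then round: serves synthetic/degenerate inputs only,
    # real panels arrive fully imputed upstream
    for j in range(calls.shape[1]):
        col = calls[:, j]
        miss = col == MISSING_CALL
        if miss.any():
            mean = col[~miss].mean()
            col[miss] = int(np.rint(mean))
    filtered = GenotypeSet(
        animal_ids=list(g.animal_ids),
        markers=g.markers.loc[keep.nonzero()[0]].reset_index(drop=True),
        calls=calls,
    )
    return filtered, report


def allele_freq(g: GenotypeSet) -> np.ndarray:
    """Frequency of the counted (second) allele per SNP, from the current
    population: p_i = mean(calls_i) / 2 over non-missing animals."""
    calls = g.calls.astype(float)
    calls[g.calls == MISSING_CALL] = np.nan
    return np.nanmean(calls, axis=0) / 2.0


def lambda_norm(p: np.ndarray) -> float:
    """Normalisation constant lambda = 1 / sum_i 2 p_i (1 - p_i), the
    ratio of per-marker to total additive variance under unweighted G."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty allele-frequency vector")
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("allele frequencies must be strictly inside (0, 1)")
    return float(1.0 / np.sum(2.0 * p * (1.0 - p)))


def centered_z(g: GenotypeSet, p: np.ndarray) -> np.ndarray:
    """Allele-frequency-centred genotype matrix Z = calls - 2p."""
    if g.has_missing:
        raise ValueError("genotypes must be QC'd/imputed before centering")
    return g.calls.astype(float) - 2.0 * np.asarray(p, dtype=float)


def g_matrix(g: GenotypeSet, p: np.ndarray, w: MarkerWeights | None = None) -> RelationshipMatrix:
    """Weighted genomic relationship matrix G* = Z diag(d) Z' * lambda.

    With d = 1 this is the standard allele-frequency-scaled genomic
    relationship matrix; marker weights d re-emphasise SNPs between
    re-weighting iterations.
    """
    p = np.asarray(p, dtype=float)
    if p.shape[0] != g.n_markers:
        raise ValueError("allele-frequency length does not match marker count")
    w = w or MarkerWeights.identity(g.n_markers)
    if w.d.shape[0] != g.n_markers:
        raise ValueError("weight length does not match marker count")
    Z = centered_z(g, p)
    G = (Z * w.d) @ Z.T * lambda_norm(p)
    return RelationshipMatrix(animal_ids=list(g.animal_ids), values=G)


def tune_and_blend(
    G: RelationshipMatrix, A22: RelationshipMatrix, tau: float = 0.05
) -> tuple[RelationshipMatrix, float, float]:
    """Tune G for compatibility with A22, then blend.

    Solves for scalars (a, b) such that mean(diag(a + bG)) equals
    mean(diag(A22)) and mean(a + bG) equals mean(A22) — a two-moment
    compatibility adjustment — then returns
    G_w = (1 - tau) (a + b G) + tau A22 along with (a, b).
    """
    if G.values.shape != A22.values.shape:
        raise ValueError("G and A22 must have the same dimension")
    if list(G.animal_ids) != list(A22.animal_ids):
        raise ValueError("G and A22 animal orders differ")
    gd, gm = float(np.mean(np.diag(G.values))), float(np.mean(G.values))
    ad, am = float(np.mean(np.diag(A22.values))), float(np.mean(A22.values))
    denom = gd - gm
    if not np.isfinite(denom) or abs(denom) < 1e-12:
        raise ValueError("degenerate G: diagonal and overall means coincide, cannot tune")
    b = (ad - am) / denom
    a = ad - b * gd
    tuned = a + b * G.values
    blended = (1.0 - tau) * tuned + tau * A22.values
    return (
        RelationshipMatrix(animal_ids=list(G.animal_ids), values=blended),
        a,
        b,
    )


def h_inverse(
    Ainv: np.ndarray,
    A22inv: np.ndarray,
    Gwinv: np.ndarray,
    animal_ids: list,
    genotyped_ids: list,
    tau: float = 0.05,
    tuning_a: float = 0.0,
    tuning_b: float = 1.0,
) -> HInverse:
    """Assemble H^-1 = A^-1 + [0 0; 0 G_w^-1 - A22^-1].

    The correction is added only into the genotyped block; rows/columns
    of non-genotyped animals are exactly those of A^-1.
    """
    n = Ainv.shape[0]
    if Ainv.shape != (n, n) or len(animal_ids) != n:
        raise ValueError("A^-1 dimension does not match animal ids")
    lookup = {a: i for i, a in enumerate(animal_ids)}
    idx = np.array([lookup[a] for a in genotyped_ids], dtype=np.intp)
    H = Ainv.copy()
    if idx.size:
        if Gwinv.shape != (idx.size, idx.size) or A22inv.shape != (idx.size, idx.size):
            raise ValueError("genotyped-block matrices do not match genotyped id count")
        H[np.ix_(idx, idx)] += Gwinv - A22inv
    H = (H + H.T) / 2.0
    return HInverse(
        animal_ids=list(animal_ids),
        values=H,
        genotyped_ids=list(genotyped_ids),
        tau=tau,
        tuning_a=tuning_a,
        tuning_b=tuning_b,
    )
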