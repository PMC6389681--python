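"""Back-solving SNP effects from genomic breeding values and testing them.

Given GEBVs of the genotyped animals, allele-substitution effects are
recovered as u = D Z' (Z D Z')^-1 a_g — the marker-space projection of
the animal-space solution.  Per-SNP variance shares u_i^2 2 p_i (1-p_i)
feed the next re-weighting iteration; significance uses a two-sided
t-test with a Bonferroni genome-wide level of alpha/N.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .datamodel import GenotypeSet
from .genomic import MarkerWeights, centered_z, lambda_norm

__all__ = [
    "SnpEffectTable",
    "backsolve_snp_effects",
    "snp_variance_shares",
    "snp_pvalues",
    "bonferroni_threshold",
]

logger = logging.getLogger(__name__)


@dataclass
class SnpEffectTable:
    """Per-SNP results of one back-solving pass."""

    markers: pd.DataFrame  # snp_id, chromosome, position_bp
    u_hat: np.ndarray  # allele-substitution effect, trait units / allele
    var_share: np.ndarray  # per-SNP variance u^2 2p(1-p), trait units^2
    weight_next: np.ndarray  # D diagonal for the next iteration, sums to M
    t_stat: np.ndarray
    p_value: np.ndarray
    minus_log10_p: np.ndarray
    pvalue_mode: str

    def to_frame(self) -> pd.DataFrame:
        return self.markers.assign(
            u_hat=self.u_hat,
            var_share=self.var_share,
            weight_next=self.weight_next,
            t_stat=self.t_stat,
            p_value=self.p_value,
            minus_log10_p=self.minus_log10_p,
        )


def backsolve_snp_effects(
    a_hat_g: np.ndarray,
    g: GenotypeSet,
    p: np.ndarray,
    w: MarkerWeights | None = None,
    fallback_gw: np.ndarray | None = None,
) -> np.ndarray:
    """Back-solve marker effects u = D Z' (Z D Z')^-1 a_g.

    Solves one n x n linear system against the unscaled relationship
    kernel Z D Z' — the lambda in the equivalent form
    u = lambda D Z' G*^-1 a_g cancels because G* = Z D Z' lambda.  If the
    kernel is numerically singular, the solve falls back (with a warning)
    to the blended matrix G_w when supplied, which is invertible by
    construction: u = lambda D Z' G_w^-1 a_g.
    """
    a_hat_g = np.asarray(a_hat_g, dtype=float)
    if a_hat_g.shape[0] != g.n_animals:
        raise ValueError("GEBV vector length does not match genotyped animal count")
    w = w or MarkerWeights.identity(g.n_markers)
    Z = centered_z(g, p)
    ZD = Z * w.d
    K = ZD @ Z.T
    try:
        cf = linalg.cho_factor(K)
        x = linalg.cho_solve(cf, a_hat_g)
    except linalg.LinAlgError:
        if fallback_gw is not None:
            logger.warning("Z D Z' singular; back-solving against the blended G_w instead")
            # trace-normalise D here: the tuning step absorbs any overall
            # scale of D into G_w, so only the normalised weights keep the
            # fallback consistent with the scale-invariant exact solve
            d_norm = w.d * (w.d.size / w.d.sum())
            x = lambda_norm(p) * linalg.solve(fallback_gw, a_hat_g, assume_a="sym")
            return (Z * d_norm).T @ x
        logger.warning("Z D Z' singular and no blended G_w available; "
                       "using the minimum-norm (pseudo-inverse) solution")
        x = np.linalg.pinv(K) @ a_hat_g
    return ZD.T @ x


def snp_variance_shares(
    u_hat: np.ndarray, p: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP variance u_i^2 2 p_i (1 - p_i) and next-iteration weights.

    Weights are the variance shares rescaled to sum to the marker count M
    (constant trace), which keeps the weighted G* on the same scale from
    one re-weighting iteration to the next.
    """
    u_hat = np.asarray(u_hat, dtype=float)
    p = np.asarray(p, dtype=float)
    if u_hat.shape != p.shape:
        raise ValueError("effect and frequency vectors must align")
    var_share = u_hat**2 * 2.0 * p * (1.0 - p)
    total = var_share.sum()
    m = var_share.size
    if total > 0:
        weight_next = var_share * (m / total)
    else:
        weight_next = np.ones(m)
    return var_share, weight_next


def snp_pvalues(
    u_hat: np.ndarray,
    var_share: np.ndarray,
    n_per_snp: np.ndarray | int,
    mode: str = "as-printed",
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided t-test per SNP.

    mode "as-printed" uses t_i = u_i / sqrt(var_share_i / n_i) with
    n_i - 1 degrees of freedom, n_i the number of animals genotyped at
    SNP i.  Because var_share_i is itself u_i^2 2p(1-p), |t_i| depends
    only on p_i — the statistic is degenerate as a test but is provided
    as the literal published recipe.  mode "empirical" standardises each
    effect by the genome-wide SD of u, a common practical alternative.
    """
    u_hat = np.asarray(u_hat, dtype=float)
    var_share = np.asarray(var_share, dtype=float)
    n = np.broadcast_to(np.asarray(n_per_snp), u_hat.shape).astype(float)
    if (n < 2).any():
        raise ValueError("need n >= 2 animals per SNP for a t-test")

    if mode == "as-printed":
        se = np.sqrt(var_share / n)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(u_hat == 0.0, 0.0, u_hat / se)
        bad = (var_share == 0.0) & (u_hat != 0.0)
        if bad.any():
            logger.warning("%d SNPs have zero variance share but nonzero effect; P set to NaN", bad.sum())
            t = np.where(bad, np.nan, t)
    elif mode == "empirical":
        sd = float(np.std(u_hat, ddof=1))
        if sd == 0:
            raise ValueError("all SNP effects identical; empirical standardisation undefined")
        t = u_hat / sd
    else:
        raise ValueError(f"unknown p-value mode {mode!r}")

    pval = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    pval = np.minimum(pval, 1.0)
    return t, pval


def bonferroni_threshold(n_snps: int, alpha: float = 0.01) -> float:
    """Genome-wide significance threshold on the -log10 scale:
    -log10(alpha / N) for N tested SNPs."""
    if n_snps < 1:
        raise ValueError("need at least one SNP")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    return float(-np.log10(alpha / n_snps))
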