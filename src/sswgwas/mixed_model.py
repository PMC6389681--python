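"""Single-trait animal model y = X beta + W a + e.

Builds treatment-coded design matrices, solves the mixed-model equations
(MME) for BLUE/BLUP given variance components, and estimates variance
components by conjugate Gibbs sampling with flat priors.  The random
animal effect has covariance H sigma2_a, where H^-1 blends pedigree and
genomic information (single-step); residuals are iid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .datamodel import Pedigree, PhenotypeTable, RunConfig, VarianceComponents
from .genomic import HInverse

__all__ = ["DesignMatrices", "ModelFit", "GibbsChain", "build_design", "solve_mme", "gibbs_vc"]

logger = logging.getLogger(__name__)

FACTORS = ("farm", "lactation", "parity")


@dataclass
class DesignMatrices:
    """Observation vector with fixed-effect and animal incidence matrices.

    X is treatment-coded (overall mean plus non-reference levels of farm,
    lactation, parity) and full column rank; W maps each record to its
    animal in pedigree order.
    """

    y: np.ndarray
    X: np.ndarray
    W: np.ndarray
    fixed_labels: list[str]
    animal_ids: list[str]  # pedigree order, defines W columns

    @property
    def n_records(self) -> int:
        return self.y.shape[0]


@dataclass
class ModelFit:
    """Solutions of the mixed model: BLUE of fixed effects, BLUP breeding
    values for every pedigree animal, and the variance components used
    (posterior means when estimated by Gibbs)."""

    beta_hat: np.ndarray
    a_hat: np.ndarray
    vc: VarianceComponents
    fixed_labels: list[str]
    animal_ids: list[str]
    posterior: dict = field(default_factory=dict)

    def gebv(self, genotyped_ids) -> np.ndarray:
        """Breeding values of the genotyped animals, in the given order."""
        lookup = {a: i for i, a in enumerate(self.animal_ids)}
        return self.a_hat[[lookup[a] for a in genotyped_ids]]


@dataclass
class GibbsChain:
    """Thinned post-burn-in Gibbs samples of the animal model."""

    sigma2_a: np.ndarray
    sigma2_e: np.ndarray
    beta: np.ndarray  # samples x fixed effects
    a: np.ndarray  # samples x animals
    seed: int
    chain_length: int
    burn_in: int
    thin: int

    @property
    def h2(self) -> np.ndarray:
        return self.sigma2_a / (self.sigma2_a + self.sigma2_e)


def build_design(ph: PhenotypeTable, ped: Pedigree, trait: str) -> DesignMatrices:
    """Design matrices for one trait: overall mean + farm + lactation +
    parity as treatment-coded fixed effects, W as the record->animal
    indicator.  A factor observed at a single level is dropped (warned),
    since its effect is absorbed by the mean."""
    ph.validate_against(ped)
    sub = ph.for_trait(trait)
    n = len(sub)

    cols = [np.ones(n)]
    labels = ["mean"]
    for factor in FACTORS:
        levels = pd.unique(sub[factor])
        if len(levels) < 2:
            logger.warning("factor %r has a single level; dropped from the model", factor)
            continue
        for level in levels[1:]:  # first level is the reference
            cols.append((sub[factor] == level).to_numpy(dtype=float))
            labels.append(f"{factor}:{level}")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design is rank deficient (confounded factor levels)")

    animal_ids = ped.animal_ids
    lookup = {a: i for i, a in enumerate(animal_ids)}
    W = np.zeros((n, len(animal_ids)))
    for r, animal in enumerate(sub["animal_id"]):
        W[r, lookup[animal]] = 1.0

    return DesignMatrices(
        y=sub["value"].to_numpy(dtype=float),
        X=X,
        W=W,
        fixed_labels=labels,
        animal_ids=list(animal_ids),
    )


def _mme_system(d: DesignMatrices, Hinv: np.ndarray, k: float):
    """Left-hand side and right-hand side of Henderson's MME."""
    X, W, y = d.X, d.W, d.y
    top = np.hstack([X.T @ X, X.T @ W])
    bottom = np.hstack([W.T @ X, W.T @ W + k * Hinv])
    lhs = np.vstack([top, bottom])
    rhs = np.concatenate([X.T @ y, W.T @ y])
    return lhs, rhs


def solve_mme(d: DesignMatrices, Hinv: HInverse | np.ndarray, vc: VarianceComponents) -> ModelFit:
    """Solve Henderson's mixed-model equations exactly.

    [X'X   X'W        ] [beta]   [X'y]
    [W'X   W'W + kH^-1] [a   ] = [W'y],   k = sigma2_e / sigma2_a.
    """
    Hmat = Hinv.values if isinstance(Hinv, HInverse) else Hinv
    if Hmat.shape[0] != len(d.animal_ids):
        raise ValueError("H^-1 dimension does not match design animal count")
    lhs, rhs = _mme_system(d, Hmat, vc.ratio)
    try:
        cf = linalg.cho_factor(lhs)
        sol = linalg.cho_solve(cf, rhs)
    except linalg.LinAlgError:
        # name the near-null-space columns to help diagnose confounding
        _, sv, vt = np.linalg.svd(lhs)
        null = np.abs(vt[-1]) > 1e-6
        labels = d.fixed_labels + [f"animal:{a}" for a in d.animal_ids]
        bad = [lab for lab, flag in zip(labels, null) if flag]
        raise ValueError(f"singular mixed-model equations; confounded columns: {bad[:8]}") from None
    resid = np.linalg.norm(lhs @ sol - rhs) / max(np.linalg.norm(rhs), 1e-300)
    if resid > 1e-8:
        raise ArithmeticError(f"MME solve residual {resid:.2e} exceeds tolerance")
    p = d.X.shape[1]
    return ModelFit(
        beta_hat=sol[:p],
        a_hat=sol[p:],
        vc=vc,
        fixed_labels=list(d.fixed_labels),
        animal_ids=list(d.animal_ids),
    )


def _ess(x: np.ndarray) -> float:
    """Effective sample size by the initial-positive-sequence estimator."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 10:
        return float(n)
    xc = x - x.mean()
    var = xc @ xc / n
    if var == 0:
        return float(n)
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (n * var)
    s = 0.0
    for lag in range(1, n // 2):
        if acf[lag] <= 0:
            break
        s += acf[lag]
    return float(n / (1.0 + 2.0 * s))


def gibbs_vc(
    d: DesignMatrices, Hinv: HInverse | np.ndarray, cfg: RunConfig
) -> tuple[GibbsChain, ModelFit]:
    """Estimate variance components by single-block conjugate Gibbs.

    Location effects (beta, a) are drawn jointly from their Gaussian full
    conditional via the MME coefficient matrix at the current variances;
    sigma2_a and sigma2_e come from scaled-inverse-chi-square full
    conditionals with flat priors (degrees of belief -2), using
    quadratic forms a'H^-1 a and e'e.  Deterministic for a fixed seed.
    """
    Hmat = Hinv.values if isinstance(Hinv, HInverse) else Hinv
    rng = np.random.default_rng(cfg.seed)
    n = d.n_records
    p = d.X.shape[1]
    q = len(d.animal_ids)

    vy = float(np.var(d.y, ddof=1)) or 1.0
    s2a, s2e = vy / 2.0, vy / 2.0  # start from an even split

    keep = [it for it in range(cfg.chain_length) if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0]
    n_keep = len(keep)
    samp_a = np.empty(n_keep)
    samp_e = np.empty(n_keep)
    samp_beta = np.empty((n_keep, p))
    samp_u = np.empty((n_keep, q))

    XtX, XtW = d.X.T @ d.X, d.X.T @ d.W
    WtW = d.W.T @ d.W
    rhs = np.concatenate([d.X.T @ d.y, d.W.T @ d.y])
    lhs = np.zeros((p + q, p + q))
    lhs[:p, :p] = XtX
    lhs[:p, p:] = XtW
    lhs[p:, :p] = XtW.T

    kept = 0
    for it in range(cfg.chain_length):
        k = s2e / s2a
        lhs[p:, p:] = WtW + k * Hmat
        cf = linalg.cho_factor(lhs, lower=False)
        mean = linalg.cho_solve(cf, rhs)
        # theta ~ N(mean, sigma2_e * lhs^-1): mean + sqrt(s2e) R^-1 z
        z = rng.standard_normal(p + q)
        theta = mean + np.sqrt(s2e) * linalg.solve_triangular(cf[0], z, lower=False)
        beta, a = theta[:p], theta[p:]

        qa = float(a @ Hmat @ a)
        s2a = qa / rng.chisquare(q - 2)
        e = d.y - d.X @ beta - d.W @ a
        s2e = float(e @ e) / rng.chisquare(n - 2)

        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            samp_a[kept] = s2a
            samp_e[kept] = s2e
            samp_beta[kept] = beta
            samp_u[kept] = a
            kept += 1

    chain = GibbsChain(
        sigma2_a=samp_a[:kept],
        sigma2_e=samp_e[:kept],
        beta=samp_beta[:kept],
        a=samp_u[:kept],
        seed=cfg.seed,
        chain_length=cfg.chain_length,
        burn_in=cfg.burn_in,
        thin=cfg.thin,
    )
    ess_a = _ess(chain.sigma2_a)
    if ess_a < 50:
        logger.warning("sigma2_a effective sample size %.1f < 50; chain may be too short", ess_a)

    vc = VarianceComponents(float(chain.sigma2_a.mean()), float(chain.sigma2_e.mean()))
    fit = solve_mme(d, Hmat, vc)
    fit.posterior = {
        "sigma2_a_mean": vc.sigma2_a,
        "sigma2_a_sd": float(chain.sigma2_a.std(ddof=1)),
        "sigma2_e_mean": vc.sigma2_e,
        "sigma2_e_sd": float(chain.sigma2_e.std(ddof=1)),
        "h2_mean": float(chain.h2.mean()),
        "h2_sd": float(chain.h2.std(ddof=1)),
        "ess_sigma2_a": ess_a,
        "n_samples": int(kept),
    }
    return chain, fit
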