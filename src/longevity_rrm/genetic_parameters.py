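"""Age-scale covariance functions, heritability trajectories, and EBVs.

Coefficient-scale posterior means are mapped onto the 14 evaluated ages
through the Legendre covariate matrix T:

    Sigma = T G0 T'   (additive),  phi = T Rq T'  (HYS),
    theta = T Rp T'   (permanent environment)

and the heritability at age j is the additive diagonal over the total:
h2_j = sigma2_a(j) / (sigma2_a(j) + sigma2_q(j) + sigma2_p(j) + sigma2_e).
An animal's EBV trajectory over the ages is T a_hat_i.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import AGES, VarianceComponents

__all__ = ["covariance_function", "CovarianceFunctions", "covariance_functions",
           "heritability_by_age", "HeritabilityTrajectory", "ebv_trajectories"]

logger = logging.getLogger(__name__)


def covariance_function(T: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Age-scale covariance T M T' with symmetry enforced numerically."""
    T = np.asarray(T, dtype=float)
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1] or T.shape[1] != M.shape[0]:
        raise ValueError(f"dimension mismatch: T is {T.shape}, M is {M.shape}")
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError("M must be symmetric")
    out = T @ M @ T.T
    return (out + out.T) / 2.0


@dataclass
class CovarianceFunctions:
    Sigma: np.ndarray  # additive, 14 x 14
    phi: np.ndarray    # herd-year-season
    theta: np.ndarray  # permanent environment


def covariance_functions(T: np.ndarray, vc: VarianceComponents) -> CovarianceFunctions:
    return CovarianceFunctions(Sigma=covariance_function(T, vc.G0),
                               phi=covariance_function(T, vc.Rq),
                               theta=covariance_function(T, vc.Rp))


@dataclass
class HeritabilityTrajectory:
    ages: np.ndarray
    h2: np.ndarray
    sigma2_a: np.ndarray
    sigma2_q: np.ndarray
    sigma2_p: np.ndarray
    sigma2_e: float
    n_clipped: int = 0

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "h2": self.h2,
                             "sigma2_a": self.sigma2_a, "sigma2_q": self.sigma2_q,
                             "sigma2_p": self.sigma2_p, "sigma2_e": self.sigma2_e})


def heritability_by_age(cf: CovarianceFunctions, sigma_e2: float) -> HeritabilityTrajectory:
    """Per-age heritability from the covariance-function diagonals.

    Negative diagonals (numerical) are clipped at zero with a warning and
    counted in ``n_clipped``.
    """
    if sigma_e2 <= 0:
        raise ValueError("sigma_e2 must be > 0")
    va = np.diag(cf.Sigma).copy()
    vq = np.diag(cf.phi).copy()
    vp = np.diag(cf.theta).copy()
    n_clipped = int((va < 0).sum() + (vq < 0).sum() + (vp < 0).sum())
    if n_clipped:
        logger.warning("clipped %d negative variance diagonals at 0", n_clipped)
    va, vq, vp = np.clip(va, 0, None), np.clip(vq, 0, None), np.clip(vp, 0, None)
    h2 = va / (va + vq + vp + sigma_e2)
    return HeritabilityTrajectory(ages=AGES.copy(), h2=h2, sigma2_a=va,
                                  sigma2_q=vq, sigma2_p=vp,
                                  sigma2_e=float(sigma_e2), n_clipped=n_clipped)


def ebv_trajectories(T: np.ndarray, a_hat: np.ndarray) -> np.ndarray:
    """EBV matrix (animals x ages): row i is T a_hat_i."""
    T = np.asarray(T, dtype=float)
    a_hat = np.atleast_2d(np.asarray(a_hat, dtype=float))
    if a_hat.shape[1] != T.shape[1]:
        raise ValueError(
            f"a_hat has {a_hat.shape[1]} coefficients but T expects {T.shape[1]}")
    return a_hat @ T.T
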