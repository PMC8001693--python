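"""Gibbs sampler for the random-regression model and MCMC diagnostics.

Location effects are updated level-by-level from their conditional
normals (the strategy of the gibbsf90 software family); covariance
matrices of the random-regression coefficients from inverted-Wishart full
conditionals; the residual variance from its scaled inverted chi-squared
conditional. Convergence checking follows Geweke's two-window z-score and
the Heidelberger-Welch stationarity/halfwidth procedure.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
from scipy.stats import invgamma, invwishart

from ._kernels import resample_additive_pe_split, sample_group
from .datatypes import ChainConfig, PriorSpec, VarianceComponents
from .rrm_model import ModelData

__all__ = ["gibbs_sample", "PosteriorDraws", "posterior_summarize",
           "PosteriorSummary", "geweke_diagnostic", "heidelberger_welch",
           "HeidelbergerWelchResult"]

RESIDUAL_REFRESH = 250  # iterations between full residual recomputations


@dataclass
class PosteriorDraws:
    """Retained draws of the variance components plus posterior means of
    every location effect (running averages over retained iterations)."""

    G0: np.ndarray        # (m, k, k)
    Rq: np.ndarray
    Rp: np.ndarray
    sigma_e2: np.ndarray  # (m,)
    location_mean: dict   # group name -> (n_levels, k)
    cfg: ChainConfig
    k: int
    location_draws: Optional[np.ndarray] = None  # (m, total) if requested
    offsets: dict = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return len(self.sigma_e2)


def _scale_move(rng, e, pred_g, theta, M, S0, nu, sig2e, k, step=0.3):
    """Joint Metropolis rescaling of one random effect and its covariance.

    Proposes (theta, M) -> (sqrt(c) theta, c M) with log c ~ N(0, step^2).
    This group move targets the overall scale of the effect -- the slowest
    direction of the single-site Gibbs chain -- and leaves the posterior
    invariant: the Gaussian prior ratio cancels the theta-Jacobian, so

      log alpha = [SSE(e) - SSE(e')]/(2 sig2e) - (k nu/2) log c
                  - (1/c - 1) tr(S0 M^-1)/2

    with e' = e + (1 - sqrt(c)) * pred_g. Returns (accepted, e, theta, M).
    """
    c = float(np.exp(rng.normal(0.0, step)))
    e_new = e + (1.0 - np.sqrt(c)) * pred_g
    log_alpha = (float(e @ e) - float(e_new @ e_new)) / (2.0 * sig2e)
    log_alpha -= 0.5 * k * nu * np.log(c)
    log_alpha -= 0.5 * (1.0 / c - 1.0) * float(np.trace(S0 @ np.linalg.inv(M)))
    if np.log(rng.random()) < log_alpha:
        return True, e_new, np.sqrt(c) * theta, c * M
    return False, e, theta, M


def _group_csr(g):
    order = np.argsort(g.rec_level, kind="stable").astype(np.int64)
    counts = np.bincount(g.rec_level, minlength=g.n_levels)
    ptr = np.zeros(g.n_levels + 1, dtype=np.int64)
    np.cumsum(counts, out=ptr[1:])
    return ptr, order


def _predicted(groups, thetas) -> np.ndarray:
    pred = 0.0
    for g, th in zip(groups, thetas):
        pred = pred + np.einsum("rk,rk->r", g.rec_cov, th[g.rec_level])
    return pred


def gibbs_sample(data: ModelData, priors: Optional[PriorSpec] = None,
                 cfg: Optional[ChainConfig] = None,
                 vc_init: Optional[VarianceComponents] = None,
                 fix_variances: bool = False,
                 store_location_draws: bool = False) -> PosteriorDraws:
    """Run the Gibbs chain and return retained posterior draws.

    With ``fix_variances`` the covariance matrices and residual variance
    stay at ``vc_init`` and only location effects are sampled, which makes
    the chain's stationary mean the BLUP (mixed-model-equation) solution.
    """
    priors = priors or PriorSpec()
    cfg = cfg or ChainConfig()
    k = data.k
    if vc_init is None:
        if fix_variances:
            raise ValueError("fix_variances requires vc_init")
        vc_init = VarianceComponents(0.01 * np.eye(k), 0.01 * np.eye(k),
                                     0.01 * np.eye(k), 0.1)
    rng = np.random.default_rng(cfg.seed)

    G0 = vc_init.G0.copy()
    Rq = vc_init.Rq.copy()
    Rp = vc_init.Rp.copy()
    sig2e = float(vc_init.sigma_e2)

    groups = data.groups
    gidx = {g.name: i for i, g in enumerate(groups)}
    thetas = [np.zeros((g.n_levels, g.k)) for g in groups]
    csr = [_group_csr(g) for g in groups]
    ainv = data.ainv.tocsr()
    ai_indptr = ainv.indptr.astype(np.int64)
    ai_indices = ainv.indices.astype(np.int64)
    ai_data = ainv.data.astype(np.float64)
    empty = np.zeros(0, dtype=np.int64)
    y = data.y.astype(float)
    e = y.copy()
    n_rec = len(y)

    # animal index of each PE level, for the split-interweaving sweep
    pe_anim = None
    pe_g = groups[gidx["pe"]]
    if pe_g.labels is not None and pe_g.n_levels and pe_g.k == k:
        try:
            pe_anim = np.array([int(lab[0]) - 1 for lab in pe_g.labels],
                               dtype=np.int64)
            if pe_anim.min() < 0 or pe_anim.max() >= data.n_animals:
                pe_anim = None
        except (TypeError, IndexError):
            pe_anim = None

    S0g = priors.scale_matrix("g", k)
    S0q = priors.scale_matrix("q", k)
    S0p = priors.scale_matrix("p", k)

    m = cfg.n_retained
    G0_d = np.empty((m, k, k))
    Rq_d = np.empty((m, k, k))
    Rp_d = np.empty((m, k, k))
    se_d = np.empty(m)
    loc_sum = [np.zeros_like(th) for th in thetas]
    total = sum(g.size for g in groups)
    loc_draws = np.empty((m, total)) if store_location_draws else None
    offsets, off = {}, 0
    for g in groups:
        offsets[g.name] = (off, off + g.size)
        off += g.size

    def prior_precision(g):
        if g.kind == "fixed":
            return np.eye(g.k) / priors.sigma_b
        if g.kind == "pedigree":
            return np.linalg.inv(G0)
        return np.linalg.inv(Rq if g.name == "hys" else Rp)

    idx_out = 0
    n_saved = 0
    for it in range(cfg.chain_length):
        for gi, g in enumerate(groups):
            ptr, order = csr[gi]
            z = rng.standard_normal((g.n_levels, g.k))
            Qp = prior_precision(g)
            if g.kind == "pedigree":
                sample_group(ptr, order, g.rec_cov, e, sig2e, thetas[gi], Qp,
                             z, ai_indptr, ai_indices, ai_data, True)
            else:
                sample_group(ptr, order, g.rec_cov, e, sig2e, thetas[gi], Qp,
                             z, empty[:1], empty, ai_data[:0], False)
        if pe_anim is not None:
            resample_additive_pe_split(
                pe_anim, thetas[gidx["animal"]], thetas[gidx["pe"]],
                np.linalg.inv(G0), np.linalg.inv(Rp),
                rng.standard_normal((len(pe_anim), k)),
                ai_indptr, ai_indices, ai_data)

        if (it + 1) % RESIDUAL_REFRESH == 0 and n_rec:
            e = y - _predicted(groups, thetas)

        if not fix_variances:
            a_mat = thetas[gidx["animal"]]
            Sg = S0g + a_mat.T @ (ainv @ a_mat)
            G0 = invwishart.rvs(df=priors.iw_df + data.n_animals,
                                scale=_sym(Sg), random_state=rng).reshape(k, k)
            q_mat = thetas[gidx["hys"]]
            Rq = invwishart.rvs(df=priors.iw_df + q_mat.shape[0],
                                scale=_sym(S0q + q_mat.T @ q_mat),
                                random_state=rng).reshape(k, k)
            p_mat = thetas[gidx["pe"]]
            Rp = invwishart.rvs(df=priors.iw_df + p_mat.shape[0],
                                scale=_sym(S0p + p_mat.T @ p_mat),
                                random_state=rng).reshape(k, k)
            sse = float(e @ e)
            shape = (priors.residual_df + n_rec) / 2.0
            scale = (priors.residual_df * priors.residual_scale + sse) / 2.0
            if shape <= 0:
                raise ValueError("improper residual posterior: no records and "
                                 "residual_df <= 0")
            sig2e = float(invgamma.rvs(shape, scale=scale, random_state=rng))

            # scale moves: jointly rescale each random effect with its
            # covariance matrix to traverse the slow 'overall scale' direction
            mats = {"animal": G0, "hys": Rq, "pe": Rp}
            scales = {"animal": S0g, "hys": S0q, "pe": S0p}
            for name in ("animal", "hys", "pe"):
                gi = gidx[name]
                g = groups[gi]
                if n_rec:
                    pred = np.einsum("rk,rk->r", g.rec_cov,
                                     thetas[gi][g.rec_level])
                else:
                    pred = e  # zero-length
                _, e, thetas[gi], mats[name] = _scale_move(
                    rng, e, pred, thetas[gi], mats[name], scales[name],
                    priors.iw_df, sig2e, k)
            G0, Rq, Rp = mats["animal"], mats["hys"], mats["pe"]

        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0 and n_saved < m:
            G0_d[n_saved] = _sym(G0)
            Rq_d[n_saved] = _sym(Rq)
            Rp_d[n_saved] = _sym(Rp)
            se_d[n_saved] = sig2e
            for ls, th in zip(loc_sum, thetas):
                ls += th
            if store_location_draws:
                loc_draws[n_saved] = np.concatenate([th.ravel() for th in thetas])
            n_saved += 1

    loc_mean = {g.name: ls / max(n_saved, 1) for g, ls in zip(groups, loc_sum)}
    return PosteriorDraws(G0=G0_d[:n_saved], Rq=Rq_d[:n_saved], Rp=Rp_d[:n_saved],
                          sigma_e2=se_d[:n_saved], location_mean=loc_mean,
                          cfg=cfg, k=k, location_draws=loc_draws,
                          offsets=offsets)


def _sym(m: np.ndarray) -> np.ndarray:
    return (m + m.T) / 2.0


@dataclass
class PosteriorSummary:
    vc_mean: VarianceComponents
    vc_sd: dict
    psd_ok: dict


def posterior_summarize(draws: PosteriorDraws) -> PosteriorSummary:
    """Elementwise posterior means and SDs; verifies the mean covariance
    matrices are positive semi-definite."""
    if draws.n_retained < 2:
        raise ValueError("need at least 2 retained draws to summarize")
    means = {name: getattr(draws, name).mean(axis=0) for name in ("G0", "Rq", "Rp")}
    sds = {name + "_sd": getattr(draws, name).std(axis=0, ddof=1)
           for name in ("G0", "Rq", "Rp")}
    sds["sigma_e2_sd"] = float(draws.sigma_e2.std(ddof=1))
    vc = VarianceComponents(G0=means["G0"], Rq=means["Rq"], Rp=means["Rp"],
                            sigma_e2=float(draws.sigma_e2.mean()))
    psd = {name: bool(np.linalg.eigvalsh(means[name]).min() >= -1e-10)
           for name in ("G0", "Rq", "Rp")}
    return PosteriorSummary(vc_mean=vc, vc_sd=sds, psd_ok=psd)


# ---------------------------------------------------------------------------
# Convergence diagnostics


def _spectral_var0(x: np.ndarray) -> float:
    """Spectral density at frequency zero (Bartlett-windowed autocovariance),
    i.e. the large-sample variance of the mean times n."""
    n = len(x)
    xc = x - x.mean()
    g0 = float(xc @ xc) / n
    lags = max(1, int(round(2 * n ** (1 / 3))))
    s = g0
    for l in range(1, min(lags, n - 1) + 1):
        gl = float(xc[:-l] @ xc[l:]) / n
        s += 2.0 * (1.0 - l / (lags + 1.0)) * gl
    return max(s, 0.0)


def geweke_diagnostic(chain, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke's convergence z-score comparing the means of the first 10%
    and last 50% of the chain, with spectral-density variance estimates."""
    x = np.asarray(chain, dtype=float)
    n = len(x)
    if n < 100:
        raise ValueError(f"chain too short for the Geweke diagnostic (n={n})")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance chain")
    a = x[: int(first * n)]
    b = x[n - int(last * n):]
    va, vb = _spectral_var0(a), _spectral_var0(b)
    denom = va / len(a) + vb / len(b)
    if denom <= 0:
        raise ValueError("zero spectral variance in both windows")
    return float((a.mean() - b.mean()) / np.sqrt(denom))


# asymptotic critical values of the Cramer-von Mises distribution
_CVM_CRITICAL = {0.10: 0.3473, 0.05: 0.4614, 0.025: 0.5806, 0.01: 0.7435}


@dataclass
class HeidelbergerWelchResult:
    stationary: bool
    start_fraction: float
    n_kept: int
    mean: float
    halfwidth: float
    halfwidth_ratio: float
    halfwidth_pass: bool
    cvm_statistic: float


def heidelberger_welch(chain, alpha: float = 0.05,
                       eps: float = 0.1) -> HeidelbergerWelchResult:
    """Heidelberger-Welch stationarity (Cramer-von Mises on the Brownian
    bridge of cumulative sums, discarding initial 10% slices up to 50%)
    and halfwidth test (95% interval halfwidth vs eps * |mean|)."""
    x = np.asarray(chain, dtype=float)
    n = len(x)
    if n < 100:
        raise ValueError(f"chain too short for Heidelberger-Welch (n={n})")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance chain")
    crit = _CVM_CRITICAL.get(round(alpha, 4))
    if crit is None:
        raise ValueError(f"alpha must be one of {sorted(_CVM_CRITICAL)}")
    s0_full = _spectral_var0(x[n // 2:])
    stationary, start, cvm = False, 0.0, np.inf
    for frac in (0.0, 0.1, 0.2, 0.3, 0.4, 0.5):
        seg = x[int(frac * n):]
        m = len(seg)
        csum = np.cumsum(seg)
        kk = np.arange(1, m + 1)
        bridge = (csum - kk * seg.mean()) / np.sqrt(m * s0_full)
        cvm = float((bridge ** 2).mean())
        if cvm <= crit:
            stationary, start = True, frac
            break
    if not stationary:
        seg = x  # report on the full chain
    keep = seg
    s0 = _spectral_var0(keep)
    mean = float(keep.mean())
    hw = 1.96 * np.sqrt(s0 / len(keep))
    ratio = hw / abs(mean) if mean != 0 else np.inf
    return HeidelbergerWelchResult(
        stationary=stationary, start_fraction=start, n_kept=len(keep),
        mean=mean, halfwidth=hw, halfwidth_ratio=float(ratio),
        halfwidth_pass=bool(stationary and ratio <= eps),
        cvm_statistic=cvm)
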