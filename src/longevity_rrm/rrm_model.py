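"""Deterministic machinery of the random-regression animal model.

The model for a longevity code y_ij of cow i at age j is

    y = Xb + Hq + Za + Wp + e

where every effect is a curve over age parameterized by k coefficients on
normalized Legendre polynomials of the standardized age. ``b`` holds the
systematic effects (embryo-transfer covariate plus fixed Legendre
regressions per year-season of birth), ``q`` herd-year-season curves,
``a`` additive genetic curves (covariance G0 x A across animals), and
``p`` permanent-environment curves.

This module provides the Legendre covariates, the sparse inverse of the
pedigree relationship matrix A (Henderson's rules with Meuwissen-Luo
inbreeding), model-data assembly shared by the Gibbs sampler, and a
direct mixed-model-equation (BLUP) solver used as the deterministic
oracle for the sampler.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from numpy.polynomial import legendre as npleg

from .datatypes import (AGE_MAX, AGE_MIN, AGES, N_AGES, UNKNOWN_PARENT,
                        Pedigree, PriorSpec, VarianceComponents)

__all__ = [
    "legendre_covariates", "basis_matrix", "inbreeding_coefficients",
    "relationship_matrix", "build_ainverse", "ModelData", "build_model_data",
    "assemble_mme", "solve_blup",
]


def standardize_age(ages) -> np.ndarray:
    """Map ages in [2, 15] onto the Legendre domain [-1, 1]."""
    ages = np.asarray(ages, dtype=float)
    if np.any(ages < AGE_MIN) or np.any(ages > AGE_MAX):
        raise ValueError(f"ages must lie in [{AGE_MIN}, {AGE_MAX}]")
    return 2.0 * (ages - AGE_MIN) / (AGE_MAX - AGE_MIN) - 1.0


def legendre_covariates(ages, k: int, normalized: bool = True) -> np.ndarray:
    """Legendre covariate matrix: column m is P_m (or the normalized
    sqrt((2m+1)/2) * P_m) evaluated at the standardized age."""
    if k < 1:
        raise ValueError("k must be >= 1")
    t = standardize_age(ages)
    V = npleg.legvander(t, k - 1)
    if normalized:
        V = V * np.sqrt((2 * np.arange(k) + 1) / 2.0)
    return V


def basis_matrix(k: int, normalized: bool = True) -> np.ndarray:
    """The 14 x k covariate matrix T over the integer ages 2..15."""
    return legendre_covariates(AGES, k, normalized)


# ---------------------------------------------------------------------------
# Pedigree algebra


def inbreeding_coefficients(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen & Luo recursion.

    Parents are 0-based sentinel ``UNKNOWN_PARENT`` (=0) in 1-based id
    space; animals must be topologically ordered.
    """
    n = len(sire)
    F = np.zeros(n + 1)  # index 0 = unknown parent (non-inbred base)
    # L[i]: contribution accumulator, D: Mendelian variances
    D = np.zeros(n + 1)
    for i in range(1, n + 1):
        s, d = sire[i - 1], dam[i - 1]
        fs = F[s] if s != UNKNOWN_PARENT else -1.0
        fd = F[d] if d != UNKNOWN_PARENT else -1.0
        D[i] = 0.5 - 0.25 * (fs + fd)
        if s == UNKNOWN_PARENT or d == UNKNOWN_PARENT:
            F[i] = 0.0
            continue
        # accumulate ancestor path coefficients, highest id first
        f = -1.0
        Ld = {i: 1.0}
        while Ld:
            j = max(Ld)
            lj = Ld.pop(j)
            f += lj * lj * D[j]
            sj, dj = sire[j - 1], dam[j - 1]
            if sj != UNKNOWN_PARENT:
                Ld[sj] = Ld.get(sj, 0.0) + 0.5 * lj
            if dj != UNKNOWN_PARENT:
                Ld[dj] = Ld.get(dj, 0.0) + 0.5 * lj
        F[i] = f
        # F of i itself does not change D[i] (D uses parents' F only)
    return F[1:]


def relationship_matrix(pedigree: Pedigree) -> np.ndarray:
    """Dense numerator relationship matrix A by the tabular method.

    Quadratic in pedigree size; intended as the small-pedigree oracle.
    """
    n = pedigree.n
    sire, dam = pedigree.sire, pedigree.dam
    A = np.zeros((n + 1, n + 1))
    for i in range(1, n + 1):
        s, d = sire[i - 1], dam[i - 1]
        A[i, i] = 1.0 + 0.5 * A[s, d]
        for j in range(1, i):
            A[i, j] = A[j, i] = 0.5 * (A[j, s] + A[j, d])
    return A[1:, 1:]


def build_ainverse(pedigree: Pedigree, use_inbreeding: bool = True) -> sp.csr_matrix:
    """Sparse A-inverse assembled by Henderson's rules.

    Mendelian-sampling variances d_i use parental inbreeding when
    ``use_inbreeding`` (Meuwissen-Luo); otherwise F=0 for all parents.
    """
    n = pedigree.n
    sire, dam = pedigree.sire, pedigree.dam
    if use_inbreeding:
        F = inbreeding_coefficients(sire, dam)
    else:
        F = np.zeros(n)
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        s, d = sire[i] - 1, dam[i] - 1  # -1 -> unknown
        fs = F[s] if s >= 0 else 0.0
        fd = F[d] if d >= 0 else 0.0
        n_known = int(s >= 0) + int(d >= 0)
        if n_known == 2:
            di = 0.5 - 0.25 * (fs + fd)
        elif n_known == 1:
            di = 0.75 - 0.25 * (fs + fd)
        else:
            di = 1.0
        alpha = 1.0 / di
        add(i, i, alpha)
        for par in (s, d):
            if par >= 0:
                add(i, par, -0.5 * alpha)
                add(par, i, -0.5 * alpha)
        for p1 in (s, d):
            for p2 in (s, d):
                if p1 >= 0 and p2 >= 0:
                    add(p1, p2, 0.25 * alpha)
    ainv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    ainv.sum_duplicates()
    return ainv


# ---------------------------------------------------------------------------
# Model data


@dataclass
class EffectGroup:
    """One effect in the model: per-record level index and covariates."""

    name: str
    kind: str  # 'fixed', 'iid', 'pedigree'
    n_levels: int
    rec_level: np.ndarray  # (n_records,) int32
    rec_cov: np.ndarray    # (n_records, k_g) float64
    labels: Optional[list] = None

    @property
    def k(self) -> int:
        return self.rec_cov.shape[1]

    @property
    def size(self) -> int:
        return self.n_levels * self.k


@dataclass
class ModelData:
    """Assembled observations and design information of one scenario fit."""

    y: np.ndarray
    groups: list
    ainv: sp.csr_matrix
    k: int
    T: np.ndarray
    n_animals: int
    animal_ids: np.ndarray  # pedigree ids, order of the animal-effect levels

    @property
    def n_records(self) -> int:
        return len(self.y)

    def group(self, name: str) -> EffectGroup:
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(name)


def build_model_data(records: pd.DataFrame, histories, pedigree: Pedigree,
                     k: int = 5, use_inbreeding: bool = True,
                     normalized: bool = True) -> ModelData:
    """Combine coded trajectory records with cow metadata into design structures.

    ``records`` is long-format (cow, age, code) with missing codes already
    dropped. HYS classes are the concatenation herd x (birth_year + age) x
    season; the fixed regressions are per year-season-of-birth class.
    """
    meta = {h.cow: h for h in histories}
    recs = records.dropna(subset=["code"]).reset_index(drop=True)
    if len(recs) == 0:
        raise ValueError("no non-missing records to fit")
    cows = recs["cow"].to_numpy(dtype=np.int64)
    ages = recs["age"].to_numpy(dtype=np.int64)
    y = recs["code"].to_numpy(dtype=float)

    missing = set(cows) - set(meta)
    if missing:
        raise KeyError(f"records reference cows without histories: {sorted(missing)[:5]}")

    herd = np.array([meta[c].herd for c in cows])
    byear = np.array([meta[c].birth_year for c in cows])
    bseason = np.array([meta[c].birth_season for c in cows])
    et = np.array([meta[c].et_flag for c in cows], dtype=float)

    phi = legendre_covariates(ages, k, normalized)

    def levels_of(keys):
        uniq, inv = np.unique(keys, axis=0, return_inverse=True)
        return len(uniq), inv.astype(np.int32), [tuple(u) for u in np.atleast_2d(uniq)]

    n_ysb, ysb_idx, ysb_labels = levels_of(np.stack([byear, bseason], axis=1))
    n_hys, hys_idx, hys_labels = levels_of(np.stack([herd, byear + ages, bseason], axis=1))

    animal_ids = pedigree.table["id"].to_numpy()
    anim_idx = (cows - 1).astype(np.int32)  # ids are 1..n in pedigree order
    n_pe, pe_idx, pe_labels = levels_of(cows.reshape(-1, 1))

    groups = [
        EffectGroup("fixed_et", "fixed", 1, np.zeros(len(y), dtype=np.int32),
                    et.reshape(-1, 1)),
        EffectGroup("fixed_ysb", "fixed", n_ysb, ysb_idx, phi, ysb_labels),
        EffectGroup("hys", "iid", n_hys, hys_idx, phi, hys_labels),
        EffectGroup("animal", "pedigree", pedigree.n, anim_idx, phi),
        EffectGroup("pe", "iid", n_pe, pe_idx, phi, pe_labels),
    ]
    ainv = build_ainverse(pedigree, use_inbreeding=use_inbreeding)
    return ModelData(y=y, groups=groups, ainv=ainv, k=k,
                     T=basis_matrix(k, normalized), n_animals=pedigree.n,
                     animal_ids=animal_ids)


# ---------------------------------------------------------------------------
# Mixed-model equations


def _design_matrix(g: EffectGroup, n_records: int) -> sp.csr_matrix:
    k = g.k
    rows = np.repeat(np.arange(n_records), k)
    cols = (g.rec_level[:, None] * k + np.arange(k)[None, :]).ravel()
    return sp.csr_matrix((g.rec_cov.ravel(), (rows, cols)),
                         shape=(n_records, g.size))


def _prior_precision(g: EffectGroup, data: ModelData, vc: VarianceComponents,
                     priors: PriorSpec) -> sp.csr_matrix:
    if g.kind == "fixed":
        return sp.identity(g.size, format="csr") / priors.sigma_b
    if g.kind == "iid":
        M = vc.Rq if g.name == "hys" else vc.Rp
        return sp.kron(sp.identity(g.n_levels), np.linalg.inv(M), format="csr")
    if g.kind == "pedigree":
        return sp.kron(data.ainv, np.linalg.inv(vc.G0), format="csr")
    raise ValueError(g.kind)


@dataclass
class MMESystem:
    C: sp.csr_matrix
    rhs: np.ndarray
    offsets: dict
    data: ModelData
    vc: VarianceComponents


def assemble_mme(data: ModelData, vc: VarianceComponents,
                 priors: Optional[PriorSpec] = None) -> MMESystem:
    """Henderson mixed-model equations for fixed variance components.

    Left-hand side M'M/sigma_e2 + blockdiag(priors); fixed block is
    ridge-stabilized by the vague prior 1/sigma_b.
    """
    priors = priors or PriorSpec()
    M = sp.hstack([_design_matrix(g, data.n_records) for g in data.groups],
                  format="csr")
    C = (M.T @ M) / vc.sigma_e2
    blocks = [_prior_precision(g, data, vc, priors) for g in data.groups]
    C = (C + sp.block_diag(blocks, format="csr")).tocsc()
    rhs = M.T @ data.y / vc.sigma_e2
    offsets, off = {}, 0
    for g in data.groups:
        offsets[g.name] = (off, off + g.size)
        off += g.size
    return MMESystem(C=C, rhs=rhs, offsets=offsets, data=data, vc=vc)


@dataclass
class BLUPSolution:
    solution: np.ndarray
    residual_norm: float
    offsets: dict
    data: ModelData

    def effect(self, name: str) -> np.ndarray:
        """Solutions of one effect, reshaped (n_levels, k)."""
        lo, hi = self.offsets[name]
        g = self.data.group(name)
        return self.solution[lo:hi].reshape(g.n_levels, g.k)


def solve_blup(system: MMESystem, method: str = "auto",
               tol: float = 1e-10, maxiter: int = 20000) -> BLUPSolution:
    """Solve the mixed-model equations.

    'direct' (sparse LU) is exact but its fill-in grows quickly with the
    pedigree coupling; 'cg' uses Jacobi-preconditioned conjugate
    gradients; 'auto' picks direct below 5,000 unknowns and CG above.
    """
    C, rhs = system.C, system.rhs
    if method == "auto":
        method = "direct" if C.shape[0] <= 5000 else "cg"
    if method == "direct":
        sol = spla.spsolve(C, rhs)
    elif method == "cg":
        d = C.diagonal()
        if np.any(d <= 0):
            raise RuntimeError("non-positive diagonal in the mixed-model equations")
        pre = spla.LinearOperator(C.shape, matvec=lambda x: x / d)
        sol, info = spla.cg(C, rhs, rtol=max(tol, 1e-12), maxiter=maxiter, M=pre)
        if info != 0:
            raise RuntimeError(f"CG failed to converge (info={info}, maxiter={maxiter})")
    else:
        raise ValueError(method)
    if not np.all(np.isfinite(sol)):
        raise RuntimeError("singular mixed-model equations: non-finite solution")
    res = float(np.linalg.norm(C @ sol - rhs) / max(np.linalg.norm(rhs), 1e-300))
    return BLUPSolution(solution=sol, residual_norm=res,
                        offsets=system.offsets, data=system.data)
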