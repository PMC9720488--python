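"""REML estimation for the single-trait animal model.

The model is ``y = Xb + a + e`` with one record per animal,
``a ~ N(0, K * sigma_a^2)`` for a pedigree (A) or genomic (G) relationship
matrix K, and ``e ~ N(0, I * sigma_e^2)``. After a one-time
eigendecomposition ``K = U D U'``, the rotated model has a diagonal
covariance ``sigma_e^2 (gamma D + I)`` in terms of the variance ratio
``gamma = sigma_a^2 / sigma_e^2``, so the restricted likelihood profiles
analytically over ``sigma_e^2`` and reduces to a one-dimensional
maximisation over ``gamma`` (coarse grid plus Brent refinement). Standard
errors come from the inverse average-information matrix evaluated at the
optimum, with the delta method for heritability. The eigendecomposition can
be reused across traits and simulation replicates that share K.

Additive genetic variance is tested with a likelihood-ratio test against
the no-animal-effect model (``gamma = 0``); because the null value lies on
the boundary of the parameter space, the default reference distribution is
the 50:50 mixture of a point mass at zero and a 1-df chi-square.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy.stats import chi2

from .kinship import RelationshipMatrix

__all__ = [
    "ModelSpec",
    "VarCompEstimate",
    "KinshipEig",
    "eigendecompose",
    "build_design",
    "fit_animal_model",
    "heritability",
    "lrt_additive_variance",
]


@dataclass
class ModelSpec:
    """Trait model: response column, categorical fixed factors (plus an
    implicit intercept), the animal-id column and the relationship source."""

    response: str
    fixed_factors: list[str]
    animal_col: str = "animal"
    relationship: str = "pedigree_A"


@dataclass
class VarCompEstimate:
    sigma_a2: float
    sigma_e2: float
    h2: float
    se_h2: float
    logL: float
    reduced_logL: float
    converged: bool
    boundary: bool
    identifiable: bool
    n_records: int
    n_evaluations: int
    cov: np.ndarray | None = None  # 2x2 sampling covariance of (sigma_a2, sigma_e2)
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "sigma_a2": self.sigma_a2,
            "sigma_e2": self.sigma_e2,
            "h2": self.h2,
            "se_h2": self.se_h2,
            "logL": self.logL,
            "reduced_logL": self.reduced_logL,
            "converged": self.converged,
            "boundary": self.boundary,
            "identifiable": self.identifiable,
            "n_records": self.n_records,
            "message": self.message,
        }


@dataclass
class KinshipEig:
    """Cached eigendecomposition K = U diag(d) U' over an ordered id set."""

    ids: list[str]
    U: np.ndarray
    d: np.ndarray


def eigendecompose(K: RelationshipMatrix) -> KinshipEig:
    d, U = linalg.eigh(K.matrix)
    return KinshipEig(list(K.ids), U, np.clip(d, 0.0, None))


def build_design(
    df: pd.DataFrame, factors: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Intercept plus treatment-coded dummies for each categorical factor,
    dropping aliased (linearly dependent) columns deterministically in
    first-occurrence order — e.g. an age class fully confounded with an
    earlier plate or hatch-week column loses its own columns."""
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for f in factors:
        if f not in df.columns:
            raise KeyError(f"fixed factor column {f!r} not in data")
        dummies = pd.get_dummies(df[f].astype("category"), prefix=f, drop_first=True)
        for c in dummies.columns:
            cols.append(dummies[c].to_numpy(dtype=float))
            names.append(str(c))
    X = np.column_stack(cols)
    # sequential rank check: drop columns dependent on earlier ones
    while True:
        R = linalg.qr(X, mode="economic")[1]
        diag = np.abs(np.diag(R))
        bad = np.flatnonzero(diag < 1e-8 * max(diag.max(), 1.0))
        if bad.size == 0:
            break
        j = int(bad[0])
        warnings.warn(
            f"dropping aliased fixed-effect column {names[j]!r}", stacklevel=2
        )
        X = np.delete(X, j, axis=1)
        del names[j]
    return X, names


def _profile_reml(
    yt: np.ndarray, Xt: np.ndarray, d: np.ndarray, gamma: float
) -> tuple[float, float, np.ndarray]:
    """Restricted log-likelihood at variance ratio gamma, with profiled
    sigma_e^2 and GLS fixed effects. Returns (logL, sigma_e2, beta)."""
    n, p = Xt.shape
    w = gamma * d + 1.0
    Xw = Xt / w[:, None]
    XtWX = Xt.T @ Xw
    beta = linalg.solve(XtWX, Xw.T @ yt, assume_a="pos")
    r = yt - Xt @ beta
    rss = float(np.sum(r * r / w))
    sigma_e2 = max(rss / (n - p), 1e-300)
    sign, logdet = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return -np.inf, sigma_e2, beta
    logL = -0.5 * (
        (n - p) * math.log(2.0 * math.pi * sigma_e2)
        + (n - p)
        + float(np.sum(np.log(w)))
        + logdet
    )
    return logL, sigma_e2, beta


def _average_information(
    yt: np.ndarray, Xt: np.ndarray, d: np.ndarray, sigma_a2: float, sigma_e2: float
) -> np.ndarray:
    """2x2 average-information matrix for (sigma_a2, sigma_e2) in the
    rotated basis, via projector-vector products only."""
    v = sigma_a2 * d + sigma_e2
    Xv = Xt / v[:, None]
    C = Xt.T @ Xv
    cho = linalg.cho_factor(C)

    def P(z: np.ndarray) -> np.ndarray:
        return z / v - Xv @ linalg.cho_solve(cho, Xv.T @ z)

    q = P(yt)
    u_a = d * q          # dV/dsigma_a2 . Py
    u_e = q              # dV/dsigma_e2 . Py
    Pu_a = P(u_a)
    Pu_e = P(u_e)
    return 0.5 * np.array(
        [
            [u_a @ Pu_a, u_a @ Pu_e],
            [u_e @ Pu_a, u_e @ Pu_e],
        ]
    )


def fit_animal_model(
    df: pd.DataFrame,
    spec: ModelSpec,
    K: RelationshipMatrix | None = None,
    k_eig: KinshipEig | None = None,
    gamma_max: float = 1e3,
    n_grid: int = 41,
    tol: float = 1e-8,
) -> VarCompEstimate:
    """REML fit of the animal model for one trait.

    ``df`` must hold the response, the fixed-factor columns and the animal
    id, one row per animal; rows with a missing response are dropped.
    Either ``K`` (covering all animals in ``df``) or a matching
    precomputed ``k_eig`` must be given.
    """
    data = df.dropna(subset=[spec.response])
    animals = data[spec.animal_col].tolist()
    if len(animals) != len(set(animals)):
        raise ValueError("animal model requires one record per animal")
    if len(animals) < 2:
        raise ValueError("need at least two phenotyped animals")
    y = data[spec.response].to_numpy(dtype=float)
    if y.var() == 0:
        raise ValueError("response has zero variance")

    if k_eig is not None and set(k_eig.ids) == set(animals):
        order = {a: i for i, a in enumerate(animals)}
        idx = [order[a] for a in k_eig.ids]
        data = data.iloc[idx]
        y = y[idx]
        eig = k_eig
    else:
        if K is None:
            raise ValueError("provide K or a k_eig matching the phenotyped animals")
        eig = eigendecompose(K.submatrix(animals))

    X, _ = build_design(data, spec.fixed_factors)
    yt = eig.U.T @ y
    Xt = eig.U.T @ X
    d = eig.d
    n, p = Xt.shape

    n_eval = 0

    def logl(gamma: float) -> float:
        nonlocal n_eval
        n_eval += 1
        return _profile_reml(yt, Xt, d, gamma)[0]

    grid = np.concatenate([[0.0], np.geomspace(1e-4, gamma_max, n_grid - 1)])
    values = np.array([logl(g) for g in grid])
    reduced_logL = float(values[0])
    best = int(np.argmax(values))
    flat = values.max() - values.min() < 1e-6

    boundary = False
    if best == 0:
        gamma_hat = 0.0
        boundary = True
    else:
        lo = grid[max(best - 1, 0)] if best > 1 else 1e-8
        hi = grid[min(best + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(
            lambda t: -logl(math.exp(t)),
            bounds=(math.log(max(lo, 1e-10)), math.log(hi)),
            method="bounded",
            options={"xatol": 1e-9},
        )
        gamma_hat = math.exp(res.x)
        if logl(gamma_hat) < values[best]:
            gamma_hat = float(grid[best])
        if gamma_hat <= 1.5e-4:
            boundary = True

    logL, sigma_e2, _ = _profile_reml(yt, Xt, d, gamma_hat)
    sigma_a2 = gamma_hat * sigma_e2
    floor = 1e-8 * y.var()
    sigma_e2 = max(sigma_e2, floor)
    total = sigma_a2 + sigma_e2
    h2 = sigma_a2 / total

    cov = None
    se_h2 = math.nan
    identifiable = not flat
    message = "flat restricted likelihood in gamma" if flat else ""
    if identifiable:
        AI = _average_information(yt, Xt, d, sigma_a2, sigma_e2)
        try:
            if np.linalg.cond(AI) > 1e10:
                raise np.linalg.LinAlgError("ill-conditioned AI matrix")
            cov = np.linalg.inv(AI)
            grad = np.array([sigma_e2, -sigma_a2]) / total**2
            se_h2 = float(math.sqrt(max(grad @ cov @ grad, 0.0)))
        except np.linalg.LinAlgError:
            identifiable = False
            message = "average-information matrix singular"

    return VarCompEstimate(
        sigma_a2=float(sigma_a2),
        sigma_e2=float(sigma_e2),
        h2=float(h2),
        se_h2=se_h2,
        logL=float(logL),
        reduced_logL=reduced_logL,
        converged=True,
        boundary=boundary,
        identifiable=identifiable,
        n_records=n,
        n_evaluations=n_eval,
        cov=cov,
        message=message,
    )


def heritability(est: VarCompEstimate) -> tuple[float, float]:
    """h2 = sigma_a^2 / (sigma_a^2 + sigma_e^2) with its delta-method SE."""
    total = est.sigma_a2 + est.sigma_e2
    if total <= 0:
        raise ValueError("zero total variance")
    return est.h2, est.se_h2


def lrt_additive_variance(
    full: VarCompEstimate,
    reduced_logL: float | None = None,
    boundary_mixture: bool = True,
) -> tuple[float, float]:
    """Likelihood-ratio test of sigma_a^2 = 0.

    The statistic is ``2 (logL_full - logL_reduced)`` clipped at zero; the
    p-value uses the boundary mixture ``0.5 chi2_0 + 0.5 chi2_1`` by
    default (``p = 0.5 P(chi2_1 >= stat)``, so a zero statistic gives
    p = 0.5), or a plain 1-df chi-square when ``boundary_mixture=False``.
    """
    if reduced_logL is None:
        reduced_logL = full.reduced_logL
    stat = 2.0 * (full.logL - reduced_logL)
    if stat < -1e-6:
        warnings.warn(
            f"reduced logL exceeds full logL by {-stat / 2:.3g}; clipping", stacklevel=2
        )
    stat = max(stat, 0.0)
    tail = float(chi2.sf(stat, df=1)) if stat > 0 else 1.0
    p = 0.5 * tail if boundary_mixture else tail
    return stat, p
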