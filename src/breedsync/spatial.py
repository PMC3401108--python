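"""Moran's I spatial autocorrelation with the standard-deviate (z) test.

Used as a diagnostic: populations at nearby locations share environments,
so residual spatial structure would bias the comparative regression. The
global Moran statistic over values v with spatial weights W is

    I = (n / S0) * sum_ab W_ab (v_a - vbar)(v_b - vbar) / sum_a (v_a - vbar)^2

with null expectation E[I] = -1/(n-1). The "standard deviate" z uses the
variance of I under the normality assumption; a 999-permutation null is
available as a cross-check.

Weights default to row-standardized k-nearest-neighbour (k = 4) adjacency
on great-circle distances, symmetrized by the max rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class SpatialWeights:
    W: np.ndarray
    scheme: str  # "knn" | "inverse_distance"
    row_standardized: bool


@dataclass(frozen=True)
class MoranResult:
    I: float
    expected_I: float
    variance_I: float
    z: float
    p: float


def great_circle_matrix(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Pairwise great-circle distances (km) from latitude/longitude degrees."""
    phi = np.radians(np.asarray(lat, float))
    lam = np.radians(np.asarray(lon, float))
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = (np.sin(dphi / 2) ** 2
         + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2)
    a = np.clip(a, 0.0, 1.0)
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def build_weights(
    lat: np.ndarray,
    lon: np.ndarray,
    scheme: str = "knn",
    k: int = 4,
    row_standardize: bool = True,
) -> SpatialWeights:
    """Spatial weights from coordinates.

    knn: weight 1 to the k nearest neighbours of each point, symmetrized
    with the max rule (a link in either direction counts). inverse_distance:
    W_ab = 1/d_ab; coincident points get an epsilon offset with a warning.
    """
    D = great_circle_matrix(lat, lon)
    n = D.shape[0]
    if scheme == "knn":
        if n < k + 1:
            raise ValueError(f"knn needs n >= k+1 (n={n}, k={k})")
        W = np.zeros((n, n))
        for i in range(n):
            order = np.argsort(D[i], kind="stable")
            nearest = [j for j in order if j != i][:k]
            W[i, nearest] = 1.0
        W = np.maximum(W, W.T)
    elif scheme == "inverse_distance":
        off = ~np.eye(n, dtype=bool)
        if (D[off] == 0).any():
            logger.warning("coincident coordinates; applying epsilon offset")
            D = D + 1e-6 * np.where(off & (D == 0), 1.0, 0.0)
        W = np.zeros((n, n))
        W[off] = 1.0 / D[off]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    np.fill_diagonal(W, 0.0)
    if row_standardize:
        rs = W.sum(axis=1, keepdims=True)
        rs[rs == 0] = 1.0
        W = W / rs
    return SpatialWeights(W=W, scheme=scheme, row_standardized=row_standardize)


def morans_i(values: np.ndarray, weights: SpatialWeights) -> MoranResult:
    """Global Moran's I with the normality-assumption z test (two-sided)."""
    v = np.asarray(values, float)
    W = weights.W
    n = v.size
    if n < 4:
        raise ValueError("need n >= 4")
    d = v - v.mean()
    ss = float(d @ d)
    if ss == 0:
        raise ValueError("zero variance in values")
    S0 = float(W.sum())
    if S0 == 0:
        raise ValueError("zero total weight")
    I = (n / S0) * float(d @ W @ d) / ss

    EI = -1.0 / (n - 1)
    S1 = 0.5 * float(((W + W.T) ** 2).sum())
    S2 = float(((W.sum(axis=1) + W.sum(axis=0)) ** 2).sum())
    var = (n * n * S1 - n * S2 + 3.0 * S0 * S0) / ((n * n - 1.0) * S0 * S0) - EI * EI
    z = (I - EI) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return MoranResult(I=I, expected_I=EI, variance_I=var, z=z, p=p)


def morans_i_permutation(
    values: np.ndarray,
    weights: SpatialWeights,
    n_perm: int = 999,
    seed: int = 0,
) -> float:
    """Two-sided permutation P for Moran's I (cross-check of the z test)."""
    rng = np.random.default_rng(seed)
    obs = morans_i(values, weights)
    v = np.asarray(values, float)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = morans_i(rng.permutation(v), weights).I
    # two-sided: distance from the null expectation
    more_extreme = np.abs(null - obs.expected_I) >= abs(obs.I - obs.expected_I)
    return float((1 + more_extreme.sum()) / (1 + n_perm))
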