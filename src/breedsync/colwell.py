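"""Colwell's predictability statistics for periodic environmental time series.

Colwell (1974) quantifies how predictable a periodic environmental variable
is by tabulating discretized observations into a state-by-time-of-year
frequency matrix and decomposing predictability (P) into two additive
components:

* **constancy** (C) — how invariant the variable is overall; high when the
  same state occurs regardless of season or year;
* **contingency** (M) — how strictly the state depends on time of year; the
  strength of the seasonal pattern.

With column totals ``X_j`` (per time-of-year category), row totals ``Y_i``
(per state), grand total ``Z`` and Shannon entropies

    H(X)  = -sum_j (X_j/Z) log(X_j/Z)
    H(Y)  = -sum_i (Y_i/Z) log(Y_i/Z)
    H(XY) = -sum_ij (N_ij/Z) log(N_ij/Z)

the statistics are

    C = 1 - H(Y)/log s
    M = (H(X) + H(Y) - H(XY))/log s
    P = 1 - (H(XY) - H(X))/log s = C + M

All three lie in [0, 1] and are invariant to the logarithm base (natural
log is used internally; the division by ``log s`` cancels the base). The
convention ``0 log 0 = 0`` applies throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DiscretizeScheme = str  # "equal_width_global" | "equal_width_local" | "quantile"

_SCHEMES = ("equal_width_global", "equal_width_local", "quantile")


@dataclass(frozen=True)
class FrequencyMatrix:
    """State-by-time-of-year count matrix, the input to Colwell's entropies.

    ``N[i, j]`` counts observations of state ``i`` at time-of-year category
    ``j``, pooled across years.
    """

    N: np.ndarray  # (s, t) non-negative counts

    def __post_init__(self) -> None:
        N = np.asarray(self.N, dtype=float)
        if N.ndim != 2:
            raise ValueError("frequency matrix must be 2-dimensional")
        if (N < 0).any():
            raise ValueError("frequency matrix counts must be non-negative")
        object.__setattr__(self, "N", N)

    @property
    def s(self) -> int:
        return self.N.shape[0]

    @property
    def t(self) -> int:
        return self.N.shape[1]

    @property
    def X(self) -> np.ndarray:
        """Column totals (observations per time-of-year category)."""
        return self.N.sum(axis=0)

    @property
    def Y(self) -> np.ndarray:
        """Row totals (observations per state)."""
        return self.N.sum(axis=1)

    @property
    def Z(self) -> float:
        return float(self.N.sum())


@dataclass(frozen=True)
class PredictabilityResult:
    """Constancy C, contingency M, predictability P = C + M, plus entropies."""

    constancy: float
    contingency: float
    predictability: float
    H_X: float
    H_Y: float
    H_XY: float


def _entropy(counts: np.ndarray, Z: float) -> float:
    """Shannon entropy (nats) of counts/Z with the 0 log 0 = 0 convention."""
    p = np.asarray(counts, dtype=float).ravel() / Z
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def discretize(
    values: np.ndarray,
    n_states: int,
    scheme: DiscretizeScheme = "equal_width_local",
) -> np.ndarray:
    """Assign each observation to one of ``n_states`` ordinal states (1..s).

    Schemes
    -------
    equal_width_global
        Bins of equal width spanning the full NDVI range [-1, 1].
    equal_width_local
        Bins of equal width spanning [min, max] of this series.
    quantile
        Bins at the empirical quantiles of this series.

    Boundary values fall in the lower bin, except the overall maximum which
    joins the top bin.
    """
    values = np.asarray(values, dtype=float)
    if n_states < 2:
        raise ValueError("n_states must be at least 2")
    if scheme not in _SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {_SCHEMES}")

    if scheme == "equal_width_global":
        edges = np.linspace(-1.0, 1.0, n_states + 1)
    elif scheme == "equal_width_local":
        lo, hi = values.min(), values.max()
        if lo == hi:
            # Degenerate but well defined: everything lands in state 1.
            return np.ones(values.shape, dtype=int)
        edges = np.linspace(lo, hi, n_states + 1)
    else:  # quantile
        if values.min() == values.max():
            raise ValueError(
                "quantile scheme undefined for a constant series; "
                "use an equal_width scheme instead"
            )
        edges = np.quantile(values, np.linspace(0.0, 1.0, n_states + 1))

    # Lower-closed convention: a value on an interior edge joins the lower
    # bin; the overall maximum falls in the top bin.
    states = np.searchsorted(edges[1:-1], values, side="left") + 1
    return states.astype(int)


def build_frequency_matrix(
    states: np.ndarray,
    periods: np.ndarray,
    n_states: int | None = None,
    periods_per_year: int | None = None,
) -> FrequencyMatrix:
    """Tabulate state labels by time-of-year category, pooling across years.

    Parameters
    ----------
    states : integer state labels in 1..s, one per observation
    periods : within-year period index in 0..t-1, one per observation
    n_states, periods_per_year : matrix dimensions; inferred from the data
        when omitted.

    Observations with missing (NaN) state or period are skipped with a
    logged count.
    """
    states = np.asarray(states, dtype=float)
    periods = np.asarray(periods, dtype=float)
    if states.shape != periods.shape:
        raise ValueError("states and periods must align")
    ok = ~(np.isnan(states) | np.isnan(periods))
    n_missing = int((~ok).sum())
    if n_missing:
        logger.info("build_frequency_matrix: skipped %d missing entries", n_missing)
    states = states[ok].astype(int)
    periods = periods[ok].astype(int)

    s = n_states if n_states is not None else int(states.max())
    t = periods_per_year if periods_per_year is not None else int(periods.max()) + 1
    N = np.zeros((s, t))
    np.add.at(N, (states - 1, periods), 1.0)
    return FrequencyMatrix(N)


def colwell_metrics(fm: FrequencyMatrix) -> PredictabilityResult:
    """Compute constancy, contingency and predictability from a frequency matrix."""
    if fm.Z <= 0:
        raise ValueError("frequency matrix is empty (Z = 0)")
    if fm.s < 2:
        raise ValueError("constancy undefined for s < 2 states (log s = 0)")

    Z = fm.Z
    H_X = _entropy(fm.X, Z)
    H_Y = _entropy(fm.Y, Z)
    H_XY = _entropy(fm.N, Z)
    log_s = np.log(fm.s)

    C = 1.0 - H_Y / log_s
    M = (H_X + H_Y - H_XY) / log_s
    P = 1.0 - (H_XY - H_X) / log_s
    return PredictabilityResult(
        constancy=C, contingency=M, predictability=P, H_X=H_X, H_Y=H_Y, H_XY=H_XY
    )


def location_predictability(
    values: np.ndarray,
    periods: np.ndarray,
    n_states: int = 8,
    scheme: DiscretizeScheme = "equal_width_local",
) -> PredictabilityResult:
    """Discretize a location NDVI series and compute Colwell's statistics.

    ``values`` and ``periods`` are parallel arrays over all observed
    (year, period) time steps.
    """
    states = discretize(values, n_states, scheme)
    fm = build_frequency_matrix(states, periods, n_states=n_states)
    return colwell_metrics(fm)


def predictability_table(
    location_values: dict[str, tuple[np.ndarray, np.ndarray]],
    n_states: int = 8,
    scheme: DiscretizeScheme = "equal_width_local",
) -> pd.DataFrame:
    """Per-location C/M/P table for a mapping location_id -> (values, periods)."""
    rows = []
    for loc, (values, periods) in location_values.items():
        res = location_predictability(values, periods, n_states=n_states, scheme=scheme)
        rows.append(
            {
                "location_id": loc,
                "constancy": res.constancy,
                "contingency": res.contingency,
                "predictability": res.predictability,
                "s": n_states,
                "t": int(np.asarray(periods).max()) + 1,
                "Z": len(np.asarray(values)),
            }
        )
    return pd.DataFrame(rows)
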