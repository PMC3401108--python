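"""Phylogenetic generalized least squares (PGLS) regression with Pagel's
lambda, AICc model comparison, and the auxiliary ordinary regressions.

The response is the natural log of birth-season length in days; candidate
predictors are NDVI contingency (seasonality), NDVI constancy (inter-annual
stability), absolute latitude, diet type, calf behaviour and gregariousness.
Residuals are modelled as MVN(0, sigma2 * V(lambda)) where V is the
population-level phylogenetic covariance and lambda scales its off-diagonal
entries; lambda is estimated by maximum likelihood jointly with each model
(profile likelihood on [0, 1]).

For fixed lambda the GLS estimates are

    beta_hat = (X' V^-1 X)^-1 X' V^-1 y,   sigma2_ML = r' V^-1 r / n

computed through the Cholesky factor of V (whitening), never an explicit
inverse. Standard errors for inference use the n - p denominator; P-values
are two-sided Student-t with n - p degrees of freedom. Model comparison
uses AICc = AIC + 2k(k+1)/(n-k-1) with k counting beta, sigma2 and lambda
(when estimated).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cholesky, solve_triangular
from scipy.optimize import minimize_scalar

from .phylo import lambda_transform

logger = logging.getLogger(__name__)

#: Variable-name mapping from formula vocabulary to trait-table columns.
FORMULA_VARS = {
    "Contingency": "contingency",
    "Constancy": "constancy",
    "Latitude": "latitude",
    "Diet": "diet",
    "Calf Behaviour": "calf_behaviour",
    "Gregariousness": "gregariousness",
}

#: Treatment-coding reference levels for the categorical predictors.
CATEGORICAL_LEVELS = {
    "diet": ("browser", "grazer", "mixed"),            # reference: browser
    "calf_behaviour": ("follower", "hider"),            # reference: follower
}

#: The default candidate set: every formula considered in the analysis.
CANDIDATE_FORMULAS = (
    "Contingency * Constancy",
    "Contingency * Constancy + Gregariousness",
    "Contingency + Constancy",
    "Contingency * Constancy + Calf Behaviour",
    "Contingency + Constancy + Gregariousness",
    "Contingency + Constancy + Latitude",
    "Contingency * Constancy + Diet",
    "Contingency + Constancy + Calf Behaviour",
    "Contingency + Constancy + Diet",
    "Latitude + Contingency",
    "Latitude + Contingency + Calf Behaviour",
    "Latitude + Contingency + Diet",
    "Latitude + Contingency + Gregariousness",
    "Latitude + Contingency * Diet",
    "Latitude",
    "Contingency",
    "Latitude + Constancy",
    "Latitude + Diet",
    "Latitude + Constancy + Diet",
    "Latitude + Constancy * Diet",
    "Constancy",
    "Calf Behaviour",
    "Diet",
)


# ---------------------------------------------------------------------------
# Model specification and design matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """A formula as a list of terms; interactions are ('a', 'b') tuples."""

    formula: str
    terms: tuple  # of str (main effect) or tuple[str, str] (interaction)

    @property
    def mains(self) -> list[str]:
        return [t for t in self.terms if isinstance(t, str)]

    @property
    def interactions(self) -> list[tuple[str, str]]:
        return [t for t in self.terms if isinstance(t, tuple)]


def parse_formula(formula: str) -> ModelSpec:
    """Parse a formula like ``"Contingency * Constancy + Diet"``.

    ``a * b`` expands to ``a + b + a:b`` (the hierarchy rule: an interaction
    always brings in both main effects).
    """
    mains: list[str] = []
    inters: list[tuple[str, str]] = []

    def add_main(name: str) -> None:
        if name not in FORMULA_VARS:
            raise ValueError(f"unknown variable {name!r} in formula {formula!r}")
        if name not in mains:
            mains.append(name)

    for chunk in (c.strip() for c in formula.split("+")):
        if "*" in chunk:
            a, b = (p.strip() for p in chunk.split("*"))
            add_main(a)
            add_main(b)
            inters.append((a, b))
        else:
            add_main(chunk)
    terms = tuple(mains) + tuple(inters)
    return ModelSpec(formula=formula, terms=terms)


def _term_columns(data: pd.DataFrame, name: str) -> tuple[np.ndarray, list[str]]:
    """Column block for one main effect (treatment coding for categoricals)."""
    col = FORMULA_VARS[name]
    if col not in data.columns:
        raise ValueError(f"trait table lacks column {col!r}")
    if col in CATEGORICAL_LEVELS:
        levels = CATEGORICAL_LEVELS[col]
        seen = set(data[col].astype(str))
        unknown = seen - set(levels)
        if unknown:
            raise ValueError(f"unseen level(s) {sorted(unknown)} in {col!r}")
        cols = [(data[col].astype(str) == lev).to_numpy(float) for lev in levels[1:]]
        labels = [f"{name}[{lev}]" for lev in levels[1:]]
        return np.column_stack(cols), labels
    x = data[col].to_numpy(float)
    if col == "latitude":
        x = np.abs(x)  # distance from the equator is the hypothesized driver
    return x[:, None], [name]


def design_matrix(data: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    """Build the design matrix: intercept first, then mains, then interactions."""
    blocks = [np.ones((len(data), 1))]
    labels = ["Intercept"]
    main_blocks: dict[str, tuple[np.ndarray, list[str]]] = {}
    for name in spec.mains:
        X, labs = _term_columns(data, name)
        main_blocks[name] = (X, labs)
        blocks.append(X)
        labels.extend(labs)
    for a, b in spec.interactions:
        Xa, la = main_blocks[a]
        Xb, lb = main_blocks[b]
        for i in range(Xa.shape[1]):
            for j in range(Xb.shape[1]):
                blocks.append((Xa[:, i] * Xb[:, j])[:, None])
                labels.append(f"{la[i]}:{lb[j]}")
    X = np.hstack(blocks)
    if np.isnan(X).any():
        raise ValueError("missing values in model columns")
    return X, labels


# ---------------------------------------------------------------------------
# PGLS fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PglsFit:
    formula: str
    coef: pd.DataFrame          # term, estimate, se, t, p
    lambda_hat: float | None
    sigma2_hat: float           # ML estimate
    logLik: float
    k: int
    n: int
    AIC: float
    AICc: float
    adj_R2: float
    residuals: np.ndarray       # raw-scale residuals y - X beta_hat


def _gls_profile(X: np.ndarray, y: np.ndarray, V: np.ndarray):
    """GLS at fixed V via Cholesky whitening.

    Returns (beta, logLik_ML, sigma2_ML, XtViX_inv, whitened (yw, fw)).
    """
    n, p = X.shape
    L = cholesky(V, lower=True)
    yw = solve_triangular(L, y, lower=True)
    Xw = solve_triangular(L, X, lower=True)
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    if rank < p:
        raise ValueError("singular design (collinear columns) under V^-1 metric")
    fw = Xw @ beta
    rw = yw - fw
    rss = float(rw @ rw)
    sigma2_ml = rss / n
    logdet = 2.0 * float(np.log(np.diag(L)).sum())
    ll = -0.5 * (n * np.log(2 * np.pi) + n * np.log(max(sigma2_ml, np.finfo(float).tiny))
                 + logdet + n)
    XtX_inv = np.linalg.inv(Xw.T @ Xw)
    return beta, ll, sigma2_ml, rss, XtX_inv, yw, fw


def pgls_fit(
    X: np.ndarray,
    y: np.ndarray,
    V: np.ndarray,
    labels: list[str] | None = None,
    estimate_lambda: bool = True,
    fixed_lambda: float | None = None,
    formula: str = "",
    lambda_tol: float = 1e-8,
    reml_se: bool = True,
) -> PglsFit:
    """Fit a PGLS model, optionally profiling Pagel's lambda by ML.

    With ``estimate_lambda=False`` and no ``fixed_lambda`` the supplied V is
    used as-is (e.g. V = I reduces exactly to OLS).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    if n <= p + 2:
        raise ValueError(f"n={n} too small for p={p} (AICc denominator)")

    if estimate_lambda:
        def nll(lam):
            return -_gls_profile(X, y, lambda_transform(V, lam))[1]

        res = minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded",
                              options={"xatol": lambda_tol})
        lam = min([float(res.x), 0.0, 1.0], key=nll)
        V_used = lambda_transform(V, lam)
        n_var_params = 2  # sigma2 + lambda
    elif fixed_lambda is not None:
        lam = float(fixed_lambda)
        V_used = lambda_transform(V, lam)
        n_var_params = 1
    else:
        lam = None
        V_used = V
        n_var_params = 1  # sigma2

    beta, ll, sigma2_ml, rss, XtX_inv, yw, fw = _gls_profile(X, y, V_used)

    dof = n - p
    sigma2_inf = rss / dof if reml_se else sigma2_ml
    se = np.sqrt(sigma2_inf * np.diag(XtX_inv))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=dof)

    k = p + n_var_params
    aic = 2 * k - 2 * ll
    aicc = aic + 2.0 * k * (k + 1) / (n - k - 1)

    # R^2 on the lambda-whitened scale: squared correlation between whitened
    # fitted and observed values, adjusted for model size.
    if p > 1 and np.std(fw) > 0:
        r2 = float(np.corrcoef(yw, fw)[0, 1] ** 2)
    else:
        r2 = 0.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / dof

    coef = pd.DataFrame(
        {
            "term": labels if labels is not None else [f"b{i}" for i in range(p)],
            "estimate": beta,
            "se": se,
            "t": tvals,
            "p": pvals,
        }
    )
    return PglsFit(
        formula=formula, coef=coef, lambda_hat=lam, sigma2_hat=sigma2_ml,
        logLik=ll, k=k, n=n, AIC=aic, AICc=aicc, adj_R2=adj_r2,
        residuals=y - X @ beta,
    )


def fit_formula(
    data: pd.DataFrame,
    formula: str,
    V: np.ndarray,
    response: str = "log_birth_season_length",
    **kwargs,
) -> PglsFit:
    """Parse a formula, build the design, and fit PGLS against ``response``."""
    spec = parse_formula(formula)
    X, labels = design_matrix(data, spec)
    y = data[response].to_numpy(float)
    return pgls_fit(X, y, V, labels=labels, formula=formula, **kwargs)


def model_comparison(
    data: pd.DataFrame,
    V: np.ndarray,
    formulas: tuple[str, ...] = CANDIDATE_FORMULAS,
    response: str = "log_birth_season_length",
    estimate_lambda: bool = True,
) -> tuple[pd.DataFrame, dict[str, PglsFit]]:
    """Fit every candidate formula and rank by AICc (ascending).

    Inestimable specifications are skipped with a logged reason. Returns the
    ranking table (formula, k, logLik, lambda, AICc, dAICc) and the fits.
    """
    fits: dict[str, PglsFit] = {}
    rows = []
    for f in formulas:
        try:
            fit = fit_formula(data, f, V, response=response,
                              estimate_lambda=estimate_lambda)
        except ValueError as exc:
            logger.warning("model %r skipped: %s", f, exc)
            continue
        fits[f] = fit
        rows.append({"formula": f, "k": fit.k, "logLik": fit.logLik,
                     "lambda": fit.lambda_hat, "AICc": fit.AICc})
    if not rows:
        raise ValueError("no candidate model could be fitted")
    table = pd.DataFrame(rows).sort_values("AICc", kind="stable").reset_index(drop=True)
    table["dAICc"] = table["AICc"] - table["AICc"].iloc[0]
    return table, fits


def prediction_surface(
    fit: PglsFit,
    contingency_range: tuple[float, float] = (0.0, 0.5),
    constancy_range: tuple[float, float] = (0.0, 1.0),
    n_grid: int = 25,
) -> pd.DataFrame:
    """Predicted log birth-season length over a contingency x constancy grid.

    Assumes the fitted model is the contingency-constancy interaction model
    (coefficient order: intercept, contingency, constancy, interaction).
    """
    b = dict(zip(fit.coef["term"], fit.coef["estimate"]))
    cont = np.linspace(*contingency_range, n_grid)
    cons = np.linspace(*constancy_range, n_grid)
    G_cont, G_cons = np.meshgrid(cont, cons, indexing="ij")
    pred = (
        b["Intercept"]
        + b["Contingency"] * G_cont
        + b["Constancy"] * G_cons
        + b.get("Contingency:Constancy", 0.0) * G_cont * G_cons
    )
    return pd.DataFrame(
        {
            "contingency": G_cont.ravel(),
            "constancy": G_cons.ravel(),
            "predicted_log_birth_season_length": pred.ravel(),
        }
    )


# ---------------------------------------------------------------------------
# Ordinary (non-phylogenetic) regression and correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OlsResult:
    slope: float
    intercept: float
    se: float
    t: float
    p: float
    r2: float


def ols_fit(x: np.ndarray, y: np.ndarray) -> OlsResult:
    """Simple linear regression; R^2 is the squared Pearson correlation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.std(x) == 0:
        raise ValueError("zero variance in x")
    res = stats.linregress(x, y)
    t = res.slope / res.stderr if res.stderr > 0 else np.inf * np.sign(res.slope)
    return OlsResult(slope=res.slope, intercept=res.intercept, se=res.stderr,
                     t=t, p=res.pvalue, r2=res.rvalue ** 2)


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Pearson correlation with its t statistic and two-sided P."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need n >= 3")
    r, p = stats.pearsonr(x, y)
    n = x.size
    denom = max(1.0 - r * r, np.finfo(float).tiny)
    t = r * np.sqrt((n - 2) / denom)
    return float(r), float(t), float(p)
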