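"""End-to-end analysis orchestration from a single plain-text config.

Stages, in order: NDVI smoothing -> Colwell predictability per location ->
population grafting onto the species tree -> trait-evolution model
selection -> PGLS model comparison and best-model coefficients -> Moran's I
diagnostics on the response and on the best-model residuals -> prediction
surface over the contingency x constancy plane.

Every output table carries the config hash so a run can be reproduced
bit-for-bit from its config file and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import colwell, ndvi, pgls, phylo, spatial

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All inputs and parameters of one analysis run."""

    ndvi_csv: str
    tree_newick: str
    traits_csv: str
    out_dir: str
    northern_locations: list[str] = field(default_factory=list)
    spike_threshold: float = ndvi.SPIKE_THRESHOLD
    min_pixel_fraction: float = ndvi.MIN_PIXEL_FRACTION
    n_states: int = 8
    scheme: str = "equal_width_local"
    formulas: list[str] = field(default_factory=lambda: list(pgls.CANDIDATE_FORMULAS))
    estimate_lambda: bool = True
    weights_scheme: str = "knn"
    knn_k: int = 4
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class RunReport:
    qc: pd.DataFrame
    predictability: pd.DataFrame
    evo_models: pd.DataFrame
    model_comparison: pd.DataFrame
    best_fit: pgls.PglsFit
    best_coefficients: pd.DataFrame
    moran: pd.DataFrame
    surface: pd.DataFrame
    config_hash: str


def _stage(name):
    """Decorator: re-raise stage failures naming the stage."""
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


@_stage("ndvi_smoothing")
def _run_smoothing(config: RunConfig):
    df = pd.read_csv(config.ndvi_csv)
    return ndvi.smooth_frame(
        df,
        northern_locations=set(config.northern_locations),
        threshold=config.spike_threshold,
        min_fraction=config.min_pixel_fraction,
    )


@_stage("predictability")
def _run_predictability(locations, config: RunConfig) -> pd.DataFrame:
    per_loc = {}
    for loc_id, loc in locations.items():
        if not loc.retained:
            continue
        flat = loc.flat()
        periods = np.tile(np.arange(loc.values.shape[1]), loc.values.shape[0])
        ok = ~np.isnan(flat)
        per_loc[loc_id] = (flat[ok], periods[ok])
    return colwell.predictability_table(
        per_loc, n_states=config.n_states, scheme=config.scheme
    )


@_stage("phylogeny")
def _run_grafting(config: RunConfig, traits: pd.DataFrame):
    with open(config.tree_newick) as fh:
        species_tree = phylo.read_newick(fh.read())
    mapping = dict(zip(traits["population_id"].astype(str),
                       traits["species_id"].astype(str)))
    pop_tree = phylo.graft_populations(species_tree, mapping)
    cov = phylo.phylo_covariance(pop_tree)
    V = cov.reorder(list(traits["population_id"].astype(str)))
    return pop_tree, V


def run_analysis(config: RunConfig) -> RunReport:
    """Run every stage and write the report bundle under ``config.out_dir``."""
    cfg_hash = config.hash()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("run %s starting (seed=%d)", cfg_hash, config.seed)

    locations, qc = _run_smoothing(config)
    pred = _run_predictability(locations, config)

    traits = pd.read_csv(config.traits_csv)
    # The NDVI-derived predictability supersedes any constancy/contingency
    # columns already in the trait table; excluded locations propagate (only
    # retained locations carry C/M values).
    traits = traits.drop(columns=["constancy", "contingency"], errors="ignore")
    traits = traits.merge(
        pred[["location_id", "constancy", "contingency"]], on="location_id", how="inner"
    )
    if "log_birth_season_length" not in traits.columns:
        traits["log_birth_season_length"] = np.log(traits["birth_season_length"])

    pop_tree, V = _run_grafting(config, traits)

    y = traits["log_birth_season_length"].to_numpy(float)
    evo_fits = [
        phylo.fit_evo_model_cov(y, V, m) for m in ("BM", "lambda", "white")
    ]
    evo_table = pd.DataFrame(
        [
            {"model": f.model, "logLik": f.logLik, "k": f.k, "AIC": f.AIC,
             "lambda": f.lam, "sigma2": f.sigma2}
            for f in sorted(evo_fits, key=lambda f: f.AIC)
        ]
    )

    comparison, fits = pgls.model_comparison(
        traits, V, formulas=tuple(config.formulas),
        estimate_lambda=config.estimate_lambda,
    )
    best = fits[comparison["formula"].iloc[0]]

    weights = spatial.build_weights(
        traits["latitude"].to_numpy(float), traits["longitude"].to_numpy(float),
        scheme=config.weights_scheme, k=config.knn_k,
    )
    moran_rows = []
    for label, vals in (("log_birth_season_length", y),
                        ("best_model_residuals", best.residuals)):
        m = spatial.morans_i(vals, weights)
        moran_rows.append({"variable": label, "I": m.I, "expected_I": m.expected_I,
                           "variance_I": m.variance_I, "z": m.z, "p": m.p,
                           "scheme": weights.scheme})
    moran = pd.DataFrame(moran_rows)

    has_both = "Contingency" in best.formula and "Constancy" in best.formula
    surface = pgls.prediction_surface(best) if has_both else pd.DataFrame()

    report = RunReport(
        qc=qc, predictability=pred, evo_models=evo_table,
        model_comparison=comparison, best_fit=best, best_coefficients=best.coef,
        moran=moran, surface=surface, config_hash=cfg_hash,
    )
    _write_report(report, out, config)
    logger.info("run %s complete", cfg_hash)
    return report


def _write_report(report: RunReport, out: Path, config: RunConfig) -> None:
    tables = {
        "qc_report.csv": report.qc,
        "predictability.csv": report.predictability,
        "evo_models.csv": report.evo_models,
        "model_comparison.csv": report.model_comparison,
        "best_model_coefficients.csv": report.best_coefficients,
        "moran.csv": report.moran,
        "prediction_surface.csv": report.surface,
    }
    for name, table in tables.items():
        t = table.copy()
        t["config_hash"] = report.config_hash
        t.to_csv(out / name, index=False)
    log = {
        "config": asdict(config),
        "config_hash": report.config_hash,
        "best_formula": report.best_fit.formula,
        "best_lambda": report.best_fit.lambda_hat,
        "best_AICc": report.best_fit.AICc,
        "best_adj_R2": report.best_fit.adj_R2,
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
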