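"""Phylogeny handling, population grafting, and trait-evolution model fitting.

A species-level tree is turned into a population-level tree by splitting
each species tip into a shallow polytomy (one child tip per population,
branch length epsilon ~ 0), so that conspecific populations share almost
the species' full root-to-tip history.

Trait evolution is modelled as a multivariate normal on the tips:

    y ~ MVN(z0 * 1, sigma2 * V(model))

where V derives from the tree. Three covariance models are compared by
maximum likelihood and AIC:

* **BM** — Brownian motion; V_ab = shared root-to-MRCA path length.
* **lambda** — Pagel's lambda; off-diagonal entries of the BM matrix are
  multiplied by lambda in [0, 1]. lambda = 1 recovers BM, lambda = 0 an
  independent (star) structure. A measure of phylogenetic signal.
* **white** — no phylogenetic structure; V = I.

Likelihoods are evaluated through Cholesky factorization (no explicit
matrix inverse); z0 and sigma2 are profiled analytically and lambda is
optimized numerically on [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from io import StringIO

import dendropy
import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)

EPSILON_HEIGHT_FRACTION = 1e-6  # graft branch length as a fraction of tree height


# ---------------------------------------------------------------------------
# Newick I/O (dendropy-backed)
# ---------------------------------------------------------------------------

def read_newick(text: str) -> dendropy.Tree:
    """Parse a rooted Newick string with branch lengths.

    Raises on malformed input or duplicate tip labels.
    """
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", rooting="default-rooted",
            preserve_underscores=True,
        )
    except dendropy.utility.error.DataParseError as exc:
        msg = str(exc)
        if "Duplicate taxon labels" in msg:
            raise ValueError(f"duplicate tip labels: {msg.split(':')[-1].strip()}") from exc
        raise ValueError(f"malformed Newick: {msg}") from exc
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    buf = StringIO()
    tree.write(file=buf, schema="newick", suppress_rooting=True, unquoted_underscores=True)
    return buf.getvalue().strip()


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def tree_height(tree: dendropy.Tree) -> float:
    """Maximum root-to-tip distance."""
    return max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())


# ---------------------------------------------------------------------------
# Population grafting
# ---------------------------------------------------------------------------

def graft_populations(
    tree: dendropy.Tree,
    mapping: dict[str, str],
    epsilon: float | None = None,
) -> dendropy.Tree:
    """Split species tips into population polytomies.

    ``mapping`` maps population id -> species tip label. A species with m
    populations becomes a degree-m polytomy of population tips at branch
    length ``epsilon`` (default 1e-6 x tree height; a zero request is
    replaced by the default with a warning, to keep the phylogenetic
    covariance positive definite). A species with a single population is
    relabelled in place.
    """
    tree = tree.clone(depth=1)
    height = tree_height(tree)
    if epsilon is None:
        epsilon = EPSILON_HEIGHT_FRACTION * height
    if epsilon <= 0:
        logger.warning("graft_populations: epsilon <= 0 replaced by %.3g",
                       EPSILON_HEIGHT_FRACTION * height)
        epsilon = EPSILON_HEIGHT_FRACTION * height

    by_species: dict[str, list[str]] = {}
    for pop, sp in mapping.items():
        by_species.setdefault(sp, []).append(pop)

    tips = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    missing = sorted(set(by_species) - set(tips))
    if missing:
        raise ValueError(f"species not found in tree: {', '.join(missing)}")

    taxa = tree.taxon_namespace
    for sp, pops in sorted(by_species.items()):
        node = tips[sp]
        if len(pops) == 1:
            node.taxon = taxa.new_taxon(label=pops[0])
            continue
        node.taxon = None
        for pop in sorted(pops):
            child = node.new_child(edge_length=epsilon)
            child.taxon = taxa.new_taxon(label=pop)
    return tree


# ---------------------------------------------------------------------------
# Phylogenetic covariance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhyloCovariance:
    """Shared root-to-MRCA path lengths between tips, in a fixed tip order."""

    V: np.ndarray
    tip_order: tuple[str, ...]

    def reorder(self, labels: list[str]) -> np.ndarray:
        """V with rows/columns permuted to match ``labels``."""
        idx = [self.tip_order.index(l) for l in labels]
        return self.V[np.ix_(idx, idx)]


def phylo_covariance(tree: dendropy.Tree) -> PhyloCovariance:
    """Brownian-motion covariance: V_ab = depth of the MRCA of tips a, b."""
    if tree.seed_node is None:
        raise ValueError("tree has no root")
    leaves = list(tree.leaf_node_iter())
    labels = [l.taxon.label for l in leaves]
    index = {id(l): i for i, l in enumerate(leaves)}
    n = len(leaves)
    V = np.zeros((n, n))

    # Postorder sweep: at each internal node of depth d, tip pairs whose
    # paths split there get covariance d.
    depth: dict[int, float] = {id(tree.seed_node): float(tree.seed_node.edge.length or 0.0)}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depth[id(node)] = depth[id(node.parent_node)] + float(node.edge.length or 0.0)

    tipsets: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[id(node)]
            tipsets[id(node)] = [i]
            V[i, i] = depth[id(node)]
            continue
        child_sets = [tipsets.pop(id(c)) for c in node.child_nodes()]
        d = depth[id(node)]
        for a in range(len(child_sets)):
            for b in range(a + 1, len(child_sets)):
                for i in child_sets[a]:
                    for j in child_sets[b]:
                        V[i, j] = V[j, i] = d
        tipsets[id(node)] = [i for s in child_sets for i in s]
    return PhyloCovariance(V=V, tip_order=tuple(labels))


def lambda_transform(V: np.ndarray, lam: float) -> np.ndarray:
    """Pagel's lambda: multiply off-diagonal entries by lambda, keep the diagonal."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    out = lam * V
    np.fill_diagonal(out, np.diag(V))
    return out


# ---------------------------------------------------------------------------
# Trait-evolution model fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvoModelFit:
    model: str  # "BM" | "lambda" | "white"
    sigma2: float
    z0: float
    lam: float | None
    logLik: float
    k: int
    AIC: float


def _profile_loglik(y: np.ndarray, V: np.ndarray) -> tuple[float, float, float]:
    """ML (z0, sigma2, logLik) for y ~ MVN(z0*1, sigma2*V), via Cholesky."""
    n = y.size
    L = cholesky(V, lower=True)
    a = solve_triangular(L, y, lower=True)
    u = solve_triangular(L, np.ones(n), lower=True)
    z0 = float(u @ a) / float(u @ u)
    r = a - z0 * u
    sigma2 = float(r @ r) / n
    logdet = 2.0 * float(np.log(np.diag(L)).sum())
    if sigma2 <= 0:
        sigma2 = np.finfo(float).tiny
    ll = -0.5 * (n * np.log(2 * np.pi) + n * np.log(sigma2) + logdet + n)
    return z0, sigma2, ll


def fit_evo_model(
    tree: dendropy.Tree,
    trait: dict[str, float],
    model: str,
    lambda_tol: float = 1e-8,
) -> EvoModelFit:
    """ML fit of one trait-evolution model ("BM", "lambda" or "white").

    ``trait`` maps tip label -> value; every tip must be present, n >= 3.
    """
    cov = phylo_covariance(tree)
    labels = list(cov.tip_order)
    missing = [l for l in labels if l not in trait]
    if missing:
        raise ValueError(f"trait missing for tips: {', '.join(missing[:5])}")
    y = np.array([trait[l] for l in labels], dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 tips")
    return fit_evo_model_cov(y, cov.V, model, lambda_tol=lambda_tol)


def fit_evo_model_cov(
    y: np.ndarray, V: np.ndarray, model: str, lambda_tol: float = 1e-8
) -> EvoModelFit:
    """As :func:`fit_evo_model` but on a precomputed BM covariance matrix."""
    n = y.size
    if model == "BM":
        z0, s2, ll = _profile_loglik(y, V)
        k, lam = 2, None
    elif model == "white":
        z0, s2, ll = _profile_loglik(y, np.eye(n))
        k, lam = 2, None
    elif model == "lambda":
        def nll(lam_):
            return -_profile_loglik(y, lambda_transform(V, lam_))[2]

        res = minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded",
                              options={"xatol": lambda_tol})
        # The bounded optimizer can stop short of a boundary optimum.
        lam = min([float(res.x), 0.0, 1.0], key=nll)
        z0, s2, ll = _profile_loglik(y, lambda_transform(V, lam))
        k = 3
    else:
        raise ValueError(f"unknown model {model!r}")
    return EvoModelFit(model=model, sigma2=s2, z0=z0, lam=lam, logLik=ll,
                       k=k, AIC=2 * k - 2 * ll)


def compare_evo_models(
    tree: dendropy.Tree,
    trait: dict[str, float],
    models: tuple[str, ...] = ("BM", "lambda", "white"),
):
    """Fit each candidate model and return fits sorted by AIC (best first)."""
    fits = [fit_evo_model(tree, trait, m) for m in models]
    return sorted(fits, key=lambda f: f.AIC)
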