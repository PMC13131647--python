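"""Phylogenetic generalized least squares (PGLS) under Brownian motion.

Species data are not independent draws: close relatives resemble each other
because they share most of their evolutionary history.  Under a
Brownian-motion model of trait evolution the expected covariance between
two species' trait values is proportional to the branch length they share —
the path from the root to their most recent common ancestor.  PGLS is
generalized least squares with that phylogenetic variance-covariance matrix
C as the error covariance:

    beta_hat = (X' C^-1 X)^-1 X' C^-1 y
    sigma2_hat = (y - X beta)' C^-1 (y - X beta) / (n - p)
    SE_j = sqrt(sigma2_hat * [(X' C^-1 X)^-1]_jj)

with t = beta/SE referred to a t distribution on n - p degrees of freedom.
Ordinary least squares is the special case C = I and serves as the
uncorrected baseline.  The covariance is the fixed Brownian VCV; no
Pagel's-lambda or Ornstein-Uhlenbeck transformation is estimated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import LinAlgError, cholesky, solve_triangular

logger = logging.getLogger(__name__)

#: Relative ridge added to a numerically singular C (times mean diagonal).
SINGULAR_RIDGE = 1e-8


@dataclass
class BrownianVCV:
    """Brownian phylogenetic covariance: C[i,j] = shared root-to-MRCA path."""

    taxa: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.taxa)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")

    def cholesky_lower(self) -> np.ndarray:
        """Lower-triangular Cholesky factor, ridging a singular C (logged)."""
        try:
            return cholesky(self.matrix, lower=True)
        except LinAlgError:
            ridge = SINGULAR_RIDGE * float(np.mean(np.diag(self.matrix)))
            logger.warning(
                "Brownian VCV numerically singular; adding ridge %.3g to diagonal",
                ridge,
            )
            return cholesky(self.matrix + ridge * np.eye(len(self.taxa)), lower=True)


@dataclass
class RegressionResult:
    """Coefficients and inference for one (P)GLS fit."""

    predictors: list[str]          # includes "intercept" first
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    sigma2: float
    n: int
    model: str                     # "PGLS" or "OLS"

    @property
    def df_resid(self) -> int:
        return self.n - len(self.predictors)

    def coef(self, name: str) -> float:
        return float(self.beta[self.predictors.index(name)])

    def pvalue(self, name: str) -> float:
        return float(self.p[self.predictors.index(name)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "predictor": self.predictors,
                "beta": self.beta,
                "se": self.se,
                "t": self.t,
                "p": self.p,
                "n": self.n,
                "model": self.model,
            }
        )


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a rooted phylogeny with branch lengths from a Newick file.

    Polytomies are allowed; zero-length branches are allowed with a
    warning; unlabeled leaves or missing branch lengths are errors.
    """
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    _validate_tree(tree)
    return tree


def tree_from_string(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    _validate_tree(tree)
    return tree


def _validate_tree(tree: dendropy.Tree) -> None:
    leaves = tree.leaf_nodes()
    if len(leaves) < 2:
        raise ValueError("phylogeny must have at least 2 leaves")
    labels = [lf.taxon.label if lf.taxon else None for lf in leaves]
    if any(lb is None for lb in labels):
        raise ValueError("phylogeny contains unlabeled leaves")
    if len(set(labels)) != len(labels):
        raise ValueError("phylogeny contains duplicate leaf labels")
    n_zero = 0
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError(
                f"branch above {_node_desc(edge.head_node)} has no length"
            )
        if edge.length < 0:
            raise ValueError(
                f"negative branch length above {_node_desc(edge.head_node)}"
            )
        if edge.length == 0:
            n_zero += 1
    if n_zero:
        logger.warning("phylogeny contains %d zero-length branches", n_zero)


def _node_desc(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    return f"internal node with {len(node.leaf_nodes())} descendant leaves"


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def normalize_species_name(name: str) -> str:
    """Casefold and map spaces to underscores so NCBI/AnAge/VertLife-style
    name variants ('Homo sapiens' vs 'Homo_sapiens') compare equal."""
    return name.strip().casefold().replace(" ", "_")


def prune_and_match(
    tree: dendropy.Tree, traits: pd.DataFrame
) -> tuple[dendropy.Tree, pd.DataFrame]:
    """Restrict tree and trait table to their common species.

    Names are matched after normalization (case-fold, spaces/underscores).
    The tree is pruned with internal path lengths preserved (collapsed
    unifurcation edges are summed); dropped names are logged.  The returned
    trait table keeps the tree's original labels in ``species_id``.
    """
    tree_norm = {normalize_species_name(lb): lb for lb in leaf_labels(tree)}
    trait_norm = {
        normalize_species_name(s): s for s in traits["species_id"].astype(str)
    }
    common = sorted(set(tree_norm) & set(trait_norm))
    if not common:
        raise ValueError("no species shared between tree and trait table")
    dropped_tree = sorted(set(tree_norm) - set(common))
    dropped_traits = sorted(set(trait_norm) - set(common))
    if dropped_tree:
        logger.info("dropping %d tree-only species: %s", len(dropped_tree), dropped_tree)
    if dropped_traits:
        logger.info(
            "dropping %d trait-only species: %s", len(dropped_traits), dropped_traits
        )

    keep_labels = [tree_norm[k] for k in common]
    pruned = tree.extract_tree_with_taxa_labels(labels=keep_labels)
    pruned.purge_taxon_namespace()

    sub = traits.copy()
    sub["_norm"] = sub["species_id"].astype(str).map(normalize_species_name)
    sub = sub[sub["_norm"].isin(common)].copy()
    # keep the tree's label spelling so vcv/taxa lookups are consistent
    sub["species_id"] = sub["_norm"].map(tree_norm)
    sub = sub.drop(columns="_norm").reset_index(drop=True)
    return pruned, sub


def brownian_vcv(tree: dendropy.Tree, taxa: list[str] | None = None) -> BrownianVCV:
    """Brownian VCV from a phylogeny: C[i,j] = root-to-MRCA path length.

    Computed in one postorder pass: each internal node at depth d (distance
    from the root) contributes d as the covariance of every leaf pair whose
    MRCA it is; the diagonal holds root-to-tip distances.
    """
    labels = leaf_labels(tree)
    if taxa is None:
        taxa = sorted(labels)
    missing = set(taxa) - set(labels)
    if missing:
        raise ValueError(f"taxa absent from tree: {sorted(missing)}")
    index = {label: i for i, label in enumerate(taxa)}

    n = len(taxa)
    C = np.zeros((n, n))

    depth: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depth[node] = 0.0
        else:
            depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)

    # postorder: collect retained-leaf indices per subtree; leaf pairs whose
    # MRCA is this node lie in different child subtrees
    below: dict[dendropy.Node, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index.get(node.taxon.label)
            below[node] = (
                np.array([i], dtype=int) if i is not None else np.empty(0, dtype=int)
            )
            if i is not None:
                C[i, i] = depth[node]
            continue
        kids = [below.pop(ch) for ch in node.child_nodes()]
        d = depth[node]
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                if kids[a].size and kids[b].size:
                    C[np.ix_(kids[a], kids[b])] = d
                    C[np.ix_(kids[b], kids[a])] = d
        below[node] = np.concatenate(kids) if kids else np.empty(0, dtype=int)
    return BrownianVCV(list(taxa), C)


def design_matrix(
    traits: pd.DataFrame, predictors: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Design matrix with an intercept column; booleans encoded 0/1."""
    n = len(traits)
    cols = [np.ones(n)]
    for name in predictors:
        v = traits[name]
        if v.dtype == bool:
            v = v.astype(float)
        cols.append(np.asarray(v, dtype=float))
    return np.column_stack(cols), ["intercept"] + list(predictors)


def gls_core(
    y: np.ndarray, X: np.ndarray, L: np.ndarray | None, names: list[str], model: str
) -> RegressionResult:
    """GLS fit given the lower Cholesky factor L of the error covariance
    (L=None means OLS).  Whitening by L^-1 reduces GLS to OLS on
    transformed data; inference uses the exact normal-theory t reference."""
    n, p = X.shape
    if n <= p:
        raise ValueError(f"n={n} too small for {p} coefficients")
    if L is not None:
        y = solve_triangular(L, y, lower=True)
        X = solve_triangular(L, X, lower=True)
    G = X.T @ X
    if np.linalg.cond(G) > 1e12:
        raise ValueError(
            f"singular design (collinear predictors among {names})"
        )
    Ginv = np.linalg.inv(G)
    beta = Ginv @ (X.T @ y)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / (n - p)
    se = np.sqrt(np.clip(sigma2 * np.diag(Ginv), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2.0 * stats.t.sf(np.abs(t), df=n - p)
    return RegressionResult(
        predictors=names,
        beta=beta,
        se=se,
        t=t,
        p=pvals,
        sigma2=sigma2,
        n=n,
        model=model,
    )


def _aligned_arrays(
    traits: pd.DataFrame,
    predictors: list[str],
    taxa: list[str],
    response: str,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    sub = traits.set_index("species_id")
    missing = [t for t in taxa if t not in sub.index]
    if missing:
        raise ValueError(f"trait table missing species: {missing}")
    sub = sub.loc[taxa]
    y = np.asarray(sub[response], dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError(f"non-finite response values in {response!r}")
    X, names = design_matrix(sub.reset_index(), predictors)
    return y, X, names


def pgls_fit(
    traits: pd.DataFrame,
    predictors: list[str],
    vcv: BrownianVCV,
    response: str = "log10_lifespan",
) -> RegressionResult:
    """PGLS of ``response`` on ``predictors`` under the Brownian VCV.

    The trait table is re-ordered internally to ``vcv.taxa``; species sets
    must match exactly (use :func:`prune_and_match` first).
    """
    y, X, names = _aligned_arrays(traits, predictors, vcv.taxa, response)
    return gls_core(y, X, vcv.cholesky_lower(), names, "PGLS")


def ols_fit(
    traits: pd.DataFrame,
    predictors: list[str],
    response: str = "log10_lifespan",
) -> RegressionResult:
    """Ordinary least squares baseline (PGLS with identity covariance)."""
    taxa = list(traits["species_id"].astype(str))
    y, X, names = _aligned_arrays(traits, predictors, taxa, response)
    return gls_core(y, X, None, names, "OLS")


def fit_each_predictor(
    traits: pd.DataFrame,
    predictors: list[str],
    vcv: BrownianVCV,
    response: str = "log10_lifespan",
) -> pd.DataFrame:
    """Separate PGLS and OLS fits per predictor (the default analysis mode:
    each sequence feature is regressed on lifespan individually)."""
    frames = []
    for name in predictors:
        for res in (
            pgls_fit(traits, [name], vcv, response=response),
            ols_fit(traits, [name], response=response),
        ):
            df = res.to_frame()
            frames.append(df[df["predictor"] == name])
    return pd.concat(frames, ignore_index=True)
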