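"""Continuous-trait evolution on the gene tree.

Two complementary analyses of repeat-region amino-acid percentages:

* Wagner (linear-cost) parsimony ancestral states — per-node optimal-state
  intervals and the global minimum total change.
* A nine-model Brownian-motion comparison ranked by AIC.  The model grid
  crosses a tree *mode* — ``pure_phylogenetic`` (the tree as given),
  ``non_phylogenetic`` (a star: tips independent and exchangeable), or
  ``punctuated_average`` (change concentrated at branching events: each
  sister-branch pair is reshaped to an asymmetric T:1 split of its summed
  length, so one descendant tracks the ancestor while the other jumps) —
  with a *lengths* variant: ``distance`` (input branch lengths), ``equal``
  (all 1), or ``free`` (lengths are fitted parameters).

Under every model the tip vector is multivariate normal with mean ``z0`` and
covariance ``σ²·C`` where ``C`` holds shared root-to-tip path lengths; ``z0``
and ``σ²`` are profiled in closed form (GLS mean / mean squared scaled
residual).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize

from .trees import PhyloTree, TreeError, TreeNode

MODES = ("pure_phylogenetic", "non_phylogenetic", "punctuated_average")
LENGTHS = ("distance", "equal", "free")

TraitData = dict  # tip label -> value


@dataclass(frozen=True)
class EvoModel:
    """One cell of the mode × lengths model grid (T only matters if punctuated)."""

    mode: str
    lengths: str
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.lengths not in LENGTHS:
            raise ValueError(f"unknown lengths variant {self.lengths!r}")
        if self.mode == "punctuated_average":
            if self.threshold is None or self.threshold <= 1:
                raise ValueError("punctuated model needs an asymmetry threshold > 1")

    @property
    def name(self) -> str:
        t = f"/T={self.threshold:g}" if self.mode == "punctuated_average" else ""
        return f"{self.mode}/{self.lengths}{t}"


@dataclass(frozen=True)
class ModelFit:
    model: EvoModel
    sigma2: float
    z0: float
    logL: float
    k: int
    aic: float

    def __post_init__(self) -> None:
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be non-negative")
        if not math.isclose(self.aic, 2 * self.k - 2 * self.logL, rel_tol=1e-12):
            raise ValueError("AIC must equal 2k − 2 logL")


@dataclass
class AncestralIntervals:
    """Wagner-parsimony state intervals per node and the minimum total cost.

    ``intervals`` is keyed by ``id(node)``; tip intervals are degenerate at
    the observed values.  Non-root internal intervals are the downpass
    (subtree-conditional) intervals; the root interval is final — it is the
    exact set of root states attaining the global minimum cost.
    """

    tree: PhyloTree
    intervals: dict[int, tuple[float, float]] = field(default_factory=dict)
    cost: float = 0.0

    def interval(self, node: TreeNode) -> tuple[float, float]:
        return self.intervals[id(node)]

    @property
    def root_interval(self) -> tuple[float, float]:
        return self.intervals[id(self.tree.root)]


def ancestral_linear_parsimony(tree: PhyloTree, traits: TraitData) -> AncestralIntervals:
    """Linear-cost (Wagner) parsimony reconstruction of a continuous trait.

    Downpass: a node's interval is the intersection of its children's
    intervals when non-empty, otherwise the closed gap between them, adding
    the gap width to the cost.  The root interval is the optimal-state set;
    the cost is the global minimum of Σ |parent − child| over branches.
    """
    if not tree.rooted:
        raise TreeError("linear parsimony needs a rooted tree")
    missing = [l.label for l in tree.leaves() if l.label not in traits]
    if missing:
        raise ValueError(f"missing trait values for tips: {missing}")
    res = AncestralIntervals(tree=tree)
    for node in tree.postorder():
        if node.is_leaf():
            v = float(traits[node.label])
            res.intervals[id(node)] = (v, v)
            continue
        if len(node.children) != 2:
            raise TreeError("linear parsimony requires a binary tree")
        (a1, b1), (a2, b2) = (res.intervals[id(c)] for c in node.children)
        lo, hi = max(a1, a2), min(b1, b2)
        if lo <= hi:  # overlap
            res.intervals[id(node)] = (lo, hi)
        else:  # disjoint: pay the gap
            res.intervals[id(node)] = (hi, lo)
            res.cost += lo - hi
    return res


# ---------------------------------------------------------------------------
# Brownian-motion likelihood machinery

def _branches(tree: PhyloTree) -> list[TreeNode]:
    """Non-root nodes in stable postorder (each represents its parent edge)."""
    return [n for n in tree.postorder() if n is not tree.root]


def _incidence(tree: PhyloTree, tip_order: list[str]) -> np.ndarray:
    """A[b, t] = 1 iff tip t lies below branch b."""
    idx = {label: i for i, label in enumerate(tip_order)}
    branches = _branches(tree)
    A = np.zeros((len(branches), len(tip_order)))
    for bi, node in enumerate(branches):
        for leaf in node.leaves():
            A[bi, idx[leaf.label]] = 1.0
    return A


def phylo_covariance(tree: PhyloTree) -> tuple[list[str], np.ndarray]:
    """Unit-rate BM covariance: C[i, j] = shared root-to-tip path length."""
    tips = tree.leaf_labels()
    lengths = np.array(
        [np.nan if n.length is None else n.length for n in _branches(tree)], dtype=float
    )
    if np.any(np.isnan(lengths)):
        raise TreeError("all non-root branches need lengths for the BM covariance")
    A = _incidence(tree, tips)
    return tips, A.T @ (lengths[:, None] * A)


def bm_loglik(tree: PhyloTree, traits: TraitData, sigma2: float, z0: float) -> float:
    """Log-likelihood of tip values under BM(σ², z0) on the given tree."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    tips, C0 = phylo_covariance(tree)
    y = np.array([float(traits[t]) for t in tips])
    C = sigma2 * C0
    try:
        cf = cho_factor(C, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular covariance matrix: {exc}") from exc
    resid = y - z0
    quad = resid @ cho_solve(cf, resid)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    n = len(y)
    return float(-0.5 * (n * math.log(2 * math.pi) + logdet + quad))


def _profiled_loglik(C0: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """ML (logL, σ̂², ẑ0) with z0 the GLS mean and σ² profiled out."""
    n = len(y)
    L = np.linalg.cholesky(C0)
    alpha = solve_triangular(L, y, lower=True)
    beta = solve_triangular(L, np.ones(n), lower=True)
    z0 = float(beta @ alpha / (beta @ beta))
    resid = alpha - z0 * beta
    sigma2 = max(float(resid @ resid) / n, 1e-12)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    logL = -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n)
    return logL, sigma2, z0


class _ModelStructure:
    """Covariance builder for one model: maps base branch lengths to C0."""

    def __init__(self, tree: PhyloTree, model: EvoModel):
        self.model = model
        if model.mode == "non_phylogenetic":
            star = TreeNode(
                children=[TreeNode(label=l, length=1.0) for l in tree.leaf_labels()]
            )
            self.tree = PhyloTree(star, rooted=True)
        else:
            self.tree = tree.copy()
        self.tips = self.tree.leaf_labels()
        self.branches = _branches(self.tree)
        self.A = _incidence(self.tree, self.tips)
        self.pairs: list[tuple[int, int]] = []  # sister-pair branch indices
        if model.mode == "punctuated_average":
            pos = {id(n): i for i, n in enumerate(self.branches)}
            for n in self.tree.postorder():
                if len(n.children) == 2:
                    self.pairs.append((pos[id(n.children[0])], pos[id(n.children[1])]))
        # polarity[i] = index (0/1) of the long side of pair i
        self.polarity = [0] * len(self.pairs)

    def base_lengths(self) -> np.ndarray:
        if self.model.mode == "non_phylogenetic" or self.model.lengths in ("equal", "free"):
            return np.ones(len(self.branches))
        lens = np.array(
            [np.nan if n.length is None else n.length for n in self.branches], dtype=float
        )
        if np.any(np.isnan(lens)):
            raise TreeError("lengths='distance' requires input branch lengths")
        return lens

    def effective_lengths(self, base: np.ndarray) -> np.ndarray:
        if self.model.mode != "punctuated_average":
            return base
        T = self.model.threshold
        eff = base.copy()
        for pi, (i, j) in enumerate(self.pairs):
            s = base[i] + base[j]
            long_idx, short_idx = (i, j) if self.polarity[pi] == 0 else (j, i)
            eff[long_idx] = s * T / (T + 1.0)
            eff[short_idx] = s / (T + 1.0)
        return eff

    def covariance(self, base: np.ndarray) -> np.ndarray:
        eff = self.effective_lengths(base)
        return self.A.T @ (eff[:, None] * self.A)


def fit_model(
    tree: PhyloTree,
    traits: TraitData,
    model: EvoModel,
    max_free_iter: int = 60,
) -> ModelFit:
    """ML fit of one trait-evolution model; AIC = 2k − 2 logL.

    ``z0`` and ``σ²`` are always profiled in closed form.  For
    ``lengths='free'`` the branch lengths are optimized (bounded quasi-Newton
    on log lengths in [1e-6, 1e3], started from equal lengths).  For the
    punctuated mode the long-branch polarity of each sister pair is chosen by
    a single deterministic postorder sweep, each pair's two assignments
    compared while the others are held fixed.
    """
    struct = _ModelStructure(tree, model)
    y = np.array([float(traits[t]) for t in struct.tips])
    if len(set(struct.tips) - set(traits)) > 0:
        raise ValueError("traits must cover every tip")
    base = struct.base_lengths()

    def loglik(b: np.ndarray) -> float:
        return _profiled_loglik(struct.covariance(b), y)[0]

    k = 2
    if model.mode == "punctuated_average":
        for pi in range(len(struct.pairs)):
            struct.polarity[pi] = 0
            l0 = loglik(base)
            struct.polarity[pi] = 1
            l1 = loglik(base)
            struct.polarity[pi] = 0 if l0 >= l1 else 1
        # each fitted long-side polarity is a discrete parameter
        k += len(struct.pairs)
    if model.lengths == "free":
        k += len(struct.branches)
        if len(struct.tips) < k:
            warnings.warn(
                f"{model.name}: {k} parameters exceed {len(struct.tips)} tips; "
                "free branch lengths are not identifiable",
                stacklevel=2,
            )

        def nll(log_b: np.ndarray) -> float:
            return -loglik(np.exp(log_b))

        res = minimize(
            nll,
            np.log(base),
            method="L-BFGS-B",
            bounds=[(math.log(1e-6), math.log(1e3))] * len(base),
            options={"maxiter": max_free_iter, "maxfun": 8 * max_free_iter},
        )
        if not np.isfinite(res.fun):
            raise RuntimeError(f"free-length optimization failed: {res.message}")
        base = np.exp(res.x)

    logL, sigma2, z0 = _profiled_loglik(struct.covariance(base), y)
    return ModelFit(model=model, sigma2=sigma2, z0=z0, logL=logL, k=k, aic=2 * k - 2 * logL)


def model_grid(T_list: list[float] = (100.0, 1000.0)) -> list[EvoModel]:
    """The nine mode × lengths models (punctuated cells expanded per threshold)."""
    models = []
    for mode in MODES:
        for lengths in LENGTHS:
            if mode == "punctuated_average":
                models.extend(EvoModel(mode, lengths, T) for T in T_list)
            else:
                models.append(EvoModel(mode, lengths))
    return models


def fit_all(
    tree: PhyloTree,
    traits: TraitData,
    T_list: list[float] = (100.0, 1000.0),
    max_free_iter: int = 60,
) -> list[ModelFit]:
    """Fit the full model grid and rank ascending by AIC (ties: model name)."""
    fits = [
        fit_model(tree, traits, m, max_free_iter=max_free_iter)
        for m in model_grid(list(T_list))
    ]
    return sorted(fits, key=lambda f: (f.aic, f.model.name))


def transform_tree(
    tree: PhyloTree,
    mode: str,
    lengths: str,
    T: float | None = None,
    polarity: dict[int, int] | None = None,
) -> PhyloTree:
    """Materialize the tree a model grid cell assumes (for inspection/export).

    For ``lengths='free'`` the returned tree carries the equal-length starting
    point — the fitted lengths live inside :func:`fit_model`.  For the
    punctuated mode, ``polarity`` maps sister-pair index (postorder) to the
    long-side child index; default: first child long.
    """
    model = EvoModel(mode, lengths, T)
    struct = _ModelStructure(tree, model)
    if polarity:
        for pi, side in polarity.items():
            struct.polarity[pi] = side
    eff = struct.effective_lengths(struct.base_lengths())
    out = struct.tree
    for node, length in zip(struct.branches, eff):
        node.length = float(length)
    out.root.length = None
    return out
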