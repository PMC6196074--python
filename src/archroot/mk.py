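"""Two-state Mk likelihood engine with a directional (non-stationary) root.

The model is a continuous-time Markov chain on {absent, present} with
stationary presence frequency π₁.  The rate matrix is normalised so that one
unit of branch length equals one expected state change per character at
stationarity (μ = 1/(2π₀π₁)).  In the *reversible* variant the root state
frequency equals π₁ and, by the pulley principle, the likelihood is
invariant to root placement.  In the *directional* variant the root
frequency ρ₁ is a free parameter: characters start at the root from
(1−ρ₁, ρ₁) and drift toward stationarity along the tree, which makes the
likelihood depend on where the root is — the property exploited to infer
the root of the tree of life from domain presence/absence data.

Rate heterogeneity across characters uses the discrete-gamma construction
(equal-probability categories represented by their means).  Ascertainment
corrections condition on a character being observable: ``no-all-absent``
divides by 1 − P(all tips absent); ``variable-only`` additionally removes
the all-present pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy.special import gammainc, logsumexp
from scipy.stats import gamma as gamma_dist

from .matrix import ABSENT, PRESENT, UNKNOWN, BinaryCharacterMatrix
from .trees import Node, PhyloTree

__all__ = [
    "MkModel",
    "LikelihoodEvaluator",
    "transition_probs",
    "discrete_gamma_rates",
    "log_likelihood",
    "effective_branch_lengths",
]

_ASC_MODES = ("none", "no-all-absent", "variable-only")
_CLOCK_MODES = ("none", "strict", "igr")


@dataclass(frozen=True)
class MkModel:
    """Parameters of the binary Mk model.

    rho1=None denotes the reversible variant (root frequency tied to pi1).
    """

    pi1: float = 0.5
    rho1: Optional[float] = None
    alpha: float = 1.0
    K: int = 1
    ascertainment: str = "no-all-absent"
    clock: str = "none"
    igr_variance: float = 0.0

    def __post_init__(self):
        if not 0.0 < self.pi1 < 1.0:
            raise ValueError("pi1 must lie strictly between 0 and 1")
        if self.rho1 is not None and not 0.0 < self.rho1 < 1.0:
            raise ValueError("rho1 must lie strictly between 0 and 1")
        if self.alpha <= 0:
            raise ValueError("gamma shape alpha must be positive")
        if self.K < 1:
            raise ValueError("need at least one rate category")
        if self.ascertainment not in _ASC_MODES:
            raise ValueError(f"ascertainment must be one of {_ASC_MODES}")
        if self.clock not in _CLOCK_MODES:
            raise ValueError(f"clock must be one of {_CLOCK_MODES}")
        if self.igr_variance < 0:
            raise ValueError("igr_variance must be non-negative")

    @property
    def reversible(self) -> bool:
        return self.rho1 is None or self.rho1 == self.pi1

    @property
    def root_freq(self) -> float:
        return self.pi1 if self.rho1 is None else self.rho1

    def with_(self, **kw) -> "MkModel":
        return replace(self, **kw)


def transition_probs(pi1: float, t: float, rate: float = 1.0) -> np.ndarray:
    """2×2 transition matrix for a branch of length ``t`` (expected changes).

    With μ = 1/(2π₀π₁): P(0→1) = π₁(1−e^{−μ·rate·t}), P(1→0) = π₀(1−e^{−μ·rate·t}).
    """
    if not 0.0 < pi1 < 1.0:
        raise ValueError("pi1 must lie strictly between 0 and 1")
    if t < 0 or rate < 0:
        raise ValueError("branch length and rate must be non-negative")
    pi0 = 1.0 - pi1
    mu = 1.0 / (2.0 * pi0 * pi1)
    f = 1.0 - np.exp(-mu * rate * t)
    return np.array([[1.0 - pi1 * f, pi1 * f], [pi0 * f, 1.0 - pi0 * f]])


def discrete_gamma_rates(alpha: float, K: int) -> np.ndarray:
    """Mean-of-category discrete gamma rate multipliers (mean exactly 1).

    The gamma(α, rate α) density is cut at its K-quantiles; each category is
    represented by its conditional mean, computed in closed form from the
    regularised incomplete gamma function.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if K < 1:
        raise ValueError("K must be >= 1")
    if K == 1:
        return np.ones(1)
    edges = gamma_dist.ppf(np.arange(1, K) / K, a=alpha, scale=1.0 / alpha)
    upper = np.concatenate([gammainc(alpha + 1.0, alpha * edges), [1.0]])
    lower = np.concatenate([[0.0], gammainc(alpha + 1.0, alpha * edges)])
    rates = K * (upper - lower)
    return rates / rates.mean()  # exact unit mean against roundoff


BranchRates = Union[None, Mapping[int, float], np.ndarray]


def _edge_rate(branch_rates: BranchRates, node: Node) -> float:
    if branch_rates is None:
        return 1.0
    if isinstance(branch_rates, np.ndarray):
        return float(branch_rates[node.index])
    return float(branch_rates.get(node.index, 1.0))


def _prune(
    tree: PhyloTree,
    tips: np.ndarray,  # (n_leaves, n_patterns, 2) conditional likelihoods
    leaf_pos: Mapping[str, int],
    pi1: float,
    root_freq: float,
    rates: np.ndarray,
    branch_rates: BranchRates,
) -> np.ndarray:
    """Log likelihood of each pattern, mixed over gamma categories."""
    n_pat = tips.shape[1]
    K = len(rates)
    root_w = np.array([1.0 - root_freq, root_freq])
    pi0 = 1.0 - pi1
    mu = 1.0 / (2.0 * pi0 * pi1)
    nodes = list(tree.postorder())
    # partials carried per node as (K, n_pat, 2); scaling is applied lazily,
    # only when values threaten to underflow, and tracked in logscale
    partial: dict[int, np.ndarray] = {}
    logscale = np.zeros((K, n_pat))
    scaled = False
    Pt = np.empty((K, 2, 2))  # transposed transition matrix buffer
    for nd in nodes:
        if nd.is_leaf:
            partial[nd.index] = np.broadcast_to(tips[leaf_pos[nd.label]], (K, n_pat, 2))
            continue
        acc = None
        for ch in nd.children:
            f = 1.0 - np.exp(-mu * rates * (_edge_rate(branch_rates, ch) * ch.length))  # (K,)
            Pt[:, 0, 0] = 1.0 - pi1 * f
            Pt[:, 1, 0] = pi1 * f
            Pt[:, 0, 1] = pi0 * f
            Pt[:, 1, 1] = 1.0 - pi0 * f
            term = partial.pop(ch.index) @ Pt
            if acc is None:
                acc = term
            else:
                acc *= term
        if acc.max() < 1e-150:
            mx = acc.max(axis=2)
            nz = mx > 0
            np.divide(acc, np.where(nz, mx, 1.0)[:, :, None], out=acc)
            with np.errstate(divide="ignore"):
                logscale = logscale + np.where(nz, np.log(np.where(nz, mx, 1.0)), -np.inf)
            scaled = True
        partial[nd.index] = acc
    lik = partial[tree.root.index] @ root_w  # (K, n_pat)
    with np.errstate(divide="ignore"):
        per_cat = np.log(lik) + logscale if scaled else np.log(lik)
    return logsumexp(per_cat, axis=0) - np.log(K)


def _compress(matrix: BinaryCharacterMatrix) -> tuple[np.ndarray, np.ndarray]:
    cols, counts = np.unique(matrix.states.T, axis=0, return_counts=True)
    return cols, counts  # (n_patterns, n_taxa), weights


_TIP_COND = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])  # absent, present, unknown


class LikelihoodEvaluator:
    """Pattern-compressed pruning likelihood bound to one matrix.

    MCMC re-evaluates the likelihood for every proposal; compressing the
    matrix into unique site patterns once and reusing the tip conditionals
    makes each call cheap.
    """

    def __init__(self, matrix: BinaryCharacterMatrix):
        self.matrix = matrix
        patterns, self.weights = _compress(matrix)
        self.tips = _TIP_COND[patterns.T]  # (n_taxa, n_patterns, 2)
        self.leaf_pos = {t: i for i, t in enumerate(matrix.taxa)}
        self.n_taxa = len(matrix.taxa)
        self.n_characters = len(matrix.characters)

    def __call__(self, tree: PhyloTree, model: MkModel, branch_rates: BranchRates = None) -> float:
        tree.validate_lengths()
        if set(tree.leaf_labels) != set(self.matrix.taxa):
            raise ValueError("tree leaf set does not match matrix taxa")
        tree.reindex()
        rates = discrete_gamma_rates(model.alpha, model.K)
        ln_site = _prune(tree, self.tips, self.leaf_pos, model.pi1, model.root_freq, rates, branch_rates)

        if model.ascertainment != "none":
            cond_patterns = [np.zeros(self.n_taxa, dtype=int)]
            if model.ascertainment == "variable-only":
                cond_patterns.append(np.ones(self.n_taxa, dtype=int))
            cond = np.stack(cond_patterns)
            ln_unobs = _prune(tree, _TIP_COND[cond.T], self.leaf_pos, model.pi1, model.root_freq, rates, branch_rates)
            p_unobs = np.exp(logsumexp(ln_unobs))
            if p_unobs >= 1.0:
                return float("-inf")
            ln_site = ln_site - np.log1p(-p_unobs)

        return float(np.dot(self.weights, ln_site))


def log_likelihood(
    tree: PhyloTree,
    matrix: BinaryCharacterMatrix,
    model: MkModel,
    branch_rates: BranchRates = None,
) -> float:
    """Felsenstein-pruning log likelihood of a rooted tree, with scaling.

    Unknown cells contribute a partial of (1, 1); the K equal-weight gamma
    categories are mixed per character; the root partials are weighted by
    (1−ρ₁, ρ₁).  Ascertainment modes divide each character's likelihood by
    the probability of the conditioning event.
    """
    return LikelihoodEvaluator(matrix)(tree, model, branch_rates)


def effective_branch_lengths(
    tree: PhyloTree,
    clock: str = "none",
    rate: float = 1.0,
    igr_variance: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    ultrametric_tol: float = 1e-6,
) -> dict[int, float]:
    """Per-edge expected-change lengths keyed by child-node index.

    ``none`` returns stored lengths; ``strict`` multiplies times by a global
    rate; ``igr`` additionally draws an independent gamma multiplier per
    branch with mean 1 and variance ``igr_variance`` (a relaxed clock).
    """
    if clock not in _CLOCK_MODES:
        raise ValueError(f"clock must be one of {_CLOCK_MODES}")
    tree.reindex()
    if clock == "none":
        return {nd.index: nd.length for nd in tree.edges()}
    if not tree.is_ultrametric(tol=ultrametric_tol):
        raise ValueError(f"{clock} clock requires an ultrametric (time-consistent) tree")
    edges = tree.edges()
    if clock == "strict" or igr_variance == 0.0:
        return {nd.index: nd.length * rate for nd in edges}
    if rng is None:
        rng = np.random.default_rng()
    shape = 1.0 / igr_variance
    mult = rng.gamma(shape, igr_variance, size=len(edges))
    return {nd.index: nd.length * rate * m for nd, m in zip(edges, mult)}
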