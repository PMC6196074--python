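"""Metropolis-coupled MCMC over Mk model parameters, branch lengths and root.

The sampler follows the MrBayes protocol used for genome-signature
matrices: several incrementally heated chains per run (chain *i* runs at
temperature 1/(1+λi)), independent runs for convergence assessment, cold
chain sampled at a fixed interval, the first half of samples discarded as
burn-in.  Convergence is measured by the average standard deviation of
split frequencies (ASDSF) between runs and the Gelman–Rubin potential scale
reduction factor (PSRF) per scalar parameter.  Marginal likelihoods use the
harmonic-mean estimator (retained for comparability; it is biased and
high-variance, and a warning is emitted for short traces).

Parameterisation of the state: an unrooted branch-length vector plus a root
position on one of its edges.  Priors: π₁, ρ₁ ~ U(0,1); α ~ Exp(1);
unrooted branch lengths ~ iid Exp(10); root position uniform over edges and
positions; clock rate ~ Exp(1); IGR variance ~ Exp(10); IGR branch
multipliers ~ Gamma(1/v, v).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .matrix import BinaryCharacterMatrix
from .mk import LikelihoodEvaluator, MkModel
from .trees import Node, PhyloTree, parse_newick, write_newick

__all__ = [
    "McmcConfig",
    "PosteriorTrace",
    "RunDiagnostics",
    "run_mcmc",
    "asdsf",
    "psrf",
    "harmonic_mean_lnL",
    "lbf",
    "lbf_label",
    "llr_rank",
]


@dataclass
class McmcConfig:
    generations: int = 10_000
    sample_interval: int = 500
    n_runs: int = 2
    chains_per_run: int = 4
    heating: float = 0.1
    burn_in: float = 0.5
    seed: int = 0
    topology_mode: str = "fixed"  # fixed | constrained | free
    constraints: list[frozenset] = field(default_factory=list)
    move_weights: Optional[dict[str, float]] = None
    # proposal tuning
    window_pi: float = 0.1
    window_rho: float = 0.1
    scale_lambda: float = 0.7  # multiplier-move log-range

    def __post_init__(self):
        if self.generations <= 0:
            raise ValueError("generations must be positive")
        if not 0.0 <= self.burn_in < 1.0:
            raise ValueError("burn_in fraction must lie in [0, 1)")
        if self.chains_per_run < 1:
            raise ValueError("need at least one chain")
        if self.topology_mode not in ("fixed", "constrained", "free"):
            raise ValueError("topology_mode must be fixed, constrained or free")


@dataclass
class PosteriorTrace:
    """Cold-chain samples of one run."""

    run_id: int
    generations: list[int]
    params: pd.DataFrame  # columns: lnL, pi1, rho1, alpha, ... one row per sample
    newicks: list[str]
    root_splits: list[frozenset]

    def __len__(self) -> int:
        return len(self.generations)

    def post_burn_in(self, burn_in: float = 0.5) -> "PosteriorTrace":
        k = int(len(self) * burn_in)
        return PosteriorTrace(
            self.run_id,
            self.generations[k:],
            self.params.iloc[k:].reset_index(drop=True),
            self.newicks[k:],
            self.root_splits[k:],
        )

    def split_samples(self, nontrivial: bool = True) -> list[set[frozenset]]:
        return [parse_newick(nw).bipartitions(nontrivial=nontrivial) for nw in self.newicks]

    @property
    def lnL(self) -> np.ndarray:
        return self.params["lnL"].to_numpy()


@dataclass
class RunDiagnostics:
    asdsf: float
    psrf: dict[str, float]
    acceptance: dict[str, float]
    swap_acceptance: float


# ------------------------------------------------------------------- moves
class _ChainState:
    __slots__ = ("tree", "pi1", "rho1", "alpha", "clock_rate", "igr_variance", "igr_mult", "lnL", "lnPrior")

    def __init__(self, tree, pi1, rho1, alpha, clock_rate, igr_variance, igr_mult):
        self.tree = tree
        self.pi1 = pi1
        self.rho1 = rho1  # None in the reversible variant
        self.alpha = alpha
        self.clock_rate = clock_rate
        self.igr_variance = igr_variance
        self.igr_mult = igr_mult  # dict edge-index -> multiplier, or None
        self.lnL = -math.inf
        self.lnPrior = -math.inf

    def copy(self) -> "_ChainState":
        s = _ChainState(
            self.tree.copy(),
            self.pi1,
            self.rho1,
            self.alpha,
            self.clock_rate,
            self.igr_variance,
            dict(self.igr_mult) if self.igr_mult is not None else None,
        )
        s.lnL, s.lnPrior = self.lnL, self.lnPrior
        return s


def _unrooted_edges(tree: PhyloTree) -> list[Node]:
    """Edges of the unrooted topology: the two root-child edges count as one
    (represented by the root's first child)."""
    out = []
    skip = tree.root.children[1] if len(tree.root.children) == 2 else None
    for nd in tree.edges():
        if nd is skip:
            continue
        out.append(nd)
    return out


def _root_edge_length(tree: PhyloTree) -> float:
    a, b = tree.root.children[:2]
    return a.length + b.length


def _ln_prior(state: _ChainState, model: MkModel, clock: str) -> float:
    lp = 0.0
    if not 0 < state.pi1 < 1:
        return -math.inf
    if state.rho1 is not None and not 0 < state.rho1 < 1:
        return -math.inf
    if state.alpha <= 0:
        return -math.inf
    lp += -state.alpha  # Exp(1)
    if clock == "none":
        root = state.tree.root
        merged = len(root.children) == 2
        for nd in _unrooted_edges(state.tree):
            L = _root_edge_length(state.tree) if (merged and nd.parent is root) else nd.length
            if L < 0:
                return -math.inf
            lp += math.log(10.0) - 10.0 * L
    else:
        if state.clock_rate <= 0:
            return -math.inf
        lp += -state.clock_rate  # Exp(1)
        if clock == "igr":
            v = state.igr_variance
            if v <= 0:
                return -math.inf
            lp += math.log(10.0) - 10.0 * v  # Exp(10)
            sh = 1.0 / v
            from scipy.stats import gamma as gd

            for m in state.igr_mult.values():
                if m <= 0:
                    return -math.inf
                lp += gd.logpdf(m, a=sh, scale=v)
    return lp


def _branch_rates(state: _ChainState, clock: str) -> Optional[dict[int, float]]:
    if clock == "none":
        return None
    state.tree.reindex()
    if clock == "strict":
        return {nd.index: state.clock_rate for nd in state.tree.edges()}
    return {nd.index: state.clock_rate * state.igr_mult.get(nd.index, 1.0) for nd in state.tree.edges()}


def _model_with(state: _ChainState, model: MkModel) -> MkModel:
    return model.with_(pi1=state.pi1, rho1=state.rho1, alpha=state.alpha)


def _default_move_weights(model: MkModel, config: McmcConfig) -> dict[str, float]:
    w = {"pi1": 2.0, "brlen": 4.0, "treescale": 1.0}
    if model.K > 1:
        w["alpha"] = 2.0
    if model.rho1 is not None:
        w["rho1"] = 2.0
        w["root"] = 4.0
    if model.clock != "none":
        w = {"pi1": 2.0, "clockrate": 2.0}
        if model.K > 1:
            w["alpha"] = 2.0
        if model.rho1 is not None:
            w["rho1"] = 2.0
            w["root"] = 4.0
        if model.clock == "igr":
            w["igr"] = 3.0
            w["igrvar"] = 1.0
    if config.topology_mode in ("constrained", "free"):
        w["nni"] = 3.0
    return w


def _reflect01(x: float) -> float:
    x = x % 2.0
    return 2.0 - x if x > 1.0 else x


def _satisfies_constraints(tree: PhyloTree, constraints: Sequence[frozenset]) -> bool:
    if not constraints:
        return True
    bips = tree.bipartitions(nontrivial=False)
    all_taxa = frozenset(tree.leaf_labels)
    anchor = min(all_taxa)
    for c in constraints:
        side = all_taxa - c if anchor in c else frozenset(c)
        if side not in bips:
            return False
    return True


def _propose(
    state: _ChainState,
    move: str,
    model: MkModel,
    config: McmcConfig,
    rng: np.random.Generator,
) -> tuple[_ChainState, float]:
    """Return (proposed state, log Hastings ratio)."""
    lam = config.scale_lambda
    new = state.copy()
    if move == "pi1":
        new.pi1 = _reflect01(state.pi1 + rng.uniform(-config.window_pi, config.window_pi))
        return new, 0.0
    if move == "rho1":
        new.rho1 = _reflect01(state.rho1 + rng.uniform(-config.window_rho, config.window_rho))
        return new, 0.0
    if move == "alpha":
        m = math.exp(lam * (rng.random() - 0.5))
        new.alpha = state.alpha * m
        return new, math.log(m)
    if move == "clockrate":
        m = math.exp(lam * (rng.random() - 0.5))
        new.clock_rate = state.clock_rate * m
        return new, math.log(m)
    if move == "igrvar":
        m = math.exp(lam * (rng.random() - 0.5))
        new.igr_variance = state.igr_variance * m
        return new, math.log(m)
    if move == "igr":
        edges = new.tree.edges()
        nd = edges[rng.integers(len(edges))]
        m = math.exp(lam * (rng.random() - 0.5))
        new.igr_mult[nd.index] = new.igr_mult.get(nd.index, 1.0) * m
        return new, math.log(m)
    if move == "brlen":
        edges = _unrooted_edges(new.tree)
        nd = edges[rng.integers(len(edges))]
        m = math.exp(lam * (rng.random() - 0.5))
        if nd.parent is new.tree.root and len(new.tree.root.children) == 2:
            # scale the merged root edge, preserving the root's relative position
            a, b = new.tree.root.children[:2]
            a.length *= m
            b.length *= m
        else:
            nd.length *= m
        return new, math.log(m)
    if move == "treescale":
        m = math.exp(lam * (rng.random() - 0.5))
        n_edges = 0
        for nd in new.tree.edges():
            nd.length *= m
            n_edges += 1
        if len(new.tree.root.children) == 2:
            n_edges -= 1  # merged root edge counts once
        return new, n_edges * math.log(m)
    if move == "root":
        tree = new.tree
        edges = _unrooted_edges(tree)
        nd = edges[rng.integers(len(edges))]
        u = rng.random()
        if nd.parent is tree.root and len(tree.root.children) == 2:
            # stay on the root edge, move the attachment point
            a, b = tree.root.children[:2]
            tot = a.length + b.length
            a.length = u * tot
            b.length = (1.0 - u) * tot
            return new, 0.0
        new.tree = tree.rerooted(nd, u)
        return new, 0.0
    if move == "nni":
        tree = new.tree
        # internal edges: child is internal, parent is not the root-merged edge end
        internal = [nd for nd in tree.edges() if not nd.is_leaf]
        if not internal:
            return new, 0.0
        nd = internal[rng.integers(len(internal))]
        parent = nd.parent
        # sibling of nd
        sibs = [c for c in parent.children if c is not nd]
        if not sibs:
            return new, 0.0
        sib = sibs[rng.integers(len(sibs))]
        child = nd.children[rng.integers(len(nd.children))]
        # swap sib and child
        parent.children[parent.children.index(sib)] = child
        nd.children[nd.children.index(child)] = sib
        sib.parent, child.parent = nd, parent
        new.tree.reindex()
        return new, 0.0
    raise ValueError(f"unknown move {move!r}")


# ------------------------------------------------------------------- sampler
def run_mcmc(
    matrix: BinaryCharacterMatrix,
    model: MkModel,
    start_tree: PhyloTree,
    config: McmcConfig,
) -> tuple[list[PosteriorTrace], RunDiagnostics]:
    """Run ``config.n_runs`` independent Metropolis-coupled samplings.

    Under ``topology_mode='fixed'`` only root position, branch lengths and
    scalar parameters are sampled.  Returns the cold-chain trace of each run
    and joint convergence diagnostics (computed post burn-in).
    """
    like = LikelihoodEvaluator(matrix)
    if set(start_tree.leaf_labels) != set(matrix.taxa):
        raise ValueError("start tree leaves do not match matrix taxa")
    weights = config.move_weights or _default_move_weights(model, config)
    move_names = sorted(weights)
    move_p = np.array([weights[m] for m in move_names], dtype=float)
    move_p /= move_p.sum()

    traces: list[PosteriorTrace] = []
    acc: dict[str, list[int]] = {m: [0, 0] for m in move_names}
    swap_acc = [0, 0]
    clock = model.clock

    for run in range(config.n_runs):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=int(config.seed), spawn_key=(run,)))
        chains: list[_ChainState] = []
        for ci in range(config.chains_per_run):
            tree = start_tree.copy()
            if clock != "none" and not tree.is_ultrametric(1e-4):
                raise ValueError("clock models require an ultrametric start tree")
            igr_mult = None
            if clock == "igr":
                tree.reindex()
                igr_mult = {nd.index: 1.0 for nd in tree.edges()}
            st = _ChainState(
                tree,
                pi1=model.pi1,
                rho1=model.rho1,
                alpha=model.alpha,
                clock_rate=1.0,
                igr_variance=model.igr_variance if model.igr_variance > 0 else 0.1,
                igr_mult=igr_mult,
            )
            st.lnPrior = _ln_prior(st, model, clock)
            st.lnL = like(st.tree, _model_with(st, model), _branch_rates(st, clock))
            if not math.isfinite(st.lnL):
                raise ValueError(
                    f"non-finite starting likelihood (lnL={st.lnL}); parameters: "
                    f"pi1={st.pi1} rho1={st.rho1} alpha={st.alpha} clock={clock}"
                )
            chains.append(st)
        betas = [1.0 / (1.0 + config.heating * i) for i in range(config.chains_per_run)]

        gens: list[int] = []
        rows: list[dict] = []
        newicks: list[str] = []
        root_splits: list[frozenset] = []

        def record(g: int) -> None:
            cold = chains[0]
            row = {"lnL": cold.lnL, "pi1": cold.pi1, "alpha": cold.alpha}
            if cold.rho1 is not None:
                row["rho1"] = cold.rho1
            if clock != "none":
                row["clock_rate"] = cold.clock_rate
            if clock == "igr":
                row["igr_variance"] = cold.igr_variance
            gens.append(g)
            rows.append(row)
            newicks.append(write_newick(cold.tree))
            root_splits.append(cold.tree.root_split() if len(cold.tree.root.children) == 2 else frozenset())

        record(0)
        for g in range(1, config.generations + 1):
            for ci, st in enumerate(chains):
                mv = move_names[rng.choice(len(move_names), p=move_p)]
                prop, lnH = _propose(st, mv, model, config, rng)
                if mv == "nni" and config.topology_mode == "fixed":
                    continue
                if mv == "nni" and not _satisfies_constraints(prop.tree, config.constraints):
                    acc[mv][1] += 1
                    continue
                prop.lnPrior = _ln_prior(prop, model, clock)
                if math.isfinite(prop.lnPrior):
                    prop.lnL = like(prop.tree, _model_with(prop, model), _branch_rates(prop, clock))
                else:
                    prop.lnL = -math.inf
                ratio = betas[ci] * ((prop.lnL + prop.lnPrior) - (st.lnL + st.lnPrior)) + lnH
                acc[mv][1] += 1
                if math.log(rng.random() + 1e-300) < ratio:
                    chains[ci] = prop
                    acc[mv][0] += 1
            if len(chains) > 1:
                i, j = rng.choice(len(chains), size=2, replace=False)
                si, sj = chains[i], chains[j]
                r = (betas[i] - betas[j]) * ((sj.lnL + sj.lnPrior) - (si.lnL + si.lnPrior))
                swap_acc[1] += 1
                if math.log(rng.random() + 1e-300) < r:
                    chains[i], chains[j] = sj, si
                    swap_acc[0] += 1
            if g % config.sample_interval == 0:
                record(g)

        traces.append(
            PosteriorTrace(run, gens, pd.DataFrame(rows), newicks, root_splits)
        )

    post = [t.post_burn_in(config.burn_in) for t in traces]
    try:
        asdsf_val = asdsf(post) if len(post) > 1 else float("nan")
    except ValueError:
        asdsf_val = 0.0  # no qualifying splits (e.g. tiny fixed-topology runs)
    psrf_vals: dict[str, float] = {}
    if len(post) > 1 and all(len(t) >= 10 for t in post):
        for col in post[0].params.columns:
            psrf_vals[col] = psrf([t.params[col].to_numpy() for t in post])
    acceptance = {m: (a / n if n else float("nan")) for m, (a, n) in acc.items()}
    diags = RunDiagnostics(
        asdsf=asdsf_val,
        psrf=psrf_vals,
        acceptance=acceptance,
        swap_acceptance=(swap_acc[0] / swap_acc[1]) if swap_acc[1] else float("nan"),
    )
    return traces, diags


# -------------------------------------------------------------- diagnostics
def _split_frequencies(split_samples: list[set[frozenset]]) -> dict[frozenset, float]:
    n = len(split_samples)
    counts: dict[frozenset, int] = {}
    for s in split_samples:
        for sp in s:
            counts[sp] = counts.get(sp, 0) + 1
    return {sp: c / n for sp, c in counts.items()}


def asdsf(traces: Sequence[PosteriorTrace], min_freq: float = 0.1) -> float:
    """Average standard deviation of split frequencies across runs.

    For every nontrivial split reaching ``min_freq`` in at least one run,
    the (n−1)-denominator standard deviation of its per-run frequencies is
    computed; the returned value is the mean over qualifying splits.
    """
    if len(traces) < 2:
        raise ValueError("ASDSF needs at least two runs")
    freqs = [_split_frequencies(t.split_samples()) for t in traces]
    qualifying = {sp for f in freqs for sp, v in f.items() if v >= min_freq}
    if not qualifying:
        raise ValueError("no splits reach the frequency threshold")
    sds = []
    for sp in qualifying:
        vals = np.array([f.get(sp, 0.0) for f in freqs])
        sds.append(vals.std(ddof=1))
    return float(np.mean(sds))


def psrf(per_run_values: Sequence[np.ndarray]) -> float:
    """Gelman–Rubin potential scale reduction factor from ≥2 runs.

    Returns NaN (undefined) when the within-run variance is zero.
    """
    runs = [np.asarray(v, dtype=float) for v in per_run_values]
    if len(runs) < 2:
        raise ValueError("PSRF needs at least two runs")
    n = min(len(v) for v in runs)
    if n < 10:
        raise ValueError("PSRF needs at least 10 samples per run")
    runs = [v[:n] for v in runs]
    means = np.array([v.mean() for v in runs])
    variances = np.array([v.var(ddof=1) for v in runs])
    W = variances.mean()
    B_over_n = means.var(ddof=1)
    if W == 0:
        return float("nan")
    var_plus = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_plus / W))


# ---------------------------------------------------- marginal lnL / ranking
def harmonic_mean_lnL(trace) -> float:
    """Harmonic-mean estimate of the marginal log likelihood.

    ``trace`` is a :class:`PosteriorTrace` (its lnL column is used) or an
    array of log likelihoods, assumed post burn-in.  Computed in log space:
    ln m̂ = ln N − logsumexp(−lnL).  The estimator is biased and has high
    (often infinite) variance; a warning is emitted for short traces.
    """
    lnL = trace.lnL if isinstance(trace, PosteriorTrace) else np.asarray(trace, dtype=float)
    if lnL.size == 0:
        raise ValueError("empty trace")
    if not np.isfinite(lnL).all():
        raise ValueError("non-finite log likelihoods in trace")
    if lnL.size < 1000:
        warnings.warn(
            "harmonic-mean marginal likelihood from fewer than 1000 samples is unstable; "
            "prefer longer runs",
            stacklevel=2,
        )
    return float(np.log(lnL.size) - logsumexp(-lnL))


def lbf(marginal_lnL_a: float, marginal_lnL_b: float) -> float:
    """Log Bayes factor of model A over model B (difference of marginal lnL)."""
    if not (math.isfinite(marginal_lnL_a) and math.isfinite(marginal_lnL_b)):
        raise ValueError("marginal log likelihoods must be finite")
    return marginal_lnL_a - marginal_lnL_b


def lbf_label(value: float) -> str:
    """Conventional verbal scale: |LBF| in 3–5 'strong', above 5 'very strong'."""
    a = abs(value)
    if a > 5:
        return "very strong"
    if a >= 3:
        return "strong"
    if a >= 1:
        return "positive"
    return "weak"


def llr_rank(log_likelihoods: dict[str, float]) -> pd.DataFrame:
    """Rank models by raw log likelihood; LLR is the difference from the best."""
    if len(log_likelihoods) < 1:
        raise ValueError("no models to rank")
    best = max(log_likelihoods.values())
    df = pd.DataFrame(
        {
            "model": list(log_likelihoods),
            "lnL": list(log_likelihoods.values()),
        }
    )
    df["LLR"] = best - df["lnL"]
    df = df.sort_values("LLR", kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
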