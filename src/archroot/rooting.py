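"""Root-hypothesis inference, model ranking and result summaries.

Orchestrates the full analysis of a presence/absence matrix: a grid of Mk
model variants is fitted by MCMC and ranked by harmonic-mean marginal
likelihood (log Bayes factors against the best model); root placements
sampled under directional models are aggregated into posterior support for
named rooting hypotheses (e.g. R1 = stem of Bacteria … R4 = stem of
Eukarya, R5 = any branch within Archaea); clade posterior probabilities and
majority-rule consensus trees summarise the topology.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .matrix import BinaryCharacterMatrix
from .mcmc import McmcConfig, PosteriorTrace, RunDiagnostics, harmonic_mean_lnL, run_mcmc
from .mk import MkModel
from .trees import PhyloTree, parse_newick

__all__ = [
    "RootHypothesis",
    "RootSupport",
    "run_model_grid",
    "default_model_grid",
    "root_support",
    "clade_pp",
    "consensus_tree",
    "report",
]


@dataclass(frozen=True)
class RootHypothesis:
    """A named root placement: the stem branch of a taxon set, or any branch
    within it (``mode='within'``, for 'root inside clade X' hypotheses)."""

    name: str
    taxa: frozenset
    mode: str = "stem"

    def __post_init__(self):
        if self.mode not in ("stem", "within"):
            raise ValueError("mode must be 'stem' or 'within'")

    def matches(self, root_side: frozenset, all_taxa: frozenset) -> bool:
        """Does a sampled root split (one side) satisfy this hypothesis?"""
        other = all_taxa - root_side
        if self.mode == "stem":
            return root_side == self.taxa or other == self.taxa
        return (root_side < self.taxa) or (other < self.taxa)


@dataclass
class RootSupport:
    """Posterior mass on root branches and on named hypotheses."""

    branch_probs: dict[frozenset, float]
    hypothesis_probs: dict[str, float]  # includes an explicit "other" row
    n_samples: int

    def best(self) -> str:
        named = {k: v for k, v in self.hypothesis_probs.items() if k != "other"}
        return max(named, key=named.get)


def _pooled_post_burn_in(traces: Sequence[PosteriorTrace], burn_in: float) -> list[PosteriorTrace]:
    return [t.post_burn_in(burn_in) for t in traces]


def root_support(
    traces: Sequence[PosteriorTrace],
    hypotheses: Sequence[RootHypothesis],
    taxa: Sequence[str],
    burn_in: float = 0.0,
) -> RootSupport:
    """Aggregate sampled root positions into per-branch and per-hypothesis mass.

    Requires traces from a directional-model run: under a reversible model
    the root is unidentifiable (pulley principle) and the operation refuses.
    ``burn_in`` may be left 0 when the traces are already post burn-in.
    """
    all_taxa = frozenset(taxa)
    for h in hypotheses:
        if not h.taxa <= all_taxa:
            raise ValueError(f"hypothesis {h.name!r} names taxa absent from the matrix")
    pooled = _pooled_post_burn_in(traces, burn_in)
    for t in pooled:
        if "rho1" not in t.params.columns:
            raise ValueError(
                "root_support requires directional-model traces; the root is not "
                "identifiable under a reversible model"
            )
    splits: list[frozenset] = [s for t in pooled for s in t.root_splits]
    if not splits:
        raise ValueError("no root samples in traces")
    n = len(splits)
    branch: dict[frozenset, float] = {}
    for s in splits:
        branch[s] = branch.get(s, 0.0) + 1.0 / n
    hyp: dict[str, float] = {h.name: 0.0 for h in hypotheses}
    other = 0.0
    for s, p in branch.items():
        matched = False
        for h in hypotheses:
            if h.matches(s, all_taxa):
                hyp[h.name] += p
                matched = True
                break
        if not matched:
            other += p
    hyp["other"] = other
    return RootSupport(branch_probs=branch, hypothesis_probs=hyp, n_samples=n)


def clade_pp(
    traces: Sequence[PosteriorTrace],
    taxon_set: Iterable[str],
    burn_in: float = 0.0,
    rooted: bool = True,
) -> float:
    """Posterior probability that ``taxon_set`` forms a clade (or, with
    ``rooted=False``, a bipartition) in the sampled trees."""
    target = frozenset(taxon_set)
    pooled = _pooled_post_burn_in(traces, burn_in)
    newicks = [nw for t in pooled for nw in t.newicks]
    if not newicks:
        raise ValueError("no tree samples in traces")
    first = parse_newick(newicks[0])
    all_taxa = frozenset(first.leaf_labels)
    missing = target - all_taxa
    if missing:
        raise ValueError(f"taxa absent from sampled trees: {sorted(missing)[:5]}")
    if len(target) in (1, len(all_taxa)):
        return 1.0
    hits = 0
    anchor = min(all_taxa)
    canon = all_taxa - target if anchor in target else target
    for nw in newicks:
        tree = parse_newick(nw)
        if rooted:
            hits += target in set(tree.clade_leafsets())
        else:
            hits += canon in tree.bipartitions()
    return hits / len(newicks)


def consensus_tree(
    traces: Sequence[PosteriorTrace],
    burn_in: float = 0.0,
    min_freq: float = 0.5,
) -> tuple[str, dict[frozenset, float]]:
    """Majority-rule consensus of pooled samples with split frequencies.

    Returns (newick with posterior-probability node labels, split→frequency
    map over all observed nontrivial splits).
    """
    pooled = _pooled_post_burn_in(traces, burn_in)
    newicks = [nw for t in pooled for nw in t.newicks]
    if not newicks:
        raise ValueError("no tree samples in traces")
    # pooled nontrivial split frequencies
    counts: dict[frozenset, int] = {}
    for t in pooled:
        for s in t.split_samples():
            for sp in s:
                counts[sp] = counts.get(sp, 0) + 1
    n = len(newicks)
    freqs = {sp: c / n for sp, c in counts.items()}

    tns = dendropy.TaxonNamespace()
    tl = dendropy.TreeList.get(data="\n".join(newicks), schema="newick", taxon_namespace=tns)
    con = tl.consensus(min_freq=min_freq)
    all_taxa = frozenset(t.label for t in tns)
    anchor = min(all_taxa)
    for nd in con.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if anchor in side:
            side = all_taxa - side
        if 1 < len(side) < len(all_taxa) - 1:
            nd.label = f"{freqs.get(side, 0.0):.3f}"
    return con.as_string(schema="newick", suppress_rooting=True).strip(), freqs


# ------------------------------------------------------------------ the grid
def default_model_grid(
    base: MkModel,
    variants: Sequence[str] = ("reversible", "directional"),
    categories: Sequence[int] = (1, 4, 8, 12),
    clocks: Sequence[str] = ("none", "strict", "igr"),
    rho1: float = 0.7,
) -> dict[str, MkModel]:
    """Cross {reversible, directional} × K × clock into labelled models."""
    grid: dict[str, MkModel] = {}
    for var in variants:
        for K in categories:
            for clock in clocks:
                label = f"Mk{'+G' + str(K) if K > 1 else ''}+{var}" + ("" if clock == "none" else f"+{clock}")
                grid[label] = base.with_(
                    rho1=None if var == "reversible" else (base.rho1 if base.rho1 is not None else rho1),
                    K=K,
                    clock=clock,
                )
    return grid


def run_model_grid(
    matrix: BinaryCharacterMatrix,
    start_tree: PhyloTree,
    grid: Mapping[str, MkModel],
    config: McmcConfig,
    asdsf_threshold: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, list[PosteriorTrace]]]:
    """One MCMC (with ``config.n_runs`` runs) per model cell; rank by LBF.

    Returns a comparison table — model, marginal lnL (harmonic mean over
    pooled post-burn-in samples), LBF versus the best model (0 for the
    best), rank, convergence flag — plus the raw traces per model.
    Non-converged cells (ASDSF above threshold) are flagged, never dropped.
    """
    if not grid:
        raise ValueError("empty model grid")
    rows = []
    all_traces: dict[str, list[PosteriorTrace]] = {}
    for label, model in grid.items():
        traces, diags = run_mcmc(matrix, model, start_tree, config)
        pooled = np.concatenate([t.post_burn_in(config.burn_in).lnL for t in traces])
        mlnl = harmonic_mean_lnL(pooled)
        rows.append(
            {
                "model": label,
                "marginal_lnL": mlnl,
                "asdsf": diags.asdsf,
                "converged": not (diags.asdsf == diags.asdsf and diags.asdsf > asdsf_threshold),
            }
        )
        all_traces[label] = traces
    df = pd.DataFrame(rows)
    best = df["marginal_lnL"].max()
    df["LBF_vs_best"] = df["marginal_lnL"] - best
    df = df.sort_values("marginal_lnL", ascending=False, kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df, all_traces


# ------------------------------------------------------------------- report
def report(
    model_table: Optional[pd.DataFrame] = None,
    root: Optional[RootSupport] = None,
    clade_pps: Optional[Mapping[str, float]] = None,
    diagnostics: Optional[RunDiagnostics] = None,
    seed: Optional[int] = None,
    out_prefix: Optional[str] = None,
) -> tuple[dict, str]:
    """Machine- and human-readable summary of completed analyses.

    Writes ``<out_prefix>.json`` and ``<out_prefix>.txt`` when a prefix is
    given; errors if nothing was analysed.
    """
    if model_table is None and root is None and clade_pps is None:
        raise ValueError("nothing to report: no completed analyses supplied")
    import archroot

    payload: dict = {"archroot_version": archroot.__version__}
    if seed is not None:
        payload["seed"] = seed
    lines = [f"archroot report (version {archroot.__version__})"]
    if model_table is not None:
        payload["models"] = model_table.to_dict(orient="records")
        lines.append("\nModel ranking (harmonic-mean marginal lnL; LBF vs best):")
        for _, r in model_table.iterrows():
            flag = "" if r.get("converged", True) else "  [NOT CONVERGED]"
            lines.append(
                f"  {int(r['rank']):2d}. {r['model']:<28s} lnL={r['marginal_lnL']:.3f}"
                f"  LBF={r['LBF_vs_best']:.3f}{flag}"
            )
    if root is not None:
        payload["root_hypotheses"] = root.hypothesis_probs
        payload["n_root_samples"] = root.n_samples
        lines.append("\nRoot-hypothesis posterior support:")
        for name, p in sorted(root.hypothesis_probs.items(), key=lambda kv: -kv[1]):
            lines.append(f"  {name:<12s} {p:.4f}")
    if clade_pps is not None:
        payload["clade_pp"] = dict(clade_pps)
        lines.append("\nClade posterior probabilities:")
        for name, p in clade_pps.items():
            lines.append(f"  {name:<12s} {p:.4f}")
    if diagnostics is not None:
        payload["diagnostics"] = {
            "asdsf": diagnostics.asdsf,
            "psrf": diagnostics.psrf,
            "acceptance": diagnostics.acceptance,
            "swap_acceptance": diagnostics.swap_acceptance,
        }
        lines.append(f"\nDiagnostics: ASDSF={diagnostics.asdsf:.4f}; PSRF=" +
                     ", ".join(f"{k}:{v:.3f}" for k, v in diagnostics.psrf.items()))
    text = "\n".join(lines) + "\n"
    if out_prefix is not None:
        with open(f"{out_prefix}.json", "w") as fh:
            json.dump(payload, fh, indent=2, default=_json_default)
        with open(f"{out_prefix}.txt", "w") as fh:
            fh.write(text)
    return payload, text


def _json_default(obj):
    if isinstance(obj, (frozenset, set)):
        return sorted(obj)
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
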