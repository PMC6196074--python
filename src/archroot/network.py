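"""Neighbor-net split networks.

The neighbor-net method generalises neighbor joining: instead of forcing a
tree it produces a *circular* ordering of the taxa by agglomerating pairs of
taxon clusters, then estimates non-negative weights for all splits
compatible with that ordering by constrained least squares.  Incompatible
signal in the distances shows up as boxes (reticulations) when the split
system is drawn; on a clean tree metric the output collapses to exactly the
tree's splits.

Stages:

1. agglomeration — clusters of one or two active nodes are merged under a
   neighbor-joining-style criterion; three-node paths are immediately
   reduced to two fresh nodes with the standard 2/3–1/3 distance blend, and
   every reduction is recorded;
2. expansion — reductions are undone in reverse on the final 3-cycle,
   yielding the circular ordering;
3. weighting — non-negative least squares over the n(n−1)/2 splits
   compatible with the ordering; weights below a threshold are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import nnls

from .distances import DistanceMatrix

__all__ = ["SplitSystem", "neighbor_net", "circular_splits", "write_splits_nexus", "read_splits_nexus"]


@dataclass
class SplitSystem:
    """Weighted bipartitions of a taxon set with a circular support ordering.

    Each split is stored as the side *not* containing the first taxon of
    ``taxa`` (a frozenset of labels), paired with a non-negative weight.
    """

    taxa: list[str]
    ordering: list[str]
    splits: list[tuple[frozenset, float]] = field(default_factory=list)

    def __post_init__(self):
        if sorted(self.taxa) != sorted(self.ordering):
            raise ValueError("ordering must be a permutation of the taxa")
        anchor = self.taxa[0]
        for side, w in self.splits:
            if w < 0:
                raise ValueError("split weights must be non-negative")
            if not side or len(side) >= len(self.taxa) or anchor in side:
                raise ValueError(f"split {set(side)} is not a proper anchored bipartition")

    def weight_of(self, side) -> float:
        side = frozenset(side)
        if self.taxa[0] in side:
            side = frozenset(self.taxa) - side
        for s, w in self.splits:
            if s == side:
                return w
        return 0.0

    def as_dict(self) -> dict[frozenset, float]:
        return {s: w for s, w in self.splits}

    def represented_distance(self, a: str, b: str) -> float:
        """Sum of weights of splits separating taxa ``a`` and ``b``."""
        return sum(w for s, w in self.splits if (a in s) != (b in s))

    def __len__(self) -> int:
        return len(self.splits)


# -------------------------------------------------------------- agglomeration
def _neighbor_net_ordering(d0: np.ndarray) -> list[int]:
    """Circular ordering of taxon indices by neighbor-net agglomeration."""
    n = d0.shape[0]
    cap = 3 * n + 4
    d = np.zeros((cap, cap))
    d[:n, :n] = d0
    next_id = n
    clusters: list[list[int]] = [[i] for i in range(n)]
    reductions: list[tuple[int, int, int, int, int]] = []  # (a, b, u, v, w)

    def cluster_dist(c1: Sequence[int], c2: Sequence[int]) -> float:
        return float(np.mean([d[x, y] for x in c1 for y in c2]))

    while len(clusters) > 1 and sum(len(c) for c in clusters) > 3:
        m = len(clusters)
        D = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                D[i, j] = D[j, i] = cluster_dist(clusters[i], clusters[j])
        R = D.sum(axis=1)
        best, best_q = None, np.inf
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - R[i] - R[j]
                if q < best_q - 1e-14:
                    best, best_q = (i, j), q
        i, j = best
        c1, c2 = clusters[i], clusters[j]

        if len(c1) == 1 and len(c2) == 1:
            newpath = [c1[0], c2[0]]
        else:
            # choose the node pair treating members of c1, c2 as singletons
            others = [clusters[k] for k in range(m) if k not in (i, j)]
            mem = c1 + c2
            mhat = len(others) + len(mem)
            best_xy, best_q2 = None, np.inf
            for x in c1:
                for y in c2:
                    rx = sum(cluster_dist([x], c) for c in others) + sum(d[x, z] for z in mem if z != x)
                    ry = sum(cluster_dist([y], c) for c in others) + sum(d[y, z] for z in mem if z != y)
                    q2 = (mhat - 2) * d[x, y] - rx - ry
                    if q2 < best_q2 - 1e-14:
                        best_xy, best_q2 = (x, y), q2
            x, y = best_xy
            p1 = c1 if c1[-1] == x else c1[::-1]
            p2 = c2 if c2[0] == y else c2[::-1]
            newpath = p1 + p2
            active = [z for c in clusters for z in c]
            while len(newpath) > 2:
                u, v, w = newpath[0], newpath[1], newpath[2]
                a, b = next_id, next_id + 1
                next_id += 2
                for z in active:
                    if z in (u, v, w):
                        continue
                    d[a, z] = d[z, a] = (2.0 / 3.0) * d[u, z] + (1.0 / 3.0) * d[v, z]
                    d[b, z] = d[z, b] = (2.0 / 3.0) * d[w, z] + (1.0 / 3.0) * d[v, z]
                d[a, b] = d[b, a] = (d[u, v] + d[v, w] + d[u, w]) / 3.0
                reductions.append((a, b, u, v, w))
                active = [z for z in active if z not in (u, v, w)] + [a, b]
                newpath = [a, b] + newpath[3:]

        clusters = [clusters[k] for k in range(m) if k not in (i, j)]
        clusters.append(newpath)

    cycle = [z for c in clusters for z in c]
    for a, b, u, v, w in reversed(reductions):
        cycle = _expand_pair(cycle, a, b, [u, v, w])
    assert sorted(cycle) == list(range(n))
    # canonical rotation/reflection: start at 0, second element the smaller neighbor
    k = cycle.index(0)
    cycle = cycle[k:] + cycle[:k]
    if len(cycle) > 2 and cycle[-1] < cycle[1]:
        cycle = [cycle[0]] + cycle[1:][::-1]
    return cycle


def _expand_pair(cycle: list[int], a: int, b: int, repl: list[int]) -> list[int]:
    """Replace adjacent pair (a, b) in a circular list by ``repl`` (oriented a→b)."""
    ln = len(cycle)
    ia = cycle.index(a)
    if cycle[(ia + 1) % ln] == b:
        start = (ia + 2) % ln
        return repl + [cycle[(start + k) % ln] for k in range(ln - 2)]
    ib = cycle.index(b)
    if cycle[(ib + 1) % ln] == a:
        start = (ib + 2) % ln
        return repl[::-1] + [cycle[(start + k) % ln] for k in range(ln - 2)]
    raise RuntimeError("reduction pair not adjacent during expansion")


# ------------------------------------------------------------------ weighting
def circular_splits(ordering: Sequence[int], n: int) -> list[frozenset]:
    """All n(n−1)/2 splits compatible with a circular ordering.

    Each split is the set of positions i..j (1 ≤ i ≤ j < n) in the ordering;
    the element at position 0 is always on the other side.
    """
    out = []
    for i in range(1, n):
        for j in range(i, n):
            out.append(frozenset(ordering[i : j + 1]))
    return out


def _nnls_weights(dist: np.ndarray, splits: list[frozenset], n: int) -> np.ndarray:
    pairs = [(p, q) for p in range(n) for q in range(p + 1, n)]
    A = np.zeros((len(pairs), len(splits)))
    for col, s in enumerate(splits):
        for row, (p, q) in enumerate(pairs):
            if (p in s) != (q in s):
                A[row, col] = 1.0
    y = np.array([dist[p, q] for p, q in pairs])
    w, _ = nnls(A, y)
    return w


def neighbor_net(dist: DistanceMatrix, min_weight: float = 1e-6) -> SplitSystem:
    """Build a circular split system from a distance matrix.

    Requires ≥3 taxa; with exactly 3 the (unique) circular ordering and the
    exact star-system weights are returned directly.
    """
    n = len(dist)
    taxa = dist.taxa
    if n < 3:
        raise ValueError("neighbor-net requires at least 3 taxa")
    d = dist.values
    if n == 3:
        ordering = list(range(3))
        splits = []
        for i in range(3):
            j, k = [x for x in range(3) if x != i]
            w = max(0.0, 0.5 * (d[i, j] + d[i, k] - d[j, k]))
            side = frozenset([taxa[i]]) if i != 0 else frozenset([taxa[1], taxa[2]])
            splits.append((side, w))
        splits = [(s, w) for s, w in splits if w >= min_weight]
        return SplitSystem(taxa=list(taxa), ordering=[taxa[i] for i in ordering], splits=splits)

    ordering = _neighbor_net_ordering(d)
    cand = circular_splits(ordering, n)
    w = _nnls_weights(d, cand, n)
    anchor_idx = 0
    allidx = frozenset(range(n))
    splits: list[tuple[frozenset, float]] = []
    for s, wt in zip(cand, w):
        if wt < min_weight:
            continue
        side = allidx - s if anchor_idx in s else s
        splits.append((frozenset(taxa[i] for i in side), float(wt)))
    splits.sort(key=lambda sw: (len(sw[0]), sorted(sw[0])))
    return SplitSystem(taxa=list(taxa), ordering=[taxa[i] for i in ordering], splits=splits)


# -------------------------------------------------------------------- NEXUS IO
def write_splits_nexus(splits: SplitSystem, path) -> None:
    """Write a SplitsTree-compatible NEXUS file (TAXA + SPLITS blocks)."""
    taxa = splits.taxa
    index = {t: i + 1 for i, t in enumerate(taxa)}  # 1-based
    cycle = [index[t] for t in splits.ordering]
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN Taxa;\n")
        fh.write(f"DIMENSIONS ntax={len(taxa)};\nTAXLABELS\n")
        for i, t in enumerate(taxa, 1):
            fh.write(f"[{i}] '{t}'\n")
        fh.write(";\nEND; [Taxa]\n\nBEGIN Splits;\n")
        fh.write(f"DIMENSIONS ntax={len(taxa)} nsplits={len(splits.splits)};\n")
        fh.write("FORMAT labels=no weights=yes confidences=no intervals=no;\n")
        fh.write("CYCLE " + " ".join(str(c) for c in cycle) + ";\n")
        fh.write("MATRIX\n")
        for k, (side, w) in enumerate(splits.splits, 1):
            ids = sorted(index[t] for t in side)
            fh.write(f"[{k}, size={len(ids)}]\t {w:.10g} \t" + " ".join(str(i) for i in ids) + ",\n")
        fh.write(";\nEND; [Splits]\n")


def read_splits_nexus(path) -> SplitSystem:
    """Re-read a file produced by :func:`write_splits_nexus`."""
    import re

    text = Path(path).read_text()
    labels = re.findall(r"\[(\d+)\]\s+'([^']*)'", text)
    taxa = [t for _, t in sorted(labels, key=lambda x: int(x[0]))]
    cyc = re.search(r"CYCLE\s+([\d\s]+);", text)
    if cyc is None:
        raise ValueError("no CYCLE statement in splits NEXUS")
    ordering = [taxa[int(i) - 1] for i in cyc.group(1).split()]
    mat = re.search(r"MATRIX\s+(.*?);", text, re.DOTALL)
    splits: list[tuple[frozenset, float]] = []
    body = mat.group(1) if mat is not None else ""
    for line in body.splitlines():
        line = re.sub(r"\[.*?\]", "", line).strip().rstrip(",")
        if not line:
            continue
        parts = line.split()
        w = float(parts[0])
        side = frozenset(taxa[int(i) - 1] for i in parts[1:])
        if taxa[0] in side:
            side = frozenset(taxa) - side
        splits.append((side, w))
    return SplitSystem(taxa=taxa, ordering=ordering, splits=splits)
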