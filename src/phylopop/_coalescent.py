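"""Internal single-population coalescent machinery.

Time is measured in mutational units: a pair separated for time t carries
Poisson(t) differences, so each lineage mutates at rate 1/2 per unit and a
population with mutation-scaled size theta imposes a pairwise coalescence
hazard of 1/theta (equilibrium mean pairwise differences = theta). A
stepwise size change from theta1 (present) to theta0 (ancestral) at time tau
models instantaneous expansion.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class SimTree:
    """Binary genealogy over n leaves; node i's parent is ``parent[i]``."""

    n_leaves: int
    parent: np.ndarray  # (2n-1,), root has parent -1
    branch_length: np.ndarray  # (2n-1,), root entry 0
    children: list[list[int]]

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_leaves - 1

    def leaf_sets(self) -> list[np.ndarray]:
        """Boolean leaf membership mask below each node."""
        masks = [np.zeros(self.n_leaves, dtype=bool) for _ in range(self.n_nodes)]
        for i in range(self.n_leaves):
            masks[i][i] = True
        # children indices are always smaller than parents (coalescent order)
        for node in range(self.n_leaves, self.n_nodes):
            for ch in self.children[node]:
                masks[node] |= masks[ch]
        return masks


def sim_genealogy(
    n: int,
    rng: np.random.Generator,
    theta1: float,
    theta0: float | None = None,
    tau: float | None = None,
) -> SimTree:
    """Coalescent genealogy under constant size or a stepwise size change.

    ``theta1`` applies from the present back to ``tau``; ``theta0`` before.
    With ``tau`` None the size is constant at ``theta1``.
    """
    if n < 2:
        raise ValueError("need n >= 2 lineages")
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=int)
    node_time = np.zeros(n_nodes)
    children: list[list[int]] = [[] for _ in range(n_nodes)]
    active = list(range(n))
    t = 0.0
    next_node = n
    while len(active) > 1:
        k = len(active)
        theta = theta1 if (tau is None or t < tau) else (theta0 or theta1)
        rate = k * (k - 1) / 2.0 / theta
        wait = rng.exponential(1.0 / rate)
        if tau is not None and t < tau < t + wait and theta0 != theta1:
            t = tau  # rate changes at the boundary; redraw from there
            continue
        t += wait
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        node = next_node
        next_node += 1
        parent[a] = parent[b] = node
        children[node] = [a, b]
        node_time[node] = t
        active = [x for x in active if x not in (a, b)] + [node]
    blen = np.zeros(n_nodes)
    for i in range(n_nodes):
        if parent[i] >= 0:
            blen[i] = node_time[parent[i]] - node_time[i]
    return SimTree(n, parent, blen, children)


def drop_mutations(tree: SimTree, rng: np.random.Generator) -> np.ndarray:
    """Poisson(branch_length / 2) mutation counts per branch."""
    return rng.poisson(tree.branch_length / 2.0)


@dataclass
class GenealogySummary:
    """Infinite-sites summaries of one simulated genealogy."""

    s: int  # segregating sites (total mutations)
    mean_pairwise: float
    n_alleles: int
    diff_matrix: np.ndarray | None  # pairwise difference counts (optional)


def summarize(
    tree: SimTree,
    mutations: np.ndarray,
    need_matrix: bool = False,
) -> GenealogySummary:
    """S, mean pairwise differences, allele count (and optionally the full
    pairwise difference matrix) under the infinite-sites model."""
    n = tree.n_leaves
    masks = tree.leaf_sets()
    total_pairs = n * (n - 1) / 2.0
    pi_sum = 0.0
    diffs = np.zeros((n, n)) if need_matrix else None
    for node in range(tree.n_nodes):
        m = int(mutations[node])
        if m == 0 or tree.parent[node] < 0:
            continue
        inside = masks[node]
        size = int(inside.sum())
        pi_sum += m * size * (n - size)
        if diffs is not None:
            out = ~inside
            diffs[np.ix_(inside, out)] += m
    if diffs is not None:
        diffs = diffs + diffs.T
    # allele identity: the multiset of mutated branches above each leaf
    mutated = {
        node for node in range(tree.n_nodes) if mutations[node] > 0
    }
    signatures = set()
    for leaf in range(n):
        sig = []
        node = leaf
        while node >= 0:
            if node in mutated:
                sig.append(node)
            node = tree.parent[node]
        signatures.add(tuple(sig))
    return GenealogySummary(
        s=int(mutations.sum()),  # root branch has length 0, never mutates
        mean_pairwise=pi_sum / total_pairs,
        n_alleles=len(signatures),
        diff_matrix=diffs,
    )


def mismatch_histogram_sim(
    n: int,
    tau: float,
    theta0: float,
    theta1: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulated pairwise-difference histogram for one genealogy."""
    tree = sim_genealogy(n, rng, theta1=theta1, theta0=theta0, tau=tau)
    muts = drop_mutations(tree, rng)
    summ = summarize(tree, muts, need_matrix=True)
    d = summ.diff_matrix
    iu = np.triu_indices(n, k=1)
    vals = d[iu].astype(int)
    hist = np.bincount(vals)
    return hist


def tmrca(tree: SimTree) -> float:
    """Height of the root (all leaves are contemporaneous at time 0)."""
    h = 0.0
    cur = 0
    while tree.parent[cur] >= 0:
        h += tree.branch_length[cur]
        cur = tree.parent[cur]
    return h
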