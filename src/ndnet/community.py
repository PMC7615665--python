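"""Consensus spin-glass community detection on the weighted symptom network."""

from __future__ import annotations

import json
import random
from collections import Counter
from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd

from ._rand import substream_seeds

__all__ = ["CommunityResult", "spinglass_consensus", "network_from_edges"]


@dataclass
class CommunityResult:
    """Modal partition across repeated spin-glass runs plus co-membership rates."""

    modal_partition: dict[str, int]
    modal_frequency: float
    n_iterations: int
    co_membership: pd.DataFrame
    partition_counts: Counter

    def communities(self) -> list[list[str]]:
        groups: dict[int, list[str]] = {}
        for node, c in self.modal_partition.items():
            groups.setdefault(c, []).append(node)
        return [groups[c] for c in sorted(groups)]

    def to_json(self, path) -> None:
        payload = {
            "modal_partition": self.modal_partition,
            "modal_frequency": self.modal_frequency,
            "n_iterations": self.n_iterations,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    def co_membership_csv(self, path) -> None:
        self.co_membership.to_csv(path)


def network_from_edges(
    labels: tuple[str, ...], weighted_edges: list[tuple[str, str, float]]
) -> ig.Graph:
    """Weighted undirected graph over the full node set (isolates allowed)."""
    g = ig.Graph()
    g.add_vertices(list(labels))
    if weighted_edges:
        g.add_edges([(a, b) for a, b, _ in weighted_edges])
        g.es["weight"] = [w for _, _, w in weighted_edges]
    return g


def _canonical(labels: tuple[str, ...], membership: dict[str, int]) -> tuple[int, ...]:
    """Relabel communities by order of first appearance along the node order."""
    remap: dict[int, int] = {}
    out = []
    for name in labels:
        c = membership[name]
        if c not in remap:
            remap[c] = len(remap)
        out.append(remap[c])
    return tuple(out)


def _one_run(g: ig.Graph, gamma: float, spins: int) -> dict[str, int]:
    """Spin-glass per connected component; singleton components stay singletons."""
    membership: dict[str, int] = {}
    offset = 0
    comps = g.connected_components()
    for comp in comps:
        names = [g.vs[i]["name"] for i in comp]
        if len(comp) == 1:
            membership[names[0]] = offset
            offset += 1
            continue
        sub = g.subgraph(comp)
        weights = sub.es["weight"] if "weight" in sub.es.attributes() else None
        # the signed-network Hamiltonian variant handles negative weights and
        # reduces to the standard one on positive graphs, with a more reliable
        # annealer -- use it unconditionally
        cl = sub.community_spinglass(
            weights=weights,
            spins=min(spins, len(comp)),
            gamma=gamma,
            implementation="negative",
        )
        for name, c in zip(sub.vs["name"], cl.membership):
            membership[name] = offset + c
        offset += max(cl.membership) + 1
    return membership


def spinglass_consensus(
    labels: tuple[str, ...],
    weighted_edges: list[tuple[str, str, float]],
    n_iter: int = 5000,
    seed: int = 0,
    gamma: float = 1.0,
    spins: int = 13,
) -> CommunityResult:
    """Repeat the spin-glass algorithm and report the modal partition.

    Each iteration reseeds the RNG from a per-run substream; partitions are
    canonicalized (community ids ordered by first member) before counting,
    so the modal frequency is invariant to label permutations.  Negative
    edge weights switch the Hamiltonian to its signed-network variant.
    """
    p = len(labels)
    if not weighted_edges:
        part = {name: i for i, name in enumerate(labels)}
        co = pd.DataFrame(np.eye(p), index=list(labels), columns=list(labels))
        return CommunityResult(part, 1.0, n_iter, co, Counter({tuple(range(p)): n_iter}))

    g = network_from_edges(labels, weighted_edges)
    counts: Counter = Counter()
    co = np.zeros((p, p))
    keep: dict[tuple[int, ...], dict[str, int]] = {}
    for s in substream_seeds(seed, n_iter):
        random.seed(s)  # python-igraph draws from Python's random module
        membership = _one_run(g, gamma, spins)
        key = _canonical(labels, membership)
        counts[key] += 1
        if key not in keep:
            keep[key] = membership
        arr = np.asarray(key)
        co += arr[:, None] == arr[None, :]

    modal_key, modal_n = counts.most_common(1)[0]
    co /= n_iter
    return CommunityResult(
        modal_partition={name: c for name, c in zip(labels, modal_key)},
        modal_frequency=modal_n / n_iter,
        n_iterations=n_iter,
        co_membership=pd.DataFrame(co, index=list(labels), columns=list(labels)),
        partition_counts=counts,
    )
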