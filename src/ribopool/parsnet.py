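"""Statistical-parsimony ribotype networks.

Haplotypes (ribotype state maps over the diagnostic columns) are connected
by single mutational steps, in increasing distance order, up to a
*connection limit*: the largest number of steps that can still be accepted
as non-homoplasious at a chosen confidence level (95% by default).  Multi-
step joins insert unsampled intermediate nodes; haplotype pairs beyond the
limit stay in separate components.  Node weights carry each accession's
percent contribution, so the network doubles as an abundance-annotated
summary of which pools share which ribotypes.

Connection-limit estimator
--------------------------
Let ``m`` be the number of aligned sites and ``J`` the number of observed
site differences between two haplotypes.  The unknown true number of
mutations ``K >= J`` is modelled by throwing ``K`` mutations uniformly onto
the ``m`` sites, each substituting the site to one of the three alternative
bases uniformly (Jukes-Cantor symmetry).  A site hit ``h`` times differs
from its original state with probability

    d_h = (3/4) * (1 - (-1/3)**h)          (d_0 = 0)

so, collecting sites with an exponential generating function
``g(x, y) = sum_h (y**h / h!) * ((1 - d_h) + d_h * x)``,

    P(J = j | K = k) = (k! / m**k) * [y**k x**j] g(x, y)**m.

With a flat prior over the true mutation count the probability that ``j``
observed differences arose from exactly ``j`` mutations (the probability of
parsimony) is the posterior

    P_par(j; m) = P(J=j | K=j) / sum_{k >= j} P(J=j | K=k),

and the connection limit at confidence ``c`` is the largest ``j`` with
``P_par(i; m) >= c`` for all ``i <= j``.  This follows the statistical-
parsimony logic of the classical estimator; tie behaviour of the historical
desktop tool is not reproduced bit-for-bit (it is undocumented), so the
limit is validated by its monotonicity properties and a small-case oracle.
"""

from __future__ import annotations

import functools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .catalog import DiagnosticMatrix, RibotypeTable, column_distance


class NetworkConfigError(ValueError):
    pass


@dataclass(frozen=True)
class NetworkConfig:
    min_reads: int = 10          # admission threshold, inclusive
    confidence: float = 0.95
    node_scale: str = "percent"

    def __post_init__(self) -> None:
        if self.min_reads < 1:
            raise NetworkConfigError("min_reads must be >= 1")
        if not 0.0 < self.confidence < 1.0:
            raise NetworkConfigError("confidence must be in (0, 1)")


@dataclass(frozen=True)
class Haplotype:
    """A network input: a named state map with pooled read support."""

    name: str
    states: Mapping[int, str]
    total_reads: int = 0
    weights: Mapping[str, int] = field(default_factory=dict)

    @property
    def total_weight(self) -> int:
        return sum(self.weights.values())


# ---------------------------------------------------------------------------
# Connection limit
# ---------------------------------------------------------------------------

def _poly_mul(a: np.ndarray, b: np.ndarray, kmax: int) -> np.ndarray:
    """Multiply 2D polynomials (axis 0: y-degree, axis 1: x-degree),
    truncating total y-degree and x-degree at ``kmax``."""
    out = np.zeros((kmax + 1, kmax + 1))
    for ya in range(min(a.shape[0], kmax + 1)):
        row = a[ya]
        if not row.any():
            continue
        for yb in range(min(b.shape[0], kmax + 1 - ya)):
            if not b[yb].any():
                continue
            conv = np.convolve(row, b[yb])[: kmax + 1]
            out[ya + yb, : conv.size] += conv
    return out


@functools.lru_cache(maxsize=64)
def _conditional_difference_probs(m: int, kmax: int) -> np.ndarray:
    """P[k, j] = P(J = j | K = k) for k, j <= kmax over m sites."""
    h = np.arange(kmax + 1)
    d = 0.75 * (1.0 - (-1.0 / 3.0) ** h)
    d[0] = 0.0
    inv_fact = np.array([1.0 / math.factorial(int(i)) for i in h])
    g = np.zeros((kmax + 1, kmax + 1))
    g[:, 0] = (1.0 - d) * inv_fact
    g[:, 1] = d * inv_fact
    # g**m by binary exponentiation
    result = np.zeros_like(g)
    result[0, 0] = 1.0
    base = g
    e = m
    while e:
        if e & 1:
            result = _poly_mul(result, base, kmax)
        e >>= 1
        if e:
            base = _poly_mul(base, base, kmax)
    k = np.arange(kmax + 1, dtype=float)
    log_scale = np.array(
        [math.lgamma(int(i) + 1) - i * math.log(m) for i in k]
    )
    return result * np.exp(log_scale)[:, None]


def probability_of_parsimony(j: int, sequence_length: int, _tail: int = 40) -> float:
    """Posterior probability that ``j`` observed differences over
    ``sequence_length`` sites reflect exactly ``j`` mutations (see module
    docstring for the estimator)."""
    if j == 0:
        return 1.0
    m = int(sequence_length)
    if m < 2:
        raise ValueError("sequence_length must be >= 2")
    kmax = j + _tail
    P = _conditional_difference_probs(m, kmax)
    numer = P[j, j]
    denom = float(P[j:, j].sum())
    if denom == 0.0:
        return 0.0
    return float(numer / denom)


def parsimony_connection_limit(sequence_length: int, confidence: float = 0.95) -> int:
    """Largest step count accepted as parsimonious at the given confidence.

    Scans j = 1, 2, ... and stops at the first j whose probability of
    parsimony drops below the confidence; the limit is j - 1 (at least 0,
    though for any realistic amplicon length the single-step probability
    exceeds conventional confidences, so the limit is >= 1).
    """
    if not 0.0 < confidence < 1.0:
        raise NetworkConfigError("confidence must be in (0, 1)")
    if sequence_length < 2:
        raise ValueError("sequence_length must be >= 2")
    j = 1
    while j <= sequence_length:
        if probability_of_parsimony(j, sequence_length) < confidence:
            return j - 1
        j += 1
    return sequence_length


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------

def _interpolate(
    a_states: Mapping[int, str], b_states: Mapping[int, str]
) -> list[dict[int, str]]:
    """Intermediate state maps on the unit-step path from a to b, flipping
    differing columns one at a time in ascending column order."""
    diff = sorted(p for p in a_states if a_states[p] != b_states[p])
    out = []
    current = dict(a_states)
    for p in diff[:-1]:
        current[p] = b_states[p]
        out.append(dict(current))
    return out


def _states_key(states: Mapping[int, str]) -> tuple:
    return tuple(sorted(states.items()))


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {i: i for i in items}

    def add(self, item: str) -> None:
        self.parent.setdefault(item, item)

    def find(self, item: str) -> str:
        root = item
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[item] != root:
            self.parent[item], item = root, self.parent[item]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def build_network(
    haplotypes: Sequence[Haplotype],
    config: NetworkConfig = NetworkConfig(),
    sequence_length: int = 330,
) -> nx.Graph:
    """Build a statistical-parsimony network over the admitted haplotypes.

    Haplotypes with pooled read support >= ``config.min_reads`` are admitted.
    All sampled pairs at distance 1 are joined directly; then, for each
    distance d = 2..limit, cross-component pairs are joined through d - 1
    unsampled intermediates, best-supported pairs first (highest node weight,
    then degree, then lexicographic name — the fixed tie rule).  Pairs beyond
    the connection limit remain in separate components.

    Node attributes: ``states`` (column -> state), ``sampled``, ``weights``
    (accession -> percent), ``weight`` (summed percent), ``component``.
    """
    admitted = [h for h in haplotypes if h.total_reads >= config.min_reads]
    limit = parsimony_connection_limit(sequence_length, config.confidence)
    G = nx.Graph(connection_limit=limit, confidence=config.confidence)
    if not admitted:
        return G
    position_set = set(admitted[0].states)
    for h in admitted:
        if set(h.states) != position_set:
            raise NetworkConfigError(
                f"haplotype {h.name!r} covers a different position set"
            )
        G.add_node(
            h.name,
            states=dict(h.states),
            sampled=True,
            weights=dict(h.weights),
            weight=float(h.total_weight),
        )
    by_states = {_states_key(G.nodes[n]["states"]): n for n in G.nodes}
    uf = _UnionFind(G.nodes)
    names = sorted(n for n in G.nodes)
    dist = {
        (a, b): column_distance(G.nodes[a]["states"], G.nodes[b]["states"])
        for i, a in enumerate(names)
        for b in names[i + 1 :]
    }
    # distance-1 edges between sampled haplotypes are always real
    for (a, b), d in sorted(dist.items()):
        if d == 1:
            G.add_edge(a, b)
            uf.union(a, b)

    def rank(node: str) -> tuple:
        return (-G.nodes[node]["weight"], -G.degree(node), node)

    iv_counter = 0
    for d in range(2, limit + 1):
        while True:
            candidates = [
                (a, b) for (a, b), dd in dist.items()
                if dd == d and uf.find(a) != uf.find(b)
            ]
            if not candidates:
                break
            a, b = min(candidates, key=lambda ab: tuple(sorted((rank(ab[0]), rank(ab[1])))))
            a, b = sorted((a, b))
            path = [a]
            for states in _interpolate(G.nodes[a]["states"], G.nodes[b]["states"]):
                key = _states_key(states)
                node = by_states.get(key)
                if node is None:
                    iv_counter += 1
                    node = f"iv{iv_counter}"
                    G.add_node(
                        node, states=states, sampled=False, weights={}, weight=0.0
                    )
                    by_states[key] = node
                    uf.add(node)
                path.append(node)
            path.append(b)
            for u, v in zip(path, path[1:]):
                G.add_edge(u, v)
                uf.union(u, v)
    roots: dict[str, int] = {}
    for n in sorted(G.nodes):
        root = uf.find(n)
        comp = roots.setdefault(root, len(roots))
        G.nodes[n]["component"] = comp
    return G


def haplotypes_from_tables(
    tables: Sequence[RibotypeTable],
    matrix: DiagnosticMatrix,
    extra_states: Mapping[str, Mapping[int, str]] | None = None,
) -> list[Haplotype]:
    """Pool per-accession tables into network inputs.

    Catalog names take their states from the matrix; names in
    ``extra_states`` (e.g. novel variants retained by a pipeline run) take
    theirs from there; other names are skipped.  Read support is summed over
    accessions; weights carry each accession's percent for entries above the
    major threshold (the historical visualization rule: only ribotypes with
    more than 1000 reads contribute their percent to node size).
    """
    extra = dict(extra_states or {})
    support: dict[str, int] = {}
    weights: dict[str, dict[str, int]] = {}
    for table in tables:
        for e in table.entries:
            if e.name not in matrix.rows and e.name not in extra:
                continue
            support[e.name] = support.get(e.name, 0) + e.read_count
            if e.is_major:
                weights.setdefault(e.name, {})[table.accession_id] = e.percent
    out = []
    for name in sorted(support):
        states = (
            dict(matrix.rows[name].states)
            if name in matrix.rows
            else dict(extra[name])
        )
        out.append(
            Haplotype(
                name=name,
                states=states,
                total_reads=support[name],
                weights=weights.get(name, {}),
            )
        )
    return out


def annotate_node_weights(
    network: nx.Graph, tables: Sequence[RibotypeTable]
) -> nx.Graph:
    """Attach per-accession percent weights to sampled nodes in place.

    Each sampled node resolvable in a table carries
    ``accession -> percent`` for entries above the major threshold; its
    ``weight`` is the summed percent.  Intermediates keep weight 0.
    """
    for node, data in network.nodes(data=True):
        if not data.get("sampled"):
            data["weights"], data["weight"] = {}, 0.0
            continue
        w: dict[str, int] = {}
        for table in tables:
            for e in table.entries:
                if e.name == node and e.is_major:
                    w[table.accession_id] = e.percent
        data["weights"] = w
        data["weight"] = float(sum(w.values()))
    return network


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def write_graphml(network: nx.Graph, path: str | Path) -> None:
    """GraphML export; dict-valued attributes are serialized as JSON."""
    H = nx.Graph(**{k: v for k, v in network.graph.items()})
    for n, data in network.nodes(data=True):
        H.add_node(
            n,
            sampled=bool(data.get("sampled", False)),
            weight=float(data.get("weight", 0.0)),
            weights=json.dumps(data.get("weights", {}), sort_keys=True),
            states=json.dumps(
                {str(k): v for k, v in sorted(data.get("states", {}).items())}
            ),
            component=int(data.get("component", -1)),
        )
    H.add_edges_from(network.edges())
    nx.write_graphml(H, str(path))


def write_edge_tsv(network: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\n")
        for u, v in sorted(map(lambda e: tuple(sorted(e)), network.edges())):
            fh.write(f"{u}\t{v}\n")


def plot_network(network: nx.Graph, path: str | Path, seed: int = 0) -> None:
    """Static figure with node radius proportional to total percent weight.

    Requires matplotlib (the ``plot`` extra); the network itself is pure
    data and does not depend on rendering.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pos = nx.spring_layout(network, seed=seed)
    sizes = [40 + 12 * network.nodes[n].get("weight", 0.0) for n in network]
    colors = [
        "#4878a8" if network.nodes[n].get("sampled") else "#c8c8c8"
        for n in network
    ]
    labels = {n: n for n in network if network.nodes[n].get("sampled")}
    fig, ax = plt.subplots(figsize=(8, 8))
    nx.draw_networkx_edges(network, pos, ax=ax, edge_color="#999999")
    nx.draw_networkx_nodes(network, pos, ax=ax, node_size=sizes, node_color=colors)
    nx.draw_networkx_labels(network, pos, labels=labels, ax=ax, font_size=8)
    ax.set_axis_off()
    fig.savefig(str(path), bbox_inches="tight")
    plt.close(fig)
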