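"""Statistical-parsimony haplotype networks.

Unique haplotypes become nodes (annotated with their frequency and the set
of groups carrying them); edges carry mutational step counts.  The network
is a tie-keeping minimum spanning network: Kruskal's algorithm run over the
Hamming distance graph where *every* edge of an accepted weight class that
joined two components distinct at the start of that class is kept, so
equally parsimonious alternative connections survive as loops.  Edges longer
than the statistical-parsimony connection limit are never added, which may
leave the network disconnected — exactly the behaviour of parsimony
networks on deeply diverged haplogroups.

The connection limit is the largest step count whose probability of being
free of superimposed (multiple-hit) substitutions still reaches the
confidence level.  Under a uniform finite-sites model — substitutions land
independently and uniformly on the L sites, and a uniform prior is placed on
the true substitution count — the posterior probability that j observed
differences arose from exactly j substitutions has the closed product form

    P_j = prod_{i=1..j} (1 - i / L),       P_0 = 1,

i.e. the cumulative recursion ``P_j = P_{j-1} * (1 - j/L)``.  (Derivation:
with a uniform prior over the true number of substitutions k, the occupancy
likelihood P(j distinct sites | k) = C(L,j) S(k,j) j! / L^k sums over k >= j
to the closed form via the Stirling-number generating function.)  For
L = 575 and 95% confidence the limit is 7 steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import ParameterError
from .sequences import Alignment
from .sumstats import _hap_collapse, _hap_distance_matrix

__all__ = [
    "Haplotypes",
    "HaploNetwork",
    "collapse_haplotypes",
    "parsimony_probability",
    "parsimony_limit",
    "build_network",
]


@dataclass
class Haplotypes:
    """Unique haplotypes with frequencies and group memberships."""

    codes: np.ndarray            # (H, L) uint8
    frequencies: np.ndarray      # int, sums to the input sequence count
    groups: list[set[int]]       # groups carrying each haplotype
    members: list[list[int]]     # input sequence indices per haplotype

    @property
    def n_haplotypes(self) -> int:
        return self.codes.shape[0]


def collapse_haplotypes(aln: Alignment) -> Haplotypes:
    """Merge identical sequences into haplotypes with exact bookkeeping."""
    haps, inv, counts = _hap_collapse(aln.codes)
    H = haps.shape[0]
    groups: list[set[int]] = [set() for _ in range(H)]
    members: list[list[int]] = [[] for _ in range(H)]
    for i, h in enumerate(inv):
        groups[h].add(int(aln.groups[i]))
        members[h].append(i)
    return Haplotypes(codes=haps, frequencies=counts, groups=groups,
                      members=members)


def parsimony_probability(j: int, n_sites: int) -> float:
    """P_j: posterior probability that j differences are non-superimposed."""
    if j < 0:
        raise ParameterError("j must be >= 0")
    if j >= n_sites:
        return 0.0
    i = np.arange(1, j + 1)
    return float(np.prod(1.0 - i / n_sites))


def parsimony_limit(n_sites: int, confidence: float = 0.95) -> int:
    """Largest step count j with parsimony probability >= ``confidence``.

    Always at least 1: single-step connections are never refused.
    """
    if n_sites < 1:
        raise ParameterError("n_sites must be >= 1")
    if not 0.0 < confidence < 1.0:
        raise ParameterError("confidence must lie in (0, 1)")
    j = 1
    while j + 1 < n_sites and parsimony_probability(j + 1, n_sites) >= confidence:
        j += 1
    return j


@dataclass
class HaploNetwork:
    """A haplotype graph; ``graph`` is a networkx Graph whose nodes are
    haplotype indices with ``frequency``/``groups`` attributes and whose
    edges carry ``steps``."""

    graph: nx.Graph
    connection_limit: float
    haplotypes: Haplotypes

    def to_graphml(self, path) -> None:
        g = nx.Graph()
        for n, data in self.graph.nodes(data=True):
            g.add_node(n, frequency=int(data["frequency"]),
                       groups=",".join(str(x) for x in sorted(data["groups"])))
        for a, b, data in self.graph.edges(data=True):
            g.add_edge(a, b, steps=int(data["steps"]))
        nx.write_graphml(g, path)

    def to_dot(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("graph haplonet {\n")
            for n, data in self.graph.nodes(data=True):
                grp = ",".join(str(x) for x in sorted(data["groups"]))
                fh.write(f'  h{n} [frequency={int(data["frequency"])}, '
                         f'groups="{grp}"];\n')
            for a, b, data in self.graph.edges(data=True):
                fh.write(f'  h{a} -- h{b} [steps={int(data["steps"])}];\n')
            fh.write("}\n")


class _UnionFind:
    def __init__(self, n: int):
        self.p = list(range(n))

    def find(self, x: int) -> int:
        while self.p[x] != x:
            self.p[x] = self.p[self.p[x]]
            x = self.p[x]
        return x

    def union(self, a: int, b: int) -> None:
        self.p[self.find(a)] = self.find(b)


def build_network(haps: Haplotypes, limit: float | None = None) -> HaploNetwork:
    """Tie-keeping minimum spanning network under a connection limit.

    ``limit=None`` means no limit (the network is connected whenever all
    distances are finite).
    """
    if haps.n_haplotypes < 1:
        raise ParameterError("need at least one haplotype")
    if limit is None:
        limit = np.inf
    D = _hap_distance_matrix(haps.codes)
    H = haps.n_haplotypes
    g = nx.Graph()
    for h in range(H):
        g.add_node(h, frequency=int(haps.frequencies[h]),
                   groups=set(haps.groups[h]))
    edges = sorted(
        (D[a, b], a, b) for a in range(H) for b in range(a + 1, H)
        if D[a, b] <= limit
    )
    uf = _UnionFind(H)
    i = 0
    while i < len(edges):
        w = edges[i][0]
        j = i
        while j < len(edges) and edges[j][0] == w:
            j += 1
        # component labels at the start of this weight class
        roots = {n: uf.find(n) for n in range(H)}
        for _w, a, b in edges[i:j]:
            if roots[a] != roots[b]:
                g.add_edge(a, b, steps=int(_w))
                uf.union(a, b)
        i = j
    return HaploNetwork(graph=g, connection_limit=float(limit), haplotypes=haps)
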