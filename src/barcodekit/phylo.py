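"""Distance-based trees and haplotype networks.

Two complementary summaries of a barcode distance matrix:

* classic neighbor-joining (Saitou–Nei, with the Q-criterion and the
  standard limb-length formulas), which is consistent on additive distances
  and deterministic here via a lexicographic tie-break; and
* haplotype collapsing followed by a minimum-spanning network (MSN): a
  minimum spanning forest over mutational-step distances, plus every
  tie edge at the weights where components merged, optionally truncated at a
  step limit.

NJ can produce negative branch lengths on non-additive input; they are kept
in the tree object and floored at zero only when writing Newick.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import dendropy
import numpy as np

from .alignio import Alignment
from .barcodegap import DistanceMatrix

logger = logging.getLogger(__name__)

_NEWICK_SPECIAL = set("():;,'[] \t\n")


class Tree:
    """Unrooted tree as an adjacency map; leaves are labeled, internal nodes
    carry synthetic ``#k`` keys."""

    def __init__(self):
        self.adj: dict[str, dict[str, float]] = {}
        self._internal_counter = 0

    def new_internal(self) -> str:
        self._internal_counter += 1
        return f"#{self._internal_counter}"

    def add_edge(self, a: str, b: str, length: float) -> None:
        self.adj.setdefault(a, {})[b] = float(length)
        self.adj.setdefault(b, {})[a] = float(length)

    @property
    def nodes(self) -> list[str]:
        return list(self.adj)

    @property
    def leaves(self) -> list[str]:
        return sorted(n for n, nb in self.adj.items() if not n.startswith("#"))

    @property
    def n_edges(self) -> int:
        return sum(len(nb) for nb in self.adj.values()) // 2

    def splits(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each canonicalized as the side that does
        not contain the lexicographically smallest leaf."""
        leaves = self.leaves
        if not leaves:
            return set()
        anchor = leaves[0]
        out: set[frozenset[str]] = set()
        for a in self.adj:
            for b in self.adj[a]:
                if a < b:
                    side = frozenset(self._leaves_beyond(b, a))
                    if anchor in side:
                        side = frozenset(leaves) - side
                    if 1 < len(side) < len(leaves) - 1:
                        out.add(side)
        return out

    def has_clade(self, leafset: set[str]) -> bool:
        """True when some edge separates exactly ``leafset`` from the rest."""
        target = frozenset(leafset)
        leaves = frozenset(self.leaves)
        if not target < leaves:
            return False
        if len(target) in (1, len(leaves) - 1):
            return True
        comp = leaves - target
        anchor = self.leaves[0]
        want = comp if anchor in target else target
        return want in self.splits()

    def _leaves_beyond(self, node: str, come_from: str) -> list[str]:
        stack, seen, out = [node], {come_from, node}, []
        while stack:
            cur = stack.pop()
            if not cur.startswith("#"):
                out.append(cur)
            for nb in self.adj[cur]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return out

    def leaf_path_lengths(self, floor_at_zero: bool = True) -> dict[tuple[str, str], float]:
        out: dict[tuple[str, str], float] = {}
        for src in self.leaves:
            dist = {src: 0.0}
            stack = [src]
            while stack:
                cur = stack.pop()
                for nb, ln in self.adj[cur].items():
                    if nb not in dist:
                        ln = max(0.0, ln) if floor_at_zero else ln
                        dist[nb] = dist[cur] + ln
                        stack.append(nb)
            for dst in self.leaves:
                if src < dst:
                    out[(src, dst)] = dist[dst]
        return out


def neighbor_joining(matrix: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbor-joining on a complete distance matrix.

    Iteratively joins the pair minimizing Q(i,j) = (r-2) d(i,j) - R_i - R_j,
    assigns limb lengths by the standard formulas, reduces the matrix, and
    closes with the three-taxon exact solution.  On equal Q the
    lexicographically smallest ``(i, j)`` node pair is joined, which makes
    the result deterministic.
    """
    n = len(matrix.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    for i, j in itertools.combinations(range(n), 2):
        if math.isnan(matrix.snp_percent[i, j]):
            raise ValueError(
                f"missing distance between {matrix.ids[i]!r} and {matrix.ids[j]!r}"
            )
    tree = Tree()
    d: dict[str, dict[str, float]] = {
        a: {
            b: float(matrix.snp_percent[i, j])
            for j, b in enumerate(matrix.ids)
            if j != i
        }
        for i, a in enumerate(matrix.ids)
    }
    active = sorted(d)
    while len(active) > 3:
        r = len(active)
        R = {i: sum(d[i][j] for j in active if j != i) for i in active}
        best = None
        best_pair = None
        for i, j in itertools.combinations(active, 2):
            q = (r - 2) * d[i][j] - R[i] - R[j]
            pair = (i, j) if i < j else (j, i)
            if best is None or q < best or (q == best and pair < best_pair):
                best, best_pair = q, pair
        i, j = best_pair
        dij = d[i][j]
        li = dij / 2.0 + (R[i] - R[j]) / (2.0 * (r - 2))
        lj = dij - li
        u = tree.new_internal()
        tree.add_edge(u, i, li)
        tree.add_edge(u, j, lj)
        d[u] = {}
        for m in active:
            if m in (i, j):
                continue
            dm = (d[i][m] + d[j][m] - dij) / 2.0
            d[u][m] = dm
            d[m][u] = dm
        for m in (i, j):
            del d[m]
            for k in d:
                d[k].pop(m, None)
        active = sorted(k for k in active if k not in (i, j))
        active.append(u)
        active.sort()
    x, y, z = active
    c = tree.new_internal()
    tree.add_edge(c, x, (d[x][y] + d[x][z] - d[y][z]) / 2.0)
    tree.add_edge(c, y, (d[x][y] + d[y][z] - d[x][z]) / 2.0)
    tree.add_edge(c, z, (d[x][z] + d[y][z] - d[x][y]) / 2.0)
    return tree


def _quote(label: str) -> str:
    if any(ch in _NEWICK_SPECIAL for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _min_leaf(tree: Tree, node: str, come_from: str) -> str:
    if not node.startswith("#"):
        return node
    return min(tree._leaves_beyond(node, come_from))


def _subtree_newick(tree: Tree, node: str, parent: str, length: float) -> str:
    blen = f"{max(0.0, length):.6f}"
    if not node.startswith("#"):
        return f"{_quote(node)}:{blen}"
    children = sorted(
        (nb for nb in tree.adj[node] if nb != parent),
        key=lambda nb: _min_leaf(tree, nb, node),
    )
    inner = ",".join(
        _subtree_newick(tree, ch, node, tree.adj[node][ch]) for ch in children
    )
    return f"({inner}):{blen}"


def to_newick(tree: Tree, rooting: str = "trifurcating-unrooted") -> str:
    """Serialize to Newick with branch lengths at fixed 6-decimal precision.

    Negative NJ branch lengths are floored at zero in the output (and the
    flooring is logged); child order is canonical (by smallest descendant
    leaf), so write -> parse -> write is byte-stable.
    """
    if rooting not in ("trifurcating-unrooted", "midpoint"):
        raise ValueError(f"unknown rooting {rooting!r}")
    if any(
        ln < 0 for nb in tree.adj.values() for ln in nb.values()
    ):
        logger.warning("negative branch lengths floored at 0 in Newick output")
    if rooting == "midpoint":
        tree = midpoint_root(tree)
        root = "#root"
    else:
        leaves = tree.leaves
        if not leaves:
            raise ValueError("cannot serialize an empty tree")
        first = leaves[0]
        nb = tree.adj[first]
        root = next(iter(nb))
        if not root.startswith("#"):  # two-leaf tree
            length = tree.adj[first][root]
            return f"({_quote(first)}:{max(0.0, length):.6f},{_quote(root)}:0.000000);"
    children = sorted(
        tree.adj[root], key=lambda nbr: _min_leaf(tree, nbr, root)
    )
    inner = ",".join(
        _subtree_newick(tree, ch, root, tree.adj[root][ch]) for ch in children
    )
    return f"({inner});"


def midpoint_root(tree: Tree) -> Tree:
    """Return a copy rooted (via an extra ``#root`` node) at the midpoint of
    the longest leaf-to-leaf path, using gap-floored branch lengths."""
    paths = tree.leaf_path_lengths(floor_at_zero=True)
    if not paths:
        raise ValueError("midpoint rooting needs at least two leaves")
    (a, b), total = max(paths.items(), key=lambda kv: (kv[1], kv[0]))
    # walk the a->b path
    parent = {a: None}
    stack = [a]
    while stack:
        cur = stack.pop()
        for nb in tree.adj[cur]:
            if nb not in parent:
                parent[nb] = cur
                stack.append(nb)
    path = [b]
    while path[-1] != a:
        path.append(parent[path[-1]])
    path.reverse()
    half = total / 2.0
    out = Tree()
    out._internal_counter = tree._internal_counter
    for x in tree.adj:
        for y, ln in tree.adj[x].items():
            if x < y:
                out.add_edge(x, y, ln)
    walked = 0.0
    for u, v in zip(path, path[1:]):
        ln = max(0.0, tree.adj[u][v])
        if walked + ln >= half or (u, v) == (path[-2], path[-1]):
            du = half - walked
            raw = tree.adj[u][v]
            del out.adj[u][v]
            del out.adj[v][u]
            out.add_edge(u, "#root", max(0.0, min(du, raw)))
            out.add_edge("#root", v, max(0.0, raw - du))
            return out
        walked += ln
    raise AssertionError("midpoint not located")  # pragma: no cover


def from_newick(text: str) -> Tree:
    """Parse Newick into a Tree (internal nodes renamed ``#k`` in preorder)."""
    dt = dendropy.Tree.get(
        data=text, schema="newick", preserve_underscores=True
    )
    tree = Tree()
    names: dict[int, str] = {}
    for node in dt.preorder_node_iter():
        if node.is_leaf():
            names[id(node)] = node.taxon.label
        else:
            names[id(node)] = tree.new_internal()
    for node in dt.preorder_node_iter():
        if node.parent_node is not None:
            ln = node.edge.length if node.edge.length is not None else 0.0
            tree.add_edge(names[id(node.parent_node)], names[id(node)], ln)
    return tree


def random_binary_tree(
    labels: list[str],
    rng: np.random.Generator,
    blen_range: tuple[float, float] = (0.1, 2.0),
) -> Tree:
    """Random unrooted binary topology over ``labels`` with i.i.d. uniform
    branch lengths — a source of exactly additive distance matrices."""
    if len(labels) < 3:
        raise ValueError("need at least 3 labels")
    lo, hi = blen_range
    tree = Tree()
    order = [labels[i] for i in rng.permutation(len(labels))]
    a, b, c = order[:3]
    hub = tree.new_internal()
    for leaf in (a, b, c):
        tree.add_edge(hub, leaf, float(rng.uniform(lo, hi)))
    for leaf in order[3:]:
        edges = sorted(
            (x, y) for x in tree.adj for y in tree.adj[x] if x < y
        )
        x, y = edges[rng.integers(len(edges))]
        ln = tree.adj[x][y]
        split = float(rng.uniform(0.0, 1.0))
        mid = tree.new_internal()
        del tree.adj[x][y]
        del tree.adj[y][x]
        tree.add_edge(x, mid, ln * split)
        tree.add_edge(mid, y, ln * (1.0 - split))
        tree.add_edge(mid, leaf, float(rng.uniform(lo, hi)))
    return tree


def tree_distance_matrix(tree: Tree) -> DistanceMatrix:
    """Additive leaf-to-leaf path-length matrix of a tree."""
    leaves = tree.leaves
    paths = tree.leaf_path_lengths(floor_at_zero=False)
    n = len(leaves)
    m = np.zeros((n, n))
    for (a, b), v in paths.items():
        i, j = leaves.index(a), leaves.index(b)
        m[i, j] = m[j, i] = v
    comp = np.ones((n, n), dtype=int)
    return DistanceMatrix(ids=leaves, snp_percent=m, comparable_sites=comp)


# ---------------------------------------------------------------------------
# haplotypes


@dataclass(frozen=True)
class Haplotype:
    sequence: str
    multiplicity: int
    member_ids: tuple[str, ...]
    label: str  # lexicographically smallest member id


@dataclass
class HaplotypeSet:
    haplotypes: list[Haplotype]
    pairwise_steps: np.ndarray  # mismatch counts between representatives

    def __post_init__(self):
        k = len(self.haplotypes)
        if self.pairwise_steps.shape != (k, k):
            raise ValueError("pairwise_steps shape must match haplotype count")

    @property
    def labels(self) -> list[str]:
        return [h.label for h in self.haplotypes]


def _rows_match(a: np.ndarray, b: np.ndarray, defined_a, defined_b) -> tuple[bool, bool]:
    """(match under N-wildcard, match needed a wildcard)."""
    both = defined_a & defined_b
    if (a[both] != b[both]).any():
        return False, False
    return True, bool((~both).any() and (defined_a ^ defined_b).any())


def collapse_haplotypes(alignment: Alignment) -> HaplotypeSet:
    """Merge rows identical at every comparable site (``N`` matches anything).

    Merging is greedy in input order; because the wildcard rule is not
    transitive in general, an N-mediated merge is logged.  Representatives
    are the lexicographically smallest member ids; ``pairwise_steps`` counts
    mismatches between representative rows at sites where both are
    unambiguous.
    """
    if not alignment.trimmed:
        raise ValueError("collapse_haplotypes requires a trimmed alignment")
    mat = alignment.matrix()
    defined = alignment.comparable_mask()
    groups: list[list[int]] = []
    for idx in range(len(alignment.ids)):
        placed = False
        for g in groups:
            ok, via_n = _rows_match(
                mat[idx], mat[g[0]], defined[idx], defined[g[0]]
            )
            if ok:
                if via_n:
                    logger.info(
                        "N-mediated haplotype merge: %s into group of %s",
                        alignment.ids[idx],
                        alignment.ids[g[0]],
                    )
                g.append(idx)
                placed = True
                break
        if not placed:
            groups.append([idx])
    haps: list[Haplotype] = []
    rep_rows: list[int] = []
    for g in groups:
        members = sorted(alignment.ids[i] for i in g)
        rep = members[0]
        rep_idx = alignment.ids.index(rep)
        rep_rows.append(rep_idx)
        haps.append(
            Haplotype(
                sequence=alignment.rows[rep],
                multiplicity=len(g),
                member_ids=tuple(members),
                label=rep,
            )
        )
    k = len(haps)
    steps = np.zeros((k, k), dtype=int)
    for i, j in itertools.combinations(range(k), 2):
        ri, rj = rep_rows[i], rep_rows[j]
        both = defined[ri] & defined[rj]
        s = int(((mat[ri] != mat[rj]) & both).sum())
        steps[i, j] = steps[j, i] = s
    return HaplotypeSet(haplotypes=haps, pairwise_steps=steps)


@dataclass
class NetworkEdges:
    """Minimum-spanning network over haplotypes.

    ``edges`` holds ``(label_i, label_j, steps)``; ``spanning_weight`` is the
    weight of a minimum spanning forest over the admissible edges (tie edges
    add to the network but not to this weight).
    """

    edges: list[tuple[str, str, int]]
    components: list[list[str]]
    step_limit: int | None
    spanning_weight: int


def parsimony_network(
    haps: HaplotypeSet, step_limit: int | None = None
) -> NetworkEdges:
    """Minimum-spanning network (Kruskal with tie inclusion).

    Process admissible edges (steps <= ``step_limit``) by increasing weight;
    at each weight level every edge joining two components *as they stood
    before the level* is included, then the components merge.  This yields
    the standard MSN: a minimum spanning forest plus all tie edges at the
    merge weights.  Haplotypes left unreachable under the limit form their
    own components.
    """
    if step_limit is not None and step_limit < 1:
        raise ValueError("step_limit must be at least 1")
    labels = haps.labels
    k = len(labels)
    parent = list(range(k))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    all_edges = [
        (int(haps.pairwise_steps[i, j]), i, j)
        for i, j in itertools.combinations(range(k), 2)
    ]
    admissible = [
        e for e in all_edges if step_limit is None or e[0] <= step_limit
    ]
    admissible.sort()
    out: list[tuple[str, str, int]] = []
    spanning_weight = 0
    pos = 0
    while pos < len(admissible):
        w = admissible[pos][0]
        level = []
        while pos < len(admissible) and admissible[pos][0] == w:
            level.append(admissible[pos])
            pos += 1
        snapshot = {i: find(i) for e in level for i in (e[1], e[2])}
        keep = [
            (w0, i, j) for w0, i, j in level if snapshot[i] != snapshot[j]
        ]
        for w0, i, j in keep:
            out.append((labels[i], labels[j], w0))
            if find(i) != find(j):
                parent[find(i)] = find(j)
                spanning_weight += w0
    comp_map: dict[int, list[str]] = {}
    for i in range(k):
        comp_map.setdefault(find(i), []).append(labels[i])
    components = sorted(
        (sorted(v) for v in comp_map.values()), key=lambda c: c[0]
    )
    return NetworkEdges(
        edges=sorted(out, key=lambda e: (e[2], e[0], e[1])),
        components=components,
        step_limit=step_limit,
        spanning_weight=spanning_weight,
    )


def network_edges_tsv(net: NetworkEdges) -> str:
    lines = ["hap_i\thap_j\tsteps"]
    for a, b, s in net.edges:
        lines.append(f"{a}\t{b}\t{s}")
    return "\n".join(lines) + "\n"


def network_nodes_tsv(haps: HaplotypeSet, labels: dict[str, str]) -> str:
    lines = ["haplotype\tmultiplicity\tmembers\tspecies_breakdown"]
    for h in haps.haplotypes:
        breakdown: dict[str, int] = {}
        for m in h.member_ids:
            sp = labels.get(m, "unknown")
            breakdown[sp] = breakdown.get(sp, 0) + 1
        bd = ",".join(f"{sp}:{breakdown[sp]}" for sp in sorted(breakdown))
        lines.append(
            f"{h.label}\t{h.multiplicity}\t{','.join(h.member_ids)}\t{bd}"
        )
    return "\n".join(lines) + "\n"
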