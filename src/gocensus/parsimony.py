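"""Maximum-parsimony inference for multistate (32-state) character matrices.

Characters are treated as ordered (Wagner) by default — the cost of a change
between states i and j is |i - j| — because the min/max ancestral-state
polarity used for rooting presupposes an ordered state scale.  An unordered
(Fitch) model is available for sensitivity checks.  Scoring uses the Sankoff
dynamic program (generalized parsimony) with integer costs throughout, so
tree lengths are exact integers.

Tree search is heuristic: random-addition starting trees (stepwise greedy
insertion in a random taxon order) improved by steepest-descent NNI and then
first-improvement SPR sweeps until no rearrangement shortens the tree.

Rooting follows the Lundberg criterion: a hypothetical ancestor with every
character fixed at the declared ancestral state (0 or 31) is attached to
each branch of the unrooted best tree in turn, and the root is placed on the
branch that minimizes total length.  Ties are broken by canonical branch
order and surfaced via a flag.

A small statsmodels-style surface (:class:`ParsimonyModel` /
:class:`ParsimonyResults`) wraps search, rooting, bootstrap support and fit
indices behind ``fit()`` and ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal, Sequence

import dendropy
import numpy as np

from .encoding import CharacterMatrixView, N_STATES

_INF = np.int32(1 << 20)


@dataclass(frozen=True)
class CostModel:
    """Transition-cost model over the 32 ordered states."""

    kind: Literal["ordered", "unordered"] = "ordered"
    state_count: int = N_STATES

    def matrix(self) -> np.ndarray:
        s = np.arange(self.state_count)
        if self.kind == "ordered":
            return np.abs(s[:, None] - s[None, :]).astype(np.int32)
        if self.kind == "unordered":
            return (s[:, None] != s[None, :]).astype(np.int32)
        raise ValueError(f"unknown cost model kind {self.kind!r}")


# ---------------------------------------------------------------------------
# unrooted topologies
# ---------------------------------------------------------------------------

class Topology:
    """Unrooted binary tree over tips 0..n_tips-1 (internal ids follow)."""

    __slots__ = ("n_tips", "adj", "_next_id")

    def __init__(self, n_tips: int, adj: dict[int, list[int]], next_id: int):
        self.n_tips = n_tips
        self.adj = adj
        self._next_id = next_id

    # -- construction -----------------------------------------------------
    @classmethod
    def star(cls, tips: Sequence[int], n_tips: int) -> "Topology":
        """Star over three (or more) tips joined at one internal node."""
        if len(tips) < 3:
            raise ValueError("need at least 3 tips")
        hub = n_tips
        adj: dict[int, list[int]] = {hub: []}
        for t in tips:
            adj[t] = [hub]
            adj[hub].append(t)
        return cls(n_tips, adj, hub + 1)

    def copy(self) -> "Topology":
        return Topology(self.n_tips, {k: list(v) for k, v in self.adj.items()},
                        self._next_id)

    def attach_tip(self, tip: int, edge: tuple[int, int]) -> None:
        """Insert ``tip`` by bisecting ``edge`` with a fresh internal node."""
        u, v = edge
        w = self._next_id
        self._next_id += 1
        self.adj[u].remove(v)
        self.adj[v].remove(u)
        self.adj[u].append(w)
        self.adj[v].append(w)
        self.adj[w] = [u, v, tip]
        self.adj[tip] = [w]

    # -- queries ----------------------------------------------------------
    def tips(self) -> list[int]:
        return sorted(n for n, nbrs in self.adj.items() if len(nbrs) == 1)

    def edges(self) -> list[tuple[int, int]]:
        return sorted((min(u, v), max(u, v))
                      for u in self.adj for v in self.adj[u] if u < v)

    def splits(self) -> set[frozenset[int]]:
        """Non-trivial bipartitions, each given as the tip side not
        containing the smallest tip id."""
        tips = self.tips()
        if len(tips) < 4:
            return set()
        anchor = tips[0]
        below = self._below_map(anchor)
        ntips = len(tips)
        out = set()
        for node, tipset in below.items():
            if 2 <= len(tipset) <= ntips - 2:
                out.add(frozenset(tipset))
        return out

    def _below_map(self, anchor_tip: int) -> dict[int, set[int]]:
        """For each node (excluding the anchor), the tips on its far side of
        the edge towards the anchor."""
        root = self.adj[anchor_tip][0]
        parent = {root: anchor_tip}
        topo = [root]
        stack = [root]
        seen = {root, anchor_tip}
        while stack:
            node = stack.pop()
            for nb in self.adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    parent[nb] = node
                    topo.append(nb)
                    stack.append(nb)
        below: dict[int, set[int]] = {}
        for node in reversed(topo):
            if len(self.adj[node]) == 1:
                below[node] = {node}
            else:
                acc: set[int] = set()
                for nb in self.adj[node]:
                    if nb != parent[node]:
                        acc |= below[nb]
                below[node] = acc
        return below

    def canonical_key(self) -> tuple:
        return tuple(sorted(tuple(sorted(s)) for s in self.splits()))

    # -- rearrangements ---------------------------------------------------
    def nni_neighbors(self) -> Iterator["Topology"]:
        """The two nearest-neighbor interchanges across each internal edge."""
        for u, v in self.edges():
            if len(self.adj[u]) == 1 or len(self.adj[v]) == 1:
                continue
            a, b = sorted(x for x in self.adj[u] if x != v)
            c, d = sorted(x for x in self.adj[v] if x != u)
            for swap in (c, d):
                t = self.copy()
                t.adj[u].remove(a)
                t.adj[a].remove(u)
                t.adj[v].remove(swap)
                t.adj[swap].remove(v)
                t.adj[u].append(swap)
                t.adj[swap].append(u)
                t.adj[v].append(a)
                t.adj[a].append(v)
                yield t

    def spr_neighbors(self) -> Iterator["Topology"]:
        """Subtree prune-and-regraft moves (both directions of every edge)."""
        for u, v in self.edges():
            for keep, prune in ((u, v), (v, u)):
                if len(self.adj[keep]) == 1:
                    continue  # nothing left to regraft onto
                t0 = self.copy()
                t0.adj[keep].remove(prune)
                t0.adj[prune].remove(keep)
                x, y = t0.adj[keep]
                t0.adj[x].remove(keep)
                t0.adj[y].remove(keep)
                t0.adj[x].append(y)
                t0.adj[y].append(x)
                del t0.adj[keep]
                # nodes reachable from x form the remaining tree
                remaining = set()
                stack = [x]
                while stack:
                    nd = stack.pop()
                    if nd in remaining:
                        continue
                    remaining.add(nd)
                    stack.extend(t0.adj[nd])
                for ex, ey in t0.edges():
                    if ex not in remaining:
                        continue
                    if {ex, ey} == {x, y}:
                        continue  # regrafting here recreates the input tree
                    t = t0.copy()
                    t.adj[ex].remove(ey)
                    t.adj[ey].remove(ex)
                    t.adj[ex].append(keep)
                    t.adj[ey].append(keep)
                    t.adj[keep] = [ex, ey, prune]
                    t.adj[prune].append(keep)
                    yield t

    # -- interop ----------------------------------------------------------
    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree, taxa: Sequence[str]) -> "Topology":
        """Build an unrooted topology from a dendropy tree, suppressing any
        degree-2 root."""
        index = {label: i for i, label in enumerate(taxa)}
        n_tips = len(taxa)
        adj: dict[int, list[int]] = {}
        next_internal = [n_tips]
        ids: dict[dendropy.Node, int] = {}

        def node_id(nd: dendropy.Node) -> int:
            if nd in ids:
                return ids[nd]
            if nd.is_leaf():
                label = nd.taxon.label if nd.taxon else nd.label
                if label not in index:
                    raise KeyError(f"leaf {label!r} not among expected taxa")
                ids[nd] = index[label]
            else:
                ids[nd] = next_internal[0]
                next_internal[0] += 1
            adj.setdefault(ids[nd], [])
            return ids[nd]

        for nd in tree.preorder_node_iter():
            if nd.parent_node is None:
                node_id(nd)
                continue
            a, b = node_id(nd.parent_node), node_id(nd)
            adj[a].append(b)
            adj[b].append(a)
        # suppress degree-2 nodes (e.g. the root of a rooted input)
        for nd in [n for n, nbrs in adj.items() if len(nbrs) == 2]:
            p, q = adj[nd]
            adj[p].remove(nd)
            adj[q].remove(nd)
            adj[p].append(q)
            adj[q].append(p)
            del adj[nd]
        top = cls(n_tips, adj, next_internal[0])
        if sorted(top.tips()) != sorted(index.values()):
            raise ValueError("tree tips do not match the expected taxa")
        return top


# ---------------------------------------------------------------------------
# Sankoff scoring
# ---------------------------------------------------------------------------

class _Scorer:
    """Vectorized Sankoff dynamic program over a fixed character matrix.

    Identical character columns are collapsed once and re-expanded through
    weights, which also makes bootstrap reweighting cheap.  The min-plus
    step against the cost matrix uses O(k) cumulative-min scans for ordered
    costs and the usual two-term closed form for unordered costs, instead
    of the dense k x k broadcast.
    """

    def __init__(self, states: np.ndarray, cost: CostModel,
                 tip_ids: Sequence[int] | None = None):
        states = np.asarray(states)
        k = cost.state_count
        if states.size and (states.min() < 0 or states.max() >= k):
            raise ValueError("character states outside the cost model range")
        self.kind = cost.kind
        if self.kind not in ("ordered", "unordered"):
            raise ValueError(f"unknown cost model kind {self.kind!r}")
        self.k = k
        self._j = np.arange(k, dtype=np.int32)
        ucols, inv = np.unique(states, axis=1, return_inverse=True)
        self.inv = np.asarray(inv).ravel()
        self.n_chars = states.shape[1]
        self.n_u = ucols.shape[1]
        self.base_w = np.bincount(self.inv, minlength=self.n_u)
        if tip_ids is None:
            tip_ids = range(states.shape[0])
        self.tipcost: dict[int, np.ndarray] = {}
        for row, tid in enumerate(tip_ids):
            tc = np.full((self.n_u, k), _INF, dtype=np.int32)
            tc[np.arange(self.n_u), ucols[row]] = 0
            self.tipcost[tid] = tc

    def _child_contrib(self, ch: np.ndarray) -> np.ndarray:
        """out[:, i] = min_j ch[:, j] + cost(i, j)."""
        if self.kind == "ordered":
            j = self._j
            left = np.minimum.accumulate(ch - j, axis=1) + j
            right = np.minimum.accumulate((ch + j)[:, ::-1], axis=1)[:, ::-1] - j
            return np.minimum(left, right)
        best = ch.min(axis=1, keepdims=True)
        return np.minimum(ch, best + 1)

    def _uweights(self, weights: np.ndarray | None) -> np.ndarray:
        if weights is None:
            return self.base_w
        return np.bincount(self.inv, weights=np.asarray(weights, dtype=float),
                           minlength=self.n_u)

    def root_costs(self, adj: dict[int, list[int]]) -> np.ndarray:
        internal = [n for n, nbrs in adj.items() if len(nbrs) > 1]
        root = min(internal) if internal else min(adj)  # 2-tip degenerate tree
        parent = {root: None}
        topo = [root]
        stack = [root]
        seen = {root}
        while stack:
            node = stack.pop()
            for nb in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    parent[nb] = node
                    topo.append(nb)
                    stack.append(nb)
        cost: dict[int, np.ndarray] = {}
        for node in reversed(topo):
            is_tip = len(adj[node]) == 1 and node in self.tipcost
            if is_tip and parent[node] is not None:
                cost[node] = self.tipcost[node]
                continue
            acc = None
            for nb in adj[node]:
                if nb == parent[node]:
                    continue
                contrib = self._child_contrib(cost.pop(nb))
                acc = contrib if acc is None else acc + contrib
            if is_tip:  # a tip serving as root contributes its own states
                acc = acc + self.tipcost[node]
            cost[node] = acc
        return cost[root]

    def per_unique_scores(self, adj: dict[int, list[int]]) -> np.ndarray:
        return self.root_costs(adj).min(axis=1)

    def score(self, top: "Topology | dict", weights: np.ndarray | None = None) -> int:
        adj = top.adj if isinstance(top, Topology) else top
        per_u = self.per_unique_scores(adj)
        return int(round(float(per_u @ self._uweights(weights))))

    def messages(self, adj: dict[int, list[int]]
                 ) -> tuple[dict, dict]:
        """Directed-edge Sankoff messages for every edge of the tree.

        ``g[(x, y)]`` is the cost profile of the component containing x when
        edge (x, y) is cut, indexed by the state of x; ``contrib[(x, y)]``
        is the same profile pushed through the cost model, indexed by the
        state of the node at the far (y) end.  With these, attaching any
        subtree to any edge is a constant number of array operations.
        """
        root = min(n for n, nbrs in adj.items() if len(nbrs) > 1)
        parent: dict[int, int | None] = {root: None}
        topo = [root]
        stack = [root]
        seen = {root}
        while stack:
            node = stack.pop()
            for nb in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    parent[nb] = node
                    topo.append(nb)
                    stack.append(nb)
        g: dict[tuple[int, int], np.ndarray] = {}
        contrib: dict[tuple[int, int], np.ndarray] = {}
        for node in reversed(topo):  # downward: child -> parent
            p = parent[node]
            if p is None:
                continue
            if len(adj[node]) == 1:
                vec = self.tipcost[node]
            else:
                vec = None
                for nb in adj[node]:
                    if nb != p:
                        c = contrib[(nb, node)]
                        vec = c if vec is None else vec + c
            g[(node, p)] = vec
            contrib[(node, p)] = self._child_contrib(vec)
        for node in topo:  # upward: parent -> child
            nbs = adj[node]
            if len(nbs) == 1:
                continue
            for v in nbs:
                if v == parent[node]:
                    continue
                vec = None
                for nb in nbs:
                    if nb == v:
                        continue
                    c = contrib[(nb, node)]
                    vec = c if vec is None else vec + c
                g[(node, v)] = vec
                contrib[(node, v)] = self._child_contrib(vec)
        return g, contrib

    def attach_profile(self, contrib: dict, edge: tuple[int, int],
                       subtree_contrib: np.ndarray) -> np.ndarray:
        """Per-unique-character cost of attaching a subtree on ``edge``."""
        x, y = edge
        tot = contrib[(x, y)] + contrib[(y, x)] + subtree_contrib
        return tot.min(axis=1)

    def char_scores(self, top: "Topology | dict") -> np.ndarray:
        adj = top.adj if isinstance(top, Topology) else top
        return self.per_unique_scores(adj)[self.inv]


def tree_length(tree: "Topology | RootedTree | dendropy.Tree",
                view: CharacterMatrixView, cost: CostModel) -> int:
    """Parsimony length (Sankoff minimum total cost) of a tree.

    The score is computed on the unrooted shape and is therefore invariant
    under re-rooting.
    """
    top = _as_topology(tree, view)
    scorer = _Scorer(view.states, cost)
    return scorer.score(top)


def _as_topology(tree, view: CharacterMatrixView) -> Topology:
    if isinstance(tree, Topology):
        return tree
    if isinstance(tree, RootedTree):
        if tree.topology is not None:
            return tree.topology
        return Topology.from_dendropy(tree.tree, view.taxa)
    if isinstance(tree, dendropy.Tree):
        return Topology.from_dendropy(tree, view.taxa)
    raise TypeError(f"cannot interpret {type(tree)!r} as a tree")


# ---------------------------------------------------------------------------
# heuristic search
# ---------------------------------------------------------------------------

@dataclass
class MpSearchResult:
    topologies: list[Topology]
    best_length: int
    tied: bool = False

    @property
    def best(self) -> Topology:
        return self.topologies[0]


def _stepwise_addition(order: Sequence[int], n_tips: int, scorer: _Scorer,
                       weights: np.ndarray | None) -> Topology:
    top = Topology.star(list(order[:3]), n_tips)
    w = scorer._uweights(weights)
    for tip in order[3:]:
        _, contrib = scorer.messages(top.adj)
        sub = scorer._child_contrib(scorer.tipcost[int(tip)])
        best_edge = None
        best_l = None
        for edge in top.edges():
            l = float(scorer.attach_profile(contrib, edge, sub) @ w)
            if best_l is None or l < best_l:
                best_edge, best_l = edge, l
        top.attach_tip(int(tip), best_edge)
    return top


def _best_nni(top: Topology, scorer: _Scorer, w: np.ndarray,
              cur_len: float) -> tuple[float, tuple] | None:
    """Steepest improving NNI move, or None; scores via edge messages."""
    _, contrib = scorer.messages(top.adj)
    best = None
    for u, v in top.edges():
        if len(top.adj[u]) == 1 or len(top.adj[v]) == 1:
            continue
        a, b = sorted(x for x in top.adj[u] if x != v)
        c, d = sorted(x for x in top.adj[v] if x != u)
        CA, CB = contrib[(a, u)], contrib[(b, u)]
        CC, CD = contrib[(c, v)], contrib[(d, v)]
        # swapping a<->c groups (b,c | a,d); a<->d groups (b,d | a,c)
        for swap, near, far in ((c, CB + CC, CA + CD),
                                (d, CB + CD, CA + CC)):
            tot = scorer._child_contrib(near) + far
            l = float(tot.min(axis=1) @ w)
            if l < cur_len and (best is None or l < best[0]):
                best = (l, (u, v, a, swap))
    return best


def _apply_nni(top: Topology, move: tuple) -> None:
    u, v, a, swap = move
    top.adj[u].remove(a)
    top.adj[a].remove(u)
    top.adj[v].remove(swap)
    top.adj[swap].remove(v)
    top.adj[u].append(swap)
    top.adj[swap].append(u)
    top.adj[v].append(a)
    top.adj[a].append(v)


def _first_spr(top: Topology, scorer: _Scorer, w: np.ndarray,
               cur_len: float) -> tuple[float, tuple] | None:
    """First prune site with an improving regraft (best target per site)."""
    g_orig, _ = scorer.messages(top.adj)
    for u, v in top.edges():
        for keep, prune in ((u, v), (v, u)):
            if len(top.adj[keep]) == 1:
                continue
            rem = top.copy()
            rem.adj[keep].remove(prune)
            rem.adj[prune].remove(keep)
            x, y = rem.adj[keep]
            rem.adj[x].remove(keep)
            rem.adj[y].remove(keep)
            rem.adj[x].append(y)
            rem.adj[y].append(x)
            del rem.adj[keep]
            remaining = set()
            stack = [x]
            while stack:
                nd = stack.pop()
                if nd in remaining:
                    continue
                remaining.add(nd)
                stack.extend(rem.adj[nd])
            if len([t for t in remaining if len(rem.adj[t]) == 1]) < 3:
                continue
            _, contrib_rem = scorer.messages(
                {n: rem.adj[n] for n in remaining})
            sub = scorer._child_contrib(g_orig[(prune, keep)])
            best = None
            for ex, ey in sorted((min(p, q), max(p, q))
                                 for p in remaining for q in rem.adj[p]
                                 if p < q):
                if {ex, ey} == {x, y}:
                    continue  # regrafting here recreates the input tree
                l = float(scorer.attach_profile(contrib_rem, (ex, ey), sub) @ w)
                if l < cur_len and (best is None or l < best[0]):
                    best = (l, (keep, prune, x, y, ex, ey))
            if best is not None:
                return best
    return None


def _apply_spr(top: Topology, move: tuple) -> None:
    keep, prune, x, y, ex, ey = move
    top.adj[keep].remove(prune)
    top.adj[prune].remove(keep)
    top.adj[x].remove(keep)
    top.adj[y].remove(keep)
    top.adj[x].append(y)
    top.adj[y].append(x)
    top.adj[ex].remove(ey)
    top.adj[ey].remove(ex)
    top.adj[ex].append(keep)
    top.adj[ey].append(keep)
    top.adj[keep] = [ex, ey, prune]
    top.adj[prune].append(keep)


def _hill_climb(top: Topology, scorer: _Scorer, weights: np.ndarray | None,
                use_spr: bool) -> tuple[Topology, int]:
    cur = top
    w = scorer._uweights(weights)
    cur_len = scorer.score(cur, weights)
    while True:
        while True:  # steepest-descent NNI
            move = _best_nni(cur, scorer, w, cur_len)
            if move is None:
                break
            _apply_nni(cur, move[1])
            cur_len = int(round(move[0]))
        if use_spr:
            move = _first_spr(cur, scorer, w, cur_len)
            if move is not None:
                _apply_spr(cur, move[1])
                cur_len = int(round(move[0]))
                continue
        break
    return cur, cur_len


def mp_search(view: CharacterMatrixView, cost: CostModel,
              n_starts: int = 10, seed: int | None = None,
              use_spr: bool = True,
              weights: np.ndarray | None = None) -> MpSearchResult:
    """Heuristic maximum-parsimony search.

    Runs ``n_starts`` random-addition starting trees, each improved by NNI
    and (optionally) SPR hill-climbing, and returns all distinct topologies
    at the best length found.  Deterministic given ``seed``.
    """
    n = len(view.taxa)
    if n < 3:
        raise ValueError("maximum-parsimony search needs at least 3 taxa")
    scorer = _Scorer(view.states, cost)
    rng = np.random.default_rng(seed)
    if n == 3:
        top = Topology.star([0, 1, 2], 3)
        return MpSearchResult([top], scorer.score(top, weights))

    best_len: int | None = None
    pool: dict[tuple, Topology] = {}
    for _ in range(max(1, n_starts)):
        order = [int(i) for i in rng.permutation(n)]
        start = _stepwise_addition(order, n, scorer, weights)
        top, length = _hill_climb(start, scorer, weights, use_spr)
        if best_len is None or length < best_len:
            best_len = length
            pool = {top.canonical_key(): top}
        elif length == best_len:
            pool.setdefault(top.canonical_key(), top)
    ordered = [pool[k] for k in sorted(pool)]
    return MpSearchResult(ordered, int(best_len), tied=len(ordered) > 1)


# ---------------------------------------------------------------------------
# rooted trees
# ---------------------------------------------------------------------------

@dataclass
class RootedTree:
    """A rooted tree over named taxa with its parsimony bookkeeping."""

    tree: dendropy.Tree
    taxa: tuple[str, ...]
    length: int
    ancestral_state: int | None = None
    rooting_score: int | None = None
    root_tie: bool = False
    topology: Topology | None = field(default=None, repr=False)

    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def clades(self) -> dict[frozenset[str], dendropy.Node]:
        """Tip-label sets of internal nodes other than the root."""
        out: dict[frozenset[str], dendropy.Node] = {}
        for node in self.tree.preorder_internal_node_iter():
            if node.parent_node is None:
                continue
            labels = frozenset(lf.taxon.label for lf in node.leaf_iter())
            out[labels] = node
        return out


def _to_rooted_dendropy(top: Topology, labels: Sequence[str],
                        root_edge: tuple[int, int]) -> dendropy.Tree:
    tns = dendropy.TaxonNamespace(list(labels))
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = True

    def build(node_id: int, come_from: int, parent: dendropy.Node) -> None:
        child = parent.new_child()
        if len(top.adj[node_id]) == 1:
            child.taxon = tns.get_taxon(labels[node_id])
            return
        for nb in sorted(top.adj[node_id]):
            if nb != come_from:
                build(nb, node_id, child)

    u, v = root_edge
    build(u, v, tree.seed_node)
    build(v, u, tree.seed_node)
    return tree


def lundberg_root(top: Topology, view: CharacterMatrixView, cost: CostModel,
                  ancestral_state: int) -> RootedTree:
    """Root an unrooted tree by the Lundberg criterion.

    A hypothetical all-``ancestral_state`` ancestor is attached to every
    branch in turn; the root is placed on the branch minimizing total
    parsimony length.  Ties are broken by canonical (sorted) branch order
    and flagged.  The returned tree contains only the original tips — the
    hypothetical ancestor is removed and its attachment point becomes the
    root.
    """
    if ancestral_state not in (0, N_STATES - 1):
        raise ValueError("ancestral_state must be 0 or 31")
    n = len(view.taxa)
    anc_id = max(top.adj) + 1
    aug_states = np.vstack([view.states,
                            np.full((1, view.states.shape[1]), ancestral_state,
                                    dtype=view.states.dtype)])
    tip_ids = list(top.tips()) + [anc_id]
    # rows of aug_states are ordered: original tips 0..n-1, then the ancestor
    aug_scorer = _Scorer(aug_states, cost, tip_ids=tip_ids)
    base_scorer = _Scorer(view.states, cost)

    best_edge = None
    best_score = None
    tie = False
    for edge in top.edges():
        cand = top.copy()
        cand._next_id = max(anc_id + 1, cand._next_id)
        cand.attach_tip(anc_id, edge)
        s = aug_scorer.score(cand)
        if best_score is None or s < best_score:
            best_edge, best_score, tie = edge, s, False
        elif s == best_score:
            tie = True
    tree = _to_rooted_dendropy(top, view.taxa, best_edge)
    return RootedTree(tree=tree, taxa=tuple(view.taxa),
                      length=base_scorer.score(top),
                      ancestral_state=ancestral_state,
                      rooting_score=int(best_score), root_tie=tie,
                      topology=top)


# ---------------------------------------------------------------------------
# bootstrap support
# ---------------------------------------------------------------------------

def bootstrap_support(view: CharacterMatrixView, cost: CostModel,
                      reference: RootedTree, n_reps: int = 1000,
                      seed: int | None = None, n_starts: int = 2,
                      use_spr: bool = False) -> dict[frozenset[str], float]:
    """Character-resampling bootstrap support for the clades of a rooted tree.

    Characters are resampled with replacement per replicate (implemented as
    multinomial reweighting), a reduced-schedule search is run, and each
    clade of the reference tree is counted when the replicate's best tree
    contains the matching bipartition.  Supports are percentages and are
    also written onto the reference tree's internal node labels.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    m = len(view.characters)
    n = len(view.taxa)
    index = {label: i for i, label in enumerate(view.taxa)}
    clades = reference.clades()
    targets = {c: frozenset(index[t] for t in c) for c in clades}
    counts = {c: 0 for c in clades}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        weights = rng.multinomial(m, np.full(m, 1.0 / m))
        rep_seed = int(rng.integers(0, 2**31 - 1))
        res = mp_search(view, cost, n_starts=n_starts, seed=rep_seed,
                        use_spr=use_spr, weights=weights)
        splits = res.best.splits()
        all_ids = frozenset(range(n))
        for c, tipset in targets.items():
            if len(tipset) <= 1 or len(tipset) >= n - 1:
                counts[c] += 1  # trivial bipartition: present in every tree
            elif tipset in splits or (all_ids - tipset) in splits:
                counts[c] += 1
    supports: dict[frozenset[str], float] = {}
    for c, node in clades.items():
        pct = 100.0 * counts[c] / n_reps
        supports[c] = pct
        node.label = f"{pct:.0f}"
    return supports


# ---------------------------------------------------------------------------
# fit indices
# ---------------------------------------------------------------------------

def fit_indices(tree: "RootedTree | Topology", view: CharacterMatrixView,
                cost: CostModel) -> tuple[float, float, float]:
    """Ensemble consistency (CI), retention (RI) and rescaled consistency
    (RC) indices of a tree on a matrix.

    Per character: minimum steps m (state range for ordered costs, distinct
    states minus one for unordered), observed steps s on the tree, and
    maximum steps g (the star-tree score).  Invariant characters contribute
    nothing and are excluded from the sums.
    """
    top = _as_topology(tree, view)
    C = cost.matrix()
    scorer = _Scorer(view.states, cost)
    obs = scorer.char_scores(top).astype(float)
    states = view.states
    smin = states.min(axis=0)
    smax = states.max(axis=0)
    ndistinct = np.array([len(np.unique(states[:, j]))
                          for j in range(states.shape[1])])
    if cost.kind == "ordered":
        m = (smax - smin).astype(float)
    else:
        m = (ndistinct - 1).astype(float)
    g = np.empty(states.shape[1])
    for j in range(states.shape[1]):
        g[j] = np.min(C[:, states[:, j]].sum(axis=1))
    informative = ndistinct >= 2
    M, S, G = m[informative].sum(), obs[informative].sum(), g[informative].sum()
    ci = 1.0 if S == 0 else M / S
    ri = 1.0 if G == M else (G - S) / (G - M)
    return float(ci), float(ri), float(ci * ri)


def per_character_fit(tree, view: CharacterMatrixView,
                      cost: CostModel):
    """Per-character steps table (character, observed, min, max star steps)."""
    import pandas as pd
    top = _as_topology(tree, view)
    C = cost.matrix()
    scorer = _Scorer(view.states, cost)
    obs = scorer.char_scores(top)
    states = view.states
    if cost.kind == "ordered":
        m = states.max(axis=0) - states.min(axis=0)
    else:
        m = np.array([len(np.unique(states[:, j])) - 1
                      for j in range(states.shape[1])])
    g = np.array([int(np.min(C[:, states[:, j]].sum(axis=1)))
                  for j in range(states.shape[1])])
    return pd.DataFrame({"character": view.characters, "observed_steps": obs,
                         "min_steps": m, "max_steps": g})


# ---------------------------------------------------------------------------
# newick I/O
# ---------------------------------------------------------------------------

def write_newick(rooted: RootedTree) -> str:
    """Newick text with supports as internal node labels."""
    for leaf in rooted.tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise ValueError("tree has unlabeled tips")
    txt = rooted.tree.as_string(schema="newick", suppress_rooting=True,
                                unquoted_underscores=True)
    return txt.strip() + "\n"


def read_newick(text: str, taxa: Sequence[str] | None = None) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=text, schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# model / results surface
# ---------------------------------------------------------------------------

class ParsimonyModel:
    """Maximum-parsimony tree model for one orientation of an encoded matrix.

    Parameters
    ----------
    view : CharacterMatrixView
        Taxa x characters state matrix (``ToL`` or ``ToF`` orientation).
    cost : CostModel or {"ordered", "unordered"}
        Transition-cost model; ordered (Wagner) by default.
    n_starts, use_spr
        Search schedule: number of random-addition starts and whether SPR
        sweeps follow NNI.
    """

    def __init__(self, view: CharacterMatrixView,
                 cost: CostModel | str = "ordered",
                 n_starts: int = 10, use_spr: bool = True):
        self.view = view
        self.cost = CostModel(cost) if isinstance(cost, str) else cost
        self.n_starts = n_starts
        self.use_spr = use_spr

    @classmethod
    def from_encoded(cls, encoded, orientation: Literal["ToF", "ToL"],
                     **kwargs) -> "ParsimonyModel":
        from .encoding import orient
        return cls(orient(encoded, orientation), **kwargs)

    def fit(self, seed: int | None = None,
            ancestral_state: int | None = None,
            n_bootstrap: int = 0,
            bootstrap_starts: int = 2,
            bootstrap_spr: bool = False) -> "ParsimonyResults":
        """Search, root and (optionally) bootstrap; returns the results."""
        if ancestral_state is None:
            ancestral_state = N_STATES - 1 if self.view.orientation == "ToF" else 0
        ss = np.random.SeedSequence(seed if seed is not None else 0)
        s_search, s_boot = (int(s.generate_state(1)[0] % (2**31 - 1))
                            for s in ss.spawn(2))
        search = mp_search(self.view, self.cost, n_starts=self.n_starts,
                           seed=s_search, use_spr=self.use_spr)
        rooted = lundberg_root(search.best, self.view, self.cost,
                               ancestral_state)
        supports = None
        if n_bootstrap > 0:
            supports = bootstrap_support(self.view, self.cost, rooted,
                                         n_reps=n_bootstrap, seed=s_boot,
                                         n_starts=bootstrap_starts,
                                         use_spr=bootstrap_spr)
        ci, ri, rc = fit_indices(rooted, self.view, self.cost)
        return ParsimonyResults(model=self, search=search, tree=rooted,
                                supports=supports, ci=ci, ri=ri, rc=rc,
                                seed=seed, n_bootstrap=n_bootstrap)


@dataclass
class ParsimonyResults:
    """Fitted parsimony tree with its diagnostics."""

    model: ParsimonyModel
    search: MpSearchResult
    tree: RootedTree
    supports: dict[frozenset[str], float] | None
    ci: float
    ri: float
    rc: float
    seed: int | None
    n_bootstrap: int

    @property
    def best_length(self) -> int:
        return self.search.best_length

    def newick(self) -> str:
        return write_newick(self.tree)

    def summary(self) -> str:
        v = self.model.view
        rows = [
            ("Orientation", v.orientation),
            ("Taxa", str(len(v.taxa))),
            ("Characters", str(len(v.characters))),
            ("Cost model", f"{self.model.cost.kind} "
             f"({'Wagner' if self.model.cost.kind == 'ordered' else 'Fitch'})"),
            ("Tree length", f"{self.best_length} steps"),
            ("Equally best topologies", str(len(self.search.topologies))),
            ("Ancestral state (root)", str(self.tree.ancestral_state)),
            ("Rooting score", str(self.tree.rooting_score)),
            ("Root tie", "yes" if self.tree.root_tie else "no"),
            ("CI / RI / RC",
             f"{self.ci:.3f} / {self.ri:.3f} / {self.rc:.3f}"),
        ]
        if self.supports is not None:
            vals = sorted(self.supports.values())
            mean = sum(vals) / len(vals) if vals else float("nan")
            rows.append(("Bootstrap replicates", str(self.n_bootstrap)))
            rows.append(("Mean clade support", f"{mean:.1f}%"))
        width = max(len(k) for k, _ in rows) + 2
        bar = "=" * 54
        lines = [bar, "Parsimony Tree Results".center(54), bar]
        lines += [f"{k + ':':<{width}} {val}" for k, val in rows]
        lines.append(bar)
        return "\n".join(lines)
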