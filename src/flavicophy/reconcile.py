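"""Event-based cophylogenetic reconciliation.

A reconciliation maps every node of a dependent ("virus") tree onto a node
of a fixed ("host") tree, consistent with the observed leaf associations.
Each internal virus node receives exactly one event:

* codivergence -- the virus node sits on an internal host node and its two
  children descend into the two distinct child subtrees of that host node;
* duplication  -- both children stay at-or-below the parent's host without
  splitting across the host divergence;
* host switch  -- exactly one child jumps to a host lineage incomparable to
  the parent's host (neither ancestor nor descendant).

Losses (sorting events) are not node events: they count the host edges a
virus edge traverses without a corresponding virus divergence.  Switches
are not checked for chronological consistency: the host tree carries no
divergence times, so any incomparable landing edge is feasible.

Optimality is the Pareto frontier over event-count vectors, maximizing
codivergences while minimizing duplications, switches and losses
separately.  Multiple reconciliations can be "potentially optimal" (POpt)
under different event-cost regimes; the frontier contains exactly the
event vectors not dominated by any alternative.

:func:`reconcile` is a dynamic program over (virus node, host node) cells,
propagating per-cell Pareto sets; :func:`brute_force_reconcile` is an
independent exhaustive enumeration used as a test oracle on small trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .trees import AssociationMap, PhyloTree, TreeError, TreeNode

__all__ = [
    "EventCount",
    "ReconciliationSolution",
    "SolutionSet",
    "ReconciliationError",
    "reconcile",
    "count_events",
    "brute_force_reconcile",
    "best_codivergence",
    "best_noncodivergence",
]

CODIVERGENCE = "codivergence"
DUPLICATION = "duplication"
SWITCH = "switch"


class ReconciliationError(ValueError):
    pass


@dataclass(frozen=True)
class EventCount:
    """Counts of the four reconciliation event types."""

    n_codivergence: int
    n_duplication: int
    n_switch: int
    n_loss: int

    @property
    def nce(self) -> int:
        """Non-codivergence events: duplications + switches + losses."""
        return self.n_duplication + self.n_switch + self.n_loss

    @property
    def ce(self) -> int:
        return self.n_codivergence

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.n_codivergence, self.n_duplication, self.n_switch, self.n_loss)

    def __post_init__(self):
        if min(self.as_tuple()) < 0:
            raise ReconciliationError("negative event count")


@dataclass
class ReconciliationSolution:
    """One mapping of virus nodes into the host tree plus its event counts."""

    virus: PhyloTree
    host: PhyloTree
    assoc: AssociationMap
    node_map: dict  # virus TreeNode -> host TreeNode
    event_map: dict  # internal virus TreeNode -> event name
    counts: EventCount
    label: str = ""

    @property
    def ce(self) -> int:
        return self.counts.n_codivergence

    @property
    def nce(self) -> int:
        return self.counts.nce


@dataclass
class SolutionSet:
    """Pareto frontier of reconciliations, labeled S1, S2, ... in order of
    decreasing codivergence count then increasing NCE."""

    solutions: tuple

    def __post_init__(self):
        for i, sol in enumerate(self.solutions):
            sol.label = f"S{i + 1}"

    def __iter__(self):
        return iter(self.solutions)

    def __len__(self):
        return len(self.solutions)

    def __getitem__(self, i):
        return self.solutions[i]

    @property
    def event_vectors(self) -> list[tuple[int, int, int, int]]:
        return [s.counts.as_tuple() for s in self.solutions]

    @property
    def max_ce(self) -> int:
        return max(s.ce for s in self.solutions)

    @property
    def min_nce(self) -> int:
        return min(s.nce for s in self.solutions)


# ---------------------------------------------------------------------------
# indexed host tree
# ---------------------------------------------------------------------------

class _HostIndex:
    """Arrays + bitmask subtree tests over the host tree (postorder indexed)."""

    def __init__(self, tree: PhyloTree):
        self.nodes = list(tree.postorder())
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        n = len(self.nodes)
        self.children = [None] * n
        self.depth = [0] * n
        self.desc_mask = [0] * n
        for i, node in enumerate(self.nodes):
            if node.is_leaf:
                self.desc_mask[i] = 1 << i
            else:
                a, b = (self.index[id(c)] for c in node.children)
                self.children[i] = (a, b)
                self.desc_mask[i] = (1 << i) | self.desc_mask[a] | self.desc_mask[b]
        root = self.index[id(tree.root)]
        order = [root]
        while order:
            i = order.pop()
            if self.children[i]:
                for c in self.children[i]:
                    self.depth[c] = self.depth[i] + 1
                    order.append(c)
        self.root = root
        self.n = n
        self.leaf_index = {
            node.label: i for i, node in enumerate(self.nodes) if node.is_leaf
        }
        self.below = [
            [bool(self.desc_mask[h] >> x & 1) for h in range(n)] for x in range(n)
        ]
        self.descendants = [
            [x for x in range(n) if self.below[x][h]] for h in range(n)
        ]
        self.incomparables = [
            [y for y in range(n) if not self.below[y][h] and not self.below[h][y]]
            for h in range(n)
        ]

    def dist_down(self, anc: int, desc: int) -> int:
        return self.depth[desc] - self.depth[anc]


def _check_assoc(virus: PhyloTree, host: PhyloTree, assoc: AssociationMap):
    amap = assoc.as_dict()
    host_leaves = set(host.leaf_labels())
    for leaf in virus.leaf_labels():
        if leaf not in amap:
            raise ReconciliationError(f"virus leaf {leaf!r} has no host association")
        if amap[leaf] not in host_leaves:
            raise ReconciliationError(
                f"host species {amap[leaf]!r} (for {leaf!r}) is not a host tree leaf"
            )
    return amap


# ---------------------------------------------------------------------------
# Pareto utilities: maximize ce, minimize d, s, l
# ---------------------------------------------------------------------------

def _dominates(a, b) -> bool:
    return (
        a[0] >= b[0]
        and a[1] <= b[1]
        and a[2] <= b[2]
        and a[3] <= b[3]
        and a != b
    )


def _pareto_filter(items):
    """items: iterable of (vec, payload). Returns dict vec -> payload with only
    non-dominated vectors (first payload kept per vector)."""
    by_vec = {}
    for vec, payload in items:
        if vec not in by_vec:
            by_vec[vec] = payload
    vecs = sorted(by_vec, key=lambda v: (-v[0], v[1], v[2], v[3]))
    kept = []
    for v in vecs:
        if not any(_dominates(k, v) for k in kept):
            kept.append(v)
    return {v: by_vec[v] for v in kept}


def _add(u, v, extra):
    return (
        u[0] + v[0] + extra[0],
        u[1] + v[1] + extra[1],
        u[2] + v[2] + extra[2],
        u[3] + v[3] + extra[3],
    )


# ---------------------------------------------------------------------------
# full Pareto dynamic program
# ---------------------------------------------------------------------------

def reconcile(virus: PhyloTree, host: PhyloTree, assoc: AssociationMap) -> SolutionSet:
    """Enumerate the Pareto-optimal reconciliations of ``virus`` into ``host``.

    Returns a :class:`SolutionSet` with one representative solution per
    non-dominated event vector, deterministically ordered and labeled.
    """
    amap = _check_assoc(virus, host, assoc)
    H = _HostIndex(host)
    vnodes = list(virus.postorder())

    # D[id(v)][h] = dict vec -> choice
    D: dict = {}
    for v in vnodes:
        if v.is_leaf:
            h = H.leaf_index[amap[v.label]]
            D[id(v)] = {h: {(0, 0, 0, 0): ("leaf",)}}
            continue
        a, b = v.children
        Aa = _below_sets(D[id(a)], H)
        Ab = _below_sets(D[id(b)], H)
        Ia = _incomparable_sets(D[id(a)], H)
        Ib = _incomparable_sets(D[id(b)], H)
        cell: dict = {}
        for h in range(H.n):
            cands = []
            kids = H.children[h]
            if kids is not None:
                hl, hr = kids
                for (va, xa, ra) in Aa.get(hl, ()):  # codivergence, a left
                    for (vb, xb, rb) in Ab.get(hr, ()):
                        cands.append(
                            (_add(va, vb, (1, 0, 0, 0)),
                             (CODIVERGENCE, (xa, ra), (xb, rb)))
                        )
                for (va, xa, ra) in Aa.get(hr, ()):  # codivergence, a right
                    for (vb, xb, rb) in Ab.get(hl, ()):
                        cands.append(
                            (_add(va, vb, (1, 0, 0, 0)),
                             (CODIVERGENCE, (xa, ra), (xb, rb)))
                        )
            for (va, xa, ra) in Aa.get(h, ()):  # duplication
                for (vb, xb, rb) in Ab.get(h, ()):
                    cands.append(
                        (_add(va, vb, (0, 1, 0, 0)),
                         (DUPLICATION, (xa, ra), (xb, rb)))
                    )
            for (va, xa, ra) in Aa.get(h, ()):  # b switches out
                for (vb, xb, rb) in Ib.get(h, ()):
                    cands.append(
                        (_add(va, vb, (0, 0, 1, 0)),
                         (SWITCH, (xa, ra), (xb, rb)))
                    )
            for (vb, xb, rb) in Ab.get(h, ()):  # a switches out
                for (va, xa, ra) in Ia.get(h, ()):
                    cands.append(
                        (_add(va, vb, (0, 0, 1, 0)),
                         (SWITCH, (xa, ra), (xb, rb)))
                    )
            if cands:
                cell[h] = _pareto_filter(cands)
        if not cell:
            raise ReconciliationError("no feasible reconciliation (internal error)")
        D[id(v)] = cell

    root_cands = []
    for h, vecs in D[id(virus.root)].items():
        for vec in vecs:
            root_cands.append((vec, h))
    frontier = _pareto_filter(root_cands)

    solutions = []
    for vec in sorted(
        frontier, key=lambda t: (-t[0], t[1] + t[2] + t[3], t[1], t[2])
    ):
        h = frontier[vec]
        node_map: dict = {}
        event_map: dict = {}
        _backtrack(virus.root, h, vec, D, H, node_map, event_map)
        solutions.append(
            ReconciliationSolution(
                virus=virus,
                host=host,
                assoc=assoc,
                node_map=node_map,
                event_map=event_map,
                counts=EventCount(*vec),
            )
        )
    return SolutionSet(tuple(solutions))


def _below_sets(cell: dict, H: _HostIndex) -> dict:
    """For child DP cell ``{h: {vec: choice}}`` compute, per host node h, the
    Pareto set of placements at-or-below h, with the loss cost of descending
    from h folded in.  Entries are (adjusted vec, actual host x, raw vec)."""
    out = {}
    for h in range(H.n):
        items = []
        for x in H.descendants[h]:
            if x in cell:
                dl = H.dist_down(h, x)
                for vec in cell[x]:
                    adj = (vec[0], vec[1], vec[2], vec[3] + dl)
                    items.append((adj, (x, vec)))
        if items:
            pareto = _pareto_filter(items)
            out[h] = [(vec, x, raw) for vec, (x, raw) in pareto.items()]
    return out


def _incomparable_sets(cell: dict, H: _HostIndex) -> dict:
    """Pareto set of placements on host nodes incomparable to h (switch
    landing sites); the landing edge itself costs no losses."""
    out = {}
    for h in range(H.n):
        items = []
        for y in H.incomparables[h]:
            if y in cell:
                for vec in cell[y]:
                    items.append((vec, (y, vec)))
        if items:
            pareto = _pareto_filter(items)
            out[h] = [(vec, y, raw) for vec, (y, raw) in pareto.items()]
    return out


def _backtrack(v: TreeNode, h: int, vec, D, H, node_map, event_map):
    node_map[v] = H.nodes[h]
    choice = D[id(v)][h][vec]
    if choice[0] == "leaf":
        return
    event, (xa, ra), (xb, rb) = choice
    event_map[v] = event
    a, b = v.children
    _backtrack(a, xa, ra, D, H, node_map, event_map)
    _backtrack(b, xb, rb, D, H, node_map, event_map)


# ---------------------------------------------------------------------------
# recount events from a solution's maps (integrity check)
# ---------------------------------------------------------------------------

def count_events(solution: ReconciliationSolution) -> EventCount:
    """Recompute the event-count vector from the node map alone.

    The event at each internal node is implied by the node map (the event
    definitions are exclusive); an event map inconsistent with the node map,
    or an infeasible node map, raises :class:`ReconciliationError`.
    """
    H = _HostIndex(solution.host)
    amap = solution.assoc.as_dict()
    ce = dup = sw = loss = 0
    for v in solution.virus.postorder():
        if v.is_leaf:
            mapped = solution.node_map[v]
            if mapped.label != amap[v.label]:
                raise ReconciliationError(
                    f"leaf {v.label!r} mapped to {mapped.label!r}, "
                    f"association says {amap[v.label]!r}"
                )
            continue
        h = H.index[id(solution.node_map[v])]
        a, b = v.children
        xa = H.index[id(solution.node_map[a])]
        xb = H.index[id(solution.node_map[b])]
        a_below = H.below[xa][h]
        b_below = H.below[xb][h]
        if a_below and b_below:
            kids = H.children[h]
            if kids is not None and (
                (H.below[xa][kids[0]] and H.below[xb][kids[1]])
                or (H.below[xa][kids[1]] and H.below[xb][kids[0]])
            ):
                event = CODIVERGENCE
                ce += 1
                la = kids[0] if H.below[xa][kids[0]] else kids[1]
                lb = kids[1] if la == kids[0] else kids[0]
                loss += H.dist_down(la, xa) + H.dist_down(lb, xb)
            else:
                event = DUPLICATION
                dup += 1
                loss += H.dist_down(h, xa) + H.dist_down(h, xb)
        else:
            inc_a = not a_below and not H.below[h][xa]
            inc_b = not b_below and not H.below[h][xb]
            if a_below and inc_b:
                event, stay = SWITCH, xa
            elif b_below and inc_a:
                event, stay = SWITCH, xb
            else:
                raise ReconciliationError(
                    "infeasible node map: child image neither below parent "
                    "image nor a valid switch landing"
                )
            sw += 1
            loss += H.dist_down(h, stay)
        if solution.event_map.get(v) != event:
            raise ReconciliationError(
                f"event map says {solution.event_map.get(v)!r}, "
                f"node map implies {event!r}"
            )
    counts = EventCount(ce, dup, sw, loss)
    n_internal = solution.virus.n_leaves - 1
    if ce + dup + sw != n_internal:
        raise ReconciliationError("event conservation violated")
    return counts


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_reconcile(
    virus: PhyloTree, host: PhyloTree, assoc: AssociationMap
) -> SolutionSet:
    """Exhaustively enumerate every feasible node map and return the Pareto
    frontier.  Independent of :func:`reconcile`; small trees only."""
    if virus.n_leaves > 8 or host.n_leaves > 8:
        raise ReconciliationError("brute force capped at 8 leaves per tree")
    amap = _check_assoc(virus, host, assoc)
    H = _HostIndex(host)
    vnodes = list(virus.postorder())
    internal = [v for v in vnodes if not v.is_leaf]
    assign: dict = {}
    events: dict = {}
    for v in vnodes:
        if v.is_leaf:
            assign[id(v)] = H.leaf_index[amap[v.label]]

    found: dict = {}

    def classify(h, xa, xb):
        """Return (event, losses) for a parent at h with child images xa, xb,
        or None if infeasible."""
        a_below = H.below[xa][h]
        b_below = H.below[xb][h]
        if a_below and b_below:
            kids = H.children[h]
            if kids is not None:
                hl, hr = kids
                if H.below[xa][hl] and H.below[xb][hr]:
                    return CODIVERGENCE, H.dist_down(hl, xa) + H.dist_down(hr, xb)
                if H.below[xa][hr] and H.below[xb][hl]:
                    return CODIVERGENCE, H.dist_down(hr, xa) + H.dist_down(hl, xb)
            return DUPLICATION, H.dist_down(h, xa) + H.dist_down(h, xb)
        inc_a = not a_below and not H.below[h][xa]
        inc_b = not b_below and not H.below[h][xb]
        if a_below and inc_b:
            return SWITCH, H.dist_down(h, xa)
        if b_below and inc_a:
            return SWITCH, H.dist_down(h, xb)
        return None

    def rec(i, ce, dup, sw, loss):
        if i == len(internal):
            vec = (ce, dup, sw, loss)
            if vec not in found:
                found[vec] = (dict(assign), dict(events))
            return
        v = internal[i]
        a, b = v.children
        xa, xb = assign[id(a)], assign[id(b)]
        for h in range(H.n):
            res = classify(h, xa, xb)
            if res is None:
                continue
            event, dl = res
            assign[id(v)] = h
            events[id(v)] = event
            rec(
                i + 1,
                ce + (event == CODIVERGENCE),
                dup + (event == DUPLICATION),
                sw + (event == SWITCH),
                loss + dl,
            )
        assign.pop(id(v), None)
        events.pop(id(v), None)

    # order internal nodes so children precede parents (postorder already does)
    rec(0, 0, 0, 0, 0)
    frontier = _pareto_filter(found.items())

    solutions = []
    for vec in sorted(
        frontier, key=lambda t: (-t[0], t[1] + t[2] + t[3], t[1], t[2])
    ):
        amap_nodes, emap_nodes = frontier[vec]
        node_map = {v: H.nodes[amap_nodes[id(v)]] for v in vnodes}
        event_map = {v: emap_nodes[id(v)] for v in internal}
        solutions.append(
            ReconciliationSolution(
                virus=virus,
                host=host,
                assoc=assoc,
                node_map=node_map,
                event_map=event_map,
                counts=EventCount(*vec),
            )
        )
    return SolutionSet(tuple(solutions))


# ---------------------------------------------------------------------------
# scalar summaries (used per randomization: best value per criterion)
# ---------------------------------------------------------------------------

def best_codivergence(virus: PhyloTree, host: PhyloTree, assoc: AssociationMap) -> int:
    """Maximum achievable codivergence count over all reconciliations."""
    amap = _check_assoc(virus, host, assoc)
    H = _HostIndex(host)
    NEG = -(10 ** 9)
    f: dict = {}
    for v in virus.postorder():
        if v.is_leaf:
            row = [NEG] * H.n
            row[H.leaf_index[amap[v.label]]] = 0
            f[id(v)] = row
            continue
        a, b = v.children
        fa, fb = f[id(a)], f[id(b)]
        fa_below = _best_below(fa, H)
        fb_below = _best_below(fb, H)
        fa_inc = _best_incomparable(fa, H)
        fb_inc = _best_incomparable(fb, H)
        row = [NEG] * H.n
        for h in range(H.n):
            best = NEG
            kids = H.children[h]
            if kids is not None:
                hl, hr = kids
                if fa_below[hl] > NEG and fb_below[hr] > NEG:
                    best = max(best, 1 + fa_below[hl] + fb_below[hr])
                if fa_below[hr] > NEG and fb_below[hl] > NEG:
                    best = max(best, 1 + fa_below[hr] + fb_below[hl])
            if fa_below[h] > NEG and fb_below[h] > NEG:
                best = max(best, fa_below[h] + fb_below[h])
            if fa_below[h] > NEG and fb_inc[h] > NEG:
                best = max(best, fa_below[h] + fb_inc[h])
            if fb_below[h] > NEG and fa_inc[h] > NEG:
                best = max(best, fb_below[h] + fa_inc[h])
            row[h] = best
        f[id(v)] = row
    return max(f[id(virus.root)])


def best_noncodivergence(
    virus: PhyloTree, host: PhyloTree, assoc: AssociationMap
) -> int:
    """Minimum achievable NCE count (duplications + switches + losses)."""
    amap = _check_assoc(virus, host, assoc)
    H = _HostIndex(host)
    INF = 10 ** 9
    g: dict = {}
    for v in virus.postorder():
        if v.is_leaf:
            row = [INF] * H.n
            row[H.leaf_index[amap[v.label]]] = 0
            g[id(v)] = row
            continue
        a, b = v.children
        ga, gb = g[id(a)], g[id(b)]
        ga_below = _min_below(ga, H)
        gb_below = _min_below(gb, H)
        ga_inc = _min_incomparable(ga, H)
        gb_inc = _min_incomparable(gb, H)
        row = [INF] * H.n
        for h in range(H.n):
            best = INF
            kids = H.children[h]
            if kids is not None:
                hl, hr = kids
                best = min(best, ga_below[hl] + gb_below[hr])
                best = min(best, ga_below[hr] + gb_below[hl])
            best = min(best, 1 + ga_below[h] + gb_below[h])
            best = min(best, 1 + ga_below[h] + gb_inc[h])
            best = min(best, 1 + gb_below[h] + ga_inc[h])
            row[h] = best
        g[id(v)] = row
    return min(g[id(virus.root)])


def _best_below(row, H: _HostIndex):
    NEG = -(10 ** 9)
    return [
        max((row[x] for x in H.descendants[h]), default=NEG) for h in range(H.n)
    ]


def _best_incomparable(row, H: _HostIndex):
    NEG = -(10 ** 9)
    return [
        max((row[y] for y in H.incomparables[h]), default=NEG) for h in range(H.n)
    ]


def _min_below(row, H: _HostIndex):
    INF = 10 ** 9
    out = []
    for h in range(H.n):
        best = INF
        for x in H.descendants[h]:
            if row[x] < INF:
                best = min(best, row[x] + H.dist_down(h, x))
        out.append(best)
    return out


def _min_incomparable(row, H: _HostIndex):
    INF = 10 ** 9
    return [
        min((row[y] for y in H.incomparables[h]), default=INF) for h in range(H.n)
    ]
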