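"""Event-based maximum-parsimony reconciliation (MPR) of a symbiont tree
onto a host tree.

The model is the classical undated event scheme: each internal symbiont
node is explained by exactly one of

* **codivergence** — the symbiont splits with a host split, its two
  children descending into the two host child subtrees;
* **duplication** — the symbiont splits on a single host lineage, both
  children staying at or below that host node;
* **switch** — one child stays on the donor lineage, the other jumps to
  any host node not ancestrally comparable with the donor;

plus **losses**, one per host edge a symbiont lineage traverses without
diverging. A dynamic program over (symbiont node x host node) computes
the minimum total cost; the backtrace reports one optimal reconciliation
under a deterministic tie-break and the number of co-optimal solutions.

Because the scheme is undated, a switch may create a temporally cyclic
scenario; :func:`is_time_consistent` flags those post hoc.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import dendropy
import pandas as pd

from .errors import PhiError, TreeStructureError, ValidationError
from .trees import leaf_labels, read_newick, tree_from_string

__all__ = [
    "Tanglegram",
    "EventCosts",
    "Event",
    "Reconciliation",
    "mpr_cost",
    "backtrace",
    "reconcile",
    "count_events",
    "is_time_consistent",
    "read_phi",
    "write_phi",
    "write_events",
]

_INF = math.inf

EVENT_TYPES = ("codivergence", "duplication", "switch", "loss")


@dataclass(frozen=True)
class EventCosts:
    """Per-event parsimony costs; defaults (0, 1, 1, 1)."""

    cospeciation: float = 0.0
    duplication: float = 1.0
    switch: float = 1.0
    loss: float = 1.0

    def __post_init__(self) -> None:
        for name in ("duplication", "switch", "loss"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValidationError(f"{name} cost must be finite and > 0, got {v}")
        if not (self.cospeciation >= 0 and math.isfinite(self.cospeciation)):
            raise ValidationError(
                f"cospeciation cost must be finite and >= 0, got {self.cospeciation}"
            )


class _IndexedTree:
    """Binary tree flattened to postorder-indexed arrays."""

    def __init__(self, tree: dendropy.Tree):
        self.labels: list[str] = []
        self.children: list[tuple[int, int] | None] = []
        self.postorder: list[int] = []
        self.parent: list[int | None] = []
        self.leaf_index: dict[str, int] = {}

        def label_of(node: dendropy.Node) -> str:
            if node.taxon is not None and node.taxon.label:
                return node.taxon.label
            return node.label or ""

        def min_leaf(node: dendropy.Node) -> str:
            return min(label_of(l) for l in node.leaf_iter())

        def build(node: dendropy.Node) -> int:
            kids = node.child_nodes()
            if len(kids) == 0:
                idx = len(self.labels)
                lab = label_of(node)
                self.labels.append(lab)
                self.children.append(None)
                self.parent.append(None)
                self.leaf_index[lab] = idx
            elif len(kids) == 2:
                ordered = sorted(kids, key=min_leaf)
                c1 = build(ordered[0])
                c2 = build(ordered[1])
                idx = len(self.labels)
                leaves = sorted(label_of(l) for l in node.leaf_iter())
                self.labels.append(
                    node.label or f"mrca({leaves[0]},{leaves[-1]})"
                )
                self.children.append((c1, c2))
                self.parent.append(None)
                self.parent[c1] = idx
                self.parent[c2] = idx
            else:
                raise TreeStructureError(
                    f"non-binary node with {len(kids)} children"
                )
            self.postorder.append(idx)
            return idx

        self.root = build(tree.seed_node)
        self.n = len(self.labels)

        # ancestry tables: desc[a][b] iff b is in the subtree of a
        self.desc = [[False] * self.n for _ in range(self.n)]
        self.dist = [[-1] * self.n for _ in range(self.n)]
        for a in self.postorder:
            self.desc[a][a] = True
            self.dist[a][a] = 0
            if self.children[a] is not None:
                for c in self.children[a]:
                    for b in range(self.n):
                        if self.desc[c][b]:
                            self.desc[a][b] = True
                            self.dist[a][b] = self.dist[c][b] + 1
        self.incomparable = [
            [b for b in range(self.n) if not self.desc[a][b] and not self.desc[b][a]]
            for a in range(self.n)
        ]

    def is_leaf(self, idx: int) -> bool:
        return self.children[idx] is None


@dataclass
class Tanglegram:
    """Host tree, symbiont tree, and the symbiont-leaf -> host-leaf map."""

    host_tree: dendropy.Tree
    symbiont_tree: dendropy.Tree
    phi: dict[str, str]

    def __post_init__(self) -> None:
        host_leaves = set(leaf_labels(self.host_tree))
        sym_leaves = set(leaf_labels(self.symbiont_tree))
        missing = sorted(sym_leaves - set(self.phi))
        if missing:
            raise PhiError(f"phi missing symbiont leaves: {missing}")
        extra = sorted(set(self.phi) - sym_leaves)
        if extra:
            raise PhiError(f"phi maps unknown symbiont leaves: {extra}")
        bad = sorted(h for h in self.phi.values() if h not in host_leaves)
        if bad:
            raise PhiError(f"phi targets outside host leaves: {bad}")

    @classmethod
    def from_strings(
        cls, host_newick: str, symbiont_newick: str, phi: dict[str, str]
    ) -> "Tanglegram":
        return cls(
            host_tree=tree_from_string(host_newick),
            symbiont_tree=tree_from_string(symbiont_newick),
            phi=dict(phi),
        )

    @classmethod
    def from_files(
        cls, host_path: str | Path, symbiont_path: str | Path, phi_path: str | Path
    ) -> "Tanglegram":
        return cls(
            host_tree=read_newick(host_path),
            symbiont_tree=read_newick(symbiont_path),
            phi=read_phi(phi_path),
        )


@dataclass(frozen=True)
class Event:
    """One reconciliation event; ``target`` is the switch landing site."""

    symbiont: str
    type: str
    host: str
    target: str | None = None


@dataclass(frozen=True)
class Reconciliation:
    mapping: dict[str, str]
    events: tuple[Event, ...]
    counts: dict[str, int]
    total_cost: float
    n_optimal: int
    costs: EventCosts

    def __post_init__(self) -> None:
        weighted = (
            self.counts["codivergence"] * self.costs.cospeciation
            + self.counts["duplication"] * self.costs.duplication
            + self.counts["switch"] * self.costs.switch
            + self.counts["loss"] * self.costs.loss
        )
        if not math.isclose(weighted, self.total_cost, abs_tol=1e-9):
            raise ValidationError(
                f"event census cost {weighted} != reported optimum {self.total_cost}"
            )


class MPRTables:
    """DP cost tables; also the backtrace workspace.

    ``cost[s][h]`` is the minimal cost of the symbiont subtree at ``s``
    when ``s`` is mapped exactly to host node ``h``; ``inc`` allows the
    lineage to first descend (paying losses); ``outc`` is the cheapest
    landing cost on any host incomparable with ``h``.
    """

    def __init__(self, tanglegram: Tanglegram, costs: EventCosts):
        self.costs = costs
        self.host = _IndexedTree(tanglegram.host_tree)
        self.sym = _IndexedTree(tanglegram.symbiont_tree)
        self.phi_idx = {
            self.sym.leaf_index[s]: self.host.leaf_index[h]
            for s, h in tanglegram.phi.items()
        }
        self._run()

    def _run(self) -> None:
        H, S = self.host, self.sym
        nh, ns = H.n, S.n
        c = self.costs
        self.cost = [[_INF] * nh for _ in range(ns)]
        self.inc = [[_INF] * nh for _ in range(ns)]
        self.outc = [[_INF] * nh for _ in range(ns)]
        self.ncost = [[0] * nh for _ in range(ns)]
        self.ninc = [[0] * nh for _ in range(ns)]
        self.noutc = [[0] * nh for _ in range(ns)]

        for s in S.postorder:
            if S.is_leaf(s):
                h0 = self.phi_idx[s]
                self.cost[s][h0] = 0.0
                self.ncost[s][h0] = 1
            else:
                u, v = S.children[s]  # type: ignore[misc]
                for h in range(nh):
                    best, nbest = _INF, 0
                    for value, count in self._options(s, u, v, h):
                        if value < best:
                            best, nbest = value, count
                        elif value == best and value < _INF:
                            nbest += count
                    self.cost[s][h] = best
                    self.ncost[s][h] = nbest
            # inc over host postorder (children before parents)
            for h in H.postorder:
                best = self.cost[s][h]
                nbest = self.ncost[s][h]
                if H.children[h] is not None:
                    for hc in H.children[h]:
                        val = self.inc[s][hc] + c.loss
                        if val < best:
                            best, nbest = val, self.ninc[s][hc]
                        elif val == best and val < _INF:
                            nbest += self.ninc[s][hc]
                self.inc[s][h] = best
                self.ninc[s][h] = nbest
            for h in range(nh):
                best, nbest = _INF, 0
                for h2 in H.incomparable[h]:
                    val = self.cost[s][h2]
                    if val < best:
                        best, nbest = val, self.ncost[s][h2]
                    elif val == best and val < _INF:
                        nbest += self.ncost[s][h2]
                self.outc[s][h] = best
                self.noutc[s][h] = nbest

        root = S.root
        self.optimum = min(self.cost[root])
        self.n_optimal = sum(
            self.ncost[root][h] for h in range(nh) if self.cost[root][h] == self.optimum
        )

    def _options(
        self, s: int, u: int, v: int, h: int
    ) -> Iterable[tuple[float, int]]:
        """Candidate (cost, multiplicity) alternatives for node s at host h,
        in deterministic preference order: codivergence, duplication, switch."""
        H, c = self.host, self.costs
        if H.children[h] is not None:
            hl, hr = H.children[h]
            yield (
                c.cospeciation + self.inc[u][hl] + self.inc[v][hr],
                self.ninc[u][hl] * self.ninc[v][hr],
            )
            yield (
                c.cospeciation + self.inc[u][hr] + self.inc[v][hl],
                self.ninc[u][hr] * self.ninc[v][hl],
            )
        yield (
            c.duplication + self.inc[u][h] + self.inc[v][h],
            self.ninc[u][h] * self.ninc[v][h],
        )
        yield (
            c.switch + self.inc[u][h] + self.outc[v][h],
            self.ninc[u][h] * self.noutc[v][h],
        )
        yield (
            c.switch + self.inc[v][h] + self.outc[u][h],
            self.ninc[v][h] * self.noutc[u][h],
        )

    def as_dict(self) -> dict[tuple[str, str], float]:
        return {
            (self.sym.labels[s], self.host.labels[h]): self.cost[s][h]
            for s in range(self.sym.n)
            for h in range(self.host.n)
        }


def mpr_cost(tanglegram: Tanglegram, costs: EventCosts | None = None) -> MPRTables:
    """Fill the (symbiont node x host node) minimal-cost table."""
    return MPRTables(tanglegram, costs or EventCosts())


def backtrace(
    tanglegram: Tanglegram,
    costs: EventCosts | None = None,
    tables: MPRTables | None = None,
) -> Reconciliation:
    """Extract one optimal reconciliation with deterministic tie-breaks.

    Preference order at equal cost: codivergence > duplication > switch;
    descent chains stop as early as possible; remaining ties resolve to
    the lexicographically smallest host label.
    """
    costs = costs or EventCosts()
    t = tables if tables is not None else mpr_cost(tanglegram, costs)
    H, S, c = t.host, t.sym, t.costs
    events: list[Event] = []
    mapping: dict[str, str] = {}

    def host_order(candidates: list[int]) -> int:
        return min(candidates, key=lambda h: H.labels[h])

    def emit(s: int, h: int) -> None:
        mapping[S.labels[s]] = H.labels[h]
        if S.is_leaf(s):
            return
        u, v = S.children[s]  # type: ignore[misc]
        target = t.cost[s][h]
        # codivergence (both orientations)
        if H.children[h] is not None:
            hl, hr = H.children[h]
            if c.cospeciation + t.inc[u][hl] + t.inc[v][hr] == target:
                events.append(Event(S.labels[s], "codivergence", H.labels[h]))
                resolve_in(u, hl)
                resolve_in(v, hr)
                return
            if c.cospeciation + t.inc[u][hr] + t.inc[v][hl] == target:
                events.append(Event(S.labels[s], "codivergence", H.labels[h]))
                resolve_in(u, hr)
                resolve_in(v, hl)
                return
        if c.duplication + t.inc[u][h] + t.inc[v][h] == target:
            events.append(Event(S.labels[s], "duplication", H.labels[h]))
            resolve_in(u, h)
            resolve_in(v, h)
            return
        for stay, moved in ((u, v), (v, u)):
            if c.switch + t.inc[stay][h] + t.outc[moved][h] == target:
                landing = host_order(
                    [
                        h2
                        for h2 in H.incomparable[h]
                        if t.cost[moved][h2] == t.outc[moved][h]
                    ]
                )
                events.append(
                    Event(S.labels[s], "switch", H.labels[h], H.labels[landing])
                )
                resolve_in(stay, h)
                emit(moved, landing)
                return
        raise AssertionError("backtrace found no achieving option")  # pragma: no cover

    def resolve_in(s: int, h: int) -> None:
        # follow the loss chain from h down to the node where s maps exactly
        while t.cost[s][h] != t.inc[s][h]:
            candidates = [
                hc
                for hc in H.children[h]  # type: ignore[union-attr]
                if t.inc[s][hc] + c.loss == t.inc[s][h]
            ]
            h_next = host_order(candidates)
            events.append(Event(S.labels[s], "loss", H.labels[h_next]))
            h = h_next
        emit(s, h)

    root = S.root
    start = host_order(
        [h for h in range(H.n) if t.cost[root][h] == t.optimum]
    )
    emit(root, start)

    counts = {etype: 0 for etype in EVENT_TYPES}
    for ev in events:
        counts[ev.type] += 1
    n_internal = sum(1 for s in range(S.n) if not S.is_leaf(s))
    assert (
        counts["codivergence"] + counts["duplication"] + counts["switch"] == n_internal
    )
    return Reconciliation(
        mapping=mapping,
        events=tuple(events),
        counts=counts,
        total_cost=t.optimum,
        n_optimal=t.n_optimal,
        costs=c,
    )


def reconcile(tanglegram: Tanglegram, costs: EventCosts | None = None) -> Reconciliation:
    """Convenience: DP plus backtrace in one call."""
    costs = costs or EventCosts()
    return backtrace(tanglegram, costs, mpr_cost(tanglegram, costs))


def count_events(rec: Reconciliation) -> dict[str, int]:
    """Recount the per-type event census from the event list."""
    counts = {etype: 0 for etype in EVENT_TYPES}
    for ev in rec.events:
        counts[ev.type] += 1
    return counts


def is_time_consistent(rec: Reconciliation, tanglegram: Tanglegram) -> bool:
    """Necessary-condition check that switches admit a host-time ordering.

    Builds a precedence digraph (host parent precedes child; a switch
    requires donor and recipient lineages to overlap in time, so each
    switch adds parent(recipient) -> donor and parent(donor) ->
    recipient) and reports whether it is acyclic.
    """
    H = _IndexedTree(tanglegram.host_tree)
    label_to_idx = {lab: i for i, lab in enumerate(H.labels)}
    edges: set[tuple[int, int]] = set()
    for h in range(H.n):
        if H.children[h] is not None:
            for hc in H.children[h]:
                edges.add((h, hc))
    for ev in rec.events:
        if ev.type != "switch" or ev.target is None:
            continue
        d = label_to_idx[ev.host]
        r = label_to_idx[ev.target]
        for a, b in ((H.parent[r], d), (H.parent[d], r)):
            if a is not None and a != b:
                edges.add((a, b))
    adj: dict[int, list[int]] = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
    WHITE, GREY, BLACK = 0, 1, 2
    state = [WHITE] * H.n

    def dfs(node: int) -> bool:
        state[node] = GREY
        for nxt in adj.get(node, ()):
            if state[nxt] == GREY:
                return False
            if state[nxt] == WHITE and not dfs(nxt):
                return False
        state[node] = BLACK
        return True

    return all(dfs(n) for n in range(H.n) if state[n] == WHITE)


# -- I/O -------------------------------------------------------------------

def read_phi(path: str | Path) -> dict[str, str]:
    """Two-column TSV: symbiont leaf, host leaf."""
    df = pd.read_csv(Path(path), sep="\t", dtype=str, keep_default_na=False)
    cols = list(df.columns)
    if len(cols) < 2:
        raise PhiError(f"{path}: expected two columns (symbiont, host)")
    phi: dict[str, str] = {}
    for row in df.itertuples(index=False):
        sym, host = row[0], row[1]
        if sym in phi:
            raise PhiError(f"{path}: symbiont leaf {sym!r} mapped twice")
        phi[sym] = host
    return phi


def write_phi(phi: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        sorted(phi.items()), columns=["symbiont", "host"]
    ).to_csv(Path(path), sep="\t", index=False)


def write_events(rec: Reconciliation, events_path: str | Path, census_path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "symbiont": ev.symbiont,
                "event": ev.type,
                "host": ev.host,
                "target": ev.target or "",
            }
            for ev in rec.events
        ],
        columns=["symbiont", "event", "host", "target"],
    ).to_csv(Path(events_path), sep="\t", index=False)
    Path(census_path).write_text(
        json.dumps(
            {
                "counts": rec.counts,
                "total_cost": rec.total_cost,
                "n_optimal": rec.n_optimal,
                "costs": {
                    "cospeciation": rec.costs.cospeciation,
                    "duplication": rec.costs.duplication,
                    "switch": rec.costs.switch,
                    "loss": rec.costs.loss,
                },
            },
            indent=2,
        )
        + "\n"
    )
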