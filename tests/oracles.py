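"""Independent oracles used by the test suite.

Everything here is deliberately written against the *naive* definition
of each quantity (exhaustive enumeration, per-host scans, direct graph
components) and never calls the implementation paths it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from hostswitch.occurrence import (
    Category,
    EcologicalGroup,
    HostIndividual,
    MiteTaxonProfile,
    OccurrenceDataset,
    OccurrenceRecord,
    SampleSource,
)
from hostswitch.reconcile import EventCosts, Tanglegram

# -- exhaustive reconciliation oracle -------------------------------------


def _label(node) -> str:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    return node.label or ""


def _is_anc_or_eq(a, b) -> bool:
    while b is not None:
        if b is a:
            return True
        b = b.parent_node
    return False


def _down_dist(a, b) -> int:
    d = 0
    while b is not a:
        b = b.parent_node
        d += 1
    return d


def brute_force_optimum(tanglegram: Tanglegram, costs: EventCosts) -> float:
    """Minimum reconciliation cost by enumerating all internal mappings.

    For each full symbiont-node -> host-node mapping the cheapest
    feasible event label is charged at every internal symbiont node
    (codivergence into distinct host child subtrees; duplication with
    both children at/below the host; switch with one child retained and
    one landing on an incomparable host), plus one loss per traversed
    host edge. Feasible only at <= 6 symbiont leaves.
    """
    hnodes = list(tanglegram.host_tree.preorder_node_iter())
    snodes_post = list(tanglegram.symbiont_tree.postorder_node_iter())
    internal = [s for s in snodes_post if s.child_nodes()]
    host_by_label = {_label(n): n for n in hnodes if not n.child_nodes()}

    def node_cost(h, h1, h2) -> float:
        best = math.inf
        kids = h.child_nodes()
        if kids:
            cl, cr = kids
            if (_is_anc_or_eq(cl, h1) and _is_anc_or_eq(cr, h2)) or (
                _is_anc_or_eq(cl, h2) and _is_anc_or_eq(cr, h1)
            ):
                best = min(
                    best,
                    costs.cospeciation
                    + costs.loss * (_down_dist(h, h1) - 1 + _down_dist(h, h2) - 1),
                )
        if _is_anc_or_eq(h, h1) and _is_anc_or_eq(h, h2):
            best = min(
                best,
                costs.duplication
                + costs.loss * (_down_dist(h, h1) + _down_dist(h, h2)),
            )
        for stay, moved in ((h1, h2), (h2, h1)):
            if _is_anc_or_eq(h, stay) and not (
                _is_anc_or_eq(h, moved) or _is_anc_or_eq(moved, h)
            ):
                best = min(best, costs.switch + costs.loss * _down_dist(h, stay))
        return best

    best_total = math.inf
    for assignment in itertools.product(hnodes, repeat=len(internal)):
        placed = {id(s): h for s, h in zip(internal, assignment)}
        for s in snodes_post:
            if not s.child_nodes():
                placed[id(s)] = host_by_label[tanglegram.phi[_label(s)]]
        total = 0.0
        for s in internal:
            c1, c2 = s.child_nodes()
            total += node_cost(placed[id(s)], placed[id(c1)], placed[id(c2)])
            if total >= best_total:
                break
        best_total = min(best_total, total)
    return best_total


# -- random tanglegrams ----------------------------------------------------


def random_binary_newick(labels: list[str], rng: np.random.Generator) -> str:
    """Uniformly random binary topology by sequential random joins."""
    parts = list(labels)
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        merged = f"({parts[i]},{parts[j]})"
        parts = [p for k, p in enumerate(parts) if k not in (i, j)] + [merged]
    return parts[0] + ";"


def random_tanglegram(
    n_host: int, n_sym: int, rng: np.random.Generator
) -> Tanglegram:
    hosts = [f"h{i}" for i in range(n_host)]
    syms = [f"s{i}" for i in range(n_sym)]
    phi = {s: hosts[int(rng.integers(n_host))] for s in syms}
    return Tanglegram.from_strings(
        random_binary_newick(hosts, rng), random_binary_newick(syms, rng), phi
    )


# -- naive co-occurrence scan ---------------------------------------------


def naive_cooccurrence(dataset: OccurrenceDataset):
    """Per-host set scan: (host combination counts, per-combination record
    counts split by category). Independent of rates.cooccurrence_table."""
    letter = {
        Category.SPECIFIC: "S",
        Category.ALIEN: "A",
        Category.QSM: "Q",
    }
    host_counts: dict[str, int] = {}
    record_counts: dict[str, dict[str, int]] = {}
    for host in dataset.hosts:
        cats = sorted(
            {letter[dataset.taxa[r.taxon].category] for r in dataset.records if r.host_id == host},
            key="SAQ".index,
        )
        key = "+".join(cats) if cats else "none"
        host_counts[key] = host_counts.get(key, 0) + 1
        rc = record_counts.setdefault(key, {"specific": 0, "alien": 0, "qsm": 0})
        for r in dataset.records:
            if r.host_id == host:
                rc[dataset.taxa[r.taxon].category.value] += 1
    return host_counts, record_counts


def random_dataset(rng: np.random.Generator) -> OccurrenceDataset:
    """Small random occurrence dataset over all three categories."""
    n_hosts = int(rng.integers(3, 15))
    n_taxa = int(rng.integers(2, 8))
    cats = [Category.SPECIFIC, Category.ALIEN, Category.QSM]
    taxa = {}
    for t in range(n_taxa):
        cat = cats[int(rng.integers(3))]
        group = (
            EcologicalGroup.QUILL_SKIN if cat is Category.QSM else EcologicalGroup.VANE
        )
        name = f"t{t}"
        taxa[name] = MiteTaxonProfile(name, "G", "F", group, cat)
    hosts = {
        f"h{i}": HostIndividual(f"h{i}", "Focalis hostis", SampleSource.WILD_CAPTURE)
        for i in range(n_hosts)
    }
    records = []
    for h in hosts:
        for t in taxa:
            if rng.random() < 0.3:
                records.append(OccurrenceRecord(h, t, int(rng.integers(1, 6))))
    return OccurrenceDataset(hosts=hosts, taxa=taxa, records=records)


# -- thresholded-graph components (delimitation oracle) --------------------


def graph_components(labels, values, threshold) -> set[frozenset]:
    """Connected components of the graph with edges d <= threshold (DSU)."""
    parent = {l: l for l in labels}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            if values[i][j] <= threshold:
                parent[find(labels[i])] = find(labels[j])
    groups: dict[str, set] = {}
    for l in labels:
        groups.setdefault(find(l), set()).add(l)
    return {frozenset(g) for g in groups.values()}
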