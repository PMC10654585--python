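"""Rooted binary tree I/O (Newick) with strict validation.

Reconciliation assumes fully bifurcating rooted trees, so polytomies and
unifurcations are rejected at parse time with a message naming the
offending clade. Writing is canonical: children are ordered by their
smallest descendant leaf label, making round-trips byte-deterministic.
"""

from __future__ import annotations

from pathlib import Path

import dendropy

from .errors import NewickParseError, TreeStructureError

__all__ = ["read_newick", "tree_from_string", "write_newick", "to_newick", "leaf_labels"]


def _clade_name(node: dendropy.Node) -> str:
    leaves = sorted(_leaf_label(l) for l in node.leaf_iter())
    if len(leaves) > 4:
        return "(" + ",".join(leaves[:4]) + ",...)"
    return "(" + ",".join(leaves) + ")"


def _leaf_label(node: dendropy.Node) -> str:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    return node.label or ""


def _validate(tree: dendropy.Tree) -> dendropy.Tree:
    labels: list[str] = []
    for node in tree.preorder_node_iter():
        n_children = len(node.child_nodes())
        if n_children == 0:
            label = _leaf_label(node)
            if not label:
                raise NewickParseError("leaf with empty label")
            labels.append(label)
        elif n_children == 1:
            raise TreeStructureError(f"unifurcation at clade {_clade_name(node)}")
        elif n_children > 2:
            raise TreeStructureError(
                f"polytomy ({n_children} children) at clade {_clade_name(node)}"
            )
    dupes = sorted({l for l in labels if labels.count(l) > 1})
    if dupes:
        raise NewickParseError(f"duplicate leaf label(s): {dupes}")
    if len(labels) < 2:
        raise TreeStructureError("tree must have at least two leaves")
    return tree


def tree_from_string(newick: str) -> dendropy.Tree:
    """Parse a single rooted binary tree from a Newick string."""
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickParseError(f"malformed newick: {exc}") from exc
    return _validate(tree)


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read exactly one rooted binary tree from a Newick file."""
    path = Path(path)
    try:
        trees = dendropy.TreeList.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise NewickParseError(f"{path}: malformed newick: {exc}") from exc
    if len(trees) != 1:
        raise NewickParseError(f"{path}: expected exactly one tree, found {len(trees)}")
    return _validate(trees[0])


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [_leaf_label(l) for l in tree.leaf_node_iter()]


def _min_leaf(node: dendropy.Node) -> str:
    return min(_leaf_label(l) for l in node.leaf_iter())


def _to_newick(node: dendropy.Node) -> str:
    children = node.child_nodes()
    if not children:
        out = _leaf_label(node)
    else:
        parts = sorted((_min_leaf(c), _to_newick(c)) for c in children)
        out = "(" + ",".join(p[1] for p in parts) + ")"
        if node.label:
            out += node.label
    if node.edge.length is not None:
        out += f":{node.edge.length:g}"
    return out


def to_newick(tree: dendropy.Tree) -> str:
    """Render with canonical child ordering (by smallest leaf label)."""
    return _to_newick(tree.seed_node) + ";"


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(to_newick(tree) + "\n")
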