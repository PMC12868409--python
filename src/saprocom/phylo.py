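"""Phylogeny handling: Newick IO, grafting, cophenetic distances.

The reference phylogeny for the species pool may be missing a few
community species; those are grafted as sister tips next to their
closest known relative.  Distances between tips are cophenetic (total
branch length along the connecting path).  Trees are handled through
dendropy; polytomies and non-ultrametric trees are allowed.
"""

from __future__ import annotations

import dendropy
import numpy as np
import pandas as pd

__all__ = ["read_newick", "write_newick", "graft_missing", "cophenetic_distance",
           "tip_labels"]


def read_newick(source) -> dendropy.Tree:
    """Read a rooted Newick tree (path or string)."""
    if isinstance(source, str) and source.lstrip().startswith("("):
        tree = dendropy.Tree.get(data=source, schema="newick")
    else:
        tree = dendropy.Tree.get(path=str(source), schema="newick")
    labels = tip_labels(tree)
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate tip labels")
    return tree


def write_newick(tree: dendropy.Tree, path=None) -> str:
    s = tree.as_string(schema="newick", suppress_rooting=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s)
    return s


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def graft_missing(tree: dendropy.Tree, species_id: str, relative_id: str,
                  epsilon: float = 0.0) -> dendropy.Tree:
    """Attach ``species_id`` as sister to the tip ``relative_id``.

    A new internal node is inserted ``epsilon`` above the relative tip;
    both the relative and the new tip hang from it with pendant length
    ``epsilon``, so all tip depths — and hence all distances among
    pre-existing tips — are preserved.  With ``epsilon = 0`` the new
    species occupies exactly its relative's position in the tree.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    tree = tree.clone(depth=1)
    labels = set(tip_labels(tree))
    if species_id in labels:
        raise ValueError(f"{species_id!r} already present in tree")
    if relative_id not in labels:
        raise ValueError(f"relative {relative_id!r} is not a tip")
    rel = next(lf for lf in tree.leaf_node_iter() if lf.taxon.label == relative_id)
    pend = rel.edge.length if rel.edge.length is not None else 0.0
    if pend < epsilon:
        raise ValueError(
            f"relative pendant length {pend} shorter than epsilon {epsilon}")
    parent = rel.parent_node
    parent.remove_child(rel)
    joint = parent.new_child(edge_length=pend - epsilon)
    rel.edge.length = epsilon
    joint.add_child(rel)
    taxon = dendropy.Taxon(label=species_id)
    tree.taxon_namespace.add_taxon(taxon)
    joint.new_child(taxon=taxon, edge_length=epsilon)
    return tree


def cophenetic_distance(tree: dendropy.Tree,
                        species_subset=None) -> pd.DataFrame:
    """Pairwise path-length (cophenetic) distance matrix between tips.

    Computed from tip depths and lowest-common-ancestor depths:
    d(i, j) = depth(i) + depth(j) - 2 * depth(lca(i, j)), which equals
    the sum of branch lengths along the path.  Returns a symmetric
    DataFrame with zero diagonal, ordered by ``species_subset`` if
    given, else by sorted tip label.
    """
    labels = tip_labels(tree)
    if species_subset is None:
        species_subset = sorted(labels)
    unknown = set(species_subset) - set(labels)
    if unknown:
        raise KeyError(f"species not in tree: {sorted(unknown)[:5]}")
    # depth of every node from the root
    depth: dict[int, float] = {}
    order: dict[int, int] = {}
    for i, node in enumerate(tree.preorder_node_iter()):
        el = node.edge.length or 0.0
        depth[id(node)] = (depth[id(node.parent_node)] + el
                           if node.parent_node is not None else 0.0)
        order[id(node)] = i
    leaf_of = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    # ancestor chains per requested tip (pool sizes here are small)
    chains = {}
    for lab in species_subset:
        chain = []
        node = leaf_of[lab]
        while node is not None:
            chain.append(id(node))
            node = node.parent_node
        chains[lab] = set(chain)
    n = len(species_subset)
    out = np.zeros((n, n))
    for i in range(n):
        a = species_subset[i]
        for j in range(i + 1, n):
            b = species_subset[j]
            common = chains[a] & chains[b]
            lca_depth = max(depth[c] for c in common)
            d = depth[id(leaf_of[a])] + depth[id(leaf_of[b])] - 2.0 * lca_depth
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=list(species_subset), columns=list(species_subset))


def read_graft_list(path) -> list[tuple[str, str]]:
    """CSV with columns species_id, relative_id."""
    df = pd.read_csv(path)
    return list(zip(df["species_id"], df["relative_id"]))


def graft_all(tree: dendropy.Tree, grafts, epsilon: float = 0.0) -> dendropy.Tree:
    for species_id, relative_id in grafts:
        tree = graft_missing(tree, species_id, relative_id, epsilon=epsilon)
    return tree
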