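"""Gene-tree / species-tree reconciliation by LCA (parsimony) mapping.

Each gene-tree node is mapped to the last common ancestor, in the
species tree, of the species its descendant genes belong to.  A gene
node is a duplication iff it maps to the same species node as one of
its children.  Losses are counted edge-wise: for a gene-tree edge whose
endpoints map d species-tree edges apart, the lineage silently skipped
d-1 speciations (d at a duplication parent), each implying one lost
copy in the sibling subtree it failed to reach.  Duplication/loss costs
are the unit parsimony costs; rearrangement of weakly supported edges
is deliberately not performed.

Both trees must be rooted and strictly binary; polytomies are rejected
rather than resolved, since any resolution policy would silently change
the counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

from .io_formats import is_binary


@dataclass
class ReconciliationResult:
    """Per-species-node duplication and loss counts plus totals.

    Species nodes are keyed by their label (leaf taxon label, or the
    sorted leaf labels joined with ``|`` for unlabeled internal nodes).
    """

    duplications: dict[str, int] = field(default_factory=dict)
    losses: dict[str, int] = field(default_factory=dict)
    total_duplications: int = 0
    total_losses: int = 0


def _require_binary(tree: dendropy.Tree, what: str) -> None:
    if not is_binary(tree):
        raise ValueError(f"{what} is not strictly binary")


def species_node_key(node: dendropy.Node) -> str:
    """Stable printable key for a species-tree node."""
    if node.is_leaf():
        return node.taxon.label
    if node.label:
        return node.label
    return "|".join(sorted(l.taxon.label for l in node.leaf_iter()))


def _index_species_tree(species_tree: dendropy.Tree):
    """Precompute per-node depth and parent for LCA walks."""
    depth: dict[int, int] = {}
    parent: dict[int, dendropy.Node] = {}
    for node in species_tree.preorder_node_iter():
        if node.parent_node is None:
            depth[id(node)] = 0
        else:
            depth[id(node)] = depth[id(node.parent_node)] + 1
            parent[id(node)] = node.parent_node
    leaf_by_label = {l.taxon.label: l for l in species_tree.leaf_node_iter()}
    return depth, parent, leaf_by_label


def _lca(a: dendropy.Node, b: dendropy.Node, depth, parent) -> dendropy.Node:
    while a is not b:
        if depth[id(a)] < depth[id(b)]:
            b = parent[id(b)]
        elif depth[id(a)] > depth[id(b)]:
            a = parent[id(a)]
        else:
            a, b = parent[id(a)], parent[id(b)]
    return a


def lca_map(
    gene_tree: dendropy.Tree,
    species_tree: dendropy.Tree,
    leaf_species_map: dict[str, str],
) -> dict[dendropy.Node, dendropy.Node]:
    """Map every gene-tree node to its species-tree LCA.

    ``leaf_species_map`` sends each gene-tree leaf label to a species
    leaf label.  Unmapped leaves and non-binary trees raise.
    """
    _require_binary(gene_tree, "gene tree")
    _require_binary(species_tree, "species tree")
    depth, parent, leaf_by_label = _index_species_tree(species_tree)

    mapping: dict[dendropy.Node, dendropy.Node] = {}
    for node in gene_tree.postorder_node_iter():
        if node.is_leaf():
            gene = node.taxon.label
            if gene not in leaf_species_map:
                raise KeyError(f"gene-tree leaf {gene!r} has no species mapping")
            species = leaf_species_map[gene]
            if species not in leaf_by_label:
                raise KeyError(
                    f"species {species!r} (leaf {gene!r}) not in the species tree"
                )
            mapping[node] = leaf_by_label[species]
        else:
            children = node.child_nodes()
            m = mapping[children[0]]
            for child in children[1:]:
                m = _lca(m, mapping[child], depth, parent)
            mapping[node] = m
    return mapping


def count_duplications_losses(
    gene_tree: dendropy.Tree,
    species_tree: dendropy.Tree,
    leaf_species_map: dict[str, str],
) -> ReconciliationResult:
    """Parsimony duplication and loss counts from the LCA mapping."""
    mapping = lca_map(gene_tree, species_tree, leaf_species_map)
    depth, parent, _ = _index_species_tree(species_tree)

    result = ReconciliationResult()
    for node in species_tree.preorder_node_iter():
        key = species_node_key(node)
        result.duplications[key] = 0
        result.losses[key] = 0

    is_dup: dict[dendropy.Node, bool] = {}
    for node in gene_tree.preorder_node_iter():
        if node.is_leaf():
            is_dup[node] = False
            continue
        m = mapping[node]
        dup = any(mapping[c] is m for c in node.child_nodes())
        is_dup[node] = dup
        if dup:
            result.duplications[species_node_key(m)] += 1
            result.total_duplications += 1

    for node in gene_tree.preorder_node_iter():
        if node.is_leaf():
            continue
        mu = mapping[node]
        for child in node.child_nodes():
            mv = mapping[child]
            if mv is mu:
                continue
            # walk species path from mv up to mu; each node strictly
            # between them (plus mu itself at a duplication) dropped a
            # copy into its off-path child
            path: list[dendropy.Node] = []
            cur = mv
            while cur is not mu:
                path.append(cur)
                cur = parent[id(cur)]
            path.append(mu)  # path = [mv, ..., mu] bottom-up
            interior = path[1:-1]
            loss_sites = list(interior)
            if is_dup[node]:
                loss_sites.append(mu)
            for w in loss_sites:
                on_path_idx = path.index(w) - 1
                on_path_child = path[on_path_idx]
                for spc in w.child_nodes():
                    if spc is not on_path_child:
                        result.losses[species_node_key(spc)] += 1
                        result.total_losses += 1
    return result
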