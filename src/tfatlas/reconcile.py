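"""Gene-tree / species-tree reconciliation and the duplication-loss atlas.

Each TF-family gene tree is embedded into the rooted species tree by the
classic last-common-ancestor (LCA) mapping: every gene-tree node maps to the
LCA of the species below it.  A node is a duplication exactly when it maps
to the same species-tree node as one of its children; this embedding is the
parsimony reconciliation, minimizing the number of duplications (and, among
those, losses).

Events are localized on species-tree branches (keyed by the branch's child
node label):

* a duplication at gene node ``v`` lies on the branch above ``M(v)``;
* on a gene-tree edge ``(u, v)`` spanning ``d`` species-tree edges, the
  lineage fails to survive in ``d`` (if ``u`` is a duplication) or ``d - 1``
  (if ``u`` is a speciation) sibling subtrees; each such loss is charged to
  the sibling branch in which the copy disappeared, so that per-species copy
  number is conserved: extant copies = 1 + duplications − losses along the
  origin-to-species path.

Summing over families gives the per-branch gain/loss atlas and per-species
turnover fractions (what share of a species' TFs arose after the common
ancestor, and what share of its lineage's TFs was lost).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "SpeciesIndex",
    "ReconciliationResult",
    "lca_map",
    "reconcile",
    "branch_atlas",
    "lineage_turnover",
    "read_species_tree",
    "read_gene_tree",
    "render_atlas_text",
]

logger = logging.getLogger(__name__)


def ensure_node_labels(tree: dendropy.Tree) -> dendropy.Tree:
    """Give every node a stable label: taxon label for leaves, postorder ids
    (``n1``, ``n2``, ... with the root as ``root``) for unlabelled internals."""
    k = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node.label = node.taxon.label if node.taxon else node.label
        elif not node.label:
            k += 1
            node.label = "root" if node.parent_node is None else f"n{k}"
    return tree


def read_species_tree(path) -> dendropy.Tree:
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    return ensure_node_labels(tree)


def read_gene_tree(path, taxon_namespace=None) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick",
                             taxon_namespace=taxon_namespace)


class SpeciesIndex:
    """Constant-time parent/depth lookups over a rooted binary species tree."""

    def __init__(self, species_tree: dendropy.Tree):
        ensure_node_labels(species_tree)
        self.tree = species_tree
        self.parent: dict = {}
        self.depth: dict = {}
        self.by_label: dict = {}
        self.leaf_by_species: dict = {}
        for node in species_tree.preorder_node_iter():
            children = node.child_nodes()
            if children and len(children) != 2:
                raise ValueError(
                    f"species tree must be binary; node {node.label!r} has "
                    f"{len(children)} children"
                )
            p = node.parent_node
            self.parent[node] = p
            self.depth[node] = 0 if p is None else self.depth[p] + 1
            self.by_label[node.label] = node
            if node.is_leaf():
                self.leaf_by_species[node.taxon.label] = node
        self.root = species_tree.seed_node

    def lca(self, a, b):
        while self.depth[a] > self.depth[b]:
            a = self.parent[a]
        while self.depth[b] > self.depth[a]:
            b = self.parent[b]
        while a is not b:
            a, b = self.parent[a], self.parent[b]
        return a

    def sibling(self, node):
        p = self.parent[node]
        c1, c2 = p.child_nodes()
        return c2 if c1 is node else c1

    def path_labels_to_root(self, species: str) -> list[str]:
        """Branch labels (child-end node labels) from a species leaf up to and
        including the root label (used for pre-divergence duplications)."""
        node = self.leaf_by_species[species]
        labels = []
        while node is not None:
            labels.append(node.label)
            node = self.parent[node]
        return labels


def _leaf_species(leaf, sep: str) -> str:
    label = leaf.taxon.label if leaf.taxon else leaf.label
    if sep not in label:
        raise ValueError(
            f"gene-tree leaf {label!r} lacks the {sep!r} species separator"
        )
    return label.rsplit(sep, 1)[1]


def lca_map(
    gene_tree: dendropy.Tree,
    species_tree: dendropy.Tree | SpeciesIndex,
    sep: str = "@",
) -> dict:
    """LCA mapping: each gene-tree node to the species-tree LCA of its leaves.

    Computed bottom-up; a leaf maps to the species-tree leaf named after the
    part of its label following ``sep``.  Unknown species names raise with
    the offending leaf label.
    """
    idx = species_tree if isinstance(species_tree, SpeciesIndex) else SpeciesIndex(species_tree)
    mapping: dict = {}
    for node in gene_tree.postorder_node_iter():
        if node.is_leaf():
            sp = _leaf_species(node, sep)
            if sp not in idx.leaf_by_species:
                raise ValueError(
                    f"gene-tree leaf {node.taxon.label!r}: species {sp!r} "
                    "not in the species tree"
                )
            mapping[node] = idx.leaf_by_species[sp]
        else:
            children = node.child_nodes()
            m = mapping[children[0]]
            for c in children[1:]:
                m = idx.lca(m, mapping[c])
            mapping[node] = m
    return mapping


@dataclass
class ReconciliationResult:
    """Events from reconciling one gene family against the species tree."""

    family: str
    origin: str  #: species-tree node label the gene-tree root maps to
    duplications: Counter = field(default_factory=Counter)  #: branch -> count
    losses: Counter = field(default_factory=Counter)  #: branch -> count
    node_events: dict = field(default_factory=dict)  #: gene node -> event
    #: per extant copy: (gene label, species, arose strictly below the root)
    leaves: list = field(default_factory=list)

    @property
    def n_duplications(self) -> int:
        return sum(self.duplications.values())

    @property
    def n_losses(self) -> int:
        return sum(self.losses.values())


def reconcile(
    gene_tree: dendropy.Tree,
    species_tree: dendropy.Tree | SpeciesIndex,
    sep: str = "@",
    family: str = "fam",
    resolve_polytomies_seed: int | None = None,
) -> ReconciliationResult:
    """Duplication-loss reconciliation of a gene tree with the species tree.

    Returns per-branch duplication and loss counts (see module docstring for
    the branch-assignment conventions), the family origin branch, and per
    extant copy whether it arose strictly below the species root.  The
    duplication total is the minimum over all valid reconciliations (a
    property of the LCA mapping, checked against a brute-force oracle in the
    test suite).

    Non-binary gene trees raise unless ``resolve_polytomies_seed`` is given,
    in which case polytomies are resolved randomly (and this is logged).
    """
    idx = species_tree if isinstance(species_tree, SpeciesIndex) else SpeciesIndex(species_tree)
    if any(len(n.child_nodes()) > 2 for n in gene_tree.preorder_node_iter()):
        if resolve_polytomies_seed is None:
            raise ValueError(
                "gene tree contains polytomies; pass resolve_polytomies_seed "
                "to resolve them randomly"
            )
        import random as _random

        logger.warning("resolving gene-tree polytomies randomly (seed=%d)",
                       resolve_polytomies_seed)
        gene_tree.resolve_polytomies(rng=_random.Random(resolve_polytomies_seed))

    M = lca_map(gene_tree, idx, sep=sep)
    res = ReconciliationResult(family=family, origin=M[gene_tree.seed_node].label)

    # event labels, bottom-up
    for v in gene_tree.postorder_node_iter():
        if v.is_leaf():
            res.node_events[v] = "leaf"
        else:
            dup = any(M[v] is M[c] for c in v.child_nodes())
            res.node_events[v] = "duplication" if dup else "speciation"
            if dup:
                res.duplications[M[v].label] += 1

    # losses along each gene-tree edge
    for v in gene_tree.preorder_node_iter():
        u = v.parent_node
        if u is None:
            continue
        top, bottom = M[u], M[v]
        u_is_dup = res.node_events[u] == "duplication"
        x = bottom
        while x is not top:
            p = idx.parent[x]
            if p is top and not u_is_dup:
                break  # the speciation at `top` itself explains this split
            res.losses[idx.sibling(x).label] += 1
            x = p

    # which extant copies arose after the species root: the second child of
    # every duplication below the root starts a new copy
    sp_root = idx.root
    new_flag = {gene_tree.seed_node: False}
    for v in gene_tree.preorder_node_iter():
        f = new_flag[v]
        children = v.child_nodes()
        if not children:
            continue
        if res.node_events[v] == "duplication" and M[v] is not sp_root:
            new_flag[children[0]] = f
            for c in children[1:]:
                new_flag[c] = True
        else:
            for c in children:
                new_flag[c] = f
    for leaf in gene_tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon else leaf.label
        res.leaves.append((label, _leaf_species(leaf, sep), new_flag[leaf]))
    return res


def branch_atlas(
    results: list[ReconciliationResult],
    species_tree: dendropy.Tree | SpeciesIndex,
) -> pd.DataFrame:
    """Per-branch gain/loss table summed over families.

    Rows are species-tree branches keyed by their child node label (the row
    ``root`` collects pre-divergence duplications).  ``share`` is each
    branch's fraction of all events tree-wide; ``family_share`` normalizes
    per family first and averages, since with very uneven family sizes the
    two weightings differ.
    """
    idx = species_tree if isinstance(species_tree, SpeciesIndex) else SpeciesIndex(species_tree)
    labels = [n.label for n in idx.tree.preorder_node_iter()]
    atlas = pd.DataFrame(0.0, index=pd.Index(labels, name="branch"),
                         columns=["duplications", "losses"])
    per_family_share = pd.Series(0.0, index=atlas.index)
    n_fam_with_events = 0
    for res in results:
        unknown = (set(res.duplications) | set(res.losses)) - set(labels)
        if unknown:
            raise ValueError(
                f"family {res.family!r} was reconciled against a different "
                f"species tree (unknown branches {sorted(unknown)})"
            )
        fam_total = res.n_duplications + res.n_losses
        for b, c in res.duplications.items():
            atlas.loc[b, "duplications"] += c
        for b, c in res.losses.items():
            atlas.loc[b, "losses"] += c
        if fam_total > 0:
            n_fam_with_events += 1
            for b in set(res.duplications) | set(res.losses):
                per_family_share[b] += (
                    res.duplications.get(b, 0) + res.losses.get(b, 0)
                ) / fam_total
    total = atlas.to_numpy().sum()
    atlas["share"] = (atlas["duplications"] + atlas["losses"]) / total if total else 0.0
    atlas["family_share"] = (
        per_family_share / n_fam_with_events if n_fam_with_events else 0.0
    )
    return atlas


def lineage_turnover(
    results: list[ReconciliationResult],
    species_tree: dendropy.Tree | SpeciesIndex,
    denominator: str = "lineage-total",
) -> pd.DataFrame:
    """Per-species TF turnover since the common ancestor, plus the average.

    For species X, ``gained_pct`` is the percentage of X's extant TF copies
    whose originating duplication maps strictly below the species root.
    ``lost_pct`` divides the loss events on the root-to-X path by the number
    of copies that ever existed on that lineage (one origin copy per family
    plus path duplications; ``denominator='lineage-total'``, the default) or
    simply by X's extant copies (``denominator='extant'``).  By copy-number
    conservation the lineage total equals extant + path losses, so the
    default can never exceed 100%.

    The last row, ``average``, is the cross-species mean of each column.
    Species with zero extant copies are excluded with a warning.
    """
    if denominator not in ("extant", "lineage-total"):
        raise ValueError("denominator must be 'extant' or 'lineage-total'")
    idx = species_tree if isinstance(species_tree, SpeciesIndex) else SpeciesIndex(species_tree)
    species = sorted(idx.leaf_by_species)
    paths = {sp: idx.path_labels_to_root(sp) for sp in species}
    rows = {}
    for sp in species:
        extant = gained = path_losses = path_dups = origin_copies = 0
        for res in results:
            full_path = paths[sp]
            if res.origin not in full_path:
                continue  # family never existed on this species' lineage
            cut = full_path.index(res.origin)
            path = full_path[: cut + 1]
            origin_copies += 1
            path_dups += sum(res.duplications.get(b, 0) for b in path)
            path_losses += sum(res.losses.get(b, 0) for b in path)
            for _, leaf_sp, is_new in res.leaves:
                if leaf_sp == sp:
                    extant += 1
                    gained += int(is_new)
        if extant == 0:
            logger.warning("species %s has no extant TF copies; excluded", sp)
            continue
        if denominator == "lineage-total":
            lost_den = origin_copies + path_dups
        else:
            lost_den = extant
        rows[sp] = {
            "extant": extant,
            "gained": gained,
            "lost": path_losses,
            "gained_pct": 100.0 * gained / extant,
            "lost_pct": 100.0 * path_losses / lost_den if lost_den else 0.0,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "species"
    if len(out):
        out.loc["average"] = out.mean(axis=0)
    return out


def render_atlas_text(atlas: pd.DataFrame, species_tree: dendropy.Tree) -> str:
    """Plain-text rendering of the gain/loss atlas on the species tree."""
    lines = []

    def walk(node, prefix: str) -> None:
        b = node.label
        gains = int(atlas.loc[b, "duplications"]) if b in atlas.index else 0
        losses = int(atlas.loc[b, "losses"]) if b in atlas.index else 0
        lines.append(f"{prefix}{b}  +{gains}/-{losses}")
        for child in node.child_nodes():
            walk(child, prefix + "  ")

    walk(species_tree.seed_node, "")
    return "\n".join(lines)
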