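"""Synthetic data generation for the TF-repertoire pipeline.

Every downstream stage (census, reconciliation, network classification,
cartography, expression contrasts, GO overlap) can be exercised end to end
on data produced here, with the generating truth recorded alongside so that
recovery can be checked exactly or statistically.

The generators are deterministic: the same seed yields byte-identical
artifacts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

__all__ = [
    "SimConfig",
    "GeneFamilyTruth",
    "simulate_species_tree",
    "simulate_gene_family",
    "simulate_domain_hits",
    "simulate_ppi_network",
    "simulate_expression",
    "simulate_go_annotations",
    "go_decay_for",
    "write_simulation",
]

#: DNA-binding-domain families used by default in synthetic hit tables.
DEFAULT_FAMILIES = (
    "zf-C2H2",
    "Homeodomain",
    "HLH",
    "Forkhead",
    "bZIP_1",
    "bZIP_2",
    "HMG_box",
    "GATA",
    "Zn_clus",
    "Ets",
)

DEFAULT_ORGANS = ("cerebellum", "heart", "kidney", "liver", "testis")


@dataclass
class SimConfig:
    """Parameters for the full synthetic dataset.

    Rates are events per copy per unit branch length; probabilities are in
    [0, 1].  The annotation probabilities default to the contrast observed
    between isolated and large-component TFs in curated mouse-phenotype and
    orthology data (lethality ~49% vs ~5%; absence in the comparator species
    ~4% vs ~37%), so that synthetic class summaries resemble real ones.
    """

    seed: int = 0

    # species tree / gene families
    n_species: int = 12
    dup_rate: float = 0.3
    loss_rate: float = 0.1
    n_families: int = 48

    # domain-hit tables
    families: tuple[str, ...] = DEFAULT_FAMILIES
    mean_family_size: float = 12.0
    mean_extra_isoforms: float = 0.7
    multi_domain_prob: float = 0.02
    decoy_hits_per_species: int = 40

    # interaction network
    n_genes: int = 1200
    n_tfs: int = 300
    n_modules: int = 4
    p_in: float = 0.12
    p_out: float = 0.01
    isolated_fraction: float = 0.33
    lethal_p_connected: float = 0.488
    lethal_p_isolated: float = 0.050
    absent_p_connected: float = 0.038
    absent_p_isolated: float = 0.367
    lethal_p_nontf: float = 0.25
    absent_p_nontf: float = 0.05

    # expression
    alpha: float = float(np.log(50.0))
    beta_k: tuple[float, ...] = (0.5, 1.0, -0.5, 0.25)
    theta: float = 2.0
    n_genes_per_type: int = 2000
    organs: tuple[str, ...] = DEFAULT_ORGANS

    # GO annotations
    n_terms: int = 2000
    go_size_min: int = 5
    go_size_max: int = 400
    go_decay: float = 0.15051499783199057  # q(100) = 0.5

    def __post_init__(self) -> None:
        for name in ("p_in", "p_out", "isolated_fraction", "multi_domain_prob",
                     "lethal_p_connected", "lethal_p_isolated",
                     "absent_p_connected", "absent_p_isolated",
                     "lethal_p_nontf", "absent_p_nontf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.dup_rate < 0 or self.loss_rate < 0:
            raise ValueError("duplication/loss rates must be >= 0")
        if self.theta <= 0:
            raise ValueError("NB dispersion theta must be > 0")
        if self.n_tfs > self.n_genes:
            raise ValueError("n_tfs cannot exceed n_genes")


# ---------------------------------------------------------------------------
# species tree

def simulate_species_tree(n_species: int, seed: int) -> dendropy.Tree:
    """Simulate a rooted, binary, ultrametric species tree.

    A pure-birth (Yule) tree is grown to ``n_species`` extant tips; terminal
    edges are then extended by a common constant so no tip edge has zero
    length.  Leaves are labelled ``sp01 .. spNN`` and internal nodes are
    labelled deterministically in postorder (root last, as ``root``).
    """
    if n_species < 2:
        raise ValueError(f"need at least 2 species, got {n_species}")
    import random as _random

    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_species,
        rng=_random.Random(int(seed)),
    )
    # the last birth leaves two zero-length tips; pad all terminals equally
    pad = max(e.length or 0.0 for e in tree.edges()) * 0.25 + 0.05
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + pad

    leaves = sorted(tree.leaf_node_iter(), key=lambda n: n.taxon.label)
    for i, leaf in enumerate(leaves, start=1):
        leaf.taxon.label = f"sp{i:02d}"
    k = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node.label = node.taxon.label
        elif node.parent_node is None:
            node.label = "root"
        else:
            k += 1
            node.label = f"anc{k:02d}"
    return tree


# ---------------------------------------------------------------------------
# gene families

@dataclass
class GeneFamilyTruth:
    """True event record for one simulated gene family.

    ``events`` holds one dict per duplication/loss, with the species-tree
    branch it occurred on (keyed by the branch's child node label) and the
    event time along that branch.
    """

    family: str
    events: list[dict] = field(default_factory=list)
    leaf_counts: dict[str, int] = field(default_factory=dict)
    extinct: bool = False

    @property
    def n_duplications(self) -> int:
        return sum(1 for e in self.events if e["type"] == "duplication")

    @property
    def n_losses(self) -> int:
        return sum(1 for e in self.events if e["type"] == "loss")


class _Lin:
    """Lineage node in the growing gene-copy forest."""

    __slots__ = ("children", "label")

    def __init__(self) -> None:
        self.children: list[_Lin] = []
        self.label: str | None = None


def _prune(node: _Lin) -> _Lin | None:
    """Drop extinct lineages and suppress single-child passthrough nodes."""
    if not node.children:
        return node if node.label is not None else None
    kept = [c for c in (_prune(c) for c in node.children) if c is not None]
    if not kept:
        return None
    if len(kept) == 1:
        return kept[0]
    node.children = kept
    return node


def _newick(node: _Lin) -> str:
    if not node.children:
        return node.label
    return "(" + ",".join(_newick(c) for c in node.children) + ")"


def simulate_gene_family(
    species_tree: dendropy.Tree,
    dup_rate: float,
    loss_rate: float,
    seed: int,
    family: str = "fam",
) -> tuple[dendropy.Tree | None, GeneFamilyTruth]:
    """Evolve one gene family along a species tree by birth-death.

    A single ancestral copy enters the species-tree root.  Along every
    species-tree branch each live copy duplicates at rate ``dup_rate`` and
    dies at rate ``loss_rate`` (continuous time); at speciations every copy
    is transmitted to both descendant branches.  Leaves of the returned gene
    tree are labelled ``<gene>@<species>``.

    Returns the pruned gene tree (``None`` if the family went extinct) and
    the true event record.  With ``loss_rate == 0`` the number of extant
    copies in each species equals one plus the number of duplications on its
    root-to-leaf path, and duplication-loss reconciliation recovers the true
    duplication count exactly.
    """
    if dup_rate < 0 or loss_rate < 0:
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    truth = GeneFamilyTruth(family=family)
    counter = {"gene": 0}

    def evolve_branch(copies: list[_Lin], branch_label: str, length: float) -> list[_Lin]:
        live = list(copies)
        total_rate = dup_rate + loss_rate
        t = 0.0
        while live and total_rate > 0:
            t += rng.exponential(1.0 / (len(live) * total_rate))
            if t >= length:
                break
            i = int(rng.integers(len(live)))
            if rng.random() < dup_rate / total_rate:
                parent = live[i]
                parent.children = [_Lin(), _Lin()]
                live[i : i + 1] = parent.children
                truth.events.append(
                    {"type": "duplication", "branch": branch_label, "time": round(t, 6)}
                )
            else:
                live.pop(i)
                truth.events.append(
                    {"type": "loss", "branch": branch_label, "time": round(t, 6)}
                )
        return live

    def visit(sp_node, copies: list[_Lin]) -> None:
        if sp_node.is_leaf():
            sp = sp_node.taxon.label
            truth.leaf_counts[sp] = len(copies)
            for c in copies:
                counter["gene"] += 1
                c.label = f"g{counter['gene']}@{sp}"
            return
        for child in sp_node.child_nodes():
            # speciation: each copy continues into both descendant branches
            entering = []
            for c in copies:
                sub = _Lin()
                c.children.append(sub)
                entering.append(sub)
            surviving = evolve_branch(entering, child.label, child.edge.length or 1.0)
            # mark dead-end lineages (no label, no children) for pruning
            visit(child, surviving)

    root_copy = _Lin()
    visit(species_tree.seed_node, [root_copy])
    for leaf in species_tree.leaf_node_iter():
        truth.leaf_counts.setdefault(leaf.taxon.label, 0)

    pruned = _prune(root_copy)
    if pruned is None or not pruned.children and pruned.label is None:
        truth.extinct = True
        return None, truth
    newick = _newick(pruned) + ";"
    gene_tree = dendropy.Tree.get(data=newick, schema="newick")
    return gene_tree, truth


def simulate_gene_families(
    species_tree: dendropy.Tree, cfg: SimConfig
) -> tuple[dict[str, dendropy.Tree], dict[str, GeneFamilyTruth]]:
    """Simulate ``cfg.n_families`` independent families (child seeds of cfg.seed)."""
    rng = np.random.default_rng(cfg.seed)
    seeds = rng.integers(0, 2**31 - 1, size=cfg.n_families)
    trees: dict[str, dendropy.Tree] = {}
    truths: dict[str, GeneFamilyTruth] = {}
    for i, s in enumerate(seeds, start=1):
        name = f"fam{i:03d}"
        tree, truth = simulate_gene_family(
            species_tree, cfg.dup_rate, cfg.loss_rate, int(s), family=name
        )
        truths[name] = truth
        if tree is not None:
            trees[name] = tree
    return trees, truths


# ---------------------------------------------------------------------------
# domain-hit tables

def simulate_domain_hits(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit a synthetic domain-hit table plus its true family-count matrix.

    Per species and family the number of TF genes is Poisson around the
    family mean; each gene may have extra isoforms (weaker-scoring hits for
    the same gene) and, rarely, a second DNA-binding domain from another
    family.  Decoy hits with E-values above any sensible threshold are mixed
    in so that E-value filtering is exercised.

    Returns ``(hits, true_counts)`` where ``hits`` has columns
    protein_id, gene_name, species, family, e_value, bit_score and
    ``true_counts`` is the species x family count table the census stage
    should recover after filtering and isoform deduplication.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    species = [f"sp{i:02d}" for i in range(1, cfg.n_species + 1)]
    families = list(cfg.families)
    fam_means = cfg.mean_family_size * np.exp(rng.normal(0.0, 0.6, size=len(families)))

    rows: list[tuple] = []
    counts = pd.DataFrame(0, index=species, columns=families, dtype=int)
    gid = 0
    for sp in species:
        for fi, fam in enumerate(families):
            n_genes = int(rng.poisson(fam_means[fi]))
            for _ in range(n_genes):
                gid += 1
                gene = f"{sp}_G{gid:05d}"
                fams_here = [fam]
                if rng.random() < cfg.multi_domain_prob:
                    other = families[int(rng.integers(len(families)))]
                    if other != fam:
                        fams_here.append(other)
                n_iso = 1 + int(rng.poisson(cfg.mean_extra_isoforms))
                scores = np.sort(rng.uniform(30, 300, size=n_iso))[::-1]
                for f2 in fams_here:
                    counts.loc[sp, f2] += 1
                    for iso in range(n_iso):
                        e_val = 10.0 ** rng.uniform(-30, -5)
                        rows.append(
                            (f"{gene}.iso{iso + 1}", gene, sp, f2, e_val,
                             round(float(scores[iso]), 1))
                        )
        for _ in range(cfg.decoy_hits_per_species):
            gid += 1
            gene = f"{sp}_G{gid:05d}"
            fam = families[int(rng.integers(len(families)))]
            e_val = 10.0 ** rng.uniform(-3.5, 0)
            rows.append(
                (f"{gene}.iso1", gene, sp, fam, e_val,
                 round(float(rng.uniform(5, 25)), 1))
            )
    hits = pd.DataFrame(
        rows, columns=["protein_id", "gene_name", "species", "family",
                       "e_value", "bit_score"]
    )
    return hits, counts


# ---------------------------------------------------------------------------
# interaction network

def simulate_ppi_network(
    cfg: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate a modular PPI network with a planted isolated-TF subset.

    Genes are split round-robin into ``n_modules`` blocks of a stochastic
    block model (edge probability ``p_in`` within, ``p_out`` between).  A
    subset of genes are TFs, spread evenly over modules; a planted fraction
    of the TFs is made *isolated*: all their TF-TF edges are removed and
    each is guaranteed at least one TF-to-non-TF edge, so they stay in the
    global network but outside the TF-TF subnetwork's large component.
    Lethality and comparator-species-absence flags are drawn with distinct
    probabilities for planted-isolated vs connected TFs.

    Edge scores follow the STRING convention: integers 0-1000, structural
    edges scored in [400, 999]; a sprinkling of sub-threshold noise edges
    (scores 150-399) between non-TF genes is included and should be removed
    by score filtering.

    Returns ``(edges, nodes, truth)``; truth records the planted isolated
    set and module assignment.
    """
    if cfg.n_tfs > cfg.n_genes:
        raise ValueError("n_tfs cannot exceed n_genes")
    if cfg.n_modules > cfg.n_genes:
        raise ValueError("more modules than genes")
    rng = np.random.default_rng(cfg.seed + 2)
    n = cfg.n_genes
    genes = np.array([f"g{i:04d}" for i in range(1, n + 1)])
    module = np.arange(n) % cfg.n_modules
    is_tf = np.zeros(n, dtype=bool)
    # TFs spread evenly across modules: first slots of each block
    tf_idx = np.concatenate(
        [np.arange(m, n, cfg.n_modules)[: _tfs_in_module(cfg, m)]
         for m in range(cfg.n_modules)]
    )
    is_tf[tf_idx] = True
    tf_positions = np.where(is_tf)[0]
    n_iso = int(round(cfg.isolated_fraction * len(tf_positions)))
    iso_positions = rng.choice(tf_positions, size=n_iso, replace=False)
    planted_isolated = np.zeros(n, dtype=bool)
    planted_isolated[iso_positions] = True

    edges: set[tuple[int, int]] = set()
    for m in range(cfg.n_modules):
        members = np.where(module == m)[0]
        iu, ju = np.triu_indices(len(members), k=1)
        mask = rng.random(len(iu)) < cfg.p_in
        for a, b in zip(members[iu[mask]], members[ju[mask]]):
            edges.add((int(a), int(b)))
    for ma in range(cfg.n_modules):
        for mb in range(ma + 1, cfg.n_modules):
            A = np.where(module == ma)[0]
            B = np.where(module == mb)[0]
            k = rng.binomial(len(A) * len(B), cfg.p_out)
            ai = rng.integers(0, len(A), size=k)
            bi = rng.integers(0, len(B), size=k)
            for a, b in zip(A[ai], B[bi]):
                edges.add((min(int(a), int(b)), max(int(a), int(b))))

    # enforce planted isolation: no TF-TF edge touches an isolated TF
    edges = {
        (a, b)
        for a, b in edges
        if not (is_tf[a] and is_tf[b] and (planted_isolated[a] or planted_isolated[b]))
    }
    # guarantee each isolated TF >= 1 TF-to-non-TF interaction (after edge
    # removal every remaining edge of an isolated TF goes to a non-TF)
    non_tf = np.where(~is_tf)[0]
    degree: dict[int, int] = {}
    for a, b in edges:
        degree[a] = degree.get(a, 0) + 1
        degree[b] = degree.get(b, 0) + 1
    for p in sorted(int(x) for x in iso_positions):
        if degree.get(p, 0) == 0:
            cands = non_tf[module[non_tf] == module[p]]
            q = int(cands[rng.integers(len(cands))])
            edges.add((min(p, q), max(p, q)))

    edge_arr = np.array(sorted(edges))
    scores = rng.integers(400, 1000, size=len(edge_arr))
    # sub-threshold noise between non-TF genes, dropped by score filtering
    n_noise = max(1, len(edge_arr) // 20)
    na = non_tf[rng.integers(0, len(non_tf), size=n_noise)]
    nb = non_tf[rng.integers(0, len(non_tf), size=n_noise)]
    noise_rows = [
        (genes[min(a, b)], genes[max(a, b)], int(s))
        for a, b, s in zip(na, nb, rng.integers(150, 400, size=n_noise))
        if a != b and (min(a, b), max(a, b)) not in edges
    ]
    edge_df = pd.DataFrame(
        [(genes[a], genes[b], int(s)) for (a, b), s in zip(edge_arr, scores)]
        + noise_rows,
        columns=["protein1", "protein2", "combined_score"],
    )

    lethal = np.where(
        is_tf,
        np.where(
            planted_isolated,
            rng.random(n) < cfg.lethal_p_isolated,
            rng.random(n) < cfg.lethal_p_connected,
        ),
        rng.random(n) < cfg.lethal_p_nontf,
    )
    absent = np.where(
        is_tf,
        np.where(
            planted_isolated,
            rng.random(n) < cfg.absent_p_isolated,
            rng.random(n) < cfg.absent_p_connected,
        ),
        rng.random(n) < cfg.absent_p_nontf,
    )
    nodes = pd.DataFrame(
        {
            "gene": genes,
            "is_tf": is_tf,
            "lethal": lethal,
            "absent_in_comparator": absent,
            "module": module,
        }
    )
    truth = {
        "isolated_tfs": sorted(genes[planted_isolated]),
        "connected_tfs": sorted(genes[is_tf & ~planted_isolated]),
        "module": {g: int(m) for g, m in zip(genes, module)},
    }
    return edge_df, nodes, truth


def _tfs_in_module(cfg: SimConfig, m: int) -> int:
    base, extra = divmod(cfg.n_tfs, cfg.n_modules)
    return base + (1 if m < extra else 0)


# ---------------------------------------------------------------------------
# expression

def simulate_expression(cfg: SimConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate NB-distributed expression by TF-interaction gene type.

    For each organ and species, genes of type ``k`` draw counts from a
    negative binomial with log-mean ``alpha + beta_k`` (type 1, genes
    without TF interactions, is the reference with beta = 0) and dispersion
    ``theta`` (variance mu + mu^2/theta).

    Returns a long table (gene, gene_type, organ, species, tpm) and the
    truth dict with alpha and the beta vector.
    """
    if cfg.theta <= 0:
        raise ValueError("theta must be > 0")
    if not np.all(np.isfinite(cfg.beta_k)):
        raise ValueError("beta offsets must be finite")
    rng = np.random.default_rng(cfg.seed + 3)
    types = ["no_TF_interaction", "orth_TF", "spec_TF_HM", "spec_TF_H", "spec_TF_M"]
    betas = np.concatenate([[0.0], np.asarray(cfg.beta_k, dtype=float)])
    n = cfg.n_genes_per_type
    frames = []
    gene_ids = np.array([f"e{i:05d}" for i in range(1, n * len(types) + 1)])
    gene_type = np.repeat(types, n)
    for species in ("human", "mouse"):
        for organ in cfg.organs:
            mu = np.exp(cfg.alpha + np.repeat(betas, n))
            vals = rng.negative_binomial(cfg.theta, cfg.theta / (cfg.theta + mu))
            frames.append(
                pd.DataFrame(
                    {
                        "gene": gene_ids,
                        "gene_type": gene_type,
                        "organ": organ,
                        "species": species,
                        "tpm": vals.astype(float),
                    }
                )
            )
    truth = {"alpha": cfg.alpha, "beta": dict(zip(types[1:], cfg.beta_k)),
             "theta": cfg.theta}
    return pd.concat(frames, ignore_index=True), truth


# ---------------------------------------------------------------------------
# GO annotations

def go_decay_for(q: float, size: int) -> float:
    """Decay rate such that the expected overlap proportion at ``size`` is ``q``."""
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    return -np.log(q) / np.log(size)


def simulate_go_annotations(
    cfg: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate per-term TF annotation sets for two species.

    Term set sizes are log-uniform on [go_size_min, go_size_max].  A term of
    size ``s`` shares ``m ~ Binomial(s, q(s))`` orthologous TFs between the
    species, with ``q(s) = s**(-go_decay)``; the remaining members are
    species-specific.  The expected overlap proportion |A ∩ B| / mean size
    therefore decays as a power of set size, mimicking the empirical pattern
    that small GO terms are regulated by mostly-orthologous TFs while large
    ones are not.

    Returns annotation tables for species A and B (columns term, species,
    tf) and the truth dict of per-term expected and realized proportions.
    """
    if cfg.n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    rng = np.random.default_rng(cfg.seed + 4)
    sizes = np.exp(
        rng.uniform(np.log(cfg.go_size_min), np.log(cfg.go_size_max), size=cfg.n_terms)
    ).astype(int)
    sizes = np.clip(sizes, 1, None)
    q_expected = np.minimum(1.0, sizes.astype(float) ** (-cfg.go_decay))
    rows_a, rows_b = [], []
    realized = {}
    pool = max(10 * cfg.go_size_max, 1000)
    for i, (s, q) in enumerate(zip(sizes, q_expected), start=1):
        term = f"GO:{i:07d}"
        m = int(rng.binomial(s, q))
        shared = rng.choice(pool, size=m, replace=False)
        spec_a = rng.choice(pool, size=s - m, replace=False)
        spec_b = rng.choice(pool, size=s - m, replace=False)
        for t in shared:
            rows_a.append((term, "A", f"OTF{t:05d}"))
            rows_b.append((term, "B", f"OTF{t:05d}"))
        for t in spec_a:
            rows_a.append((term, "A", f"ATF{t:05d}"))
        for t in spec_b:
            rows_b.append((term, "B", f"BTF{t:05d}"))
        realized[term] = {"size": int(s), "q_expected": float(q), "q_realized": m / s}
    cols = ["term", "species", "tf"]
    return (
        pd.DataFrame(rows_a, columns=cols),
        pd.DataFrame(rows_b, columns=cols),
        {"decay": cfg.go_decay, "terms": realized},
    )


# ---------------------------------------------------------------------------
# batch writer

def write_simulation(cfg: SimConfig, outdir: str | Path) -> Path:
    """Generate the full dataset and write it as plain-text files.

    Produces Newick trees (species + per-family gene trees), a domain-hit
    TSV, STRING-dialect edge list, node annotations, expression and GO
    tables, and a ``ground_truth.json`` sidecar.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sp_tree = simulate_species_tree(cfg.n_species, cfg.seed)
    (out / "species.nwk").write_text(
        sp_tree.as_string(schema="newick", suppress_rooting=True)
    )
    gene_trees, truths = simulate_gene_families(sp_tree, cfg)
    gt_dir = out / "genetrees"
    gt_dir.mkdir(exist_ok=True)
    for name, tree in gene_trees.items():
        (gt_dir / f"{name}.nwk").write_text(
            tree.as_string(schema="newick", suppress_rooting=True)
        )
    hits, true_counts = simulate_domain_hits(cfg)
    hits.to_csv(out / "hits.tsv", sep="\t", index=False)
    true_counts.to_csv(out / "true_family_counts.tsv", sep="\t")
    edges, nodes, net_truth = simulate_ppi_network(cfg)
    edges.to_csv(out / "edges.tsv", sep="\t", index=False)
    nodes.to_csv(out / "nodes.tsv", sep="\t", index=False)
    expr, expr_truth = simulate_expression(cfg)
    expr.to_csv(out / "expression.tsv", sep="\t", index=False)
    go_a, go_b, go_truth = simulate_go_annotations(cfg)
    go_a.to_csv(out / "go_speciesA.tsv", sep="\t", index=False)
    go_b.to_csv(out / "go_speciesB.tsv", sep="\t", index=False)
    truth = {
        "config": dataclasses.asdict(cfg),
        "families": {
            name: {
                "events": t.events,
                "leaf_counts": t.leaf_counts,
                "extinct": t.extinct,
            }
            for name, t in truths.items()
        },
        "network": net_truth,
        "expression": expr_truth,
        "go": go_truth,
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1, default=str))
    return out
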