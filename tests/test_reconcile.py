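"""LCA mapping, duplication-loss events, atlas and turnover."""

from collections import Counter

import dendropy
import pytest

from conftest import tree_from_newick
from tfatlas import reconcile as R
from tfatlas import simulate as S


@pytest.fixture()
def abc_tree():
    return R.ensure_node_labels(tree_from_newick("((A,B),C);"))


class TestLcaMap:
    def test_two_leaf_root(self):
        sp = R.ensure_node_labels(tree_from_newick("(A,B);"))
        gt = tree_from_newick("(a1@A,b1@B);")
        M = R.lca_map(gt, sp)
        assert M[gt.seed_node] is sp.seed_node

    def test_inner_node_maps_to_leaf(self, abc_tree):
        gt = tree_from_newick("((a1@A,a2@A),b1@B);")
        M = R.lca_map(gt, abc_tree)
        inner = gt.seed_node.child_nodes()[0]
        assert M[inner].taxon.label == "A"
        ab = abc_tree.seed_node.child_nodes()[0]
        assert M[gt.seed_node] is ab

    def test_unknown_species_names_the_leaf(self, abc_tree):
        gt = tree_from_newick("(a1@A,x1@X);")
        with pytest.raises(ValueError, match="x1@X"):
            R.lca_map(gt, abc_tree)

    def test_missing_separator_rejected(self, abc_tree):
        gt = tree_from_newick("(a1A,b1@B);")
        with pytest.raises(ValueError, match="separator"):
            R.lca_map(gt, abc_tree)

    @pytest.mark.parametrize("seed", range(20))
    def test_congruent_trees_map_isomorphically(self, seed):
        """On a congruent gene tree, M is the natural isomorphism; checked
        against an independent recursive oracle over the leaf-set pairing."""
        sp = S.simulate_species_tree(7, seed=seed)
        gt, _ = S.simulate_gene_family(sp, 0.0, 0.0, seed=seed)
        M = R.lca_map(gt, sp)

        def oracle(gnode, snode):
            gleaves = {l.taxon.label.split("@")[1] for l in gnode.leaf_iter()}
            sleaves = {l.taxon.label for l in snode.leaf_iter()}
            assert gleaves == sleaves
            assert M[gnode] is snode
            if not gnode.is_leaf():
                gkids = gnode.child_nodes()
                skids = snode.child_nodes()
                key = lambda n, f: min(f(l) for l in n.leaf_iter())
                gkids = sorted(gkids, key=lambda n: key(n, lambda l: l.taxon.label.split("@")[1]))
                skids = sorted(skids, key=lambda n: key(n, lambda l: l.taxon.label))
                for g, s in zip(gkids, skids):
                    oracle(g, s)

        oracle(gt.seed_node, sp.seed_node)

    def test_ancestry_respected(self, species_tree8):
        gt, _ = S.simulate_gene_family(species_tree8, 0.4, 0.2, seed=13)
        idx = R.SpeciesIndex(species_tree8)
        M = R.lca_map(gt, idx)
        for v in gt.preorder_node_iter():
            for c in v.child_nodes():
                # M(v) is an ancestor-or-equal of M(c)
                x = M[c]
                while x is not None and x is not M[v]:
                    x = idx.parent[x]
                assert x is M[v]


class TestReconcile:
    def test_congruent_tree_no_events(self, species_tree8):
        gt, _ = S.simulate_gene_family(species_tree8, 0.0, 0.0, seed=2)
        res = R.reconcile(gt, species_tree8)
        assert res.n_duplications == 0 and res.n_losses == 0
        assert res.origin == "root"

    def test_four_leaf_duplication_with_loss(self, abc_tree):
        gt = tree_from_newick("((a1@A,(a2@A,b1@B)),c1@C);")
        res = R.reconcile(gt, abc_tree)
        assert res.n_duplications == 1
        assert res.n_losses == 1
        # the duplication sits on the branch above the A+B ancestor and the
        # loss on the B branch (a1's sister lineage died out in B)
        ab_label = abc_tree.seed_node.child_nodes()[0].label
        assert res.duplications == Counter({ab_label: 1})
        assert res.losses == Counter({"B": 1})

    def test_simulated_duplications_recovered_exactly_without_loss(self, species_tree8):
        for seed in range(30):
            gt, truth = S.simulate_gene_family(species_tree8, 0.35, 0.0, seed=seed)
            res = R.reconcile(gt, species_tree8)
            assert res.n_losses == 0
            true_by_branch = Counter(e["branch"] for e in truth.events)
            assert +res.duplications == true_by_branch

    def test_polytomy_rejected_without_seed(self, abc_tree):
        gt = tree_from_newick("(a1@A,b1@B,c1@C);")
        with pytest.raises(ValueError, match="polytom"):
            R.reconcile(gt, abc_tree)
        res = R.reconcile(gt, abc_tree, resolve_polytomies_seed=1)
        assert set(res.node_events.values()) <= {"leaf", "speciation", "duplication"}

    def test_copy_number_conservation_under_loss(self, species_tree8):
        """Reconstructed events explain every species' extant copy number."""
        idx = R.SpeciesIndex(species_tree8)
        checked = 0
        for seed in range(40):
            gt, _ = S.simulate_gene_family(species_tree8, 0.3, 0.15, seed=seed)
            if gt is None:
                continue
            res = R.reconcile(gt, idx)
            for sp in idx.leaf_by_species:
                full = idx.path_labels_to_root(sp)
                if res.origin not in full:
                    expected = 0
                else:
                    path = full[: full.index(res.origin) + 1]
                    expected = (1
                                + sum(res.duplications.get(b, 0) for b in path)
                                - sum(res.losses.get(b, 0) for b in path))
                extant = sum(1 for _, s, _ in res.leaves if s == sp)
                assert extant == expected
            checked += 1
        assert checked >= 20


class TestBranchAtlas:
    def test_single_event_single_cell(self, abc_tree):
        gt = tree_from_newick("(((a1@A,a2@A),b1@B),c1@C);")
        res = R.reconcile(gt, abc_tree)
        atlas = R.branch_atlas([res], abc_tree)
        nonzero = atlas[(atlas.duplications + atlas.losses) > 0]
        assert list(nonzero.index) == ["A"]
        assert nonzero.duplications.iloc[0] == 1
        assert atlas.losses.sum() == 0

    def test_empty_result_list_all_zero(self, abc_tree):
        atlas = R.branch_atlas([], abc_tree)
        assert (atlas[["duplications", "losses"]] == 0).all().all()

    def test_additivity(self, species_tree8):
        gts = [S.simulate_gene_family(species_tree8, 0.3, 0.1, seed=s)[0]
               for s in (1, 2)]
        results = [R.reconcile(g, species_tree8) for g in gts if g is not None]
        combined = R.branch_atlas(results, species_tree8)
        parts = [R.branch_atlas([r], species_tree8) for r in results]
        total = sum(p[["duplications", "losses"]] for p in parts)
        assert combined[["duplications", "losses"]].equals(total)

    def test_mismatched_species_tree_rejected(self, species_tree8, abc_tree):
        gt = tree_from_newick("((a1@A,a2@A),c1@C);")
        res = R.reconcile(gt, abc_tree)
        with pytest.raises(ValueError, match="different"):
            R.branch_atlas([res], species_tree8)


class TestLineageTurnover:
    def test_no_events_all_zero(self, species_tree8):
        gt, _ = S.simulate_gene_family(species_tree8, 0.0, 0.0, seed=1)
        res = R.reconcile(gt, species_tree8)
        out = R.lineage_turnover([res], species_tree8)
        assert (out.gained_pct == 0).all()
        assert (out.lost_pct == 0).all()

    def test_terminal_duplication_gained_half(self, abc_tree):
        gt = tree_from_newick("(((a1@A,a2@A),b1@B),c1@C);")
        res = R.reconcile(gt, abc_tree)
        out = R.lineage_turnover([res], abc_tree)
        assert out.loc["A", "extant"] == 2
        assert out.loc["A", "gained_pct"] == pytest.approx(50.0)
        assert out.loc["B", "gained_pct"] == 0.0

    def test_denominator_variants(self, species_tree8):
        trees = []
        for s in range(10):
            gt, _ = S.simulate_gene_family(species_tree8, 0.3, 0.15, seed=s)
            if gt is not None:
                trees.append(R.reconcile(gt, species_tree8))
        a = R.lineage_turnover(trees, species_tree8, denominator="lineage-total")
        b = R.lineage_turnover(trees, species_tree8, denominator="extant")
        assert (a.lost_pct.drop("average") <= 100.0).all()
        assert (a.gained + a.extant > 0).all()
        with pytest.raises(ValueError):
            R.lineage_turnover(trees, species_tree8, denominator="bogus")

    def test_simulated_turnover_matches_truth_without_loss(self, species_tree8):
        """With loss_rate 0, gained fractions agree exactly with the
        generator's event record."""
        idx = R.SpeciesIndex(species_tree8)
        results, truths = [], []
        for s in range(15):
            gt, truth = S.simulate_gene_family(species_tree8, 0.4, 0.0, seed=s)
            results.append(R.reconcile(gt, idx))
            truths.append(truth)
        out = R.lineage_turnover(results, idx)
        for sp in idx.leaf_by_species:
            extant = sum(t.leaf_counts[sp] for t in truths)
            path = set(idx.path_labels_to_root(sp))
            gained = sum(1 for t in truths for e in t.events
                         if e["type"] == "duplication" and e["branch"] in path)
            assert out.loc[sp, "extant"] == extant
            assert out.loc[sp, "gained_pct"] == pytest.approx(100 * gained / extant)
            assert out.loc[sp, "lost_pct"] == 0.0


def test_render_atlas_text_mentions_every_branch(species_tree8):
    gt, _ = S.simulate_gene_family(species_tree8, 0.3, 0.1, seed=3)
    res = R.reconcile(gt, species_tree8)
    atlas = R.branch_atlas([res], species_tree8)
    text = R.render_atlas_text(atlas, species_tree8)
    for label in atlas.index:
        assert label in text
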