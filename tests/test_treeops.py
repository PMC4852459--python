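"""Distances, neighbor joining, clade reduction, links, incongruence."""

import math

import dendropy
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nlrevo.famsim import SimConfig, simulate_family
from nlrevo.treeops import (
    DistanceMatrix,
    SpeciesMap,
    distance_matrix,
    nearest_paralogue_links,
    nj_tree,
    p_distance,
    poisson_distance,
    read_newick,
    recursive_reduce,
    same_species_clades,
    tree_incongruence,
    write_newick,
)

proteins = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=60)


def bipartitions(tree):
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    ref, full = labels[0], frozenset(labels)
    out = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = full - side
        if 2 <= len(side) <= len(full) - 2:
            out.add(side)
    return out


class TestPoissonDistance:
    def test_identical(self):
        assert poisson_distance("MKV", "MKV") == 0

    def test_closed_form(self):
        a = "A" * 100
        b = "C" * 10 + "A" * 90
        assert poisson_distance(a, b) == pytest.approx(-math.log(0.9))

    def test_saturated_invalid(self):
        assert math.isnan(poisson_distance("AAA", "CCC"))

    def test_no_comparable_sites(self):
        with pytest.raises(ValueError):
            poisson_distance("--", "AA")

    @given(a=proteins, b=proteins)
    def test_poisson_at_least_p(self, a, b):
        n = min(len(a), len(b))
        a, b = a[:n], b[:n]
        d = poisson_distance(a, b)
        if not math.isnan(d):
            assert d >= p_distance(a, b) - 1e-12


class TestDistanceMatrix:
    def test_consistent_with_pairwise(self):
        seqs = {"a": "MKVA", "b": "MKVA", "c": "MKIL"}
        dm = distance_matrix(seqs)
        assert dm.values[0, 1] == 0
        assert dm.values[0, 2] == pytest.approx(poisson_distance("MKVA", "MKIL"))
        assert (dm.values == dm.values.T).all()

    def test_simulated_within_less_than_between(self, small_dataset):
        dm = distance_matrix(small_dataset.proteins())
        gm = small_dataset.group_map
        within, between = [], []
        for i in range(len(dm.ids)):
            for j in range(i + 1, len(dm.ids)):
                (within if gm[dm.ids[i]] == gm[dm.ids[j]] else between).append(
                    dm.values[i, j]
                )
        assert np.mean(within) < np.mean(between)


class TestNeighborJoining:
    def test_star_matrix_resolves_without_crash(self):
        ids = list("ABCD")
        m = np.ones((4, 4)) - np.eye(4)
        t = nj_tree(DistanceMatrix(ids=ids, values=m))
        assert sorted(lf.taxon.label for lf in t.leaf_node_iter()) == ids

    def test_input_order_invariance(self):
        ids = list("ABCD")
        m = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        t1 = nj_tree(DistanceMatrix(ids=ids, values=m))
        perm = [2, 0, 3, 1]
        t2 = nj_tree(
            DistanceMatrix(
                ids=[ids[i] for i in perm], values=m[np.ix_(perm, perm)]
            )
        )
        assert bipartitions(t1) == bipartitions(t2)

    def test_matches_dendropy_nj_topology(self):
        rng = np.random.default_rng(8)
        # random additive tree -> distances -> both NJ implementations
        tree = dendropy.simulate.treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, num_extant_tips=8,
            rng=__import__("random").Random(5),
        )
        for e in tree.preorder_edge_iter():
            if e.length is not None:
                e.length = float(rng.uniform(0.05, 1.0))
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        pdm = tree.phylogenetic_distance_matrix()
        tx = {t.label: t for t in tree.taxon_namespace}
        n = len(labels)
        m = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                m[i, j] = m[j, i] = pdm.patristic_distance(
                    tx[labels[i]], tx[labels[j]]
                )
        mine = nj_tree(DistanceMatrix(ids=labels, values=m))
        theirs = pdm.nj_tree()
        assert bipartitions(mine) == bipartitions(theirs)

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(ids=["a", "b"], values=np.zeros((2, 2))))


class TestSameSpeciesClades:
    SM = SpeciesMap(
        species={"z1": "zf", "z2": "zf", "z3": "zf", "c1": "carp", "c2": "carp"}
    )

    def test_nested_paralogues_collapse_to_maximal(self):
        t = read_newick("(((z1,z2),z3),c1);")
        assert same_species_clades(t, self.SM) == [frozenset({"z1", "z2", "z3"})]

    def test_no_single_species_cherry(self):
        t = read_newick("((z1,c1),(z2,c2));")
        assert same_species_clades(t, self.SM) == []

    def test_all_one_species(self):
        t = read_newick("((z1,z2),z3);")
        sm = SpeciesMap(species={"z1": "zf", "z2": "zf", "z3": "zf"})
        assert same_species_clades(t, sm) == [frozenset({"z1", "z2", "z3"})]

    def test_missing_leaf_raises(self):
        t = read_newick("((z1,z2),(c1,x9));")
        with pytest.raises(KeyError):
            same_species_clades(t, self.SM)


@pytest.fixture(scope="module")
def two_species_family():
    # 8 conversion-isolated groups = 4 major groups x {zebrafish, carp}
    cfg = SimConfig(
        n_groups=8,
        genes_per_group=3,
        codons_per_domain={"nacht": 60},
        generations=250,
        omega_profile={"nacht": (0.0, 0.5, 1.0)},
        conversion_policy={"nacht": "within_group"},
        conversion_rate=2.0,
        embedded_motifs={},
        chrom_lengths={"c1": 200_000},
        seed=21,
    )
    ds = simulate_family(cfg)
    species, groups = {}, {}
    for gid, lab in ds.group_map.items():
        k = int(lab[1:]) - 1
        species[gid] = "zebrafish" if k % 2 == 0 else "carp"
        groups[gid] = f"major{k // 2 + 1}"
    # drop one gene from each carp group (asymmetric sampling)
    drop = {f"g{k + 1}_003" for k in range(8) if k % 2 == 1}
    seqs = {g: p for g, p in ds.proteins().items() if g not in drop}
    return seqs, SpeciesMap(species=species, groups=groups)


class TestRecursiveReduce:
    def test_fixpoint_when_no_clades(self):
        seqs = {"z1": "MKVA", "c1": "MKIL", "z2": "MAAA", "c2": "MAIA"}
        sm = SpeciesMap(
            species={"z1": "zf", "c1": "carp", "z2": "zf", "c2": "carp"}
        )
        # species interleave: no single-species bipartition side exists
        kept, log = recursive_reduce(
            seqs, sm, builder=lambda s: read_newick("((z1,c1),(z2,c2));")
        )
        assert kept == ["c1", "c2", "z1", "z2"]
        assert log == []

    def test_hand_traced_example(self):
        sm = SpeciesMap(
            species={"z1": "zf", "z2": "zf", "z3": "zf", "c1": "carp"}
        )
        seqs = {"z1": "MKVA", "z2": "MKVL", "z3": "MKIL", "c1": "MAAA"}
        kept, log = recursive_reduce(
            seqs, sm, builder=lambda s: read_newick("(((z1,z2),z3),c1);")
        )
        assert kept == ["c1", "z1"]
        assert {(r, rep) for _, r, rep in log} == {("z2", "z1"), ("z3", "z1")}

    def test_simulated_family_reduces_to_anchors(self, two_species_family):
        seqs, sm = two_species_family
        kept, log = recursive_reduce(seqs, sm)
        combos = {(sm.species_of(g), sm.group_of(g)) for g in kept}
        # exactly one representative per (species, major group)
        assert len(kept) == len(combos) == 8
        input_combos = {(sm.species_of(g), sm.group_of(g)) for g in seqs}
        assert combos == input_combos

    def test_reduction_is_idempotent(self, two_species_family):
        seqs, sm = two_species_family
        kept, _ = recursive_reduce(seqs, sm)
        again, log2 = recursive_reduce({g: seqs[g] for g in kept}, sm)
        assert again == kept
        assert log2 == []


class TestNearestLinks:
    @staticmethod
    def _loci(assignments):
        from nlrevo.genomelayout import GeneRecord

        return [
            GeneRecord(id=g, species="zf", group="", chrom=c, start=0, end=10)
            for g, c in assignments.items()
        ]

    def test_two_genes_mutual(self):
        dm = DistanceMatrix(ids=["a", "b"], values=np.array([[0, 1.0], [1.0, 0]]))
        links = nearest_paralogue_links(dm, self._loci({"a": "c1", "b": "c1"}))
        assert [(l.gene, l.nearest) for l in links] == [("a", "b"), ("b", "a")]
        assert all(l.same_chromosome for l in links)

    def test_tie_broken_lexicographically(self):
        m = np.array([[0, 1, 5], [1, 0, 5], [5, 5, 0]], float)
        dm = DistanceMatrix(ids=["A", "B", "C"], values=m)
        links = nearest_paralogue_links(
            dm, self._loci({"A": "c1", "B": "c2", "C": "c3"})
        )
        by_gene = {l.gene: l for l in links}
        assert by_gene["C"].nearest == "A"  # tie A/B -> lexicographic

    def test_most_links_stay_on_chromosome(self, default_dataset):
        dm = distance_matrix(default_dataset.proteins())
        links = nearest_paralogue_links(dm, default_dataset.loci)
        frac = np.mean([l.same_chromosome for l in links])
        assert frac >= 0.8


class TestTreeIncongruence:
    def test_identical_trees(self):
        a = read_newick("((A,B),(C,D));")
        b = read_newick("((A,B),(C,D));")
        shared, rf, pairing = tree_incongruence(a, b)
        assert rf == 0 and shared == ["A", "B", "C", "D"]

    def test_alternative_quartet(self):
        a = read_newick("((A,B),(C,D));")
        b = read_newick("((A,C),(B,D));")
        assert tree_incongruence(a, b)[1] == 2

    def test_requires_shared_leaves(self):
        a = read_newick("((A,B),(C,D));")
        b = read_newick("((A,B),(X,Y));")
        with pytest.raises(ValueError):
            tree_incongruence(a, b)

    def test_domain_trees_disagree_under_crossgroup_conversion(
        self, default_dataset
    ):
        from nlrevo.codondiv import CodonAlignment, domain_slice

        ds = default_dataset
        ids = ds.gene_ids
        aln = CodonAlignment(
            ids=ids, rows=[ds.sequences[g] for g in ids], partitions=ds.partitions
        )

        def domain_tree(dom):
            sub = domain_slice(aln, dom)
            prots = {
                g: row for g, row in zip(sub.ids, sub.rows)
            }
            from nlrevo._codons import translate_cds

            return nj_tree(
                distance_matrix({g: translate_cds(r) for g, r in prots.items()})
            )

        t_nacht = domain_tree("nacht")
        t_b302 = domain_tree("b30.2")
        # NACHT tree keeps the groups monophyletic...
        clades = same_species_clades(
            t_nacht, SpeciesMap(species=ds.group_map)
        )
        group_sets = {}
        for g, lab in ds.group_map.items():
            group_sets.setdefault(lab, set()).add(g)
        assert {frozenset(s) for s in group_sets.values()} <= set(clades)
        # ...while the cross-group-converted domain tells a different story
        _, rf, _ = tree_incongruence(t_nacht, t_b302)
        assert rf > 0

    def test_newick_roundtrip(self, tmp_path):
        t = read_newick("((A:1,B:2):0.5,(C:1,D:1):0.5);")
        path = tmp_path / "t.nwk"
        write_newick(t, path)
        again = read_newick(path)
        assert bipartitions(t) == bipartitions(again)
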